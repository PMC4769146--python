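"""Derive stand structure and canopy fuel summaries from a diameter distribution.

Builds a reverse-J black spruce patch (many small stems, few large ones),
computes per-class allometric attributes, and prints the patch-level
structure variables that drive fire behaviour.
"""

import numpy as np

from firesev import (
    DiameterClassScheme,
    PatchStructure,
    Species,
    class_attributes,
    patch_summary,
    structure_label,
)

scheme = DiameterClassScheme()
counts = np.array([900, 640, 450, 320, 230, 160, 115, 80, 60, 40, 30, 20, 15, 10, 6])
patch = PatchStructure(species=Species.BLACK_SPRUCE, counts=counts, region="C3")

attrs = class_attributes(scheme, patch)
summary = patch_summary(patch, attrs)

print(f"stems/ha          {summary.total_density}")
print(f"basal area        {summary.basal_area:.1f} m2/ha")
print(f"canopy base (CBH) {summary.cbh:.2f} m   # mean height to live crown")
print(f"canopy length     {summary.cl:.2f} m")
print(f"canopy fuel load  {summary.cfl:.0f} kg/ha")
print(f"bulk density CBD  {summary.cbd:.3f} kg/m3  # load over depth")
print(f"SWDI              {summary.swdi:.2f} -> {structure_label(summary.swdi)}-sized")
print(f"% stems in 10 cm class {summary.pct_class10:.1f}")
# A low canopy base and CBD above ~0.11 kg/m3 make this patch prone to
# crown-fire initiation at moderate surface intensities.
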