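"""Follow one fire through the crown-fire chain on a single patch.

For a surface fire of given intensity: build the vertical fuel profile,
find the available canopy bulk density, test the two crowning conditions,
update the intensity if the fire crowns, and compute the scorch height
and the resulting expected severity.
"""

import numpy as np

from firesev import (
    DiameterClassScheme,
    PatchStructure,
    Species,
    available_cbd,
    class_attributes,
    critical_crown_base_height,
    expected_severity,
    patch_summary,
    resolve_fire,
    vertical_fuel_profile,
)

scheme = DiameterClassScheme()
counts = np.array([1400, 1000, 700, 500, 360, 250, 180, 125, 90, 60, 45, 30, 22, 15, 9])
patch = PatchStructure(species=Species.BLACK_SPRUCE, counts=counts)
attrs = class_attributes(scheme, patch)
summary = patch_summary(patch, attrs)
profile = vertical_fuel_profile(patch, attrs)
avail = available_cbd(profile, window=3.0, threshold=0.11)

print(f"available CBD {avail.value:.3f} kg/m3, combustible stratum top "
      f"{avail.layer_top_height:.0f} m, patch CBH {summary.cbh:.2f} m")
for intensity in (100.0, 500.0, 2000.0):
    outcome = resolve_fire(intensity, summary, avail, attrs)
    print(f"I_i={intensity:6.0f} kW/m  critical CBH={critical_crown_base_height(intensity):5.2f} m  "
          f"crowned={outcome.crowned!s:5}  I_used={outcome.intensity_used:8.0f} kW/m  "
          f"scorch={outcome.scorch_height:5.1f} m  "
          f"E[severity]={expected_severity(patch, attrs, outcome):5.1f} %")
# The 2000 kW/m fire reaches the canopy base, crowns, and its intensity is
# updated to the Byram intensity of a flame topping the combustible stratum;
# expected severity approaches complete basal-area loss.
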