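"""Vertical canopy fuel profile and "available" canopy bulk density.

Each class's crown fuel mass is spread uniformly over the 1-m layers its
crown spans (cylindrical crown approximation), summed over classes and
divided by the layer volume (patch area x 1 m).  The "available" CBD used
in the crowning decision is the peak running mean of this profile, which
locates the densest canopy stratum rather than averaging over the whole
canopy depth as the load-over-depth CBD does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .stand import PATCH_AREA_M2, ClassAttributes, PatchStructure

__all__ = ["FuelProfile", "AvailableCBD", "vertical_fuel_profile", "available_cbd"]


@dataclass(frozen=True)
class FuelProfile:
    """Canopy fuel density in 1-m vertical layers from the ground.

    layer_density[k] is the fuel density (kg/m3) of the layer spanning
    [k, k+1) m; total mass is sum(layer_density) * patch area * 1 m.
    """

    layer_density: np.ndarray
    layer_depth: float = 1.0

    def __post_init__(self) -> None:
        dens = np.asarray(self.layer_density, dtype=float)
        if dens.ndim != 1 or dens.size == 0:
            raise ValueError("layer_density must be a non-empty 1-D array")
        if np.any(dens < 0):
            raise ValueError("layer densities must be non-negative")
        object.__setattr__(self, "layer_density", dens)

    @property
    def total_load(self) -> float:
        """Total canopy fuel load implied by the profile, kg/ha."""
        return float(self.layer_density.sum() * PATCH_AREA_M2 * self.layer_depth)

    @property
    def occupied_span(self) -> tuple[int, int]:
        """(first, last+1) indices of the non-zero layers."""
        nz = np.nonzero(self.layer_density)[0]
        if nz.size == 0:
            return (0, 0)
        return (int(nz[0]), int(nz[-1]) + 1)


class AvailableCBD(NamedTuple):
    """Peak running-mean canopy density and combustible-stratum top height."""

    value: float  # kg/m3
    layer_top_height: float  # m; 0 if no stratum reaches the threshold


def vertical_fuel_profile(
    patch: PatchStructure, attrs: Sequence[ClassAttributes]
) -> FuelProfile:
    """Build the 1-m layered canopy fuel profile of a patch.

    Each class's fuel mass FM_i (kg/ha) is allocated uniformly over
    [crown_base_i, height_i]; layer density is the summed allocation
    divided by the layer volume (10 000 m2 x 1 m), so the profile
    conserves canopy fuel load exactly.
    """
    if patch.total_density <= 0:
        raise ValueError("patch has no stems")
    top = max(a.height for a in attrs if a.count > 0)
    n_layers = max(1, math.ceil(top))
    mass = np.zeros(n_layers)
    for a in attrs:
        if a.count == 0 or a.fuel_mass == 0.0:
            continue
        lo, hi = a.crown_base, a.height
        span = hi - lo
        if span <= 0:  # degenerate crown; put all mass in the top layer
            mass[min(n_layers - 1, int(hi))] += a.fuel_mass
            continue
        for k in range(int(math.floor(lo)), min(n_layers, math.ceil(hi))):
            overlap = min(k + 1.0, hi) - max(float(k), lo)
            if overlap > 0:
                mass[k] += a.fuel_mass * overlap / span
    return FuelProfile(layer_density=mass / (PATCH_AREA_M2 * 1.0))


def available_cbd(
    profile: FuelProfile, window: float = 3.0, threshold: float = 0.11
) -> AvailableCBD:
    """Peak running-mean canopy bulk density and combustible stratum top.

    The running mean is taken over contiguous windows of ``window`` metres
    (whole layers); the returned value is its maximum over positions (ties
    broken by the lowest position).  ``layer_top_height`` is the top (m) of
    the highest layer covered by any window whose mean reaches
    ``threshold`` — the top of the deepest canopy stratum capable of
    sustaining combustion — or 0 if no window qualifies.  If the window is
    wider than the profile the mean over the occupied span is used.
    """
    if window < 1.0:
        raise ValueError("window must be at least 1 m")
    dens = profile.layer_density
    n = dens.size
    w = max(1, int(round(window / profile.layer_depth)))
    if w >= n:
        lo, hi = profile.occupied_span
        if hi == lo:
            return AvailableCBD(0.0, 0.0)
        value = float(dens[lo:hi].mean())
        top = float(hi * profile.layer_depth) if value >= threshold else 0.0
        return AvailableCBD(value, top)
    csum = np.concatenate(([0.0], np.cumsum(dens)))
    means = (csum[w:] - csum[:-w]) / w  # means[j] covers layers j .. j+w-1
    value = float(means.max())
    qualifying = np.nonzero(means >= threshold)[0]
    if qualifying.size == 0:
        top = 0.0
    else:
        top_layer = int(qualifying[-1]) + w  # exclusive top index of that window
        # a stratum cannot extend past the last fuel-bearing layer
        top_layer = min(top_layer, profile.occupied_span[1])
        top = float(top_layer * profile.layer_depth)
    return AvailableCBD(value, top)
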