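"""Crown-fire initiation, crown-fire intensity update, and scorch height.

Crowning follows the Van Wagner criterion: a surface fire of intensity I
ignites the canopy when the stand's canopy base height is at or below the
critical height CBH_c = 100 I^(2/3) / h, h = 460 + 25.9 FMC (FMC the
foliar moisture content, %), and the canopy can sustain the fire when the
available canopy bulk density reaches 0.11 kg/m3.  On crowning, fireline
intensity is updated by inverting Byram's flame-length relation
(L = 0.0775 I^0.46) with the flame length set by the top of the deepest
combustible canopy stratum: I_f = 259.833 L^2.174.  Scorch height follows
Byram's two-thirds power law SH = 0.1483 I^(2/3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .canopy import AvailableCBD
from .stand import ClassAttributes, PatchSummary

__all__ = [
    "FireBehaviourParams",
    "FireOutcome",
    "critical_crown_base_height",
    "critical_intensity",
    "crowning_decision",
    "updated_intensity",
    "scorch_height",
    "resolve_fire",
]

TWO_THIRDS = 2.0 / 3.0


@dataclass(frozen=True)
class FireBehaviourParams:
    """Fixed coefficients of the fire-behaviour relations.

    fmc : foliar moisture content, % (100 for boreal conifers in summer)
    cbd_threshold : minimum available canopy bulk density to sustain an
        active crown fire, kg/m3 (empirical 0.11 for FBP conifer types)
    fmc_intercept, fmc_coeff : heat-of-ignition terms, h = 460 + 25.9 FMC
    byram_a, byram_b : I = byram_a * L**byram_b, the inversion of Byram's
        flame length L = 0.0775 I^0.46
    scorch_a, scorch_b : SH = scorch_a * I**scorch_b
    """

    fmc: float = 100.0
    cbd_threshold: float = 0.11
    fmc_intercept: float = 460.0
    fmc_coeff: float = 25.9
    byram_a: float = 259.833
    byram_b: float = 2.174
    scorch_a: float = 0.1483
    scorch_b: float = TWO_THIRDS
    crowning_exponent: float = TWO_THIRDS
    flame_length_scale: float = 1.0  # multiplier on stratum top -> flame length

    def __post_init__(self) -> None:
        for name in ("fmc", "cbd_threshold", "fmc_intercept", "fmc_coeff",
                     "byram_a", "byram_b", "scorch_a", "scorch_b",
                     "crowning_exponent", "flame_length_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def ignition_heat(self) -> float:
        return self.fmc_intercept + self.fmc_coeff * self.fmc


@dataclass(frozen=True)
class FireOutcome:
    """Resolved fire behaviour on a patch."""

    crowned: bool
    intensity_initial: float  # I_i, kW/m
    intensity_used: float  # I_f if crowned else I_i, kW/m
    scorch_height: float  # m, from intensity_used
    flame_height: float = 0.0  # m, crown-flame length when crowned


def critical_crown_base_height(
    intensity: float, params: FireBehaviourParams = FireBehaviourParams()
) -> float:
    """Critical canopy base height (m) for crown-fire initiation at I (kW/m).

    CBH_c = 100 I^(2/3) / (460 + 25.9 FMC); canopies with base at or below
    this height are ignited by a surface fire of the given intensity.
    """
    if intensity <= 0:
        raise ValueError("intensity must be positive")
    return 100.0 * intensity**params.crowning_exponent / params.ignition_heat


def critical_intensity(
    cbh: float, params: FireBehaviourParams = FireBehaviourParams()
) -> float:
    """Critical surface intensity (kW/m) for crowning at canopy base height cbh.

    I0 = (0.01 cbh (460 + 25.9 FMC))^1.5 — the inverse formulation of
    :func:`critical_crown_base_height`.
    """
    if cbh <= 0:
        raise ValueError("cbh must be positive")
    return (0.01 * cbh * params.ignition_heat) ** (1.0 / params.crowning_exponent)


def crowning_decision(
    intensity: float,
    patch_cbh: float,
    available_cbd: float,
    params: FireBehaviourParams = FireBehaviourParams(),
) -> bool:
    """True iff both crowning conditions hold.

    (1) the canopy base is within reach of the surface fire
    (patch_cbh <= CBH_c(I)); and (2) the available canopy bulk density can
    sustain an active crown fire (>= cbd_threshold).
    """
    return (
        patch_cbh <= critical_crown_base_height(intensity, params)
        and available_cbd >= params.cbd_threshold
    )


def updated_intensity(
    flame_height: float, params: FireBehaviourParams = FireBehaviourParams()
) -> float:
    """Crown-fire intensity (kW/m) from flame height (m) by Byram inversion.

    I_f = 259.833 L^2.174, the inverse of L = 0.0775 I^0.46, with the
    flame length L tied to the top height of the crowning canopy stratum
    (no wind effect on flame geometry).
    """
    if flame_height <= 0:
        raise ValueError("flame height must be positive")
    return params.byram_a * flame_height**params.byram_b


def scorch_height(
    intensity: float, params: FireBehaviourParams = FireBehaviourParams()
) -> float:
    """Scorch height (m): SH = 0.1483 I^(2/3), I in kW/m."""
    if intensity <= 0:
        raise ValueError("intensity must be positive")
    return params.scorch_a * intensity**params.scorch_b


def resolve_fire(
    intensity_initial: float,
    summary: PatchSummary,
    available: AvailableCBD,
    attrs: Sequence[ClassAttributes] | None = None,
    params: FireBehaviourParams = FireBehaviourParams(),
) -> FireOutcome:
    """Resolve fire behaviour on a patch for an initial surface intensity.

    If both crowning conditions hold, the flame height is the top of the
    deepest combustible canopy stratum (from the available-CBD running
    mean; falls back to CBH + CL if no stratum qualified) and the
    intensity is updated through Byram's relation, never below the
    initial surface intensity.  Scorch height is computed from the
    intensity actually used.
    """
    crowned = crowning_decision(intensity_initial, summary.cbh, available.value, params)
    flame = 0.0
    if crowned:
        top = available.layer_top_height
        if top <= 0.0:
            top = summary.cbh + summary.cl
        flame = params.flame_length_scale * top
        used = max(intensity_initial, updated_intensity(flame, params))
    else:
        used = intensity_initial
    return FireOutcome(
        crowned=crowned,
        intensity_initial=intensity_initial,
        intensity_used=used,
        scorch_height=scorch_height(used, params),
        flame_height=flame,
    )
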