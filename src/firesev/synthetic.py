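"""Synthetic stand and fire-record generators.

The real inputs of the study system — provincial forest-inventory plots
and the provincial fire-protection agency's fire archive — are not public.
These generators emit tables with the same statistical structure so the
whole simulation chain is testable: reverse-J (truncated-geometric) or
unimodal (discretised-Gaussian) diameter distributions hitting target
density and basal area, and fire records whose log-normal sizes are
positively associated with log-normal head intensities (small fires tend
to be low-intensity ones).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .sampling import FireRecord
from .stand import DiameterClassScheme, N_CLASSES, PatchStructure, Species

__all__ = [
    "PlotGeneratorSpec",
    "FireGeneratorSpec",
    "generate_plots",
    "generate_fire_records",
    "synthetic_inputs",
    "escaped_fraction",
]

# Stand targets typical of the study system: dense black spruce
# (~4000 stems/ha, ~22 m2/ha) and sparser jack pine (~2200 stems/ha,
# ~15 m2/ha).
DEFAULT_TARGETS = {
    Species.BLACK_SPRUCE: {"target_density": 4000.0, "target_ba": 22.0},
    Species.JACK_PINE: {"target_density": 2200.0, "target_ba": 15.0},
}

EVEN_SIGMA = 1.1  # classes; gives SWDI near the even-sized 1.2-1.7 band

# Head-fire intensity scales by FBP fuel type: C-2 (black spruce) fires run
# markedly hotter than C-3 (jack pine) fires in the emulated archive.
DEFAULT_LOG_INTENSITY_MEAN = {"C2": math.log(800.0), "C3": math.log(400.0)}


@dataclass(frozen=True)
class PlotGeneratorSpec:
    """Targets for synthetic 1.0-ha plot generation.

    structure "uneven" draws reverse-J (geometric-decay) diameter
    distributions characteristic of old, uneven-sized stands; "even"
    draws unimodal distributions characteristic of stands regenerated by
    a recent stand-replacing disturbance.  The shape parameter of either
    family is solved per plot so the (jittered) density and basal-area
    targets are met.
    """

    species: Species
    structure: str = "uneven"  # "even" | "uneven"
    target_density: float = 0.0  # stems/ha; 0 -> species default
    target_ba: float = 0.0  # m2/ha; 0 -> species default
    region: str = ""
    rng_seed: int | None = None
    density_jitter: float = 0.12  # lognormal sd of per-plot density
    ba_jitter: float = 0.10  # lognormal sd of per-plot basal area
    count_noise: float = 0.15  # lognormal sd of per-class counts

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", Species(self.species))
        if self.structure not in ("even", "uneven"):
            raise ValueError("structure must be 'even' or 'uneven'")
        defaults = DEFAULT_TARGETS[self.species]
        if self.target_density <= 0:
            object.__setattr__(self, "target_density", defaults["target_density"])
        if self.target_ba <= 0:
            object.__setattr__(self, "target_ba", defaults["target_ba"])


def _class_weights_uneven(r: float) -> np.ndarray:
    return r ** np.arange(N_CLASSES)


def _class_weights_even(mu: float, sigma: float = EVEN_SIGMA) -> np.ndarray:
    i = np.arange(1, N_CLASSES + 1, dtype=float)
    return np.exp(-((i - mu) ** 2) / (2.0 * sigma**2))


def _solve_shape(structure: str, mean_tree_ba: float, tree_ba: np.ndarray) -> np.ndarray:
    """Find class weights whose weighted mean per-tree basal area hits target."""

    def mean_ba(weights: np.ndarray) -> float:
        return float(np.sum(weights * tree_ba) / weights.sum())

    if structure == "uneven":
        lo, hi = 1e-3, 0.999999
        f = lambda r: mean_ba(_class_weights_uneven(r)) - mean_tree_ba
        make = _class_weights_uneven
    else:
        lo, hi = -2.0, float(N_CLASSES) + 2.0
        f = lambda mu: mean_ba(_class_weights_even(mu)) - mean_tree_ba
        make = _class_weights_even
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(
            f"infeasible targets: mean tree basal area {mean_tree_ba:.5f} m2 "
            f"outside the achievable range of the {structure} family"
        )
    root = brentq(f, lo, hi, xtol=1e-10)
    return make(root)


def generate_plots(
    spec: PlotGeneratorSpec,
    n: int,
    scheme: DiameterClassScheme | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[PatchStructure]:
    """Generate n synthetic 1.0-ha plots for the spec.

    Per plot, the density and basal-area targets are jittered
    (log-normally), the family shape parameter is solved so the expected
    basal area at the drawn density matches the drawn target, per-class
    counts get multiplicative log-normal noise, and counts are rounded to
    integers per ha.  Deterministic for a fixed seed.
    """
    if scheme is None:
        scheme = DiameterClassScheme()
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    else:
        rng = np.random.default_rng(rng)
    tree_ba = (scheme.qmd / 2.0) ** 2 * math.pi / 10_000.0
    plots: list[PatchStructure] = []
    for _ in range(n):
        density = spec.target_density * rng.lognormal(0.0, spec.density_jitter)
        ba = spec.target_ba * rng.lognormal(0.0, spec.ba_jitter)
        weights = _solve_shape(spec.structure, ba / density, tree_ba)
        p = weights / weights.sum()
        counts = density * p * rng.lognormal(0.0, spec.count_noise, size=N_CLASSES)
        counts = np.round(counts).astype(np.int64)
        if counts.sum() == 0:
            counts[int(np.argmax(p))] = 1
        plots.append(
            PatchStructure(species=spec.species, counts=counts, region=spec.region)
        )
    return plots


@dataclass(frozen=True)
class FireGeneratorSpec:
    """Parameters of the synthetic fire-record generator.

    Head intensities are log-normal; final sizes are log-normal with a
    positive log-log regression on intensity of slope
    ``size_intensity_beta`` (0 gives independence), emulating the
    observed association of low intensities with small fires.
    """

    region: str = ""
    fuel_type: str = "C2"
    n: int = 1000
    log_intensity_mean: float = 0.0  # 0 -> fuel-type default
    log_intensity_sd: float = 1.3
    size_intensity_beta: float = 0.5
    log_size_mean: float = 0.0  # median final size 1.0 ha
    log_size_sd: float = 1.8
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if self.size_intensity_beta < 0:
            raise ValueError("size-intensity association must be non-negative")
        Species.from_fuel_type(self.fuel_type)
        if self.log_intensity_mean == 0.0:
            key = self.fuel_type.upper().replace("-", "")
            object.__setattr__(
                self, "log_intensity_mean", DEFAULT_LOG_INTENSITY_MEAN[key]
            )


def generate_fire_records(
    spec: FireGeneratorSpec, rng: np.random.Generator | int | None = None
) -> list[FireRecord]:
    """Generate a synthetic fire-record table.  Deterministic under seed."""
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    else:
        rng = np.random.default_rng(rng)
    log_i = rng.normal(spec.log_intensity_mean, spec.log_intensity_sd, size=spec.n)
    log_s = (
        spec.log_size_mean
        + spec.size_intensity_beta * (log_i - spec.log_intensity_mean)
        + rng.normal(0.0, spec.log_size_sd, size=spec.n)
    )
    return [
        FireRecord(
            region=spec.region,
            fuel_type=spec.fuel_type,
            head_intensity=float(np.exp(li)),
            final_size=float(np.exp(ls)),
        )
        for li, ls in zip(log_i, log_s)
    ]


def synthetic_inputs(
    regions: Sequence[str] = ("A2", "B3", "C3", "D4"),
    plots_per_stratum: int = 40,
    fires_per_stratum: int = 300,
    seed: int = 0,
) -> tuple[list[PatchStructure], list[FireRecord]]:
    """Full synthetic inputs for a stratified experiment.

    Per region and species, the plot pool mixes uneven- and even-sized
    stands half and half (real inventories contain both), and a
    fire-record table is generated for the matching fuel type.
    Deterministic under ``seed``.
    """
    plots: list[PatchStructure] = []
    records: list[FireRecord] = []
    for si, species in enumerate((Species.BLACK_SPRUCE, Species.JACK_PINE)):
        for ri, region in enumerate(regions):
            ss = np.random.SeedSequence((seed, si, ri))
            rng = np.random.default_rng(ss)
            half = plots_per_stratum // 2
            for structure, m in (("uneven", half), ("even", plots_per_stratum - half)):
                spec = PlotGeneratorSpec(
                    species=species, structure=structure, region=region
                )
                plots.extend(generate_plots(spec, m, rng=rng))
            fspec = FireGeneratorSpec(
                region=region, fuel_type=species.fuel_type, n=fires_per_stratum
            )
            records.extend(generate_fire_records(fspec, rng=rng))
    return plots, records


def escaped_fraction(records: Sequence[FireRecord], threshold: float = 3.0) -> float:
    """Fraction of fires whose final size reaches the containment target (ha)."""
    if not records:
        raise ValueError("no records")
    return sum(r.final_size >= threshold for r in records) / len(records)
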