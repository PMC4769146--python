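"""The stratified fire-severity simulation experiment.

For every stratum (fire region x dominant species), patches are resampled
with replacement from the plot pool and initial intensities are drawn by
the three-stage scheme (size-weighted head intensities x elliptical
within-fire relative intensities).  Each run chains: class attributes ->
patch summary -> vertical fuel profile -> available CBD -> crowning
decision -> intensity update -> scorch -> binomial mortality -> percent
basal-area loss.  The study design runs 3000 simulations per stratum over
four regions and two species (24 000 runs); smaller designs are just
config changes.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .canopy import available_cbd, vertical_fuel_profile
from .fire import FireBehaviourParams, FireOutcome, resolve_fire
from .sampling import (
    EllipseModel,
    FireRecord,
    initial_intensities,
    relative_intensity_sample,
    size_weighted_sample,
)
from .severity import SeverityResult, apply_fire
from .stand import (
    ClassAttributes,
    DiameterClassScheme,
    PatchStructure,
    PatchSummary,
    Species,
    class_attributes,
    patch_summary,
)

__all__ = ["ExperimentConfig", "PreparedPatch", "prepare_patch", "run_once",
           "run_experiment", "summarize"]

logger = logging.getLogger(__name__)

DEFAULT_REGIONS = ("A2", "B3", "C3", "D4")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce a simulation experiment."""

    regions: tuple[str, ...] = DEFAULT_REGIONS
    species: tuple[Species, ...] = (Species.BLACK_SPRUCE, Species.JACK_PINE)
    runs_per_stratum: int = 3000
    master_seed: int = 0
    plot_table: str | None = None
    fire_table: str | None = None
    min_size_ha: float = 0.1
    cbd_window: float = 3.0
    lb_black_spruce: float = 3.0
    lb_jack_pine: float = 3.0
    no_scorch_no_mortality: bool = False
    fire_params: FireBehaviourParams = field(default_factory=FireBehaviourParams)

    def __post_init__(self) -> None:
        if self.runs_per_stratum < 1:
            raise ValueError("runs_per_stratum must be >= 1")
        object.__setattr__(
            self, "species", tuple(Species(s) for s in self.species)
        )
        object.__setattr__(self, "regions", tuple(self.regions))

    def length_to_breadth(self, species: Species) -> float:
        return (
            self.lb_black_spruce
            if species is Species.BLACK_SPRUCE
            else self.lb_jack_pine
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        """Load a config from a structured YAML file.

        Top-level keys mirror the dataclass fields; an optional
        ``fire_behaviour`` mapping overrides :class:`FireBehaviourParams`
        coefficients.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fire_raw = raw.pop("fire_behaviour", {})
        params = FireBehaviourParams(**fire_raw)
        return cls(fire_params=params, **raw)


@dataclass(frozen=True)
class PreparedPatch:
    """A patch with its derived attributes, summary and canopy profile."""

    patch: PatchStructure
    attrs: tuple[ClassAttributes, ...]
    summary: PatchSummary
    available_value: float
    available_top: float


def prepare_patch(
    patch: PatchStructure,
    config: ExperimentConfig = ExperimentConfig(),
    scheme: DiameterClassScheme | None = None,
) -> PreparedPatch:
    """Precompute the intensity-independent stage of the chain for a patch."""
    if scheme is None:
        scheme = DiameterClassScheme()
    attrs = class_attributes(scheme, patch)
    summary = patch_summary(patch, attrs)
    profile = vertical_fuel_profile(patch, attrs)
    avail = available_cbd(
        profile, window=config.cbd_window, threshold=config.fire_params.cbd_threshold
    )
    return PreparedPatch(
        patch=patch,
        attrs=tuple(attrs),
        summary=summary,
        available_value=avail.value,
        available_top=avail.layer_top_height,
    )


def run_once(
    patch: PatchStructure | PreparedPatch,
    intensity: float,
    config: ExperimentConfig = ExperimentConfig(),
    seed: int | np.random.Generator | None = None,
) -> tuple[SeverityResult, PreparedPatch, FireOutcome]:
    """Simulate one fire of initial intensity I_i (kW/m) on one patch.

    Deterministic for a fixed seed; the stochastic step is the per-class
    binomial draw of killed stems.
    """
    prepared = patch if isinstance(patch, PreparedPatch) else prepare_patch(patch, config)
    from .canopy import AvailableCBD

    outcome = resolve_fire(
        intensity,
        prepared.summary,
        AvailableCBD(prepared.available_value, prepared.available_top),
        prepared.attrs,
        config.fire_params,
    )
    result = apply_fire(
        prepared.patch,
        prepared.attrs,
        outcome,
        rng=seed,
        no_scorch_no_mortality=config.no_scorch_no_mortality,
    )
    return result, prepared, outcome


def _stratum_records(
    records: Sequence[FireRecord], region: str, species: Species
) -> list[FireRecord]:
    return [r for r in records if r.region == region and r.species is species]


def run_experiment(
    plots: Sequence[PatchStructure],
    records: Sequence[FireRecord],
    config: ExperimentConfig = ExperimentConfig(),
) -> pd.DataFrame:
    """Run the full stratified experiment; one row per simulated fire.

    Plots and fire records are matched to strata by their region label
    and species (fuel type C-2 = black spruce, C-3 = jack pine).  Within
    a stratum, plots are sampled with replacement; head intensities are
    size-weighted samples of the stratum's fire records, multiplied
    index-wise by elliptical within-fire relative intensities.  Fully
    deterministic under the master seed.
    """
    scheme = DiameterClassScheme()
    rows: list[dict] = []
    n = config.runs_per_stratum
    for si, species in enumerate(config.species):
        ellipse = EllipseModel(config.length_to_breadth(species))
        for ri, region in enumerate(config.regions):
            pool = [p for p in plots if p.region == region and p.species is species]
            recs = _stratum_records(records, region, species)
            if not pool:
                raise ValueError(f"no plots for stratum ({region}, {species.value})")
            if not recs:
                raise ValueError(f"no fire records for stratum ({region}, {species.value})")
            ss = np.random.SeedSequence((config.master_seed, si, ri))
            rng = np.random.default_rng(ss)
            heads = size_weighted_sample(recs, n, config.min_size_ha, rng)
            rels = relative_intensity_sample(ellipse, n, rng)
            intensities = initial_intensities(heads, rels)
            idx = rng.integers(0, len(pool), size=n)
            run_seeds = rng.integers(0, 2**31 - 1, size=n)
            prepared = {}
            for k in range(n):
                j = int(idx[k])
                if j not in prepared:
                    prepared[j] = prepare_patch(pool[j], config, scheme)
                prep = prepared[j]
                result, _, outcome = run_once(
                    prep, float(intensities[k]), config, int(run_seeds[k])
                )
                s = prep.summary
                rows.append(
                    {
                        "region": region,
                        "species": species.value,
                        "seed": int(run_seeds[k]),
                        "head_intensity": float(heads[k]),
                        "I_i": float(intensities[k]),
                        "intensity_used": result.intensity_used,
                        "crowned": result.crowned,
                        "scorch_height": outcome.scorch_height,
                        "ba_before": result.ba_before,
                        "ba_after": result.ba_after,
                        "severity": result.severity,
                        "severity_class": result.severity_class,
                        "total_density": s.total_density,
                        "cbh": s.cbh,
                        "cbd": s.cbd,
                        "available_cbd": prep.available_value,
                        "cfl": s.cfl,
                        "cl": s.cl,
                        "swdi": s.swdi,
                        "pct_class10": s.pct_class10,
                        "pct_class14": s.pct_class14,
                    }
                )
            logger.info(
                "stratum (%s, %s): %d runs done", region, species.value, n
            )
    return pd.DataFrame(rows)


def summarize(
    results: pd.DataFrame, by: Sequence[str] = ("species", "region")
) -> pd.DataFrame:
    """Per-stratum severity summary.

    Mean and median severity, proportions of the three severity classes
    (they sum to 1 within a stratum) and the crowning fraction.
    """
    by = list(by)
    out = []
    for key, grp in results.groupby(by, sort=True):
        key = (key,) if not isinstance(key, tuple) else key
        rec = dict(zip(by, key))
        rec.update(
            n_runs=len(grp),
            mean_severity=float(grp["severity"].mean()),
            median_severity=float(grp["severity"].median()),
            prop_low=float((grp["severity_class"] == "low").mean()),
            prop_moderate=float((grp["severity_class"] == "moderate").mean()),
            prop_high=float((grp["severity_class"] == "high").mean()),
            crowning_fraction=float(grp["crowned"].mean()),
        )
        out.append(rec)
    return pd.DataFrame(out)
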