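"""Plain-CSV readers and writers for plot and fire-record tables.

Plot CSV: species,region,n01,...,n15 — per-ha integer stem counts in the
fifteen 2-cm DBH classes in ascending order.  Fire-record CSV:
region,fuel_type,head_intensity_kw_m,final_size_ha.  Both round-trip
exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .canopy import FuelProfile
from .sampling import FireRecord
from .stand import N_CLASSES, PatchStructure, Species

__all__ = [
    "read_plots",
    "write_plots",
    "read_fire_records",
    "write_fire_records",
    "write_profile",
]

_COUNT_COLS = [f"n{i:02d}" for i in range(1, N_CLASSES + 1)]


def write_plots(plots: Sequence[PatchStructure], path: str | Path) -> None:
    rows = [
        {"species": p.species.value, "region": p.region,
         **{c: int(n) for c, n in zip(_COUNT_COLS, p.counts)}}
        for p in plots
    ]
    pd.DataFrame(rows, columns=["species", "region", *_COUNT_COLS]).to_csv(
        path, index=False
    )


def read_plots(path: str | Path) -> list[PatchStructure]:
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in ("species", "region", *_COUNT_COLS) if c not in df.columns]
    if missing:
        raise ValueError(f"plot table {path} is missing columns {missing}")
    return [
        PatchStructure(
            species=Species(row["species"]),
            counts=np.array([row[c] for c in _COUNT_COLS], dtype=np.int64),
            region=str(row["region"]),
        )
        for _, row in df.iterrows()
    ]


def write_fire_records(records: Sequence[FireRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"region": r.region, "fuel_type": r.fuel_type,
             "head_intensity_kw_m": r.head_intensity, "final_size_ha": r.final_size}
            for r in records
        ],
        columns=["region", "fuel_type", "head_intensity_kw_m", "final_size_ha"],
    ).to_csv(path, index=False, float_format="%.17g")  # exact float round-trip


def read_fire_records(path: str | Path) -> list[FireRecord]:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    needed = ["region", "fuel_type", "head_intensity_kw_m", "final_size_ha"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"fire-record table {path} is missing columns {missing}")
    return [
        FireRecord(
            region=str(row["region"]),
            fuel_type=str(row["fuel_type"]),
            head_intensity=float(row["head_intensity_kw_m"]),
            final_size=float(row["final_size_ha"]),
        )
        for _, row in df.iterrows()
    ]


def write_profile(profile: FuelProfile, path: str | Path) -> None:
    """Dump a vertical fuel profile as (layer_bottom_m, density_kg_m3) rows."""
    pd.DataFrame(
        {
            "layer_bottom_m": np.arange(profile.layer_density.size) * profile.layer_depth,
            "density_kg_m3": profile.layer_density,
        }
    ).to_csv(path, index=False)
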