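"""Diameter-class stand representation and allometry.

A 1.0 ha patch of mono-specific black spruce or jack pine is represented
by live-stem counts in fifteen 2-cm DBH classes (1–3 cm up to 29–31 cm).
Class-level attributes (quadratic mean diameter, top height, crown ratio,
crown biomass, bark thickness) are derived from species-specific
allometries, and patch-level fuel/structure summaries (canopy base height,
canopy fuel load, canopy length, bulk density, Shannon–Wiener diversity of
the diameter distribution) are stem-count-weighted aggregates of those.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Species",
    "DiameterClassScheme",
    "SpeciesAllometry",
    "PatchStructure",
    "ClassAttributes",
    "PatchSummary",
    "quadratic_mean_diameter",
    "class_attributes",
    "patch_summary",
    "structure_label",
]

N_CLASSES = 15
CLASS_WIDTH_CM = 2.0
PATCH_AREA_M2 = 10_000.0  # 1.0 ha


class Species(str, enum.Enum):
    """The two boreal conifers modelled (FBP fuel types C-2 and C-3)."""

    BLACK_SPRUCE = "black_spruce"
    JACK_PINE = "jack_pine"

    @classmethod
    def from_fuel_type(cls, fuel_type: str) -> "Species":
        """Map a Canadian FBP fuel-type label to a species."""
        ft = fuel_type.upper().replace("-", "")
        if ft == "C2":
            return cls.BLACK_SPRUCE
        if ft == "C3":
            return cls.JACK_PINE
        raise ValueError(f"unsupported fuel type {fuel_type!r} (expected C-2 or C-3)")

    @property
    def fuel_type(self) -> str:
        return "C2" if self is Species.BLACK_SPRUCE else "C3"


@dataclass(frozen=True)
class DiameterClassScheme:
    """The fixed DBH binning: 15 contiguous 2-cm classes from 1–3 to 29–31 cm."""

    class_bounds: tuple[tuple[float, float], ...] = tuple(
        (1.0 + 2.0 * i, 3.0 + 2.0 * i) for i in range(N_CLASSES)
    )

    def __post_init__(self) -> None:
        b = self.class_bounds
        if len(b) != N_CLASSES:
            raise ValueError(f"expected {N_CLASSES} classes, got {len(b)}")
        for (lo, hi) in b:
            if not math.isclose(hi - lo, CLASS_WIDTH_CM):
                raise ValueError(f"class ({lo}, {hi}) is not {CLASS_WIDTH_CM} cm wide")
        for (_, hi), (lo, _) in zip(b, b[1:]):
            if not math.isclose(hi, lo):
                raise ValueError("diameter classes must be contiguous")
        if b[0] != (1.0, 3.0) or b[-1] != (29.0, 31.0):
            raise ValueError("scheme must span 1–3 cm to 29–31 cm")

    @property
    def qmd(self) -> np.ndarray:
        """Quadratic mean diameter of each class (cm)."""
        return np.array([quadratic_mean_diameter(lo, hi) for lo, hi in self.class_bounds])

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([(lo + hi) / 2.0 for lo, hi in self.class_bounds])


def quadratic_mean_diameter(lower: float, upper: float) -> float:
    """QMD of a diameter class, sqrt((X2^3 - X1^3) / (3 (X2 - X1))).

    This is the root-mean-square diameter of a uniform diameter density
    over [lower, upper]; it always lies strictly inside the class.

    Parameters
    ----------
    lower, upper : float
        Class bounds in cm, 0 <= lower < upper.
    """
    if lower < 0 or upper <= lower:
        raise ValueError(f"invalid class bounds ({lower}, {upper})")
    return math.sqrt((upper**3 - lower**3) / (3.0 * (upper - lower)))


@dataclass(frozen=True)
class SpeciesAllometry:
    """Species-specific allometric coefficients.

    Height: H = 1.3 + a * QMD^b (m; 1.3 m breast-height intercept).
    Crown ratio: CR = (c1/(1 + c2*BA) + c3*(1 - exp(-c4*QMD)) + c5) / 10,
    with BA the stand basal area in m2/ha, clamped to (cr_min, 1].
    Crown biomass: TCB = t0 + t1*QMD^e1 + t2*QMD^e2 (kg; needles plus live
    branchwood up to 1 cm diameter).
    Bark thickness: BT = bark_factor * 2.54 * QMD (cm).
    """

    species: Species
    height_a: float
    height_b: float
    cr_coeffs: tuple[float, float, float, float, float]
    tcb_coeffs: tuple[float, float, float, float, float]  # t0, t1, e1, t2, e2
    bark_factor: float
    length_to_breadth: float = 3.0
    cr_min: float = 0.01

    @classmethod
    def for_species(cls, species: Species | str, **overrides) -> "SpeciesAllometry":
        species = Species(species)
        base = _DEFAULT_ALLOMETRY[species]
        if overrides:
            from dataclasses import replace

            return replace(base, **overrides)
        return base

    def height(self, qmd: np.ndarray | float) -> np.ndarray | float:
        return 1.3 + self.height_a * np.asarray(qmd, dtype=float) ** self.height_b

    def crown_ratio(self, qmd: np.ndarray | float, stand_ba: float) -> np.ndarray:
        c1, c2, c3, c4, c5 = self.cr_coeffs
        q = np.asarray(qmd, dtype=float)
        cr = (c1 / (1.0 + c2 * stand_ba) + c3 * (1.0 - np.exp(-c4 * q)) + c5) / 10.0
        return np.clip(cr, self.cr_min, 1.0)

    def crown_biomass(self, qmd: np.ndarray | float) -> np.ndarray:
        t0, t1, e1, t2, e2 = self.tcb_coeffs
        q = np.asarray(qmd, dtype=float)
        return t0 + t1 * q**e1 + t2 * q**e2

    def bark_thickness(self, qmd: np.ndarray | float) -> np.ndarray:
        return self.bark_factor * 2.54 * np.asarray(qmd, dtype=float)


_DEFAULT_ALLOMETRY = {
    Species.BLACK_SPRUCE: SpeciesAllometry(
        species=Species.BLACK_SPRUCE,
        height_a=1.065,
        height_b=0.886,
        cr_coeffs=(5.54, 0.007, 4.20, 0.053, -0.45),
        tcb_coeffs=(0.63, 0.02, 2.2, 0.0, 1.0),
        bark_factor=0.032,
    ),
    Species.JACK_PINE: SpeciesAllometry(
        species=Species.JACK_PINE,
        height_a=1.306,
        height_b=0.834,
        cr_coeffs=(6.64, 0.013, 3.20, 0.052, -0.45),
        tcb_coeffs=(0.0, 0.0079, 2.41, 0.0389, 1.729),
        bark_factor=0.040,
    ),
}


@dataclass
class PatchStructure:
    """A 1.0 ha mono-specific patch: per-class live stem counts (trees/ha)."""

    species: Species
    counts: np.ndarray
    region: str = ""

    def __post_init__(self) -> None:
        self.species = Species(self.species)
        counts = np.asarray(self.counts)
        if counts.shape != (N_CLASSES,):
            raise ValueError(f"counts must have length {N_CLASSES}")
        if np.any(counts < 0):
            raise ValueError("stem counts must be non-negative")
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("stem counts must be integers (trees per ha)")
        self.counts = np.round(counts).astype(np.int64)

    @property
    def total_density(self) -> int:
        return int(self.counts.sum())

    def scaled(self, factor: float) -> "PatchStructure":
        return PatchStructure(
            species=self.species,
            counts=np.round(self.counts * factor).astype(np.int64),
            region=self.region,
        )


@dataclass(frozen=True)
class ClassAttributes:
    """Derived attributes of one diameter class."""

    qmd: float  # cm
    count: int  # trees/ha
    tree_ba: float  # m2 per tree
    height: float  # m
    crown_ratio: float  # fraction of height that is live crown
    crown_base: float  # m, = height * (1 - crown_ratio)
    crown_biomass: float  # kg per tree
    fuel_mass: float  # kg/ha for the class, = crown_biomass * count
    bark_thickness: float  # cm

    @property
    def crown_length(self) -> float:
        return self.height - self.crown_base


@dataclass(frozen=True)
class PatchSummary:
    """Patch-level stand structure and canopy fuel summary."""

    basal_area: float  # m2/ha
    total_density: int  # stems/ha
    cbh: float  # canopy base height, m (count-weighted mean crown base)
    cfl: float  # canopy fuel load, kg/ha
    cl: float  # canopy length, m (count-weighted mean crown length)
    cbd: float  # load-over-depth canopy bulk density, kg/m3
    swdi: float  # Shannon-Wiener diversity of the diameter distribution
    pct_class10: float  # % of stems in the 9-11 cm class
    pct_class14: float  # % of stems in the 13-15 cm class


def class_attributes(
    scheme: DiameterClassScheme,
    patch: PatchStructure,
    allometry: SpeciesAllometry | None = None,
) -> list[ClassAttributes]:
    """Compute per-class attributes from the diameter distribution.

    Stand basal area (needed by the crown-ratio model) is computed first
    from the class quadratic mean diameters and stem counts.
    """
    if allometry is None:
        allometry = SpeciesAllometry.for_species(patch.species)
    if allometry.species != patch.species:
        raise ValueError(
            f"allometry is for {allometry.species.value}, patch is {patch.species.value}"
        )
    qmd = scheme.qmd
    counts = patch.counts
    tree_ba = (qmd / 2.0) ** 2 * math.pi / PATCH_AREA_M2  # cm2 -> m2
    stand_ba = float(np.sum(tree_ba * counts))
    height = allometry.height(qmd)
    cr = allometry.crown_ratio(qmd, stand_ba)
    tcb = allometry.crown_biomass(qmd)
    bt = allometry.bark_thickness(qmd)
    return [
        ClassAttributes(
            qmd=float(qmd[i]),
            count=int(counts[i]),
            tree_ba=float(tree_ba[i]),
            height=float(height[i]),
            crown_ratio=float(cr[i]),
            crown_base=float(height[i] * (1.0 - cr[i])),
            crown_biomass=float(tcb[i]),
            fuel_mass=float(tcb[i] * counts[i]),
            bark_thickness=float(bt[i]),
        )
        for i in range(N_CLASSES)
    ]


def patch_summary(patch: PatchStructure, attrs: Sequence[ClassAttributes]) -> PatchSummary:
    """Patch-level structure summary from per-class attributes.

    CBH and CL are stem-count-weighted means of class crown base and crown
    length; CFL sums crown biomass over stems; CBD is the load-over-depth
    ratio (CFL / 10 000 m2/ha) / CL in kg/m3.  Classes with zero stems are
    skipped in all weighted sums.
    """
    counts = np.array([a.count for a in attrs], dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("patch has no stems")
    occ = counts > 0
    w = counts[occ] / counts[occ].sum()
    heights = np.array([a.height for a in attrs])[occ]
    cr = np.array([a.crown_ratio for a in attrs])[occ]
    cbh = float(np.sum(heights * (1.0 - cr) * w))
    cl = float(np.sum(heights * cr * w))
    cfl = float(sum(a.fuel_mass for a in attrs))
    cbd = (cfl / PATCH_AREA_M2) / cl
    p = counts / total
    swdi = float(-np.sum(p[p > 0] * np.log(p[p > 0])))
    ba = float(sum(a.tree_ba * a.count for a in attrs))
    return PatchSummary(
        basal_area=ba,
        total_density=int(total),
        cbh=cbh,
        cfl=cfl,
        cl=cl,
        cbd=cbd,
        swdi=swdi,
        pct_class10=float(100.0 * counts[4] / total),  # 9-11 cm is class index 4
        pct_class14=float(100.0 * counts[6] / total),  # 13-15 cm is class index 6
    )


def structure_label(swdi: float, threshold: float = 1.8) -> str:
    """Label a diameter distribution even- vs uneven-sized by its SWDI.

    Values of roughly 1.2–1.7 characterise even-sized (recently disturbed)
    stands and 1.8–2.4 uneven-sized stands; the conventional split is 1.8.
    """
    return "uneven" if swdi >= threshold else "even"
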