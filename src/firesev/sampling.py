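"""Three-stage sampling of patch-level initial fire intensities.

Stage 1 resamples historical head fire intensities with replacement,
weighted by final fire size (so the intensities represent area burned, not
fire counts).  Stage 2 samples the theoretical within-fire distribution of
local fireline intensity relative to the head intensity, assuming
self-similar elliptical growth from an ignition at the rear focus: a point
drawn uniformly over the final burned area is projected radially from the
focus to the perimeter, and its relative intensity is the front-normal
displacement over the head displacement.  Stage 3 multiplies the two,
pairing the vectors index-wise, to give the patch-level I_i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .stand import Species

__all__ = [
    "FireRecord",
    "EllipseModel",
    "size_weighted_sample",
    "relative_intensity_sample",
    "relative_intensity_grid",
    "initial_intensities",
]


@dataclass(frozen=True)
class FireRecord:
    """One historical fire: head intensity of the first burning day and final size."""

    region: str
    fuel_type: str  # "C2" (black spruce) or "C3" (jack pine)
    head_intensity: float  # kW/m
    final_size: float  # ha

    def __post_init__(self) -> None:
        Species.from_fuel_type(self.fuel_type)  # validates
        if self.head_intensity <= 0:
            raise ValueError("head intensity must be positive")
        if self.final_size < 0:
            raise ValueError("final size must be non-negative")

    @property
    def species(self) -> Species:
        return Species.from_fuel_type(self.fuel_type)


@dataclass(frozen=True)
class EllipseModel:
    """Elliptical fire-growth geometry set by the length-to-breadth ratio."""

    length_to_breadth: float = 3.0

    def __post_init__(self) -> None:
        if self.length_to_breadth < 1.0:
            raise ValueError("length-to-breadth ratio must be >= 1")

    @property
    def eccentricity(self) -> float:
        return math.sqrt(1.0 - 1.0 / self.length_to_breadth**2)

    @property
    def back_to_head_ratio(self) -> float:
        """q = (1-e)/(1+e): back-fire intensity relative to the head."""
        e = self.eccentricity
        return (1.0 - e) / (1.0 + e)


def size_weighted_sample(
    records: Sequence[FireRecord],
    n: int,
    min_size: float = 0.1,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Resample head fire intensities with probability proportional to size.

    Fires smaller than ``min_size`` ha are excluded.  Weighting by area
    burned down-weights the small, low-intensity fires so the sample is
    representative of the intensity distribution over area burned.
    """
    rng = np.random.default_rng(rng)
    eligible = [r for r in records if r.final_size >= min_size]
    if not eligible:
        raise ValueError(f"no fire records with final size >= {min_size} ha")
    sizes = np.array([r.final_size for r in eligible])
    intensities = np.array([r.head_intensity for r in eligible])
    idx = rng.choice(len(eligible), size=n, replace=True, p=sizes / sizes.sum())
    return intensities[idx]


def _relative_from_points(x: np.ndarray, y: np.ndarray, ellipse: EllipseModel) -> np.ndarray:
    """Relative intensity of interior points (x, y) of the unit-semi-major ellipse.

    The ignition focus is F = (-e, 0); each point is projected radially
    from F to the perimeter point P, and the relative intensity is the
    front-normal component of (P - F) over the head value (a + c = 1 + e).
    Scale-free: depends only on the length-to-breadth ratio.
    """
    a = 1.0
    b = 1.0 / ellipse.length_to_breadth
    e = ellipse.eccentricity
    fx = -e
    dx, dy = x - fx, y
    # solve ((fx + t dx)/a)^2 + ((t dy)/b)^2 = 1 for t > 0
    A = (dx / a) ** 2 + (dy / b) ** 2
    B = 2.0 * (fx * dx / a**2)
    C = (fx / a) ** 2 - 1.0
    degenerate = A <= 0.0  # point exactly at the focus
    A = np.where(degenerate, 1.0, A)
    t = (-B + np.sqrt(B**2 - 4.0 * A * C)) / (2.0 * A)
    px, py = fx + t * dx, t * dy
    nx, ny = px / a**2, py / b**2
    norm = np.sqrt(nx**2 + ny**2)
    rel = ((px - fx) * nx + py * ny) / norm / (a + e)
    return np.where(degenerate, 1.0, rel)


def relative_intensity_sample(
    ellipse: EllipseModel,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sample the area-weighted within-fire relative intensity distribution.

    Values lie in [(1-e)/(1+e), 1]: 1 at the head, the minimum at the
    back; a circular fire (LB = 1) gives the constant 1.
    """
    rng = np.random.default_rng(rng)
    if ellipse.length_to_breadth == 1.0:
        return np.ones(n)
    # uniform points in the ellipse: uniform in the unit disk, then scaled
    r = np.sqrt(rng.uniform(0.0, 1.0, size=n))
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
    x = r * np.cos(theta)
    y = r * np.sin(theta) / ellipse.length_to_breadth
    return _relative_from_points(x, y, ellipse)


def relative_intensity_grid(
    ellipse: EllipseModel, resolution: int = 400
) -> np.ndarray:
    """Deterministic dense-grid version of the within-fire distribution.

    Evaluates the same focus projection on a uniform rectangular grid over
    the ellipse area (each interior cell carries equal area weight) and
    returns the relative intensity values; their empirical distribution is
    a quadrature approximation of the area-weighted law, used as a
    cross-check of the Monte-Carlo sampler.
    """
    a, b = 1.0, 1.0 / ellipse.length_to_breadth
    # offset grid so no node sits exactly on the focus or boundary
    xs = np.linspace(-a, a, resolution + 1)[:-1] + a / resolution
    ys = np.linspace(-b, b, resolution + 1)[:-1] + b / resolution
    gx, gy = np.meshgrid(xs, ys)
    inside = (gx / a) ** 2 + (gy / b) ** 2 < 1.0
    return _relative_from_points(gx[inside], gy[inside], ellipse)


def initial_intensities(
    head_samples: np.ndarray | Sequence[float],
    relative_samples: np.ndarray | Sequence[float],
) -> np.ndarray:
    """Patch-level initial intensities: element-wise product of the stages."""
    head = np.asarray(head_samples, dtype=float)
    rel = np.asarray(relative_samples, dtype=float)
    if head.shape != rel.shape:
        raise ValueError("head and relative samples must have equal length")
    return head * rel
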