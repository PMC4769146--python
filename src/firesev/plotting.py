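"""Small plotting helpers for simulation output."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .severity import SEVERITY_HIGH_MIN, SEVERITY_LOW_MAX

__all__ = ["severity_ecdf"]


def severity_ecdf(results: pd.DataFrame, ax=None):
    """Empirical distribution function of severity by species.

    Vertical lines mark the low/moderate/high severity class boundaries
    (25% and 75% basal-area reduction).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for species, grp in results.groupby("species"):
        s = np.sort(grp["severity"].to_numpy())
        ax.step(s, np.arange(1, s.size + 1) / s.size, where="post", label=species)
    for x in (SEVERITY_LOW_MAX, SEVERITY_HIGH_MIN):
        ax.axvline(x, color="grey", linestyle="--", linewidth=0.8)
    ax.set_xlabel("fire severity (% basal-area reduction)")
    ax.set_ylabel("empirical CDF")
    ax.set_xlim(0, 100)
    ax.legend()
    return ax
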