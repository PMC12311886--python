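"""Matplotlib helpers for the sweep and MST diagnostics (optional)."""

from __future__ import annotations

import numpy as np

from .network import MSTResult, ordered_distance_curve
from .threshold import SweepResult


def plot_sweep(result: SweepResult, ax=None):
    """Dual-axis plot of normalized M(d_5%) vs explained-ion removal."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    norm = result.m_d5 / result.m_d5[0] if result.m_d5[0] > 0 else result.m_d5
    ax.plot(result.cutoffs * 100, norm, color="tab:red",
            label="M(d_5%) / M(d_5%) at cutoff 0")
    ax.plot(result.cutoffs * 100, result.explained_removed_frac, color="tab:blue",
            label="explained ions removed")
    if result.tailored_point is not None:
        erf_t, md5_t = result.tailored_point
        ax.axhline(erf_t, ls="--", lw=0.8, color="black")
        ax.plot([], [], "k*", label="tailored filter")
    ax.set_xlabel("cutoff (% of base peak)")
    ax.set_ylabel("normalized value")
    ax.legend()
    return ax


def plot_ordered_distances(results: dict[str, MSTResult], ax=None):
    """Ordered MST distance curves (square-root scale) per condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    table = ordered_distance_curve(results)
    for label, grp in table.groupby("label"):
        ax.plot(grp["rank"], grp["sqrt_distance"], label=str(label))
    ax.set_xlabel("MST edge rank")
    ax.set_ylabel(r"$\sqrt{d}$")
    ax.legend()
    return ax
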