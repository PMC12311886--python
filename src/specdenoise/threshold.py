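"""Data-dependent selection of the optimal noise cutoff.

A stricter intensity cutoff removes more background — but past a point it
also removes structurally explainable (informative) ions and makes related
compounds' spectra indistinguishable, collapsing the molecular network.
The workflow quantifies both costs across a cutoff sweep (0–10% of the
base-peak intensity):

* the fraction of explained ions removed (pooled over all spectra), which
  rises with the cutoff, and
* M(d_5%), the median of the lowest fifth percentile of MST distances,
  which falls toward zero as the network collapses.

Normalizing M(d_5%) by its value at cutoff 0 puts both quantities on a
[0, 1] scale; the grid cutoff closest to the crossing of the two curves
balances explained-ion retention against network collapse. The tailored
per-spectrum filter is evaluated once alongside the sweep for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .denoise import TailoredConfig, percent_cutoff_denoise, tailored_denoise
from .network import mst, similarity_matrix
from .similarity import DEFAULT_TOLERANCE
from .spectrum import Spectrum

__all__ = [
    "SweepResult",
    "explained_removed_fraction",
    "sweep",
    "optimal_cutoff",
    "DEFAULT_CUTOFFS",
]

#: 41 grid points over 0–10% of base-peak intensity
DEFAULT_CUTOFFS = np.round(np.arange(0.0, 0.10 + 1e-12, 0.0025), 6)


@dataclass
class SweepResult:
    """Per-cutoff metrics of the denoising sweep.

    ``tailored_point`` holds (explained_removed_frac, m_d5) for the
    tailored RLM filter, evaluated once on the same spectra.
    """

    cutoffs: np.ndarray
    explained_removed_frac: np.ndarray
    m_d5: np.ndarray
    zero_counts: np.ndarray
    tailored_point: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        n = len(self.cutoffs)
        for name in ("explained_removed_frac", "m_d5", "zero_counts"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match cutoffs")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "cutoff": self.cutoffs,
            "explained_removed_frac": self.explained_removed_frac,
            "m_d5": self.m_d5,
            "zero_count": self.zero_counts,
        })
        return df


def _pooled_removed_explained(results) -> tuple[int, int]:
    removed = total = 0
    for r in results:
        if r.source.explained is None:
            raise ValueError(f"spectrum {r.source.id!r} lacks explained flags")
        total += int(r.source.explained.sum())
        removed += int((r.source.explained & ~r.keep).sum())
    return removed, total


def explained_removed_fraction(spectra: list[Spectrum], cutoff: float) -> float:
    """Fraction of explained ions removed by a percentage cutoff.

    Counts are pooled over all spectra (ion-weighted), not averaged per
    spectrum. Requires explained flags on every spectrum and at least one
    explained ion overall.
    """
    results = [percent_cutoff_denoise(s, cutoff) for s in spectra]
    removed, total = _pooled_removed_explained(results)
    if total == 0:
        raise ValueError("no explained ions present in the collection")
    return removed / total


def sweep(
    spectra: list[Spectrum],
    cutoffs: np.ndarray | None = None,
    tol: float = DEFAULT_TOLERANCE,
    tailored_cfg: TailoredConfig | None = None,
    include_tailored: bool = True,
) -> SweepResult:
    """Run the cutoff sweep: denoise, rebuild the network, measure collapse.

    For each cutoff all spectra are denoised, the similarity matrix and MST
    recomputed, and M(d_5%), the zero-distance count and the pooled
    explained-ion removal recorded. The tailored filter is evaluated once
    and reported as ``tailored_point``.
    """
    if len(spectra) < 3:
        raise ValueError("sweep requires at least 3 spectra")
    cutoffs = DEFAULT_CUTOFFS if cutoffs is None else np.asarray(cutoffs, dtype=float)
    if len(cutoffs) == 0:
        raise ValueError("empty cutoff grid")

    erf, md5, zeros = [], [], []
    for c in cutoffs:
        results = [percent_cutoff_denoise(s, float(c)) for s in spectra]
        removed, total = _pooled_removed_explained(results)
        if total == 0:
            raise ValueError("no explained ions present in the collection")
        erf.append(removed / total)
        tree = mst(similarity_matrix([r.spectrum for r in results], tol=tol))
        md5.append(tree.m_d5)
        zeros.append(tree.zero_count)

    tailored_point = None
    if include_tailored:
        results = [tailored_denoise(s, tailored_cfg) for s in spectra]
        removed, total = _pooled_removed_explained(results)
        tree = mst(similarity_matrix([r.spectrum for r in results], tol=tol))
        tailored_point = (removed / total, tree.m_d5)

    return SweepResult(
        cutoffs=cutoffs,
        explained_removed_frac=np.array(erf),
        m_d5=np.array(md5),
        zero_counts=np.array(zeros, dtype=int),
        tailored_point=tailored_point,
    )


def optimal_cutoff(r: SweepResult, normalization: str = "first") -> float:
    """Grid cutoff closest to the crossing of the two sweep curves.

    M(d_5%) is normalized to its cutoff-0 value (``"first"``, so it starts
    at 1 and decreases) or min–max rescaled (``"minmax"``); the explained
    removal curve is already in [0, 1] and increasing. The returned cutoff
    minimizes the absolute gap between the two normalized curves; ties go
    to the smaller cutoff.
    """
    if len(r.cutoffs) < 3:
        raise ValueError("optimal_cutoff requires a sweep over at least 3 cutoffs")
    if not r.m_d5[0] > 0:
        raise ValueError("network already collapsed at zero cutoff (m_d5[0] = 0)")
    if normalization == "first":
        norm = r.m_d5 / r.m_d5[0]
    elif normalization == "minmax":
        span = r.m_d5.max() - r.m_d5.min()
        norm = (r.m_d5 - r.m_d5.min()) / span if span > 0 else np.ones_like(r.m_d5)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    gap = np.abs(norm - r.explained_removed_frac)
    return float(r.cutoffs[int(np.argmin(gap))])
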