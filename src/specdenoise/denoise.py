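"""Noise management for individual MS/MS spectra.

Three procedures are provided:

``tailored_denoise``
    A data-dependent filter relying only on peak intensities. Background
    ions (e.g. electronic noise) have intensities drawn from a roughly
    uniform distribution, so when ions are ordered by increasing intensity
    the background forms a straight line, while true fragment ions deviate
    upward from it. A robust linear model (RLM) fitted to the lowest 75% of
    intensity-ordered ions estimates that background trend; ions exceeding
    the trend line by more than 3 residual standard deviations are declared
    signal, and the spectrum is cut at the least intense such ion. If no ion
    exceeds the boundary the spectrum is kept unchanged.

``percent_cutoff_denoise``
    The conventional absolute cutoff: remove ions below a fixed percentage
    of the base-peak intensity.

``consensus_spectrum``
    Merge replicate scans of the same compound, retaining ion groups present
    in at least a minimum fraction of the scans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Sequence

import numpy as np
import statsmodels.api as sm

from .spectrum import Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "DenoiseMethod",
    "DenoiseResult",
    "TailoredConfig",
    "tailored_denoise",
    "percent_cutoff_denoise",
    "consensus_spectrum",
]


class DenoiseMethod(str, Enum):
    TAILORED = "tailored"
    PERCENT_CUTOFF = "percent_cutoff"
    CONSENSUS = "consensus"


@dataclass
class DenoiseResult:
    """Outcome of a single-spectrum denoising step.

    ``keep`` is a boolean mask over the source peaks; ``threshold_intensity``
    is the intensity cut actually applied (0 when no peak was removed).
    """

    source: Spectrum
    keep: np.ndarray
    threshold_intensity: float
    method: DenoiseMethod
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if len(self.keep) != len(self.source):
            raise ValueError("keep mask length mismatch")
        if self.threshold_intensity < 0:
            raise ValueError("threshold_intensity must be nonnegative")

    @property
    def spectrum(self) -> Spectrum:
        """The denoised spectrum (kept peaks only, annotations preserved)."""
        return self.source.subset(self.keep)

    @property
    def n_removed(self) -> int:
        return int((~self.keep).sum())


@dataclass(frozen=True)
class TailoredConfig:
    """Parameters of the tailored RLM filter.

    fit_quantile : fraction of intensity-ordered ions used to fit the
        background trend (default 0.75, i.e. the lowest 75th percentile).
    k_sd : boundary height in residual standard deviations above the trend
        line (default 3).
    sd_on_all : compute the residual SD over all peaks instead of the fitted
        subset only (default False).
    cut_at_last_exceeding : cut at the *most* intense boundary-exceeding ion
        instead of the least intense one. With increasing-intensity ranks a
        literal reading of "the last-ranked exceeding ion" would be the most
        intense one, which removes nearly the whole spectrum; the default
        cuts at the least intense exceeding ion so that all of the
        high-intensity tail is retained.
    """

    fit_quantile: float = 0.75
    k_sd: float = 3.0
    sd_on_all: bool = False
    cut_at_last_exceeding: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.fit_quantile <= 1:
            raise ValueError("fit_quantile must be in (0, 1]")
        if not self.k_sd > 0:
            raise ValueError("k_sd must be positive")


def _fit_background_line(ranks: np.ndarray, values: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Robust straight-line fit (Huber M-estimator) of intensity on rank.

    Returns (intercept, slope, residuals). Falls back to OLS when the robust
    fit cannot be computed (e.g. zero residual scale on degenerate data).
    """
    X = sm.add_constant(ranks.astype(float))
    if np.ptp(values) == 0:
        # flat spectrum: the trend is the constant itself, residuals all zero
        return float(values[0]), 0.0, np.zeros_like(values)
    try:
        fit = sm.RLM(values, X, M=sm.robust.norms.HuberT()).fit()
        if not np.all(np.isfinite(fit.params)):
            raise ValueError("non-finite RLM coefficients")
        a, b = fit.params
        return float(a), float(b), values - (a + b * ranks)
    except Exception as exc:  # pragma: no cover - rare degenerate inputs
        logger.warning("RLM fit failed (%s); falling back to OLS", exc)
        fit = sm.OLS(values, X).fit()
        a, b = fit.params
        return float(a), float(b), values - (a + b * ranks)


def tailored_denoise(s: Spectrum, cfg: TailoredConfig | None = None) -> DenoiseResult:
    """Apply the tailored RLM noise filter to one spectrum.

    Steps: (1) order ions by increasing intensity (ties broken by ascending
    m/z) and assign ranks 1..N; (2) fit a robust linear model intensity ~
    rank over ranks 1..ceil(fit_quantile*N); (3) take the SD of the RLM
    residuals over the fitted subset; (4) the upper boundary at rank r is
    trend(r) + k_sd*SD; (5) if no ion exceeds its boundary the spectrum is
    returned unchanged, otherwise the threshold is the minimum intensity
    among boundary-exceeding ions and every ion with intensity >= threshold
    is kept.

    Spectra with fewer than 4 peaks are returned unchanged with a warning:
    a line fit to fewer points is meaningless.
    """
    cfg = cfg or TailoredConfig()
    n = len(s)
    if not np.all(np.isfinite(s.intensity)):
        raise ValueError(f"spectrum {s.id!r}: non-finite intensities")
    params = {"fit_quantile": cfg.fit_quantile, "k_sd": cfg.k_sd}
    if n < 4:
        logger.warning("spectrum %r has %d < 4 peaks: returned unchanged", s.id, n)
        return DenoiseResult(s, np.ones(n, bool), 0.0, DenoiseMethod.TAILORED, params)

    order = np.lexsort((s.mz, s.intensity))  # increasing intensity, m/z breaks ties
    ordered = s.intensity[order]
    ranks = np.arange(1, n + 1, dtype=float)

    m = int(np.ceil(cfg.fit_quantile * n))
    a, b, resid = _fit_background_line(ranks[:m], ordered[:m])
    if cfg.sd_on_all:
        resid = ordered - (a + b * ranks)
    sd = float(np.std(resid, ddof=1)) if len(resid) > 1 else 0.0

    boundary = a + b * ranks + cfg.k_sd * sd
    # relative tolerance guards against spurious exceedance when the
    # background is exactly linear and the residual SD underflows
    exceeds = ordered > boundary + 1e-9 * ordered[-1]
    if not exceeds.any():
        # all ions within the boundary: spectrum kept unchanged
        return DenoiseResult(s, np.ones(n, bool), 0.0, DenoiseMethod.TAILORED, params)

    pick = ordered[exceeds].max() if cfg.cut_at_last_exceeding else ordered[exceeds].min()
    threshold = float(pick)
    keep = s.intensity >= threshold
    return DenoiseResult(s, keep, threshold, DenoiseMethod.TAILORED, params)


def percent_cutoff_denoise(s: Spectrum, pct: float) -> DenoiseResult:
    """Remove ions strictly below ``pct`` of the base-peak intensity.

    ``pct`` is a fraction in [0, 1] (0.05 = a 5% cutoff); 0 keeps every
    peak. A peak exactly at the threshold is kept.
    """
    if not 0 <= pct <= 1:
        raise ValueError(f"pct must be in [0, 1], got {pct}")
    if len(s) == 0:
        raise ValueError("cannot denoise an empty spectrum")
    threshold = pct * s.base_peak_intensity
    keep = s.intensity >= threshold
    return DenoiseResult(s, keep, float(threshold), DenoiseMethod.PERCENT_CUTOFF,
                         {"pct": pct})


def consensus_spectrum(
    spectra: Sequence[Spectrum],
    min_presence: float = 0.7,
    min_n: int = 3,
    mz_tol: float = 0.01,
) -> Spectrum:
    """Merge replicate scans of one compound into a consensus spectrum.

    Peaks from all scans are pooled and grouped by single-linkage on the
    sorted m/z axis (a gap larger than ``mz_tol`` starts a new group). A
    group is retained when it contains peaks from at least ``min_presence``
    of the scans; its consensus m/z is the intensity-weighted mean and its
    intensity the mean of member intensities. The consensus precursor m/z is
    the mean of the inputs.

    Requires at least ``min_n`` scans (the condition is not always met in
    real data sets — this is an error, not a silent pass-through), matching
    polarity and precursor m/z within ``mz_tol``.
    """
    spectra = list(spectra)
    if len(spectra) < min_n:
        raise ValueError(f"consensus requires at least {min_n} spectra, got {len(spectra)}")
    if len({s.polarity for s in spectra}) != 1:
        raise ValueError("consensus requires a single polarity")
    precursors = np.array([s.precursor_mz for s in spectra])
    if precursors.max() - precursors.min() > mz_tol:
        raise ValueError("precursor m/z spread exceeds mz_tol: not replicates of one compound")

    pooled_mz = np.concatenate([s.mz for s in spectra])
    pooled_int = np.concatenate([s.intensity for s in spectra])
    pooled_src = np.concatenate([np.full(len(s), i) for i, s in enumerate(spectra)])
    order = np.argsort(pooled_mz, kind="stable")
    pooled_mz, pooled_int, pooled_src = pooled_mz[order], pooled_int[order], pooled_src[order]

    # single-linkage groups: split where consecutive sorted m/z gap > tol
    breaks = np.nonzero(np.diff(pooled_mz) > mz_tol)[0] + 1
    group_edges = np.concatenate([[0], breaks, [len(pooled_mz)]])

    need = min_presence * len(spectra)
    cons_mz, cons_int = [], []
    for lo, hi in zip(group_edges[:-1], group_edges[1:]):
        presence = len(np.unique(pooled_src[lo:hi]))
        if presence < need:
            continue
        weights = pooled_int[lo:hi]
        cons_mz.append(float(np.average(pooled_mz[lo:hi], weights=weights))
                       if weights.sum() > 0 else float(np.mean(pooled_mz[lo:hi])))
        cons_int.append(float(np.mean(weights)))

    cons_mz = np.asarray(cons_mz)
    cons_int = np.asarray(cons_int)
    # group means of disjoint sorted intervals are nondecreasing; enforce strictness
    if len(cons_mz) > 1 and np.any(np.diff(cons_mz) <= 0):  # pragma: no cover
        keep = np.concatenate([[True], np.diff(cons_mz) > 0])
        cons_mz, cons_int = cons_mz[keep], cons_int[keep]
    return Spectrum(
        id=f"consensus({spectra[0].id})",
        precursor_mz=float(precursors.mean()),
        polarity=spectra[0].polarity,
        mz=cons_mz,
        intensity=cons_int,
        metadata={"method": DenoiseMethod.CONSENSUS.value,
                  "n_spectra": len(spectra), "min_presence": min_presence},
    )
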