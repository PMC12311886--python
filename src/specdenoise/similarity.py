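"""GNPS-style (modified-cosine) spectral similarity.

The score between two MS/MS spectra is a normalized dot product over peak
pairs matched either *directly* (equal fragment m/z within tolerance) or by
*neutral loss* (fragment m/z difference equal to the precursor m/z
difference within tolerance — the same neutral fragment lost from two
related precursors). Intensities are square-root transformed and each
spectrum normalized to unit Euclidean norm, so the score lies in [0, 1]
with 1 for identical spectra. Each peak may participate in at most one
matched pair; the pairing is chosen greedily by descending pair weight.

Because the normalization denominator includes *all* peaks, adding ions
that match nothing in the partner spectrum strictly lowers the score — this
is the mechanism by which low-intensity noise degrades library matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .spectrum import Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "MatchKind",
    "PeakMatchSet",
    "join_peaks_gnps",
    "gnps_score",
    "low_intensity_sum",
]

DEFAULT_TOLERANCE = 0.01  # Da


class MatchKind(str, Enum):
    DIRECT = "direct"
    SHIFTED = "shifted"


@dataclass
class PeakMatchSet:
    """Candidate matched peak pairs between two spectra.

    ``pairs`` holds (index_in_a, index_in_b, kind, weight); a peak may occur
    in several candidate pairs. Weights are products of the two peaks'
    scaled, normalized intensities.
    """

    pairs: list[tuple[int, int, MatchKind, float]]
    tolerance: float

    def __len__(self) -> int:
        return len(self.pairs)


def _scaled_unit_intensities(s: Spectrum, sqrt_transform: bool) -> np.ndarray:
    v = np.sqrt(s.intensity) if sqrt_transform else s.intensity.astype(float)
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def _candidate_indices(mz_a: np.ndarray, mz_b: np.ndarray, offset: float,
                       tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i, j) with |mz_a[i] - (mz_b[j] + offset)| <= tol.

    Both arrays are sorted, so a two-pointer searchsorted sweep suffices.
    """
    shifted = mz_b + offset
    lo = np.searchsorted(shifted, mz_a - tol, side="left")
    hi = np.searchsorted(shifted, mz_a + tol, side="right")
    counts = hi - lo
    ia = np.repeat(np.arange(len(mz_a)), counts)
    jb = np.concatenate([np.arange(l, h) for l, h in zip(lo, hi)]) if counts.sum() else \
        np.empty(0, dtype=int)
    return ia, jb


def join_peaks_gnps(
    a: Spectrum,
    b: Spectrum,
    tol: float = DEFAULT_TOLERANCE,
    sqrt_transform: bool = True,
) -> PeakMatchSet:
    """Enumerate candidate peak pairs between two spectra.

    Direct pairs satisfy |mz_a - mz_b| <= tol; shifted (neutral-loss) pairs
    satisfy |(mz_a - mz_b) - (prec_a - prec_b)| <= tol. A pair qualifying
    both ways is reported once, as direct. Pair weight is the product of the
    two peaks' square-root-transformed, unit-normalized intensities.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("join_peaks_gnps requires nonempty spectra")
    na = _scaled_unit_intensities(a, sqrt_transform)
    nb = _scaled_unit_intensities(b, sqrt_transform)
    shift = a.precursor_mz - b.precursor_mz

    pairs: list[tuple[int, int, MatchKind, float]] = []
    seen: set[tuple[int, int]] = set()
    ia, jb = _candidate_indices(a.mz, b.mz, 0.0, tol)
    for i, j in zip(ia, jb):
        pairs.append((int(i), int(j), MatchKind.DIRECT, float(na[i] * nb[j])))
        seen.add((int(i), int(j)))
    ia, jb = _candidate_indices(a.mz, b.mz, shift, tol)
    for i, j in zip(ia, jb):
        if (int(i), int(j)) not in seen:
            pairs.append((int(i), int(j), MatchKind.SHIFTED, float(na[i] * nb[j])))
    return PeakMatchSet(pairs=pairs, tolerance=tol)


def _greedy_assignment(pairs, mz_a, mz_b) -> float:
    """One-to-one selection by descending weight.

    Weight ties are broken on the *sorted* m/z pair (smaller first) so the
    selection — and hence the score — is invariant under swapping the two
    spectra.
    """
    def key(p):
        i, j, _, w = p
        lo, hi = sorted((mz_a[i], mz_b[j]))
        return (-w, lo, hi)

    used_a: set[int] = set()
    used_b: set[int] = set()
    total = 0.0
    for i, j, _, w in sorted(pairs, key=key):
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        total += w
    return total


def _optimal_assignment(pairs, n_a, n_b) -> float:
    """Maximum-weight one-to-one assignment over the candidate pairs."""
    from scipy.optimize import linear_sum_assignment

    w = np.zeros((n_a, n_b))
    for i, j, _, wij in pairs:
        w[i, j] = max(w[i, j], wij)
    rows, cols = linear_sum_assignment(w, maximize=True)
    return float(w[rows, cols].sum())


def gnps_score(
    a: Spectrum,
    b: Spectrum,
    tol: float = DEFAULT_TOLERANCE,
    sqrt_transform: bool = True,
    assignment: str = "greedy",
) -> float:
    """GNPS-style modified-cosine similarity in [0, 1].

    ``assignment`` selects how multiply-matched peaks are resolved:
    ``"greedy"`` (descending-weight selection, the conventional choice) or
    ``"optimal"`` (maximum-weight bipartite assignment).
    """
    if len(a) == 0 or len(b) == 0:
        logger.warning("gnps_score on empty spectrum: score 0")
        return 0.0
    matches = join_peaks_gnps(a, b, tol=tol, sqrt_transform=sqrt_transform)
    if not matches.pairs:
        return 0.0
    if assignment == "greedy":
        score = _greedy_assignment(matches.pairs, a.mz, b.mz)
    elif assignment == "optimal":
        score = _optimal_assignment(matches.pairs, len(a), len(b))
    else:
        raise ValueError(f"unknown assignment {assignment!r}")
    return float(min(max(score, 0.0), 1.0))


def low_intensity_sum(s: Spectrum, frac: float = 0.05) -> float:
    """Summed relative intensity of low-intensity ions.

    Low-intensity ions are those strictly below ``frac`` of the base-peak
    intensity; their intensities, normalized so the base peak is 1, are
    summed. A large value marks a spectrum dominated by near-baseline ions
    and predicts poor similarity scores against replicates.
    """
    if len(s) == 0:
        raise ValueError("empty spectrum")
    base = s.base_peak_intensity
    if base == 0:
        return 0.0
    rel = s.intensity / base
    return float(rel[rel < frac].sum())
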