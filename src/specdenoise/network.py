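"""Molecular networks and minimum-spanning-tree diagnostics.

A molecular network (MN) has one node per MS/MS spectrum and an edge for
every pair whose similarity exceeds a threshold; with a zero threshold every
strictly positive similarity becomes an edge, avoiding any bias from
threshold selection. Converting similarities s to distances d = 1 - s and
taking the minimum spanning tree (MST) of the complete graph yields a
compact summary of the network's structure: the sorted MST edge distances
show how tightly related the closest spectra are, the number of exact zeros
counts indistinguishable spectrum pairs, and M(d_5%) — the median of the
lowest fifth percentile of MST distances — tracks the onset of network
collapse (distinct compounds becoming indistinguishable after aggressive
denoising).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .similarity import DEFAULT_TOLERANCE, gnps_score
from .spectrum import Spectrum

__all__ = [
    "SimilarityMatrix",
    "MSTResult",
    "similarity_matrix",
    "network_edges",
    "mst",
    "compute_m_d5",
    "ordered_distance_curve",
]

ZERO_DISTANCE_EPS = 1e-12  # absorbs float noise from scores clamped to 1


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise similarity scores with spectrum ids."""

    ids: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.ids)
        if self.S.shape != (n, n):
            raise ValueError(f"matrix shape {self.S.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise ValueError("spectrum ids must be unique")
        if not np.allclose(self.S, self.S.T):
            raise ValueError("similarity matrix must be symmetric")
        if self.S.min() < -1e-12 or self.S.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")
        if not np.allclose(np.diag(self.S), 1.0):
            raise ValueError("similarity matrix must have unit diagonal")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.ids, columns=self.ids)


@dataclass
class MSTResult:
    """Minimum spanning tree of the distance graph d = 1 - S.

    ``edges`` are the n-1 tree edges; ``sorted_distances`` their
    nondecreasing distance multiset; ``zero_count`` the number of exact-zero
    distances; ``m_d5`` the median of the lowest fifth percentile.
    """

    ids: list[str]
    edges: list[tuple[str, str, float]]
    sorted_distances: np.ndarray
    zero_count: int
    m_d5: float

    @property
    def total_weight(self) -> float:
        return float(self.sorted_distances.sum())


def similarity_matrix(
    spectra: Sequence[Spectrum],
    tol: float = DEFAULT_TOLERANCE,
    **score_kwargs,
) -> SimilarityMatrix:
    """All-pairs GNPS scores over a single-polarity spectrum collection.

    Networks are built per ionization mode; mixing polarities is an error.
    The diagonal is forced to exactly 1.
    """
    spectra = list(spectra)
    if len({s.polarity for s in spectra}) > 1:
        raise ValueError("similarity_matrix requires a single polarity; "
                         "build networks per ionization mode")
    n = len(spectra)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = gnps_score(spectra[i], spectra[j], tol=tol, **score_kwargs)
    return SimilarityMatrix(ids=[s.id for s in spectra], S=S)


def network_edges(
    M: SimilarityMatrix, threshold: float = 0.0
) -> list[tuple[str, str, float]]:
    """Edge list of the molecular network: pairs with score > threshold.

    The default zero threshold keeps every strictly positive similarity
    ("zero-thresholding"), leaving edge pruning to downstream analysis.
    """
    out = []
    for i in range(M.n):
        for j in range(i + 1, M.n):
            if M.S[i, j] > threshold:
                out.append((M.ids[i], M.ids[j], float(M.S[i, j])))
    return out


def mst(M: SimilarityMatrix) -> MSTResult:
    """Minimum spanning tree of the complete distance graph d = 1 - S.

    The MST is computed on the complete graph (zero-similarity pairs enter
    at distance 1) so the tree always spans every spectrum. Kruskal's
    algorithm with edges pre-sorted lexicographically by id pair gives a
    deterministic tree under ties; the sorted distance multiset is unique
    regardless (MSTs of a graph share their weight multiset).
    """
    if M.n < 2:
        raise ValueError("MST requires at least 2 spectra")
    order = np.argsort(M.ids)
    g = nx.Graph()
    for a in range(M.n):
        for b in range(a + 1, M.n):
            i, j = int(order[a]), int(order[b])
            g.add_edge(M.ids[i], M.ids[j], weight=float(1.0 - M.S[i, j]))
    tree = nx.minimum_spanning_tree(g, weight="weight", algorithm="kruskal")
    edges = sorted(
        (min(u, v), max(u, v), float(d["weight"])) for u, v, d in tree.edges(data=True)
    )
    dist = np.sort(np.array([e[2] for e in edges]))
    return MSTResult(
        ids=list(M.ids),
        edges=edges,
        sorted_distances=dist,
        zero_count=int((dist < ZERO_DISTANCE_EPS).sum()),
        m_d5=compute_m_d5(dist),
    )


def compute_m_d5(sorted_distances: np.ndarray, quantile: float = 0.05) -> float:
    """Median of the lowest ``quantile`` fraction of a sorted distance array.

    The subset size is ceil(quantile * len); the median uses the midpoint
    convention for even counts. As this statistic approaches zero a
    significant portion of the network has collapsed.
    """
    d = np.asarray(sorted_distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance array")
    if np.any(np.diff(d) < 0):
        raise ValueError("distances must be sorted nondecreasing")
    k = int(np.ceil(quantile * d.size))
    return float(np.median(d[:k]))


def ordered_distance_curve(results: Mapping[str, MSTResult]) -> pd.DataFrame:
    """Long-format table of ordered MST distances for several conditions.

    One row per (label, rank): the rank-th smallest MST distance under that
    denoising condition, with its square root (square-root scaling makes
    low-magnitude differences near zero visible when plotted). All results
    must be over the same spectrum set.
    """
    node_sets = {frozenset(r.ids) for r in results.values()}
    if len(node_sets) > 1:
        raise ValueError("ordered_distance_curve requires MSTs over the same spectrum set")
    rows = []
    for label, r in results.items():
        for rank, d in enumerate(r.sorted_distances, start=1):
            rows.append((label, rank, float(d), float(np.sqrt(d))))
    return pd.DataFrame(rows, columns=["label", "rank", "distance", "sqrt_distance"])
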