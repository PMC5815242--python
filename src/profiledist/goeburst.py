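"""goeBURST minimum spanning forest over the threshold graph.

Given the truncated distance matrix (all pairs at Hamming distance <= k),
goeBURST links profiles greedily in Kruskal fashion over the graph
G = (P, {(u, v) : H(u, v) <= k}).  Its underlying model: a founder
genotype expands clonally and diversifies, so a founder should have many
single-locus variants (SLVs); ties between links at equal distance are
broken in favour of endpoints with more SLVs, then DLVs, TLVs, higher
isolate frequency, and finally lower input rank.  The problem is a graphic
matroid, so the greedy forest is optimal and, under the strict total order
on links, unique; components are the clonal complexes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import DisjointSet
from sklearn.base import BaseEstimator, ClusterMixin

from .pairs import closest_pairs

__all__ = [
    "LVProfile",
    "Forest",
    "lv_counts",
    "edge_sort_key",
    "edge_less",
    "goeburst_forest",
    "GoeBURST",
]


@dataclass(frozen=True)
class LVProfile:
    """Per-profile locus-variant context used by the link comparator."""

    slv: int  # neighbours at Hamming distance exactly 1
    dlv: int  # ... exactly 2
    tlv: int  # ... exactly 3
    freq: int  # isolate (observation) frequency
    id_rank: int  # input-order ordinal; the final tie-breaker


def lv_counts(pairs, d: int, freq=None) -> list[LVProfile]:
    """SLV/DLV/TLV counts per profile from a truncated distance matrix.

    Counts at distances above the matrix's k are structurally zero (for
    k < 3 the missing levels cannot be observed; compute the matrix at
    max(k, 3) if full locus-variant tie-breaking is wanted).
    """
    pair_set = pairs.pairs if hasattr(pairs, "pairs") else pairs
    counts = np.zeros((d, 3), dtype=np.int64)
    for i, j, h in pair_set:
        if 1 <= h <= 3:
            counts[i, h - 1] += 1
            counts[j, h - 1] += 1
    if freq is None:
        freq = np.ones(d, dtype=np.int64)
    return [
        LVProfile(slv=int(c[0]), dlv=int(c[1]), tlv=int(c[2]),
                  freq=int(freq[r]), id_rank=r)
        for r, c in enumerate(counts)
    ]


def edge_sort_key(edge: tuple[int, int, int], lv: list[LVProfile]) -> tuple:
    """Sort key realising the goeBURST total order on links.

    Lexicographic: distance ascending; then, for SLV, DLV, TLV in turn, the
    larger endpoint count descending then the smaller descending; then the
    larger and smaller endpoint frequencies descending; finally the larger
    then smaller endpoint input ranks ascending (which makes the order
    strict: no two distinct edges share both ranks).
    """
    i, j, h = edge
    a, b = lv[i], lv[j]
    return (
        h,
        -max(a.slv, b.slv), -min(a.slv, b.slv),
        -max(a.dlv, b.dlv), -min(a.dlv, b.dlv),
        -max(a.tlv, b.tlv), -min(a.tlv, b.tlv),
        -max(a.freq, b.freq), -min(a.freq, b.freq),
        max(a.id_rank, b.id_rank), min(a.id_rank, b.id_rank),
    )


def edge_less(e1, e2, lv: list[LVProfile]) -> bool:
    """Strict total order on links: does e1 precede e2?"""
    return edge_sort_key(e1, lv) < edge_sort_key(e2, lv)


@dataclass
class Forest:
    """goeBURST minimum spanning forest."""

    edges: list[tuple[int, int, int]]  # accepted links, in acceptance order
    labels: np.ndarray  # component label per profile row
    n_components: int
    ids: list[str]
    lv: list[LVProfile]


def goeburst_forest(profiles, k: int, lv_k: int | None = None) -> Forest:
    """The goeBURST minimum spanning forest of the threshold graph at k.

    Parameters
    ----------
    profiles : ProfileSet or (d, m) integer array
    k : int
        Maximum Hamming distance defining the graph, ``0 < k < m``.
    lv_k : int, optional
        Threshold for the auxiliary pass that computes SLV/DLV/TLV
        tie-break counts (useful as ``max(k, 3)`` when ``k < 3``); defaults
        to reusing the k-pass.
    """
    matrix = profiles.matrix if hasattr(profiles, "matrix") else np.asarray(profiles)
    d = matrix.shape[0]
    freq = profiles.freq if hasattr(profiles, "freq") else None
    td = closest_pairs(profiles, k)

    if lv_k is not None and lv_k != k:
        lv_src = closest_pairs(profiles, lv_k)
    else:
        lv_src = td
    lv = lv_counts(lv_src, d, freq=freq)

    edges = sorted(td.pairs, key=lambda e: edge_sort_key(e, lv))
    ds = DisjointSet(range(d))
    accepted: list[tuple[int, int, int]] = []
    for i, j, h in edges:
        if ds.merge(i, j):
            accepted.append((i, j, h))

    labels = np.empty(d, dtype=np.int64)
    root_label: dict[int, int] = {}
    for r in range(d):
        root = ds[r]
        labels[r] = root_label.setdefault(root, len(root_label))
    return Forest(
        edges=accepted,
        labels=labels,
        n_components=len(root_label),
        ids=td.ids,
        lv=lv,
    )


class GoeBURST(ClusterMixin, BaseEstimator):
    """goeBURST clonal-complex inference as a clustering estimator.

    ``fit(X)`` computes the truncated distance matrix at threshold ``k``,
    builds the minimum spanning forest under the goeBURST total order, and
    labels each profile with its clonal complex (connected component).

    Parameters
    ----------
    k : int
        Maximum Hamming distance for linking, ``0 < k < m``.
    lv_k : int, optional
        Separate threshold for the SLV/DLV/TLV tie-break pass.

    Attributes
    ----------
    edges_ : list of (i, j, h)
        Accepted forest links in acceptance order.
    labels_ : ndarray of shape (d,)
        Clonal-complex label per profile.
    n_components_ : int
    lv_counts_ : list of LVProfile
    """

    def __init__(self, k: int = 1, lv_k: int | None = None):
        self.k = k
        self.lv_k = lv_k

    def fit(self, X, y=None, sample_weight=None):
        matrix = X.matrix if hasattr(X, "matrix") else np.asarray(X)
        if sample_weight is not None:
            from .io import ProfileSet

            ids = list(X.ids) if hasattr(X, "ids") else [str(i) for i in range(len(matrix))]
            X = ProfileSet(ids=ids, matrix=matrix, freq=np.asarray(sample_weight))
        forest = goeburst_forest(X, self.k, self.lv_k)
        self.forest_ = forest
        self.edges_ = forest.edges
        self.labels_ = forest.labels
        self.n_components_ = forest.n_components
        self.lv_counts_ = forest.lv
        self.n_features_in_ = matrix.shape[1]
        return self
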