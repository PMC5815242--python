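"""k-closest queries against an indexed profile database.

Given an external profile ``u`` of the same length as the indexed set,
the blocks of ``u`` are searched in the suffix array (binary search per
block); a match must be aligned at the same block ordinal in its profile.
Candidate rows are deduplicated and verified by direct positionwise
comparison (u itself is not indexed, so letter comparison in O(m) is the
verification step).  Classification assigns the label of the closest hit,
or a "new" sentinel when nothing lies within k.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .index import ConcatIndex, build_concat_index
from .pairs import BlockScheme, _sa_interval

__all__ = ["query_profile", "classify", "intersect_hits", "ProfileNeighbors", "NEW_LABEL"]

NEW_LABEL = "new"


def query_profile(index: ConcatIndex, profiles, u, k: int) -> list[tuple[int, int]]:
    """All indexed profiles within Hamming distance k of the query ``u``.

    Parameters
    ----------
    index : ConcatIndex
        Index built over *profiles*.
    profiles : ProfileSet or (d, m) integer array
        The indexed set (used for verification).
    u : length-m integer sequence
        Query profile in the same encoding as the indexed set; symbols
        unseen at indexing time must use codes >= sigma so they never match.
    k : int
        ``0 < k < m``.

    Returns
    -------
    list of (row, distance), sorted by (distance, row).
    """
    matrix = profiles.matrix if hasattr(profiles, "matrix") else np.asarray(profiles)
    d, m = matrix.shape
    u = np.asarray(u)
    if u.shape != (m,):
        raise ValueError(f"query profile has shape {u.shape}, expected ({m},)")
    if not 0 < k < m:
        raise ValueError(f"threshold must satisfy 0 < k < m, got k={k}, m={m}")
    scheme = BlockScheme.of(m, d, k)
    L = scheme.L
    s_l = index.s.tolist()
    u_l = u.tolist()
    sa = index.sa
    candidates: set[int] = set()
    for t in range(scheme.blocks_per_profile):
        ell = t * L
        block = u_l[ell: ell + L]
        lo, hi = _sa_interval(index, s_l, block)
        for p in range(lo, hi):
            pos = int(sa[p])
            if pos % m == ell:  # must be aligned at the same block ordinal
                candidates.add(pos // m)
    hits = []
    for row in candidates:
        h = int(np.count_nonzero(matrix[row] != u))
        if h <= k:
            hits.append((row, h))
    hits.sort(key=lambda rh: (rh[1], rh[0]))
    return hits


def classify(index: ConcatIndex, profiles, u, k: int, labels, new_label: str = NEW_LABEL) -> str:
    """Label of the closest profile within k (ties: lower row), else "new"."""
    hits = query_profile(index, profiles, u, k)
    if not hits:
        return new_label
    row, _h = hits[0]
    return labels[row]


def intersect_hits(hit_lists: list[list[tuple[int, int]]]) -> list[int]:
    """Rows present in every per-query hit list (multi-strain intersection)."""
    if not hit_lists:
        return []
    common = set.intersection(*({row for row, _ in hits} for hits in hit_lists))
    return sorted(common)


class ProfileNeighbors(BaseEstimator):
    """Radius-bounded Hamming neighbour search / classifier over an indexed
    profile database.

    ``fit(X, y)`` indexes the database (labels ``y`` optional, needed only
    for :meth:`predict`).  ``query(u)`` returns all rows within ``k`` of a
    single profile; ``predict(U)`` classifies each row of ``U`` with the
    label of its closest hit, or ``new_label`` when none lies within k.

    The index is immutable once fitted: adding profiles means re-fitting.
    """

    def __init__(self, k: int = 1, new_label: str = NEW_LABEL):
        self.k = k
        self.new_label = new_label

    def fit(self, X, y=None):
        matrix = X.matrix if hasattr(X, "matrix") else np.asarray(X)
        if not 0 < self.k < matrix.shape[1]:
            raise ValueError(
                f"threshold must satisfy 0 < k < m, got k={self.k}, m={matrix.shape[1]}"
            )
        self._X = X
        self.matrix_ = matrix
        self.index_ = build_concat_index(matrix)
        self.labels_fit_ = None if y is None else list(y)
        self.n_features_in_ = matrix.shape[1]
        return self

    def query(self, u) -> list[tuple[int, int]]:
        check_is_fitted(self, "index_")
        return query_profile(self.index_, self.matrix_, u, self.k)

    def predict(self, U):
        check_is_fitted(self, "index_")
        if self.labels_fit_ is None:
            raise ValueError("predict requires labels y at fit time")
        U = np.asarray(U)
        if U.ndim == 1:
            U = U[None, :]
        out = []
        for u in U:
            out.append(
                classify(self.index_, self.matrix_, u, self.k, self.labels_fit_,
                         new_label=self.new_label)
            )
        return np.asarray(out, dtype=object)
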