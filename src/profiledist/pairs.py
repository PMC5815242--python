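"""All profile pairs within Hamming distance k, in average-case linear time.

The pigeonhole filter: split each length-``m`` profile into non-overlapping
blocks of length ``L = floor(m / (k+1))``.  Two profiles within Hamming
distance ``k`` must agree verbatim on at least one aligned block, so it
suffices to enumerate pairs of profiles sharing an aligned block (via the
suffix-array index) and verify only those.  Verification uses the kangaroo
method: repeated longest-common-extension jumps, one mismatch per jump,
O(k) per candidate pair.

Two enumeration strategies are provided — a single scan over the LCP array
(clusters of adjacent suffixes with LCP >= L) and per-block binary search
over the suffix array — plus the naive all-pairs scan as the oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from sklearn.base import BaseEstimator

from .index import ConcatIndex, build_concat_index, lce

__all__ = [
    "BlockScheme",
    "TruncatedDistance",
    "make_block_scheme",
    "hamming_capped",
    "candidates_lcp",
    "candidates_binary_search",
    "closest_pairs",
    "naive_pairs",
    "ClosePairs",
]

STRATEGIES = ("lcp", "binary", "naive")


@dataclass(frozen=True)
class BlockScheme:
    """Pigeonhole block partition for threshold ``k`` on length-``m`` profiles."""

    k: int
    L: int
    blocks_per_profile: int
    B: int

    @classmethod
    def of(cls, m: int, d: int, k: int) -> "BlockScheme":
        if not 0 < k < m:
            raise ValueError(f"threshold must satisfy 0 < k < m, got k={k}, m={m}")
        L = m // (k + 1)
        bpp = m // L
        return cls(k=k, L=L, blocks_per_profile=bpp, B=d * bpp)


def make_block_scheme(m: int, k: int, d: int = 1) -> BlockScheme:
    """Block length ``L = floor(m/(k+1))`` and block counts for threshold k."""
    return BlockScheme.of(m, d, k)


@dataclass
class TruncatedDistance:
    """The pairs (i, j, H) with i < j and H(i, j) <= k — a truncated
    distance matrix, sufficient for goeBURST-style inference."""

    pairs: set[tuple[int, int, int]]
    k: int
    ids: list[str]
    n_candidates: int = 0
    n_verified: int = 0

    def to_sparse(self):
        """Distances as a symmetric COO matrix (explicit zeros kept for
        duplicate profiles are not representable; use ``pairs`` for those)."""
        from scipy import sparse

        d = len(self.ids)
        if not self.pairs:
            return sparse.coo_matrix((d, d), dtype=np.int64)
        ii, jj, hh = zip(*sorted(self.pairs))
        return sparse.coo_matrix(
            (list(hh) + list(hh), (list(ii) + list(jj), list(jj) + list(ii))),
            shape=(d, d),
            dtype=np.int64,
        )


def _hamming_lce(index: ConcatIndex, pi: int, pj: int, cap: int) -> int:
    """min(cap, H(pi, pj)) via LCE jumps, each capped at the profile end."""
    m = index.m
    base_i = pi * m
    base_j = pj * m
    off = 0
    mism = 0
    while off < m:
        e = lce(index, base_i + off, base_j + off)
        if e > m - off:  # never extend across the profile boundary
            e = m - off
        off += e
        if off >= m:
            break
        mism += 1
        if mism >= cap:
            return cap
        off += 1
    return mism


def hamming_capped(index: ConcatIndex, pi: int, pj: int, k: int) -> int:
    """min(k, H(pi, pj)) for profile rows pi, pj; exact whenever < k.

    Runs in O(k) longest-common-extension jumps (kangaroo verification),
    terminating as soon as k mismatches are seen.
    """
    d = index.d
    if not (0 <= pi < d and 0 <= pj < d):
        raise IndexError(f"profile rows ({pi}, {pj}) out of range for d={d}")
    return _hamming_lce(index, pi, pj, k)


def candidates_lcp(index: ConcatIndex, scheme: BlockScheme) -> Iterator[tuple[int, int, int]]:
    """Candidate pairs from one scan of the LCP array.

    Maximal runs of SA ranks whose adjacent LCP is >= L are exactly the
    maximal SA intervals of suffixes sharing an L-length prefix; within a
    run, aligned suffix starts with the same block ordinal t belong to
    profiles sharing that block verbatim.  Yields (i, j, t) with i < j.
    """
    L = scheme.L
    m = index.m
    # run id changes wherever adjacent LCP drops below L (lcp[0] = 0 always breaks)
    run_id = np.cumsum(index.lcp < L)
    pos = index.sa
    ell = pos % m
    keep = (ell % L == 0) & (ell + L <= m)
    rid = run_id[keep]
    t_ord = ell[keep] // L
    row = pos[keep] // m
    order = np.lexsort((row, t_ord, rid))
    rid, t_ord, row = rid[order], t_ord[order], row[order]
    n = len(rid)
    start = 0
    while start < n:
        stop = start + 1
        while stop < n and rid[stop] == rid[start] and t_ord[stop] == t_ord[start]:
            stop += 1
        if stop - start > 1:
            group = row[start:stop]
            t = int(t_ord[start])
            for a in range(len(group)):
                ga = int(group[a])
                for b in range(a + 1, len(group)):
                    gb = int(group[b])
                    if ga < gb:
                        yield ga, gb, t
                    else:
                        yield gb, ga, t
        start = stop


def _compare_suffix_block(s_l: list, n: int, pos: int, block: list) -> int:
    """Lexicographic comparison of suffix(pos) truncated to len(block) vs the
    block: -1 below, 0 if the suffix starts with the block, +1 above.  A
    suffix shorter than the block that matches to its end compares below
    (the shorter-prefix-wins suffix order)."""
    L = len(block)
    end = min(pos + L, n)
    i = pos
    j = 0
    while i < end:
        a = s_l[i]
        b = block[j]
        if a != b:
            return -1 if a < b else 1
        i += 1
        j += 1
    return 0 if j == L else -1


def _sa_interval(index: ConcatIndex, s_l: list, block: list) -> tuple[int, int]:
    """[lo, hi) interval of SA ranks whose suffixes start with *block*."""
    sa = index.sa
    n = index.n
    lo, hi = 0, n
    while lo < hi:  # first suffix >= block
        mid = (lo + hi) // 2
        if _compare_suffix_block(s_l, n, int(sa[mid]), block) < 0:
            lo = mid + 1
        else:
            hi = mid
    start = lo
    hi = n
    while lo < hi:  # first suffix > block
        mid = (lo + hi) // 2
        if _compare_suffix_block(s_l, n, int(sa[mid]), block) <= 0:
            lo = mid + 1
        else:
            hi = mid
    return start, lo


def candidates_binary_search(
    index: ConcatIndex, scheme: BlockScheme
) -> Iterator[tuple[int, int, int]]:
    """Candidate pairs by per-block binary search over the suffix array.

    For every profile row and block ordinal t, the SA interval of suffixes
    prefixed by that block is located in O(L log n); matches that are not
    aligned at the same ordinal t are discarded.  Yields (i, j, t) with
    i < j (each unordered pair may appear once per side and per shared
    block; callers deduplicate).
    """
    L = scheme.L
    m = index.m
    d = index.d
    sa = index.sa
    s_l = index.s.tolist()
    for i in range(d):
        base = i * m
        for t in range(scheme.blocks_per_profile):
            ell = t * L
            block = s_l[base + ell: base + ell + L]
            lo, hi = _sa_interval(index, s_l, block)
            for p in range(lo, hi):
                pos = int(sa[p])
                if pos % m != ell:
                    continue  # match not aligned with the initial block
                j = pos // m
                if j != i:
                    yield (i, j, t) if i < j else (j, i, t)


def naive_pairs(matrix: np.ndarray, k: int) -> set[tuple[int, int, int]]:
    """Direct all-pairs positionwise comparison — the Theta(m d^2) oracle."""
    matrix = np.asarray(matrix)
    d = matrix.shape[0]
    out: set[tuple[int, int, int]] = set()
    for i in range(d - 1):
        dist = np.count_nonzero(matrix[i + 1:] != matrix[i], axis=1)
        for off in np.flatnonzero(dist <= k):
            out.add((i, i + 1 + int(off), int(dist[off])))
    return out


def closest_pairs(profiles, k: int, strategy: str = "lcp") -> TruncatedDistance:
    """All pairs of profiles at Hamming distance <= k, with exact distances.

    Parameters
    ----------
    profiles : ProfileSet or (d, m) integer array
    k : int
        Maximum Hamming distance, ``0 < k < m``.
    strategy : {'lcp', 'binary', 'naive'}
        Candidate enumeration strategy; 'naive' is the direct all-pairs scan.
    """
    matrix = profiles.matrix if hasattr(profiles, "matrix") else np.asarray(profiles)
    ids = list(profiles.ids) if hasattr(profiles, "ids") else [str(i) for i in range(len(matrix))]
    d, m = matrix.shape
    if not 0 < k < m:
        raise ValueError(f"threshold must satisfy 0 < k < m, got k={k}, m={m}")
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")

    if strategy == "naive" or d < 2:
        pairs = naive_pairs(matrix, k) if d >= 2 else set()
        n_cand = d * (d - 1) // 2
        return TruncatedDistance(pairs=pairs, k=k, ids=ids,
                                 n_candidates=n_cand, n_verified=n_cand)

    index = build_concat_index(matrix)
    scheme = BlockScheme.of(m, d, k)
    stream = candidates_lcp(index, scheme) if strategy == "lcp" else \
        candidates_binary_search(index, scheme)

    seen: set[tuple[int, int]] = set()
    pairs: set[tuple[int, int, int]] = set()
    n_candidates = 0
    for i, j, _t in stream:
        n_candidates += 1
        key = (i, j)
        if key in seen:
            continue
        seen.add(key)
        # cap at k+1 so a result of exactly k is unambiguous (min(k+1, H) <= k iff H <= k)
        h = _hamming_lce(index, i, j, k + 1)
        if h <= k:
            pairs.add((i, j, h))
    return TruncatedDistance(pairs=pairs, k=k, ids=ids,
                             n_candidates=n_candidates, n_verified=len(seen))


class ClosePairs(BaseEstimator):
    """Radius-neighbors-style finder of all profile pairs within Hamming
    distance ``k``.

    Parameters
    ----------
    k : int
        Maximum Hamming distance (``0 < k < m``).
    strategy : {'lcp', 'binary', 'naive'}
        Candidate enumeration strategy; 'lcp' scans the LCP array once,
        'binary' binary-searches the suffix array per block, 'naive'
        compares all pairs directly.

    Attributes
    ----------
    pairs_ : set of (i, j, h)
        All pairs with ``i < j`` and exact distance ``h <= k``.
    n_candidates_ : int
        Candidate pair emissions before deduplication.
    n_verified_ : int
        Distinct candidate pairs actually verified.
    """

    def __init__(self, k: int = 1, strategy: str = "lcp"):
        self.k = k
        self.strategy = strategy

    def fit(self, X, y=None):
        result = closest_pairs(X, self.k, self.strategy)
        self.result_ = result
        self.pairs_ = result.pairs
        self.ids_ = result.ids
        self.n_candidates_ = result.n_candidates
        self.n_verified_ = result.n_verified
        self.n_features_in_ = (X.matrix if hasattr(X, "matrix") else np.asarray(X)).shape[1]
        return self

    def transform(self, X=None):
        """Return the truncated distances as a symmetric sparse matrix."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "result_")
        return self.result_.to_sparse()
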