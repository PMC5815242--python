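"""Concatenated-profile text index: suffix array, LCP array, RMQ, LCE.

The ``d`` profiles of length ``m`` are concatenated row-major into a single
integer string ``s`` of length ``n = m*d`` with no separator symbols; this
keeps ``n`` exactly ``md`` at the cost that suffix comparisons may run
across profile boundaries, so every distance computation downstream caps
its extensions at the profile end.

The suffix array is built by prefix doubling (numpy ``lexsort`` passes,
terminating as soon as all ranks are distinct, which for typing data
happens after very few rounds), the LCP array by Kasai's algorithm, and
range-minimum queries are answered by a sparse table: O(n log n)
preprocessing, O(1) per query.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConcatIndex",
    "SparseTableRMQ",
    "suffix_array",
    "lcp_array",
    "build_concat_index",
    "lce",
    "aligned",
]

_SERIAL_VERSION = 1


def suffix_array(s: np.ndarray) -> np.ndarray:
    """Suffix array of an integer sequence by prefix doubling.

    A suffix that is a proper prefix of another sorts first (positions past
    the end of ``s`` compare below every symbol).
    """
    s = np.asarray(s)
    n = len(s)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    rank = np.unique(s, return_inverse=True)[1].astype(np.int64)
    width = 1
    sa = np.argsort(rank, kind="stable")
    while rank[sa[-1]] != n - 1:
        second = np.full(n, -1, dtype=np.int64)
        second[: n - width] = rank[width:]
        sa = np.lexsort((second, rank))
        r_sa = rank[sa]
        s_sa = second[sa]
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        np.cumsum((r_sa[1:] != r_sa[:-1]) | (s_sa[1:] != s_sa[:-1]), out=changed[1:])
        rank = np.empty(n, dtype=np.int64)
        rank[sa] = changed
        width *= 2
    return sa


def lcp_array(s: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """LCP array by Kasai's algorithm: ``lcp[i]`` is the longest common
    prefix of the suffixes at SA ranks ``i-1`` and ``i``; ``lcp[0] = 0``."""
    n = len(s)
    lcp = np.zeros(n, dtype=np.int64)
    if n == 0:
        return lcp
    isa = np.empty(n, dtype=np.int64)
    isa[sa] = np.arange(n)
    s_l = s.tolist()
    sa_l = sa.tolist()
    isa_l = isa.tolist()
    out = lcp.tolist()
    h = 0
    for i in range(n):
        r = isa_l[i]
        if r > 0:
            j = sa_l[r - 1]
            while i + h < n and j + h < n and s_l[i + h] == s_l[j + h]:
                h += 1
            out[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return np.asarray(out, dtype=np.int64)


class SparseTableRMQ:
    """Index-of-minimum queries over a fixed array in O(1) after O(n log n)
    table construction; ties resolve to the leftmost index."""

    def __init__(self, values: np.ndarray):
        values = np.asarray(values)
        self.values = values
        n = len(values)
        table = [np.arange(n, dtype=np.int64)]
        j = 1
        while (1 << j) <= n:
            prev = table[-1]
            span = 1 << (j - 1)
            left = prev[: n - (1 << j) + 1]
            right = prev[span: span + len(left)]
            table.append(np.where(values[right] < values[left], right, left))
            j += 1
        self._table = table

    def query(self, i: int, j: int) -> int:
        """Index of a minimum of ``values[i..j]`` (inclusive)."""
        if not 0 <= i <= j < len(self.values):
            raise IndexError(f"RMQ range [{i}, {j}] out of bounds")
        level = (j - i + 1).bit_length() - 1
        a = int(self._table[level][i])
        b = int(self._table[level][j - (1 << level) + 1])
        return a if self.values[a] <= self.values[b] else b


@dataclass
class ConcatIndex:
    """Suffix-array index over the concatenation of all profiles."""

    s: np.ndarray
    sa: np.ndarray
    lcp: np.ndarray
    isa: np.ndarray
    rmq: SparseTableRMQ
    m: int
    d: int

    @property
    def n(self) -> int:
        return len(self.s)

    def save(self, path) -> None:
        """Serialize ``s``, ``sa`` and ``lcp`` (the RMQ table is rebuilt on
        load, being cheaper to recompute than to store)."""
        np.savez_compressed(
            path,
            version=np.int64(_SERIAL_VERSION),
            s=self.s,
            sa=self.sa,
            lcp=self.lcp,
            m=np.int64(self.m),
            d=np.int64(self.d),
        )

    @classmethod
    def load(cls, path) -> "ConcatIndex":
        with np.load(path) as z:
            if int(z["version"]) != _SERIAL_VERSION:
                raise ValueError(f"unsupported index version {int(z['version'])}")
            s, sa, lcp = z["s"], z["sa"], z["lcp"]
            m, d = int(z["m"]), int(z["d"])
        isa = np.empty(len(sa), dtype=np.int64)
        isa[sa] = np.arange(len(sa))
        return cls(s=s, sa=sa, lcp=lcp, isa=isa, rmq=SparseTableRMQ(lcp), m=m, d=d)


def build_concat_index(profiles) -> ConcatIndex:
    """Build the :class:`ConcatIndex` for a ProfileSet (or (d, m) int array)."""
    matrix = profiles.matrix if hasattr(profiles, "matrix") else np.asarray(profiles)
    if matrix.size == 0:
        raise ValueError("cannot index an empty profile set")
    d, m = matrix.shape
    s = np.ascontiguousarray(matrix, dtype=np.int32).reshape(-1)
    sa = suffix_array(s)
    lcp = lcp_array(s, sa)
    isa = np.empty(len(sa), dtype=np.int64)
    isa[sa] = np.arange(len(sa))
    return ConcatIndex(s=s, sa=sa, lcp=lcp, isa=isa, rmq=SparseTableRMQ(lcp), m=m, d=d)


def lce(index: ConcatIndex, i: int, j: int) -> int:
    """Longest common extension: length of the longest common prefix of the
    suffixes of ``s`` starting at ``i`` and ``j``.

    Answered as the minimum of the LCP array over the open-left rank range
    between the two suffixes; ``lce(i, i) = n - i``.  The result may run
    across profile boundaries; callers cap it where that matters.
    """
    n = index.n
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"suffix start out of range: ({i}, {j}) for n={n}")
    if i == j:
        return n - i
    ri = int(index.isa[i])
    rj = int(index.isa[j])
    if ri > rj:
        ri, rj = rj, ri
    return int(index.lcp[index.rmq.query(ri + 1, rj)])


def aligned(i: int, index: ConcatIndex, L: int) -> int:
    """Block ordinal of suffix start ``i`` under block length ``L``, or -1.

    With ``ell = i mod m`` (the offset of the suffix inside its profile),
    returns ``ell // L`` when ``ell`` is a multiple of ``L`` and the block
    fits inside the profile (``ell + L <= m``); otherwise -1.  The fit guard
    keeps accepted blocks from spilling across the separator-free profile
    boundary.
    """
    if not 0 <= i < index.n:
        raise IndexError(f"suffix start {i} out of range for n={index.n}")
    if not 1 <= L <= index.m:
        raise ValueError(f"block length {L} not in [1, m={index.m}]")
    ell = i % index.m
    if ell % L == 0 and ell + L <= index.m:
        return ell // L
    return -1
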