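"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own data structures:
suffix arrays are sorted with Python string/tuple comparison, distances
are positionwise scans, so that index/pair tests check against a fully
independent reference.
"""

from itertools import combinations

import numpy as np
import pytest

from profiledist import ProfileSet


def brute_suffix_array(s) -> list[int]:
    """Suffix sort by direct comparison of suffix tuples."""
    s = list(s)
    return sorted(range(len(s)), key=lambda i: s[i:])


def brute_lcp_array(s, sa) -> list[int]:
    """Adjacent-suffix longest-common-prefix scan; lcp[0] = 0."""
    s = list(s)
    n = len(s)
    out = [0] * n
    for r in range(1, n):
        i, j = sa[r - 1], sa[r]
        h = 0
        while i + h < n and j + h < n and s[i + h] == s[j + h]:
            h += 1
        out[r] = h
    return out


def brute_lce(s, i, j) -> int:
    s = list(s)
    n = len(s)
    h = 0
    while i + h < n and j + h < n and s[i + h] == s[j + h]:
        h += 1
    return h


def hamming(u, v) -> int:
    return int(np.count_nonzero(np.asarray(u) != np.asarray(v)))


def brute_pair_set(matrix, k) -> set:
    """{(i, j, H) : i < j, H <= k} by direct positionwise comparison."""
    matrix = np.asarray(matrix)
    out = set()
    for i, j in combinations(range(matrix.shape[0]), 2):
        h = hamming(matrix[i], matrix[j])
        if h <= k:
            out.add((i, j, h))
    return out


def random_matrix(rng, d, m, sigma):
    return rng.integers(0, sigma, size=(d, m), dtype=np.int32)


@pytest.fixture
def abc_profiles() -> ProfileSet:
    """The worked three-profile instance: "abab", "abbb", "bbbb" (a=0, b=1)."""
    return ProfileSet(
        ids=["A", "B", "C"],
        matrix=np.array([[0, 1, 0, 1], [0, 1, 1, 1], [1, 1, 1, 1]]),
        tokens=["a", "b"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
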