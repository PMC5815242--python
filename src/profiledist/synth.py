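"""Synthetic typing data and average-case admissibility bounds.

The average-case analysis of the block-filtered pair search assumes
profiles whose symbols are i.i.d. uniform over an alphabet of size sigma.
This module generates exactly that model (the binary, uniformly sampled
sequences used for validating the asymptotics are sigma=2), can plant a
pair at an exact Hamming distance for completeness tests, and evaluates
the admissibility condition

    k < (m - k - 1) * log(sigma) / log(m * d)

under which the filtered search runs in O(m d) expected time, together
with its closed-form simplification floor(m / (2 log2 m)) for the square
binary regime d = m, sigma = 2.
"""

from __future__ import annotations

import math

import numpy as np

from .io import ProfileSet

__all__ = [
    "random_profiles",
    "plant_pair",
    "max_admissible_k",
    "simplified_max_k",
    "expected_candidate_bound",
]


def random_profiles(d: int, m: int, sigma: int, seed: int) -> ProfileSet:
    """d i.i.d.-uniform profiles of length m over the alphabet {0..sigma-1}.

    Deterministic per seed (numpy PCG64 generator); ids are "P0".."P{d-1}"
    and every isolate frequency is 1.
    """
    if d < 1 or m < 1:
        raise ValueError(f"need d >= 1 and m >= 1, got d={d}, m={m}")
    if sigma < 2:
        raise ValueError(f"alphabet size must be > 1, got sigma={sigma}")
    rng = np.random.default_rng(seed)
    matrix = rng.integers(0, sigma, size=(d, m), dtype=np.int32)
    return ProfileSet(
        ids=[f"P{i}" for i in range(d)],
        matrix=matrix,
        tokens=[str(c) for c in range(sigma)],
    )


def plant_pair(profiles: ProfileSet, i: int, j: int, h: int, seed: int) -> ProfileSet:
    """Copy of *profiles* where row j is row i mutated at exactly h positions.

    The h positions are drawn uniformly without replacement and each gets a
    uniformly chosen *different* symbol, so H(i, j) = h exactly.
    """
    m = profiles.m
    if not 0 <= h <= m:
        raise ValueError(f"planted distance must be in [0, m], got h={h}")
    if i == j:
        raise ValueError("planted pair needs two distinct rows")
    sigma = profiles.sigma
    if sigma < 2 and h > 0:
        raise ValueError("cannot plant mismatches over a unary alphabet")
    rng = np.random.default_rng(seed)
    matrix = profiles.matrix.copy()
    matrix[j] = matrix[i]
    positions = rng.choice(m, size=h, replace=False)
    shifts = rng.integers(1, sigma, size=h)
    matrix[j, positions] = (matrix[j, positions] + shifts) % sigma
    return ProfileSet(
        ids=list(profiles.ids),
        matrix=matrix,
        tokens=list(profiles.tokens),
        freq=profiles.freq.copy(),
    )


def _admissible(k: int, m: int, d: int, sigma: int) -> bool:
    return k < (m - k - 1) * math.log(sigma) / math.log(m * d)


def max_admissible_k(m: int, d: int, sigma: int) -> int:
    """Largest k in [1, m-1] satisfying the average-case admissibility
    condition k < (m-k-1) log(sigma) / log(md); 0 if none does.

    The right-hand side is strictly decreasing in k while the left-hand
    side increases, so the admissible set is a prefix of [1, m-1]."""
    if m < 2 or d < 1:
        raise ValueError(f"need m >= 2 and d >= 1, got m={m}, d={d}")
    if sigma < 2:
        raise ValueError(f"alphabet size must be > 1, got sigma={sigma}")
    lo, hi = 0, m - 1  # invariant: k=lo admissible or 0, k=hi+1 not
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _admissible(mid, m, d, sigma):
            lo = mid
        else:
            hi = mid - 1
    return lo


def simplified_max_k(m: int) -> int:
    """floor(m / (2 log2 m)) — the closed-form admissibility bound for the
    square binary regime (d = m, sigma = 2); an upper bound on
    max_admissible_k(m, m, 2)."""
    if m < 2:
        raise ValueError(f"need m >= 2, got m={m}")
    return int(m // (2 * math.log2(m)))


def expected_candidate_bound(m: int, d: int, sigma: int, k: int) -> float:
    """Upper bound B * d / sigma**L on the expected number of candidate
    pairs under the i.i.d. uniform model, where B = d * floor(m/L) is the
    total block count and L = floor(m/(k+1))."""
    L = m // (k + 1)
    B = d * (m // L)
    return B * d / float(sigma) ** L
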