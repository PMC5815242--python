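"""Block scheme, kangaroo verification, candidate enumeration, closest pairs."""

import numpy as np
import pytest

from profiledist import (
    build_concat_index,
    candidates_binary_search,
    candidates_lcp,
    closest_pairs,
    hamming_capped,
    make_block_scheme,
    plant_pair,
    random_profiles,
)
from profiledist.pairs import BlockScheme

from conftest import brute_pair_set, hamming, random_matrix


class TestBlockScheme:
    @pytest.mark.parametrize("m,k,L,bpp", [(4096, 170, 23, 178), (4, 1, 2, 2), (7, 2, 2, 3)])
    def test_examples(self, m, k, L, bpp):
        sch = make_block_scheme(m, k)
        assert sch.L == L
        assert sch.blocks_per_profile == bpp
        assert (sch.k + 1) * sch.L <= m
        assert sch.blocks_per_profile >= sch.k + 1

    @pytest.mark.parametrize("k", [0, -1, 4, 9])
    def test_threshold_out_of_range(self, k):
        with pytest.raises(ValueError):
            make_block_scheme(4, k)


class TestHammingCapped:
    def test_identical_rows(self):
        idx = build_concat_index(np.tile([1, 2, 3, 4], (2, 1)))
        assert hamming_capped(idx, 0, 1, 3) == 0

    def test_exact_when_below_cap(self, abc_profiles):
        idx = build_concat_index(abc_profiles)
        assert hamming_capped(idx, 0, 1, 2) == 1  # "abab" vs "abbb"

    def test_capped_at_k(self, abc_profiles):
        idx = build_concat_index(abc_profiles)
        assert hamming_capped(idx, 0, 2, 1) == 1  # true distance 2, cap 1

    def test_matches_min_of_k_and_naive(self, rng):
        mat = random_matrix(rng, 20, 24, 3)
        idx = build_concat_index(mat)
        for _ in range(300):
            i, j = (int(v) for v in rng.integers(0, 20, size=2))
            if i == j:
                continue
            k = int(rng.integers(1, 24))
            got = hamming_capped(idx, i, j, k)
            true = hamming(mat[i], mat[j])
            assert got == min(k, true)
            if got < k:
                assert got == true

    def test_row_bounds(self, abc_profiles):
        idx = build_concat_index(abc_profiles)
        with pytest.raises(IndexError):
            hamming_capped(idx, 0, 3, 1)


def _distinct_pairs(stream):
    return {(i, j) for i, j, _t in stream}


class TestCandidateStreams:
    def test_worked_instance_both_strategies(self, abc_profiles):
        idx = build_concat_index(abc_profiles)
        sch = BlockScheme.of(4, 3, 1)  # k=1 -> L=2
        assert _distinct_pairs(candidates_lcp(idx, sch)) == {(0, 1), (1, 2)}
        assert _distinct_pairs(candidates_binary_search(idx, sch)) == {(0, 1), (1, 2)}

    def test_no_shared_block_means_empty_stream(self):
        # all-distinct symbols everywhere: no repeated aligned substring
        mat = np.arange(12).reshape(3, 4)
        idx = build_concat_index(mat)
        sch = BlockScheme.of(4, 3, 1)
        assert _distinct_pairs(candidates_lcp(idx, sch)) == set()
        assert _distinct_pairs(candidates_binary_search(idx, sch)) == set()

    def test_identical_profiles_emit_every_pair(self):
        mat = np.tile([0, 1, 0, 1], (5, 1))
        idx = build_concat_index(mat)
        sch = BlockScheme.of(4, 5, 1)
        want = {(i, j) for i in range(5) for j in range(i + 1, 5)}
        assert _distinct_pairs(candidates_lcp(idx, sch)) == want
        assert _distinct_pairs(candidates_binary_search(idx, sch)) == want

    def test_single_profile_empty(self):
        mat = np.array([[0, 1, 0, 1]])
        idx = build_concat_index(mat)
        sch = BlockScheme.of(4, 1, 1)
        assert list(candidates_binary_search(idx, sch)) == []
        assert list(candidates_lcp(idx, sch)) == []

    def test_streams_agree_on_random_instances(self, rng):
        for _ in range(25):
            d, m = int(rng.integers(2, 20)), int(rng.integers(4, 33))
            sigma = int(rng.choice([2, 4]))
            k = int(rng.integers(1, m))
            mat = random_matrix(rng, d, m, sigma)
            idx = build_concat_index(mat)
            sch = BlockScheme.of(m, d, k)
            assert _distinct_pairs(candidates_lcp(idx, sch)) == \
                _distinct_pairs(candidates_binary_search(idx, sch))


class TestClosestPairs:
    def test_worked_instance(self, abc_profiles):
        assert closest_pairs(abc_profiles, 1).pairs == {(0, 1, 1), (1, 2, 1)}
        assert closest_pairs(abc_profiles, 2).pairs == {(0, 1, 1), (0, 2, 2), (1, 2, 1)}

    def test_identical_rows_all_pairs_at_zero(self):
        mat = np.tile([3, 1, 2, 1], (4, 1))
        td = closest_pairs(mat, 3)
        assert td.pairs == {(i, j, 0) for i in range(4) for j in range(i + 1, 4)}

    @pytest.mark.parametrize("strategy", ["lcp", "binary", "naive"])
    def test_oracle_equivalence(self, rng, strategy):
        for _ in range(20):
            d, m = int(rng.integers(2, 30)), int(rng.integers(4, 49))
            sigma = int(rng.choice([2, 4, 20]))
            k = int(rng.integers(1, m))
            mat = random_matrix(rng, d, m, sigma)
            assert closest_pairs(mat, k, strategy).pairs == brute_pair_set(mat, k)

    def test_pairs_exactly_at_k_are_reported_with_exact_distance(self, rng):
        # the cap must not blur H = k against H > k
        for seed in range(10):
            ps = random_profiles(12, 20, 4, seed=seed)
            k = 5
            ps = plant_pair(ps, 0, 1, k, seed=seed + 100)
            td = closest_pairs(ps, k)
            assert (0, 1, k) in td.pairs
            td_naive = closest_pairs(ps, k, "naive")
            assert td.pairs == td_naive.pairs

    def test_monotone_in_k(self, rng):
        for _ in range(10):
            mat = random_matrix(rng, 15, 24, 2)
            k1 = int(rng.integers(1, 12))
            k2 = int(rng.integers(k1 + 1, 24))
            p1 = {(i, j) for i, j, _ in closest_pairs(mat, k1).pairs}
            p2 = {(i, j) for i, j, _ in closest_pairs(mat, k2).pairs}
            assert p1 <= p2

    def test_soundness_of_reported_distances(self, rng):
        mat = random_matrix(rng, 25, 16, 2)
        td = closest_pairs(mat, 6)
        for i, j, h in td.pairs:
            assert h <= 6
            assert hamming(mat[i], mat[j]) == h

    def test_parameter_errors(self, abc_profiles):
        with pytest.raises(ValueError):
            closest_pairs(abc_profiles, 0)
        with pytest.raises(ValueError):
            closest_pairs(abc_profiles, 4)
        with pytest.raises(ValueError):
            closest_pairs(abc_profiles, 1, "magic")


class TestClosePairsEstimator:
    def test_fit_sets_sklearn_attributes(self, abc_profiles):
        from sklearn.base import clone

        from profiledist import ClosePairs

        est = ClosePairs(k=1, strategy="binary")
        assert clone(est).get_params() == {"k": 1, "strategy": "binary"}
        est.fit(abc_profiles.matrix)
        assert est.pairs_ == {(0, 1, 1), (1, 2, 1)}
        assert est.n_features_in_ == 4
        assert est.n_verified_ >= len(est.pairs_)

    def test_transform_sparse_symmetry(self, abc_profiles):
        from profiledist import ClosePairs

        est = ClosePairs(k=2).fit(abc_profiles)
        mat = est.transform().toarray()
        np.testing.assert_array_equal(mat, mat.T)
        assert mat[0, 2] == 2
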