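"""EMD, bootstrap-KS, rank-sum and comparison matrices against independent
oracles (CDF-area integral, exact rank enumeration, construction)."""

import itertools

import numpy as np
import pytest

from abrsig.compare import (
    Histogram,
    bootstrap_ks,
    comparison_matrix,
    emd,
    make_histogram,
    normalized_emd,
    ranksum,
    shared_histograms,
)


def emd_cdf_oracle(x, y):
    """Area between empirical CDFs by brute-force step integration."""
    x, y = np.sort(x), np.sort(y)
    grid = np.sort(np.concatenate([x, y]))
    area = 0.0
    for lo, hi in zip(grid[:-1], grid[1:]):
        fx = np.searchsorted(x, lo, side="right") / len(x)
        fy = np.searchsorted(y, lo, side="right") / len(y)
        area += abs(fx - fy) * (hi - lo)
    return area


class TestEMD:
    def test_identical_samples_zero(self, rng):
        x = rng.normal(size=50)
        assert emd(x, x.copy()) == 0.0

    def test_point_masses_closed_form(self):
        assert emd([2.0], [5.0]) == pytest.approx(3.0, abs=1e-12)

    def test_matches_cdf_area_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(3, 40))
            y = rng.normal(1, 2, size=rng.integers(3, 40))
            assert emd(x, y) == pytest.approx(emd_cdf_oracle(x, y), abs=1e-9)

    def test_metric_properties(self, rng):
        for _ in range(30):
            x, y, z = (rng.normal(rng.uniform(-1, 1), 1, size=25) for _ in range(3))
            assert abs(emd(x, y) - emd(y, x)) < 1e-12
            assert emd(x, y) + emd(y, z) >= emd(x, z) - 1e-12
            assert emd(x, y) >= 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            emd([], [1.0])

    def test_histogram_path(self):
        h1 = Histogram(np.array([0.0, 1.0, 2.0]), np.array([1.0, 0.0]))
        h2 = Histogram(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0]))
        # point mass at 0.5 vs point mass at 1.5
        assert emd(h1, h2) == pytest.approx(1.0, abs=1e-12)


class TestHistogram:
    def test_frequencies_sum_to_one(self, rng):
        h = make_histogram(rng.normal(size=300))
        assert h.frequencies.sum() == pytest.approx(1.0, abs=1e-12)

    def test_shared_edges(self, rng):
        h1, h2 = shared_histograms(rng.normal(size=100), rng.normal(2, 1, size=80))
        np.testing.assert_array_equal(h1.bin_edges, h2.bin_edges)

    def test_invalid_histogram_rejected(self):
        with pytest.raises(ValueError):
            Histogram(np.array([0.0, 1.0]), np.array([1.0, 2.0]))


class TestNormalizedEMD:
    def test_max_maps_to_one(self, rng):
        m = np.tril(rng.uniform(0.1, 5.0, (4, 4)), k=-1)
        out = normalized_emd(m)
        assert out.max() == pytest.approx(1.0)

    def test_all_zero_unchanged(self):
        z = np.zeros((3, 3))
        np.testing.assert_array_equal(normalized_emd(z), z)

    def test_ordering_preserved(self, rng):
        m = np.tril(rng.uniform(0.1, 5.0, (5, 5)), k=-1)
        out = normalized_emd(m)
        i = np.tril_indices(5, k=-1)
        assert np.array_equal(np.argsort(m[i]), np.argsort(out[i]))


class TestBootstrapKS:
    def test_identical_equal_sets_statistic_zero(self, rng):
        x = rng.normal(size=100)
        with pytest.warns(UserWarning, match="equal sample sizes"):
            p, ps = bootstrap_ks(x, x.copy())
        assert p == 1.0 and len(ps) == 1

    def test_large_shift_tiny_p(self, rng):
        a = rng.normal(0, 1, size=500)
        b = rng.normal(0, 1, size=100) + 5.0
        p, _ = bootstrap_ks(a, b, seed=0)
        assert p < 1e-6

    def test_seed_determinism_and_order_invariance(self, rng):
        a = rng.normal(size=400)
        b = rng.normal(size=80)
        p1, _ = bootstrap_ks(a, b, seed=7)
        p2, _ = bootstrap_ks(a[::-1].copy(), b, seed=7)
        assert p1 == p2

    def test_returns_n_boot_pvalues(self, rng):
        a, b = rng.normal(size=300), rng.normal(size=50)
        _, ps = bootstrap_ks(a, b, n_boot=25, seed=1)
        assert len(ps) == 25

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ks([], [1.0, 2.0])


class TestRanksum:
    def test_identical_samples_p_one(self, rng):
        x = rng.normal(size=60)
        assert ranksum(x, x.copy()) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_supports_tiny_p(self, rng):
        a = rng.uniform(0, 1, size=50)
        b = rng.uniform(10, 11, size=50)
        assert ranksum(a, b) < 1e-10

    def test_matches_exact_enumeration_small(self):
        # n=3 vs 3, all distinct: enumerate all C(6,3) rank splits
        a = np.array([1.0, 5.0, 9.0])
        b = np.array([2.0, 3.0, 11.0])
        pooled = np.concatenate([a, b])
        ranks = pooled.argsort().argsort() + 1
        w_obs = ranks[:3].sum()
        all_ranks = np.arange(1, 7)
        ws = [sum(c) for c in itertools.combinations(all_ranks, 3)]
        mu = np.mean(ws)
        p_exact = np.mean([abs(w - mu) >= abs(w_obs - mu) for w in ws])
        assert ranksum(a, b) == pytest.approx(p_exact, abs=1e-12)


class TestComparisonMatrix:
    def test_two_groups_single_cell(self, rng):
        m = comparison_matrix(
            {"a": rng.normal(size=30), "b": rng.normal(size=30)},
            metric="ranksum_p",
        )
        assert np.isfinite(m.values[1, 0])
        assert np.isnan(m.values[0, 1]) and np.isnan(m.values[0, 0])

    def test_cell_count_combinatorial(self, rng):
        groups = {f"g{i}": rng.normal(size=20) for i in range(5)}
        m = comparison_matrix(groups, metric="emd_normalized")
        assert np.isfinite(m.values[np.tril_indices(5, k=-1)]).sum() == 10

    def test_stars_consistent_with_p(self, rng):
        groups = {
            "a": rng.normal(0, 1, size=60),
            "b": rng.normal(0.2, 1, size=60),
            "c": rng.normal(5, 1, size=60),
        }
        m = comparison_matrix(groups, metric="ranksum_p")
        for i in range(1, 3):
            for j in range(i):
                p = m.values[i, j]
                expected = "**" if p < 0.01 else ("*" if p < 0.05 else "")
                assert m.stars[i, j] == expected

    def test_emd_ordering_matches_configured_shifts(self, rng):
        base = rng.normal(0, 1, size=400)
        groups = {"g0": base, "g1": base + 1.0, "g2": base + 3.0}
        m = comparison_matrix(groups, metric="emd_normalized")
        assert m.cell("g2", "g0") > m.cell("g1", "g0")
        assert m.cell("g2", "g0") == pytest.approx(1.0)

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError, match="fewer than 2"):
            comparison_matrix({"a": [1.0], "b": rng.normal(size=10)})

    def test_ks_matrix_seed_deterministic(self, rng):
        groups = {"a": rng.normal(size=300), "b": rng.normal(size=60)}
        m1 = comparison_matrix(groups, metric="ks_median_p", seed=3)
        m2 = comparison_matrix(groups, metric="ks_median_p", seed=3)
        np.testing.assert_array_equal(
            m1.values[np.tril_indices(2, k=-1)], m2.values[np.tril_indices(2, k=-1)]
        )
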