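"""Pearson correlation and the region/sample variance decomposition."""

import numpy as np
import pytest
from scipy import optimize
from scipy import stats as sps

from callomap import (
    DataError,
    RoiSampleTable,
    correlate_all,
    pearson,
    variance_decomposition,
)

from conftest import table_from_matrix


def bruteforce_r(x, y):
    """Product-moment correlation straight from the definition."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5


class TestPearson:
    def test_matches_bruteforce_fixed_example(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.0, 4.0, 5.0, 4.0]
        assert pearson(x, y).r == pytest.approx(bruteforce_r(x, y), abs=1e-12)

    def test_matches_bruteforce_random_vectors(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            x = rng.normal(size=92)
            y = rng.normal(size=92)
            assert pearson(x, y).r == pytest.approx(bruteforce_r(x, y), abs=1e-12)

    def test_self_correlation(self):
        x = np.arange(10.0)
        res = pearson(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_anticorrelation(self):
        x = np.arange(10.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        assert pearson(x, y).r == pytest.approx(pearson(y, x).r, abs=1e-14)
        assert pearson(3.0 * x + 7.0, y).r == pytest.approx(pearson(x, y).r, abs=1e-10)
        assert pearson(-2.0 * x, y).r == pytest.approx(-pearson(x, y).r, abs=1e-10)

    def test_r_squared_consistency(self):
        rng = np.random.default_rng(9)
        res = pearson(rng.normal(size=30), rng.normal(size=30))
        assert res.r_squared == res.r * res.r

    def test_p_from_t_transform(self):
        """Two-sided p equals the t transform with n-2 degrees of freedom."""
        rng = np.random.default_rng(10)
        x = rng.normal(size=92)
        y = 0.4 * x + rng.normal(size=92)
        res = pearson(x, y)
        t = res.r * np.sqrt((res.n - 2) / (1 - res.r**2))
        assert res.p_two_sided == pytest.approx(2 * sps.t.sf(abs(t), res.n - 2), rel=1e-9)

    def test_critical_r_at_p_001_n_92(self):
        """|r| where p crosses 0.001 matches the tabulated t critical value."""

        def synthetic_pair(r, n=92):
            z1 = np.sin(np.arange(n))
            z2 = np.cos(2.3 * np.arange(n))
            z1 = (z1 - z1.mean()) / z1.std()
            z2 = z2 - z2.mean()
            z2 -= (z2 @ z1) / (z1 @ z1) * z1
            z2 /= z2.std()
            return z1, r * z1 + np.sqrt(1 - r * r) * z2

        def p_of_r(r):
            return pearson(*synthetic_pair(r)).p_two_sided - 0.001

        r_cross = optimize.brentq(p_of_r, 0.1, 0.9, xtol=1e-12)
        t_crit = sps.t.isf(0.0005, 90)
        r_expected = t_crit / np.sqrt(90 + t_crit**2)
        assert r_cross == pytest.approx(r_expected, abs=1e-6)

    def test_permutation_p_close_to_exact(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        exact = pearson(x, y).p_two_sided
        perm = pearson(x, y, method="permutation", n_permutations=4000, seed=0)
        assert perm.p_two_sided == pytest.approx(exact, abs=0.02)

    def test_constant_input_rejected(self):
        with pytest.raises(DataError):
            pearson(np.ones(10), np.arange(10.0))

    def test_too_short_rejected(self):
        with pytest.raises(DataError):
            pearson([1.0, 2.0], [2.0, 1.0])

    def test_nan_pairs_dropped_and_n_reported(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 3.0, 5.0, np.nan, 7.0])
        res = pearson(x, y)
        assert res.n == 4


class TestVarianceDecomposition:
    def test_identical_samples_zero_sample_sd(self):
        v = np.linspace(1, 7, 92)
        table = table_from_matrix(np.tile(v, (3, 1)), units="rescaled_1_7")
        out = variance_decomposition(table, "X")
        assert out.sd_across_samples == pytest.approx(0.0)
        assert out.n_samples == 3 and out.n_rois == 92

    def test_arithmetic_sequence_closed_form(self):
        """SD across regions of 1..92 equals sqrt(n(n+1)/12)."""
        seq = np.arange(1.0, 93.0)
        table = table_from_matrix(np.tile(seq, (2, 1)))
        out = variance_decomposition(table, "X")
        assert out.sd_across_regions == pytest.approx(np.sqrt(92 * 93 / 12), rel=1e-12)

    def test_sample_sd_estimates_noise_sd(self):
        """With iid noise sigma on a shared profile, sd_across_samples -> sigma."""
        rng = np.random.default_rng(42)
        sigma = 0.7
        base = np.linspace(2, 6, 92)
        matrix = base[None, :] + rng.normal(0, sigma, size=(200, 92))
        out = variance_decomposition(table_from_matrix(matrix), "X")
        assert out.sd_across_samples == pytest.approx(sigma, rel=0.10)

    def test_single_sample_rejected(self):
        with pytest.raises(DataError):
            variance_decomposition(table_from_matrix(np.random.rand(1, 92)), "X")


class TestCorrelateAll:
    def _three_modality_table(self, seed=0):
        rng = np.random.default_rng(seed)
        parts = [
            table_from_matrix(rng.uniform(1, 7, size=(2, 92)), modality=m)
            for m in ("A", "B", "C")
        ]
        return RoiSampleTable.concat(parts)

    def test_three_pairs_three_results(self):
        table = self._three_modality_table()
        results = correlate_all(table, [("A", "B"), ("B", "C"), ("A", "C")])
        assert len(results) == 3
        assert [(r.modality_a, r.modality_b) for r in results] == [
            ("A", "B"), ("B", "C"), ("A", "C"),
        ]

    def test_self_pair_r_one(self):
        table = self._three_modality_table()
        assert correlate_all(table, [("A", "A")])[0].r == pytest.approx(1.0)

    def test_samples_averaged_before_correlating(self):
        table = self._three_modality_table(seed=4)
        res = correlate_all(table, [("A", "B")])[0]
        expected = bruteforce_r(table.matrix("A").mean(axis=0),
                                table.matrix("B").mean(axis=0))
        assert res.r == pytest.approx(expected, abs=1e-12)

    def test_missing_modality_rejected(self):
        with pytest.raises(DataError, match="Z"):
            correlate_all(self._three_modality_table(), [("A", "Z")])
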