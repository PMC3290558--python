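"""Curve estimation, Spearman correlation and Mann-Whitney contrasts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from collmove import best_family, curve_estimation, mann_whitney, spearman_rho


class TestCurveEstimation:
    def test_exact_linear_recovery(self):
        x = np.arange(1.0, 6.0)
        fit = curve_estimation(x, 2 * x + 1, "linear")
        assert fit.a == pytest.approx(2.0)
        assert fit.b == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.f_stat >= 1e12  # capped sentinel on collinear data
        assert 0 < fit.p_value <= 1

    def test_exact_exponential_recovery(self):
        x = np.arange(0.0, 6.0)
        fit = curve_estimation(x, 3 * np.exp(0.5 * x), "exponential")
        assert fit.a == pytest.approx(3.0)
        assert fit.b == pytest.approx(0.5)
        assert fit.r_squared == pytest.approx(1.0)

    def test_exact_logarithmic_recovery(self):
        x = np.arange(1.0, 7.0)
        fit = curve_estimation(x, 2.0 * np.log(x) + 1.0, "logarithmic")
        assert fit.a == pytest.approx(2.0)
        assert fit.b == pytest.approx(1.0)

    def test_noisy_linear_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        x = np.array([0.0, 0.05, 0.33, 0.65, 0.77, 0.85])
        y = 19.293 * x + 0.6889 + rng.normal(0, 0.5, x.size)
        fit = curve_estimation(x, y, "linear")
        # independent oracle: solve the normal equations from raw sums
        n, sx, sy = x.size, x.sum(), y.sum()
        sxx, sxy = (x * x).sum(), (x * y).sum()
        slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        intercept = (sy - slope * sx) / n
        assert fit.a == pytest.approx(slope, abs=1e-12)
        assert fit.b == pytest.approx(intercept, abs=1e-12)
        resid = y - (slope * x + intercept)
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert fit.r_squared == pytest.approx(r2, abs=1e-12)
        assert fit.f_stat == pytest.approx(r2 * 4 / (1 - r2), abs=1e-9)
        assert fit.df == (1, 4)

    def test_pair_order_invariance(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0.1, 1.0, 8)
        y = 5 * x + rng.normal(0, 0.3, 8)
        perm = rng.permutation(8)
        a = curve_estimation(x, y, "linear")
        b = curve_estimation(x[perm], y[perm], "linear")
        assert a.a == pytest.approx(b.a) and a.r_squared == pytest.approx(b.r_squared)

    def test_domain_errors(self):
        with pytest.raises(ValueError, match="y > 0"):
            curve_estimation([1, 2, 3], [1.0, -1.0, 2.0], "exponential")
        with pytest.raises(ValueError, match="x > 0"):
            curve_estimation([0.0, 1, 2], [1.0, 2.0, 3.0], "logarithmic")
        with pytest.raises(ValueError, match="zero variance"):
            curve_estimation([2.0, 2.0, 2.0], [1.0, 2.0, 3.0], "linear")
        with pytest.raises(ValueError, match="at least 3"):
            curve_estimation([1.0, 2.0], [1.0, 2.0], "linear")
        with pytest.raises(ValueError, match="family"):
            curve_estimation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "quadratic")

    def test_best_family_prefers_generating_model(self):
        x = np.linspace(0.0, 0.85, 6)
        y = 0.5 * np.exp(4.0 * x)
        assert best_family(x, y).family == "exponential"


class TestSpearman:
    def test_perfect_agreement_and_reversal(self):
        assert spearman_rho([1, 2, 3, 4], [1, 2, 3, 4])[0] == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3, 4], [4, 3, 2, 1])[0] == pytest.approx(-1.0)

    def test_tied_values_match_brute_force_averaged_ranks(self):
        a, b = [1.0, 2.0, 2.0, 4.0], [2.0, 1.0, 3.0, 4.0]

        def avg_ranks(vals):
            order = sorted(range(len(vals)), key=lambda i: vals[i])
            ranks = [0.0] * len(vals)
            i = 0
            while i < len(vals):
                j = i
                while j + 1 < len(vals) and vals[order[j + 1]] == vals[order[i]]:
                    j += 1
                mean_rank = (i + j) / 2 + 1
                for k in range(i, j + 1):
                    ranks[order[k]] = mean_rank
                i = j + 1
            return ranks

        ra, rb = np.array(avg_ranks(a)), np.array(avg_ranks(b))
        expected = np.corrcoef(ra, rb)[0, 1]  # Pearson on averaged ranks
        assert spearman_rho(a, b)[0] == pytest.approx(expected, abs=1e-12)

    def test_constant_sequence_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(
        data=st.lists(
            st.floats(-50, 50, allow_nan=False).map(lambda v: round(v, 3)),
            min_size=4,
            max_size=15,
            unique=True,
        ),
        seed=st.integers(0, 99),
    )
    def test_invariance_under_monotone_transforms(self, data, seed):
        rng = np.random.default_rng(seed)
        other = rng.normal(size=len(data))
        base = spearman_rho(data, other)[0]
        assert spearman_rho(np.exp(0.05 * np.asarray(data)), other)[0] == pytest.approx(
            base, abs=1e-12
        )


class TestMannWhitney:
    def test_disjoint_samples_give_extreme_u(self):
        u, z, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0  # no a-value ever beats a b-value
        assert z < 0
        assert p < 0.2

    def test_identical_samples(self):
        u, z, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_sign_convention_lower_ranks_negative(self):
        rng = np.random.default_rng(0)
        low = rng.normal(0, 1, 200)
        high = rng.normal(1, 1, 200)
        _, z, p = mann_whitney(low, high)
        assert z < -3 and p < 0.01

    def test_p_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 10, 150).astype(float)  # heavy ties
        b = rng.integers(2, 12, 180).astype(float)
        _, _, p = mann_whitney(a, b)
        ref = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    @given(
        a=st.lists(st.integers(0, 8), min_size=1, max_size=25),
        b=st.lists(st.integers(0, 8), min_size=1, max_size=25),
    )
    def test_u_statistics_of_both_orientations_sum_to_pair_count(self, a, b):
        u_ab, _, _ = mann_whitney(a, b)
        u_ba, _, _ = mann_whitney(b, a)
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])
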