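"""PRCC, Agresti–Coull, percentile bootstrap, Wilcoxon, ROC."""

import numpy as np
import pytest
import scipy.stats as sps

from qspvct.stats import (
    agresti_coull_ci,
    bootstrap_orr_ci,
    prcc,
    prcc_matrix,
    roc_curve,
    wilcoxon_rank_sum,
)


# ---------------------------------------------------------------------------
# PRCC
# ---------------------------------------------------------------------------

def _brute_force_prcc(X, y):
    """Independent oracle: explicit projection-matrix residualisation."""
    R = sps.rankdata(X, axis=0)
    ry = sps.rankdata(y)
    out = []
    for j in range(X.shape[1]):
        A = np.column_stack([np.ones(X.shape[0]), np.delete(R, j, axis=1)])
        P = np.eye(len(ry)) - A @ np.linalg.pinv(A)
        rx, ryy = P @ R[:, j], P @ ry
        out.append(rx @ ryy / np.sqrt((rx @ rx) * (ryy @ ryy)))
    return np.array(out)


class TestPRCC:
    def test_strict_monotone_dependence_gives_unit_coefficient(self):
        rng = np.random.default_rng(0)
        x1 = rng.uniform(0, 1, 60)
        X = np.column_stack([x1, rng.normal(size=60), rng.normal(size=60)])
        y = np.exp(3 * x1)  # strictly monotone in x1 only
        res = prcc(X, y)
        assert res.prcc[0] == pytest.approx(1.0, abs=1e-9)

    def test_independent_output_gives_null_coefficients(self):
        rng = np.random.default_rng(1)
        n = 400
        X = rng.normal(size=(n, 4))
        y = rng.normal(size=n)
        res = prcc(X, y)
        assert np.all(np.abs(res.prcc) < 3 / np.sqrt(n))

    def test_agrees_with_projection_oracle_to_1e10(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 4))
        y = X @ [0.5, -1.0, 0.2, 0.0] + rng.normal(size=50)
        assert np.allclose(prcc(X, y).prcc, _brute_force_prcc(X, y), atol=1e-10)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0.1, 2.0, size=(80, 3))
        y = X[:, 0] - 2 * X[:, 1] + rng.normal(size=80)
        base = prcc(X, y).prcc
        X2 = np.column_stack([np.exp(X[:, 0]), X[:, 1] ** 3, np.log(X[:, 2])])
        assert np.allclose(prcc(X2, np.exp(y)).prcc, base, atol=1e-12)

    def test_constant_column_is_rejected_by_name(self):
        X = np.column_stack([np.ones(30), np.arange(30.0)])
        with pytest.raises(ValueError, match="frozen"):
            prcc(X, np.arange(30.0), parameter_names=["frozen", "live"])

    def test_matrix_form_stacks_outputs(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 3))
        Y = np.column_stack([X[:, 0] + rng.normal(size=40), -X[:, 1]])
        res = prcc_matrix(X, Y, output_names=None)
        assert res.prcc.shape == (3, 2)
        assert res.prcc[1, 1] == pytest.approx(-1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Agresti–Coull
# ---------------------------------------------------------------------------

class TestAgrestiCoull:
    def test_reported_cohort_interval_to_three_decimals(self):
        lo, hi = agresti_coull_ci(320, 1196)
        assert round(lo, 3) == 0.243
        assert round(hi, 3) == 0.293

    def test_matches_statsmodels_formulation(self):
        import statsmodels.stats.proportion as smp

        for x, n in [(3, 10), (50, 80), (320, 1196)]:
            lo, hi = agresti_coull_ci(x, n)
            slo, shi = smp.proportion_confint(x, n, method="agresti_coull")
            assert (lo, hi) == pytest.approx((slo, shi), abs=1e-12)

    def test_clipping_at_domain_edges(self):
        lo, _ = agresti_coull_ci(0, 15)
        _, hi = agresti_coull_ci(15, 15)
        assert lo == 0.0 and hi == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            agresti_coull_ci(5, 4)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

class TestBootstrap:
    def test_no_responders_degenerate_interval(self):
        assert bootstrap_orr_ci(0, 100, reps=2000, seed=0) == (0.0, 0.0)

    @pytest.mark.parametrize("x,n,size", [(320, 1196, 15), (40, 200, 25), (5, 60, 15)])
    def test_quantiles_match_exact_binomial(self, x, n, size):
        """Empirical order-statistic quantiles converge to Binomial ppf."""
        p = x / n
        lo, hi = bootstrap_orr_ci(x, n, sample_size=size, reps=200_000, seed=7)
        assert lo == pytest.approx(sps.binom.ppf(0.025, size, p) / size)
        assert hi == pytest.approx(sps.binom.ppf(0.975, size, p) / size)

    def test_interval_on_the_proportion_grid(self):
        lo, hi = bootstrap_orr_ci(320, 1196, reps=10_000, seed=1)
        assert (round(lo * 15, 6)).is_integer() and (round(hi * 15, 6)).is_integer()

    def test_reps_floor_enforced(self):
        with pytest.raises(ValueError):
            bootstrap_orr_ci(10, 100, reps=10, seed=0)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_disjoint_triples_exact_p(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_extreme_shift_gives_extreme_statistic(self):
        w, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [100.0, 101.0, 102.0, 103.0])
        assert w == 1 + 2 + 3
        assert p == pytest.approx(2 / 35)  # 2·C(7,3)⁻¹·... both one-sided extremes

    def test_large_sample_agrees_with_scipy_normal_approximation(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 1.0, 40)
        b = rng.normal(0.6, 1.0, 55)
        _, p = wilcoxon_rank_sum(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=5e-2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

class TestROC:
    def test_perfect_separation_auc_one(self):
        res = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == pytest.approx(1.0)

    def test_random_labels_auc_near_half(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=4000)
        lab = rng.integers(0, 2, size=4000).astype(bool)
        assert roc_curve(v, lab).auc == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_mann_whitney_u_statistic(self):
        rng = np.random.default_rng(7)
        pos = rng.normal(1.0, 1.0, 30)
        neg = rng.normal(0.0, 1.0, 30)
        v = np.concatenate([pos, neg])
        lab = np.array([True] * 30 + [False] * 30)
        auc = roc_curve(v, lab).auc
        u = sps.mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert auc == pytest.approx(u / (30 * 30), abs=1e-12)

    def test_orientation_not_forced_above_half(self):
        """Lower-is-responder biomarkers keep their stated direction."""
        v = [1, 2, 3, 10, 11, 12]
        lab = [1, 1, 1, 0, 0, 0]
        assert roc_curve(v, lab, higher_is_positive=True).auc == pytest.approx(0.0)
        assert roc_curve(v, lab, higher_is_positive=False).auc == pytest.approx(1.0)

    def test_curve_monotone_nondecreasing(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=100)
        lab = rng.integers(0, 2, 100).astype(bool)
        res = roc_curve(v, lab)
        assert np.all(np.diff(res.tpr) >= 0) and np.all(np.diff(res.fpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2], [1, 1])
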