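import numpy as np
import pytest
from scipy import integrate, special, stats

from semsim.bayes import (
    BayesError,
    bf_anova_oneway,
    bf_contingency,
    bf_correlation,
    bf_ttest_independent,
    bf_ttest_paired,
    correlation_bf10,
    jzs_bf10_from_t,
)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def jzs_oracle(t, nu, neff, w=0.707):
    """JZS Bayes factor via the effect-size marginal: integrate the
    noncentral-t likelihood against the Cauchy prior on delta (no g-mixture
    representation; a genuinely different route than the implementation)."""

    def num(d):
        return stats.nct.pdf(t, nu, d * np.sqrt(neff)) * stats.cauchy.pdf(d, scale=w)

    val, _ = integrate.quad(num, -np.inf, np.inf, limit=400, epsabs=1e-13, epsrel=1e-11)
    return val / stats.t.pdf(t, nu)


def anova_oracle_balanced(groups, r=0.5):
    """Balanced one-way g-prior Bayes factor in scalar closed form from the
    between/total sum-of-squares ratio."""
    groups = [np.asarray(g, float) for g in groups]
    a = len(groups)
    n = groups[0].size
    assert all(g.size == n for g in groups)
    y = np.concatenate(groups)
    N = y.size
    gm = y.mean()
    ssb = n * sum((g.mean() - gm) ** 2 for g in groups)
    sst = ((y - gm) ** 2).sum()
    R2 = ssb / sst

    def integrand(g):
        prior = stats.invgamma.pdf(g, 0.5, scale=r ** 2 / 2)
        return (
            prior
            * (1 + n * g) ** (-(a - 1) / 2)
            * (1 - g * n * R2 / (1 + g * n)) ** (-(N - 1) / 2)
        )

    val, _ = integrate.quad(integrand, 0, np.inf, limit=400)
    return val


def contingency_oracle_2x2(table, a=1.0):
    """2x2 independent-multinomial Bayes factor by direct numeric integration
    of the row-binomial marginals (H1: two independent Beta(a, a) rates;
    H0: one shared Beta(2a, 2a) rate)."""
    (y11, y12), (y21, y22) = table

    def beta_marginal(k, n, al, be):
        f = lambda th: th ** k * (1 - th) ** (n - k) * stats.beta.pdf(th, al, be)
        return integrate.quad(f, 0, 1, limit=200)[0]

    m1 = beta_marginal(y11, y11 + y12, a, a) * beta_marginal(y21, y21 + y22, a, a)
    m0 = beta_marginal(y11 + y21, y11 + y12 + y21 + y22, 2 * a, 2 * a)
    return m1 / m0


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

class TestJzsTtest:
    def test_zero_t_favours_null(self):
        res = bf_ttest_independent(summary=(5.0, 1.0, 36, 5.0, 1.0, 36))
        assert res.bf10 < 1

    @pytest.mark.parametrize("t", [0.0, 0.5, 1.5, 2.0, 3.0, 6.0])
    @pytest.mark.parametrize("n1, n2", [(10, 10), (20, 20), (36, 46), (13, None)])
    def test_matches_quadrature_oracle(self, t, n1, n2):
        if n2 is None:
            nu, neff = n1 - 1, n1
        else:
            nu, neff = n1 + n2 - 2, n1 * n2 / (n1 + n2)
        mine = jzs_bf10_from_t(t, nu, neff)
        ref = jzs_oracle(t, nu, neff)
        assert mine == pytest.approx(ref, rel=1e-6)

    def test_even_in_t_and_monotone_in_magnitude(self):
        nu, neff = 40, 10.5
        grid = [0.25, 0.5, 1.0, 1.5, 2.5, 4.0]
        vals = [jzs_bf10_from_t(t, nu, neff) for t in grid]
        for t, v in zip(grid, vals):
            assert jzs_bf10_from_t(-t, nu, neff) == pytest.approx(v, rel=1e-9)
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_sufficiency_raw_equals_summary(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 18), rng.normal(0.5, 1.3, 22)
        raw = bf_ttest_independent(x, y)
        summ = bf_ttest_independent(
            summary=(x.mean(), x.std(ddof=1), 18, y.mean(), y.std(ddof=1), 22)
        )
        assert raw.bf10 == pytest.approx(summ.bf10, rel=1e-12)
        assert summ.rounded_input and not raw.rounded_input

    def test_welch_differs_under_unequal_variance(self):
        pooled = bf_ttest_independent(summary=(0, 1, 10, 1, 5, 40), variance_rule="pooled")
        welch = bf_ttest_independent(summary=(0, 1, 10, 1, 5, 40), variance_rule="welch")
        assert pooled.bf10 != pytest.approx(welch.bf10, rel=1e-3)

    def test_degenerate_sd_is_domain_error(self):
        with pytest.raises(BayesError):
            bf_ttest_independent(summary=(1, 0.0, 10, 2, 1.0, 10))

    def test_paired_zero_change_favours_null(self):
        res = bf_ttest_paired(summary=(0.0, 1.0, 20))
        assert res.bf10 < 1

    def test_paired_raw_equals_difference_summary(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(1, 1, 15), rng.normal(0, 1, 15)
        d = x - y
        raw = bf_ttest_paired(x, y)
        summ = bf_ttest_paired(summary=(d.mean(), d.std(ddof=1), 15))
        assert raw.bf10 == pytest.approx(summ.bf10, rel=1e-12)

    def test_result_records_prior_and_n(self):
        res = bf_ttest_independent(summary=(0, 1, 10, 1, 1, 12), cauchy_width=1.0)
        assert res.prior == {"cauchy_width": 1.0}
        assert res.n_info == {"n1": 10, "n2": 12}
        assert res.bf01 == pytest.approx(1 / res.bf10)
        assert res.ci95[0] < res.ci95[1]

    def test_credible_interval_null_coverage(self):
        """Under the null, the central 95% delta interval should contain 0
        about 95% of the time."""
        rng = np.random.default_rng(12345)
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            x = rng.normal(0, 1, 20)
            res = bf_ttest_paired(summary=(x.mean(), x.std(ddof=1), 20))
            lo, hi = res.ci95
            hits += lo <= 0 <= hi
        assert abs(hits / n_sim - 0.95) <= 0.03


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

class TestCorrelation:
    def test_zero_r_favours_null(self):
        for n in (10, 30, 100):
            assert correlation_bf10(0.0, n) < 1

    def test_matches_independent_closed_form(self):
        """Cross-check against the hypergeometric closed form of the default
        correlation Bayes factor (pingouin's implementation)."""
        pingouin = pytest.importorskip("pingouin")
        for r in (-0.6, -0.2, 0.0, 0.105, 0.4, 0.8):
            for n in (5, 20, 46, 82):
                mine = correlation_bf10(r, n)
                ref = float(pingouin.bayesfactor_pearson(r, n))
                assert mine == pytest.approx(ref, rel=1e-4), (r, n)

    def test_sign_symmetry_and_monotone_in_magnitude(self):
        n = 30
        grid = [0.05, 0.15, 0.3, 0.5, 0.7]
        vals = [correlation_bf10(r, n) for r in grid]
        for r, v in zip(grid, vals):
            assert correlation_bf10(-r, n) == pytest.approx(v, rel=1e-8)
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_one_sided_consistency(self):
        # the two sided factors average the sided ones for a symmetric prior
        r, n = 0.4, 25
        two = correlation_bf10(r, n)
        gt = correlation_bf10(r, n, alternative="greater")
        lt = correlation_bf10(r, n, alternative="less")
        assert two == pytest.approx((gt + lt) / 2, rel=1e-7)
        assert gt > two > lt

    def test_raw_pairs_match_summary(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=25)
        y = 0.5 * x + rng.normal(size=25)
        r = float(np.corrcoef(x, y)[0, 1])
        raw = bf_correlation(x=x, y=y)
        summ = bf_correlation(r=r, n=25)
        assert raw.bf10 == pytest.approx(summ.bf10, rel=1e-9)

    def test_perfect_correlation_is_domain_error(self):
        with pytest.raises(BayesError):
            bf_correlation(r=1.0, n=10)
        x = np.arange(10.0)
        with pytest.raises(BayesError):
            bf_correlation(x=x, y=2 * x)

    def test_small_n_rejected(self):
        with pytest.raises(BayesError):
            bf_correlation(r=0.5, n=2)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

class TestAnova:
    def test_identical_groups_favour_null(self):
        rng = np.random.default_rng(8)
        base = rng.normal(0, 1, 15)
        res = bf_anova_oneway([base, base.copy(), base.copy()])
        assert res.bf10 < 1

    def test_two_groups_match_jzs_ttest(self):
        """With two groups the g-prior ANOVA equals the JZS t-test whose
        Cauchy width is sqrt(2) times the fixed-effect scale."""
        rng = np.random.default_rng(9)
        x, y = rng.normal(0, 1, 20), rng.normal(0.8, 1, 25)
        anova = bf_anova_oneway([x, y], g_prior_scale=0.5)
        ttest = bf_ttest_independent(x, y, cauchy_width=0.5 * np.sqrt(2))
        assert anova.bf10 == pytest.approx(ttest.bf10, rel=1e-6)
        # and stays within 5% of the default-width t-test
        default_t = bf_ttest_independent(x, y)
        assert anova.bf10 == pytest.approx(default_t.bf10, rel=0.05)

    def test_matches_balanced_closed_form_oracle(self):
        rng = np.random.default_rng(10)
        groups = [rng.normal(m, 1.2, 12) for m in (0.0, 0.4, 1.0)]
        res = bf_anova_oneway(groups)
        assert res.bf10 == pytest.approx(anova_oracle_balanced(groups), rel=1e-6)

    def test_zero_variance_group_handled(self):
        res = bf_anova_oneway([[1.0, 1.0, 1.0], [2.0, 3.0, 4.0]])
        assert np.isfinite(res.bf10) and res.bf10 > 0

    def test_all_identical_rejected(self):
        with pytest.raises(BayesError):
            bf_anova_oneway([[1.0, 1.0], [1.0, 1.0]])

    def test_effect_size_interval_ordered_and_deterministic(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(m, 1, 10) for m in (0, 1)]
        a = bf_anova_oneway(groups)
        b = bf_anova_oneway(groups)
        assert a.ci95 == b.ci95 and a.ci95[0] < a.ci95[1]


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

class TestContingency:
    def test_proportional_table_favours_null(self):
        assert bf_contingency([[10, 20], [20, 40]]).bf10 < 1

    @pytest.mark.parametrize("table", [[[24, 12], [35, 11]], [[5, 15], [18, 4]], [[9, 9], [9, 9]]])
    def test_matches_numeric_integration_oracle(self, table):
        res = bf_contingency(table)
        assert res.bf10 == pytest.approx(contingency_oracle_2x2(table), rel=1e-6)

    def test_zero_margin_is_domain_error(self):
        with pytest.raises(BayesError):
            bf_contingency([[0, 0], [5, 5]])
        with pytest.raises(BayesError):
            bf_contingency([[0, 5], [0, 5]])

    def test_2xk_supported(self):
        res = bf_contingency([[10, 12, 9], [3, 18, 12]])
        assert np.isfinite(res.bf10) and res.bf10 > 0

    def test_nonincreasing_under_stronger_prior_smoothing(self):
        strong = bf_contingency([[20, 5], [5, 20]], concentration=10).bf10
        weak = bf_contingency([[20, 5], [5, 20]], concentration=1).bf10
        assert strong != pytest.approx(weak, rel=1e-6)
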