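"""GLM fits, quasi-F tests, simultaneous contrasts and letter displays."""

import numpy as np
import pytest
from scipy.stats import f_oneway

from benthograd.univariate import (
    PairwiseResult,
    eta_squared,
    fit_glm,
    global_test,
    letter_display,
    pairwise_compare,
)

LEVELS_DESIGN = np.repeat(["A", "B", "C", "D"], [5, 5, 5, 10])


def _poisson_counts(rng, means=(230, 270, 280, 210)):
    return rng.poisson(np.repeat(means, [5, 5, 5, 10])).astype(float)


class TestFitGlm:
    @pytest.mark.parametrize("family", ["quasipoisson", "gaussian"])
    def test_saturated_means_equal_observed(self, family, rng):
        y = _poisson_counts(rng) if family == "quasipoisson" else rng.normal(
            10, 3, 25
        )
        if family == "gaussian":
            y = np.round(y, 6)
        fit = fit_glm(y, LEVELS_DESIGN, family)
        obs = [y[LEVELS_DESIGN == g].mean() for g in fit.levels]
        assert np.allclose(fit.means, obs, atol=1e-8)

    def test_design_df(self, rng):
        fit = fit_glm(_poisson_counts(rng), LEVELS_DESIGN, "quasipoisson")
        assert fit.df_model == 3
        assert fit.df_resid == 21

    def test_quasipoisson_point_estimates_equal_poisson_ml(self, rng):
        import statsmodels.api as sm

        y = _poisson_counts(rng)
        X = np.column_stack([(LEVELS_DESIGN == g).astype(float)
                             for g in sorted(set(LEVELS_DESIGN))])
        ml = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        fit = fit_glm(y, LEVELS_DESIGN, "quasipoisson")
        assert np.allclose(fit.coef, ml.params, atol=1e-8)

    def test_poisson_dispersion_near_one(self, rng):
        """Equal-dispersion Poisson data: mean phi ~ 1 over simulations."""
        phis = [
            fit_glm(_poisson_counts(rng), LEVELS_DESIGN, "quasipoisson").phi
            for _ in range(400)
        ]
        phis = np.asarray(phis)
        se = phis.std(ddof=1) / np.sqrt(phis.size)
        assert abs(phis.mean() - 1.0) < 3 * se + 1e-3

    def test_integer_requirement(self):
        with pytest.raises(ValueError):
            fit_glm(np.array([1.5] * 25), LEVELS_DESIGN, "quasipoisson")

    def test_zero_level_boundary_flagged(self, rng):
        y = np.concatenate([np.zeros(5), rng.poisson(10, 20)]).astype(float)
        fit = fit_glm(y, LEVELS_DESIGN, "quasipoisson")
        assert fit.boundary
        assert fit.means[0] == 0.0
        assert np.allclose(
            fit.means, [y[LEVELS_DESIGN == g].mean() for g in fit.levels]
        )
        F, *_ = global_test(fit)
        assert np.isfinite(F) and F > 0


class TestGlobalTest:
    def test_equal_means_give_zero_f(self, rng):
        y = np.round(rng.normal(0, 1, 25), 6)
        # centre each level: between-level deviance difference is exactly 0
        for g in "ABCD":
            y[LEVELS_DESIGN == g] -= y[LEVELS_DESIGN == g].mean()
        fit = fit_glm(y, LEVELS_DESIGN, "gaussian")
        F, _, _, p = global_test(fit)
        assert F == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_gaussian_equals_classical_anova(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(5, 2, 25) + np.repeat([0, 1, 0.5, 0], [5, 5, 5, 10])
        fit = fit_glm(y, LEVELS_DESIGN, "gaussian")
        F, df1, df2, p = global_test(fit)
        oracle = f_oneway(*[y[LEVELS_DESIGN == g] for g in "ABCD"])
        assert F == pytest.approx(oracle.statistic, rel=1e-9)
        assert p == pytest.approx(oracle.pvalue, rel=1e-9)
        assert (df1, df2) == (3, 21)

    def test_degenerate_constant_data(self):
        y = np.full(25, 4.0)
        fit = fit_glm(y, LEVELS_DESIGN, "gaussian")
        F, _, _, p = global_test(fit)
        assert F == 0.0 and p == 1.0


class TestPairwise:
    def test_identical_groups_not_significant(self, rng):
        y = np.concatenate([
            rng.poisson(200, 5), rng.poisson(200, 5),
            rng.poisson(600, 5), rng.poisson(600, 10),
        ]).astype(float)
        y[5:10] = y[:5]  # B identical to A
        fit = fit_glm(y, LEVELS_DESIGN, "quasipoisson")
        pw = pairwise_compare(fit, seed=1)
        idx = pw.pairs.index(("A", "B"))
        assert pw.p_adj[idx] > 0.9

    def test_adjusted_at_least_raw(self, rng):
        fit = fit_glm(_poisson_counts(rng), LEVELS_DESIGN, "quasipoisson")
        pw = pairwise_compare(fit, seed=1)
        assert np.all(pw.p_adj >= pw.p_raw - 1e-12)
        assert np.all((pw.p_adj >= 0) & (pw.p_adj <= 1))
        assert pw.mc_error < 1e-3

    def test_two_levels_adjustment_is_exact(self, rng):
        levels = np.repeat(["A", "D"], [5, 10])
        y = rng.poisson([200] * 5 + [260] * 10).astype(float)
        pw = pairwise_compare(fit_glm(y, levels, "quasipoisson"), seed=1)
        assert len(pw.pairs) == 1
        assert pw.p_adj[0] == pytest.approx(pw.p_raw[0])
        assert pw.method == "exact t"


def _fake_pairwise(p_by_pair, alpha=0.05):
    pairs = list(p_by_pair)
    p = np.array([p_by_pair[k] for k in pairs])
    n = len(pairs)
    return PairwiseResult(
        pairs=pairs, estimates=np.zeros(n), se=np.ones(n),
        tstats=np.zeros(n), p_raw=p, p_adj=p, df=21, alpha=alpha,
        mc_error=0.0, method="fake",
    )


class TestLetters:
    def test_all_pairs_distinct(self):
        pw = _fake_pairwise({(a, b): 0.001 for a, b in
                             [("A", "B"), ("A", "C"), ("A", "D"),
                              ("B", "C"), ("B", "D"), ("C", "D")]})
        letters = letter_display(pw)
        assert len({v for v in letters.values()}) == 4
        assert all(len(v) == 1 for v in letters.values())

    def test_no_pairs_significant_single_letter(self):
        pw = _fake_pairwise({(a, b): 0.9 for a, b in
                             [("A", "B"), ("A", "C"), ("A", "D"),
                              ("B", "C"), ("B", "D"), ("C", "D")]})
        letters = letter_display(pw)
        assert set(letters.values()) == {"a"}

    def test_step_down_pattern(self):
        # A differs from everything; B, C, D mutually indistinct
        pw = _fake_pairwise({
            ("A", "B"): 0.001, ("A", "C"): 0.001, ("A", "D"): 0.001,
            ("B", "C"): 0.8, ("B", "D"): 0.8, ("C", "D"): 0.8,
        })
        letters = letter_display(pw)
        assert letters["A"] == "a"
        assert letters["B"] == letters["C"] == letters["D"] == "b"

    def test_intransitive_pattern_multiple_letters(self):
        # A = B, B = C, but A != C: B must carry both letters
        pw = _fake_pairwise({("A", "B"): 0.5, ("B", "C"): 0.5, ("A", "C"): 0.01})
        letters = letter_display(pw)
        assert set(letters["B"]) == set(letters["A"]) | set(letters["C"])
        assert not set(letters["A"]) & set(letters["C"])

    def test_consistency_with_significance_graph(self, rng):
        fit = fit_glm(_poisson_counts(rng), LEVELS_DESIGN, "quasipoisson")
        pw = pairwise_compare(fit, seed=0)
        letters = pw.letters
        for (a, b), p in zip(pw.pairs, pw.p_adj):
            share = bool(set(letters[a]) & set(letters[b]))
            assert share == (p >= pw.alpha)


class TestEtaSquared:
    def test_distinct_constants_give_one(self):
        y = np.repeat([1.0, 2.0, 3.0, 4.0], [5, 5, 5, 10])
        assert eta_squared(y, LEVELS_DESIGN) == pytest.approx(1.0)

    def test_null_expectation_matches_permutation_oracle(self, rng):
        """Random labels: E[eta^2] = (k-1)/(n-1)."""
        n, k = 120, 4
        y = rng.normal(size=n)
        vals = []
        for _ in range(300):
            labels = rng.permutation(np.repeat(np.arange(k), n // k))
            vals.append(eta_squared(y, labels))
        expected = (k - 1) / (n - 1)
        assert np.mean(vals) == pytest.approx(expected, abs=3 * np.std(vals) /
                                              np.sqrt(len(vals)))

    def test_equal_means_large_n_near_zero(self, rng):
        y = rng.normal(10, 1, 4000)
        labels = np.repeat(np.arange(4), 1000)
        assert eta_squared(y, labels) < 0.01

    def test_zero_variance_flagged(self):
        assert np.isnan(eta_squared(np.ones(25), LEVELS_DESIGN))
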