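"""Propensity model, caliper matching and balance diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from psynetkit import (
    chi_square_independence,
    default_scenario,
    fit_propensity,
    match_dataset,
    match_nearest,
    sample_dataset,
    standardized_mean_difference,
    welch_t_from_summary,
)
from psynetkit.matching import PropensityResult, balance_table


def covariate_frame(n, rng, registration=None):
    return pd.DataFrame({
        "age": rng.normal(16, 1.2, n),
        "sex": rng.binomial(1, 0.5, n),
        "registration": registration if registration is not None
        else rng.choice(["city", "township", "other_city", "other_province"], n),
        "only_child": rng.binomial(1, 0.5, n),
        "father_drunkenness": rng.binomial(1, 0.1, n),
    })


class TestFitPropensity:
    def test_null_model_coefficients_near_zero(self):
        rng = np.random.default_rng(3)
        cov = covariate_frame(5000, rng)
        exposure = rng.binomial(1, 0.2, 5000)
        result = fit_propensity(cov, exposure)
        # roughly 3-SE bounds for binary/continuous predictors at n = 5000
        for name, coef in result.coefficients.items():
            if name != "const":
                assert abs(coef) < 0.35, name
        assert result.converged

    def test_planted_odds_ratio_recovered(self):
        rng = np.random.default_rng(5)
        n = 20000
        cov = covariate_frame(n, rng)
        eta = -2.0 + np.log(2) * cov["father_drunkenness"].to_numpy()
        exposure = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        result = fit_propensity(cov, exposure)
        assert result.coefficients["father_drunkenness"] == pytest.approx(
            np.log(2), abs=0.1
        )

    def test_interceptish_prevalence(self):
        rng = np.random.default_rng(7)
        n = 30000
        cov = covariate_frame(n, rng)
        exposure = rng.binomial(1, 0.085, n)
        result = fit_propensity(cov, exposure)
        fitted_marginal = result.scores.mean()
        assert fitted_marginal == pytest.approx(exposure.mean(), abs=1e-6)
        assert np.median(result.linear_predictor) == pytest.approx(
            logit(0.085), abs=0.15
        )

    def test_scores_consistent_with_linear_predictor(self):
        rng = np.random.default_rng(11)
        cov = covariate_frame(500, rng)
        result = fit_propensity(cov, rng.binomial(1, 0.3, 500))
        np.testing.assert_allclose(
            result.scores, 1 / (1 + np.exp(-result.linear_predictor)), atol=1e-12
        )
        assert np.all((result.scores > 0) & (result.scores < 1))

    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        cov = covariate_frame(100, rng)
        with pytest.raises(ValueError, match="both exposure classes"):
            fit_propensity(cov, np.zeros(100, dtype=int))

    def test_rank_deficiency_rejected(self):
        rng = np.random.default_rng(1)
        cov = covariate_frame(200, rng, registration=["city"] * 200)
        with pytest.raises(ValueError, match="rank deficient"):
            fit_propensity(cov, rng.binomial(1, 0.3, 200))


def propensity_from_logits(eta):
    eta = np.asarray(eta, dtype=float)
    return PropensityResult(
        scores=1 / (1 + np.exp(-eta)),
        linear_predictor=eta,
        coefficients=pd.Series({"const": 0.0}),
        converged=True,
    )


class TestMatchNearest:
    def test_identical_point_sets_match_everyone_at_zero_distance(self):
        eta = np.concatenate([np.linspace(-1, 1, 20)] * 2)
        exposure = np.array([1] * 20 + [0] * 20)
        ids = np.arange(40)
        result = match_nearest(propensity_from_logits(eta), exposure, ids)
        assert result.n_matched == 20
        assert not result.unmatched_exposed
        pos = {i: k for k, i in enumerate(ids)}
        for e, c in result.pairs:
            assert eta[pos[e]] == pytest.approx(eta[pos[c]])

    def test_caliper_excludes_distant_exposed(self):
        eta = np.array([3.0, -0.5, -1.0, -2.0])
        exposure = np.array([1, 0, 0, 0])
        ids = np.array([10, 11, 12, 13])
        ps = propensity_from_logits(eta)
        # caliper smaller than the 3.5 logit gap
        result = match_nearest(ps, exposure, ids, caliper_sd_multiplier=0.3)
        assert result.n_matched == 0
        assert result.unmatched_exposed == [10]

    def test_controls_used_at_most_once(self):
        rng = np.random.default_rng(2)
        eta = rng.normal(0, 1, 300)
        exposure = (rng.random(300) < 0.4).astype(int)
        result = match_nearest(propensity_from_logits(eta), exposure, np.arange(300))
        controls = [c for _, c in result.pairs]
        assert len(controls) == len(set(controls))
        assert result.n_matched <= min(exposure.sum(), (1 - exposure).sum())

    def test_pairs_respect_caliper_bound(self):
        rng = np.random.default_rng(3)
        eta = rng.normal(0, 1, 500)
        exposure = (rng.random(500) < 0.3).astype(int)
        ps = propensity_from_logits(eta)
        result = match_nearest(ps, exposure, np.arange(500))
        assert result.caliper_width == pytest.approx(0.2 * np.std(eta))
        pos = {i: k for k, i in enumerate(np.arange(500))}
        for e, c in result.pairs:
            assert abs(eta[pos[e]] - eta[pos[c]]) <= result.caliper_width + 1e-12

    def test_deterministic_under_control_relabelling(self):
        # permuting control storage order must not change matched distances
        eta_e = np.array([0.5, 0.0])
        eta_c = np.array([0.45, 0.05, -0.4])
        ids_c = np.array([100, 101, 102])
        for order in ([0, 1, 2], [2, 1, 0], [1, 0, 2]):
            eta = np.concatenate([eta_e, eta_c[order]])
            exposure = np.array([1, 1, 0, 0, 0])
            ids = np.concatenate([[1, 2], ids_c[order]])
            result = match_nearest(
                propensity_from_logits(eta), exposure, ids, caliper_sd_multiplier=3.0
            )
            assert sorted(result.pairs) == [(1, 100), (2, 101)]

    def test_no_controls_returns_all_unmatched(self):
        eta = np.array([0.1, 0.2])
        result = match_nearest(
            propensity_from_logits(eta), np.array([1, 1]), np.array([5, 6])
        )
        assert result.n_matched == 0
        assert sorted(result.unmatched_exposed) == [5, 6]


class TestSummaryTests:
    def test_group_gap_significant_at_study_size(self):
        # somatization-like summary gap over two groups of 766
        t, df, p = welch_t_from_summary(15.98, 6.29, 766, 21.41, 10.18, 766)
        assert p < 0.001
        assert t < 0  # first group scores lower

    def test_identical_summaries_null(self):
        t, df, p = welch_t_from_summary(10, 2, 50, 10, 2, 50)
        assert t == 0
        assert p == pytest.approx(1.0)

    def test_welch_df_between_bounds(self):
        t, df, p = welch_t_from_summary(1, 1, 30, 0, 3, 40)
        assert min(30, 40) - 1 <= df <= 30 + 40 - 2

    def test_invalid_summaries_rejected(self):
        with pytest.raises(ValueError):
            welch_t_from_summary(1, 0, 30, 0, 1, 30)
        with pytest.raises(ValueError):
            welch_t_from_summary(1, 1, 1, 0, 1, 30)

    def test_chi_square_perfect_independence(self):
        stat, df, p = chi_square_independence([[10, 10], [10, 10]])
        assert stat == 0
        assert p == pytest.approx(1.0)

    def test_chi_square_hand_computed_values(self):
        stat, df, p = chi_square_independence([[20, 0], [0, 20]])
        assert (stat, df) == (pytest.approx(40.0), 1)
        stat, df, p = chi_square_independence([[50, 30], [30, 50]])
        # N(ad - bc)^2 / (r1 r2 c1 c2) = 160 * (2500-900)^2 / 80^4
        assert (stat, df) == (pytest.approx(10.0), 1)

    def test_chi_square_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_independence([[0, 0], [5, 5]])


class TestBalance:
    def test_exact_balance_gives_zero_smd(self):
        x = np.array([1.0, 2.0, 3.0])
        assert standardized_mean_difference(x, x.copy()) == 0.0

    def test_matching_improves_balance_across_seeds(self):
        improved = 0
        for seed in range(10):
            data = sample_dataset(default_scenario(n_per_group=766, seed=seed))
            pre = balance_table(data).set_index("covariate")["smd"].abs()
            matched, _, _ = match_dataset(data)
            post = balance_table(matched).set_index("covariate")["smd"].abs()
            if (post < pre).all():
                improved += 1
        assert improved >= 8

    def test_pre_match_confounding_then_post_match_none(self):
        # chi-square associations significant pre-match become non-significant
        data = sample_dataset(default_scenario(n_per_group=766, seed=1))
        pre = balance_table(data).set_index("covariate")
        matched, _, _ = match_dataset(data)
        post = balance_table(matched).set_index("covariate")
        assert (post["p_value"] > 0.05).all()
        assert post["smd"].abs().max() < 0.1
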