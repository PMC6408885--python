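import warnings

import numpy as np
import pytest
import statsmodels.api as sm

from feedercalls import aggregation, synthetic
from feedercalls.glmm import (DesignError, RESPONSE_FAMILY, build_design,
                              fit_glmm, fit_playback_model, select_interaction,
                              species_subset)


class TestBuildDesign:
    def test_balanced_experiment_gives_full_rank_four_column_matrix(
            self, playback_records_df):
        X, y, codes, terms, labels = build_design(playback_records_df, "latency")
        assert X.shape == (48, 4)
        assert np.linalg.matrix_rank(X) == 4
        assert terms == ["intercept", "time_of_day", "treatment", "order"]
        assert len(labels) == 12

    def test_interaction_adds_a_fifth_column(self, playback_records_df):
        X, _, _, terms, _ = build_design(playback_records_df, "latency",
                                         interaction=True)
        assert X.shape[1] == 5
        assert terms[-1] == "time_of_day:treatment"
        pm, pb = X[:, 1], X[:, 2]
        np.testing.assert_array_equal(X[:, 4], pm * pb)

    def test_reference_levels_are_am_and_control(self, playback_records_df):
        X, _, _, _, _ = build_design(playback_records_df, "latency")
        df = playback_records_df
        np.testing.assert_array_equal(X[:, 1], (df["time_of_day"] == "PM").astype(float))
        np.testing.assert_array_equal(X[:, 2], (df["treatment"] == "PLAYBACK").astype(float))

    def test_order_column_carries_raw_order_values(self, playback_records_df):
        X, _, _, _, _ = build_design(playback_records_df, "latency")
        np.testing.assert_array_equal(X[:, 3], playback_records_df["order"].to_numpy(float))

    def test_single_level_factor_names_the_term(self, playback_records_df):
        am_only = playback_records_df[playback_records_df["time_of_day"] == "AM"]
        with pytest.raises(DesignError, match="time_of_day"):
            build_design(am_only, "latency")

    def test_count_responses_drop_missing_rows(self, playback_records_df):
        n_missing = playback_records_df["initial_recruitment"].isna().sum()
        X, y, _, _, _ = build_design(playback_records_df, "initial_recruitment")
        assert len(y) == len(playback_records_df) - n_missing
        assert not np.isnan(y).any()


class TestGlmReduction:
    """With the site variance pinned to 0 the fit must equal an ordinary GLM."""

    @pytest.mark.parametrize("response,family", [
        ("latency", sm.families.Gamma(sm.families.links.Log())),
        ("initial_recruitment", sm.families.Poisson()),
        ("total_birds", sm.families.Poisson()),
    ])
    def test_matches_statsmodels_irls_to_1e6(self, playback_records_df,
                                             response, family):
        X, y, codes, terms, _ = build_design(playback_records_df, response)
        ours = fit_glmm(X, y, codes, RESPONSE_FAMILY[response],
                        var_fixed=0.0, terms=terms)
        ref = sm.GLM(y, X, family=family).fit()
        np.testing.assert_allclose(ours.coef, ref.params, rtol=1e-6)
        assert ours.re_variance == 0.0
        assert ours.loglik == pytest.approx(float(ref.llf), abs=1e-4) \
            or RESPONSE_FAMILY[response] == "gamma"

    def test_poisson_standard_errors_match_glm(self, playback_records_df):
        X, y, codes, terms, _ = build_design(playback_records_df, "total_birds")
        ours = fit_glmm(X, y, codes, "poisson", var_fixed=0.0, terms=terms)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(ours.se, ref.bse, rtol=1e-5)


class TestMixedFit:
    def test_laplace_agrees_with_25_node_quadrature(self, playback_records_df):
        for response in ("latency", "total_birds"):
            f1 = fit_playback_model(playback_records_df, response, n_quadrature=1)
            f25 = fit_playback_model(playback_records_df, response, n_quadrature=25)
            assert f1.converged and f25.converged
            np.testing.assert_allclose(f1.coef, f25.coef, atol=1e-3)

    def test_site_relabelling_leaves_fixed_effects_unchanged(
            self, playback_records_df):
        relabelled = playback_records_df.copy()
        relabelled["site_id"] = relabelled["site_id"].map(lambda s: "Z" + s[::-1])
        a = fit_playback_model(playback_records_df, "total_birds")
        b = fit_playback_model(relabelled, "total_birds")
        np.testing.assert_allclose(a.coef, b.coef, atol=1e-8)

    def test_fit_is_deterministic(self, playback_records_df):
        a = fit_playback_model(playback_records_df, "latency")
        b = fit_playback_model(playback_records_df, "latency")
        np.testing.assert_array_equal(a.coef, b.coef)

    def test_result_invariants_on_convergence(self, playback_records_df):
        for response in ("latency", "initial_recruitment", "total_birds"):
            fit = fit_playback_model(playback_records_df, response)
            assert fit.converged
            assert (fit.se > 0).all()
            assert ((fit.p > 0) & (fit.p <= 1)).all()
            assert fit.re_variance >= 0
            if RESPONSE_FAMILY[response] == "gamma":
                assert fit.shape > 0

    def test_quadrature_refinement_increases_then_stabilises_loglik(
            self, playback_records_df):
        # the adaptive rule is effectively exact once nodes cover the
        # integrand: 15 and 25 nodes must agree to numerical precision
        f15 = fit_playback_model(playback_records_df, "latency", n_quadrature=15)
        f25 = fit_playback_model(playback_records_df, "latency", n_quadrature=25)
        assert f15.loglik == pytest.approx(f25.loglik, abs=1e-4)

    def test_single_replicate_estimates_near_generating_values(
            self, playback_records_df):
        # one seeded experiment: estimates within 3 Wald SEs of the truth
        truths = {"latency": (3.0, 1.03, -1.17, -0.59),
                  "initial_recruitment": (1.25, -0.09, 0.52, 0.31),
                  "total_birds": (1.70, -0.09, 0.53, 0.31)}
        for response, true in truths.items():
            fit = fit_playback_model(playback_records_df, response)
            assert np.all(np.abs(fit.coef - np.array(true)) < 3.5 * fit.se), response


class TestInteractionRule:
    def test_zero_interaction_data_usually_drops_the_term(self, playback_records_df):
        sel = select_interaction(playback_records_df, "total_birds")
        assert sel.interaction_p == sel.full.term("time_of_day:treatment")["p"]
        if sel.interaction_p >= 0.05:
            assert not sel.kept_interaction
            assert len(sel.chosen.terms) == 4
        else:  # seeded data happened to cross the threshold: full model kept
            assert sel.kept_interaction
            assert len(sel.chosen.terms) == 5

    def test_strong_interaction_is_kept(self):
        effects = synthetic.PlaybackEffectConfig(
            total=synthetic.ResponseEffects(1.70, -0.09, 0.53, 0.31, interaction=1.0))
        trials, vbt = synthetic.simulate_playback_experiment(12, effects, seed=21)
        records = aggregation.playback_records(trials, vbt)
        sel = select_interaction(records, "total_birds")
        assert sel.kept_interaction
        assert sel.chosen.term("time_of_day:treatment")["coefficient"] > 0

    def test_threshold_is_inclusive_of_alpha(self, playback_records_df):
        # a p-value exactly at the threshold must drop the interaction
        p_int = select_interaction(playback_records_df, "total_birds").interaction_p
        at_boundary = select_interaction(playback_records_df, "total_birds",
                                         alpha=p_int)
        assert not at_boundary.kept_interaction
        just_above = select_interaction(playback_records_df, "total_birds",
                                        alpha=np.nextafter(p_int, np.inf))
        assert just_above.kept_interaction


class TestSpeciesSubsets:
    def test_full_data_subset_equals_pooled_fit(self, playback_records_df):
        pooled = select_interaction(playback_records_df, "total_birds")
        again = species_subset({"ALL": playback_records_df}, "total_birds")["ALL"]
        np.testing.assert_allclose(again.chosen.coef, pooled.chosen.coef, atol=1e-8)

    def test_empty_subset_is_skipped_with_warning(self, playback_records_df):
        empty = playback_records_df.iloc[0:0]
        with pytest.warns(UserWarning, match="no usable trials"):
            out = species_subset({"MARTI": empty}, "total_birds")
        assert out["MARTI"] is None

    def test_species_with_shared_effects_recover_the_same_signs(
            self, playback_experiment):
        trials, visits_by_trial = playback_experiment
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            by_species = {
                sp: aggregation.playback_records(trials, visits_by_trial, species=sp)
                for sp in ("GRETI", "BLUTI")
            }
            fits = species_subset(by_species, "total_birds")
        signs = {sp: np.sign(sel.chosen.term("treatment")["coefficient"])
                 for sp, sel in fits.items() if sel is not None}
        assert set(signs.values()) == {1.0}
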