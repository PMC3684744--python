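"""Enumeration, the quadratic pre-screen, and two-stage selection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import dispersalkit as dk
from dispersalkit.glm import fit_glm
from dispersalkit.selection import enumerate_models, screen_quadratic, select_two_stage, term_stability
from dispersalkit.terms import ModelSpec, interaction, linear, quadratic

from conftest import effects_recovered, exact_recovery


class TestEnumeration:
    def test_count_matches_combinatorial_closed_form(self):
        """10 linear candidates, cap 8: sum_{k<=8} C(10,k) = 1013 models."""
        cands = [linear(f"t{i}") for i in range(10)]
        models = list(enumerate_models(cands, cap=8))
        assert len(models) == sum(math.comb(10, k) for k in range(9)) == 1013

    def test_three_linear_candidates_power_set(self):
        cands = [linear(f"t{i}") for i in range(3)]
        assert len(list(enumerate_models(cands, cap=8))) == 8

    def test_includes_intercept_only_and_is_deterministic(self):
        cands = [linear("a"), linear("b")]
        runs = [tuple(tuple(m.terms) for m in enumerate_models(cands, cap=8)) for _ in range(2)]
        assert runs[0] == runs[1]
        assert () in runs[0]

    def test_marginality_by_exhaustive_listing(self):
        """2 mains + their interaction: every admissible subset, and only
        those, compared against a brute-force power-set filter."""
        a, b, ab = linear("a"), linear("b"), interaction("a", "b")
        got = {frozenset(m.terms) for m in enumerate_models([a, b, ab], cap=8)}
        brute = set()
        for r in range(4):
            for combo in itertools.combinations([a, b, ab], r):
                if ab in combo and not (a in combo and b in combo):
                    continue
                brute.add(frozenset(combo))
        assert got == brute
        assert all(ab not in m or {a, b} <= m for m in got)

    def test_quadratic_pair_counts_two_coefficients(self):
        cands = [quadratic("a"), linear("b")]
        # cap 2 admits: {}, {poly(a)}, {b}; not {poly(a), b} (3 coefs)
        assert len(list(enumerate_models(cands, cap=2))) == 3

    def test_cap_validation(self):
        with pytest.raises(ValueError):
            list(enumerate_models([linear("a")], cap=0))


class TestScreenQuadratic:
    def test_detects_curvature(self):
        rng = np.random.default_rng(0)
        t = np.linspace(-2, 2, 40)
        y = 1.0 + 0.2 * t + 1.5 * t**2 + rng.normal(0, 0.3, t.size)
        assert screen_quadratic(y, t) == "quadratic_pair"

    def test_pure_linear_with_noise_stays_linear(self):
        rng = np.random.default_rng(1)
        t = np.linspace(-2, 2, 200)
        y = 1.0 + 0.8 * t + rng.normal(0, 0.2, t.size)
        assert screen_quadratic(y, t) == "linear"

    def test_exactly_linear_zero_noise(self):
        t = np.linspace(0, 5, 30)
        assert screen_quadratic(2 - 0.5 * t, t) == "linear"

    def test_exactly_quadratic_zero_noise(self):
        t = np.linspace(0, 5, 30)
        assert screen_quadratic(1 + t - t**2, t) == "quadratic_pair"

    def test_marginal_significance_pooled(self):
        """The threshold pools significant and marginally significant
        curvature: p just under 0.1 gives a polynomial."""
        # search for a noise realisation with quadratic p in (0.05, 0.1)
        import statsmodels.api as sm
        t = np.linspace(-2, 2, 50)
        tc = t - t.mean()
        X = np.column_stack([np.ones_like(t), tc, tc**2])
        for seed in range(400):
            rng = np.random.default_rng(seed)
            y = 0.5 * t + rng.normal(0, 1.0, t.size)
            p = sm.OLS(y, X).fit().pvalues[2]
            if 0.05 < p < 0.1:
                assert screen_quadratic(y, t) == "quadratic_pair"
                break
            if 0.1 < p < 0.2:
                assert screen_quadratic(y, t) == "linear"
        else:  # pragma: no cover
            pytest.fail("no suitable noise realisation found")

    def test_constant_trait_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            screen_quadratic(np.arange(10.0), np.ones(10))

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            screen_quadratic([1.0, 2, 3], [1.0, 2, 3])


class TestTermStability:
    def test_singleton_top_set(self):
        spec = ModelSpec(None, (linear("a"), linear("b")))
        freq = term_stability([spec])
        assert (freq == 1.0).all()

    def test_shared_and_private_terms(self):
        s1 = ModelSpec(None, (linear("a"), linear("b")))
        s2 = ModelSpec(None, (linear("a"), linear("c")))
        freq = term_stability([s1, s2])
        assert freq["a"] == 1.0 and freq["b"] == 0.5 and freq["c"] == 0.5

    def test_empty_top_set_rejected(self):
        with pytest.raises(ValueError):
            term_stability([])


class TestTwoStage:
    def test_zero_noise_recovers_generating_model(self, trait_table_29, candidates_10):
        true = dk.TrueModel(
            "mean_distance",
            (dk.TrueTerm("larval_growth_rate", "linear", -1.2),
             dk.TrueTerm("ovigeny_index", "linear", 1.0)),
            noise_sd=0.0,
        )
        sim = dk.simulate_responses(trait_table_29, true, seed=0)
        sel = select_two_stage(
            sim.latent, dk.predictor_frame(trait_table_29), candidates=candidates_10,
            element="mean_distance",
        )
        assert exact_recovery(sel.chosen.spec, true)
        assert sel.chosen.rsquared == pytest.approx(1.0, abs=1e-10)

    def test_noise_candidates_never_displace_true_terms(self, trait_table_29):
        """At zero noise the chosen model keeps the true variables no matter
        how many pure-noise candidates compete."""
        true = dk.TrueModel(
            "mean_distance",
            (dk.TrueTerm("voltinism", "linear", 1.0),
             dk.TrueTerm("mate_location", "linear", -1.0)),
            noise_sd=0.0,
        )
        sim = dk.simulate_responses(trait_table_29, true, seed=1)
        all_cands = list(dk.predictor_frame(trait_table_29).columns)
        sel = select_two_stage(
            sim.latent, dk.predictor_frame(trait_table_29), candidates=all_cands,
            element="mean_distance", max_coef=6,
        )
        assert {"voltinism", "mate_location"} <= set(sel.chosen.spec.variables)
        assert exact_recovery(sel.chosen.spec, true)

    def test_interaction_recovered(self, trait_table_29, candidates_10):
        true = dk.TrueModel(
            "mean_distance",
            (dk.TrueTerm("voltinism", "linear", 1.0),
             dk.TrueTerm("fecundity", "linear", 0.8),
             dk.TrueTerm(("voltinism", "fecundity"), "interaction", 1.0)),
            noise_sd=0.0,
        )
        sim = dk.simulate_responses(trait_table_29, true, seed=2)
        sel = select_two_stage(
            sim.latent, dk.predictor_frame(trait_table_29), candidates=candidates_10,
            element="mean_distance",
        )
        assert effects_recovered(sel.chosen.spec, true)

    def test_best_model_delta_is_zero_and_chosen_max_r2(self, trait_table_29, candidates_10,
                                                        recovery_true_model):
        sim = dk.simulate_responses(trait_table_29, recovery_true_model, seed=3)
        sel = select_two_stage(
            sim.latent, dk.predictor_frame(trait_table_29), candidates=candidates_10,
            element="mean_distance",
        )
        assert sel.stage2_top["delta_aicc"].iloc[0] == 0.0
        chosen_r2 = sel.chosen.rsquared
        assert (sel.stage2_top["rsquared"] <= chosen_r2 + 1e-12).all()
        # the chosen spec is a member of the stage-2 top set
        assert any(set(s.terms) == set(sel.chosen.spec.terms) for s in sel.stage2_specs)

    def test_search_aicc_matches_independent_refit(self, trait_table_29, candidates_10,
                                                   recovery_true_model):
        """Every stage-2 top-set model's AICc from the Gram search equals a
        from-scratch statsmodels refit."""
        sim = dk.simulate_responses(trait_table_29, recovery_true_model, seed=4)
        pred = dk.predictor_frame(trait_table_29)
        sel = select_two_stage(sim.latent, pred, candidates=candidates_10,
                               element="mean_distance")
        for spec, aicc_val in zip(sel.stage2_specs, sel.stage2_top["aicc"]):
            refit = fit_glm(ModelSpec(None, spec.terms), sim.latent, pred)
            assert refit.aicc == pytest.approx(aicc_val, abs=1e-8)

    def test_missing_data_complete_cases(self, trait_table_29, candidates_10,
                                         recovery_true_model):
        sim = dk.simulate_responses(trait_table_29, recovery_true_model, seed=5)
        pred = dk.predictor_frame(trait_table_29)
        pred.loc[pred.index[:3], "voltinism"] = np.nan
        sel = select_two_stage(sim.latent, pred, candidates=candidates_10,
                               element="mean_distance")
        assert sel.n == 26

    def test_no_candidates_rejected(self, trait_table_29):
        with pytest.raises(ValueError):
            select_two_stage(pd.Series(dtype=float), dk.predictor_frame(trait_table_29),
                             candidates=[])


class TestModelInterface:
    def test_from_tables_and_summary(self, trait_table_29, candidates_10, recovery_true_model):
        sim = dk.simulate_responses(trait_table_29, recovery_true_model, seed=6)
        model = dk.DispersalTraitModel.from_tables(
            sim.dataset, trait_table_29, "mean_distance", candidates=candidates_10
        )
        res = model.fit()
        text = res.summary()
        assert "mean_distance" in text and "AICc" in text
        assert res.nobs == 29
        assert set(res.term_stability.index) >= {t.label for t in res.spec.terms}
        assert (res.term_stability.loc[[t.label for t in res.spec.terms]] > 0).all()
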