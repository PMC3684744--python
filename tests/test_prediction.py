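"""Prediction for unmeasured species: truncation, applicability, summaries."""

import numpy as np
import pandas as pd
import pytest

import dispersalkit as dk
from dispersalkit.prediction import applicability_mask, predict_species, summarize_distribution
from dispersalkit.terms import ModelSpec, linear


@pytest.fixture(scope="module")
def fitted(trait_table_29):
    true = dk.TrueModel(
        "propensity",
        (dk.TrueTerm("thermal_tolerance", "linear", -0.15),),
        intercept=-0.5, noise_sd=0.05,
    )
    sim = dk.simulate_responses(trait_table_29, true, seed=50)
    model = dk.DispersalTraitModel(
        sim.dataset.series("propensity"), dk.predictor_frame(trait_table_29),
        "propensity", candidates=["thermal_tolerance", "fecundity", "voltinism"],
    )
    fit = model.fit_spec(ModelSpec("propensity", (linear("thermal_tolerance"),)))
    return fit, dk.predictor_frame(trait_table_29)


class TestPredictSpecies:
    def test_back_transform_and_flags(self, fitted):
        fit, pred = fitted
        ps = predict_species(fit, pred, training=pred)
        assert set(ps.table.columns) == {"pred_transformed", "pred_natural", "truncated", "in_range"}
        nat = ps.table["pred_natural"].dropna()
        assert ((nat >= 0) & (nat <= 1)).all()
        # untruncated rows invert exactly
        ok = ~ps.table["truncated"]
        np.testing.assert_allclose(
            ps.table.loc[ok, "pred_natural"],
            np.square(ps.table.loc[ok, "pred_transformed"]),
            atol=1e-10,
        )

    def test_out_of_image_prediction_truncated(self, fitted):
        import dataclasses

        fit, pred = fitted
        # force a positive transformed prediction (outside the -sqrt image)
        shifted = dataclasses.replace(fit, params=fit.params.copy())
        shifted.params["intercept"] = 2.0
        ps = predict_species(shifted, pred, training=pred)
        assert ps.table["truncated"].any()
        assert (ps.table.loc[ps.table["truncated"], "pred_natural"].dropna() == 0.0).all()

    def test_species_with_missing_retained_trait_skipped(self, fitted):
        fit, pred = fitted
        pred2 = pred.copy()
        pred2.loc[pred2.index[0], "thermal_tolerance"] = np.nan
        ps = predict_species(fit, pred2, training=pred)
        assert ps.skipped == [pred2.index[0]]
        assert len(ps.table) == len(pred2) - 1


class TestApplicability:
    def test_all_inside_training_ranges(self, fitted):
        fit, pred = fitted
        mask = applicability_mask(fit, pred, training=pred)
        assert mask.all()

    def test_value_above_training_max_flagged(self, fitted):
        fit, pred = fitted
        out = pred.copy()
        sp = out.index[3]
        out.loc[sp, "thermal_tolerance"] = pred["thermal_tolerance"].max() * 1.1
        mask = applicability_mask(fit, out, training=pred)
        assert not mask[sp]
        assert mask.drop(sp).all()

    def test_boundary_value_in_range(self, fitted):
        """Closed-interval convention: a value exactly at the training max
        is applicable."""
        fit, pred = fitted
        out = pred.copy()
        sp = out.index[0]
        out.loc[sp, "thermal_tolerance"] = pred["thermal_tolerance"].max()
        assert applicability_mask(fit, out, training=pred)[sp]

    def test_out_of_range_natural_value_suppressed_unless_extrapolating(self, fitted):
        fit, pred = fitted
        out = pred.copy()
        sp = out.index[5]
        out.loc[sp, "thermal_tolerance"] = pred["thermal_tolerance"].max() + 2
        ps = predict_species(fit, out, training=pred)
        assert np.isnan(ps.table.loc[sp, "pred_natural"])
        assert np.isfinite(ps.table.loc[sp, "pred_transformed"])
        ps2 = predict_species(fit, out, training=pred, extrapolate=True)
        assert np.isfinite(ps2.table.loc[sp, "pred_natural"])


class TestSummaries:
    def test_quantile_matches_order_statistics_oracle(self, fitted):
        fit, pred = fitted
        ps = predict_species(fit, pred, training=pred)
        vals = np.arange(1.0, 11.0)
        ps.table = ps.table.iloc[:10].copy()
        ps.table["pred_natural"] = vals / 20.0
        summ = summarize_distribution(ps)
        # type-7: q90 of (1..10)/20 is (9.1)/20 via linear interpolation
        assert summ.loc["predicted", "q90"] == pytest.approx(9.1 / 20.0)
        assert summ.loc["predicted", "mean"] == pytest.approx(vals.mean() / 20.0)

    def test_identical_groups_identical_summaries(self, fitted):
        fit, pred = fitted
        ps = predict_species(fit, pred, training=pred)
        obs = pd.Series(ps.table["pred_natural"].to_numpy(), index=ps.table.index)
        summ = summarize_distribution(ps, observed=obs)
        pd.testing.assert_series_equal(
            summ.loc["predicted"], summ.loc["observed"], check_names=False
        )

    def test_two_value_group(self, fitted):
        fit, pred = fitted
        ps = predict_species(fit, pred, training=pred)
        ps.table = ps.table.iloc[:2].copy()
        summ = summarize_distribution(ps)
        assert summ.loc["predicted", "n"] == 2

    def test_empty_group_rejected(self, fitted):
        fit, pred = fitted
        ps = predict_species(fit, pred, training=pred)
        ps.table = ps.table.iloc[:1].copy()
        with pytest.raises(ValueError, match=">= 2 values"):
            summarize_distribution(ps)


def test_results_predict_roundtrip(trait_table_29, candidates_10, recovery_true_model):
    """End to end: selection then prediction on a fresh, larger table with
    truncation bounds respected."""
    sim = dk.simulate_responses(trait_table_29, recovery_true_model, seed=60)
    res = dk.DispersalTraitModel.from_tables(
        sim.dataset, trait_table_29, "mean_distance", candidates=candidates_10
    ).fit()
    big = dk.simulate_trait_table(dk.SimulationConfig(n_species=142, seed=61))
    ps = res.predict(big)
    assert len(ps.table) == 142
    nat = ps.table["pred_natural"].dropna()
    assert (nat > 0).all()  # mean distance: exp back-transform, no truncation
    assert not ps.table["truncated"].any()


def test_plot_helpers_render(fitted, trait_table_29):
    """Smoke test of the matplotlib helpers on a non-interactive backend."""
    import matplotlib

    matplotlib.use("Agg")
    from dispersalkit.plotting import plot_dispersal_distribution, plot_observed_vs_predicted
    from dispersalkit.validation import cross_validate

    fit, pred = fitted
    y = pd.Series(fit.design.matrix(pred) @ fit.params.to_numpy(), index=pred.index)
    cv = cross_validate(fit.spec, y + 0.01 * np.arange(len(y)), pred, n_partitions=20, seed=1)
    ax = plot_observed_vs_predicted(cv, label="propensity")
    assert ax.get_xlabel()
    ps = predict_species(fit, pred, training=pred)
    ax2 = plot_dispersal_distribution(ps)
    assert ax2.get_ylabel() == "density"
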