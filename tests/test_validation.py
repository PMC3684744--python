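"""Cross-validation metrics: rightness, imprecision, and gain reports."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dispersalkit as dk
from dispersalkit.terms import ModelSpec, linear
from dispersalkit.validation import (
    compare_models,
    cross_validate,
    imprecision,
    performance_with_se,
    rightness,
)


class TestRightness:
    def test_perfect_predictions_give_unit_slope(self):
        x = np.array([0.3, 1.2, -0.5, 2.0])
        assert rightness(x, x) == pytest.approx(1.0)

    def test_hand_ols_oracle(self):
        # obs (1,2,3) on pred (1,1,2): Sxy = 1, Sxx = 2/3 -> slope 1.5
        assert rightness([1, 2, 3], [1, 1, 2]) == pytest.approx(1.5)

    def test_constant_predictions_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rightness([1, 2, 3], [1, 1, 1])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            rightness([1, 2], [1, 2])


class TestImprecision:
    def test_perfect_predictions(self):
        x = np.array([0.3, 1.2, -0.5])
        assert imprecision(x, x) == 0.0

    def test_absolute_arithmetic_oracle(self):
        # |1-1| + |2-1| + |3-2| = 2, over 3 pairs
        assert imprecision([1, 2, 3], [1, 1, 2]) == pytest.approx(2.0 / 3.0)

    def test_relative_division_by_observed(self):
        assert imprecision([2, 4], [1, 2], relative=True) == pytest.approx(0.5)

    def test_relative_with_zero_observation_rejected(self):
        with pytest.raises(ValueError, match="zero observation"):
            imprecision([0.0, 1.0], [0.1, 1.0], relative=True)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_relative_invariant_under_rescaling(self, c):
        obs = np.array([1.0, 2.5, 4.0])
        pred = np.array([1.2, 2.0, 4.4])
        base = imprecision(obs, pred, relative=True)
        assert imprecision(c * obs, c * pred, relative=True) == pytest.approx(base, rel=1e-9)


@pytest.fixture(scope="module")
def noisy_fixture():
    traits = dk.simulate_trait_table(dk.SimulationConfig(n_species=29, seed=100))
    true = dk.TrueModel(
        "mean_distance",
        (dk.TrueTerm("larval_growth_rate", "linear", -1.2),
         dk.TrueTerm("ovigeny_index", "linear", 1.0)),
        noise_sd=0.25,
    )
    sim = dk.simulate_responses(traits, true, seed=101)
    spec = ModelSpec("mean_distance", (linear("larval_growth_rate"), linear("ovigeny_index")))
    return sim.latent, dk.predictor_frame(traits), spec


class TestCrossValidate:
    def test_partition_sizes_75_25(self, noisy_fixture):
        y, pred, spec = noisy_fixture
        cv = cross_validate(spec, y, pred, n_partitions=10, seed=0)
        assert cv.train_size == 22  # round(0.75 * 29) half-up
        assert (cv.predictions["n_heldout"].sum()) == 10 * (29 - 22)

    def test_fixed_seed_reproducible(self, noisy_fixture):
        y, pred, spec = noisy_fixture
        a = cross_validate(spec, y, pred, n_partitions=20, seed=42).predictions
        b = cross_validate(spec, y, pred, n_partitions=20, seed=42).predictions
        pd.testing.assert_frame_equal(a, b)

    def test_zero_noise_heldout_predictions_exact(self, trait_table_29):
        true = dk.TrueModel("mean_distance",
                            (dk.TrueTerm("voltinism", "linear", 1.0),), noise_sd=0.0)
        sim = dk.simulate_responses(trait_table_29, true, seed=1)
        spec = ModelSpec("mean_distance", (linear("voltinism"),))
        cv = cross_validate(spec, sim.latent, dk.predictor_frame(trait_table_29),
                            n_partitions=50, seed=1)
        held = cv.predictions.dropna(subset=["mean"])
        np.testing.assert_allclose(
            held["mean"].to_numpy(), cv.observed.loc[held.index].to_numpy(), atol=1e-8
        )

    def test_too_few_species(self):
        idx = pd.Index([f"s{i}" for i in range(5)])
        y = pd.Series(np.arange(5.0), index=idx)
        data = pd.DataFrame({"t": np.arange(5.0)}, index=idx)
        with pytest.raises(ValueError, match=">= 8 species"):
            cross_validate(ModelSpec(None, (linear("t"),)), y, data)


class TestPerformance:
    def test_zero_noise_rightness_one_imprecision_zero(self, trait_table_29):
        true = dk.TrueModel("mean_distance",
                            (dk.TrueTerm("voltinism", "linear", 1.0),), noise_sd=0.0)
        sim = dk.simulate_responses(trait_table_29, true, seed=2)
        spec = ModelSpec("mean_distance", (linear("voltinism"),))
        perf = performance_with_se(spec, sim.latent, dk.predictor_frame(trait_table_29),
                                   n_repeats=5, n_partitions=30, seed=3, relative=False)
        assert perf.rightness == pytest.approx(1.0, abs=1e-8)
        assert perf.imprecision < 1e-8
        assert perf.rightness_se == pytest.approx(0.0, abs=1e-8)

    def test_two_seeds_give_overlapping_estimates(self, noisy_fixture):
        y, pred, spec = noisy_fixture
        a = performance_with_se(spec, y, pred, n_repeats=8, n_partitions=40, seed=1)
        b = performance_with_se(spec, y, pred, n_repeats=8, n_partitions=40, seed=2)
        assert a.rightness != b.rightness
        assert abs(a.rightness - b.rightness) < 4 * (a.rightness_se + b.rightness_se)

    def test_single_repeat_se_missing(self, noisy_fixture):
        y, pred, spec = noisy_fixture
        perf = performance_with_se(spec, y, pred, n_repeats=1, n_partitions=20, seed=4)
        assert perf.rightness_se is None and perf.imprecision_se is None

    def test_element_convention_sets_relative_flag(self, noisy_fixture):
        y, pred, spec = noisy_fixture
        perf = performance_with_se(spec, y, pred, n_repeats=2, n_partitions=10, seed=5)
        assert perf.relative  # mean distance is scale dependent


class TestCompareModels:
    def test_identical_models_null_gains(self, noisy_fixture):
        y, pred, spec = noisy_fixture
        a = performance_with_se(spec, y, pred, n_repeats=6, n_partitions=30, seed=7)
        b = performance_with_se(spec, y, pred, n_repeats=6, n_partitions=30, seed=7)
        gain = compare_models(a, b)
        assert gain.gain_rightness == pytest.approx(0.0, abs=1e-12)
        assert gain.gain_precision == pytest.approx(1.0, abs=1e-12)
        assert gain.p_rightness > 0.99 and gain.p_imprecision > 0.99

    def test_trait_model_beats_wing_only_reference(self, noisy_fixture):
        """Syndrome-structured data, wing size pure noise: precision gain > 1."""
        y, pred, spec = noisy_fixture
        trait_perf = performance_with_se(spec, y, pred, n_repeats=10, n_partitions=50, seed=8)
        ref_perf = performance_with_se(
            dk.wing_reference_spec("mean_distance"), y, pred,
            n_repeats=10, n_partitions=50, seed=8, relative=trait_perf.relative,
        )
        gain = compare_models(trait_perf, ref_perf)
        assert gain.gain_precision > 1.0
        assert gain.p_imprecision < 0.01

    def test_mismatched_repeats_rejected(self, noisy_fixture):
        y, pred, spec = noisy_fixture
        a = performance_with_se(spec, y, pred, n_repeats=3, n_partitions=10, seed=9)
        b = performance_with_se(spec, y, pred, n_repeats=4, n_partitions=10, seed=9)
        with pytest.raises(ValueError):
            compare_models(a, b)
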