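import numpy as np
import pandas as pd
import pytest

import dispersalkit as dk


@pytest.fixture(scope="session")
def trait_table_29():
    """Synthetic table at the species count of the mean-distance dataset."""
    return dk.simulate_trait_table(dk.SimulationConfig(n_species=29, seed=1234))


@pytest.fixture(scope="session")
def candidates_10():
    """Ten candidate predictors used by the recovery fixtures."""
    return [
        "larval_growth_rate", "ovigeny_index", "fecundity", "voltinism",
        "flight_period", "myrmecophily", "mate_location", "thermal_tolerance",
        "adult_lifetime", "log_wing_length",
    ]


@pytest.fixture(scope="session")
def recovery_true_model():
    """Two strong linear effects (>= 1 response-SD per trait-SD) among the candidates."""
    return dk.TrueModel(
        "mean_distance",
        (
            dk.TrueTerm("larval_growth_rate", "linear", -1.2),
            dk.TrueTerm("ovigeny_index", "linear", 1.0),
        ),
        intercept=-1.5,
        noise_sd=0.25,
    )


def effects_recovered(chosen_spec, true_model):
    """Effect-level recovery: every generating effect is contained in the model.

    A generating linear effect counts as present when the trait enters as a
    linear term or as a quadratic pair (which includes the linear slope);
    quadratic and interaction effects must match in kind.
    """
    chosen = set(chosen_spec.terms)
    for t in true_model.terms:
        want = t.model_term
        if want in chosen:
            continue
        if t.form == "linear" and dk.quadratic(t.traits[0]) in chosen:
            continue
        return False
    return True


def exact_recovery(chosen_spec, true_model):
    """Chosen variables equal the generating variables and effects are contained."""
    return (
        effects_recovered(chosen_spec, true_model)
        and chosen_spec.variables == true_model.variables
    )
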