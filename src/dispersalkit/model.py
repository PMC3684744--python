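"""Top-level modelling interface: DispersalTraitModel / DispersalTraitResults.

The model object holds one dispersal response (on its transformed scale)
and the candidate predictor table; ``fit()`` runs the two-stage exhaustive
AICc selection and returns a results object carrying the chosen GLM, its
coefficient table, the top model sets, and entry points for everything
downstream: cross-validated quality assessment, comparison against the
wing-size-only reference, R^2 partitioning, the PGLS phylogenetic check,
and prediction for species without dispersal measurements.

Typical use::

    model = DispersalTraitModel.from_tables(dispersal, traits, "mean_distance")
    res = model.fit()
    print(res.summary())
    perf = res.cross_validate(seed=1)
    gain = res.compare_with_reference(seed=1)
    imp = res.importance()
    preds = res.predict(all_species_traits)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import DispersalDataset
from .elements import Element
from .glm import FitResult, fit_glm
from .importance import ImportanceDecomposition, r2_partition_lmg
from .phylo import PGLSModel, PGLSResult, Phylogeny
from .prediction import PredictionSet, predict_species
from .selection import SelectionResult, select_two_stage
from .terms import ModelSpec, linear
from .traits import TraitTable, predictor_frame
from .validation import (
    CVPerformance,
    GainReport,
    compare_models,
    cross_validate,
    performance_with_se,
)

__all__ = ["DispersalTraitModel", "DispersalTraitResults", "wing_reference_spec"]


def wing_reference_spec(element: Element | str | None) -> ModelSpec:
    """The reference model: log wing length as the only regressor."""
    return ModelSpec(element, (linear("log_wing_length"),))


class DispersalTraitModel:
    """One dispersal element modelled from candidate life-history traits.

    Parameters
    ----------
    response : Series
        Transformed-scale dispersal values indexed by species.
    predictors : DataFrame
        Candidate predictor columns (same index); build it from a
        :class:`~dispersalkit.traits.TraitTable` with
        :func:`~dispersalkit.traits.predictor_frame`, which log-transforms
        wing length.
    element : Element or str, optional
        Which dispersal measurement the response is; controls
        back-transformation and the imprecision convention downstream.
    candidates : sequence of str, optional
        Subset of predictor columns to search over (default: all).
    """

    def __init__(self, response: pd.Series, predictors: pd.DataFrame,
                 element: Element | str | None = None, candidates=None):
        self.element = Element(element) if element is not None else None
        self.candidates = list(candidates) if candidates is not None else list(predictors.columns)
        common = response.index.intersection(predictors.index)
        self.response = response.loc[common].astype(float)
        self.predictors = predictors.loc[common]

    @classmethod
    def from_tables(cls, dispersal: DispersalDataset, traits: TraitTable,
                    element: Element | str, candidates=None) -> "DispersalTraitModel":
        """Build from a dispersal dataset and a trait table."""
        element = Element(element)
        return cls(dispersal.series(element), predictor_frame(traits), element, candidates)

    def fit(self, max_coef: int = 8, delta: float = 2.0, screen_alpha: float = 0.1,
            interactions: bool = True) -> "DispersalTraitResults":
        """Run the two-stage exhaustive AICc selection."""
        sel = select_two_stage(
            self.response, self.predictors, candidates=self.candidates,
            element=self.element, max_coef=max_coef, delta=delta,
            screen_alpha=screen_alpha, interactions=interactions,
        )
        return DispersalTraitResults(self, sel)

    def fit_spec(self, spec: ModelSpec) -> FitResult:
        """Fit one fixed specification (no selection)."""
        frame = pd.concat([self.response.rename("__y__"), self.predictors], axis=1).dropna(
            subset=["__y__", *spec.variables]
        )
        return fit_glm(spec, frame["__y__"], frame)


class DispersalTraitResults:
    """Results of the two-stage selection for one dispersal element.

    Exposes the chosen model's coefficient table (``params``, ``bse``,
    ``pvalues``), fit statistics, the stage top sets with per-term
    inclusion frequencies, and the downstream analyses.
    """

    def __init__(self, model: DispersalTraitModel, selection: SelectionResult):
        self.model = model
        self.selection = selection
        self.chosen: FitResult = selection.chosen

    # -- chosen-model surface -------------------------------------------------
    @property
    def spec(self) -> ModelSpec:
        return self.chosen.spec

    @property
    def params(self) -> pd.Series:
        return self.chosen.params

    @property
    def bse(self) -> pd.Series:
        return self.chosen.bse

    @property
    def pvalues(self) -> pd.Series:
        return self.chosen.pvalues

    @property
    def rsquared(self) -> float:
        return self.chosen.rsquared

    @property
    def rsquared_adj(self) -> float:
        return self.chosen.rsquared_adj

    @property
    def aicc(self) -> float:
        return self.chosen.aicc

    @property
    def nobs(self) -> int:
        return self.chosen.nobs

    @property
    def term_stability(self) -> pd.Series:
        """Inclusion frequency of each term across the stage-2 top set."""
        return self.selection.term_frequency

    def summary(self) -> str:
        sel = self.selection
        lines = [
            "Two-stage exhaustive AICc selection",
            "=" * 60,
            f"response: {sel.element.value if sel.element else 'y'} (n = {sel.n} complete cases)",
            f"stage 1: {sel.stage1_n_models} models searched, {len(sel.stage1_specs)} within delta AICc <= 2",
            f"stage 2: {sel.stage2_n_models} models searched, {len(sel.stage2_specs)} within delta AICc <= 2",
            "",
            self.chosen.summary(),
            "",
            "Term stability (inclusion frequency in the stage-2 top set):",
        ]
        lines += [f"  {k:<40}{v:>8.2f}" for k, v in self.term_stability.items()]
        return "\n".join(lines)

    # -- downstream analyses --------------------------------------------------
    def cross_validate(self, n_repeats: int = 20, n_partitions: int = 100,
                       frac: float = 0.75, seed=None) -> CVPerformance:
        """Cross-validated rightness/imprecision of the chosen model."""
        return performance_with_se(
            self.spec, self.model.response, self.model.predictors,
            n_repeats=n_repeats, n_partitions=n_partitions, frac=frac, seed=seed,
            label=str(self.spec),
        )

    def compare_with_reference(self, reference_spec: ModelSpec | None = None,
                               n_repeats: int = 20, n_partitions: int = 100,
                               frac: float = 0.75, seed=None) -> GainReport:
        """Gain metrics against the wing-size-only reference model."""
        if reference_spec is None:
            reference_spec = wing_reference_spec(self.model.element)
        rng = np.random.default_rng(seed)
        trait_perf = self.cross_validate(n_repeats=n_repeats, n_partitions=n_partitions,
                                         frac=frac, seed=rng)
        ref_perf = performance_with_se(
            reference_spec, self.model.response, self.model.predictors,
            relative=trait_perf.relative, n_repeats=n_repeats,
            n_partitions=n_partitions, frac=frac, seed=rng, label=str(reference_spec),
        )
        return compare_models(trait_perf, ref_perf)

    def importance(self, mode: str = "unit", **kwargs) -> ImportanceDecomposition:
        """LMG partition of the chosen model's R^2 among its terms."""
        return r2_partition_lmg(self.spec, self.model.response, self.model.predictors,
                                mode=mode, **kwargs)

    def pgls_check(self, tree: Phylogeny, **kwargs) -> PGLSResult:
        """Refit the chosen model by PGLS with ML Pagel's lambda.

        The preliminary check that species can be treated as independent:
        a negligible lambda (LR test not rejecting 0) justifies the plain
        GLM.
        """
        return PGLSModel(self.spec, self.model.response, self.model.predictors, tree).fit(**kwargs)

    def predict(self, traits: TraitTable | pd.DataFrame, extrapolate: bool = False) -> PredictionSet:
        """Predict this dispersal element for a (full) species table.

        Training trait ranges come from the species the model was fitted
        on; out-of-range species get no natural-scale value unless
        ``extrapolate`` is set.
        """
        frame = traits if isinstance(traits, pd.DataFrame) else predictor_frame(traits)
        training = self.model.predictors.loc[
            self.model.response.dropna().index.intersection(self.model.predictors.index)
        ]
        return predict_species(self.chosen, frame, training=training, extrapolate=extrapolate)

    def __repr__(self) -> str:
        return f"DispersalTraitResults({self.spec}, n={self.nobs}, R^2={self.rsquared:.3f})"
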