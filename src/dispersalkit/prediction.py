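"""Trait-based prediction of dispersal for species without measurements.

A selected model is applied to the full trait table; transformed-scale
predictions are back-transformed to the natural scale with truncation into
each element's valid domain (LDD frequency to (0, 1]; propensity and gene
flow to [0, 1]; mean dispersal distance needs none, the exponential
back-transform being always positive).

Because a trait's effect is only known over the range spanned by the
species used to fit the model, species whose retained-trait values fall
outside the training min-max (closed interval) are flagged not applicable
and their natural-scale predictions suppressed by default; an
``extrapolate`` override reports them anyway.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.stats

from .data import DispersalDataset
from .elements import Element, clip_to_domain
from .glm import FitResult

__all__ = ["PredictionSet", "predict_species", "applicability_mask", "summarize_distribution"]


@dataclasses.dataclass
class PredictionSet:
    """Per-species predictions of one dispersal element.

    ``table`` is indexed by species with columns ``pred_transformed``,
    ``pred_natural`` (NaN for out-of-range species unless extrapolating),
    ``truncated`` and ``in_range``; ``training_ranges`` records the
    [min, max] per retained trait used for the applicability flags, and
    ``skipped`` the species lacking a retained trait value.
    """

    element: Element
    table: pd.DataFrame
    training_ranges: pd.DataFrame
    skipped: list[str]

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "element", self.element.value)
        out.to_csv(path)


def applicability_mask(chosen: FitResult, traits: pd.DataFrame, training: pd.DataFrame) -> pd.Series:
    """Flag species whose retained-trait values lie inside training ranges.

    A species is in range when every trait retained by the model falls
    within the closed [min, max] interval observed in the training data.
    """
    variables = sorted(chosen.spec.variables)
    lo = training[variables].min()
    hi = training[variables].max()
    sub = traits[variables]
    ok = ((sub >= lo) & (sub <= hi)).all(axis=1) & sub.notna().all(axis=1)
    return ok.rename("in_range")


def predict_species(
    chosen: FitResult,
    traits: pd.DataFrame,
    training: pd.DataFrame | None = None,
    extrapolate: bool = False,
) -> PredictionSet:
    """Apply a selected model to a predictor table and back-transform.

    ``traits`` and ``training`` are predictor frames (wing length already
    log-transformed, as at model building).  Species missing any retained
    trait are skipped and listed; out-of-range species keep their
    transformed-scale prediction but get no natural-scale value unless
    ``extrapolate`` is set.
    """
    element = chosen.spec.element
    if element is None:
        raise ValueError("the chosen model carries no dispersal element")
    variables = sorted(chosen.spec.variables)
    usable = traits[variables].notna().all(axis=1)
    skipped = list(traits.index[~usable])
    frame = traits.loc[usable]
    eta = chosen.predict(frame)
    raw, truncated = clip_to_domain(element, eta)
    if training is not None:
        in_range = applicability_mask(chosen, frame, training)
    else:
        in_range = pd.Series(True, index=frame.index, name="in_range")
    natural = np.asarray(raw, dtype=float).copy()
    if not extrapolate:
        natural[~in_range.to_numpy()] = np.nan
    table = pd.DataFrame(
        {
            "pred_transformed": eta,
            "pred_natural": natural,
            "truncated": truncated,
            "in_range": in_range.to_numpy(),
        },
        index=frame.index,
    )
    variables_frame = (training if training is not None else frame)[variables]
    ranges = pd.DataFrame({"min": variables_frame.min(), "max": variables_frame.max()})
    return PredictionSet(element=element, table=table, training_ranges=ranges, skipped=skipped)


def summarize_distribution(
    preds: PredictionSet,
    observed: DispersalDataset | pd.Series | None = None,
    quantiles: tuple[float, ...] = (0.1, 0.5, 0.9),
) -> pd.DataFrame:
    """Distributional summary of predicted (and observed) natural values.

    Rows are the groups ('predicted', and 'observed' when supplied);
    columns are n, mean, min, max and the requested quantiles (linear
    interpolation of order statistics, the type-7 convention, which the
    '90% of species' statements depend on).  A Gaussian kernel-density
    estimate per group is attached as ``summary.attrs['kde']`` for
    plotting.
    """
    groups: dict[str, np.ndarray] = {}
    pred_vals = preds.table["pred_natural"].dropna().to_numpy()
    groups["predicted"] = pred_vals
    if observed is not None:
        if isinstance(observed, DispersalDataset):
            obs_vals = observed.series(preds.element, transformed=False).to_numpy()
        else:
            obs_vals = pd.Series(observed).dropna().to_numpy()
        groups["observed"] = obs_vals
    rows, kdes = {}, {}
    for name, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {name!r} needs >= 2 values")
        row = {"n": vals.size, "mean": vals.mean(), "min": vals.min(), "max": vals.max()}
        for q in quantiles:
            row[f"q{int(round(q * 100))}"] = float(np.quantile(vals, q))  # type-7
        rows[name] = row
        kdes[name] = scipy.stats.gaussian_kde(vals) if np.ptp(vals) > 0 else None
    out = pd.DataFrame(rows).T
    out.attrs["kde"] = kdes
    return out
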