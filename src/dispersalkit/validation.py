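"""Cross-validated quality assessment of dispersal predictions.

The protocol: random 75-25 partitions of the species with measured
dispersal; the model (a fixed term set) is re-parameterized on each
training partition and applied to the held-out species; 100 independent
partitions give per-species mean predictions and their standard errors.
Two performance measures are computed from observations vs mean
predictions:

* **rightness** — the slope of the regression of observations on mean
  predictions (ideally 1);
* **imprecision** — the mean absolute difference between observed and
  predicted values; for the scale-dependent measures (mean dispersal
  distance, long-distance dispersal frequency) each difference is divided
  by the observed value.

Twenty independent repeats of the whole cross-validation give standard
errors on both measures.  Relative performance against the reference model
(wing size as the only regressor) is reported as a difference in rightness
and a ratio of imprecisions, with significance from a regression of the
per-repeat performance on the model-type indicator.

All metrics operate on the transformed scale on which the models are fit.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .elements import RELATIVE_IMPRECISION_ELEMENTS, Element
from .terms import Design, ModelSpec

__all__ = [
    "cross_validate",
    "rightness",
    "imprecision",
    "performance_with_se",
    "compare_models",
    "CrossValidation",
    "CVPerformance",
    "GainReport",
]


def rightness(observed, predicted) -> float:
    """Slope of the OLS regression of observations on predictions.

    Includes an intercept; a perfect predictor gives exactly 1.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size != pred.size or obs.size < 3:
        raise ValueError("need >= 3 matched (observed, predicted) pairs")
    if np.ptp(pred) == 0:
        raise ValueError("predictions are constant: regression slope undefined")
    pc = pred - pred.mean()
    return float(pc @ (obs - obs.mean()) / (pc @ pc))


def imprecision(observed, predicted, relative: bool = False) -> float:
    """Mean absolute difference between observed and predicted values.

    With ``relative=True`` each difference is divided by the corresponding
    observed value (scale-dependent measures); a zero observation is then
    an error.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size != pred.size or obs.size < 1:
        raise ValueError("need >= 1 matched (observed, predicted) pair")
    diff = np.abs(obs - pred)
    if relative:
        if np.any(obs == 0):
            raise ValueError("relative imprecision undefined with a zero observation")
        diff = diff / np.abs(obs)
    return float(diff.mean())


@dataclasses.dataclass
class CrossValidation:
    """Held-out predictions from one set of random partitions.

    ``predictions`` is indexed by species with columns ``mean`` (mean
    held-out prediction), ``se`` (SE over the partitions in which the
    species was held out; NaN when held out fewer than twice) and
    ``n_heldout``.  Species never held out are listed separately.
    """

    predictions: pd.DataFrame
    observed: pd.Series
    n_partitions: int
    train_size: int
    never_heldout: list[str]
    n_resampled: int = 0

    def metrics(self, relative: bool = False) -> tuple[float, float]:
        """(rightness, imprecision) on species with held-out predictions."""
        held = self.predictions.dropna(subset=["mean"])
        obs = self.observed.loc[held.index]
        return (
            rightness(obs, held["mean"]),
            imprecision(obs, held["mean"], relative=relative),
        )


def _train_size(n: int, frac: float) -> int:
    # round half-up, so 0.75 * 29 = 21.75 -> 22 train / 7 test
    return int(np.floor(frac * n + 0.5))


def cross_validate(
    spec: ModelSpec,
    response: pd.Series,
    data: pd.DataFrame,
    frac: float = 0.75,
    n_partitions: int = 100,
    seed: int | np.random.Generator | None = None,
) -> CrossValidation:
    """Random-partition cross-validation of one fixed model specification.

    Each partition holds out ``1 - frac`` of the species, refits the model
    coefficients on the rest, and predicts the held-out species on the
    transformed scale.  Partitions whose training design is rank deficient
    are redrawn (counted in ``n_resampled``).
    """
    frame = pd.concat([response.rename("__y__"), data], axis=1, join="inner").dropna(
        subset=["__y__", *spec.variables]
    )
    y = frame["__y__"].to_numpy(dtype=float)
    n = y.size
    if n < 8:
        raise ValueError(f"need >= 8 species for 75-25 cross-validation, got {n}")
    n_train = _train_size(n, frac)
    if n_train < spec.k + 2 or n_train >= n:
        raise ValueError(f"training size {n_train} cannot fit k={spec.k} slopes and still hold species out")
    design = Design(spec, frame)
    X = design.matrix(frame)
    ncol = X.shape[1]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    sums = np.zeros(n)
    sumsq = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    n_resampled = 0
    for _ in range(n_partitions):
        for _attempt in range(1000):
            perm = rng.permutation(n)
            train, test = perm[:n_train], perm[n_train:]
            Xt = X[train]
            beta, _, rank, _ = np.linalg.lstsq(Xt, y[train], rcond=None)
            if rank == ncol:
                break
            n_resampled += 1
        else:
            raise np.linalg.LinAlgError("could not draw a full-rank training partition")
        pred = X[test] @ beta
        sums[test] += pred
        sumsq[test] += pred**2
        counts[test] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = np.where(counts > 1, (sumsq - counts * mean**2) / np.maximum(counts - 1, 1), np.nan)
        se = np.sqrt(np.maximum(var, 0.0) / np.maximum(counts, 1))
        se[counts <= 1] = np.nan
    preds = pd.DataFrame(
        {"mean": mean, "se": se, "n_heldout": counts}, index=frame.index
    )
    never = list(frame.index[counts == 0])
    return CrossValidation(
        predictions=preds,
        observed=frame["__y__"],
        n_partitions=n_partitions,
        train_size=n_train,
        never_heldout=never,
        n_resampled=n_resampled,
    )


@dataclasses.dataclass
class CVPerformance:
    """Rightness and imprecision of one model, with SEs over repeats."""

    label: str
    rightness: float
    rightness_se: float | None
    imprecision: float
    imprecision_se: float | None
    relative: bool
    n_partitions: int
    n_repeats: int
    per_repeat: pd.DataFrame  # columns: rightness, imprecision

    def __repr__(self) -> str:
        f = lambda v, s: f"{v:.4f}" + (f" +/- {s:.4f}" if s is not None else "")
        return (
            f"CVPerformance({self.label}: rightness {f(self.rightness, self.rightness_se)}, "
            f"imprecision {f(self.imprecision, self.imprecision_se)}"
            f"{' (relative)' if self.relative else ''}, "
            f"{self.n_repeats} repeats x {self.n_partitions} partitions)"
        )


def performance_with_se(
    spec: ModelSpec,
    response: pd.Series,
    data: pd.DataFrame,
    relative: bool | None = None,
    n_repeats: int = 20,
    n_partitions: int = 100,
    frac: float = 0.75,
    seed: int | np.random.Generator | None = None,
    label: str | None = None,
) -> CVPerformance:
    """Run ``n_repeats`` independent cross-validations and summarize.

    Each repeat draws a fresh set of ``n_partitions`` partitions; rightness
    and imprecision are computed per repeat and reported as mean +/- SE
    (SE undefined for a single repeat).  ``relative`` defaults to the
    convention of the response element (relative for mean distance and LDD
    frequency) and to absolute when the spec carries no element.
    """
    if relative is None:
        relative = spec.element in RELATIVE_IMPRECISION_ELEMENTS
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for _ in range(n_repeats):
        cv = cross_validate(spec, response, data, frac=frac, n_partitions=n_partitions, seed=rng)
        r, i = cv.metrics(relative=relative)
        rows.append((r, i))
    per_repeat = pd.DataFrame(rows, columns=["rightness", "imprecision"])
    ses = (
        per_repeat.std(ddof=1) / np.sqrt(n_repeats) if n_repeats > 1 else pd.Series({"rightness": None, "imprecision": None})
    )
    return CVPerformance(
        label=label or str(spec),
        rightness=float(per_repeat["rightness"].mean()),
        rightness_se=None if n_repeats < 2 else float(ses["rightness"]),
        imprecision=float(per_repeat["imprecision"].mean()),
        imprecision_se=None if n_repeats < 2 else float(ses["imprecision"]),
        relative=relative,
        n_partitions=n_partitions,
        n_repeats=n_repeats,
        per_repeat=per_repeat,
    )


@dataclasses.dataclass
class GainReport:
    """Relative performance of the trait model against the reference.

    Gain in rightness is a difference of slopes; gain in precision is the
    ratio reference imprecision / trait-model imprecision (> 1 means the
    trait model is more precise).  p-values come from a regression of the
    per-repeat performance values on a model-type indicator.
    """

    gain_rightness: float
    gain_precision: float
    p_rightness: float
    p_imprecision: float
    trait: CVPerformance
    reference: CVPerformance

    def summary(self) -> str:
        return (
            f"gain in rightness: {self.gain_rightness:+.4f} (p = {self.p_rightness:.3g})\n"
            f"gain in precision: x {self.gain_precision:.3f} (p = {self.p_imprecision:.3g})"
        )


def _type_effect_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """p-value of the model-type indicator in performance ~ type."""
    y = np.concatenate([a, b])
    x = np.concatenate([np.zeros(a.size), np.ones(b.size)])
    res = sm.OLS(y, sm.add_constant(x)).fit()
    p = res.pvalues[1]
    return 1.0 if np.isnan(p) else float(p)


def compare_models(trait_perf: CVPerformance, reference_perf: CVPerformance) -> GainReport:
    """Gain metrics of the trait-syndrome model over the reference model."""
    if trait_perf.n_repeats != reference_perf.n_repeats:
        raise ValueError("performances must come from the same number of repeats")
    if trait_perf.relative != reference_perf.relative:
        raise ValueError("performances must use the same imprecision convention")
    if trait_perf.imprecision == 0:
        gain_prec = 1.0 if reference_perf.imprecision == 0 else np.inf
    else:
        gain_prec = reference_perf.imprecision / trait_perf.imprecision
    return GainReport(
        gain_rightness=trait_perf.rightness - reference_perf.rightness,
        gain_precision=gain_prec,
        p_rightness=_type_effect_pvalue(
            trait_perf.per_repeat["rightness"].to_numpy(),
            reference_perf.per_repeat["rightness"].to_numpy(),
        ),
        p_imprecision=_type_effect_pvalue(
            trait_perf.per_repeat["imprecision"].to_numpy(),
            reference_perf.per_repeat["imprecision"].to_numpy(),
        ),
        trait=trait_perf,
        reference=reference_perf,
    )
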