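"""Two-stage exhaustive GLM selection for dispersal syndromes.

Stage 0 (pre-screen): each non-binary candidate trait is checked for a
curved (U or inverted-U) relationship with the response by fitting
``y ~ t + t^2``; traits whose quadratic coefficient reaches p < 0.1
(significant and marginally significant cases pooled) enter all later
models as a second-degree polynomial, the rest as simple linear effects.

Stage 1: every subset of the candidate main-effect terms with at most
``max_coef`` slope coefficients (default 8, guarding against saturation at
the small species counts available) is fitted and ranked by AICc.

Stage 2: the variables appearing in any stage-1 model within ``delta``
AICc points of the best (default 2) are pooled, all first-order
interactions among them are added as candidates, and the exhaustive search
is repeated under the same cap.  Marginality is enforced: an interaction is
only admissible alongside both of its main effects.

The final model is the one with the highest R^2 among the stage-2 top set
(it captures the most deviance, and prediction is the goal).  AICc ties
are broken deterministically by higher adjusted R^2, then fewer
coefficients, then lexicographic term order.

The exhaustive search solves each candidate model from a precomputed Gram
matrix (Cholesky on X'X); the chosen model is refit through
:func:`dispersalkit.glm.fit_glm` for its public coefficient table.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .elements import Element
from .glm import FitResult, aicc, fit_glm, gaussian_loglik
from .terms import Design, ModelSpec, ModelTerm, interaction, linear, quadratic, term_sort_key

__all__ = [
    "screen_quadratic",
    "enumerate_models",
    "select_two_stage",
    "term_stability",
    "SelectionResult",
]

#: models whose RSS falls below this fraction of the total sum of squares
#: are treated as numerically perfect (their likelihood is unbounded)
_PERFECT_RTOL = 1e-12


def screen_quadratic(response, trait, alpha: float = 0.1) -> str:
    """Decide the functional form for one trait: 'linear' or 'quadratic_pair'.

    Fits ``y ~ t + t^2`` (centered powers) and returns ``quadratic_pair``
    when the quadratic coefficient's p-value is below ``alpha`` (0.1 pools
    significant and marginally significant curvature), else ``linear``.
    Noise-free fits (zero residual) fall back to the coefficient itself:
    curvature must be numerically non-zero to count.
    """
    y = np.asarray(response, dtype=float)
    t = np.asarray(trait, dtype=float)
    if y.size != t.size or y.size < 5:
        raise ValueError("need >= 5 paired observations for the curvature screen")
    if np.ptp(t) == 0:
        raise ValueError("constant trait vector: curvature screen undefined")
    tc = t - t.mean()
    X = np.column_stack([np.ones_like(t), tc, tc**2])
    if np.linalg.matrix_rank(X) < 3:
        raise np.linalg.LinAlgError("trait has too few distinct values for a quadratic fit")
    res = sm.OLS(y, X).fit()
    tss = float(np.sum((y - y.mean()) ** 2))
    if res.ssr <= 1e-12 * max(tss, 1.0) or np.isnan(res.pvalues[2]):
        # numerically perfect fit: there is no sampling noise to test
        # against, so judge curvature by the coefficient itself
        scale = max(np.abs(res.params).max(), 1.0)
        return "quadratic_pair" if abs(res.params[2]) > 1e-8 * scale else "linear"
    return "quadratic_pair" if res.pvalues[2] < alpha else "linear"


def _main_subsets(mains: Sequence[ModelTerm], cap: int) -> Iterator[tuple[ModelTerm, ...]]:
    for size in range(len(mains) + 1):
        if size > cap:
            break
        for combo in itertools.combinations(mains, size):
            if sum(t.ncoef for t in combo) <= cap:
                yield combo


def enumerate_models(candidates: Sequence[ModelTerm], cap: int = 8,
                     element: Element | str | None = None) -> Iterator[ModelSpec]:
    """Yield every admissible model over ``candidates`` with <= ``cap`` slopes.

    Includes the intercept-only model; enforces marginality (interactions
    need both mains).  Order is deterministic: main-effect subsets by
    ascending size in candidate order, each followed by its admissible
    interaction augmentations.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    mains = [t for t in candidates if t.kind in ("linear", "quadratic_pair")]
    inters = [t for t in candidates if t.kind == "interaction"]
    for main_combo in _main_subsets(mains, cap):
        yield ModelSpec(element, main_combo)
        if not inters:
            continue
        variables = {t.traits[0] for t in main_combo}
        admissible = [t for t in inters if t.variables <= variables]
        budget = cap - sum(t.ncoef for t in main_combo)
        for r in range(1, min(len(admissible), budget) + 1):
            for icombo in itertools.combinations(admissible, r):
                yield ModelSpec(element, main_combo + icombo)


class _GramSearch:
    """Exhaustive OLS over term subsets from one precomputed Gram matrix."""

    def __init__(self, candidates: Sequence[ModelTerm], data: pd.DataFrame, y: np.ndarray,
                 centers: dict[str, float]):
        self.candidates = list(candidates)
        self.n = y.size
        cols = [np.ones(self.n)]
        self.term_cols: dict[ModelTerm, tuple[int, ...]] = {}
        for t in self.candidates:
            start = len(cols)
            if t.kind == "linear":
                cols.append(data[t.traits[0]].to_numpy(dtype=float))
            elif t.kind == "quadratic_pair":
                v = data[t.traits[0]].to_numpy(dtype=float)
                cols += [v, (v - centers[t.traits[0]]) ** 2]
            else:
                a = data[t.traits[0]].to_numpy(dtype=float) - centers[t.traits[0]]
                b = data[t.traits[1]].to_numpy(dtype=float) - centers[t.traits[1]]
                cols.append(a * b)
            self.term_cols[t] = tuple(range(start, len(cols)))
        Z = np.column_stack(cols)
        self.G = Z.T @ Z
        self.Zy = Z.T @ y
        self.yy = float(y @ y)
        self.tss = float(np.sum((y - y.mean()) ** 2))

    def rss(self, terms: tuple[ModelTerm, ...]) -> float | None:
        """RSS of the OLS fit on the given terms; None if rank deficient."""
        idx = [0]
        for t in terms:
            idx.extend(self.term_cols[t])
        ix = np.ix_(idx, idx)
        try:
            c, low = scipy.linalg.cho_factor(self.G[ix], check_finite=False)
        except scipy.linalg.LinAlgError:
            return None
        beta = scipy.linalg.cho_solve((c, low), self.Zy[idx], check_finite=False)
        return max(self.yy - float(beta @ self.Zy[idx]), 0.0)


@dataclasses.dataclass
class _Candidate:
    terms: tuple[ModelTerm, ...]
    k: int
    rss: float
    aicc: float
    rsquared: float
    rsquared_adj: float


def _rank(models: list[_Candidate], delta: float) -> tuple[list[_Candidate], list[_Candidate]]:
    """Sort by (AICc, -adjR2, k, lexicographic) and extract the delta set."""
    models.sort(key=lambda m: (m.aicc, -m.rsquared_adj, m.k, term_sort_key(m.terms)))
    best = models[0].aicc
    if np.isneginf(best):
        top = [m for m in models if np.isneginf(m.aicc)]
    else:
        top = [m for m in models if m.aicc - best <= delta]
    return models, top


def _evaluate(search: _GramSearch, subsets: Iterator[tuple[ModelTerm, ...]],
              n: int) -> list[_Candidate]:
    out = []
    tss = search.tss
    for terms in subsets:
        k = sum(t.ncoef for t in terms)
        if n - (k + 2) - 1 < 1:  # AICc saturated: not comparable, skip
            continue
        rss = search.rss(terms)
        if rss is None:
            continue
        if rss <= _PERFECT_RTOL * max(tss, 1.0):
            # numerically perfect fit: R^2 is 1 to machine precision (so
            # ties resolve by parsimony, not floating-point residue) and
            # the Gaussian likelihood is unbounded
            r2, r2adj, a = 1.0, 1.0, -np.inf
        else:
            r2 = 0.0 if tss == 0 else min(max(1.0 - rss / tss, 0.0), 1.0)
            r2adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1) if n - k - 1 > 0 else np.nan
            a = aicc(gaussian_loglik(rss, n), k + 2, n)
        out.append(_Candidate(terms, k, rss, a, r2, r2adj))
    if not out:
        raise ValueError("no fittable model under the coefficient cap")
    return out


def _subset_stream(mains, inters, cap):
    for main_combo in _main_subsets(mains, cap):
        yield main_combo
        if inters:
            variables = {t.traits[0] for t in main_combo}
            admissible = [t for t in inters if t.variables <= variables]
            budget = cap - sum(t.ncoef for t in main_combo)
            for r in range(1, min(len(admissible), budget) + 1):
                for icombo in itertools.combinations(admissible, r):
                    yield main_combo + icombo


@dataclasses.dataclass
class SelectionResult:
    """Outcome of the two-stage search for one dispersal element."""

    element: Element | None
    n: int
    candidates: list[str]
    forms: dict[str, str]
    chosen: FitResult
    stage1_top: pd.DataFrame
    stage2_top: pd.DataFrame
    stage1_specs: list[ModelSpec]
    stage2_specs: list[ModelSpec]
    stage1_n_models: int
    stage2_n_models: int
    term_frequency: pd.Series

    def __repr__(self) -> str:
        return (
            f"SelectionResult({self.chosen.spec}, n={self.n}, "
            f"stage1: {self.stage1_n_models} models / top {len(self.stage1_specs)}, "
            f"stage2: {self.stage2_n_models} models / top {len(self.stage2_specs)})"
        )


def _top_table(top: list[_Candidate], element) -> tuple[pd.DataFrame, list[ModelSpec]]:
    specs = [ModelSpec(element, m.terms) for m in top]
    best = top[0].aicc
    rows = [
        {
            "model": str(s),
            "k": m.k,
            "aicc": m.aicc,
            "delta_aicc": 0.0 if np.isneginf(m.aicc) else m.aicc - best,
            "rsquared": m.rsquared,
            "rsquared_adj": m.rsquared_adj,
        }
        for m, s in zip(top, specs)
    ]
    return pd.DataFrame(rows), specs


def term_stability(specs: Sequence[ModelSpec]) -> pd.Series:
    """Fraction of models in a top set containing each term unit."""
    if not specs:
        raise ValueError("empty top set")
    labels = sorted({t.label for s in specs for t in s.terms})
    freq = {
        lab: sum(any(t.label == lab for t in s.terms) for s in specs) / len(specs)
        for lab in labels
    }
    return pd.Series(freq, name="inclusion_frequency")


def select_two_stage(
    response: pd.Series,
    data: pd.DataFrame,
    candidates: Sequence[str] | None = None,
    element: Element | str | None = None,
    max_coef: int = 8,
    delta: float = 2.0,
    screen_alpha: float = 0.1,
    interactions: bool = True,
) -> SelectionResult:
    """Run the full two-stage exhaustive AICc selection.

    Parameters
    ----------
    response : Series
        Transformed-scale dispersal values, indexed by species.
    data : DataFrame
        Candidate predictor columns (wing length already log-transformed by
        the caller), same index.
    candidates : sequence of str, optional
        Predictor columns to search over; defaults to all columns of
        ``data``.
    max_coef : int
        Cap on slope coefficients per model (intercept excluded).
    delta : float
        AICc window for the top set at both stages.
    screen_alpha : float
        p-value threshold of the quadratic pre-screen.
    interactions : bool
        Whether stage 2 adds first-order interactions.
    """
    if candidates is None:
        candidates = list(data.columns)
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate predictors")
    element = Element(element) if element is not None else None

    # complete cases over response + full candidate set so AICc is compared
    # on one fixed dataset
    frame = pd.concat([response.rename("__y__"), data[candidates]], axis=1, join="inner").dropna()
    y = frame["__y__"].to_numpy(dtype=float)
    n = y.size
    if n < 4:
        raise ValueError(f"only {n} complete cases; too few to select a model")
    X = frame[candidates]
    centers = {c: float(X[c].mean()) for c in candidates}

    # stage 0: functional form per candidate
    forms: dict[str, str] = {}
    for c in candidates:
        v = X[c].to_numpy(dtype=float)
        if np.unique(v).size <= 2:  # binary / two-level traits stay linear
            forms[c] = "linear"
        else:
            forms[c] = screen_quadratic(y, v, alpha=screen_alpha)
    mains = [quadratic(c) if forms[c] == "quadratic_pair" else linear(c) for c in candidates]

    search = _GramSearch(mains, X, y, centers)
    stage1 = _evaluate(search, _subset_stream(mains, [], max_coef), n)
    stage1_n = len(stage1)
    stage1, top1 = _rank(stage1, delta)

    # stage 2: pool = union of variables over all stage-1 top models
    pool = sorted({t.traits[0] for m in top1 for t in m.terms})
    mains2 = [quadratic(c) if forms[c] == "quadratic_pair" else linear(c) for c in pool]
    inters2 = [interaction(a, b) for a, b in itertools.combinations(pool, 2)] if interactions else []
    search2 = _GramSearch(mains2 + inters2, X, y, centers)
    stage2 = _evaluate(search2, _subset_stream(mains2, inters2, max_coef), n)
    stage2_n = len(stage2)
    stage2, top2 = _rank(stage2, delta)

    # final choice: highest R^2 within the stage-2 top set
    chosen_cand = min(top2, key=lambda m: (-m.rsquared, m.k, term_sort_key(m.terms)))
    chosen_spec = ModelSpec(element, chosen_cand.terms)
    design = Design(chosen_spec, X, centers={v: centers[v] for v in chosen_spec.variables})
    chosen = fit_glm(chosen_spec, frame["__y__"], X, design=design)

    table1, specs1 = _top_table(top1, element)
    table2, specs2 = _top_table(top2, element)
    return SelectionResult(
        element=element,
        n=n,
        candidates=candidates,
        forms=forms,
        chosen=chosen,
        stage1_top=table1,
        stage2_top=table2,
        stage1_specs=specs1,
        stage2_specs=specs2,
        stage1_n_models=stage1_n,
        stage2_n_models=stage2_n,
        term_frequency=term_stability(specs2),
    )
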