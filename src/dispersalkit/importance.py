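"""Relative importance of regressors: LMG decomposition of R^2.

The contribution of each regressor unit is the average, over all orderings
of the units, of the R^2 increase it brings when entered after the units
preceding it.  Contributions are non-negative (each increment is an R^2
increase) and sum exactly to the full-model R^2 (telescoping identity).

By default a quadratic pair is one unit and an interaction is one unit
(one contribution per listed model term); a per-coefficient mode averages
over orderings of individual design columns instead.

For moderate unit counts the exact subset-weighted form is used (2^p
submodels, weight |S|! (p-|S|-1)! / p! for the increment after subset S);
above ``exact_limit`` units a seeded random sample of orderings is
averaged instead.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd

from .terms import Design, ModelSpec

__all__ = ["ImportanceDecomposition", "r2_partition_lmg"]


@dataclasses.dataclass
class ImportanceDecomposition:
    """Per-unit contributions to the full-model R^2."""

    contributions: pd.Series
    total_rsquared: float
    n_orderings: int  # factorial(p) when exact
    exact: bool
    mode: str

    def __repr__(self) -> str:
        parts = ", ".join(f"{k}: {v:.4f}" for k, v in self.contributions.items())
        return f"ImportanceDecomposition(R^2 = {self.total_rsquared:.4f}; {parts})"


def _group_columns(spec: ModelSpec, design: Design, mode: str) -> list[tuple[str, list[int]]]:
    """Column indices (into the interceptless design) per importance unit."""
    groups: list[tuple[str, list[int]]] = []
    pos = 0
    for t in spec.terms:
        nc = t.ncoef
        cols = list(range(pos, pos + nc))
        pos += nc
        if mode == "unit":
            groups.append((t.label, cols))
        else:
            for c in cols:
                groups.append((design.column_names[1 + c], [c]))
    return groups


def _rss_cache(X: np.ndarray, y: np.ndarray, groups: list[tuple[str, list[int]]]):
    """R^2 of the OLS fit for any subset of units, memoized."""
    n = y.size
    yc = y - y.mean()
    tss = float(yc @ yc)
    cache: dict[frozenset[int], float] = {}

    def r2(units: frozenset[int]) -> float:
        if units in cache:
            return cache[units]
        if tss == 0:
            cache[units] = 0.0
            return 0.0
        cols = sorted(c for u in units for c in groups[u][1])
        if not cols:
            val = 0.0
        else:
            Xi = np.column_stack([np.ones(n), X[:, cols]])
            beta, rss_arr, rank, _ = np.linalg.lstsq(Xi, y, rcond=None)
            if rank < Xi.shape[1]:
                raise np.linalg.LinAlgError(
                    f"rank-deficient submodel over units {[groups[u][0] for u in sorted(units)]}"
                )
            resid = y - Xi @ beta
            val = 1.0 - float(resid @ resid) / tss
        cache[units] = val
        return val

    return r2


def r2_partition_lmg(
    spec: ModelSpec,
    response: pd.Series,
    data: pd.DataFrame,
    mode: str = "unit",
    exact_limit: int = 10,
    n_orderings: int = 5000,
    seed: int | None = None,
) -> ImportanceDecomposition:
    """Partition the model's R^2 among its regressors (LMG averaging).

    Parameters
    ----------
    spec : ModelSpec
        The fitted model whose R^2 is to be decomposed.
    response, data : aligned response and predictor columns (complete cases).
    mode : {"unit", "coefficient"}
        "unit" gives one contribution per model term (a quadratic pair or
        an interaction counts once); "coefficient" decomposes per design
        column.
    exact_limit : int
        Up to this many units the exact subset-weighted computation is
        used; above it, ``n_orderings`` random orderings are sampled
        (``seed`` required for reproducibility).
    """
    if mode not in ("unit", "coefficient"):
        raise ValueError("mode must be 'unit' or 'coefficient'")
    frame = pd.concat([response.rename("__y__"), data], axis=1, join="inner").dropna(
        subset=["__y__", *spec.variables]
    )
    y = frame["__y__"].to_numpy(dtype=float)
    design = Design(spec, frame)
    X = design.matrix(frame)[:, 1:]
    groups = _group_columns(spec, design, mode)
    p = len(groups)
    if p < 1:
        raise ValueError("model has no regressors to decompose")
    r2 = _rss_cache(X, y, groups)
    full = r2(frozenset(range(p)))

    contrib = np.zeros(p)
    if p <= exact_limit:
        # exact: weight each increment after subset S by |S|!(p-|S|-1)!/p!
        fact = [math.factorial(i) for i in range(p + 1)]
        for j in range(p):
            others = [u for u in range(p) if u != j]
            total = 0.0
            for size in range(p):
                w = fact[size] * fact[p - size - 1] / fact[p]
                for S in itertools.combinations(others, size):
                    s = frozenset(S)
                    total += w * (r2(s | {j}) - r2(s))
            contrib[j] = total
        n_used, exact = math.factorial(p), True
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_orderings):
            order = rng.permutation(p)
            prev: frozenset[int] = frozenset()
            prev_r2 = 0.0
            for j in order:
                cur = prev | {j}
                cur_r2 = r2(cur)
                contrib[j] += cur_r2 - prev_r2
                prev, prev_r2 = cur, cur_r2
        contrib /= n_orderings
        n_used, exact = n_orderings, False

    labels = [g[0] for g in groups]
    return ImportanceDecomposition(
        contributions=pd.Series(contrib, index=labels, name="contribution_to_R2"),
        total_rsquared=full,
        n_orderings=n_used,
        exact=exact,
        mode=mode,
    )
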