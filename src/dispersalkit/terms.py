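"""Model terms, model specifications, and design-matrix construction.

A model is a set of *term units* over the candidate predictors:

* ``linear`` — one slope for one trait;
* ``quadratic_pair`` — centered first- and second-degree terms of one
  trait, always entered together (2 slopes);
* ``interaction`` — the product of two distinct traits' centered linear
  terms (1 slope), only admissible when both main effects are present
  (marginality).

Quadratic and interaction columns are built from centered raw powers;
centering improves conditioning and, because marginality keeps the linear
spans identical, leaves fitted values and model comparison untouched.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from .elements import Element

__all__ = ["ModelTerm", "ModelSpec", "Design", "linear", "quadratic", "interaction"]


@dataclasses.dataclass(frozen=True, order=True)
class ModelTerm:
    """One term unit of a model specification."""

    kind: str
    traits: tuple[str, ...]

    def __post_init__(self):
        if self.kind not in ("linear", "quadratic_pair", "interaction"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        n_expected = 2 if self.kind == "interaction" else 1
        if len(self.traits) != n_expected:
            raise ValueError(f"{self.kind} term must reference {n_expected} trait(s), got {self.traits}")
        if self.kind == "interaction":
            if self.traits[0] == self.traits[1]:
                raise ValueError("interaction must reference two distinct traits")
            # canonical order so (a, b) == (b, a)
            object.__setattr__(self, "traits", tuple(sorted(self.traits)))

    @property
    def ncoef(self) -> int:
        """Slope coefficients contributed (quadratic pair counts 2)."""
        return 2 if self.kind == "quadratic_pair" else 1

    @property
    def variables(self) -> frozenset[str]:
        return frozenset(self.traits)

    @property
    def label(self) -> str:
        if self.kind == "linear":
            return self.traits[0]
        if self.kind == "quadratic_pair":
            return f"poly({self.traits[0]}, 2)"
        return f"{self.traits[0]}:{self.traits[1]}"

    def __str__(self) -> str:
        return self.label


def linear(trait: str) -> ModelTerm:
    return ModelTerm("linear", (trait,))


def quadratic(trait: str) -> ModelTerm:
    return ModelTerm("quadratic_pair", (trait,))


def interaction(a: str, b: str) -> ModelTerm:
    return ModelTerm("interaction", (a, b))


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """A response element plus an ordered set of term units."""

    element: Element | None
    terms: tuple[ModelTerm, ...]

    def __post_init__(self):
        if self.element is not None:
            object.__setattr__(self, "element", Element(self.element))
        object.__setattr__(self, "terms", tuple(self.terms))
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms in model specification")
        mains = {t.traits[0] for t in self.terms if t.kind in ("linear", "quadratic_pair")}
        for t in self.terms:
            if t.kind == "interaction" and not t.variables <= mains:
                raise ValueError(
                    f"interaction {t.label} violates marginality: both main effects must be present"
                )

    @property
    def k(self) -> int:
        """Total slope-coefficient count (intercept excluded)."""
        return sum(t.ncoef for t in self.terms)

    @property
    def variables(self) -> frozenset[str]:
        return frozenset().union(*(t.variables for t in self.terms)) if self.terms else frozenset()

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.terms)

    def __str__(self) -> str:
        rhs = " + ".join(self.labels) if self.terms else "1"
        lhs = self.element.value if self.element is not None else "y"
        return f"{lhs} ~ {rhs}"


class Design:
    """Maps a :class:`ModelSpec` to a numeric design matrix.

    Centers for quadratic/interaction construction are taken from the data
    the design is built on and reused verbatim for prediction, so train and
    test rows always pass through identical column definitions.
    """

    def __init__(self, spec: ModelSpec, data: pd.DataFrame, centers: dict[str, float] | None = None):
        self.spec = spec
        missing = sorted(v for v in spec.variables if v not in data.columns)
        if missing:
            raise ValueError(f"data lacks predictor column(s): {missing}")
        if centers is None:
            centers = {v: float(data[v].mean()) for v in spec.variables}
        self.centers = centers
        self.column_names = ["intercept"]
        for t in spec.terms:
            if t.kind == "linear":
                self.column_names.append(t.traits[0])
            elif t.kind == "quadratic_pair":
                self.column_names += [t.traits[0], f"{t.traits[0]}^2"]
            else:
                self.column_names.append(t.label)

    def matrix(self, data: pd.DataFrame) -> np.ndarray:
        """Build the (n, k+1) design matrix, intercept first."""
        cols = [np.ones(len(data))]
        for t in self.spec.terms:
            if t.kind == "linear":
                cols.append(data[t.traits[0]].to_numpy(dtype=float))
            elif t.kind == "quadratic_pair":
                v = data[t.traits[0]].to_numpy(dtype=float)
                c = self.centers[t.traits[0]]
                cols += [v, (v - c) ** 2]
            else:
                a = data[t.traits[0]].to_numpy(dtype=float) - self.centers[t.traits[0]]
                b = data[t.traits[1]].to_numpy(dtype=float) - self.centers[t.traits[1]]
                cols.append(a * b)
        return np.column_stack(cols)


def term_sort_key(terms: Iterable[ModelTerm]) -> tuple:
    """Deterministic lexicographic key over a term set (tie-breaking)."""
    return tuple(sorted((t.kind, t.traits) for t in terms))
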