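"""Dispersal observations: per-species values of the four dispersal elements."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .elements import Element, transform

__all__ = ["DispersalObservation", "DispersalDataset", "read_dispersal_table"]


@dataclasses.dataclass(frozen=True)
class DispersalObservation:
    """One species' measurement of one dispersal element.

    ``raw_value`` is on the natural scale (km, probability, fraction, or
    F_ST); ``transformed_value`` is the normalized analysis value and is
    always ``transform(element, raw_value)``.
    """

    species_id: str
    element: Element
    raw_value: float
    transformed_value: float = dataclasses.field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "element", Element(self.element))
        expected = transform(self.element, self.raw_value)
        if self.transformed_value is None:
            object.__setattr__(self, "transformed_value", expected)
        elif not np.isclose(self.transformed_value, expected, rtol=0, atol=1e-12):
            raise ValueError(
                f"{self.species_id}/{self.element.value}: transformed_value "
                f"{self.transformed_value} != transform(raw) = {expected}"
            )


class DispersalDataset:
    """Collection of dispersal observations grouped by element.

    At most one observation per (species, element) pair; per-element species
    counts are exposed as ``n``.
    """

    def __init__(self, observations: list[DispersalObservation]):
        seen: set[tuple[str, Element]] = set()
        groups: dict[Element, list[DispersalObservation]] = {}
        for obs in observations:
            key = (obs.species_id, obs.element)
            if key in seen:
                raise ValueError(f"duplicate observation for {obs.species_id}/{obs.element.value}")
            seen.add(key)
            groups.setdefault(obs.element, []).append(obs)
        self._groups = groups

    @property
    def elements(self) -> list[Element]:
        return list(self._groups)

    @property
    def n(self) -> dict[Element, int]:
        """Species count per element."""
        return {e: len(g) for e, g in self._groups.items()}

    def observations(self, element: Element | str) -> list[DispersalObservation]:
        return list(self._groups.get(Element(element), []))

    def series(self, element: Element | str, transformed: bool = True) -> pd.Series:
        """Values for one element as a species-indexed Series."""
        obs = self.observations(element)
        attr = "transformed_value" if transformed else "raw_value"
        return pd.Series(
            [getattr(o, attr) for o in obs],
            index=pd.Index([o.species_id for o in obs], name="species_id"),
            name=Element(element).value,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame (species_id, element, raw_value, transformed_value)."""
        rows = [
            (o.species_id, o.element.value, o.raw_value, o.transformed_value)
            for group in self._groups.values()
            for o in group
        ]
        return pd.DataFrame(rows, columns=["species_id", "element", "raw_value", "transformed_value"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame()[["species_id", "element", "raw_value"]].to_csv(path, index=False)

    def __repr__(self) -> str:
        counts = ", ".join(f"{e.value}: n={n}" for e, n in self.n.items())
        return f"DispersalDataset({counts})"


def read_dispersal_table(path: str | Path) -> DispersalDataset:
    """Read a long-format dispersal CSV (species_id, element, raw_value).

    The transformed analysis value is computed on read; unknown element
    labels and duplicate (species, element) pairs are errors.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"could not parse dispersal table {path}: {exc}") from exc
    required = {"species_id", "element", "raw_value"}
    if not required.issubset(df.columns):
        raise ValueError(f"dispersal table needs columns {sorted(required)}, got {list(df.columns)}")
    obs = [
        DispersalObservation(str(r.species_id), Element(r.element), float(r.raw_value))
        for r in df.itertuples()
    ]
    return DispersalDataset(obs)
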