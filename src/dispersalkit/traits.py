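"""Life-history trait registry and the species x trait table.

Eighteen candidate predictors of dispersal are recognised: seventeen
life-history traits (demography, ecological specialization, behaviour) plus
wing length.  Ordinal scores (9-level fecundity categories, 1-8 maturation
levels, ...) are coded as their integer score and treated as numeric, so
polynomial terms over them are meaningful.  Binary traits are coded 0/1.

Wing length is stored in millimetres; it is log-transformed at
model-building time (allometric relationships are power-shaped), never in
storage.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TraitDef",
    "TRAIT_REGISTRY",
    "TRAIT_NAMES",
    "TraitTable",
    "read_trait_table",
    "predictor_frame",
]


@dataclasses.dataclass(frozen=True)
class TraitDef:
    """Definition of one candidate trait: coding kind and valid range."""

    name: str
    kind: str  # "continuous" | "ordinal" | "binary"
    low: float
    high: float
    description: str = ""

    def validate(self, values: np.ndarray) -> np.ndarray:
        """Boolean mask of invalid (non-missing, out-of-range) entries."""
        v = np.asarray(values, dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (v < self.low) | (v > self.high)
            if self.kind in ("ordinal", "binary"):
                bad |= (v != np.round(v)) & ~np.isnan(v)
        return bad & ~np.isnan(v)

    @property
    def levels(self) -> np.ndarray:
        """Admissible levels for ordinal/binary traits."""
        if self.kind == "continuous":
            raise ValueError(f"{self.name} is continuous; it has no discrete levels")
        return np.arange(int(self.low), int(self.high) + 1)


_DEFS = [
    TraitDef("fecundity", "ordinal", 1, 9, "mean lifetime egg number, 9 categories"),
    TraitDef("adult_lifetime", "continuous", 5, 60, "mean adult-stage duration, days (capped at 60 for adult overwintering)"),
    TraitDef("voltinism", "continuous", 0.5, 3, "generations per year, 0.5 (biannual) to 3"),
    TraitDef("larval_growth_rate", "continuous", 16, 186, "larval feeding-period duration, days, averaged over generations"),
    TraitDef("ripe_egg_load", "ordinal", 1, 9, "mature eggs at female emergence, 9 levels"),
    TraitDef("ovigeny_index", "continuous", 0, 1, "proportion of eggs mature at emergence"),
    TraitDef("female_maturation", "ordinal", 1, 8, "time from emergence to first laying, 8 levels"),
    TraitDef("overwintering_stage", "ordinal", 0, 7, "overwintering stage, 0 (egg) to 6 (adult) plus 7 = no overwintering"),
    TraitDef("life_cycle_flexibility", "binary", 0, 1, "1 = flexible life cycle (prolonged/repeated diapause etc.)"),
    TraitDef("flight_period", "continuous", 3, 32, "flight-period length, weeks"),
    TraitDef("thermal_tolerance", "ordinal", 1, 9, "adult tolerance to temperature extremes, 9 levels"),
    TraitDef("adult_habitat_range", "ordinal", 1, 7, "number of ecosystems used by adults"),
    TraitDef("larval_dietary_breadth", "ordinal", 1, 4, "host-plant breadth: 1 species .. 4 several families"),
    TraitDef("myrmecophily", "ordinal", 0, 9, "association with ants, 0 none to 9 obligate"),
    TraitDef("female_precision", "ordinal", 1, 9, "precision of egg-laying site choice, 9 levels"),
    TraitDef("laying_strategy", "binary", 0, 1, "0 = single-egg layer, 1 = batch layer"),
    TraitDef("mate_location", "ordinal", 1, 7, "male mate-location strategy, sit-and-wait to lek"),
    TraitDef("wing_length", "continuous", np.nextafter(0.0, 1.0), np.inf, "wing length, mm (species averages roughly 11-37.5)"),
]

TRAIT_REGISTRY: dict[str, TraitDef] = {d.name: d for d in _DEFS}
TRAIT_NAMES: tuple[str, ...] = tuple(TRAIT_REGISTRY)


class TraitTable:
    """Species x trait values with a missing-value mask.

    Thin wrapper over a :class:`pandas.DataFrame` indexed by species id with
    one column per registered trait.  Missing cells are NaN; ``mask`` exposes
    them explicitly.  Values are validated against each trait's admissible
    range on construction.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.copy()
        df.index = df.index.astype(str)
        df.index.name = "species_id"
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate species_id: {dupes}")
        missing_cols = [t for t in TRAIT_NAMES if t not in df.columns]
        if missing_cols:
            raise ValueError(f"trait table lacks columns: {missing_cols}")
        extra = [c for c in df.columns if c not in TRAIT_REGISTRY]
        if extra:
            warnings.warn(f"ignoring unknown trait columns: {extra}", stacklevel=2)
        df = df[list(TRAIT_NAMES)].astype(float)
        if validate:
            self._validate(df)
        self.df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        problems = []
        for name, tdef in TRAIT_REGISTRY.items():
            bad = tdef.validate(df[name].to_numpy())
            for sp in df.index[bad]:
                problems.append(f"{sp}: {name}={df.at[sp, name]!r} outside [{tdef.low}, {tdef.high}]")
        if problems:
            raise ValueError("invalid trait values:\n  " + "\n  ".join(problems[:20]))

    @property
    def species(self) -> pd.Index:
        return self.df.index

    @property
    def n_species(self) -> int:
        return len(self.df)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missing-value mask (True = missing)."""
        return self.df.isna()

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"TraitTable({self.n_species} species, {len(TRAIT_NAMES)} traits, {int(self.mask.to_numpy().sum())} missing cells)"

    def complete_cases(self, traits: list[str]) -> pd.Index:
        """Species with no missing value among ``traits``."""
        return self.df.index[~self.df[list(traits)].isna().any(axis=1)]

    def to_csv(self, path: str | Path) -> None:
        """Write as the canonical CSV (one row per species; '' = missing)."""
        self.df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TraitTable":
        try:
            df = pd.read_csv(path, index_col="species_id")
        except Exception as exc:  # malformed CSV or missing index column
            raise ValueError(f"could not parse trait table {path}: {exc}") from exc
        return cls(df)


def read_trait_table(path: str | Path) -> TraitTable:
    """Read a species x trait CSV (columns = species_id + the 18 trait names)."""
    return TraitTable.from_csv(path)


def predictor_frame(traits: TraitTable) -> pd.DataFrame:
    """Model-building predictors: 17 life-history traits plus log wing length.

    Wing length enters the candidate set log-transformed (allometries are
    power shaped) as an ordinary candidate, not a forced covariate.
    """
    df = traits.df.drop(columns="wing_length").copy()
    df["log_wing_length"] = np.log(traits.df["wing_length"])
    return df
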