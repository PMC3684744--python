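"""Synthetic data: trait tables, syndrome-structured responses, MRR
distances, residency counts, F_ST values, and trees with Brownian traits.

No machine-readable species data accompany the trait/dispersal
compilations this package is designed for, so every downstream stage is
exercised on synthetic data that emulates their documented structure:
trait values drawn within each trait's admissible range, dispersal
responses generated as Gaussian-noise linear/quadratic/interaction
syndromes on the transformed scales, movement distances from negative
exponential or inverse-power kernels, per-patch residency counts, F_ST
values in a realistic [0, 0.18] band, and Brownian-motion traits on
pure-birth trees for the phylogenetic-signal check.

Traits are drawn independently by default (a Gaussian copula with a
user-supplied correlation matrix is available, since real traits co-vary);
independence keeps model-recovery tests interpretable.  Responses are
generated on the transformed scale, where the models live, and clipped
into each element's valid raw domain after back-transformation, with
clipping recorded per species.
"""

from __future__ import annotations

import dataclasses
import random as _pyrandom

import dendropy
import numpy as np
import pandas as pd
import scipy.stats
from dendropy.simulate import treesim

from .data import DispersalDataset, DispersalObservation
from .elements import Element, clip_to_domain
from .phylo import Phylogeny
from .terms import ModelTerm, interaction, linear, quadratic
from .traits import TRAIT_NAMES, TRAIT_REGISTRY, TraitTable, predictor_frame

__all__ = [
    "TrueTerm",
    "TrueModel",
    "SimulationConfig",
    "simulate_trait_table",
    "simulate_responses",
    "SimulatedResponse",
    "simulate_mrr_distances",
    "simulate_residency_counts",
    "simulate_fst",
    "simulate_tree_and_trait",
]

#: default draw range for wing length (mm); species averages of NW-European
#: butterflies span roughly this band
_WING_RANGE = (11.0, 37.5)


@dataclasses.dataclass(frozen=True)
class TrueTerm:
    """One generating effect: trait(s), functional form, and coefficient.

    Coefficients act on internally standardized (z-scored) trait values so
    their magnitude reads directly as effect size in response-SD units per
    trait-SD.
    """

    traits: tuple[str, ...] | str
    form: str  # "linear" | "quadratic" | "interaction"
    coef: float

    def __post_init__(self):
        traits = (self.traits,) if isinstance(self.traits, str) else tuple(self.traits)
        object.__setattr__(self, "traits", traits)
        if self.form not in ("linear", "quadratic", "interaction"):
            raise ValueError(f"unknown form {self.form!r}")
        if len(traits) != (2 if self.form == "interaction" else 1):
            raise ValueError(f"{self.form} term needs {'2 traits' if self.form == 'interaction' else '1 trait'}")

    @property
    def model_term(self) -> ModelTerm:
        """The selection-side term unit this effect should be detected as."""
        if self.form == "linear":
            return linear(self.traits[0])
        if self.form == "quadratic":
            return quadratic(self.traits[0])
        return interaction(*self.traits)


@dataclasses.dataclass(frozen=True)
class TrueModel:
    """Ground-truth dispersal syndrome used to generate responses."""

    element: Element
    terms: tuple[TrueTerm, ...]
    intercept: float = 0.0
    noise_sd: float = 0.25

    def __post_init__(self):
        object.__setattr__(self, "element", Element(self.element))
        object.__setattr__(self, "terms", tuple(self.terms))
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        for t in self.terms:
            for tr in t.traits:
                if tr not in TRAIT_REGISTRY and tr != "log_wing_length":
                    raise ValueError(f"true model references unknown trait {tr!r}")

    @property
    def expected_terms(self) -> frozenset[ModelTerm]:
        return frozenset(t.model_term for t in self.terms)

    @property
    def variables(self) -> frozenset[str]:
        return frozenset(tr for t in self.terms for tr in t.traits)


@dataclasses.dataclass
class SimulationConfig:
    """Settings for the synthetic generator; a seed is mandatory."""

    n_species: int
    seed: int
    trait_ranges: dict[str, tuple[float, float]] = dataclasses.field(default_factory=dict)
    trait_correlation: np.ndarray | None = None
    kernel_alpha: float = 5.0       # per km: mean movement 200 m
    kernel_b: float = 2.0           # inverse-power tail exponent
    kernel_d_min: float = 0.05      # km, reference (minimum) distance
    residency_totals: tuple[int, ...] = (40, 25, 15)  # recaptures per patch
    fst_range: tuple[float, float] = (0.0, 0.18)

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.seed is None:
            raise ValueError("a seed is mandatory for all stochastic draws")


def _draw_trait(name: str, u: np.ndarray, overrides: dict[str, tuple[float, float]]) -> np.ndarray:
    """Map uniform(0,1) draws onto one trait's admissible values."""
    tdef = TRAIT_REGISTRY[name]
    if name in overrides:
        low, high = overrides[name]
    elif name == "wing_length":
        low, high = _WING_RANGE
    else:
        low, high = tdef.low, tdef.high
    if tdef.kind == "continuous":
        return low + u * (high - low)
    levels = np.arange(int(low), int(high) + 1)
    idx = np.minimum((u * levels.size).astype(int), levels.size - 1)
    return levels[idx].astype(float)


def simulate_trait_table(config: SimulationConfig) -> TraitTable:
    """Draw a species x trait table within each trait's admissible range.

    Continuous traits are uniform over their range; ordinal and binary
    traits uniform over their levels.  With ``trait_correlation`` set, the
    18 uniforms per species come from a Gaussian copula with that
    correlation matrix (order of :data:`TRAIT_NAMES`); the default is
    independence.
    """
    rng = np.random.default_rng(config.seed)
    k = len(TRAIT_NAMES)
    if config.trait_correlation is not None:
        R = np.asarray(config.trait_correlation, dtype=float)
        if R.shape != (k, k):
            raise ValueError(f"trait_correlation must be {k}x{k} (order of TRAIT_NAMES)")
        z = rng.multivariate_normal(np.zeros(k), R, size=config.n_species, method="cholesky")
        u = scipy.stats.norm.cdf(z)
    else:
        u = rng.random((config.n_species, k))
    data = {
        name: _draw_trait(name, u[:, j], config.trait_ranges)
        for j, name in enumerate(TRAIT_NAMES)
    }
    idx = pd.Index([f"sp{i + 1}" for i in range(config.n_species)], name="species_id")
    return TraitTable(pd.DataFrame(data, index=idx))


@dataclasses.dataclass
class SimulatedResponse:
    """Generated responses: the dataset plus generation-time diagnostics."""

    dataset: DispersalDataset
    latent: pd.Series      # transformed-scale values before domain clipping
    clipped: pd.Series     # True where back-transformation required clipping


def simulate_responses(traits: TraitTable, model: TrueModel,
                       seed: int | np.random.Generator | None = 0) -> SimulatedResponse:
    """Generate one element's responses from a ground-truth syndrome.

    Trait columns are standardized internally before the coefficients are
    applied; the transformed-scale response is
    intercept + sum(coef * term) + Normal(0, noise_sd), and the raw value
    is the back-transform clipped into the element's valid domain.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pred = predictor_frame(traits)
    z = {}
    for v in model.variables:
        col = pred[v].to_numpy(dtype=float)
        sd = col.std(ddof=0)
        if sd == 0:
            raise ValueError(f"trait {v} is constant: cannot standardize")
        z[v] = (col - col.mean()) / sd
    eta = np.full(len(pred), model.intercept, dtype=float)
    for t in model.terms:
        if t.form == "linear":
            eta += t.coef * z[t.traits[0]]
        elif t.form == "quadratic":
            eta += t.coef * z[t.traits[0]] ** 2
        else:
            eta += t.coef * z[t.traits[0]] * z[t.traits[1]]
    eta = eta + rng.normal(0.0, model.noise_sd, size=eta.size)
    latent = pd.Series(eta, index=pred.index, name=model.element.value)
    raw, truncated = clip_to_domain(model.element, eta)
    obs = [
        DispersalObservation(sp, model.element, float(r))
        for sp, r in zip(pred.index, raw)
    ]
    return SimulatedResponse(
        dataset=DispersalDataset(obs),
        latent=latent,
        clipped=pd.Series(truncated, index=pred.index, name="clipped"),
    )


def simulate_mrr_distances(family: str, params: dict, n: int,
                           seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Draw MRR movement distances (km) from a dispersal kernel.

    ``negexp`` draws are Exponential with rate alpha (mean 1/alpha);
    ``invpower`` draws are Pareto with survival (d/d_min)^-(b-1) for
    d >= d_min.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if family == "negexp":
        alpha = params["alpha"]
        if alpha <= 0:
            raise ValueError("alpha must be > 0")
        return rng.exponential(scale=1.0 / alpha, size=n)
    if family == "invpower":
        b, d_min = params["b"], params["d_min"]
        if b <= 1 or d_min <= 0:
            raise ValueError("invpower needs b > 1 and d_min > 0")
        u = rng.random(n)
        return d_min * u ** (-1.0 / (b - 1.0))
    raise ValueError(f"unknown kernel family {family!r}")


def simulate_residency_counts(propensity: float, totals: tuple[int, ...],
                              seed: int | np.random.Generator | None = None) -> list[tuple[int, int]]:
    """Per-patch (residents, total recaptures) with a common leave probability."""
    if not 0.0 <= propensity <= 1.0:
        raise ValueError("propensity must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [(int(rng.binomial(t, 1.0 - propensity)), int(t)) for t in totals]


def simulate_fst(n: int, fst_range: tuple[float, float] = (0.0, 0.18),
                 seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Uniform F_ST draws in the observed band (weak genetic structuring)."""
    lo, hi = fst_range
    if not 0.0 <= lo <= hi <= 1.0:
        raise ValueError("F_ST range must satisfy 0 <= lo <= hi <= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return lo + (hi - lo) * rng.random(n)


def simulate_tree_and_trait(
    n_tips: int,
    lambda_signal: float,
    seed: int,
    sigma2: float = 1.0,
    birth_rate: float = 1.0,
) -> tuple[Phylogeny, pd.Series]:
    """A pure-birth tree and one Brownian trait with tunable signal.

    The trait is multivariate normal with covariance sigma2 * C_lambda,
    where C is the tree's Brownian covariance and lambda multiplies its
    off-diagonal entries (Pagel rescaling of internal branches).
    lambda = 0 gives i.i.d. tip values; lambda = 1 full Brownian motion.
    """
    if n_tips < 3:
        raise ValueError("need >= 3 tips")
    if not 0.0 <= lambda_signal <= 1.0:
        raise ValueError("lambda_signal must lie in [0, 1]")
    pyrng = _pyrandom.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_tips, rng=pyrng
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        if leaf.taxon is None:
            leaf.taxon = tree.taxon_namespace.new_taxon(label=f"sp{i + 1}")
        else:
            leaf.taxon.label = f"sp{i + 1}"
    phylo = Phylogeny(tree)
    C = phylo.brownian_covariance().to_numpy()
    Clam = np.diag(np.diag(C)) + lambda_signal * (C - np.diag(np.diag(C)))
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(sigma2 * Clam + 1e-12 * np.eye(n_tips))
    trait = L @ rng.standard_normal(n_tips)
    return phylo, pd.Series(trait, index=pd.Index(phylo.tip_labels, name="species_id"), name="trait")
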