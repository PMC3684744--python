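"""Dispersal-kernel fitting and the four dispersal measurements.

Two kernel families are supported, both fitted to mark-release-recapture
(MRR) movement distances:

* negative exponential, P(D) = exp(-alpha * D): the mean dispersal
  distance is 1/alpha;
* inverse power, P(D) = a * D^(-b), handled as a Pareto distribution with
  reference (minimum) distance d_min, used for the probability of
  long-distance (> 5 km) movements.

Both have closed-form maximum-likelihood estimators, so no numerical
optimizer is involved.  A weighted-least-squares path on log binned
densities is provided as an alternative for data available only as binned
kernels.

The tail probability P(D > t) is computed as the integrated tail mass of
the fitted density, not a point evaluation of the density at t.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data import DispersalObservation
from .elements import Element

__all__ = [
    "KernelFit",
    "fit_negexp",
    "fit_invpower",
    "fit_binned",
    "tail_probability",
    "propensity_from_recaptures",
    "geneflow_from_fst",
]


@dataclasses.dataclass(frozen=True)
class KernelFit:
    """A fitted dispersal kernel.

    ``params`` holds ``{"alpha": ...}`` (per km) for the negative
    exponential or ``{"a": ..., "b": ..., "d_min": ...}`` for the inverse
    power.  ``mean_distance`` (km) is defined for the negative exponential
    (1/alpha) and for the inverse power when b > 2.
    """

    family: str
    params: dict[str, float]
    n: int
    loglik: float

    def __post_init__(self):
        if self.family not in ("negexp", "invpower"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "negexp" and self.params["alpha"] <= 0:
            raise ValueError("negexp requires alpha > 0")
        if self.family == "invpower" and self.params["b"] <= 1:
            raise ValueError("invpower requires b > 1 (finite tail mass)")

    @property
    def mean_distance(self) -> float:
        """Mean dispersal distance (km) under the fitted kernel."""
        if self.family == "negexp":
            return 1.0 / self.params["alpha"]
        b, d_min = self.params["b"], self.params["d_min"]
        if b <= 2:
            return np.inf
        return d_min * (b - 1) / (b - 2)

    def density(self, d):
        """Fitted probability density at distance(s) ``d`` (km)."""
        d = np.asarray(d, dtype=float)
        if self.family == "negexp":
            a = self.params["alpha"]
            return a * np.exp(-a * d)
        a, b, d_min = self.params["a"], self.params["b"], self.params["d_min"]
        return np.where(d >= d_min, a * np.power(d, -b, where=d > 0), 0.0)


def fit_negexp(distances) -> KernelFit:
    """Maximum-likelihood negative-exponential fit to raw distances (km).

    alpha-hat = 1 / sample mean, so the fitted mean dispersal distance is
    exactly the sample mean.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 distances to fit a kernel")
    if np.any(d <= 0):
        raise ValueError("all distances must be strictly positive")
    alpha = 1.0 / d.mean()
    loglik = d.size * np.log(alpha) - alpha * d.sum()
    return KernelFit("negexp", {"alpha": float(alpha)}, int(d.size), float(loglik))


def fit_invpower(distances, d_min: float) -> KernelFit:
    """Maximum-likelihood inverse-power (Pareto) fit to raw distances (km).

    The density is f(d) = (b-1) d_min^(b-1) d^(-b) for d >= d_min, i.e.
    a = (b-1) d_min^(b-1) by normalization, and the MLE is the closed form
    b-hat = 1 + n / sum(ln(d_i / d_min)).
    """
    d = np.asarray(distances, dtype=float)
    if d_min <= 0:
        raise ValueError("d_min must be > 0")
    if d.size < 2:
        raise ValueError("need at least 2 distances to fit a kernel")
    if np.any(d < d_min):
        raise ValueError("all distances must be >= d_min")
    log_ratio = np.log(d / d_min)
    s = log_ratio.sum()
    if s <= 0:
        raise ValueError("all distances equal d_min: tail exponent is not identifiable")
    b = 1.0 + d.size / s
    a = (b - 1.0) * d_min ** (b - 1.0)
    loglik = d.size * np.log(b - 1.0) + d.size * (b - 1.0) * np.log(d_min) - b * np.log(d).sum()
    return KernelFit("invpower", {"a": float(a), "b": float(b), "d_min": float(d_min)}, int(d.size), float(loglik))


def fit_binned(family: str, midpoints, densities, d_min: float | None = None, weights=None) -> KernelFit:
    """Fit a kernel to a binned density (density probability vs distance class).

    Weighted least squares on the log density: log f is linear in d for the
    negative exponential and linear in log d for the inverse power.  Use
    when raw distances are unavailable; the raw-distance MLE is preferred
    otherwise.  ``weights`` defaults to equal weighting of classes.
    """
    mid = np.asarray(midpoints, dtype=float)
    dens = np.asarray(densities, dtype=float)
    if mid.size != dens.size or mid.size < 2:
        raise ValueError("need >= 2 matching (midpoint, density) pairs")
    if np.any(dens <= 0) or np.any(mid <= 0):
        raise ValueError("midpoints and densities must be strictly positive")
    w = np.ones_like(mid) if weights is None else np.asarray(weights, dtype=float)
    y = np.log(dens)
    x = mid if family == "negexp" else np.log(mid)
    X = np.column_stack([np.ones_like(x), x])
    W = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * W[:, None], y * W, rcond=None)
    if family == "negexp":
        alpha = -coef[1]
        if alpha <= 0:
            raise ValueError("binned fit produced non-positive alpha; data not exponential-like")
        return KernelFit("negexp", {"alpha": float(alpha)}, int(mid.size), float("nan"))
    if family == "invpower":
        b = -coef[1]
        if b <= 1:
            raise ValueError("binned fit produced b <= 1 (infinite tail mass)")
        dm = d_min if d_min is not None else float(mid.min())
        a = float(np.exp(coef[0]))
        return KernelFit("invpower", {"a": a, "b": float(b), "d_min": dm}, int(mid.size), float("nan"))
    raise ValueError(f"unknown kernel family {family!r}")


def tail_probability(fit: KernelFit, threshold: float) -> float:
    """Probability of a dispersal movement beyond ``threshold`` km.

    Integrated tail mass of the fitted density, clamped to [0, 1]:
    exp(-alpha t) for the negative exponential, (t / d_min)^-(b-1) for the
    inverse power (defined for t >= d_min).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if fit.family == "negexp":
        p = np.exp(-fit.params["alpha"] * threshold)
    else:
        b, d_min = fit.params["b"], fit.params["d_min"]
        if b <= 1:
            raise ValueError("b <= 1: tail mass is infinite")
        if threshold < d_min:
            raise ValueError(f"threshold {threshold} below reference distance d_min={d_min}")
        p = (threshold / d_min) ** (-(b - 1.0))
    return float(min(max(p, 0.0), 1.0))


def propensity_from_recaptures(per_patch: list[tuple[int, int]]) -> float:
    """Dispersal propensity from per-patch MRR recapture counts.

    Each entry is ``(residents, total_recaptures)`` for one patch; the
    propensity to leave a patch is 1 - residents/total, averaged over
    patches with equal weight (patches differ in size; the average is
    unweighted).
    """
    if not per_patch:
        raise ValueError("need at least one patch")
    props = []
    for residents, total in per_patch:
        if total < 1:
            raise ValueError("each patch needs >= 1 recapture")
        if residents < 0 or residents > total:
            raise ValueError(f"residents {residents} outside [0, total={total}]")
        props.append(1.0 - residents / total)
    return float(np.mean(props))


def geneflow_from_fst(species_id: str, fst: float) -> DispersalObservation:
    """Build the gene-flow observation for one species from its F_ST.

    F_ST quantifies genetic structuring among local populations and is
    inversely related to gene flow; the stored raw value is F_ST and the
    analysis value is its normalizing transform.
    """
    if not 0.0 <= fst <= 1.0:
        raise ValueError(f"F_ST must lie in [0, 1], got {fst}")
    return DispersalObservation(species_id, Element.GENE_FLOW, float(fst))
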