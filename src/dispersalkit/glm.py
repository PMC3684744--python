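"""Gaussian GLM (OLS) fitting, log-likelihood, and small-sample AIC.

Dispersal responses are modelled on their transformed (normalized) scales,
so the GLM is a Gaussian identity-link model fitted by ordinary least
squares.  The log-likelihood uses the maximum-likelihood residual variance
(RSS/n), and model comparison uses AICc, whose parameter count includes the
intercept and the residual variance in addition to the slopes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .terms import Design, ModelSpec

__all__ = ["FitResult", "fit_glm", "aicc", "gaussian_loglik"]


def gaussian_loglik(rss: float, n: int) -> float:
    """Gaussian log-likelihood at the MLE variance sigma^2 = RSS/n."""
    if n <= 0:
        raise ValueError("n must be positive")
    if rss <= 0:
        # numerically perfect fit: likelihood is unbounded; report +inf so
        # such models always rank first, which is the correct limit
        return np.inf
    return -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


def aicc(loglik: float, p: int, n: int) -> float:
    """Akaike Information Criterion corrected for small samples.

    AICc = -2 loglik + 2p + 2p(p+1)/(n - p - 1), where ``p`` counts *all*
    estimated parameters: intercept, slopes, and the residual variance.
    """
    if n - p - 1 < 1:
        raise ValueError(f"model saturated: n={n}, p={p} leaves n-p-1={n - p - 1} < 1")
    return -2.0 * loglik + 2.0 * p + 2.0 * p * (p + 1.0) / (n - p - 1.0)


@dataclasses.dataclass
class FitResult:
    """A fitted Gaussian GLM for one dispersal response.

    Coefficients, their uncertainties, the Gaussian log-likelihood (MLE
    variance), AICc, and goodness of fit.  ``params`` is indexed by design
    column name, intercept first.
    """

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    resid_sd: float
    loglik: float
    aicc: float
    rsquared: float
    rsquared_adj: float
    nobs: int
    design: Design = dataclasses.field(repr=False)

    @property
    def k(self) -> int:
        return self.spec.k

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Transformed-scale predictions for new species."""
        return self.design.matrix(data) @ self.params.to_numpy()

    def summary(self) -> str:
        lines = [
            f"Model: {self.spec}",
            f"n = {self.nobs}, slopes k = {self.k}, AICc = {self.aicc:.3f}",
            f"R^2 = {self.rsquared:.4f}, adj. R^2 = {self.rsquared_adj:.4f}, residual SD = {self.resid_sd:.4f}",
            "",
            f"{'term':<40}{'estimate':>12}{'SE':>12}{'p':>10}",
        ]
        for name in self.params.index:
            p = self.pvalues[name]
            lines.append(
                f"{name:<40}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}"
                f"{'' if np.isnan(p) else format(p, '>10.4f'):>10}"
            )
        return "\n".join(lines)


def fit_glm(spec: ModelSpec, response: pd.Series, data: pd.DataFrame,
            design: Design | None = None) -> FitResult:
    """Fit a Gaussian identity-link GLM (OLS) on the transformed response.

    ``response`` and ``data`` must be aligned on the same index (complete
    cases).  Raises a singularity error naming the collinear columns when
    the design is rank deficient.
    """
    y = response.to_numpy(dtype=float)
    n = y.size
    if n < spec.k + 2:
        raise ValueError(f"need at least k+2 = {spec.k + 2} complete cases, got {n}")
    if design is None:
        design = Design(spec, data)
    X = design.matrix(data)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design ({rank} < {X.shape[1]}): collinear terms among {design.column_names[1:]}"
        )
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    tss = float(np.sum((y - y.mean()) ** 2))
    # the intercept is always included, so R^2 is bounded in [0, 1];
    # clamp away floating-point residue
    r2 = 0.0 if tss == 0 else min(max(1.0 - rss / tss, 0.0), 1.0)
    k = spec.k
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1) if n - k - 1 > 0 else np.nan
    ll = gaussian_loglik(rss, n)
    idx = pd.Index(design.column_names)
    return FitResult(
        spec=spec,
        params=pd.Series(res.params, index=idx),
        bse=pd.Series(res.bse, index=idx),
        pvalues=pd.Series(res.pvalues, index=idx),
        resid_sd=float(np.sqrt(rss / n)),
        loglik=ll,
        aicc=aicc(ll, k + 2, n),
        rsquared=r2,
        rsquared_adj=r2_adj,
        nobs=n,
        design=design,
    )
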