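"""Plot helpers: cross-validation scatter and dispersal-distribution panels.

matplotlib is an optional dependency (install the ``plot`` extra); it is
imported lazily so the analysis stack works without it.
"""

from __future__ import annotations

import numpy as np

from .prediction import PredictionSet, summarize_distribution
from .validation import CrossValidation

__all__ = ["plot_observed_vs_predicted", "plot_dispersal_distribution"]


def _pyplot():
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (pip install dispersalkit[plot])") from exc
    return plt


def plot_observed_vs_predicted(cv: CrossValidation, ax=None, label: str | None = None):
    """Observed dispersal against mean held-out predictions.

    Error bars show the SE over partitions; the solid line is the
    rightness regression, the dotted line the 1:1 ideal, the gray line the
    regression forced through the origin.
    """
    plt = _pyplot()
    if ax is None:
        _, ax = plt.subplots()
    held = cv.predictions.dropna(subset=["mean"])
    x = held["mean"].to_numpy()
    y = cv.observed.loc[held.index].to_numpy()
    ax.errorbar(x, y, xerr=held["se"].to_numpy(), fmt="o", ms=4, color="k", ecolor="0.6")
    xs = np.linspace(x.min(), x.max(), 50)
    xc = x - x.mean()
    slope = float(xc @ (y - y.mean()) / (xc @ xc))
    ax.plot(xs, y.mean() + slope * (xs - x.mean()), "k-", label=f"slope {slope:.2f}")
    ax.plot(xs, xs, "k:", label="1:1")
    ax.plot(xs, float(x @ y / (x @ x)) * xs, color="0.6", label="through origin")
    ax.set_xlabel("mean predicted (transformed scale)")
    ax.set_ylabel("observed (transformed scale)")
    if label:
        ax.set_title(label)
    ax.legend(frameon=False)
    return ax


def plot_dispersal_distribution(preds: PredictionSet, observed=None, ax=None, n_grid: int = 200):
    """Kernel-density curves of predicted (and observed) natural-scale values."""
    plt = _pyplot()
    if ax is None:
        _, ax = plt.subplots()
    summary = summarize_distribution(preds, observed=observed)
    for name, kde in summary.attrs["kde"].items():
        if kde is None:
            continue
        lo, hi = summary.loc[name, "min"], summary.loc[name, "max"]
        pad = 0.1 * (hi - lo)
        xs = np.linspace(lo - pad, hi + pad, n_grid)
        style = {"predicted": {"color": "0.3"}, "observed": {"color": "0.6", "ls": "--"}}[name]
        ax.plot(xs, kde(xs), label=f"{name} (n={int(summary.loc[name, 'n'])})", **style)
    ax.set_xlabel(f"{preds.element.value} (natural scale)")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    return ax
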