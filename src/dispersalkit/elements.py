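"""Dispersal elements and their normalizing transforms.

Four measurements of butterfly dispersal are modelled, each on a transformed
scale chosen to normalize the species-level distribution:

================  =========================================  ==============
element           raw value                                  transform
================  =========================================  ==============
mean_distance     mean dispersal distance (km), > 0          x' = ln(x)
ldd_frequency     probability of > 5 km movements, (0, 1]    x' = log10(x)
propensity        probability of leaving the natal patch,    x' = -sqrt(x)
                  in [0, 1]
gene_flow         F_ST among local populations, in [0, 1]    x' = 1 - sqrt(F_ST)
================  =========================================  ==============

The gene-flow analysis value 1 - sqrt(F_ST) increases with gene flow
(F_ST is inversely related to gene flow); the raw value stored is always
F_ST itself.
"""

from __future__ import annotations

import enum

import numpy as np

__all__ = [
    "Element",
    "ELEMENTS",
    "transform",
    "inverse_transform",
    "raw_domain",
    "clip_to_domain",
    "RELATIVE_IMPRECISION_ELEMENTS",
]


class Element(str, enum.Enum):
    """The four dispersal measurements."""

    MEAN_DISTANCE = "mean_distance"
    LDD_FREQUENCY = "ldd_frequency"
    PROPENSITY = "propensity"
    GENE_FLOW = "gene_flow"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


ELEMENTS: tuple[Element, ...] = tuple(Element)

#: Elements whose cross-validation imprecision is reported relative to the
#: observed value (scale-dependent measures).
RELATIVE_IMPRECISION_ELEMENTS = frozenset(
    {Element.MEAN_DISTANCE, Element.LDD_FREQUENCY}
)

# Closed raw-value domain per element: (low, high, low_open).
_DOMAINS: dict[Element, tuple[float, float, bool]] = {
    Element.MEAN_DISTANCE: (0.0, np.inf, True),
    Element.LDD_FREQUENCY: (0.0, 1.0, True),
    Element.PROPENSITY: (0.0, 1.0, False),
    Element.GENE_FLOW: (0.0, 1.0, False),
}


def _as_element(element: Element | str) -> Element:
    if isinstance(element, Element):
        return element
    try:
        return Element(element)
    except ValueError:
        valid = ", ".join(e.value for e in Element)
        raise ValueError(f"unknown dispersal element {element!r}; expected one of: {valid}") from None


def raw_domain(element: Element | str) -> tuple[float, float, bool]:
    """Return ``(low, high, low_open)`` for the element's raw-value domain."""
    return _DOMAINS[_as_element(element)]


def _check_domain(element: Element, x: np.ndarray) -> None:
    low, high, low_open = _DOMAINS[element]
    bad = (x < low) | (x > high) | (low_open & (x <= low)) if low_open else (x < low) | (x > high)
    if np.any(bad):
        op = ">" if low_open else ">="
        raise ValueError(
            f"{element.value}: raw value(s) {np.asarray(x)[np.asarray(bad)][:5]} outside "
            f"valid domain ({op} {low}, <= {high})"
        )


def transform(element: Element | str, x):
    """Map a raw dispersal value onto the normalized analysis scale.

    Parameters
    ----------
    element : Element or str
        Which dispersal measurement ``x`` is.
    x : float or array_like
        Raw value(s) in the element's valid domain (strictly positive for
        the two logarithmic transforms).

    Returns
    -------
    float or ndarray
        Transformed value(s) x'.
    """
    element = _as_element(element)
    arr = np.asarray(x, dtype=float)
    _check_domain(element, arr)
    if element is Element.MEAN_DISTANCE:
        out = np.log(arr)
    elif element is Element.LDD_FREQUENCY:
        out = np.log10(arr)
    elif element is Element.PROPENSITY:
        out = -np.sqrt(arr)
    else:  # gene flow: raw value is F_ST
        out = 1.0 - np.sqrt(arr)
    return out if isinstance(x, np.ndarray) else float(out) if np.ndim(x) == 0 else out


def inverse_transform(element: Element | str, xprime):
    """Invert :func:`transform`; exact on each element's valid domain.

    Raises ``ValueError`` when ``xprime`` lies outside the image of the
    transform (e.g. a positive value for the propensity scale, whose image
    is [-1, 0]).  Use :func:`clip_to_domain` for lenient back-transformation
    of model predictions.
    """
    element = _as_element(element)
    arr = np.asarray(xprime, dtype=float)
    if element is Element.MEAN_DISTANCE:
        out = np.exp(arr)
    elif element is Element.LDD_FREQUENCY:
        if np.any(arr > 0):
            raise ValueError("ldd_frequency transformed values must be <= 0 (raw <= 1)")
        out = np.power(10.0, arr)
    elif element is Element.PROPENSITY:
        if np.any(arr > 0) or np.any(arr < -1):
            raise ValueError("propensity transformed values must lie in [-1, 0]")
        out = np.square(arr)
    else:
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("gene_flow transformed values must lie in [0, 1]")
        out = np.square(1.0 - arr)
    return out if isinstance(xprime, np.ndarray) else float(out) if np.ndim(xprime) == 0 else out


def clip_to_domain(element: Element | str, xprime):
    """Back-transform with truncation into the element's valid raw domain.

    Transformed-scale predictions can fall outside the image of the
    transform; truncation moves them to the nearest boundary before
    inversion.  Mean dispersal distance needs no truncation (exp is always
    positive); LDD frequency is clipped to (0, 1]; propensity and gene flow
    to [0, 1].

    Returns
    -------
    raw : ndarray or float
        Back-transformed value(s), inside the valid domain.
    truncated : ndarray of bool or bool
        True where clipping moved the prediction.
    """
    element = _as_element(element)
    arr = np.asarray(xprime, dtype=float)
    if element is Element.MEAN_DISTANCE:
        clipped = arr
    elif element is Element.LDD_FREQUENCY:
        clipped = np.minimum(arr, 0.0)
    elif element is Element.PROPENSITY:
        clipped = np.clip(arr, -1.0, 0.0)
    else:
        clipped = np.clip(arr, 0.0, 1.0)
    truncated = clipped != arr
    raw = inverse_transform(element, clipped)
    if np.ndim(xprime) == 0:
        return float(raw), bool(truncated)
    return raw, truncated
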