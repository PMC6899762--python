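"""Mapping a continuous efficacy endpoint onto the probability scale.

The trade-off criterion consumes an efficacy *probability*, but many trial
endpoints (e.g. the change in log tumour-marker level) live on the real line.
The bridge is a monotone link-based transformation

    T(xi) = linkinv(alpha + beta * xi)

with ``linkinv`` the inverse logit (default), the standard-normal CDF, or the
inverse complementary log-log.  ``beta < 0`` encodes endpoints where *lower*
values mean better response (the tumour-marker convention used throughout the
built-in scenarios).

The intercept/slope are solved from two clinical anchors: the lowest efficacy
bound ``psi`` maps to a small probability (default 0.01) and the best
clinically feasible value ``psi_prime`` maps to a high one (default 0.9).
Unlike a linear rescaling onto [psi, psi_prime], the link keeps the map total
on the real line, so observations outside the anchor interval need no
truncation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit, logit, ndtr, ndtri

__all__ = ["TransformSpec", "solve_anchors", "transform_value", "inverse_transform"]

_FAMILIES = ("logistic", "probit", "cloglog")


def _link(p: float, family: str) -> float:
    """The link function (probability -> real line) for each family."""
    if family == "logistic":
        return float(logit(p))
    if family == "probit":
        return float(ndtri(p))
    if family == "cloglog":
        return math.log(-math.log(1.0 - p))
    raise ValueError(f"unknown transform family {family!r}")


def solve_anchors(
    psi: float,
    psi_prime: float,
    p_low: float = 0.01,
    p_high: float = 0.9,
    family: str = "logistic",
) -> tuple[float, float]:
    """Solve (alpha, beta) from the two anchor conditions.

    Imposes ``T(psi) = p_low`` and ``T(psi_prime) = p_high`` for the given
    link family, i.e.

        beta  = (link(p_high) - link(p_low)) / (psi_prime - psi)
        alpha = link(p_low) - beta * psi.

    The sign of beta is determined by the orientation of the anchors: when the
    best feasible value ``psi_prime`` lies below the bound ``psi``, beta comes
    out negative.
    """
    if psi == psi_prime:
        raise ValueError("psi and psi_prime must differ (degenerate anchor geometry)")
    for name, p in (("p_low", p_low), ("p_high", p_high)):
        if not (0.0 < p < 1.0):
            raise ValueError(f"{name} must lie strictly in (0, 1), got {p}")
    if not p_low < p_high:
        raise ValueError(f"p_low must be below p_high, got {p_low} >= {p_high}")
    lo = _link(p_low, family)
    hi = _link(p_high, family)
    beta = (hi - lo) / (psi_prime - psi)
    alpha = lo - beta * psi
    return alpha, beta


@dataclass(frozen=True)
class TransformSpec:
    """A fully specified endpoint transformation.

    Attributes
    ----------
    family : str
        One of ``logistic`` (default), ``probit``, ``cloglog``.
    alpha, beta : float
        Shift and slope of the linear predictor ``alpha + beta * xi``.
    psi, psi_prime : float
        The anchor values on the original endpoint scale (lowest efficacy
        bound and highest clinically feasible value).
    p_low, p_high : float
        The probabilities the anchors map to.
    """

    family: str = "logistic"
    alpha: float = 0.0
    beta: float = -1.0
    psi: float = 0.0
    psi_prime: float = -4.5
    p_low: float = 0.01
    p_high: float = 0.9

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}, got {self.family!r}")
        if self.beta == 0.0:
            raise ValueError("beta must be nonzero")

    @classmethod
    def from_anchors(
        cls,
        psi: float,
        psi_prime: float,
        p_low: float = 0.01,
        p_high: float = 0.9,
        family: str = "logistic",
        solve_per_family: bool = False,
    ) -> "TransformSpec":
        """Build a spec by solving the anchor conditions.

        By default the non-logistic families reuse the logistic-solved
        (alpha, beta) — the same-parameter convention of the reference
        specification — so the three curves are directly comparable.  Pass
        ``solve_per_family=True`` to re-solve the two-anchor system with the
        family's own link, in which case the anchors hold exactly for that
        family too.
        """
        solve_family = family if solve_per_family else "logistic"
        alpha, beta = solve_anchors(psi, psi_prime, p_low, p_high, family=solve_family)
        return cls(family, alpha, beta, psi, psi_prime, p_low, p_high)

    def with_family(self, family: str) -> "TransformSpec":
        return replace(self, family=family)


def transform_value(xi, spec: TransformSpec):
    """Map an efficacy value (scalar or array) into (0, 1).

    Total on the reals; ``scipy.special.expit``/``ndtr`` keep the evaluation
    overflow-free for arbitrarily large linear predictors.
    """
    eta = spec.alpha + spec.beta * np.asarray(xi, dtype=float)
    if spec.family == "logistic":
        out = expit(eta)
    elif spec.family == "probit":
        out = ndtr(eta)
    else:  # cloglog
        # 1 - exp(-exp(eta)); -expm1 keeps precision for small exp(eta)
        with np.errstate(over="ignore"):
            out = -np.expm1(-np.exp(eta))
    if np.ndim(xi) == 0:
        return float(out)
    return out


def inverse_transform(p, spec: TransformSpec):
    """Map a probability back to the original endpoint scale.

    Inverse of :func:`transform_value`; raises for p outside the open unit
    interval where the inverse link is undefined.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0.0) or np.any(p_arr >= 1.0):
        raise ValueError("p must lie strictly in (0, 1)")
    if spec.family == "logistic":
        eta = logit(p_arr)
    elif spec.family == "probit":
        eta = ndtri(p_arr)
    else:
        eta = np.log(-np.log1p(-p_arr))
    out = (eta - spec.alpha) / spec.beta
    if np.ndim(p) == 0:
        return float(out)
    return out
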