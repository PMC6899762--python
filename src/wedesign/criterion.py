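"""Information-theoretic toxicity--efficacy trade-off criterion.

A regimen in a seamless Phase I/II trial is summarised by a trinomial outcome
probability vector ``theta = (theta1, theta2, theta3)`` for the events
"efficacy and no toxicity", "no efficacy and no toxicity" and "toxicity"
(efficacy is assumed observable only in the absence of toxicity, so the two
toxic cells are merged).  The trade-off criterion scores the divergence of
``theta`` from a clinician-specified target profile ``gamma``:

    delta(theta, gamma) = gamma1^2/theta1 + gamma2^2/theta2
                          + (1-gamma1-gamma2)^2 / (1-theta1-theta2) - 1.

The criterion is non-negative, vanishes exactly at ``theta = gamma`` and
diverges whenever any outcome probability collapses to zero, which is what
makes it usable as an allocation loss: it penalises both over-toxic and
under-dosed regimens without any parametric dose--response model.  Smaller is
better; the design recommends the admissible regimen minimising the plug-in
estimate of ``delta``.

Under independence of toxicity and efficacy the trinomial vector factorises
through the marginal toxicity probability ``p_t`` and efficacy probability
``p_e`` via ``theta1 = (1-p_t) p_e``, ``theta2 = (1-p_t)(1-p_e)``,
``theta3 = p_t``; :func:`trade_off_marginal` evaluates the criterion on that
parametrisation, which is the form the trial engine uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "TargetProfile",
    "OutcomeTriple",
    "CriterionWeights",
    "trade_off_outcome",
    "trade_off_marginal",
    "delta_from_margins",
    "rank_regimens",
    "NO_RECOMMENDATION",
]

#: Clamp guard keeping outcome probabilities away from {0, 1} before division.
#: Finite-sample posterior means can hit the boundary to machine precision;
#: the guard turns the criterion's pole into a very large finite penalty.
EPS_GUARD = 1e-12

#: Sentinel returned when no admissible regimen exists.
NO_RECOMMENDATION = None


@dataclass(frozen=True)
class TargetProfile:
    """Target toxicity/efficacy probabilities and the derived trinomial target.

    Parameters
    ----------
    gamma_t : float
        Target toxicity probability, strictly in (0, 1).
    gamma_e : float
        Target efficacy probability (on the unit scale of the transformed
        endpoint), strictly in (0, 1).
    """

    gamma_t: float
    gamma_e: float

    def __post_init__(self) -> None:
        for name in ("gamma_t", "gamma_e"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")

    @property
    def gamma1(self) -> float:
        """Target probability of efficacy without toxicity."""
        return (1.0 - self.gamma_t) * self.gamma_e

    @property
    def gamma2(self) -> float:
        """Target probability of neither efficacy nor toxicity."""
        return (1.0 - self.gamma_t) * (1.0 - self.gamma_e)

    @property
    def gamma3(self) -> float:
        """Target toxicity probability (third trinomial cell)."""
        return self.gamma_t

    def as_triple(self) -> "OutcomeTriple":
        return OutcomeTriple(self.gamma1, self.gamma2, self.gamma3)


@dataclass(frozen=True)
class OutcomeTriple:
    """Trinomial outcome probabilities (efficacy&no-tox, no-eff&no-tox, tox)."""

    theta1: float
    theta2: float
    theta3: float

    def __post_init__(self) -> None:
        t = (self.theta1, self.theta2, self.theta3)
        if any(v <= 0.0 for v in t):
            raise ValueError(f"outcome probabilities must be strictly positive, got {t}")
        if abs(sum(t) - 1.0) > 1e-9:
            raise ValueError(f"outcome probabilities must sum to 1, got {sum(t)}")

    @classmethod
    def from_margins(cls, p_t: float, p_e: float) -> "OutcomeTriple":
        """Build the triple from marginal toxicity/efficacy probabilities."""
        if not (0.0 < p_t < 1.0):
            raise ValueError(f"p_t must lie strictly in (0, 1), got {p_t}")
        if not (0.0 < p_e < 1.0):
            raise ValueError(f"p_e must lie strictly in (0, 1), got {p_e}")
        return cls((1.0 - p_t) * p_e, (1.0 - p_t) * (1.0 - p_e), p_t)


@dataclass(frozen=True)
class CriterionWeights:
    """Optional exponents tuning the contribution of each criterion term.

    The weighted criterion raises each of the three terms to powers
    ``omega1``, ``omega2`` and ``3 - omega1 - omega2``.  The default (1, 1)
    recovers the unweighted criterion used throughout the reproduction suite.
    """

    omega1: float = 1.0
    omega2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("omega1", "omega2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def omega3(self) -> float:
        return 3.0 - self.omega1 - self.omega2

    @property
    def is_unweighted(self) -> bool:
        return self.omega1 == 1.0 and self.omega2 == 1.0


def trade_off_outcome(
    theta: OutcomeTriple,
    target: TargetProfile,
    weights: CriterionWeights | None = None,
) -> float:
    """Evaluate the trade-off criterion on a trinomial outcome triple.

    Returns a non-negative score (for unit weights) measuring how far the
    regimen's outcome profile sits from the target; zero iff ``theta`` equals
    the target triple.
    """
    if theta.theta1 <= 0 or theta.theta2 <= 0 or theta.theta3 <= 0:
        raise ValueError("degenerate regimen profile: theta components must be > 0")
    g1, g2, g3 = target.gamma1, target.gamma2, target.gamma3
    t1 = g1 * g1 / theta.theta1
    t2 = g2 * g2 / theta.theta2
    t3 = g3 * g3 / (1.0 - theta.theta1 - theta.theta2)
    if weights is None or weights.is_unweighted:
        return t1 + t2 + t3 - 1.0
    return t1 ** weights.omega1 + t2 ** weights.omega2 + t3 ** weights.omega3 - 1.0


def trade_off_marginal(
    p_t: float,
    p_e: float,
    target: TargetProfile,
    weights: CriterionWeights | None = None,
) -> float:
    """Trade-off criterion in the marginal (p_t, p_e) parametrisation.

    Equivalent to :func:`trade_off_outcome` applied to the independence
    mapping ``theta = ((1-p_t) p_e, (1-p_t)(1-p_e), p_t)``.
    """
    return trade_off_outcome(OutcomeTriple.from_margins(p_t, p_e), target, weights)


def delta_from_margins(
    p_t: np.ndarray,
    p_e: np.ndarray,
    target: TargetProfile,
    weights: CriterionWeights | None = None,
) -> np.ndarray:
    """Vectorised plug-in criterion with the machine-epsilon clamp guard.

    This is the hot path of the trial engine: posterior means may sit
    numerically at 0 or 1, so each trinomial cell is clamped to
    ``[EPS_GUARD, inf)`` before division instead of raising.
    """
    p_t = np.asarray(p_t, dtype=float)
    p_e = np.asarray(p_e, dtype=float)
    th1 = np.maximum((1.0 - p_t) * p_e, EPS_GUARD)
    th2 = np.maximum((1.0 - p_t) * (1.0 - p_e), EPS_GUARD)
    th3 = np.maximum(p_t, EPS_GUARD)
    g1, g2, g3 = target.gamma1, target.gamma2, target.gamma3
    t1 = g1 * g1 / th1
    t2 = g2 * g2 / th2
    t3 = g3 * g3 / th3
    if weights is None or weights.is_unweighted:
        return t1 + t2 + t3 - 1.0
    return t1 ** weights.omega1 + t2 ** weights.omega2 + t3 ** weights.omega3 - 1.0


def rank_regimens(
    deltas: Sequence[float],
    admissible: Sequence[bool] | None = None,
    toxicity_estimates: Sequence[float] | None = None,
) -> list[int]:
    """Order admissible regimens by ascending trade-off score.

    Ties are broken by lower estimated toxicity, then by lower regimen index
    (a conservative, deterministic rule).  Returns an empty list when no
    regimen is admissible; the caller maps that to ``NO_RECOMMENDATION``.
    """
    deltas = np.asarray(deltas, dtype=float)
    m = deltas.shape[0]
    if admissible is None:
        mask = np.ones(m, dtype=bool)
    else:
        mask = np.asarray(admissible, dtype=bool)
    if toxicity_estimates is None:
        tox = np.zeros(m)
    else:
        tox = np.asarray(toxicity_estimates, dtype=float)
    idx = np.flatnonzero(mask)
    key = sorted(idx, key=lambda j: (deltas[j], tox[j], j))
    return list(map(int, key))
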