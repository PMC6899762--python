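"""Per-regimen conjugate posteriors for toxicity and efficacy.

Each regimen is modelled independently (no borrowing across regimens): a
Beta-binomial pair for the binary toxicity endpoint and a
Normal-inverse-Gamma (NIG) pair for the continuous efficacy endpoint.

Toxicity.  With prior Beta(nu, beta_strength - nu) — prior mean
``nu / beta_strength`` carrying ``beta_strength`` pseudo-observations — and
``t`` toxicities in ``n`` patients, the posterior is
Beta(nu + t, (beta_strength - nu) + (n - t)) with mean
``(t + nu) / (n + beta_strength)``.

Efficacy.  Observations are modelled N(mu, sigma^2) with
(mu, sigma^2) ~ NIG(mu0, lam, zeta, zeta_prime).  The standard conjugate
update applies; the futility rule uses a normal approximation to the marginal
posterior of mu with mean ``mu_hat`` and variance
``rate / ((zeta + n_e/2)(lam + n_e))``.  The efficacy sample size ``n_e`` may
lag the toxicity sample size when efficacy responses are delayed or missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from scipy.special import betainc, ndtr

__all__ = [
    "ToxicityPosterior",
    "EfficacyPosterior",
    "update_toxicity",
    "update_efficacy",
    "toxicity_exceedance",
    "efficacy_futility_prob",
]


@dataclass(frozen=True)
class ToxicityPosterior:
    """Beta posterior state for a regimen's toxicity probability.

    ``nu`` is the prior mean mass and ``beta_strength`` the prior total mass,
    so the prior is Beta(nu, beta_strength - nu) with 0 < nu < beta_strength.
    """

    nu: float
    beta_strength: float = 1.0
    t: int = 0
    n: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.nu < self.beta_strength):
            raise ValueError(
                f"need 0 < nu < beta_strength, got nu={self.nu}, "
                f"beta_strength={self.beta_strength}"
            )
        if self.t < 0 or self.n < 0 or self.t > self.n:
            raise ValueError(f"invalid counts t={self.t}, n={self.n}")

    @property
    def a(self) -> float:
        """First Beta shape parameter, nu + t."""
        return self.nu + self.t

    @property
    def b(self) -> float:
        """Second Beta shape parameter, (beta_strength - nu) + (n - t)."""
        return (self.beta_strength - self.nu) + (self.n - self.t)

    @property
    def mean(self) -> float:
        return (self.t + self.nu) / (self.n + self.beta_strength)

    def update(self, new_tox: int, new_n: int) -> "ToxicityPosterior":
        if new_tox < 0 or new_n < 0 or new_tox > new_n:
            raise ValueError(f"invalid counts new_tox={new_tox}, new_n={new_n}")
        return replace(self, t=self.t + new_tox, n=self.n + new_n)

    def exceedance(self, phi: float) -> float:
        """Posterior probability that the toxicity probability exceeds phi."""
        if not (0.0 < phi < 1.0):
            raise ValueError(f"phi must lie strictly in (0, 1), got {phi}")
        return float(1.0 - betainc(self.a, self.b, phi))


@dataclass(frozen=True)
class EfficacyPosterior:
    """Normal-inverse-Gamma posterior state for a regimen's efficacy mean.

    Prior hyperparameters: ``mu0`` (prior mean), ``lam`` (pseudo-observations
    behind the mean), ``zeta`` (shape strength), ``zeta_prime`` (prior sum of
    squared deviations).  ``n_e, sum_x, sum_x2`` are the sufficient statistics
    of the efficacy observations incorporated so far.
    """

    mu0: float
    lam: float = 1.0
    zeta: float = 2.0
    zeta_prime: float = 3.0
    n_e: int = 0
    sum_x: float = 0.0
    sum_x2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lam", "zeta", "zeta_prime"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        if self.n_e < 0:
            raise ValueError("n_e must be non-negative")

    @property
    def mean(self) -> float:
        """Posterior mean (lam*mu0 + sum x) / (lam + n_e)."""
        return (self.lam * self.mu0 + self.sum_x) / (self.lam + self.n_e)

    @property
    def lam_post(self) -> float:
        return self.lam + self.n_e

    @property
    def shape_post(self) -> float:
        return self.zeta + self.n_e / 2.0

    @property
    def rate_post(self) -> float:
        """Posterior rate: zeta' + SS/2 + n_e*lam*(xbar-mu0)^2 / (2(lam+n_e))."""
        if self.n_e == 0:
            return self.zeta_prime
        xbar = self.sum_x / self.n_e
        css = max(self.sum_x2 - self.sum_x * xbar, 0.0)
        shrink = self.n_e * self.lam * (xbar - self.mu0) ** 2 / (2.0 * (self.lam + self.n_e))
        return self.zeta_prime + 0.5 * css + shrink

    @property
    def mean_variance(self) -> float:
        """Approximate posterior variance of mu: rate / (shape * lam_post)."""
        return self.rate_post / (self.shape_post * self.lam_post)

    def update(self, observations: Iterable[float]) -> "EfficacyPosterior":
        xs = np.asarray(list(observations), dtype=float)
        if xs.size == 0:
            return self
        if not np.all(np.isfinite(xs)):
            raise ValueError("efficacy observations must be finite")
        return replace(
            self,
            n_e=self.n_e + xs.size,
            sum_x=self.sum_x + float(xs.sum()),
            sum_x2=self.sum_x2 + float((xs * xs).sum()),
        )

    def futility_prob(self, psi_star: float, higher_is_better: bool = True) -> float:
        """Posterior mass on the futile side of the efficacy threshold.

        With the normal approximation: the lower tail below ``psi_star`` when
        higher responses are better, the upper tail above it otherwise.
        """
        var = self.mean_variance
        if var <= 0.0 or not math.isfinite(var):
            raise FloatingPointError(f"non-positive posterior variance {var}")
        z = (self.mean - psi_star) / math.sqrt(var)
        return float(ndtr(-z)) if higher_is_better else float(ndtr(z))


# Thin functional wrappers mirroring the operation-style surface.

def update_toxicity(prior: ToxicityPosterior, new_tox: int, new_n: int) -> ToxicityPosterior:
    return prior.update(new_tox, new_n)


def update_efficacy(prior: EfficacyPosterior, observations: Iterable[float]) -> EfficacyPosterior:
    return prior.update(observations)


def toxicity_exceedance(post: ToxicityPosterior, phi: float) -> float:
    return post.exceedance(phi)


def efficacy_futility_prob(
    post: EfficacyPosterior, psi_star: float, higher_is_better: bool = True
) -> float:
    return post.futility_prob(psi_star, higher_is_better)
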