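"""The adaptive trial engine: allocation, constraints, recommendation.

The design treats ``m`` regimens (doses, or dose combinations under a partial
toxicity ordering) independently.  Patients enter in cohorts; after each
cohort the engine

1. updates the per-regimen conjugate posteriors from the data visible at that
   decision point (efficacy may lag toxicity, see the observation models),
2. flags regimens as unsafe/futile against time-varying controlling
   probability schedules (the flags are absorbing, and unsafety propagates
   upward along the known toxicity ordering),
3. computes the plug-in trade-off score ``delta_hat`` for every regimen from
   the posterior toxicity mean and the transformed posterior efficacy mean,
4. restricts candidates by coherence (no skipping of untried regimens when
   moving up the ordering; no escalation immediately after a cohort with
   observed toxicity fraction >= phi at a just-treated regimen) and
   randomises the next cohort between the two smallest scores with
   probabilities proportional to ``1/delta_hat``.  By default each patient
   of the cohort is randomised individually between the two candidates
   (``DesignConfig.allocation = "patient"``); ``"cohort"`` assigns the whole
   cohort to one sampled candidate.

The trial ends when the patient budget is exhausted or when no admissible
regimen remains (early termination).  The final recommendation is the
regimen with the smallest plug-in score among tried regimens that pass the
end-of-trial controlling probabilities *and* whose plug-in toxicity estimate
satisfies the trial's safety definition (posterior mean <= phi) — the
recommended regimen must itself qualify as an optimal biological regimen on
the final estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Any, Protocol, Sequence

import numpy as np
from scipy.special import betainc, ndtr

from .criterion import CriterionWeights, TargetProfile, delta_from_margins
from .posteriors import EfficacyPosterior, ToxicityPosterior
from .transform import TransformSpec, transform_value

__all__ = [
    "RegimenOrdering",
    "DesignConfig",
    "RegimenState",
    "TrialResult",
    "eta_schedule",
    "admissible_regimens",
    "plug_in_delta",
    "allocation_probabilities",
    "allocate_next_cohort",
    "run_trial",
    "single_agent_design",
    "combination_design",
]

# Reference trial defaults (tumour-marker endpoint, lower values better).
SCCA_PRIOR_TOX_SINGLE = (0.10, 0.14, 0.18, 0.22)
SCCA_PRIOR_EFF_SINGLE = (-1.000, -1.025, -1.050, -1.075)
SCCA_PRIOR_TOX_COMBO = (0.10, 0.14, 0.18, 0.22, 0.14, 0.18, 0.22, 0.26)
SCCA_PRIOR_EFF_COMBO = (-1.000, -1.025, -1.050, -1.075, -1.025, -1.050, -1.075, -1.100)


class RegimenOrdering:
    """Known partial ordering of regimens by toxicity.

    ``above[j, k]`` is True when regimen ``k`` is strictly above ``j`` (at
    least as toxic in every coordinate, and not identical).  ``predecessors``
    lists each regimen's immediate predecessors, used by the no-skipping rule.
    """

    def __init__(self, above: np.ndarray, predecessors: Sequence[Sequence[int]]):
        self.above = np.asarray(above, dtype=bool)
        self.predecessors = tuple(tuple(p) for p in predecessors)
        self.m = self.above.shape[0]
        # pred_matrix[j, p]: p is an immediate predecessor of j
        pm = np.zeros_like(self.above)
        for j, preds in enumerate(self.predecessors):
            for p in preds:
                pm[j, p] = True
        self.pred_matrix = pm

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegimenOrdering):
            return NotImplemented
        return (
            self.predecessors == other.predecessors
            and np.array_equal(self.above, other.above)
        )

    def __repr__(self) -> str:
        return f"RegimenOrdering(m={self.m})"

    @classmethod
    def chain(cls, m: int) -> "RegimenOrdering":
        """Total order 0 < 1 < ... < m-1 (single-agent dose escalation)."""
        above = np.triu(np.ones((m, m), dtype=bool), k=1)
        preds = [[] if j == 0 else [j - 1] for j in range(m)]
        return cls(above, preds)

    @classmethod
    def grid(cls, n_a: int, n_b: int) -> "RegimenOrdering":
        """Product partial order for an (n_a x n_b) combination layout.

        Regimen index = b * n_a + a; (a, b) <= (a', b') iff a <= a', b <= b'.
        """
        m = n_a * n_b
        above = np.zeros((m, m), dtype=bool)
        preds: list[list[int]] = [[] for _ in range(m)]
        for b in range(n_b):
            for a in range(n_a):
                j = b * n_a + a
                for b2 in range(n_b):
                    for a2 in range(n_a):
                        k = b2 * n_a + a2
                        if (a2 >= a and b2 >= b) and k != j:
                            above[j, k] = True
                if a > 0:
                    preds[j].append(b * n_a + (a - 1))
                if b > 0:
                    preds[j].append((b - 1) * n_a + a)
        return cls(above, preds)

    def minimal_elements(self) -> np.ndarray:
        return np.flatnonzero(~self.above.any(axis=0) | ~self.pred_matrix.any(axis=1))


def _default_transform() -> TransformSpec:
    return TransformSpec.from_anchors(psi=0.0, psi_prime=-4.5)


@dataclass(frozen=True)
class DesignConfig:
    """All tuning constants of the design.

    Per-regimen prior hyperparameters are tuples of length ``m``:
    ``nu``/``beta_strength`` for the toxicity Beta prior (prior mean
    ``nu/beta_strength``), ``mu0``/``lam``/``zeta``/``zeta_prime`` for the
    efficacy NIG prior.  ``eta1_0 - r_t * n`` (floored at ``eta1_bar``) is the
    safety controlling-probability schedule, and likewise ``eta2_0``,
    ``r_e``, ``eta2_bar`` for futility.
    """

    m: int
    n_max: int
    nu: tuple[float, ...]
    mu0: tuple[float, ...]
    ordering: RegimenOrdering
    beta_strength: tuple[float, ...] = ()
    lam: tuple[float, ...] = ()
    zeta: tuple[float, ...] = ()
    zeta_prime: tuple[float, ...] = ()
    cohort_size: int = 3
    phi: float = 0.3
    psi_star: float = 0.20
    target: TargetProfile = field(default_factory=lambda: TargetProfile(0.01, 0.99))
    transform: TransformSpec = field(default_factory=_default_transform)
    r_t: float = 0.02
    r_e: float = 0.02
    eta1_0: float = 0.95
    eta2_0: float = 0.80
    eta1_bar: float = 0.60
    eta2_bar: float = 0.30
    start_regimen: int = 0
    lower_is_better: bool = True
    constraints_enabled: bool = True
    allocation: str = "patient"
    weights: CriterionWeights | None = None
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        def _fill(name: str, default: float) -> None:
            v = getattr(self, name)
            if len(v) == 0:
                object.__setattr__(self, name, (default,) * self.m)
        _fill("beta_strength", 1.0)
        _fill("lam", 1.0)
        _fill("zeta", 2.0)
        _fill("zeta_prime", 3.0)
        if len(self.labels) == 0:
            object.__setattr__(self, "labels", tuple(f"regimen {j + 1}" for j in range(self.m)))
        for name in ("nu", "mu0", "beta_strength", "lam", "zeta", "zeta_prime", "labels"):
            if len(getattr(self, name)) != self.m:
                raise ValueError(f"{name} must have length m={self.m}")
        for v, b in zip(self.nu, self.beta_strength):
            if not (0.0 < v < b):
                raise ValueError(f"toxicity prior needs 0 < nu < beta_strength, got ({v}, {b})")
        if self.r_t < 0 or self.r_e < 0:
            raise ValueError("schedule rates r_t, r_e must be non-negative")
        if not (0.0 < self.phi < 1.0):
            raise ValueError("phi must lie strictly in (0, 1)")
        if self.n_max < 0 or self.cohort_size < 1:
            raise ValueError("n_max must be >= 0 and cohort_size >= 1")
        if self.ordering.m != self.m:
            raise ValueError("ordering size must match m")
        if self.allocation not in ("patient", "cohort"):
            raise ValueError("allocation must be 'patient' or 'cohort'")
        if self.ordering.above[:, self.start_regimen].any():
            raise ValueError("start_regimen must be minimal in the toxicity ordering")

    @cached_property
    def _arrays(self) -> dict[str, np.ndarray]:
        return {
            "nu": np.asarray(self.nu, dtype=float),
            "b0": np.asarray(self.beta_strength, dtype=float),
            "mu0": np.asarray(self.mu0, dtype=float),
            "lam": np.asarray(self.lam, dtype=float),
            "zeta": np.asarray(self.zeta, dtype=float),
            "zp": np.asarray(self.zeta_prime, dtype=float),
        }

    def prior_states(self) -> list["RegimenState"]:
        return [
            RegimenState(
                tox=ToxicityPosterior(self.nu[j], self.beta_strength[j]),
                eff=EfficacyPosterior(
                    self.mu0[j], self.lam[j], self.zeta[j], self.zeta_prime[j]
                ),
            )
            for j in range(self.m)
        ]


def single_agent_design(
    n_max: int = 36,
    prior_tox: Sequence[float] = SCCA_PRIOR_TOX_SINGLE,
    prior_eff: Sequence[float] = SCCA_PRIOR_EFF_SINGLE,
    **overrides: Any,
) -> DesignConfig:
    """Four-dose single-agent design with the reference-trial defaults."""
    m = len(prior_tox)
    return DesignConfig(
        m=m,
        n_max=n_max,
        nu=tuple(prior_tox),
        mu0=tuple(prior_eff),
        ordering=RegimenOrdering.chain(m),
        labels=tuple(f"dA{j + 1}" for j in range(m)),
        **overrides,
    )


def combination_design(
    n_max: int = 72,
    n_a: int = 4,
    n_b: int = 2,
    prior_tox: Sequence[float] = SCCA_PRIOR_TOX_COMBO,
    prior_eff: Sequence[float] = SCCA_PRIOR_EFF_COMBO,
    **overrides: Any,
) -> DesignConfig:
    """Dual-agent (n_a x n_b) combination design under the product order."""
    m = n_a * n_b
    labels = tuple(f"(dA{a + 1},dB{b + 1})" for b in range(n_b) for a in range(n_a))
    return DesignConfig(
        m=m,
        n_max=n_max,
        nu=tuple(prior_tox),
        mu0=tuple(prior_eff),
        ordering=RegimenOrdering.grid(n_a, n_b),
        labels=labels,
        **overrides,
    )


@dataclass(frozen=True)
class RegimenState:
    """Posterior state and admissibility flags for one regimen."""

    tox: ToxicityPosterior
    eff: EfficacyPosterior
    unsafe: bool = False
    futile: bool = False

    @property
    def n_assigned(self) -> int:
        return self.tox.n


@dataclass
class TrialResult:
    """Outcome of one simulated or replayed trial."""

    recommendation: int | None
    terminated: bool
    n_assigned: np.ndarray
    tox_by_regimen: np.ndarray
    tox_count: int
    eff_values: np.ndarray
    treated: int
    final_deltas: np.ndarray
    final_admissible: np.ndarray | None = None
    decision_log: list[dict] | None = None


def eta_schedule(n, eta0: float, rate: float, eta_bar: float):
    """Linear controlling-probability schedule max(eta0 - rate * n, eta_bar)."""
    out = np.maximum(eta0 - rate * np.asarray(n, dtype=float), eta_bar)
    if np.ndim(n) == 0:
        return float(out)
    return out


def _summaries(
    t: np.ndarray,
    n: np.ndarray,
    ne: np.ndarray,
    sx: np.ndarray,
    sxx: np.ndarray,
    config: DesignConfig,
) -> dict[str, np.ndarray]:
    """Vectorised posterior summaries for all regimens at a decision point."""
    pri = config._arrays
    nu, b0, mu0, lam, zeta, zp = (
        pri["nu"], pri["b0"], pri["mu0"], pri["lam"], pri["zeta"], pri["zp"]
    )
    pt_hat = (t + nu) / (n + b0)
    lam_n = lam + ne
    mu_hat = (lam * mu0 + sx) / lam_n
    ne_safe = np.maximum(ne, 1.0)
    xbar = np.where(ne > 0, sx / ne_safe, mu0)
    css = np.maximum(sxx - sx * xbar, 0.0)
    rate = zp + 0.5 * css + ne * lam * (xbar - mu0) ** 2 / (2.0 * lam_n)
    var = rate / ((zeta + ne / 2.0) * lam_n)
    pe_hat = transform_value(mu_hat, config.transform)
    delta = delta_from_margins(pt_hat, pe_hat, config.target, config.weights)
    safety_tail = 1.0 - betainc(nu + t, (b0 - nu) + (n - t), config.phi)
    z = (mu_hat - config.psi_star) / np.sqrt(var)
    fut = ndtr(z) if config.lower_is_better else ndtr(-z)
    return {
        "pt_hat": pt_hat,
        "mu_hat": mu_hat,
        "mu_var": var,
        "pe_hat": np.asarray(pe_hat, dtype=float),
        "delta": delta,
        "safety_tail": safety_tail,
        "futility_prob": fut,
    }


def _propagate_unsafe(unsafe: np.ndarray, ordering: RegimenOrdering) -> np.ndarray:
    """A regimen declared unsafe renders everything above it unsafe too."""
    if unsafe.any():
        unsafe = unsafe | ordering.above[unsafe].any(axis=0)
    return unsafe


def _update_flags(
    unsafe: np.ndarray,
    futile: np.ndarray,
    summ: dict[str, np.ndarray],
    n: np.ndarray,
    config: DesignConfig,
    final: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the safety/futility constraints; flags are absorbing.

    At interim decisions the schedules are evaluated at each regimen's own
    sample size; at the final analysis the end-of-trial floors apply.
    """
    if final:
        eta1 = config.eta1_bar
        eta2 = config.eta2_bar
    else:
        eta1 = eta_schedule(n, config.eta1_0, config.r_t, config.eta1_bar)
        eta2 = eta_schedule(n, config.eta2_0, config.r_e, config.eta2_bar)
    unsafe = _propagate_unsafe(unsafe | (summ["safety_tail"] >= eta1), config.ordering)
    futile = futile | (summ["futility_prob"] >= eta2)
    return unsafe, futile


def _states_to_arrays(states: Sequence[RegimenState]):
    t = np.array([s.tox.t for s in states], dtype=float)
    n = np.array([s.tox.n for s in states], dtype=float)
    ne = np.array([s.eff.n_e for s in states], dtype=float)
    sx = np.array([s.eff.sum_x for s in states], dtype=float)
    sxx = np.array([s.eff.sum_x2 for s in states], dtype=float)
    return t, n, ne, sx, sxx


def admissible_regimens(states: Sequence[RegimenState], config: DesignConfig) -> np.ndarray:
    """Boolean mask of regimens that are neither unsafe nor futile.

    Evaluates the time-varying constraints at the current per-regimen sample
    sizes, honours flags already set on the states, and propagates unsafety
    upward along the toxicity ordering.
    """
    t, n, ne, sx, sxx = _states_to_arrays(states)
    summ = _summaries(t, n, ne, sx, sxx, config)
    unsafe = np.array([s.unsafe for s in states], dtype=bool)
    futile = np.array([s.futile for s in states], dtype=bool)
    if config.constraints_enabled:
        unsafe, futile = _update_flags(unsafe, futile, summ, n, config)
    return ~(unsafe | futile)


def plug_in_delta(state: RegimenState, config: DesignConfig) -> float:
    """Plug-in trade-off score from posterior toxicity mean and T(mu_hat)."""
    pe = transform_value(state.eff.mean, config.transform)
    return float(
        delta_from_margins(
            np.asarray(state.tox.mean), np.asarray(pe), config.target, config.weights
        )
    )


def _coherence_filter(
    allowed: np.ndarray,
    n: np.ndarray,
    config: DesignConfig,
    last_regimen: int | None,
    last_tox_fraction: float | None,
) -> np.ndarray:
    """Restrict candidates by the coherence rules along the known ordering."""
    allowed = allowed.copy()
    ordering = config.ordering
    untried = n == 0
    # No skipping: an untried regimen is reachable only once all of its
    # immediate predecessors in the ordering have been tried.
    blocked = untried & (ordering.pred_matrix & untried[None, :]).any(axis=1)
    allowed &= ~blocked
    # No escalation right after a cohort with excessive observed toxicity.
    if (
        last_regimen is not None
        and last_tox_fraction is not None
        and last_tox_fraction >= config.phi
    ):
        allowed &= ~ordering.above[last_regimen]
    return allowed


def _top_two(
    deltas: np.ndarray,
    allowed: np.ndarray,
    pt_hat: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Candidates (two smallest scores) and 1/delta randomisation weights.

    Ties are broken by lower toxicity estimate, then lower index.  A single
    candidate gets probability one; two exactly-zero scores split 50/50 (the
    limit of the proportionality rule, via the clamp guard).
    """
    idx = np.flatnonzero(allowed)
    order = sorted(idx, key=lambda j: (deltas[j], pt_hat[j], j))
    top = np.array(order[:2], dtype=int)
    if top.size <= 1:
        return top, np.ones(top.size)
    w = 1.0 / np.maximum(deltas[top], 1e-12)
    return top, w / w.sum()


def allocation_probabilities(
    states: Sequence[RegimenState],
    config: DesignConfig,
    last_regimen: int | None = None,
    last_tox_fraction: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate regimens and randomisation probabilities for the next cohort.

    Deterministic companion of :func:`allocate_next_cohort` used for interim
    decision support; returns empty arrays when the trial should terminate.
    """
    t, n, ne, sx, sxx = _states_to_arrays(states)
    summ = _summaries(t, n, ne, sx, sxx, config)
    allowed = admissible_regimens(states, config)
    allowed = _coherence_filter(allowed, n, config, last_regimen, last_tox_fraction)
    idx = np.flatnonzero(allowed)
    if idx.size == 0:
        return np.array([], dtype=int), np.array([])
    order = sorted(idx, key=lambda j: (summ["delta"][j], summ["pt_hat"][j], j))
    top = np.array(order[:2], dtype=int)
    if top.size == 1:
        return top, np.array([1.0])
    w = 1.0 / np.maximum(summ["delta"][top], 1e-12)
    return top, w / w.sum()


def allocate_next_cohort(
    states: Sequence[RegimenState],
    config: DesignConfig,
    rng: np.random.Generator,
    last_regimen: int | None = None,
    last_tox_fraction: float | None = None,
) -> int | None:
    """Sample the regimen for the next cohort; ``None`` signals termination."""
    cand, probs = allocation_probabilities(states, config, last_regimen, last_tox_fraction)
    if cand.size == 0:
        return None
    if cand.size == 1:
        return int(cand[0])
    return int(cand[0] if rng.random() < probs[0] else cand[1])


class OutcomeOracle(Protocol):
    """Supplier of patient outcomes for a cohort at a given regimen."""

    def draw(self, regimen: int, size: int, rng: np.random.Generator):
        """Return (toxicity 0/1 array, efficacy float array) for ``size`` patients."""
        ...


def run_trial(
    outcome_oracle: OutcomeOracle,
    config: DesignConfig,
    rng: np.random.Generator,
    observation_model=None,
    collect_log: bool = False,
) -> TrialResult:
    """Run one trial of the design against an outcome oracle.

    ``rng`` is the trial's single generator: outcomes for the patients of a
    cohort are drawn first, in patient order (two standard normals per
    patient for the built-in scenario oracle), then the interim decision
    consumes one uniform per patient of the next cohort (``allocation =
    "patient"``) or a single uniform (``"cohort"``).  Fixed seed implies a
    bit-for-bit replayable decision log.
    """
    m = config.m
    delayed = bool(getattr(observation_model, "delayed", False))
    missing = bool(getattr(observation_model, "missing_on_toxicity", False))
    per_patient = config.allocation == "patient"

    t = np.zeros(m)
    n = np.zeros(m)
    ne = np.zeros(m)
    sx = np.zeros(m)
    sxx = np.zeros(m)
    unsafe = np.zeros(m, dtype=bool)
    futile = np.zeros(m, dtype=bool)

    eff_all: list[float] = []
    log: list[dict] | None = [] if collect_log else None
    tox_total = 0
    treated = 0
    terminated = False
    assignment = np.full(min(config.cohort_size, config.n_max), config.start_regimen)
    buffer: list[tuple[int, np.ndarray]] = []
    cohort_index = 0

    def incorporate(j: int, vals: np.ndarray) -> None:
        if vals.size:
            ne[j] += vals.size
            sx[j] += vals.sum()
            sxx[j] += (vals * vals).sum()

    while treated < config.n_max:
        k = min(config.cohort_size, config.n_max - treated)
        assignment = assignment[:k]
        cohort_index += 1
        treated += k
        # Draw outcomes in patient order; group consecutive same-regimen
        # patients so the generator consumption is independent of grouping.
        drawn: list[tuple[int, np.ndarray, np.ndarray]] = []
        start = 0
        for i in range(1, k + 1):
            if i == k or assignment[i] != assignment[start]:
                j = int(assignment[start])
                tox, eff = outcome_oracle.draw(j, i - start, rng)
                drawn.append((j, np.asarray(tox), np.asarray(eff, dtype=float)))
                start = i
        pending: list[tuple[int, np.ndarray]] = []
        cohort_tox: dict[int, list[int]] = {}
        for j, tox, eff in drawn:
            n[j] += tox.size
            ntox = int(tox.sum())
            t[j] += ntox
            tox_total += ntox
            eff_all.extend(eff.tolist())
            pending.append((j, eff[tox == 0] if missing else eff))
            acc = cohort_tox.setdefault(j, [0, 0])
            acc[0] += ntox
            acc[1] += tox.size
        fractions = {j: a[0] / a[1] for j, a in cohort_tox.items()}
        if delayed:
            for item in buffer:
                incorporate(*item)
            buffer = pending
        else:
            for item in pending:
                incorporate(*item)

        if treated >= config.n_max:
            break

        summ = _summaries(t, n, ne, sx, sxx, config)
        if config.constraints_enabled:
            unsafe, futile = _update_flags(unsafe, futile, summ, n, config)
        allowed = ~(unsafe | futile)
        # Coherence: no skipping of untried regimens along the ordering, and
        # no escalation above a regimen whose just-observed cohort toxicity
        # fraction reached the upper bound.
        untried = n == 0
        blocked = untried & (config.ordering.pred_matrix & untried[None, :]).any(axis=1)
        allowed &= ~blocked
        for j, frac in fractions.items():
            if frac >= config.phi:
                allowed &= ~config.ordering.above[j]
        if not allowed.any():
            terminated = True
            if collect_log:
                log.append(
                    {
                        "cohort": cohort_index,
                        "assignment": assignment.tolist(),
                        "tox_fractions": fractions,
                        "event": "terminated",
                        "unsafe": unsafe.tolist(),
                        "futile": futile.tolist(),
                    }
                )
            break
        top, probs = _top_two(summ["delta"], allowed, summ["pt_hat"])
        k_next = min(config.cohort_size, config.n_max - treated)
        if top.size == 1:
            assignment = np.full(k_next, int(top[0]))
        elif per_patient:
            u = rng.random(k_next)
            assignment = np.where(u < probs[0], top[0], top[1])
        else:
            chosen = int(top[0] if rng.random() < probs[0] else top[1])
            assignment = np.full(k_next, chosen)
        if collect_log:
            log.append(
                {
                    "cohort": cohort_index,
                    "tox_fractions": fractions,
                    "deltas": summ["delta"].tolist(),
                    "unsafe": unsafe.tolist(),
                    "futile": futile.tolist(),
                    "allowed": allowed.tolist(),
                    "candidates": top.tolist(),
                    "probabilities": probs.tolist(),
                    "next_assignment": assignment.tolist(),
                }
            )

    # Final analysis: wait for complete follow-up of every non-missing response.
    for item in buffer:
        incorporate(*item)
    summ = _summaries(t, n, ne, sx, sxx, config)
    recommendation: int | None = None
    final_ok = np.zeros(m, dtype=bool)
    if not terminated and treated > 0:
        if config.constraints_enabled:
            unsafe, futile = _update_flags(unsafe, futile, summ, n, config, final=True)
        ok = ~(unsafe | futile) & (n > 0)
        if config.constraints_enabled:
            # The recommended regimen must itself satisfy the trial's safety
            # definition on the plug-in estimate.
            ok &= summ["pt_hat"] <= config.phi
        final_ok = ok
        if ok.any():
            idx = np.flatnonzero(ok)
            recommendation = int(
                min(idx, key=lambda j: (summ["delta"][j], summ["pt_hat"][j], j))
            )
        else:
            terminated = True
    else:
        terminated = True

    return TrialResult(
        recommendation=recommendation,
        terminated=terminated,
        n_assigned=n.astype(int),
        tox_by_regimen=t.astype(int),
        tox_count=tox_total,
        eff_values=np.asarray(eff_all),
        treated=treated,
        final_deltas=summ["delta"],
        final_admissible=final_ok,
        decision_log=log,
    )
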