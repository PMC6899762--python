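"""Synthetic patients, observation models, and operating characteristics.

Outcomes are generated by the latent bivariate-normal construction (the Tate
procedure): each patient carries a standard bivariate normal pair (u, v) with
correlation of magnitude ``r``; toxicity is the indicator
``Phi(u) > 1 - p_t`` and the continuous efficacy response is
``mu + sigma * v``.  The orientation is such that positive ``r`` couples
toxicity with *lower* efficacy values (better-coded responses in the
lower-is-better tumour-marker convention): after safety screening, which
retains low-toxicity observations, more toxic regimens then show
higher-than-true (worse) observed efficacy, shifting selection toward the
beginning of the dose range as the correlation grows.

Nine built-in scenarios define per-regimen true toxicity probabilities and
efficacy means for a four-dose single agent (trials of 36 patients) and a
4 x 2 dual-agent combination (72 patients), together with each scenario's
optimal biological regimen (OBR) where one exists.  Efficacy standard
deviation is 1 throughout and the baseline outcome correlation is r = 0.2.

``simulate_oc`` replicates full trials of the design and aggregates selection
percentages, early-termination rate, average toxicity burden and average
efficacy response.  Replicate ``k`` of a run seeded with ``seed`` uses
``SeedSequence((seed, k))``, so replicates are reproducible bit-for-bit and
independent of execution order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .engine import (
    DesignConfig,
    TrialResult,
    combination_design,
    run_trial,
    single_agent_design,
)

__all__ = [
    "Scenario",
    "ObservationModel",
    "OCReport",
    "ScenarioOracle",
    "draw_patient",
    "apply_observation_model",
    "simulate_oc",
    "builtin_scenarios",
]


@dataclass(frozen=True)
class Scenario:
    """True generating parameters for one simulation scenario."""

    name: str
    p_t: tuple[float, ...]
    mu: tuple[float, ...]
    obr: int | None
    layout: str = "single"  # "single" or "combination"
    sigma: float = 1.0
    r: float = 0.2
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.layout not in ("single", "combination"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if len(self.p_t) != len(self.mu):
            raise ValueError("p_t and mu must have equal length")
        if any(not (0.0 <= p < 1.0) for p in self.p_t):
            raise ValueError("toxicity probabilities must lie in [0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (-1.0 < self.r < 1.0):
            raise ValueError("correlation r must lie strictly in (-1, 1)")

    @property
    def m(self) -> int:
        return len(self.p_t)

    def default_config(self, **overrides) -> DesignConfig:
        if self.layout == "single":
            return single_agent_design(**overrides)
        return combination_design(**overrides)


@dataclass(frozen=True)
class ObservationModel:
    """Availability of efficacy responses at interim decisions.

    ``delayed``: efficacy takes one extra decision cycle to be evaluated, so
    a cohort's efficacy responses are visible only from the second decision
    after that cohort (toxicity is visible from the first).
    ``missing_on_toxicity``: patients with a toxicity are treated off
    protocol and their efficacy response is never observed.
    """

    delayed: bool = False
    missing_on_toxicity: bool = False


@dataclass
class OCReport:
    """Aggregated operating characteristics over replicated trials."""

    scenario: str
    labels: tuple[str, ...]
    selection_pct: np.ndarray
    termination_pct: float
    avg_toxicity_pct: float
    avg_efficacy: float
    reps: int
    seed: int
    n_assigned_mean: np.ndarray

    def selection(self, j: int) -> float:
        return float(self.selection_pct[j])

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "regimen": lab,
                "selection_pct": float(s),
                "mean_patients": float(nm),
            }
            for lab, s, nm in zip(self.labels, self.selection_pct, self.n_assigned_mean)
        ]
        rows.append(
            {
                "regimen": "termination",
                "selection_pct": self.termination_pct,
                "mean_patients": float("nan"),
            }
        )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "labels": list(self.labels),
            "selection_pct": [float(x) for x in self.selection_pct],
            "termination_pct": float(self.termination_pct),
            "avg_toxicity_pct": float(self.avg_toxicity_pct),
            "avg_efficacy": float(self.avg_efficacy),
            "reps": self.reps,
            "seed": self.seed,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


class ScenarioOracle:
    """Outcome oracle drawing correlated toxicity/efficacy per patient.

    Consumes exactly two standard normals per patient from the trial
    generator regardless of the regimen assigned, so simulations driven by
    the same seed share patient-level randomness across design variants
    (common random numbers).
    """

    def __init__(self, scenario: Scenario, r: float | None = None):
        self.scenario = scenario
        self.r = scenario.r if r is None else float(r)
        if not (-1.0 < self.r < 1.0):
            raise ValueError("correlation r must lie strictly in (-1, 1)")
        with np.errstate(divide="ignore"):
            self._thresh = ndtri(1.0 - np.asarray(scenario.p_t, dtype=float))
        self._mu = np.asarray(scenario.mu, dtype=float)
        self._sigma = scenario.sigma
        self._rho_c = np.sqrt(1.0 - self.r * self.r)

    def draw(self, regimen: int, size: int, rng: np.random.Generator):
        z = rng.standard_normal((size, 2))
        u = z[:, 0]
        # Negative loading on u: positive r pairs toxicity with lower
        # (better-coded) efficacy values; see the module docstring.
        v = -self.r * u + self._rho_c * z[:, 1]
        tox = (u > self._thresh[regimen]).astype(np.int64)
        eff = self._mu[regimen] + self._sigma * v
        return tox, eff


def draw_patient(
    p_t: float,
    mu: float,
    sigma: float,
    r: float,
    rng: np.random.Generator,
) -> tuple[int, float]:
    """Draw one patient's (toxicity, efficacy) via the latent-normal coupling."""
    if not (-1.0 < r < 1.0):
        raise ValueError("correlation r must lie strictly in (-1, 1)")
    sc = Scenario("adhoc", (p_t,), (mu,), obr=None, sigma=sigma, r=r)
    tox, eff = ScenarioOracle(sc).draw(0, 1, rng)
    return int(tox[0]), float(eff[0])


def apply_observation_model(
    timeline: Sequence[tuple[int, int, int, float]],
    model: ObservationModel,
    decision_after_cohort: int,
) -> pd.DataFrame:
    """Visible-data view of a patient timeline at a given decision point.

    ``timeline`` rows are (cohort, regimen, toxicity, efficacy) with cohorts
    numbered from 1.  The decision after cohort ``c`` sees toxicity from
    cohorts <= c and efficacy from cohorts <= c (or <= c-1 when delayed),
    with toxic patients' efficacy removed permanently under the missing
    model.  Returns a frame with columns ``cohort, regimen, toxicity,
    efficacy`` where unavailable efficacy is NaN.
    """
    df = pd.DataFrame(timeline, columns=["cohort", "regimen", "toxicity", "efficacy"])
    df = df[df["cohort"] <= decision_after_cohort].copy()
    eff_horizon = decision_after_cohort - 1 if model.delayed else decision_after_cohort
    hidden = df["cohort"] > eff_horizon
    if model.missing_on_toxicity:
        hidden |= df["toxicity"] == 1
    df.loc[hidden, "efficacy"] = np.nan
    return df


def _single_scenario(name, rows, obr):
    p_t, mu = zip(*rows)
    return Scenario(
        name,
        tuple(p_t),
        tuple(mu),
        obr,
        layout="single",
        labels=tuple(f"dA{j + 1}" for j in range(4)),
    )


def _combo_scenario(name, rows_b1, rows_b2, obr):
    rows = list(rows_b1) + list(rows_b2)
    p_t, mu = zip(*rows)
    labels = tuple(f"(dA{a + 1},dB{b + 1})" for b in range(2) for a in range(4))
    return Scenario(name, tuple(p_t), tuple(mu), obr, layout="combination", labels=labels)


def builtin_scenarios() -> dict[int, Scenario]:
    """The nine built-in scenarios (single-agent 1-6, combination 7-9).

    OBR indices are 0-based into the regimen vector; scenarios 5 and 6 have
    no OBR (no efficacious respectively no safe regimen).  Combination
    regimens are indexed ``b * 4 + a`` matching the product-order layout.
    """
    s = {
        1: _single_scenario(
            "scenario 1",
            [(0.01, 0.5), (0.15, -0.5), (0.45, -1.5), (0.65, -3.0)],
            obr=1,
        ),
        2: _single_scenario(
            "scenario 2",
            [(0.05, -0.5), (0.50, -0.6), (0.60, -0.7), (0.70, -0.8)],
            obr=0,
        ),
        3: _single_scenario(
            "scenario 3",
            [(0.01, 0.5), (0.03, -0.5), (0.05, -1.5), (0.08, -3.0)],
            obr=3,
        ),
        4: _single_scenario(
            "scenario 4",
            [(0.01, 0.5), (0.10, -2.0), (0.30, -2.0), (0.60, -2.0)],
            obr=1,
        ),
        5: _single_scenario(
            "scenario 5",
            [(0.01, 2.0), (0.05, 2.0), (0.10, 2.0), (0.15, 2.0)],
            obr=None,
        ),
        6: _single_scenario(
            "scenario 6",
            [(0.50, 0.0), (0.60, -0.3), (0.70, -0.7), (0.80, -1.0)],
            obr=None,
        ),
        7: _combo_scenario(
            "scenario 7",
            [(0.01, 0.5), (0.10, 0.0), (0.40, -1.5), (0.50, -2.5)],
            [(0.05, -1.5), (0.15, -2.0), (0.45, -3.5), (0.55, -4.5)],
            obr=4 + 1,  # (dA2, dB2)
        ),
        8: _combo_scenario(
            "scenario 8",
            [(0.01, 0.0), (0.05, -0.5), (0.15, -3.5), (0.45, -5.5)],
            [(0.45, -1.0), (0.50, -1.5), (0.60, -4.5), (0.90, -6.5)],
            obr=2,  # (dA3, dB1)
        ),
        9: _combo_scenario(
            "scenario 9",
            [(0.01, 0.0), (0.15, -2.0), (0.40, -2.0), (0.50, -2.0)],
            [(0.05, 0.0), (0.20, -2.0), (0.45, -2.0), (0.55, -2.0)],
            obr=1,  # (dA2, dB1)
        ),
    }
    return s


def replicate_rng(seed: int, k: int) -> np.random.Generator:
    """The generator replicate ``k`` of a run seeded with ``seed`` uses."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, k))))


def simulate_oc(
    scenario: Scenario,
    config: DesignConfig,
    model: ObservationModel | None = None,
    reps: int = 1000,
    seed: int = 0,
    r: float | None = None,
    collect_results: bool = False,
) -> OCReport | tuple[OCReport, list[TrialResult]]:
    """Replicate trials and aggregate operating characteristics.

    The average toxicity percentage is total toxicities over total treated
    patients; the average efficacy response averages every efficacy value
    generated for a treated patient, including values hidden from the
    estimators by the observation model, so the burden metrics stay
    comparable across observation models.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if scenario.m != config.m:
        raise ValueError(
            f"scenario has {scenario.m} regimens but design has {config.m}"
        )
    model = model or ObservationModel()
    oracle = ScenarioOracle(scenario, r=r)
    sel = np.zeros(config.m, dtype=np.int64)
    term = 0
    tox_total = 0
    treated_total = 0
    eff_sum = 0.0
    eff_n = 0
    n_assigned_sum = np.zeros(config.m, dtype=np.int64)
    results: list[TrialResult] = []
    for k in range(reps):
        res = run_trial(oracle, config, replicate_rng(seed, k), observation_model=model)
        if res.recommendation is None:
            term += 1
        else:
            sel[res.recommendation] += 1
        tox_total += res.tox_count
        treated_total += res.treated
        eff_sum += float(res.eff_values.sum())
        eff_n += res.eff_values.size
        n_assigned_sum += res.n_assigned
        if collect_results:
            results.append(res)
    report = OCReport(
        scenario=scenario.name,
        labels=scenario.labels or config.labels,
        selection_pct=100.0 * sel / reps,
        termination_pct=100.0 * term / reps,
        avg_toxicity_pct=100.0 * tox_total / max(treated_total, 1),
        avg_efficacy=eff_sum / max(eff_n, 1),
        reps=reps,
        seed=seed,
        n_assigned_mean=n_assigned_sum / reps,
    )
    if collect_results:
        return report, results
    return report
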