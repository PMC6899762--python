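"""Grid-search calibration of the prior toxicity/efficacy means.

The prior means act like a CRM skeleton: before any data, the plug-in
trade-off scores are determined entirely by the prior toxicity means
``p_j = start_tox + (j-1) * step_tox`` and prior efficacy means
``mu_j = start_eff + (j-1) * step_eff``.  Candidates that do not preserve the
clinician's initial regimen ordering (prior scores strictly increasing with
the regimen index) are excluded.  Each admissible candidate is scored by the
geometric mean of the correct-selection proportions under two pivot
scenarios with opposite OBR locations (first vs last regimen), simulated with
the safety/futility constraints disabled.  Common random numbers across
candidates keep the ranking stable at modest replicate counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import DesignConfig
from .simulate import Scenario, simulate_oc

__all__ = [
    "PriorCandidate",
    "preserves_ordering",
    "calibrate",
    "CalibrationResult",
    "full_grid",
    "step_grid",
]


@dataclass(frozen=True)
class PriorCandidate:
    """Linear prior-mean generator for an m-regimen design."""

    start_tox: float
    step_tox: float
    start_eff: float
    step_eff: float

    def toxicity_means(self, m: int) -> tuple[float, ...]:
        return tuple(self.start_tox + j * self.step_tox for j in range(m))

    def efficacy_means(self, m: int) -> tuple[float, ...]:
        return tuple(self.start_eff + j * self.step_eff for j in range(m))

    def is_valid(self, m: int, beta_strength: Sequence[float]) -> bool:
        """Generated toxicity means must be proper prior means in (0, 1)."""
        return all(
            0.0 < p < 1.0 and p < b
            for p, b in zip(self.toxicity_means(m), beta_strength)
        )

    def apply(self, config: DesignConfig) -> DesignConfig:
        """Design config with this candidate's prior means installed."""
        return replace(
            config,
            nu=self.toxicity_means(config.m),
            mu0=self.efficacy_means(config.m),
        )


def _prior_deltas(candidate: PriorCandidate, config: DesignConfig) -> np.ndarray:
    from .engine import plug_in_delta

    cfg = candidate.apply(config)
    return np.array([plug_in_delta(s, cfg) for s in cfg.prior_states()])


def preserves_ordering(candidate: PriorCandidate, config: DesignConfig) -> bool:
    """True iff the prior plug-in scores are strictly increasing in the index.

    This is the "initial ordering" admissibility filter: with no data the
    design must rank regimen 1 ahead of 2 ahead of 3 ... under the
    configured transformation and target.
    """
    if not candidate.is_valid(config.m, config.beta_strength):
        return False
    d = _prior_deltas(candidate, config)
    return bool(np.all(np.diff(d) > 0))


def full_grid() -> list[PriorCandidate]:
    """The 600-candidate calibration grid over starts and steps."""
    start_tox = (0.05, 0.10, 0.15)
    start_eff = (-0.80, -0.90, -1.00, -1.10, -1.20)
    step_tox = tuple(round(0.03 + 0.01 * i, 2) for i in range(8))  # 0.03..0.10
    step_eff = (-0.01, -0.025, -0.05, -0.075, -0.1)
    return [
        PriorCandidate(st, dt, se, de)
        for st, dt, se, de in product(start_tox, step_tox, start_eff, step_eff)
    ]


def step_grid(
    start_tox: float = 0.10,
    start_eff: float = -1.00,
) -> list[PriorCandidate]:
    """Step-only sweep at fixed starts: 15 x 15 toxicity/efficacy steps."""
    step_tox = tuple(round(0.01 * i, 2) for i in range(1, 16))  # 0.01..0.15
    step_eff = tuple(round(-0.005 - 0.01 * i, 3) for i in range(15))  # -0.005..-0.145
    return [
        PriorCandidate(start_tox, dt, start_eff, de)
        for dt, de in product(step_tox, step_eff)
    ]


@dataclass
class CalibrationResult:
    """Ranked calibration table plus the near-optimal candidate set."""

    table: pd.DataFrame
    band: float

    @property
    def best(self) -> PriorCandidate:
        r = self.table.iloc[0]
        return PriorCandidate(r.start_tox, r.step_tox, r.start_eff, r.step_eff)

    @property
    def near_optimal(self) -> pd.DataFrame:
        cutoff = self.table["score"].max() * (1.0 - self.band)
        return self.table[self.table["score"] >= cutoff]

    def in_band(self, candidate: PriorCandidate) -> bool:
        sub = self.near_optimal
        hit = (
            (sub["start_tox"] == candidate.start_tox)
            & (sub["step_tox"] == candidate.step_tox)
            & (sub["start_eff"] == candidate.start_eff)
            & (sub["step_eff"] == candidate.step_eff)
        )
        return bool(hit.any())


def calibrate(
    grid: Sequence[PriorCandidate],
    pivot_scenarios: Sequence[Scenario],
    reps: int,
    seed: int,
    config: DesignConfig,
    band: float = 0.015,
    disable_constraints: bool = True,
) -> CalibrationResult:
    """Score a candidate grid by geometric-mean correct selection.

    Every pivot scenario must declare an OBR.  All candidates are simulated
    with the same replicate seeds (common random numbers).  Candidates
    failing the ordering filter are dropped before simulation; an empty
    admissible grid is an error.
    """
    for sc in pivot_scenarios:
        if sc.obr is None:
            raise ValueError(f"pivot scenario {sc.name!r} declares no OBR")
    base = replace(config, constraints_enabled=not disable_constraints)
    admissible = [c for c in grid if preserves_ordering(c, base)]
    if not admissible:
        raise ValueError("no candidate on the grid preserves the initial ordering")
    rows = []
    for cand in admissible:
        cfg = cand.apply(base)
        props = []
        for sc in pivot_scenarios:
            rep = simulate_oc(sc, cfg, reps=reps, seed=seed)
            props.append(rep.selection(sc.obr) / 100.0)
        score = float(np.exp(np.mean(np.log(np.maximum(props, 1e-300)))))
        row = {
            "start_tox": cand.start_tox,
            "step_tox": cand.step_tox,
            "start_eff": cand.start_eff,
            "step_eff": cand.step_eff,
            "score": score,
        }
        for sc, p in zip(pivot_scenarios, props):
            row[f"prop[{sc.name}]"] = p
        rows.append(row)
    table = (
        pd.DataFrame(rows)
        .sort_values("score", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return CalibrationResult(table=table, band=band)
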