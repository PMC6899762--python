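"""Interim decision support as a fitted-model interface.

`WETrialModel` is built from accumulated patient records (a DataFrame with
one row per patient: regimen, binary toxicity, real-valued or missing
efficacy) together with a design configuration.  ``fit()`` performs the
conjugate Bayesian update for every regimen and returns a
:class:`WETrialResults` carrying the posterior estimates and their
uncertainties, the plug-in trade-off scores, the admissibility diagnostics
and the randomisation probabilities for the next cohort, with a
``summary()`` table in the spirit of statsmodels results objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import (
    DesignConfig,
    RegimenState,
    _coherence_filter,
    _states_to_arrays,
    _summaries,
    _update_flags,
    eta_schedule,
)

__all__ = ["WETrialModel", "WETrialResults"]

REQUIRED_COLUMNS = ("regimen", "toxicity")


class WETrialModel:
    """Per-regimen conjugate Bayesian model of an ongoing trial.

    Parameters
    ----------
    records : pandas.DataFrame or None
        One row per patient with columns ``regimen`` (1-based index),
        ``toxicity`` (0/1) and ``efficacy`` (float; NaN/NA when the response
        is missing or not yet available).  ``None`` fits the prior state.
    config : DesignConfig
        The design's tuning constants, including per-regimen priors.
    """

    def __init__(self, records: pd.DataFrame | None, config: DesignConfig):
        self.config = config
        if records is None:
            records = pd.DataFrame(
                {"regimen": pd.Series(dtype=int), "toxicity": pd.Series(dtype=int),
                 "efficacy": pd.Series(dtype=float)}
            )
        for col in REQUIRED_COLUMNS:
            if col not in records.columns:
                raise ValueError(f"records must have a {col!r} column")
        if "efficacy" not in records.columns:
            records = records.assign(efficacy=np.nan)
        reg = records["regimen"].to_numpy()
        if len(reg) and (reg.min() < 1 or reg.max() > config.m):
            raise ValueError(
                f"regimen indices must lie in 1..{config.m} (1-based), "
                f"got range {reg.min()}..{reg.max()}"
            )
        tox = records["toxicity"].to_numpy()
        if len(tox) and not np.isin(tox, (0, 1)).all():
            raise ValueError("toxicity must be coded 0/1")
        self.records = records

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame, config: DesignConfig) -> "WETrialModel":
        return cls(records, config)

    @classmethod
    def from_csv(cls, path, config: DesignConfig) -> "WETrialModel":
        return cls(pd.read_csv(path), config)

    def regimen_states(self) -> list[RegimenState]:
        states = []
        for j, prior in enumerate(self.config.prior_states()):
            sub = self.records[self.records["regimen"] == j + 1]
            tox = prior.tox.update(int(sub["toxicity"].sum()), len(sub))
            eff_vals = sub["efficacy"].dropna().to_numpy(dtype=float)
            eff = prior.eff.update(eff_vals)
            states.append(RegimenState(tox=tox, eff=eff))
        return states

    def fit(self) -> "WETrialResults":
        states = self.regimen_states()
        t, n, ne, sx, sxx = _states_to_arrays(states)
        summ = _summaries(t, n, ne, sx, sxx, self.config)
        unsafe = np.zeros(self.config.m, dtype=bool)
        futile = np.zeros(self.config.m, dtype=bool)
        if self.config.constraints_enabled:
            unsafe, futile = _update_flags(unsafe, futile, summ, n, self.config)
        allowed = ~(unsafe | futile)
        allowed = _coherence_filter(allowed, n, self.config, None, None)
        idx = np.flatnonzero(allowed)
        order = sorted(idx, key=lambda j: (summ["delta"][j], summ["pt_hat"][j], j))
        top = np.array(order[:2], dtype=int)
        if top.size == 0:
            probs = np.array([])
        elif top.size == 1:
            probs = np.array([1.0])
        else:
            w = 1.0 / np.maximum(summ["delta"][top], 1e-12)
            probs = w / w.sum()
        return WETrialResults(
            model=self,
            n_assigned=n.astype(int),
            n_efficacy=ne.astype(int),
            toxicity_mean=summ["pt_hat"],
            efficacy_mean=summ["mu_hat"],
            efficacy_sd=np.sqrt(summ["mu_var"]),
            efficacy_prob=summ["pe_hat"],
            delta=summ["delta"],
            safety_tail=summ["safety_tail"],
            futility_prob=summ["futility_prob"],
            unsafe=unsafe,
            futile=futile,
            candidates=top,
            allocation_probs=probs,
        )


@dataclass
class WETrialResults:
    """Posterior estimates, diagnostics and the next-cohort allocation."""

    model: WETrialModel
    n_assigned: np.ndarray
    n_efficacy: np.ndarray
    toxicity_mean: np.ndarray
    efficacy_mean: np.ndarray
    efficacy_sd: np.ndarray
    efficacy_prob: np.ndarray
    delta: np.ndarray
    safety_tail: np.ndarray
    futility_prob: np.ndarray
    unsafe: np.ndarray
    futile: np.ndarray
    candidates: np.ndarray
    allocation_probs: np.ndarray

    @property
    def config(self) -> DesignConfig:
        return self.model.config

    @property
    def admissible(self) -> np.ndarray:
        return ~(self.unsafe | self.futile)

    @property
    def recommendation(self) -> int | None:
        """Regimen the design would recommend if the trial stopped now.

        Applies the end-of-trial controlling probabilities to tried regimens;
        ``None`` means termination (no admissible tried regimen).
        """
        cfg = self.config
        ok = (self.n_assigned > 0)
        if cfg.constraints_enabled:
            ok &= self.safety_tail < cfg.eta1_bar
            ok &= self.futility_prob < cfg.eta2_bar
            ok &= self.toxicity_mean <= cfg.phi
            ok &= self.admissible
        idx = np.flatnonzero(ok)
        if idx.size == 0:
            return None
        return int(min(idx, key=lambda j: (self.delta[j], self.toxicity_mean[j], j)))

    def to_frame(self) -> pd.DataFrame:
        cfg = self.config
        return pd.DataFrame(
            {
                "regimen": cfg.labels,
                "n": self.n_assigned,
                "n_eff": self.n_efficacy,
                "p_tox": self.toxicity_mean,
                "mu_eff": self.efficacy_mean,
                "sd(mu)": self.efficacy_sd,
                "T(mu)": self.efficacy_prob,
                "delta": self.delta,
                "P(tox>phi)": self.safety_tail,
                "eta1(n)": eta_schedule(self.n_assigned, cfg.eta1_0, cfg.r_t, cfg.eta1_bar),
                "P(futile)": self.futility_prob,
                "eta2(n)": eta_schedule(self.n_assigned, cfg.eta2_0, cfg.r_e, cfg.eta2_bar),
                "unsafe": self.unsafe,
                "futile": self.futile,
            }
        )

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "WE dose-finding interim analysis",
            "=" * 80,
            f"regimens: {cfg.m}   patients: {int(self.n_assigned.sum())}/{cfg.n_max}"
            f"   cohort size: {cfg.cohort_size}",
            f"targets: gamma_t={cfg.target.gamma_t}, gamma_e={cfg.target.gamma_e}"
            f"   phi={cfg.phi}, psi*={cfg.psi_star}",
            "",
            self.to_frame().to_string(
                index=False, float_format=lambda x: f"{x: .4f}"
            ),
            "",
        ]
        if self.candidates.size:
            alloc = ", ".join(
                f"{cfg.labels[j]}: {p:.3f}"
                for j, p in zip(self.candidates, self.allocation_probs)
            )
            lines.append(f"next-cohort randomisation -> {alloc}")
        else:
            lines.append("no admissible regimen: the trial should terminate")
        rec = self.recommendation
        lines.append(
            "recommendation if stopped now: "
            + (cfg.labels[rec] if rec is not None else "terminate without recommendation")
        )
        return "\n".join(lines)

    def simulate_forward(self, scenario, reps: int = 1000, seed: int = 0, **kwargs):
        """Operating characteristics of continuing this design from scratch.

        Convenience hook into :func:`wedesign.simulate.simulate_oc` with this
        results object's configuration.
        """
        from .simulate import simulate_oc

        return simulate_oc(scenario, self.config, reps=reps, seed=seed, **kwargs)
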