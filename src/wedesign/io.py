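"""Configuration files, run manifests, and report serialisation.

A run is described by one YAML or JSON document with a ``design`` block (all
tuning constants of the dose-finding design), an optional ``scenario`` (a
built-in scenario number or explicit true parameters), an ``observation``
block and the stochastic run parameters (``seed``, ``reps``,
``correlation``).  Missing design fields fall back to the reference-trial
specification (single-agent: four doses, 36 patients, calibrated prior
means, logistic transform anchored at psi=0 / psi'=-4.5).

Every stochastic output carries a :class:`RunManifest` whose digest is a
SHA-256 hash of the canonical design-relevant dictionary: identical manifests
imply identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import yaml

from .criterion import TargetProfile
from .engine import DesignConfig, combination_design, single_agent_design
from .simulate import ObservationModel, Scenario, builtin_scenarios
from .transform import TransformSpec

__all__ = ["RunSpec", "RunManifest", "load_config", "save_config", "config_to_dict"]


@dataclass
class RunSpec:
    """A fully resolved run: design + scenario + observation model + seeds."""

    design: DesignConfig
    scenario: Scenario | None
    observation: ObservationModel
    seed: int | None
    reps: int
    correlation: float | None


@dataclass
class RunManifest:
    """Provenance record attached to stochastic outputs."""

    digest: str
    seed: int | None
    reps: int
    package: str
    created: str

    @classmethod
    def build(cls, spec: RunSpec) -> "RunManifest":
        from . import __version__

        payload = {
            "design": config_to_dict(spec.design),
            "scenario": None if spec.scenario is None else _scenario_to_dict(spec.scenario),
            "observation": asdict(spec.observation),
            "correlation": spec.correlation,
        }
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()
        return cls(
            digest=digest,
            seed=spec.seed,
            reps=spec.reps,
            package=f"wedesign {__version__}",
            created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def to_dict(self) -> dict:
        return asdict(self)


class ConfigError(ValueError):
    """Schema violation in a configuration document."""


def _require(cond: bool, fieldname: str, message: str) -> None:
    if not cond:
        raise ConfigError(f"config field {fieldname!r}: {message}")


def config_to_dict(config: DesignConfig) -> dict[str, Any]:
    t = config.transform
    return {
        "layout": "combination" if config.m == 8 else "single",
        "m": config.m,
        "n_max": config.n_max,
        "cohort_size": config.cohort_size,
        "phi": config.phi,
        "psi_star": config.psi_star,
        "gamma_t": config.target.gamma_t,
        "gamma_e": config.target.gamma_e,
        "transform": {
            "family": t.family,
            "alpha": t.alpha,
            "beta": t.beta,
            "psi": t.psi,
            "psi_prime": t.psi_prime,
            "p_low": t.p_low,
            "p_high": t.p_high,
        },
        "prior_tox": list(config.nu),
        "prior_eff": list(config.mu0),
        "beta_strength": list(config.beta_strength),
        "lam": list(config.lam),
        "zeta": list(config.zeta),
        "zeta_prime": list(config.zeta_prime),
        "r_t": config.r_t,
        "r_e": config.r_e,
        "eta1_0": config.eta1_0,
        "eta2_0": config.eta2_0,
        "eta1_bar": config.eta1_bar,
        "eta2_bar": config.eta2_bar,
        "start_regimen": config.start_regimen,
        "lower_is_better": config.lower_is_better,
        "constraints_enabled": config.constraints_enabled,
    }


def _scenario_to_dict(sc: Scenario) -> dict[str, Any]:
    return {
        "name": sc.name,
        "layout": sc.layout,
        "p_t": list(sc.p_t),
        "mu": list(sc.mu),
        "sigma": sc.sigma,
        "r": sc.r,
        "obr": sc.obr,
        "labels": list(sc.labels),
    }


def _design_from_dict(d: dict[str, Any]) -> DesignConfig:
    layout = d.get("layout", "single")
    _require(layout in ("single", "combination"), "design.layout",
             f"must be 'single' or 'combination', got {layout!r}")
    factory = single_agent_design if layout == "single" else combination_design

    overrides: dict[str, Any] = {}
    if "gamma_t" in d or "gamma_e" in d:
        gt = d.get("gamma_t", 0.01)
        ge = d.get("gamma_e", 0.99)
        _require(0.0 < gt < 1.0, "design.gamma_t", f"must lie strictly in (0, 1), got {gt}")
        _require(0.0 < ge < 1.0, "design.gamma_e", f"must lie strictly in (0, 1), got {ge}")
        overrides["target"] = TargetProfile(gt, ge)
    tdict = d.get("transform")
    if tdict is not None:
        if "alpha" in tdict and "beta" in tdict:
            overrides["transform"] = TransformSpec(
                family=tdict.get("family", "logistic"),
                alpha=tdict["alpha"],
                beta=tdict["beta"],
                psi=tdict.get("psi", 0.0),
                psi_prime=tdict.get("psi_prime", -4.5),
                p_low=tdict.get("p_low", 0.01),
                p_high=tdict.get("p_high", 0.9),
            )
        else:
            overrides["transform"] = TransformSpec.from_anchors(
                psi=tdict.get("psi", 0.0),
                psi_prime=tdict.get("psi_prime", -4.5),
                p_low=tdict.get("p_low", 0.01),
                p_high=tdict.get("p_high", 0.9),
                family=tdict.get("family", "logistic"),
                solve_per_family=tdict.get("solve_per_family", False),
            )
    scalar_fields = (
        "n_max", "cohort_size", "phi", "psi_star", "r_t", "r_e",
        "eta1_0", "eta2_0", "eta1_bar", "eta2_bar", "start_regimen",
        "lower_is_better", "constraints_enabled",
    )
    for name in scalar_fields:
        if name in d:
            overrides[name] = d[name]
    kwargs: dict[str, Any] = {}
    if "prior_tox" in d:
        kwargs["prior_tox"] = tuple(d["prior_tox"])
    if "prior_eff" in d:
        kwargs["prior_eff"] = tuple(d["prior_eff"])
    for name, target in (
        ("beta_strength", "beta_strength"),
        ("lam", "lam"),
        ("zeta", "zeta"),
        ("zeta_prime", "zeta_prime"),
    ):
        if name in d:
            v = d[name]
            overrides[target] = tuple(v) if isinstance(v, (list, tuple)) else ()
            if not isinstance(v, (list, tuple)):
                # scalar broadcast: postpone until m is known via factory default
                overrides[target] = ()
                kwargs.setdefault("_scalar_" + name, v)
    try:
        scalars = {k[8:]: kwargs.pop(k) for k in list(kwargs) if k.startswith("_scalar_")}
        cfg = factory(**kwargs, **overrides)
        if scalars:
            from dataclasses import replace

            cfg = replace(cfg, **{k: (v,) * cfg.m for k, v in scalars.items()})
        return cfg
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid design block: {exc}") from exc


def _scenario_from(d: Any) -> Scenario | None:
    if d is None:
        return None
    if isinstance(d, int):
        cat = builtin_scenarios()
        _require(d in cat, "scenario", f"unknown built-in scenario id {d}")
        return cat[d]
    _require(isinstance(d, dict), "scenario", "must be an id or a mapping")
    for fieldname in ("p_t", "mu"):
        _require(fieldname in d, f"scenario.{fieldname}", "is required")
    try:
        return Scenario(
            name=d.get("name", "custom"),
            p_t=tuple(d["p_t"]),
            mu=tuple(d["mu"]),
            obr=d.get("obr"),
            layout=d.get("layout", "single"),
            sigma=d.get("sigma", 1.0),
            r=d.get("r", 0.2),
            labels=tuple(d.get("labels", ())),
        )
    except ValueError as exc:
        raise ConfigError(f"invalid scenario block: {exc}") from exc


def load_config(path: str | Path) -> RunSpec:
    """Parse and validate a YAML/JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    _require(isinstance(doc, dict), "<root>", "document must be a mapping")
    design = _design_from_dict(doc.get("design", {}))
    scenario = _scenario_from(doc.get("scenario"))
    if scenario is not None:
        _require(
            scenario.m == design.m,
            "scenario",
            f"has {scenario.m} regimens but the design has {design.m}",
        )
    obs = doc.get("observation", {}) or {}
    observation = ObservationModel(
        delayed=bool(obs.get("delayed", False)),
        missing_on_toxicity=bool(obs.get("missing_on_toxicity", False)),
    )
    reps = int(doc.get("reps", 1000))
    _require(reps >= 1, "reps", "must be >= 1")
    seed = doc.get("seed")
    if seed is not None:
        seed = int(seed)
    corr = doc.get("correlation")
    if corr is not None:
        corr = float(corr)
        _require(-1.0 < corr < 1.0, "correlation", "must lie strictly in (-1, 1)")
    return RunSpec(design, scenario, observation, seed, reps, corr)


def save_config(spec: RunSpec, path: str | Path) -> None:
    """Write a RunSpec back to YAML/JSON; load(save(x)) is an identity."""
    path = Path(path)
    doc: dict[str, Any] = {
        "design": config_to_dict(spec.design),
        "scenario": None if spec.scenario is None else _scenario_to_dict(spec.scenario),
        "observation": asdict(spec.observation),
        "reps": spec.reps,
        "seed": spec.seed,
        "correlation": spec.correlation,
    }
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2))
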