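"""Scenario configuration, validation and deterministic scenario runs.

A scenario file (YAML, or JSON — YAML is a superset) describes one cascade
simulation: growth law, engine, circulation, grid, horizon, evaluation times.
``run_scenario`` executes it and writes the trajectory, the per-order
colonization intensities, the colony registry and a JSON summary; all
randomness (none in the expected-value cascade itself, but used by optional
course sampling) flows from the single configured seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .calibration import calibrate_m_to_iks
from .cascade import (
    CirculationParams,
    GrowthVariant,
    full_cascade,
    mass_parity_time,
)
from .growth import (
    GenerationConfig,
    GompertzParams,
    fit_gdr_decrement,
    gdr_trajectory,
    generation_time,
    initial_doubling_time,
    ms_trajectory,
)

__all__ = ["ConfigError", "RunConfig", "load_config", "run_scenario"]


class ConfigError(ValueError):
    """Invalid scenario configuration; ``fields`` lists the offending entries."""

    def __init__(self, fields: dict):
        self.fields = fields
        msgs = "; ".join(f"{k}: {v}" for k, v in fields.items())
        super().__init__(f"invalid configuration — {msgs}")


@dataclass
class RunConfig:
    scenario: str = "hepatocellular"
    engine: str = "MS"
    b: float = 7.3e10
    mu: float = 0.00286
    d_i: float = 2.0 / 3.0
    m: float | None = None  # None: calibrate against the colony-size reference
    alpha_d: float = 1.0
    epsilon: float | None = None  # None: fit so the GDR asymptote equals b
    d_f: float = 0.5
    T_env: float = 1.0
    c_frac: float = 1e-4
    grid_dt: float = 1.0
    horizon: float = 2200.0
    max_order: int = 1
    growth_variant: str = "primary_like"
    visibility_threshold: float = 4.6e7
    excision_time: float | None = None
    eval_times: list = field(default_factory=lambda: [1110.0])
    iks_gamma: float = 5.3e-8
    iks_alpha: float = 0.663
    seed: int = 1

    def validate(self) -> None:
        bad = {}
        if self.engine not in ("MS", "GDR"):
            bad["engine"] = f"must be MS or GDR, got {self.engine!r}"
        if not self.b > 1:
            bad["b"] = "must exceed 1 cell"
        if not self.mu > 0:
            bad["mu"] = "must be positive"
        if not 0.5 < self.d_i <= 1.0:
            bad["d_i"] = "must lie in (1/2, 1]"
        if self.alpha_d not in (1.0, 2.0 / 3.0, 1.0 / 3.0):
            bad["alpha_d"] = "must be 1, 2/3 or 1/3"
        if self.m is not None and self.m < 0:
            bad["m"] = "must be non-negative"
        if not self.T_env > 0:
            bad["T_env"] = "must be positive"
        if not 0 <= self.c_frac <= 1:
            bad["c_frac"] = "must lie in [0, 1]"
        if not self.grid_dt > 0:
            bad["grid_dt"] = "must be positive"
        if not self.horizon > 0:
            bad["horizon"] = "must be positive"
        if self.max_order < 1:
            bad["max_order"] = "must be at least 1"
        if self.growth_variant not in (
            "primary_like",
            "gdr_inherited_d",
            "ms_inherited_TG",
        ):
            bad["growth_variant"] = f"unknown variant {self.growth_variant!r}"
        if self.visibility_threshold < 1:
            bad["visibility_threshold"] = "must be at least one cell"
        if not isinstance(self.seed, int):
            bad["seed"] = "must be an integer"
        if bad:
            raise ConfigError(bad)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON scenario file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError({"<root>": "scenario file must contain a mapping"})
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError({k: "unknown field" for k in sorted(unknown)})
    # YAML 1.1 reads scientific notation without a sign ("7.3e10") as a string
    float_fields = {
        "b", "mu", "d_i", "m", "alpha_d", "epsilon", "d_f", "T_env", "c_frac",
        "grid_dt", "horizon", "visibility_threshold", "excision_time",
        "iks_gamma", "iks_alpha",
    }
    bad = {}
    for key, val in list(raw.items()):
        if key in float_fields and val is not None:
            try:
                raw[key] = float(val)
            except (TypeError, ValueError):
                bad[key] = f"not a number: {val!r}"
        elif key == "eval_times":
            try:
                raw[key] = [float(v) for v in val]
            except (TypeError, ValueError):
                bad[key] = f"not a list of numbers: {val!r}"
    if bad:
        raise ConfigError(bad)
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def run_scenario(cfg: RunConfig, outdir) -> dict:
    """Execute a scenario and write its result files.

    Writes ``trajectory.csv``, ``intensity.csv`` (all orders),
    ``registry.csv`` and ``summary.json`` under ``outdir``; returns the
    summary dict.  Outputs are deterministic given the configuration.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = GompertzParams(b=cfg.b, mu=cfg.mu)
    T_G0 = generation_time(initial_doubling_time(p), cfg.d_i)
    epsilon = cfg.epsilon
    if cfg.engine == "GDR" and epsilon is None:
        epsilon = fit_gdr_decrement(p, d_i=cfg.d_i, d_f=cfg.d_f)
    m = cfg.m
    calibrated = False
    if m is None:
        from .iks import IksParams

        cal = calibrate_m_to_iks(
            cfg.engine,
            p=p,
            circ=CirculationParams(cfg.T_env, cfg.c_frac),
            iks=IksParams(cfg.iks_gamma, cfg.iks_alpha),
            x_min=cfg.visibility_threshold,
            horizon=cfg.horizon,
            grid_dt=cfg.grid_dt,
        )
        m = cal["m"]
        calibrated = True
    gen_cfg = GenerationConfig(
        engine=cfg.engine,
        T_G0=T_G0,
        d_i=cfg.d_i,
        m=m,
        alpha_d=cfg.alpha_d,
        epsilon=epsilon or 0.0,
        d_f=cfg.d_f,
    )
    traj = (ms_trajectory if cfg.engine == "MS" else gdr_trajectory)(
        p, gen_cfg, cfg.horizon
    )
    circ = CirculationParams(cfg.T_env, cfg.c_frac)
    intensities, registries = full_cascade(
        traj,
        circ,
        GrowthVariant(cfg.growth_variant),
        grid_dt=cfg.grid_dt,
        max_order=cfg.max_order,
        excision_time=cfg.excision_time,
    )
    traj.to_csv(outdir / "trajectory.csv")
    import pandas as pd

    pd.concat([i.to_frame() for i in intensities]).to_csv(
        outdir / "intensity.csv", index=False
    )
    pd.concat([r.to_frame() for r in registries]).to_csv(
        outdir / "registry.csv", index=False
    )
    parity = mass_parity_time(registries[0], traj, grid_dt=cfg.grid_dt)
    summary = {
        "scenario": cfg.scenario,
        "engine": cfg.engine,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "m": float(m),
        "m_calibrated": calibrated,
        "epsilon": float(epsilon) if epsilon is not None else None,
        "T_G0_days": float(T_G0),
        "total_colonizers_per_order": [float(i.total()) for i in intensities],
        "mass_parity_day": parity,
        "visible_counts": {
            str(t): {
                f"order_{r.order}": float(
                    r.visible_count(float(t), cfg.visibility_threshold)
                )
                for r in registries
            }
            for t in cfg.eval_times
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
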