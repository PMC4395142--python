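"""YAML configuration covering arm parameters, gains, oscillation and plan.

All matrices are row-major nested lists; the virtual damper may be given
as a 2-vector (its diagonal).  Every key is optional — omitted sections
fall back to the package defaults, so an empty file is a valid config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .fixtures import MarkerNoiseSpec
from .params import ArmParameters, ArmState, GainSet
from .simulate import OscillationSpec, SimulationPlan

__all__ = ["Config", "load_config", "default_config"]


@dataclass(frozen=True)
class Config:
    arm: ArmParameters = field(default_factory=ArmParameters.default)
    gains: GainSet = field(default_factory=GainSet)
    oscillation: OscillationSpec = field(default_factory=OscillationSpec)
    plan: SimulationPlan = field(default_factory=SimulationPlan)
    noise: MarkerNoiseSpec = field(default_factory=MarkerNoiseSpec)


def default_config() -> Config:
    return Config()


def _arm_from(d: dict) -> ArmParameters:
    base = ArmParameters.default()
    return ArmParameters(
        mass=d.get("mass", base.mass),
        length=d.get("length", base.length),
        com_offset=d.get("com_offset", base.com_offset),
        inertia=d.get("inertia", base.inertia),
        gravity=float(d.get("gravity", base.gravity)),
    )


def _gains_from(d: dict) -> GainSet:
    base = GainSet()
    posture = d.get("desired_posture_deg")
    if posture is not None:
        posture = np.deg2rad(np.asarray(posture, dtype=float))
    else:
        posture = d.get("desired_posture", base.desired_posture)
    return GainSet(
        stiffness=d.get("stiffness", base.stiffness),
        viscosity=d.get("viscosity", base.viscosity),
        virtual_damper=d.get("virtual_damper", base.virtual_damper),
        desired_posture=posture,
    )


def load_config(path: str | Path) -> Config:
    """Load a config file; missing sections use package defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = default_config()
    arm = _arm_from(raw.get("arm", {}))
    gains = _gains_from(raw.get("gains", {}))
    osc = raw.get("oscillation", {})
    oscillation = OscillationSpec(
        amplitude=float(osc.get("amplitude", cfg.oscillation.amplitude)),
        frequency=float(osc.get("frequency", cfg.oscillation.frequency)),
        phase=float(osc.get("phase", cfg.oscillation.phase)),
    )
    pl = raw.get("plan", {})
    initial = pl.get("initial_state")
    initial_state = (
        ArmState(
            angles=initial["angles"],
            angular_velocities=initial.get("angular_velocities", [0.0, 0.0, 0.0]),
        )
        if initial
        else None
    )
    plan = SimulationPlan(
        dt=float(pl.get("dt", cfg.plan.dt)),
        duration=float(pl.get("duration", cfg.plan.duration)),
        steady_window=tuple(pl.get("steady_window", cfg.plan.steady_window)),
        initial_state=initial_state,
        controller=pl.get("controller", cfg.plan.controller),
    )
    nz = raw.get("noise", {})
    noise = MarkerNoiseSpec(
        noise_sd=float(nz.get("noise_sd", cfg.noise.noise_sd)),
        seed=int(nz.get("seed", cfg.noise.seed)),
        rate=float(nz.get("rate", cfg.noise.rate)),
        duration=float(nz.get("duration", cfg.noise.duration)),
    )
    return Config(arm=arm, gains=gains, oscillation=oscillation, plan=plan, noise=noise)
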