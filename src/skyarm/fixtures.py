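"""Synthetic marker-trajectory generator.

Emulates an optical motion-capture recording of the oscillation task:
the simulator produces the true part trajectories and independent
Gaussian noise is added to every marker coordinate (the short-range
error model of marker-based systems; 0.5 mm standard deviation by
default).  Soft-tissue artefact, marker dropout and between-subject
variability are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ArmParameters, GainSet
from .simulate import PARTS, OscillationSpec, SimulationPlan, TrajectoryRecord, simulate

__all__ = ["MarkerNoiseSpec", "generate_markers"]


@dataclass(frozen=True)
class MarkerNoiseSpec:
    """Noise and recording parameters for synthetic marker data."""

    noise_sd: float = 5e-4  # m
    seed: int = 0
    rate: float = 100.0  # Hz
    duration: float = 120.0  # s

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


def generate_markers(
    params: ArmParameters,
    gains: GainSet,
    spec: OscillationSpec,
    plan: SimulationPlan | None,
    noise: MarkerNoiseSpec,
) -> pd.DataFrame:
    """Simulate the task and return a noisy marker table.

    Columns: ``time`` plus ``<part>_x`` / ``<part>_y`` for shoulder,
    elbow, wrist and hand — the same schema as the simulator's output
    table, so the analysis pipeline applies unchanged.  Deterministic
    for a fixed seed; with ``noise_sd = 0`` the table equals the
    noise-free simulator output exactly.
    """
    if plan is None:
        plan = SimulationPlan(
            dt=1.0 / noise.rate, duration=noise.duration, controller="active",
            steady_window=(30.0, min(90.0, noise.duration)),
        )
    record = simulate(params, gains, spec, plan)
    rng = np.random.default_rng(noise.seed)
    data: dict[str, np.ndarray] = {"time": record.time}
    for part in PARTS:
        pos = record.positions[part]
        if noise.noise_sd > 0:
            pos = pos + rng.normal(0.0, noise.noise_sd, size=pos.shape)
        data[f"{part}_x"] = pos[:, 0]
        data[f"{part}_y"] = pos[:, 1]
    return pd.DataFrame(data)


def markers_to_record(table: pd.DataFrame) -> TrajectoryRecord:
    """View a marker table as a trajectory record for the analysis pipeline."""
    return TrajectoryRecord.from_frame(table)
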