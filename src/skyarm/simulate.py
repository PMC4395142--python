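"""Fixed-step RK4 simulation of the controlled arm under base oscillation.

The shoulder is driven along a horizontal sinusoid and the arm responds
under one of the two suppression controllers.  Integration uses the
classic fourth-order Runge–Kutta scheme with the control torque and base
motion re-evaluated at every internal stage time (continuous control,
not zero-order hold).  The run is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from . import control
from .arm import _coupling_constants, _terms_fast, joint_positions
from .params import ArmParameters, ArmState, BaseMotionSample, GainSet

__all__ = [
    "OscillationSpec",
    "SimulationPlan",
    "TrajectoryRecord",
    "base_motion",
    "simulate",
    "PARTS",
]

PARTS = ("shoulder", "elbow", "wrist", "hand")

Controller = Literal["passive", "active"]


@dataclass(frozen=True)
class OscillationSpec:
    """Horizontal sinusoidal base oscillation X_x(t) = A sin(2πf t + φ)."""

    amplitude: float = 0.03
    frequency: float = 1.09
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency


@dataclass(frozen=True)
class SimulationPlan:
    """Integration grid, steady-state window, initial state and controller.

    The initial state defaults to rest at the controller's desired
    posture; with the default 100 s run the 30–90 s window safely
    excludes the start-up transient.
    """

    dt: float = 0.01
    duration: float = 100.0
    steady_window: tuple[float, float] = (30.0, 90.0)
    initial_state: ArmState | None = None
    controller: Controller = "passive"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        lo, hi = self.steady_window
        if not (0.0 <= lo < hi <= self.duration):
            raise ValueError("steady_window must lie within [0, duration]")
        if self.controller not in ("passive", "active"):
            raise ValueError(f"unknown controller {self.controller!r}")


@dataclass(frozen=True)
class TrajectoryRecord:
    """Time series produced by one simulation run (or loaded from file)."""

    time: NDArray[np.float64]
    positions: dict[str, NDArray[np.float64]]  # part -> (T, 2)
    angles: NDArray[np.float64] | None = None  # (T, 3)
    torques: NDArray[np.float64] | None = None  # (T, 3)
    rate: float = 100.0

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the delimited-table schema: time, <part>_x, <part>_y
        for each of shoulder/elbow/wrist/hand, then theta1-3, tau1-3."""
        data: dict[str, NDArray] = {"time": self.time}
        for part in PARTS:
            data[f"{part}_x"] = self.positions[part][:, 0]
            data[f"{part}_y"] = self.positions[part][:, 1]
        if self.angles is not None:
            for i in range(3):
                data[f"theta{i + 1}"] = self.angles[:, i]
        if self.torques is not None:
            for i in range(3):
                data[f"tau{i + 1}"] = self.torques[:, i]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrajectoryRecord":
        time = frame["time"].to_numpy(dtype=float)
        if len(time) < 2:
            raise ValueError("trajectory table must have at least two samples")
        positions = {
            part: np.column_stack(
                [frame[f"{part}_x"].to_numpy(float), frame[f"{part}_y"].to_numpy(float)]
            )
            for part in PARTS
            if f"{part}_x" in frame
        }
        angles = None
        if all(f"theta{i + 1}" in frame for i in range(3)):
            angles = np.column_stack(
                [frame[f"theta{i + 1}"].to_numpy(float) for i in range(3)]
            )
        torques = None
        if all(f"tau{i + 1}" in frame for i in range(3)):
            torques = np.column_stack(
                [frame[f"tau{i + 1}"].to_numpy(float) for i in range(3)]
            )
        rate = 1.0 / float(np.median(np.diff(time)))
        return cls(time=time, positions=positions, angles=angles, torques=torques, rate=rate)


def base_motion(spec: OscillationSpec, t: float) -> BaseMotionSample:
    """Base kinematics at time ``t`` with exact analytic derivatives."""
    w = spec.omega
    arg = w * t + spec.phase
    return BaseMotionSample(
        position=[spec.amplitude * np.sin(arg), 0.0],
        velocity=[spec.amplitude * w * np.cos(arg), 0.0],
        acceleration=[-spec.amplitude * w * w * np.sin(arg), 0.0],
    )


def simulate(
    params: ArmParameters,
    gains: GainSet,
    spec: OscillationSpec,
    plan: SimulationPlan,
) -> TrajectoryRecord:
    """Integrate the controlled arm and record all part trajectories.

    Raises ``FloatingPointError`` naming the step if the state diverges.
    """
    n_steps = int(round(plan.duration / plan.dt))
    dt = plan.dt
    init = plan.initial_state or ArmState(
        angles=gains.desired_posture, angular_velocities=np.zeros(3)
    )

    b, c = _coupling_constants(params)
    link_inertia, g = params.inertia, params.gravity
    K, D, C = gains.stiffness, gains.viscosity, gains.virtual_damper
    theta_d = gains.desired_posture
    from .arm import gravity_torque

    g_comp = gravity_torque(params, theta_d)
    active = plan.controller == "active"
    A, w, ph = spec.amplitude, spec.omega, spec.phase
    length = params.length

    def torque(theta, omega, xdot):
        tau = -K @ (theta - theta_d) + g_comp
        if active:
            phi = np.cumsum(theta)
            tang = length[:, None] * np.stack([-np.sin(phi), np.cos(phi)], axis=1)
            J = np.cumsum(tang[::-1], axis=0)[::-1].T
            v = J @ omega + xdot
            tau = tau - J.T @ (C @ v)
        return tau

    def deriv(t, theta, omega):
        arg = w * t + ph
        xdot = np.array([A * w * np.cos(arg), 0.0])
        xddot = np.array([-A * w * w * np.sin(arg), 0.0])
        tau = torque(theta, omega, xdot)
        I_m, M, V, G = _terms_fast(b, c, link_inertia, g, theta, omega)
        acc = np.linalg.solve(I_m, tau - M @ xddot - V - G - D @ omega)
        return omega, acc, tau

    T = n_steps + 1
    times = np.arange(T) * dt
    angles = np.empty((T, 3))
    velocities = np.empty((T, 3))
    torques = np.empty((T, 3))
    theta, omega = init.angles.copy(), init.angular_velocities.copy()

    for i in range(T):
        angles[i], velocities[i] = theta, omega
        t = times[i]
        k1_th, k1_om, tau0 = deriv(t, theta, omega)
        torques[i] = tau0
        if i == n_steps:
            break
        k2_th, k2_om, _ = deriv(t + dt / 2, theta + dt / 2 * k1_th, omega + dt / 2 * k1_om)
        k3_th, k3_om, _ = deriv(t + dt / 2, theta + dt / 2 * k2_th, omega + dt / 2 * k2_om)
        k4_th, k4_om, _ = deriv(t + dt, theta + dt * k3_th, omega + dt * k3_om)
        theta = theta + dt / 6 * (k1_th + 2 * k2_th + 2 * k3_th + k4_th)
        omega = omega + dt / 6 * (k1_om + 2 * k2_om + 2 * k3_om + k4_om)
        if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(omega))):
            raise FloatingPointError(
                f"simulation diverged at step {i + 1} (t = {t + dt:.3f} s)"
            )

    # workspace positions of all parts on the sample grid
    phi = np.cumsum(angles, axis=1)
    links = length[None, :, None] * np.stack([np.cos(phi), np.sin(phi)], axis=2)
    base_x = A * np.sin(w * times + ph)
    shoulder = np.column_stack([base_x, np.zeros(T)])
    cum = np.cumsum(links, axis=1)
    positions = {
        "shoulder": shoulder,
        "elbow": shoulder + cum[:, 0, :],
        "wrist": shoulder + cum[:, 1, :],
        "hand": shoulder + cum[:, 2, :],
    }
    return TrajectoryRecord(
        time=times, positions=positions, angles=angles, torques=torques, rate=1.0 / dt
    )
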