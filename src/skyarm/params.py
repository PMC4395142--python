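"""Physical parameters, state containers and controller gains.

The model is a three-link arm (upper arm, forearm, hand segment) moving in
a vertical plane.  The shoulder — the base of the chain — is not free: its
workspace position ``X(t)`` is prescribed from outside (a platform shaking
the subject), so the configuration of the system is fully described by the
three joint angles.

Coordinate and angle conventions
--------------------------------
* ``x`` is horizontal (anterior–posterior, the oscillation axis), ``y`` is
  vertical; gravity acts along ``-y``.
* ``theta[0]`` is the upper-arm angle measured counter-clockwise from the
  +x axis; ``theta[1]`` and ``theta[2]`` are relative inter-segment angles
  (elbow and wrist flexion).  Absolute link angles are the cumulative sums.

Defaults reproduce the anthropometric segment parameters, joint viscosity
and standard joint stiffness used throughout this package's simulation
experiments; the hand-segment mass includes a held cup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "ArmParameters",
    "ArmState",
    "BaseMotionSample",
    "DynamicsTerms",
    "GainSet",
    "DEFAULT_VISCOSITY",
    "DEFAULT_STIFFNESS",
    "DEFAULT_POSTURE",
]

#: Joint viscosity matrix D [N·m·s/rad]; off-diagonal terms model
#: biarticular muscles spanning shoulder and elbow.
DEFAULT_VISCOSITY = np.array(
    [[1.5, 0.5, 0.0],
     [0.5, 1.0, 0.0],
     [0.0, 0.0, 0.4]]
)

#: Standard joint stiffness matrix K [N·m/rad] (empirical arm-impedance
#: magnitudes for posture maintenance).
DEFAULT_STIFFNESS = np.array(
    [[20.0, 5.0, 0.0],
     [5.0, 10.0, 0.0],
     [0.0, 0.0, 5.0]]
)

#: Default desired posture theta_d [rad]: upper arm hanging 80 deg below
#: the horizontal, elbow flexed 90 deg (forearm 10 deg above horizontal),
#: wrist straight.  WARNING: this is this package's choice of a plausible
#: cup-holding posture — a config value, not an empirically measured one;
#: see docs/methods.md for the posture set it was chosen from.
DEFAULT_POSTURE = np.deg2rad([-80.0, 90.0, 0.0])


def _vec(x: ArrayLike, n: int, name: str) -> NDArray[np.float64]:
    arr = np.asarray(x, dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {arr}")
    return arr


def _mat(x: ArrayLike, shape: tuple[int, int], name: str) -> NDArray[np.float64]:
    arr = np.asarray(x, dtype=float)
    if arr.shape != shape:
        raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass(frozen=True)
class ArmParameters:
    """Segment masses, lengths, centre-of-mass offsets and inertias.

    Parameters
    ----------
    mass : (3,) array, kg
    length : (3,) array, m
        Joint-to-joint segment lengths.
    com_offset : (3,) array, m
        Distance from each segment's proximal joint to its centre of mass.
    inertia : (3,) array, kg·m²
        Moment of inertia of each segment about its own centre of mass.
    gravity : float, m/s²
        Magnitude of gravitational acceleration (acts along -y).
    """

    mass: NDArray[np.float64]
    length: NDArray[np.float64]
    com_offset: NDArray[np.float64]
    inertia: NDArray[np.float64]
    gravity: float = 9.81

    def __post_init__(self) -> None:
        object.__setattr__(self, "mass", _vec(self.mass, 3, "mass"))
        object.__setattr__(self, "length", _vec(self.length, 3, "length"))
        object.__setattr__(self, "com_offset", _vec(self.com_offset, 3, "com_offset"))
        object.__setattr__(self, "inertia", _vec(self.inertia, 3, "inertia"))
        if np.any(self.mass <= 0) or np.any(self.length <= 0):
            raise ValueError("masses and lengths must be strictly positive")
        if np.any(self.com_offset <= 0) or np.any(self.com_offset > self.length):
            raise ValueError("com_offset must satisfy 0 < com_offset <= length")
        if np.any(self.inertia < 0):
            raise ValueError("inertia must be non-negative")

    @classmethod
    def default(cls) -> "ArmParameters":
        """Anthropometric defaults (172.1 cm / 63.8 kg adult male; the
        hand-segment mass includes a 0.39 kg cup)."""
        return cls(
            mass=[1.79, 1.02, 0.77],
            length=[0.24, 0.22, 0.17],
            com_offset=[0.10, 0.09, 0.08],
            inertia=[3.00e-2, 1.34e-2, 0.73e-2],
        )


@dataclass(frozen=True)
class ArmState:
    """Joint angles and angular velocities at one time instant."""

    angles: NDArray[np.float64]
    angular_velocities: NDArray[np.float64]
    time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "angles", _vec(self.angles, 3, "angles"))
        object.__setattr__(
            self, "angular_velocities", _vec(self.angular_velocities, 3, "angular_velocities")
        )


@dataclass(frozen=True)
class BaseMotionSample:
    """Shoulder (base) position, velocity and acceleration in the workspace."""

    position: NDArray[np.float64] = field(default_factory=lambda: np.zeros(2))
    velocity: NDArray[np.float64] = field(default_factory=lambda: np.zeros(2))
    acceleration: NDArray[np.float64] = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", _vec(self.position, 2, "position"))
        object.__setattr__(self, "velocity", _vec(self.velocity, 2, "velocity"))
        object.__setattr__(self, "acceleration", _vec(self.acceleration, 2, "acceleration"))


@dataclass(frozen=True)
class DynamicsTerms:
    """Configuration-dependent terms of the arm's equation of motion

    ``I(θ) θ̈ + M(θ) Ẍ + V(θ, θ̇) + G(θ) + D θ̇ = τ_in``

    where ``I`` is the joint-space inertia matrix, ``M`` couples the
    prescribed base acceleration into joint torques, ``V`` collects
    centripetal/Coriolis torques and ``G`` the gravity torques.
    """

    inertia_matrix: NDArray[np.float64]
    base_coupling: NDArray[np.float64]
    coriolis: NDArray[np.float64]
    gravity_torque: NDArray[np.float64]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "inertia_matrix", _mat(self.inertia_matrix, (3, 3), "inertia_matrix")
        )
        object.__setattr__(
            self, "base_coupling", _mat(self.base_coupling, (3, 2), "base_coupling")
        )
        object.__setattr__(self, "coriolis", _vec(self.coriolis, 3, "coriolis"))
        object.__setattr__(self, "gravity_torque", _vec(self.gravity_torque, 3, "gravity_torque"))


@dataclass(frozen=True)
class GainSet:
    """Controller gains: joint stiffness K, joint viscosity D, workspace
    virtual damper C (diagonal) and the desired posture θ_d."""

    stiffness: NDArray[np.float64] = field(default_factory=lambda: DEFAULT_STIFFNESS.copy())
    viscosity: NDArray[np.float64] = field(default_factory=lambda: DEFAULT_VISCOSITY.copy())
    virtual_damper: NDArray[np.float64] = field(default_factory=lambda: np.zeros((2, 2)))
    desired_posture: NDArray[np.float64] = field(default_factory=lambda: DEFAULT_POSTURE.copy())

    def __post_init__(self) -> None:
        object.__setattr__(self, "stiffness", _mat(self.stiffness, (3, 3), "stiffness"))
        object.__setattr__(self, "viscosity", _mat(self.viscosity, (3, 3), "viscosity"))
        damper = np.asarray(self.virtual_damper, dtype=float)
        if damper.shape == (2,):  # diagonal given as a 2-vector
            damper = np.diag(damper)
        object.__setattr__(self, "virtual_damper", _mat(damper, (2, 2), "virtual_damper"))
        object.__setattr__(
            self, "desired_posture", _vec(self.desired_posture, 3, "desired_posture")
        )
        if not np.allclose(self.stiffness, self.stiffness.T):
            raise ValueError("stiffness matrix must be symmetric")
        if np.any(np.linalg.eigvalsh(self.stiffness) < -1e-12):
            raise ValueError("stiffness matrix must be positive semi-definite")
        if self.virtual_damper[0, 1] != 0.0 or self.virtual_damper[1, 0] != 0.0:
            raise ValueError("virtual damper must be diagonal")
        if np.any(np.diag(self.virtual_damper) < 0):
            raise ValueError("virtual damper entries must be non-negative")

    def with_damper(self, c: float | ArrayLike) -> "GainSet":
        """Return a copy with virtual damper ``diag(c, c)`` (scalar ``c``)
        or ``diag(c)`` (2-vector ``c``)."""
        c_arr = np.asarray(c, dtype=float)
        diag = np.full(2, float(c_arr)) if c_arr.ndim == 0 else c_arr
        return GainSet(
            stiffness=self.stiffness,
            viscosity=self.viscosity,
            virtual_damper=np.diag(diag),
            desired_posture=self.desired_posture,
        )

    def with_stiffness_scale(self, scale: float) -> "GainSet":
        """Return a copy with the whole stiffness matrix multiplied by ``scale``."""
        return GainSet(
            stiffness=scale * self.stiffness,
            viscosity=self.viscosity,
            virtual_damper=self.virtual_damper,
            desired_posture=self.desired_posture,
        )
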