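"""Torque laws for vibration suppression.

Two controllers are implemented, both built on the spring-like behaviour
of a joint driven by opposing muscle groups (equilibrium-point control):

* **Passive suppression** — hold the desired posture with joint springs
  plus gravity compensation; damp hand vibration only by *lowering* the
  joint stiffness:

      τ_in = −K (θ − θ_d) + G(θ_d)

* **Active suppression** — additionally tether the hand to a virtual
  plane fixed in the workspace through a virtual viscous damper C
  (skyhook control); the damper force is mapped to joint torques by the
  transposed hand Jacobian:

      τ_in = −K (θ − θ_d) + G(θ_d) − Jᵀ C ẋ_ha|vp

Because the virtual plane is stationary in the world frame, the hand
velocity relative to it is the absolute workspace hand velocity
``ẋ_ha|vp = J θ̇ + Ẋ`` — base motion included.

Rewriting the active law as a pure spring ``τ_in = −K (θ − θ_eq)`` shows
that skyhook control is an *equilibrium-point shift*:

    θ_eq = θ_d − K⁻¹ G(θ_d) − K⁻¹ Jᵀ C ẋ_ha|vp

with the first two terms constant (posture maintenance) and the last one
the time-varying, velocity-dependent shift that dissipates hand motion.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import NDArray

from .arm import gravity_torque, hand_jacobian
from .params import ArmParameters, ArmState, BaseMotionSample, GainSet

__all__ = [
    "passive_torque",
    "relative_hand_velocity",
    "active_torque",
    "equilibrium_point",
]


def passive_torque(
    gains: GainSet, state: ArmState, params: ArmParameters
) -> NDArray[np.float64]:
    """Stiffness-plus-gravity-compensation torque −K(θ−θ_d) + G(θ_d).

    Gravity compensation is evaluated at the *desired* posture, so it is
    constant in time; with K = 0 the controller degenerates to feeding
    forward the posture-holding torque.
    """
    return -gains.stiffness @ (state.angles - gains.desired_posture) + gravity_torque(
        params, gains.desired_posture
    )


def relative_hand_velocity(
    params: ArmParameters, state: ArmState, base: BaseMotionSample
) -> NDArray[np.float64]:
    """Hand velocity relative to the (world-fixed) virtual plane: J θ̇ + Ẋ."""
    return hand_jacobian(params, state) @ state.angular_velocities + base.velocity


def active_torque(
    gains: GainSet, state: ArmState, base: BaseMotionSample, params: ArmParameters
) -> NDArray[np.float64]:
    """Skyhook torque: passive law minus the reflected virtual-damper force.

    With C = diag(0, 0) this is exactly the passive law.
    """
    J = hand_jacobian(params, state)
    v = J @ state.angular_velocities + base.velocity
    return (
        -gains.stiffness @ (state.angles - gains.desired_posture)
        + gravity_torque(params, gains.desired_posture)
        - J.T @ (gains.virtual_damper @ v)
    )


def equilibrium_point(
    gains: GainSet, state: ArmState, base: BaseMotionSample, params: ArmParameters
) -> NDArray[np.float64]:
    """Instantaneous equilibrium point θ_eq of the active controller.

    θ_eq = θ_d − K⁻¹ G(θ_d) − K⁻¹ Jᵀ C ẋ_ha|vp; satisfies
    τ_in = −K (θ − θ_eq).  Raises if K is singular (the equilibrium point
    is undefined without joint stiffness).
    """
    J = hand_jacobian(params, state)
    v = J @ state.angular_velocities + base.velocity
    load = gravity_torque(params, gains.desired_posture) - J.T @ (
        gains.virtual_damper @ v
    )
    try:
        shift = np.linalg.solve(gains.stiffness, load)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "equilibrium point undefined: stiffness matrix is singular"
        ) from exc
    if not np.all(np.isfinite(shift)):
        raise ValueError("equilibrium point undefined: stiffness matrix is singular")
    return gains.desired_posture + shift
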