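"""Kinematics and rigid-body dynamics of the three-link arm.

The equation of motion is obtained from the Lagrangian of three rigid
links whose base point (the shoulder) translates along a prescribed
trajectory ``X(t)``:

    I(θ) θ̈ + M(θ) Ẍ + V(θ, θ̇) + G(θ) + D θ̇ = τ_in

The closed forms below are derived in *absolute* link angles
``φ = (φ₁, φ₂, φ₃)``, ``φ_k = θ₁ + … + θ_k``, where they are compact:
with ``a[k, j]`` the distance contributed by joint ``j`` to the centre of
mass of link ``k`` (``l_j`` for ``j < k``, ``l_g,k`` for ``j = k``) and

    b[j, m] = Σ_k  m_k a[k, j] a[k, m]         (kg·m²)
    c[j]    = Σ_k  m_k a[k, j]                 (kg·m)

the absolute-angle terms are

    Ĩ[j, m] = b[j, m] cos(φ_j − φ_m) + δ_jm I_j
    Ṽ[j]    = Σ_m b[j, m] sin(φ_j − φ_m) φ̇_m²
    M̃[j]    = c_j (−sin φ_j, cos φ_j)
    G̃[j]    = g c_j cos φ_j

and the relative-coordinate terms follow by the congruence φ = T θ with T
the lower-triangular matrix of ones: I = Tᵀ Ĩ T, V = Tᵀ Ṽ, M = Tᵀ M̃,
G = Tᵀ G̃.  The test-suite checks these expressions against an
independently derived symbolic Euler–Lagrange oracle.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import NDArray

from .params import ArmParameters, ArmState, BaseMotionSample, DynamicsTerms

__all__ = [
    "forward_kinematics",
    "joint_positions",
    "hand_jacobian",
    "gravity_torque",
    "dynamics_terms",
    "forward_dynamics",
    "mechanical_energy",
]

# φ = _TRIL @ θ maps relative joint angles to absolute link angles.
_TRIL = np.tril(np.ones((3, 3)))


def _coupling_constants(params: ArmParameters) -> tuple[NDArray, NDArray]:
    """Configuration-independent mass-coupling constants b (3×3) and c (3,)."""
    m, l, lg = params.mass, params.length, params.com_offset
    a = np.zeros((3, 3))
    for k in range(3):
        a[k, :k] = l[:k]
        a[k, k] = lg[k]
    b = np.einsum("k,kj,km->jm", m, a, a)
    c = m @ a
    return b, c


def _absolute(theta: NDArray, omega: NDArray | None = None):
    phi = np.cumsum(theta)
    if omega is None:
        return phi
    return phi, np.cumsum(omega)


def joint_positions(
    params: ArmParameters, state: ArmState, base: BaseMotionSample
) -> NDArray[np.float64]:
    """Workspace positions of shoulder, elbow, wrist and hand, shape (4, 2)."""
    phi = _absolute(state.angles)
    links = params.length[:, None] * np.stack([np.cos(phi), np.sin(phi)], axis=1)
    pts = np.empty((4, 2))
    pts[0] = base.position
    pts[1:] = base.position + np.cumsum(links, axis=0)
    return pts


def forward_kinematics(
    params: ArmParameters, state: ArmState, base: BaseMotionSample
) -> tuple[NDArray, NDArray, NDArray]:
    """Workspace positions of elbow, wrist and hand (each shape (2,))."""
    pts = joint_positions(params, state, base)
    return pts[1], pts[2], pts[3]


def hand_jacobian(params: ArmParameters, state: ArmState) -> NDArray[np.float64]:
    """Jacobian J (2×3) of the hand position relative to the base.

    Absolute hand velocity = ``J @ θ̇ + Ẋ``.  Singular configurations are
    allowed: J is only ever used forward or transposed.
    """
    phi = _absolute(state.angles)
    # tangent vector of each link, scaled by its length
    w = params.length[:, None] * np.stack([-np.sin(phi), np.cos(phi)], axis=1)
    # column m = Σ_{j >= m} w[j]
    rev = np.cumsum(w[::-1], axis=0)[::-1]
    return rev.T


def gravity_torque(params: ArmParameters, angles: NDArray) -> NDArray[np.float64]:
    """Joint torques G(θ) needed to balance gravity at posture ``angles``."""
    _, c = _coupling_constants(params)
    phi = np.cumsum(np.asarray(angles, dtype=float))
    return _TRIL.T @ (params.gravity * c * np.cos(phi))


def dynamics_terms(params: ArmParameters, state: ArmState) -> DynamicsTerms:
    """All configuration-dependent terms of the equation of motion."""
    b, c = _coupling_constants(params)
    I_m, M, V, G = _terms_fast(
        b, c, params.inertia, params.gravity, state.angles, state.angular_velocities
    )
    return DynamicsTerms(
        inertia_matrix=I_m, base_coupling=M, coriolis=V, gravity_torque=G
    )


def _terms_fast(b, c, link_inertia, g, theta, omega):
    """Raw-array dynamics terms; the hot path for the simulator."""
    phi, dphi = _absolute(theta, omega)
    sin_p, cos_p = np.sin(phi), np.cos(phi)
    # cos/sin of pairwise angle differences via addition formulas
    cos_d = cos_p[:, None] * cos_p[None, :] + sin_p[:, None] * sin_p[None, :]
    sin_d = sin_p[:, None] * cos_p[None, :] - cos_p[:, None] * sin_p[None, :]
    I_abs = b * cos_d + np.diag(link_inertia)
    V_abs = (b * sin_d) @ (dphi * dphi)
    M_abs = c[:, None] * np.stack([-sin_p, cos_p], axis=1)
    G_abs = g * c * cos_p
    T = _TRIL
    return T.T @ I_abs @ T, T.T @ M_abs, T.T @ V_abs, T.T @ G_abs


def forward_dynamics(
    params: ArmParameters,
    state: ArmState,
    base: BaseMotionSample,
    viscosity: NDArray,
    input_torque: NDArray,
) -> NDArray[np.float64]:
    """Joint angular accelerations θ̈ from the equation of motion.

    Solves ``θ̈ = I(θ)⁻¹ (τ_in − M(θ) Ẍ − V − G − D θ̇)``.
    """
    tau = np.asarray(input_torque, dtype=float)
    D = np.asarray(viscosity, dtype=float)
    if tau.shape != (3,) or not np.all(np.isfinite(tau)):
        raise ValueError(f"input torque must be a finite 3-vector, got {input_torque!r}")
    if not np.all(np.isfinite(state.angles)) or not np.all(
        np.isfinite(state.angular_velocities)
    ):
        raise ValueError("arm state must be finite")
    terms = dynamics_terms(params, state)
    rhs = (
        tau
        - terms.base_coupling @ base.acceleration
        - terms.coriolis
        - terms.gravity_torque
        - D @ state.angular_velocities
    )
    return np.linalg.solve(terms.inertia_matrix, rhs)


def mechanical_energy(
    params: ArmParameters, state: ArmState, base: BaseMotionSample
) -> float:
    """Total kinetic plus gravitational potential energy of the three links.

    Includes the base's contribution to link velocities; the potential
    reference is y = 0.
    """
    phi, dphi = _absolute(state.angles, state.angular_velocities)
    m, l, lg = params.mass, params.length, params.com_offset
    a = np.zeros((3, 3))
    for k in range(3):
        a[k, :k] = l[:k]
        a[k, k] = lg[k]
    tangent = np.stack([-np.sin(phi), np.cos(phi)], axis=1)  # u'(φ_j)
    upos = np.stack([np.cos(phi), np.sin(phi)], axis=1)
    energy = 0.0
    for k in range(3):
        v_com = base.velocity + (a[k, :, None] * tangent * dphi[:, None]).sum(axis=0)
        y_com = base.position[1] + (a[k] * upos[:, 1]).sum()
        energy += (
            0.5 * m[k] * v_com @ v_com
            + 0.5 * params.inertia[k] * dphi[k] ** 2
            + m[k] * params.gravity * y_com
        )
    return float(energy)
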