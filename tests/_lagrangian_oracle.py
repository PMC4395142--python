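"""Independent symbolic Euler–Lagrange oracle for the arm dynamics.

Derives the generalized joint forces of three rigid planar links on a
translating base directly from d/dt ∂L/∂θ̇ − ∂L/∂θ with sympy, without
reusing any closed form from the package.  Link centre-of-mass positions
are written from first principles (base point plus segment vectors) and
the base trajectory enters as exogenous symbols for position, velocity
and acceleration.
"""

from __future__ import annotations

import numpy as np
import sympy as sp


def build_oracle():
    """Return ``f(params, theta, omega, alpha, base_acc) -> tau`` where tau
    is the generalized force I(θ)θ̈ + M(θ)Ẍ + V + G (no viscosity/input)."""
    t = sp.symbols("t")
    m = sp.symbols("m1:4", positive=True)
    l = sp.symbols("l1:4", positive=True)
    lg = sp.symbols("lg1:4", positive=True)
    Iz = sp.symbols("I1:4", nonnegative=True)
    grav = sp.symbols("g", positive=True)

    th = [sp.Function(f"th{i}")(t) for i in range(3)]
    bx = sp.Function("bx")(t)
    by = sp.Function("by")(t)

    # absolute link angles and centre-of-mass positions from scratch
    phi = [th[0], th[0] + th[1], th[0] + th[1] + th[2]]
    joints = [(bx, by)]
    for i in range(3):
        px, py = joints[-1]
        joints.append((px + l[i] * sp.cos(phi[i]), py + l[i] * sp.sin(phi[i])))
    lagrangian = sp.S.Zero
    for i in range(3):
        px, py = joints[i]
        cx = px + lg[i] * sp.cos(phi[i])
        cy = py + lg[i] * sp.sin(phi[i])
        vx, vy = sp.diff(cx, t), sp.diff(cy, t)
        kinetic = m[i] * (vx**2 + vy**2) / 2 + Iz[i] * sp.diff(phi[i], t) ** 2 / 2
        lagrangian += kinetic - m[i] * grav * cy

    taus = [
        sp.diff(sp.diff(lagrangian, sp.diff(q, t)), t) - sp.diff(lagrangian, q)
        for q in th
    ]

    # substitute flat symbols for the time-dependent quantities
    q = sp.symbols("q1:4")
    dq = sp.symbols("dq1:4")
    ddq = sp.symbols("ddq1:4")
    ax, ay = sp.symbols("ax ay")
    subs = {}
    for i in range(3):
        subs[sp.Derivative(th[i], (t, 2))] = ddq[i]
        subs[sp.Derivative(th[i], t)] = dq[i]
        subs[th[i]] = q[i]
    subs[sp.Derivative(bx, (t, 2))] = ax
    subs[sp.Derivative(by, (t, 2))] = ay
    subs[sp.Derivative(bx, t)] = 0  # base velocity does not enter the EOM
    subs[sp.Derivative(by, t)] = 0
    subs[bx] = 0
    subs[by] = 0

    flat = [sp.simplify(expr.subs(subs)) for expr in taus]
    args = (*m, *l, *lg, *Iz, grav, *q, *dq, *ddq, ax, ay)
    func = sp.lambdify(args, flat, modules="numpy")

    def oracle(params, theta, omega, alpha, base_acc):
        vals = (
            *params.mass, *params.length, *params.com_offset, *params.inertia,
            params.gravity, *theta, *omega, *alpha, *base_acc,
        )
        return np.asarray(func(*vals), dtype=float)

    return oracle
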