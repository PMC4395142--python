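# Methods

## The model

`skyarm` models a seated person whose shoulder is shaken horizontally
(for example by an oscillating platform) while they try to keep their
hand — and a cup held in it — steady.  The arm is three rigid links
(upper arm, forearm, hand segment) moving in the sagittal plane; the
shoulder is the base of the chain and its workspace position `X(t)` is
prescribed, not a degree of freedom.  With joint angles `θ ∈ ℝ³` the
equation of motion is

    I(θ) θ̈ + M(θ) Ẍ + V(θ, θ̇) + G(θ) + D θ̇ = τ_in

where `I(θ)` is the joint-space inertia matrix, `M(θ)` couples the
prescribed base acceleration into joint torques, `V` collects
centripetal/Coriolis torques, `G(θ)` gravity torques and `D` is a
constant joint-viscosity matrix.

### Derivation of the closed forms

The explicit matrices are derived from the Lagrangian of the three links
with the base position treated as an exogenous input.  In *absolute*
link angles `φ = cumsum(θ)` the terms are compact.  Writing `a[k, j]`
for the lever of joint `j` at the centre of mass of link `k` (`l_j` for
`j < k`, `l_g,k` for `j = k`) and

    b[j, m] = Σ_k m_k a[k, j] a[k, m],     c[j] = Σ_k m_k a[k, j],

the absolute-angle equations have mass matrix
`b[j,m] cos(φ_j − φ_m) + δ_jm I_j`, Coriolis vector
`Σ_m b[j,m] sin(φ_j − φ_m) φ̇_m²`, base coupling
`c_j (−sin φ_j, cos φ_j)` and gravity `g c_j cos φ_j`.  The
relative-coordinate terms follow from the congruence `φ = T θ` with `T`
the lower-triangular matrix of ones.  An independent symbolic
Euler–Lagrange derivation (sympy, in the test suite) checks these
closed forms at 1e-8 relative accuracy on random states with nonzero
base acceleration, and an energy-conservation test checks the
conservative part of the vector field directly.

### Conventions

* `x` horizontal (the oscillation axis), `y` vertical, gravity `−y`,
  `g = 9.81 m/s²`; SI units throughout.
* `θ₁` is the upper-arm angle counter-clockwise from `+x`; `θ₂`, `θ₃`
  are relative elbow and wrist angles.  Any self-consistent convention
  gives the same physics; this one is assumed everywhere in the package.

## Controllers

Both controllers exploit the spring-like behaviour of a joint driven by
opposing muscle groups: torque `−K(θ − θ_eq)` pulls the arm toward an
equilibrium point.

**Passive suppression** holds a fixed equilibrium and relies on the
*magnitude* of the joint stiffness:

    τ_in = −K (θ − θ_d) + G(θ_d)

Gravity compensation is evaluated at the desired posture `θ_d`, so the
feedforward term is constant; `K = 0` degenerates to pure torque
feedforward (the "compute the required torque" strategy).  Vibration
transmission to the hand is reduced only by *lowering* `K`.

**Active suppression** adds skyhook control: the hand behaves as if
tethered to a plane fixed in the workspace through a viscous damper `C`,
whose force is reflected to the joints by the transposed hand Jacobian:

    τ_in = −K (θ − θ_d) + G(θ_d) − Jᵀ C ẋ_ha|vp

Because the virtual plane is world-fixed, the hand velocity relative to
it is the absolute workspace hand velocity `ẋ_ha|vp = J θ̇ + Ẋ`,
including the base velocity.  (A body-frame reading would make the
damper blind to exactly the base-driven motion the controller exists to
remove.)  Rewriting the law as `−K(θ − θ_eq)` shows it is an
equilibrium-point controller whose set point shifts by
`−K⁻¹ Jᵀ C ẋ_ha|vp` around the constant posture-holding point
`θ_d − K⁻¹ G(θ_d)`.

## Parameters and defaults

| quantity | default | units | note |
|---|---|---|---|
| masses `m` | 1.79, 1.02, 0.77 | kg | anthropometric (172.1 cm / 63.8 kg); hand-segment mass includes a 0.39 kg cup |
| lengths `l` | 0.24, 0.22, 0.17 | m | |
| COM offsets `l_g` | 0.10, 0.09, 0.08 | m | from proximal joint |
| link inertias `I` | 3.00e-2, 1.34e-2, 0.73e-2 | kg·m² | about each COM |
| viscosity `D` | [[1.5,0.5,0],[0.5,1.0,0],[0,0,0.4]] | N·m·s/rad | off-diagonals: biarticular muscles |
| stiffness `K` | [[20,5,0],[5,10,0],[0,0,5]] | N·m/rad | empirical posture-holding magnitudes |
| virtual damper `C` | diag(0, 0); studied at 20, 40, 60 | N·s/m | diagonal by construction |
| oscillation | 0.03 m, 1.09 Hz, horizontal | | the task drive |
| integration | RK4, dt = 0.01 s, 100 s | | control recomputed at stage times |
| steady window | 30–90 s | | transient discarded |

### Desired posture

The desired posture `θ_d` is a free parameter: in the motivating
experiments it came from measured subject data that are not available
as numbers.  The package therefore documents a set of plausible
seated cup-holding postures — upper arm hanging 80–90° below the
horizontal, elbow flexed 90–100° so the forearm points forward and
slightly upward ("looking into the cup"), wrist straight — and ships
the member of that set whose simulated behaviour shows all the
qualitative signatures listed below with the widest margins:

    θ_d = (−80°, +90°, 0°)

i.e. upper arm 80° below the horizontal, forearm 10° above it, wrist
straight.  The posture matters: configurations with the arm extended
far forward put the dominant resonant mode of the stiff arm largely
into the vertical direction at the hand, which buries the
stiffness-sweep amplitude trends; the hanging-arm, flexed-elbow family
keeps the stiff-arm response nearly horizontal, and softening the
joints then converts base translation into arc motion about the
shoulder — horizontal amplitude falls while vertical amplitude grows,
the signature the sweep looks for.  **This value is the package's
choice, not a measured one**; it is exposed in the config
(`gains.desired_posture_deg`).

## Simulation

Classic fixed-step RK4 on the state `(θ, θ̇)` with the controller torque
and base kinematics re-evaluated at every internal stage time
(continuous control; a zero-order hold at 100 Hz changes the steady
metrics negligibly but is not what the continuous model means).  The
initial state is rest at `θ_d` and the drive starts at phase 0; both
choices only affect the discarded transient.  Runs are deterministic —
there is no randomness anywhere in the simulator.

## Evaluation pipeline

Identical for simulated and measured-style tables (this is what makes
the comparison fair):

1. second-order Butterworth low-pass, 5 Hz cut-off, applied
   forward–backward (zero phase — phases matter when comparing parts);
2. jerk = third derivative via three central first differences (exact
   for cubics; 3 samples trimmed at each end rather than padded),
   low-pass filtered again;
3. every series — jerk included — cut into consecutive drive periods
   phase-locked to the known drive frequency (no event detection),
   linearly resampled onto a 128-point phase grid and averaged over the
   steady window;
4. mean sum of squared jerk `⟨j_x² + j_y²⟩` per arm part taken over the
   mean one-cycle jerk (averaging before squaring means components not
   phase-locked to the drive — marker noise above all — cancel instead
   of biasing the metric; for the noise-free periodic simulation the
   two orders agree);
5. amplitude of the mean cycle per direction as **half peak-to-peak**
   (the convention in which the 0.03 m drive has amplitude 0.03 m);
   full peak-to-peak is reported alongside because "amplitude" is used
   both ways in the literature.

A useful analytic anchor: the drive sinusoid itself has amplitude `A`
and mean sum of squared jerk `A²ω⁶/2` (`ω = 2πf`); the pipeline
recovers both within 1% / 3%, the residual coming from the filter's
passband ripple and the finite-difference stencil.

## Synthetic marker data

`fixtures.generate_markers` emulates an optical motion-capture
recording of the task: simulator output for the four markers
(shoulder, elbow, wrist, hand) plus i.i.d. Gaussian noise per
coordinate, 0.5 mm SD by default — typical short-range precision of
optical systems.  It does **not** model soft-tissue artefact, marker
dropout, trunk compliance or between-subject variability, so tests
passing on fixtures certify the pipeline's numerics, not robustness to
those real-data effects.

## Qualitative behaviour the defaults reproduce

With the shipped defaults the simulations show the signatures expected
of this system:

* **Baseline** (standard `K`, no damper): the arm resonantly amplifies
  the base motion — hand horizontal amplitude exceeds the 0.03 m drive
  and elbow/wrist/hand all jerk more than the shoulder.
* **Active suppression**: both amplitude directions fall monotonically
  as `C` grows through 0, 20, 40, 60 N·s/m; at `C = diag(40,40)` and
  `diag(60,60)` the hand moves less than the platform and every distal
  jerk drops below the shoulder jerk — workspace damping beats the
  vibration source.
* **Passive suppression** (`K` scaled by 1, 0.1, 0.01, 0): distal jerks
  fall as the arm softens, but the hand jerk never falls below the
  shoulder jerk, and the horizontal gain comes at the price of growing
  vertical swing — the softened arm pivots about the shoulder, trading
  translation for arc motion.

## Numerical choices and limitations

* `filtfilt` uses odd-padding with the scipy default pad length; series
  shorter than the pad are rejected rather than padded differently.
* Cycle averaging interpolates linearly; at 100 Hz sampling and 1.09 Hz
  drive each cycle holds ~92 samples, making interpolation error
  negligible against the metrics' tolerances.
* `K = 0` makes the equilibrium point undefined (`K⁻¹` does not exist);
  `equilibrium_point` raises, while the torque laws remain valid.
* Joint limits, muscle-level (Hill-type) actuation, 3-D motion, trunk
  and head segments, and sensory (visual/vestibular) models are out of
  scope; the controllers are ideal torque sources with exact state
  feedback.
* The integrator is fixed-step; stiff parameter regimes far outside the
  defaults may need a smaller `dt` (the RK4 self-convergence test shows
  how to check).
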