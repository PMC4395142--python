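# Full configuration example for skyarm. Every key is optional; omitted
# sections use the package defaults shown here. Matrices are row-major.
arm:
  mass: [1.79, 1.02, 0.77]          # kg; hand segment includes the cup
  length: [0.24, 0.22, 0.17]        # m
  com_offset: [0.10, 0.09, 0.08]    # m, proximal joint -> centre of mass
  inertia: [0.0300, 0.0134, 0.0073] # kg m^2, about each centre of mass
  gravity: 9.81                     # m/s^2

gains:
  stiffness:                        # K, N m/rad (symmetric PSD)
    - [20, 5, 0]
    - [5, 10, 0]
    - [0, 0, 5]
  viscosity:                        # D, N m s/rad
    - [1.5, 0.5, 0]
    - [0.5, 1.0, 0]
    - [0, 0, 0.4]
  virtual_damper: [0, 0]            # diagonal of C, N s/m (skyhook damper)
  # Desired posture: upper arm 80 deg below horizontal, elbow flexed 90 deg,
  # wrist straight. WARNING: a package choice, not a measured posture.
  desired_posture_deg: [-80, 90, 0]

oscillation:
  amplitude: 0.03                   # m
  frequency: 1.09                   # Hz
  phase: 0.0                        # rad

plan:
  dt: 0.01                          # s
  duration: 100.0                   # s
  steady_window: [30.0, 90.0]       # s
  controller: passive               # passive | active

noise:                              # synthetic marker recordings
  noise_sd: 0.0005                  # m
  seed: 0
  rate: 100.0                       # Hz
  duration: 120.0                   # s
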