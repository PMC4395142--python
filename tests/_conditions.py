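"""Shared simulation conditions for the behavioural test suites.

One place defines the study conditions (defaults everywhere, 100 s runs,
30-90 s steady window) and caches the handful of expensive simulation
runs that several tests score.
"""

from __future__ import annotations

from functools import lru_cache

from skyarm import (
    ArmParameters,
    GainSet,
    OscillationSpec,
    SimulationPlan,
    analyze_record,
    simulate,
)

WINDOW = (30.0, 90.0)


def _plan(controller: str) -> SimulationPlan:
    return SimulationPlan(duration=100.0, steady_window=WINDOW, controller=controller)


@lru_cache(maxsize=None)
def active_condition(damper: float):
    """Jerk and amplitude summaries for the active controller with a
    diagonal virtual damper of the given magnitude (0 = baseline)."""
    params = ArmParameters.default()
    gains = GainSet().with_damper(damper)
    rec = simulate(params, gains, OscillationSpec(), _plan("active"))
    return analyze_record(rec, OscillationSpec(), WINDOW)


@lru_cache(maxsize=None)
def passive_condition(stiffness_scale: float):
    """Jerk and amplitude summaries for the passive controller with the
    standard stiffness matrix scaled by the given factor."""
    params = ArmParameters.default()
    gains = GainSet().with_stiffness_scale(stiffness_scale)
    rec = simulate(params, gains, OscillationSpec(), _plan("passive"))
    return analyze_record(rec, OscillationSpec(), WINDOW)
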