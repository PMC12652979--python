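"""Event-segmented integration under treatment schedules and outcome calls.

Treatments are step changes of the external inputs (stressor addition,
escalation, washout, autophagy-inducer addition) at given times.  The state is
continuous across events; only the inputs jump, so integration restarts at
each event with the pre-event state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from erswitch.model import (
    FIELD_NAMES_INPUT,
    STATE_NAMES,
    ModelState,
    ParameterSet,
    StressorInput,
    _jac_raw,
    _rhs_raw,
)

__all__ = [
    "TreatmentEvent",
    "TreatmentSchedule",
    "Trajectory",
    "OutcomeLabel",
    "IntegrationError",
    "simulate",
    "classify_outcome",
    "detect_transient_peak",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
DEFAULT_HORIZON = 200.0
POINTS_PER_SEGMENT = 500


class IntegrationError(RuntimeError):
    """Integrator failure; carries the failing segment's time interval."""

    def __init__(self, message: str, segment: tuple[float, float]):
        super().__init__(f"{message} (segment t = {segment[0]}..{segment[1]})")
        self.segment = segment


@dataclass(frozen=True)
class TreatmentEvent:
    """Step change of one stressor-input field at a given time."""

    time: float
    field: str
    value: float

    def validate(self) -> None:
        if self.field not in FIELD_NAMES_INPUT:
            raise ValueError(
                f"unknown stressor-input field {self.field!r};"
                f" expected one of {FIELD_NAMES_INPUT}"
            )
        if self.time < 0.0:
            raise ValueError("event time must be >= 0")
        if self.value < 0.0:
            raise ValueError("event value must be >= 0")


@dataclass(frozen=True)
class TreatmentSchedule:
    """Initial inputs plus an ordered list of step-change events."""

    initial_input: StressorInput
    events: tuple[TreatmentEvent, ...] = ()
    t_end: float = DEFAULT_HORIZON

    def __post_init__(self):
        object.__setattr__(self, "events", tuple(self.events))

    def validate(self) -> None:
        self.initial_input.validate()
        times = [e.time for e in self.events]
        for e in self.events:
            e.validate()
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if times and times[-1] >= self.t_end:
            raise ValueError("all event times must be < t_end")
        if self.t_end <= 0.0:
            raise ValueError("t_end must be > 0")

    def input_at(self, t: float) -> StressorInput:
        """The (piecewise-constant) input in effect at time t (right limit)."""
        inp = self.initial_input
        for e in self.events:
            if e.time <= t:
                inp = replace(inp, **{e.field: e.value})
        return inp

    def segments(self) -> list[tuple[float, float, StressorInput]]:
        """(t0, t1, input) pieces covering [0, t_end]."""
        cuts = [0.0] + [e.time for e in self.events] + [self.t_end]
        inp = self.initial_input
        out = []
        for i, (t0, t1) in enumerate(zip(cuts, cuts[1:])):
            if i > 0:
                e = self.events[i - 1]
                inp = replace(inp, **{e.field: e.value})
            out.append((t0, t1, inp))
        return out

    def with_event(self, event: TreatmentEvent) -> "TreatmentSchedule":
        evs = sorted(self.events + (event,), key=lambda e: e.time)
        return replace(self, events=tuple(evs))


@dataclass
class Trajectory:
    """Dense solution: times (event times appear twice, pre/post), states,
    the schedule that produced it, and integrator statistics."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 5), columns in STATE_NAMES order
    schedule: TreatmentSchedule
    params: ParameterSet
    integrator_stats: dict = field(default_factory=dict)

    def variable(self, name: str) -> np.ndarray:
        if name not in STATE_NAMES:
            raise ValueError(f"unknown state variable {name!r}")
        return self.states[:, STATE_NAMES.index(name)]

    @property
    def final_state(self) -> ModelState:
        return ModelState.from_array(self.states[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, **{n: self.variable(n) for n in STATE_NAMES}}
        )


@dataclass(frozen=True)
class OutcomeLabel:
    """Qualitative outcome of a treatment simulation.

    ``onset_time_apoptosis`` is the first time APO-A crosses its threshold
    (present iff the label is apoptosis); ``aut_peak`` is the (time, height)
    of the maximal AUT-A excursion when AUT-A is transient.
    """

    label: str  # homeostasis | autophagy | apoptosis
    onset_time_apoptosis: float | None = None
    aut_peak: tuple[float, float] | None = None


def simulate(params: ParameterSet, schedule: TreatmentSchedule,
             init: ModelState, rtol: float = DEFAULT_RTOL,
             atol: float = DEFAULT_ATOL,
             points_per_segment: int = POINTS_PER_SEGMENT) -> Trajectory:
    """Integrate the model piecewise between events with a stiff-capable method.

    Dense output on >= ``points_per_segment`` points per segment plus the
    segment endpoints; event times appear twice in the grid (pre/post event).
    """
    params.validate()
    schedule.validate()
    init.validate(params, tol=1e-9)

    y = init.to_array()
    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    stats = {"n_segments": 0, "nfev": 0, "njev": 0, "rtol": rtol, "atol": atol}

    for t0, t1, inp in schedule.segments():
        args = (params, inp.stress, inp.tg, inp.dtt, inp.kaua_mult)
        t_eval = np.linspace(t0, t1, max(points_per_segment, 2))
        sol = solve_ivp(
            lambda t, y, *a: _rhs_raw(y, *a),
            (t0, t1),
            y,
            method="LSODA",
            jac=lambda t, y, *a: _jac_raw(y, *a),
            args=args,
            rtol=rtol,
            atol=atol,
            t_eval=t_eval,
        )
        if not sol.success:
            raise IntegrationError(sol.message, (t0, t1))
        times_out.append(sol.t)
        states_out.append(sol.y.T)
        y = sol.y[:, -1].copy()
        stats["n_segments"] += 1
        stats["nfev"] += sol.nfev
        stats["njev"] += getattr(sol, "njev", 0) or 0

    times = np.concatenate(times_out)
    states = np.vstack(states_out)
    # the integrator may undershoot the box by round-off; clip within tolerance
    np.clip(states, 0.0, None, out=states)
    return Trajectory(times=times, states=states, schedule=schedule,
                      params=params, integrator_stats=stats)


def classify_outcome(traj: Trajectory, theta_apo: float | None = None,
                     theta_aut: float | None = None,
                     tail_fraction: float = 0.1) -> OutcomeLabel:
    """Label a trajectory as homeostasis, autophagy, or apoptosis.

    Apoptosis iff APO-A exceeds ``theta_apo`` on the entire final
    ``tail_fraction`` of the horizon; else autophagy iff AUT-A exceeds
    ``theta_aut`` there; else homeostasis.  Default thresholds are half the
    respective total pools.
    """
    p = traj.params
    theta_apo = 0.5 * p.apo_t if theta_apo is None else theta_apo
    theta_aut = 0.5 * p.aut_t if theta_aut is None else theta_aut

    last_event = max((e.time for e in traj.schedule.events), default=0.0)
    horizon = traj.schedule.t_end
    if horizon - last_event < 10.0:
        raise ValueError(
            "trajectory horizon extends less than 10 time units beyond the"
            " last event; increase t_end"
        )

    tail = traj.times >= horizon - tail_fraction * (horizon - last_event)
    apo = traj.variable("apo_a")
    aut = traj.variable("aut_a")

    if np.all(apo[tail] > theta_apo):
        crossing = np.nonzero(apo > theta_apo)[0][0]
        peak = detect_transient_peak(traj, "aut_a")
        return OutcomeLabel("apoptosis",
                            onset_time_apoptosis=float(traj.times[crossing]),
                            aut_peak=peak)
    if np.all(aut[tail] > theta_aut):
        return OutcomeLabel("autophagy")
    return OutcomeLabel("homeostasis")


def detect_transient_peak(traj: Trajectory, variable: str,
                          falloff: float = 0.25) -> tuple[float, float] | None:
    """(time, height) of the global maximum if the trace later falls below
    ``falloff`` x that height before the horizon; ``None`` otherwise."""
    x = traj.variable(variable)
    k = int(np.argmax(x))
    height = float(x[k])
    if height <= 0.0:
        return None
    if np.any(x[k:] < falloff * height):
        return (float(traj.times[k]), height)
    return None


def constant_schedule(inp: StressorInput,
                      t_end: float = DEFAULT_HORIZON) -> TreatmentSchedule:
    """Convenience: a schedule with no events."""
    return TreatmentSchedule(initial_input=inp, events=(), t_end=t_end)
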