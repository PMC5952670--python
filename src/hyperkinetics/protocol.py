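"""Protocol schedules: the timed events that drive a biosensor recording.

A recording is described by an ordered list of events on a time axis in
minutes: H2O2 pulses (``pulse_start``/``pulse_end`` with a concentration in
µM), intracellular pH clamps (``ph_clamp_start`` with a target pH), and
pharmacological treatment windows (``treatment_start``/``treatment_end``).
The same schedule object drives both the forward simulation and the phase
segmentation of measured traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "Event",
    "ProtocolSchedule",
    "ScheduleError",
    "default_two_pulse_schedule",
    "single_pulse_schedule",
    "fine_sampling_schedule",
    "ph_clamp_schedule",
]

EVENT_KINDS = frozenset(
    {"pulse_start", "pulse_end", "ph_clamp_start", "treatment_start", "treatment_end"}
)


class ScheduleError(ValueError):
    """Raised for malformed protocol schedules."""


@dataclass(frozen=True)
class Event:
    """A single protocol event.

    Parameters
    ----------
    t_min : float
        Event time in minutes from recording start.
    kind : str
        One of ``pulse_start``, ``pulse_end``, ``ph_clamp_start``,
        ``treatment_start``, ``treatment_end``.
    conc_uM : float, optional
        H2O2 concentration for ``pulse_start`` events (µM).
    ph : float, optional
        Target intracellular pH for ``ph_clamp_start`` events.
    """

    t_min: float
    kind: str
    conc_uM: float | None = None
    ph: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ScheduleError(f"unknown event kind: {self.kind!r}")
        if self.kind == "pulse_start" and (self.conc_uM is None or self.conc_uM < 0):
            raise ScheduleError("pulse_start requires a non-negative conc_uM")
        if self.kind == "ph_clamp_start" and self.ph is None:
            raise ScheduleError("ph_clamp_start requires a target ph")


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered event list plus recording duration and sampling interval.

    Invariants checked on construction: events are time-ordered and inside
    the recording, ``pulse_start``/``pulse_end`` strictly alternate, and the
    sampling interval is positive.
    """

    events: tuple[Event, ...]
    duration_min: float
    sample_interval_s: float = 20.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        if self.sample_interval_s <= 0:
            raise ScheduleError("sample_interval_s must be > 0")
        if self.duration_min <= 0:
            raise ScheduleError("duration_min must be > 0")
        times = [e.t_min for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ScheduleError("events must be time-ordered")
        if any(t < 0 or t > self.duration_min for t in times):
            raise ScheduleError("event outside recording window")
        state = "closed"
        for e in self.events:
            if e.kind == "pulse_start":
                if state == "open":
                    raise ScheduleError("pulse_start before previous pulse_end")
                state = "open"
            elif e.kind == "pulse_end":
                if state != "open":
                    raise ScheduleError("pulse_end without matching pulse_start")
                state = "closed"
        if state == "open":
            raise ScheduleError("unterminated pulse (missing pulse_end)")

    # -- derived views -------------------------------------------------

    @property
    def pulses(self) -> list[tuple[float, float, float]]:
        """Pulses as ``(t_start, t_end, conc_uM)`` triples, in order."""
        out: list[tuple[float, float, float]] = []
        start: Event | None = None
        for e in self.events:
            if e.kind == "pulse_start":
                start = e
            elif e.kind == "pulse_end":
                assert start is not None
                out.append((start.t_min, e.t_min, float(start.conc_uM)))
                start = None
        return out

    @property
    def ph_clamps(self) -> list[tuple[float, float]]:
        """pH-clamp events as ``(t_start, target_ph)`` pairs."""
        return [(e.t_min, float(e.ph)) for e in self.events if e.kind == "ph_clamp_start"]

    @property
    def treatments(self) -> list[tuple[float, float]]:
        """Treatment windows ``(t_start, t_end)``; an unmatched start runs to the end."""
        out = []
        t0 = None
        for e in self.events:
            if e.kind == "treatment_start":
                t0 = e.t_min
            elif e.kind == "treatment_end" and t0 is not None:
                out.append((t0, e.t_min))
                t0 = None
        if t0 is not None:
            out.append((t0, self.duration_min))
        return out

    @property
    def final_pulse_end(self) -> float | None:
        p = self.pulses
        return p[-1][1] if p else None

    def sample_times_min(self) -> "np.ndarray":
        import numpy as np

        dt = self.sample_interval_s / 60.0
        n = int(np.floor(self.duration_min / dt)) + 1
        return np.arange(n) * dt

    def external_h2o2(self, t_min: float) -> float:
        """Scheduled extracellular H2O2 concentration at time ``t_min`` (µM)."""
        for t0, t1, conc in self.pulses:
            if t0 <= t_min < t1:
                return conc
        return 0.0

    def with_sampling(self, sample_interval_s: float) -> "ProtocolSchedule":
        return replace(self, sample_interval_s=sample_interval_s)


def default_two_pulse_schedule(
    baseline_min: float = 20.0,
    pulse1_uM: float = 50.0,
    pulse1_min: float = 5.0,
    washout_min: float = 10.0,
    pulse2_uM: float = 500.0,
    pulse2_min: float = 4.0,
    recovery_min: float = 12.0,
    sample_interval_s: float = 20.0,
) -> ProtocolSchedule:
    """Standard recording: 20 min baseline, a submaximal 50 µM pulse, washout,
    then a saturating 500 µM pulse followed by spontaneous recovery."""
    t1 = baseline_min
    t2 = t1 + pulse1_min
    t3 = t2 + washout_min
    t4 = t3 + pulse2_min
    events = (
        Event(t1, "pulse_start", conc_uM=pulse1_uM),
        Event(t2, "pulse_end"),
        Event(t3, "pulse_start", conc_uM=pulse2_uM),
        Event(t4, "pulse_end"),
    )
    return ProtocolSchedule(events, duration_min=t4 + recovery_min,
                            sample_interval_s=sample_interval_s)


def single_pulse_schedule(
    baseline_min: float = 20.0,
    conc_uM: float = 500.0,
    pulse_min: float = 4.0,
    recovery_min: float = 15.0,
    sample_interval_s: float = 20.0,
) -> ProtocolSchedule:
    """Single saturating pulse, used for compartment comparisons."""
    events = (
        Event(baseline_min, "pulse_start", conc_uM=conc_uM),
        Event(baseline_min + pulse_min, "pulse_end"),
    )
    return ProtocolSchedule(
        events,
        duration_min=baseline_min + pulse_min + recovery_min,
        sample_interval_s=sample_interval_s,
    )


def fine_sampling_schedule(
    baseline_min: float = 1.0,
    conc_uM: float = 500.0,
    pulse_min: float = 0.5,
    recovery_min: float = 2.0,
    sample_interval_s: float = 0.5,
    ph_clamp: float | None = None,
) -> ProtocolSchedule:
    """Short, finely sampled single-pulse recording for fast recovery
    kinetics (rates of tens per minute are unresolvable at 20 s sampling)."""
    events: list[Event] = []
    if ph_clamp is not None:
        events.append(Event(0.0, "ph_clamp_start", ph=ph_clamp))
    events.append(Event(baseline_min, "pulse_start", conc_uM=conc_uM))
    events.append(Event(baseline_min + pulse_min, "pulse_end"))
    return ProtocolSchedule(
        tuple(events),
        duration_min=baseline_min + pulse_min + recovery_min,
        sample_interval_s=sample_interval_s,
    )


def ph_clamp_schedule(ph: float, baseline_min: float = 3.0,
                      conc_uM: float = 500.0, pulse_min: float = 0.5,
                      recovery_min: float = 2.0,
                      sample_interval_s: float = 0.5) -> ProtocolSchedule:
    """Finely sampled pH-clamp recording: the clamp starts at t=0 and the
    longer baseline lets intracellular pH equilibrate fully (several clamp
    time constants) before the pulse, as in ionophore experiments where
    the oxidant is applied only once equilibrium is reached."""
    return fine_sampling_schedule(
        baseline_min=baseline_min, conc_uM=conc_uM, pulse_min=pulse_min,
        recovery_min=recovery_min, sample_interval_s=sample_interval_s,
        ph_clamp=ph,
    )
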