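"""Operant event logs: parsing, response-type classification, session summaries.

Free-operant sessions produce a timestamped stream of nose-pokes at two
ports.  Only the active port is ever reinforced, on a fixed-ratio (FR)
schedule: every ``fr``-th eligible active poke delivers the outcome and
opens a time-out (default 20 s) during which further pokes are recorded
but have no programmed consequence.  Downstream waveform statistics group
pokes into four response types: ``active_rewarded``, ``active_punished``,
``active_nonrewarded`` and ``inactive``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Phase",
    "Port",
    "Outcome",
    "ResponseType",
    "BehaviorEvent",
    "EventLog",
    "EventLogError",
    "parse_event_log",
    "classify_responses",
    "session_summary",
]


class Phase(str, enum.Enum):
    """Experimental phase: self-administration, punishment, extinction, or seeking test."""

    SA = "SA"
    PUN = "PUN"
    EXT = "EXT"
    TEST = "TEST"


class Port(str, enum.Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"


class Outcome(str, enum.Enum):
    NICOTINE = "nicotine"
    NICOTINE_SHOCK = "nicotine_shock"
    SALINE = "saline"
    CUE_ONLY = "cue_only"
    NONE = "none"


class ResponseType(str, enum.Enum):
    ACTIVE_REWARDED = "active_rewarded"
    ACTIVE_PUNISHED = "active_punished"
    ACTIVE_NONREWARDED = "active_nonrewarded"
    INACTIVE = "inactive"


#: Outcomes that deliver the reinforcer (drug or its stand-in).
REINFORCED_OUTCOMES = frozenset(
    {Outcome.NICOTINE, Outcome.NICOTINE_SHOCK, Outcome.SALINE, Outcome.CUE_ONLY}
)


class EventLogError(ValueError):
    """Raised for malformed, inconsistent, or unclassifiable event logs."""


@dataclass
class BehaviorEvent:
    """A single nose-poke.

    Parameters
    ----------
    time_s : float
        Session time in seconds from session start.
    port : Port
        Which nose-poke port was entered.
    outcome : Outcome
        Programmed consequence of the poke (``none`` for inactive-port,
        sub-ratio, and time-out pokes).
    in_timeout : bool
        True if the poke fell inside the post-reinforcement time-out.
    response_type : ResponseType | None
        Analysis grouping; ``None`` until :func:`classify_responses` runs.
    """

    time_s: float
    port: Port
    outcome: Outcome = Outcome.NONE
    in_timeout: bool = False
    response_type: ResponseType | None = None

    def __post_init__(self) -> None:
        self.port = Port(self.port)
        self.outcome = Outcome(self.outcome)
        if self.response_type is not None:
            self.response_type = ResponseType(self.response_type)
        if self.port is Port.INACTIVE and self.outcome is not Outcome.NONE:
            raise EventLogError(
                f"inactive-port poke at t={self.time_s} cannot have outcome {self.outcome.value}"
            )
        if self.in_timeout and self.outcome is not Outcome.NONE:
            raise EventLogError(
                f"time-out poke at t={self.time_s} cannot have outcome {self.outcome.value}"
            )


@dataclass
class EventLog:
    """An ordered session of :class:`BehaviorEvent`."""

    phase: Phase
    events: list[BehaviorEvent] = field(default_factory=list)
    duration: float = 3600.0
    session_id: str = "session"

    def __post_init__(self) -> None:
        self.phase = Phase(self.phase)
        times = [e.time_s for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise EventLogError("event times must be nondecreasing")
        if times and (times[0] < 0 or times[-1] > self.duration):
            raise EventLogError("event times must lie within [0, duration]")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time_s for e in self.events], dtype=float)

    @property
    def is_classified(self) -> bool:
        return all(e.response_type is not None for e in self.events)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with one row per event."""
        return pd.DataFrame(
            {
                "time_s": [e.time_s for e in self.events],
                "port": [e.port.value for e in self.events],
                "outcome": [e.outcome.value for e in self.events],
                "response_type": [
                    "" if e.response_type is None else e.response_type.value
                    for e in self.events
                ],
                "flags": ["timeout" if e.in_timeout else "" for e in self.events],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def parse_event_log(
    path,
    phase: Phase | str,
    duration: float = 3600.0,
    session_id: str = "session",
) -> EventLog:
    """Read an event-log CSV into a validated :class:`EventLog`.

    Expected dialect: comma-separated with header ``time_s,port,outcome,flags``
    (``outcome``, ``flags`` and ``response_type`` optional; unknown columns
    ignored).  ``flags`` is a semicolon-separated token list; the ``timeout``
    token marks time-out pokes.  Malformed rows raise :class:`EventLogError`
    naming the offending row (1-based, excluding the header).
    """
    phase = Phase(phase)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "time_s" not in df.columns or "port" not in df.columns:
        raise EventLogError(f"{path}: missing required columns time_s/port")
    events: list[BehaviorEvent] = []
    prev_t = -np.inf
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        try:
            t = float(d["time_s"])
        except ValueError as exc:
            raise EventLogError(f"row {i}: unparseable time {d['time_s']!r}") from exc
        if t < prev_t:
            raise EventLogError(f"row {i}: time {t} precedes previous event at {prev_t}")
        prev_t = t
        try:
            port = Port(d["port"])
        except ValueError as exc:
            raise EventLogError(f"row {i}: unknown port code {d['port']!r}") from exc
        outcome_code = d.get("outcome", "") or "none"
        try:
            outcome = Outcome(outcome_code)
        except ValueError as exc:
            raise EventLogError(f"row {i}: unknown outcome code {outcome_code!r}") from exc
        flags = {tok for tok in d.get("flags", "").split(";") if tok}
        rtype = d.get("response_type", "") or None
        try:
            events.append(
                BehaviorEvent(
                    time_s=t,
                    port=port,
                    outcome=outcome,
                    in_timeout="timeout" in flags,
                    response_type=rtype,
                )
            )
        except (ValueError, EventLogError) as exc:
            raise EventLogError(f"row {i}: {exc}") from exc
    if events:
        duration = max(duration, events[-1].time_s)
    return EventLog(phase=phase, events=events, duration=duration, session_id=session_id)


def classify_responses(
    log: EventLog, fr: int = 3, timeout: float = 20.0
) -> EventLog:
    """Assign a response type to every event by replaying the FR schedule.

    The FR counter counts active pokes outside time-out; when it reaches
    ``fr`` the poke is reinforced, the counter resets, and a time-out of
    ``timeout`` seconds opens.  The time-out window is open on both ends,
    ``(t_reinforced, t_reinforced + timeout)``: a poke exactly at expiry
    counts toward the next ratio.  Recorded outcomes, where present, are
    authoritative for the rewarded/punished split and are validated
    against the replayed schedule; a reinforcement recorded at the wrong
    ratio count raises :class:`EventLogError`.

    Idempotent: classifying an already-classified log reproduces it.
    """
    if fr not in (1, 2, 3):
        raise EventLogError(f"fixed-ratio requirement must be 1, 2 or 3, got {fr}")
    if timeout < 0:
        raise EventLogError("timeout must be nonnegative")
    has_outcomes = any(e.outcome is not Outcome.NONE for e in log.events)
    out: list[BehaviorEvent] = []
    counter = 0
    timeout_until = -np.inf  # end of current time-out window (exclusive)
    for i, ev in enumerate(log.events):
        if ev.port is Port.INACTIVE:
            out.append(
                replace(ev, in_timeout=ev.time_s < timeout_until,
                        response_type=ResponseType.INACTIVE)
            )
            continue
        # active port
        if ev.time_s < timeout_until:
            if ev.outcome is not Outcome.NONE:
                raise EventLogError(
                    f"event {i} at t={ev.time_s}: reinforcement recorded during time-out"
                )
            out.append(
                replace(ev, in_timeout=True, response_type=ResponseType.ACTIVE_NONREWARDED)
            )
            continue
        counter += 1
        if counter < fr:
            if ev.outcome in REINFORCED_OUTCOMES:
                raise EventLogError(
                    f"event {i} at t={ev.time_s}: reinforcement recorded at ratio count "
                    f"{counter} < FR{fr}"
                )
            out.append(
                replace(ev, in_timeout=False, response_type=ResponseType.ACTIVE_NONREWARDED)
            )
            continue
        # ratio complete: reinforced poke
        counter = 0
        timeout_until = ev.time_s + timeout
        outcome = ev.outcome
        if outcome is Outcome.NONE:
            if has_outcomes:
                raise EventLogError(
                    f"event {i} at t={ev.time_s}: schedule predicts reinforcement "
                    "but none recorded"
                )
            outcome = _phase_default_outcome(log.phase)
        rtype = (
            ResponseType.ACTIVE_PUNISHED
            if outcome is Outcome.NICOTINE_SHOCK
            else ResponseType.ACTIVE_REWARDED
        )
        if outcome is Outcome.NICOTINE_SHOCK and log.phase is not Phase.PUN:
            raise EventLogError(
                f"event {i} at t={ev.time_s}: shock outcome outside punishment phase"
            )
        out.append(replace(ev, in_timeout=False, outcome=outcome, response_type=rtype))
    return EventLog(
        phase=log.phase, events=out, duration=log.duration, session_id=log.session_id
    )


def _phase_default_outcome(phase: Phase) -> Outcome:
    # For logs without recorded outcomes: reinforced pokes yield the phase's
    # programmed consequence (punishment draws cannot be reconstructed, so PUN
    # defaults to the unpunished outcome).
    if phase in (Phase.SA, Phase.PUN):
        return Outcome.NICOTINE
    if phase is Phase.EXT:
        return Outcome.SALINE
    return Outcome.CUE_ONLY


def session_summary(log: EventLog) -> dict:
    """Per-session behavioral counts and hourly rates.

    Infusions count rewarded plus punished pokes (both deliver the
    reinforcer).  Requires a classified log.
    """
    if not log.is_classified:
        raise EventLogError("session_summary requires a classified log")
    counts = {rt: 0 for rt in ResponseType}
    for ev in log.events:
        counts[ev.response_type] += 1
    infusions = counts[ResponseType.ACTIVE_REWARDED] + counts[ResponseType.ACTIVE_PUNISHED]
    active = infusions + counts[ResponseType.ACTIVE_NONREWARDED]
    hours = log.duration / 3600.0
    summary = {
        "session_id": log.session_id,
        "phase": log.phase.value,
        "n_events": len(log),
        "infusions": infusions,
        "active_pokes": active,
        "inactive_pokes": counts[ResponseType.INACTIVE],
        "nonrewarded_active_pokes": counts[ResponseType.ACTIVE_NONREWARDED],
        "punished_pokes": counts[ResponseType.ACTIVE_PUNISHED],
        "duration_s": log.duration,
    }
    if hours > 0:
        summary["infusions_per_hour"] = infusions / hours
        summary["active_per_hour"] = active / hours
        summary["inactive_per_hour"] = counts[ResponseType.INACTIVE] / hours
    return summary
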