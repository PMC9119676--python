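"""Synthetic operant sessions with matching two-channel photometry.

Generates behavioral event streams under FR/punishment schedules and the
demodulated fluorescence a fiber-photometry rig would save for such a
session, with known ground truth, so that every downstream stage
(preprocessing, epoching, inference) can be tested without real
recordings.

Signal model
------------
The calcium-dependent channel (470 nm excitation) is::

    F470(t) = baseline_470 * (1 - bleach(t)) + artifact(t)
              + baseline_470 * sum_k amp_k * kernel(t - t_k) + noise470(t)

and the isosbestic control channel (405 nm excitation) is the same
minus the event-locked transients::

    F405(t) = baseline_405 * (1 - bleach(t)) + gain405 * artifact(t) + noise405(t)

where ``bleach(t) = bleach_frac * (1 - exp(-t / bleach_tau))`` is slow
photobleaching, ``artifact(t)`` is a shared Ornstein-Uhlenbeck motion
artifact (the common-mode disturbance isosbestic regression exists to
remove), and the calcium transient kernel is a peak-normalized double
exponential,

    kernel(t) = (exp(-t/tau_decay) - exp(-t/tau_rise)) / peak,  t >= 0,

so that ``amp_k`` is the transient's peak in dF/F units of the
unbleached baseline.  Transient amplitude depends on response type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .behavior import (
    BehaviorEvent,
    EventLog,
    EventLogError,
    Outcome,
    Phase,
    Port,
    ResponseType,
    classify_responses,
)
from .preprocess import PhotometryRecording

__all__ = ["SyntheticConfig", "GroundTruth", "simulate_behavior", "simulate_photometry",
           "simulate_session"]


def _default_amp() -> dict:
    # Peak dF/F per response type.  Real recordings show transients after
    # every poke type, largest for punished and reinforced pokes.
    return {
        ResponseType.ACTIVE_REWARDED: 0.08,
        ResponseType.ACTIVE_PUNISHED: 0.12,
        ResponseType.ACTIVE_NONREWARDED: 0.03,
        ResponseType.INACTIVE: 0.02,
    }


@dataclass
class SyntheticConfig:
    """Parameters of a simulated session.

    Times are seconds, fluorescence arbitrary units (a.u.), amplitudes
    dF/F fractions of the unbleached 470 baseline.
    """

    fs_native: float = 1017.25     # acquisition rate of the saved signals, Hz
    duration: float = 3600.0       # session length, s
    phase: Phase = Phase.SA
    fr: int = 3                    # fixed-ratio requirement
    timeout: float = 20.0          # post-reinforcement time-out, s
    punish_prob: float = 0.5       # P(footshock | reinforced poke), PUN phase only
    rate_active: float = 0.02      # active-port poke hazard, events/s
    rate_inactive: float = 0.008   # inactive-port poke hazard, events/s
    tau_rise: float = 0.2          # transient rise time constant, s
    tau_decay: float = 1.5         # transient decay time constant, s
    amp: dict = field(default_factory=_default_amp)   # response type -> peak dF/F
    noise_sd: float = 31.0         # per-channel white noise SD at fs_native, a.u.
    bleach_tau: float = 1200.0     # photobleaching time constant, s
    bleach_frac: float = 0.2       # asymptotic fractional fluorescence loss
    artifact_sd: float = 2.0       # stationary SD of shared OU motion artifact, a.u.
    artifact_tau: float = 5.0      # OU correlation time, s
    artifact_gain_405: float = 1.0 # artifact amplitude in 405 relative to 470
    baseline_470: float = 100.0    # mean unbleached fluorescence, a.u.
    baseline_405: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.phase = Phase(self.phase)
        self.amp = {ResponseType(k): float(v) for k, v in self.amp.items()}
        if self.fs_native <= 0 or self.duration <= 0:
            raise ValueError("fs_native and duration must be positive")
        if self.fr not in (1, 2, 3):
            raise ValueError(f"fr must be 1, 2 or 3, got {self.fr}")
        if not 0.0 <= self.punish_prob <= 1.0:
            raise ValueError("punish_prob must lie in [0, 1]")
        if not self.tau_rise < self.tau_decay:
            raise ValueError("tau_rise must be smaller than tau_decay")
        for name in ("timeout", "rate_active", "rate_inactive", "tau_rise",
                     "noise_sd", "bleach_tau", "bleach_frac", "artifact_sd",
                     "artifact_tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class GroundTruth:
    """What the simulator actually injected, for recovery checks."""

    transient_times: np.ndarray          # s; subset of the event-log times
    transient_amplitudes: np.ndarray     # peak dF/F
    response_types: list[ResponseType]   # per transient
    bleach: np.ndarray | None = None     # per-sample bleach fraction realization
    artifact: np.ndarray | None = None   # per-sample shared artifact, a.u.

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.transient_times,
                "amplitude_dff": self.transient_amplitudes,
                "response_type": [rt.value for rt in self.response_types],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _behavior_rng(config: SyntheticConfig) -> tuple[np.random.Generator, np.random.Generator]:
    # Dedicated substreams: poke times and punishment draws are reproducible
    # independently of each other and of the photometry noise stream.
    seq = np.random.SeedSequence(config.seed)
    pokes, punish, _signal = seq.spawn(3)
    return np.random.default_rng(pokes), np.random.default_rng(punish)


def _signal_rng(config: SyntheticConfig) -> np.random.Generator:
    seq = np.random.SeedSequence(config.seed)
    _pokes, _punish, signal = seq.spawn(3)
    return np.random.default_rng(signal)


def _poisson_times(rng: np.random.Generator, rate: float, duration: float) -> np.ndarray:
    if rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def simulate_behavior(config: SyntheticConfig) -> EventLog:
    """Simulate a session's nose-poke stream and classify it.

    Pokes at each port follow independent homogeneous Poisson processes.
    The FR schedule, 20-s time-out and (in the punishment phase) the
    independent ``punish_prob`` shock draw are applied while walking the
    merged stream; time-out pokes are emitted and flagged but never
    reinforced.  Identical seeds give identical logs.
    """
    poke_rng, punish_rng = _behavior_rng(config)
    t_active = _poisson_times(poke_rng, config.rate_active, config.duration)
    t_inactive = _poisson_times(poke_rng, config.rate_inactive, config.duration)
    merged = sorted(
        [(t, Port.ACTIVE) for t in t_active] + [(t, Port.INACTIVE) for t in t_inactive]
    )
    events: list[BehaviorEvent] = []
    counter = 0
    timeout_until = -np.inf
    for t, port in merged:
        if port is Port.INACTIVE:
            events.append(BehaviorEvent(t, port, Outcome.NONE, in_timeout=t < timeout_until))
            continue
        if t < timeout_until:
            events.append(BehaviorEvent(t, port, Outcome.NONE, in_timeout=True))
            continue
        counter += 1
        if counter < config.fr:
            events.append(BehaviorEvent(t, port, Outcome.NONE))
            continue
        counter = 0
        timeout_until = t + config.timeout
        if config.phase is Phase.SA:
            outcome = Outcome.NICOTINE
        elif config.phase is Phase.PUN:
            punished = punish_rng.random() < config.punish_prob
            outcome = Outcome.NICOTINE_SHOCK if punished else Outcome.NICOTINE
        elif config.phase is Phase.EXT:
            outcome = Outcome.SALINE
        else:  # TEST: response-contingent nicotine cue, no drug
            outcome = Outcome.CUE_ONLY
        events.append(BehaviorEvent(t, port, outcome))
    log = EventLog(
        phase=config.phase,
        events=events,
        duration=config.duration,
        session_id=f"sim-{config.phase.value}-{config.seed}",
    )
    return classify_responses(log, fr=config.fr, timeout=config.timeout)


def transient_kernel(
    tau_rise: float, tau_decay: float, fs: float, cut: float = 1e-4
) -> np.ndarray:
    """Peak-normalized double-exponential kernel sampled at ``fs``.

    Truncated where the decay envelope falls below ``cut`` of the peak.
    """
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    peak = math.exp(-t_peak / tau_decay) - math.exp(-t_peak / tau_rise)
    t_end = -tau_decay * math.log(cut * peak)
    t = np.arange(0.0, t_end, 1.0 / fs)
    return (np.exp(-t / tau_decay) - np.exp(-t / tau_rise)) / peak


def _ou_process(
    rng: np.random.Generator, n: int, fs: float, sd: float, tau: float
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck sample path via its exact AR(1) discretization."""
    if sd == 0 or tau == 0:
        return np.zeros(n)
    phi = math.exp(-1.0 / (fs * tau))
    innov = rng.standard_normal(n) * sd * math.sqrt(1.0 - phi * phi)
    innov[0] = rng.standard_normal() * sd  # stationary start
    return scipy.signal.lfilter([1.0], [1.0, -phi], innov)


def simulate_photometry(
    events: EventLog, config: SyntheticConfig, keep_realizations: bool = False
) -> tuple[PhotometryRecording, GroundTruth]:
    """Render the two-channel recording for a simulated (classified) event log.

    Event-locked transients are added to the 470 channel only; bleaching
    and the shared motion artifact appear in both channels.  Returns the
    recording together with the injected ground truth.
    """
    if len(events) and (events.times.min() < 0 or events.times.max() > config.duration):
        raise ValueError("event outside the session window")
    if not events.is_classified:
        raise EventLogError("simulate_photometry requires a classified log")
    rng = _signal_rng(config)
    n = int(round(config.duration * config.fs_native))
    t = np.arange(n) / config.fs_native

    bleach = config.bleach_frac * (1.0 - np.exp(-t / config.bleach_tau)) \
        if config.bleach_frac > 0 else np.zeros(n)
    artifact = _ou_process(rng, n, config.fs_native, config.artifact_sd, config.artifact_tau)

    transients = np.zeros(n)
    tr_times, tr_amps, tr_types = [], [], []
    kernel = transient_kernel(config.tau_rise, config.tau_decay, config.fs_native)
    for ev in events:
        amp = config.amp.get(ev.response_type, 0.0)
        tr_times.append(ev.time_s)
        tr_amps.append(amp)
        tr_types.append(ev.response_type)
        if amp == 0.0:
            continue
        i0 = int(round(ev.time_s * config.fs_native))
        seg = kernel[: max(0, n - i0)]
        transients[i0 : i0 + len(seg)] += amp * seg

    noise470 = rng.standard_normal(n) * config.noise_sd
    noise405 = rng.standard_normal(n) * config.noise_sd
    sig470 = config.baseline_470 * (1.0 - bleach + transients) + artifact + noise470
    sig405 = (
        config.baseline_405 * (1.0 - bleach)
        + config.artifact_gain_405 * artifact
        + noise405
    )
    rec = PhotometryRecording(
        fs_native=config.fs_native,
        sig470=sig470,
        sig405=sig405,
        session_id=events.session_id,
        phase=events.phase.value,
    )
    truth = GroundTruth(
        transient_times=np.asarray(tr_times),
        transient_amplitudes=np.asarray(tr_amps),
        response_types=tr_types,
        bleach=bleach if keep_realizations else None,
        artifact=artifact if keep_realizations else None,
    )
    return rec, truth


def simulate_session(
    config: SyntheticConfig,
) -> tuple[EventLog, PhotometryRecording, GroundTruth]:
    """Convenience wrapper: behavior stream plus matching recording."""
    log = simulate_behavior(config)
    rec, truth = simulate_photometry(log, config)
    return log, rec, truth
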