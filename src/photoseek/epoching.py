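"""Event exclusion, peri-event epoch extraction, and baseline z-scoring.

Epochs run from 5 s before to 10 s after each retained nose-poke.  Each
trace is z-scored against the first 4 s of its own baseline (-5 to -1 s
relative to the poke), leaving the final pre-poke second free to express
anticipatory ramps.  Two exclusion rules prevent duplicate traces from
overlapping epochs: pokes within 20 s after a rewarded poke (i.e., all
time-out responses) are dropped, and unrewarded active/inactive pokes
within 5 s after another active/inactive poke are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior import EventLog, EventLogError, ResponseType
from .preprocess import DffSignal

__all__ = ["EpochSet", "exclude_events", "extract_epochs", "zscore_epochs"]

#: Response types whose outcome delivered the reinforcer.
_REWARDED_TYPES = frozenset({ResponseType.ACTIVE_REWARDED, ResponseType.ACTIVE_PUNISHED})


@dataclass
class EpochSet:
    """Matrix of peri-event dF/F traces with response-type labels.

    ``traces`` is (n_traces, n_samples); ``time_axis`` gives each
    column's time in seconds relative to the poke (negative = before).
    """

    traces: np.ndarray
    time_axis: np.ndarray
    labels: list[ResponseType]
    fs: float
    zscored: bool = False
    baseline_window: tuple[float, float] = (-5.0, -1.0)
    n_dropped_boundary: int = 0
    n_dropped_flat: int = 0

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.labels = [ResponseType(lb) for lb in self.labels]
        if self.traces.shape[0] != len(self.labels):
            raise ValueError("one label per trace required")
        if self.traces.shape[1] != self.time_axis.size:
            raise ValueError("time axis must match trace length")

    @property
    def n_traces(self) -> int:
        return self.traces.shape[0]

    def counts(self) -> dict:
        out = {rt: 0 for rt in ResponseType}
        for lb in self.labels:
            out[lb] += 1
        return {rt.value: n for rt, n in out.items()}

    def select(self, response_type: ResponseType | str) -> np.ndarray:
        """Trace matrix restricted to one response type."""
        rt = ResponseType(response_type)
        mask = np.array([lb is rt for lb in self.labels])
        return self.traces[mask]

    def baseline_slice(self) -> slice:
        lo, hi = self.baseline_window
        idx = np.flatnonzero((self.time_axis >= lo) & (self.time_axis < hi))
        if idx.size == 0:
            raise ValueError("baseline window contains no samples")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("traces", data=self.traces)
            f.create_dataset(
                "labels", data=np.array([lb.value for lb in self.labels], dtype="S")
            )
            f.create_dataset("time_axis", data=self.time_axis)
            f.attrs["fs"] = self.fs
            f.attrs["zscored"] = self.zscored
            f.attrs["baseline_window"] = list(self.baseline_window)

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                traces=f["traces"][:],
                time_axis=f["time_axis"][:],
                labels=[s.decode() for s in f["labels"][:]],
                fs=float(f.attrs["fs"]),
                zscored=bool(f.attrs["zscored"]),
                baseline_window=tuple(f.attrs["baseline_window"]),
            )

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (trace, timepoint)."""
        n, m = self.traces.shape
        return pd.DataFrame(
            {
                "trace_id": np.repeat(np.arange(n), m),
                "response_type": np.repeat([lb.value for lb in self.labels], m),
                "time_s": np.tile(self.time_axis, n),
                "z" if self.zscored else "dff": self.traces.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def exclude_events(
    log: EventLog,
    post_reward_window: float = 20.0,
    refractory: float = 5.0,
    punished_counts_as_rewarded: bool = True,
) -> EventLog:
    """Drop nose-pokes whose epochs would duplicate a neighbor's.

    Rule (a): any poke with ``0 < t - t_rewarded <= post_reward_window``
    for some preceding rewarded poke is dropped (this removes all
    time-out responses).  Rule (b): any unrewarded active or inactive
    poke with ``0 < t - t_prev <= refractory`` for some preceding poke at
    either port is dropped; rewarded pokes are never dropped by rule (b).
    Both rules are evaluated against the raw event sequence, so an
    excluded predecessor still disqualifies its successors.  Idempotent.
    """
    if not log.is_classified:
        raise EventLogError("exclude_events requires a classified log")
    rewarded = _REWARDED_TYPES if punished_counts_as_rewarded \
        else frozenset({ResponseType.ACTIVE_REWARDED})
    keep = []
    last_rewarded_t = -np.inf
    prev_t = -np.inf
    for ev in log.events:
        is_rewarded = ev.response_type in rewarded
        drop = 0.0 < ev.time_s - last_rewarded_t <= post_reward_window
        if not is_rewarded:
            drop = drop or (0.0 < ev.time_s - prev_t <= refractory)
        if not drop:
            keep.append(replace(ev))
        if is_rewarded:
            last_rewarded_t = ev.time_s
        prev_t = ev.time_s
    return EventLog(
        phase=log.phase, events=keep, duration=log.duration, session_id=log.session_id
    )


def extract_epochs(
    dff: DffSignal,
    events: EventLog,
    pre: float = 5.0,
    post: float = 10.0,
    baseline: tuple[float, float] = (-5.0, -1.0),
) -> EpochSet:
    """Cut one raw (not yet z-scored) trace per event from the dF/F signal.

    The event is aligned to the nearest sample of the downsampled grid;
    the window holds ``round((pre + post) * fs)`` samples of which
    ``round(pre * fs)`` precede the event sample.  Events whose window
    would run off either end of the signal are dropped and counted in
    ``n_dropped_boundary``.
    """
    if not events.is_classified:
        raise EventLogError("extract_epochs requires a classified log")
    fs = dff.fs
    n_total = int(round((pre + post) * fs))
    n_pre = int(round(pre * fs))
    if n_total < 2:
        raise ValueError("epoch window too short at this sampling rate")
    time_axis = (np.arange(n_total) - n_pre) / fs
    rows, labels, dropped = [], [], 0
    n = dff.dff.size
    for ev in events:
        center = int(round((ev.time_s - dff.t0) * fs))
        lo = center - n_pre
        hi = lo + n_total
        if lo < 0 or hi > n:
            dropped += 1
            continue
        rows.append(dff.dff[lo:hi])
        labels.append(ev.response_type)
    traces = np.array(rows) if rows else np.empty((0, n_total))
    return EpochSet(
        traces=traces,
        time_axis=time_axis,
        labels=labels,
        fs=fs,
        zscored=False,
        baseline_window=baseline,
        n_dropped_boundary=dropped,
    )


def zscore_epochs(epochs: EpochSet, sd_floor: float = 1e-12) -> EpochSet:
    """Baseline-z-score each trace against its own baseline window.

    z = (x - mean(baseline)) / sd(baseline), using the sample SD (ddof=1).
    Traces whose baseline SD falls below ``sd_floor`` carry no usable
    baseline noise estimate; they are dropped and counted in
    ``n_dropped_flat``.  Refuses already-z-scored input.
    """
    if epochs.zscored:
        raise ValueError("epochs are already z-scored")
    sl = epochs.baseline_slice()
    base = epochs.traces[:, sl]
    mu = base.mean(axis=1, keepdims=True)
    sd = base.std(axis=1, ddof=1, keepdims=True)
    ok = sd[:, 0] >= sd_floor
    z = (epochs.traces[ok] - mu[ok]) / sd[ok]
    return EpochSet(
        traces=z if ok.any() else np.empty((0, epochs.traces.shape[1])),
        time_axis=epochs.time_axis,
        labels=[lb for lb, keep in zip(epochs.labels, ok) if keep],
        fs=epochs.fs,
        zscored=True,
        baseline_window=epochs.baseline_window,
        n_dropped_boundary=epochs.n_dropped_boundary,
        n_dropped_flat=int((~ok).sum()),
    )
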