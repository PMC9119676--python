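"""Waveform-level inference on peri-event trace sets.

Two complementary tests, both applied per timepoint along the epoch axis
and both guarded by a consecutive-significance threshold:

* **Bootstrap CI vs. baseline** — does the mean z-scored trace of one
  response type differ from 0?  Traces are resampled with replacement
  (n traces, 5000 iterations by default); the 95% CI from the 2.5th and
  97.5th bootstrap percentiles is expanded about the bootstrap mean by
  sqrt(n/(n-1)) to correct the narrowness bias of the percentile
  bootstrap at finite n.

* **Permutation test between response types** — the observed difference
  of group mean traces is referred to a null distribution built by
  randomly regrouping traces (group sizes preserved; 1000 permutations
  by default), giving a two-sided p per timepoint with the add-one rule
  p >= 1/(n_perm + 1).

Familywise error along the waveform is controlled by a Bonferroni
adjustment of alpha over the number of pairwise comparisons and by
counting only runs of significance sustained for at least 0.25 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .behavior import ResponseType
from .epoching import EpochSet

__all__ = [
    "BootstrapResult",
    "PermutationResult",
    "PairedComparison",
    "bootstrap_ci",
    "permutation_test",
    "bonferroni_alpha",
    "consecutive_filter",
    "mean_window_change",
]


@dataclass
class BootstrapResult:
    """Pointwise bootstrap CI of a mean trace, with significant windows."""

    response_type: ResponseType | None
    time_axis: np.ndarray
    mean_trace: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_traces: int
    n_boot: int
    ci_level: float
    expansion: float
    windows: list[tuple[float, float]] = field(default_factory=list)
    positive_windows: list[tuple[float, float]] = field(default_factory=list)
    negative_windows: list[tuple[float, float]] = field(default_factory=list)
    min_dur: float = 0.25
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_axis,
                "mean": self.mean_trace,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
            }
        )


@dataclass
class PermutationResult:
    """Pointwise permutation p-values for a two-group comparison."""

    pair: tuple[ResponseType | None, ResponseType | None]
    time_axis: np.ndarray
    observed_diff: np.ndarray
    p_values: np.ndarray
    n_perm: int
    alpha: float
    windows: list[tuple[float, float]] = field(default_factory=list)
    min_dur: float = 0.25
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time_axis, "diff": self.observed_diff, "p": self.p_values}
        )


@dataclass
class PairedComparison:
    """Within-trace pre- vs post-event mean dF/F comparison (paired t)."""

    pre_window: tuple[float, float]
    post_window: tuple[float, float]
    n: int
    mean_pre: float
    mean_post: float
    mean_diff: float
    t: float
    df: int
    p: float
    degenerate: bool = False


def consecutive_filter(
    sig_mask, fs: float, min_dur: float = 0.25, t_start: float = 0.0
) -> list[tuple[float, float]]:
    """Maximal runs of True lasting at least ``min_dur`` seconds.

    A run must span ``ceil(min_dur * fs)`` samples.  Windows are returned
    as ``(start_s, end_s)`` on the epoch time axis, where ``t_start`` is
    the time of the mask's first sample and ``end_s`` is the time of the
    run's last significant sample.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    mask = np.asarray(sig_mask, dtype=bool)
    min_run = max(1, math.ceil(min_dur * fs))
    padded = np.concatenate([[False], mask, [False]])
    edges = np.diff(padded.astype(int))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)  # exclusive
    return [
        (t_start + s / fs, t_start + (e - 1) / fs)
        for s, e in zip(starts, ends)
        if e - s >= min_run
    ]


def _resample_means(
    traces: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Bootstrap distribution of the mean trace, (n_boot, n_timepoints).

    Resampling n traces with replacement is realized through multinomial
    resample counts, so the (n_boot x n) weight matrix multiplies the
    trace matrix directly instead of materializing resampled copies.
    """
    n = traces.shape[0]
    counts = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot)
    return (counts / n) @ traces


def bootstrap_ci(
    epochs: EpochSet,
    response_type: ResponseType | str | None = None,
    n_boot: int = 5000,
    ci: float = 0.95,
    min_dur: float = 0.25,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Bootstrap CI of the mean trace for one response type (or all traces).

    The percentile CI is widened about the bootstrap-distribution mean by
    the narrowness-bias factor sqrt(n/(n-1)); significance ("CI excludes
    0", strictly) is then filtered for runs of at least ``min_dur`` s.
    """
    traces = epochs.traces if response_type is None else epochs.select(response_type)
    n = traces.shape[0]
    if n < 2:
        raise ValueError(
            f"bootstrap requires at least 2 traces (narrowness expansion undefined), got {n}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    boot = _resample_means(traces, n_boot, rng)
    lo_q, hi_q = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    lo = np.percentile(boot, lo_q, axis=0)
    hi = np.percentile(boot, hi_q, axis=0)
    center = boot.mean(axis=0)
    factor = math.sqrt(n / (n - 1))
    lo = center - factor * (center - lo)
    hi = center + factor * (hi - center)
    pos = lo > 0
    neg = hi < 0
    kw = dict(fs=epochs.fs, min_dur=min_dur, t_start=float(epochs.time_axis[0]))
    return BootstrapResult(
        response_type=None if response_type is None else ResponseType(response_type),
        time_axis=epochs.time_axis,
        mean_trace=traces.mean(axis=0),
        ci_lo=lo,
        ci_hi=hi,
        n_traces=n,
        n_boot=n_boot,
        ci_level=ci,
        expansion=factor,
        windows=consecutive_filter(pos | neg, **kw),
        positive_windows=consecutive_filter(pos, **kw),
        negative_windows=consecutive_filter(neg, **kw),
        min_dur=min_dur,
        seed=seed,
    )


def permutation_test(
    epochs_a: EpochSet | np.ndarray,
    epochs_b: EpochSet | np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    min_dur: float = 0.25,
    fs: float | None = None,
    t_start: float | None = None,
    pair: tuple = (None, None),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Two-sided permutation test of the group mean-trace difference.

    Labels are shuffled across the pooled traces preserving group sizes;
    per timepoint, ``p = (1 + #{|perm diff| >= |observed diff|}) / (n_perm + 1)``.
    Significant windows are runs of ``p < alpha`` lasting >= ``min_dur`` s.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if isinstance(epochs_a, EpochSet):
        fs = epochs_a.fs if fs is None else fs
        t_start = float(epochs_a.time_axis[0]) if t_start is None else t_start
        a = epochs_a.traces
    else:
        a = np.atleast_2d(np.asarray(epochs_a, dtype=float))
    b = epochs_b.traces if isinstance(epochs_b, EpochSet) else \
        np.atleast_2d(np.asarray(epochs_b, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both groups must contain at least one trace")
    if fs is None:
        raise ValueError("fs required when passing raw trace matrices")
    if t_start is None:
        t_start = 0.0
    if rng is None:
        rng = np.random.default_rng(seed)
    na, nb = a.shape[0], b.shape[0]
    pooled = np.vstack([a, b])
    n = na + nb
    obs = a.mean(axis=0) - b.mean(axis=0)
    # One label shuffle per permutation: rank the row keys, take the first
    # na columns as group A.  Weight matrix x pooled gives all mean diffs.
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    weights = np.full((n_perm, n), -1.0 / nb)
    np.put_along_axis(weights, order[:, :na], 1.0 / na, axis=1)
    perm_diffs = weights @ pooled
    p = (1 + (np.abs(perm_diffs) >= np.abs(obs)).sum(axis=0)) / (n_perm + 1)
    time_axis = epochs_a.time_axis if isinstance(epochs_a, EpochSet) else \
        t_start + np.arange(a.shape[1]) / fs
    return PermutationResult(
        pair=tuple(pair),
        time_axis=np.asarray(time_axis, dtype=float),
        observed_diff=obs,
        p_values=p,
        n_perm=n_perm,
        alpha=alpha,
        windows=consecutive_filter(p < alpha, fs=fs, min_dur=min_dur, t_start=t_start),
        min_dur=min_dur,
        seed=seed,
    )


def bonferroni_alpha(n_conditions: int, base: float = 0.05) -> float:
    """Alpha corrected over all pairwise comparisons: base / C(k, 2).

    Returns the unrounded value; round to 3 decimals for reporting
    (e.g., 4 conditions -> 0.05/6 -> reported 0.008).  An explicit alpha
    can always be passed to :func:`permutation_test` instead.
    """
    if n_conditions < 2:
        raise ValueError("need at least 2 conditions to compare")
    return base / math.comb(n_conditions, 2)


def mean_window_change(
    epochs: EpochSet,
    pre_window: tuple[float, float] = (-2.0, 0.0),
    post_window: tuple[float, float] = (0.0, 5.0),
) -> PairedComparison:
    """Paired t-test of per-trace mean dF/F before vs after the poke.

    Each trace contributes its mean over ``pre_window`` and over
    ``post_window`` (windows are [lo, hi) on the epoch axis); the paired
    t statistic with n-1 degrees of freedom tests the per-trace
    differences.  Zero-variance differences yield a degenerate result
    (t undefined, flagged) rather than an error.
    """
    if epochs.n_traces < 2:
        raise ValueError("paired comparison requires at least 2 traces")
    t_ax = epochs.time_axis

    def window_mean(win):
        sel = (t_ax >= win[0]) & (t_ax < win[1])
        if not sel.any():
            raise ValueError(f"window {win} contains no samples")
        return epochs.traces[:, sel].mean(axis=1)

    pre = window_mean(pre_window)
    post = window_mean(post_window)
    diff = post - pre
    n = diff.size
    if np.allclose(diff.std(ddof=1), 0.0):
        degenerate = bool(not np.allclose(diff, 0.0))
        return PairedComparison(
            pre_window=tuple(pre_window),
            post_window=tuple(post_window),
            n=n,
            mean_pre=float(pre.mean()),
            mean_post=float(post.mean()),
            mean_diff=float(diff.mean()),
            t=0.0 if not degenerate else math.inf * np.sign(diff.mean()),
            df=n - 1,
            p=1.0 if not degenerate else 0.0,
            degenerate=degenerate,
        )
    res = scipy.stats.ttest_rel(post, pre)
    return PairedComparison(
        pre_window=tuple(pre_window),
        post_window=tuple(post_window),
        n=n,
        mean_pre=float(pre.mean()),
        mean_post=float(post.mean()),
        mean_diff=float(diff.mean()),
        t=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
        degenerate=False,
    )
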