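"""One-command orchestration: simulate/load -> preprocess -> epoch -> analyze.

A :class:`RunConfig` (built directly or loaded from YAML) drives every
stage; a single master seed spawns independent substreams for the
simulator, the bootstrap and the permutation tests, so a config plus
seed fully determines the run.  All intermediate artifacts and a JSON
report are written to the output directory.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .behavior import EventLog, Phase, ResponseType, classify_responses, parse_event_log, \
    session_summary
from .epoching import exclude_events, extract_epochs, zscore_epochs
from .inference import bonferroni_alpha, bootstrap_ci, mean_window_change, permutation_test
from .preprocess import PhotometryRecording, preprocess_pipeline
from .synthetic import SyntheticConfig, simulate_behavior, simulate_photometry

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("photoseek")


@dataclass
class RunConfig:
    """All stage parameters for an end-to-end run."""

    out_dir: str = "photoseek_out"
    seed: int = 0
    phase: str = "SA"
    # input: either simulate=True (synthetic session) or paths to real data
    simulate: bool = True
    synthetic: dict = field(default_factory=dict)   # SyntheticConfig overrides
    recording_path: str | None = None
    events_path: str | None = None
    # schedule (for classification of loaded logs)
    fr: int = 3
    timeout: float = 20.0
    # preprocess
    downsample_factor: int = 64
    detrend_window: float = 90.0
    lowpass_cutoff: float = 3.0
    # epoching
    pre: float = 5.0
    post: float = 10.0
    baseline: tuple = (-5.0, -1.0)
    post_reward_window: float = 20.0
    refractory: float = 5.0
    # inference
    n_boot: int = 5000
    n_perm: int = 1000
    ci_level: float = 0.95
    alpha: float | None = None      # None: Bonferroni over observed conditions
    alpha_base: float = 0.05
    min_dur: float = 0.25
    write_artifacts: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["baseline"] = list(d["baseline"])
        return d


def load_config(path) -> RunConfig:
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)


def _spawn_seeds(seed: int, n: int = 3) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run report."""
    out = Path(config.out_dir)
    if config.write_artifacts:
        out.mkdir(parents=True, exist_ok=True)
    sim_seq, boot_seq, perm_seq = _spawn_seeds(config.seed)
    report: dict = {"config": config.to_dict(), "seed": config.seed}

    stage = "simulate" if config.simulate else "load"
    try:
        if config.simulate:
            syn = SyntheticConfig(
                phase=Phase(config.phase),
                fr=config.fr,
                timeout=config.timeout,
                seed=int(sim_seq.generate_state(1)[0] % (2**31)),
                **config.synthetic,
            )
            events = simulate_behavior(syn)
            rec, truth = simulate_photometry(events, syn)
            if config.write_artifacts:
                events.to_csv(out / "events.csv")
                truth.to_csv(out / "ground_truth.csv")
                rec.to_hdf5(out / "recording.h5")
        else:
            if config.recording_path is None or config.events_path is None:
                raise ValueError("recording_path and events_path required when simulate=false")
            rec = (
                PhotometryRecording.from_hdf5(config.recording_path)
                if str(config.recording_path).endswith((".h5", ".hdf5"))
                else PhotometryRecording.from_csv(config.recording_path)
            )
            events = parse_event_log(config.events_path, phase=config.phase,
                                     duration=rec.sig470.size / rec.fs_native)
        if not events.is_classified:
            events = classify_responses(events, fr=config.fr, timeout=config.timeout)
        report["behavior"] = session_summary(events)

        stage = "preprocess"
        dff = preprocess_pipeline(
            rec,
            factor=config.downsample_factor,
            detrend_window=config.detrend_window,
            cutoff=config.lowpass_cutoff,
        )
        if config.write_artifacts:
            dff.to_hdf5(out / "dff.h5")
        report["preprocess"] = dff.provenance

        stage = "epoch"
        retained = exclude_events(
            events,
            post_reward_window=config.post_reward_window,
            refractory=config.refractory,
        )
        raw_epochs = extract_epochs(
            dff, retained, pre=config.pre, post=config.post,
            baseline=tuple(config.baseline),
        )
        epochs = zscore_epochs(raw_epochs)
        if config.write_artifacts:
            epochs.to_hdf5(out / "epochs.h5")
        report["epochs"] = {
            "n_events": len(events),
            "n_retained_events": len(retained),
            "n_excluded_events": len(events) - len(retained),
            "n_dropped_boundary": raw_epochs.n_dropped_boundary,
            "n_dropped_flat": epochs.n_dropped_flat,
            "traces_per_type": epochs.counts(),
        }

        stage = "analyze"
        present = [rt for rt in ResponseType if epochs.counts()[rt.value] >= 2]
        boot_rng = np.random.default_rng(boot_seq)
        report["bootstrap"] = {}
        for rt in present:
            res = bootstrap_ci(
                epochs, rt, n_boot=config.n_boot, ci=config.ci_level,
                min_dur=config.min_dur, rng=boot_rng,
            )
            report["bootstrap"][rt.value] = {
                "n_traces": res.n_traces,
                "windows": [[float(a), float(b)] for a, b in res.windows],
                "positive_windows": [[float(a), float(b)] for a, b in res.positive_windows],
                "negative_windows": [[float(a), float(b)] for a, b in res.negative_windows],
            }
            if config.write_artifacts:
                res.to_frame().to_csv(out / f"bootstrap_{rt.value}.csv", index=False)

        alpha = config.alpha
        if alpha is None and len(present) >= 2:
            alpha = bonferroni_alpha(len(present), base=config.alpha_base)
        report["alpha"] = alpha
        perm_rng = np.random.default_rng(perm_seq)
        report["permutation"] = {}
        for rt_a, rt_b in itertools.combinations(present, 2):
            res = permutation_test(
                _subset(epochs, rt_a), _subset(epochs, rt_b),
                n_perm=config.n_perm, alpha=alpha, min_dur=config.min_dur,
                pair=(rt_a, rt_b), rng=perm_rng,
            )
            key = f"{rt_a.value}_vs_{rt_b.value}"
            report["permutation"][key] = {
                "n": [int(epochs.counts()[rt_a.value]), int(epochs.counts()[rt_b.value])],
                "windows": [[float(a), float(b)] for a, b in res.windows],
            }
            if config.write_artifacts:
                res.to_frame().to_csv(out / f"permutation_{key}.csv", index=False)

        report["mean_dff_change"] = {}
        for rt in present:
            cmp = mean_window_change(_subset(epochs, rt))
            report["mean_dff_change"][rt.value] = {
                "n": cmp.n, "t": cmp.t, "df": cmp.df, "p": cmp.p,
                "mean_pre": cmp.mean_pre, "mean_post": cmp.mean_post,
                "degenerate": cmp.degenerate,
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    if config.write_artifacts:
        with open(out / "report.json", "w") as f:
            json.dump(report, f, indent=2, sort_keys=True)
    return report


def _subset(epochs, rt):
    """EpochSet-like view holding one response type's traces."""
    from .epoching import EpochSet

    traces = epochs.select(rt)
    return EpochSet(
        traces=traces,
        time_axis=epochs.time_axis,
        labels=[rt] * traces.shape[0],
        fs=epochs.fs,
        zscored=epochs.zscored,
        baseline_window=epochs.baseline_window,
    )
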