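import numpy as np
import pytest

import photoseek as ps

FS = 1017.25 / 64  # downsampled rate, Hz


@pytest.fixture(scope="session")
def fs():
    return FS


def make_epochs(traces, fs=FS, zscored=True, label=ps.ResponseType.INACTIVE):
    """EpochSet around a plain trace matrix on the standard -5..+10 s axis."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n_pre = int(round(5 * fs))
    time_axis = (np.arange(traces.shape[1]) - n_pre) / fs
    return ps.EpochSet(
        traces=traces,
        time_axis=time_axis,
        labels=[label] * traces.shape[0],
        fs=fs,
        zscored=zscored,
    )


@pytest.fixture
def make_epochset():
    return make_epochs


@pytest.fixture(scope="session")
def small_session():
    """A short simulated punishment session shared by read-only tests."""
    cfg = ps.SyntheticConfig(duration=900.0, phase=ps.Phase.PUN, fr=2,
                             rate_active=0.05, rate_inactive=0.02, seed=7)
    log, rec, truth = ps.simulate_session(cfg)
    return cfg, log, rec, truth


def detection_session(seed, amp_rewarded, duration=3600.0):
    """FR1 session yielding >= 100 reinforced traces; transients only on
    rewarded pokes, at the default noise level (peri-event SNR ~ 3 when
    amp_rewarded = 0.08)."""
    amp = {
        ps.ResponseType.ACTIVE_REWARDED: amp_rewarded,
        ps.ResponseType.ACTIVE_PUNISHED: 0.0,
        ps.ResponseType.ACTIVE_NONREWARDED: 0.0,
        ps.ResponseType.INACTIVE: 0.0,
    }
    return ps.SyntheticConfig(duration=duration, fr=1, rate_active=0.1,
                              rate_inactive=0.0, amp=amp, seed=seed)


def run_to_epochs(cfg):
    """Simulate -> preprocess -> exclude -> epoch -> z-score."""
    log, rec, _ = ps.simulate_session(cfg)
    dff = ps.preprocess_pipeline(rec)
    return ps.zscore_epochs(ps.extract_epochs(dff, ps.exclude_events(log)))
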