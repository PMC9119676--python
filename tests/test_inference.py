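"""Bootstrap CIs, permutation tests, alpha correction, consecutive filter,
and the paired pre/post comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import photoseek as ps


def paired_t_oracle(diff):
    """Closed-form paired t: t = mean(d) / (sd(d)/sqrt(n)), two-sided p."""
    import scipy.stats

    n = len(diff)
    t = diff.mean() / (diff.std(ddof=1) / math.sqrt(n))
    p = 2 * scipy.stats.t.sf(abs(t), n - 1)
    return t, p


class TestConsecutiveFilter:
    def test_min_run_is_four_samples_at_downsampled_rate(self, fs):
        assert math.ceil(0.25 * fs) == 4
        mask = np.zeros(50, dtype=bool)
        mask[10:14] = True  # exactly 4 samples
        wins = ps.consecutive_filter(mask, fs)
        assert len(wins) == 1

    def test_three_sample_run_rejected(self, fs):
        mask = np.zeros(50, dtype=bool)
        mask[10:13] = True
        assert ps.consecutive_filter(mask, fs) == []

    def test_two_runs_with_bounds(self, fs):
        mask = np.zeros(60, dtype=bool)
        mask[5:9] = True    # 4 samples
        mask[20:26] = True  # 6 samples
        wins = ps.consecutive_filter(mask, fs, t_start=-5.0)
        assert len(wins) == 2
        assert wins[0] == pytest.approx((-5 + 5 / fs, -5 + 8 / fs))
        assert wins[1] == pytest.approx((-5 + 20 / fs, -5 + 25 / fs))

    def test_empty_mask(self, fs):
        assert ps.consecutive_filter(np.zeros(10, dtype=bool), fs) == []

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.booleans(), min_size=1, max_size=200))
    def test_windows_disjoint_ordered_long_enough(self, bits):
        fs = 15.89453125
        wins = ps.consecutive_filter(bits, fs)
        min_len = (math.ceil(0.25 * fs) - 1) / fs
        prev_end = -np.inf
        for s, e in wins:
            assert e - s >= min_len - 1e-12
            assert s > prev_end
            prev_end = e


class TestBootstrapCI:
    def test_identical_constant_traces(self, make_epochset):
        eps = make_epochset(np.ones((10, 238)))
        res = ps.bootstrap_ci(eps, None, seed=0)
        assert np.allclose(res.mean_trace, 1.0)
        assert np.allclose(res.ci_lo, 1.0) and np.allclose(res.ci_hi, 1.0)
        assert len(res.positive_windows) == 1
        assert res.positive_windows[0] == pytest.approx(
            (eps.time_axis[0], eps.time_axis[-1]))

    def test_expansion_factor_value(self, make_epochset):
        rng = np.random.default_rng(0)
        eps = make_epochset(rng.standard_normal((5, 238)))
        res = ps.bootstrap_ci(eps, None, seed=0)
        assert res.expansion == pytest.approx(1.1180, abs=5e-5)  # sqrt(5/4)

    def test_single_trace_rejected(self, make_epochset):
        with pytest.raises(ValueError, match="at least 2"):
            ps.bootstrap_ci(make_epochset(np.ones((1, 238))), None)

    def test_ci_brackets_pointwise(self, make_epochset):
        rng = np.random.default_rng(1)
        eps = make_epochset(rng.standard_normal((30, 238)))
        res = ps.bootstrap_ci(eps, None, seed=1)
        assert np.all(res.ci_lo <= res.ci_hi)
        # CI straddles the sample mean almost everywhere (up to expansion jitter)
        inside = (res.ci_lo <= res.mean_trace) & (res.mean_trace <= res.ci_hi)
        assert inside.mean() > 0.99

    def test_seed_reproducibility(self, make_epochset):
        rng = np.random.default_rng(2)
        eps = make_epochset(rng.standard_normal((20, 238)))
        a = ps.bootstrap_ci(eps, None, seed=7)
        b = ps.bootstrap_ci(eps, None, seed=7)
        assert np.array_equal(a.ci_lo, b.ci_lo)
        c = ps.bootstrap_ci(eps, None, seed=8)
        assert not np.array_equal(c.ci_lo, a.ci_lo)

    def test_ci_width_shrinks_with_n(self, make_epochset):
        rng = np.random.default_rng(3)
        widths = []
        for n in (10, 40, 160):
            eps = make_epochset(rng.standard_normal((n, 238)))
            res = ps.bootstrap_ci(eps, None, seed=4)
            widths.append(float(np.mean(res.ci_hi - res.ci_lo)))
        assert widths[0] > widths[1] > widths[2]


class TestPermutationTest:
    def test_identical_groups_no_signal(self, make_epochset):
        rng = np.random.default_rng(0)
        traces = rng.standard_normal((15, 238))
        a, b = make_epochset(traces), make_epochset(traces.copy())
        res = ps.permutation_test(a, b, alpha=0.05, seed=0)
        assert np.allclose(res.observed_diff, 0.0)
        assert res.windows == []
        assert np.all(res.p_values >= 0.5)

    def test_minimal_p_is_add_one_bound(self, make_epochset):
        rng = np.random.default_rng(1)
        a = make_epochset(rng.standard_normal((20, 238)) + 100.0)
        b = make_epochset(rng.standard_normal((20, 238)))
        res = ps.permutation_test(a, b, n_perm=1000, alpha=0.008, seed=1)
        assert res.p_values.min() == pytest.approx(1 / 1001)
        assert np.all(res.p_values >= 1 / 1001 - 1e-15)

    @pytest.mark.parametrize("seed", range(5))
    def test_shifted_segment_detected(self, make_epochset, seed, fs=15.89453125):
        # group B = group A + 5 over one second: a window inside the shift
        rng = np.random.default_rng(100 + seed)
        shift_sel = slice(100, 116)  # ~1 s
        a = rng.standard_normal((40, 238))
        b = rng.standard_normal((40, 238))
        b[:, shift_sel] += 5.0
        res = ps.permutation_test(make_epochset(a), make_epochset(b),
                                  alpha=0.008, seed=seed)
        t_lo = (100 - 79) / fs
        t_hi = (115 - 79) / fs
        # a window overlapping the shifted segment, extending at most a
        # couple of samples past it (neighbors can go sub-alpha by chance)
        slack = 2 / fs + 1e-9
        assert any(s <= t_hi and e >= t_lo and s >= t_lo - slack and e <= t_hi + slack
                   for s, e in res.windows)

    def test_group_swap_symmetry(self, make_epochset):
        # the test is two-sided, so swapping the groups negates the observed
        # difference exactly and leaves the p-values unchanged up to
        # Monte-Carlo resolution of the sampled permutations
        rng = np.random.default_rng(2)
        a = make_epochset(rng.standard_normal((25, 238)) + 0.3)
        b = make_epochset(rng.standard_normal((25, 238)))
        r1 = ps.permutation_test(a, b, n_perm=2000, alpha=0.05, seed=3)
        r2 = ps.permutation_test(b, a, n_perm=2000, alpha=0.05, seed=3)
        assert np.allclose(r1.observed_diff, -r2.observed_diff)
        assert np.abs(r1.p_values - r2.p_values).max() < 0.06

    def test_common_shift_invariance(self, make_epochset):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((20, 238))
        b = rng.standard_normal((20, 238))
        r1 = ps.permutation_test(make_epochset(a), make_epochset(b), alpha=0.05, seed=5)
        shift = np.zeros(238)
        shift[50] = 17.0  # same constant added to both groups at one timepoint
        r2 = ps.permutation_test(make_epochset(a + shift), make_epochset(b + shift),
                                 alpha=0.05, seed=5)
        assert np.allclose(r1.p_values, r2.p_values)

    def test_bad_alpha_rejected(self, make_epochset):
        rng = np.random.default_rng(5)
        eps = make_epochset(rng.standard_normal((5, 238)))
        with pytest.raises(ValueError, match="alpha"):
            ps.permutation_test(eps, eps, alpha=1.5)

    def test_empty_group_rejected(self, make_epochset):
        rng = np.random.default_rng(6)
        eps = make_epochset(rng.standard_normal((5, 238)))
        empty = make_epochset(np.empty((0, 238)))
        with pytest.raises(ValueError, match="at least one"):
            ps.permutation_test(eps, empty, alpha=0.05)


class TestBonferroniAlpha:
    def test_four_conditions_reported_008(self):
        assert round(ps.bonferroni_alpha(4), 3) == 0.008
        assert ps.bonferroni_alpha(4) == pytest.approx(0.05 / 6)

    def test_two_conditions(self):
        assert ps.bonferroni_alpha(2) == pytest.approx(0.05)

    def test_three_conditions(self):
        assert round(ps.bonferroni_alpha(3), 3) == 0.017

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            ps.bonferroni_alpha(1)


class TestMeanWindowChange:
    def test_post_equals_pre_gives_null(self, make_epochset):
        rng = np.random.default_rng(0)
        traces = np.zeros((10, 238))
        per_trace = rng.standard_normal(10)
        sel_pre = slice(47, 79)    # -2..0 s
        sel_post = slice(79, 159)  # 0..5 s
        traces[:, sel_pre] = per_trace[:, None]
        traces[:, sel_post] = per_trace[:, None]
        res = ps.mean_window_change(make_epochset(traces))
        assert res.t == 0.0 and res.p == 1.0 and not res.degenerate

    def test_matches_closed_form_oracle(self, make_epochset):
        rng = np.random.default_rng(1)
        traces = rng.standard_normal((50, 238)) + 0.1
        eps = make_epochset(traces)
        res = ps.mean_window_change(eps)
        t_ax = eps.time_axis
        pre = traces[:, (t_ax >= -2) & (t_ax < 0)].mean(axis=1)
        post = traces[:, (t_ax >= 0) & (t_ax < 5)].mean(axis=1)
        t0, p0 = paired_t_oracle(post - pre)
        assert res.t == pytest.approx(t0, abs=1e-10)
        assert res.p == pytest.approx(p0, abs=1e-10)
        assert res.df == 49

    def test_single_trace_rejected(self, make_epochset):
        with pytest.raises(ValueError, match="at least 2"):
            ps.mean_window_change(make_epochset(np.ones((1, 238))))

    def test_constant_nonzero_difference_flagged_degenerate(self, make_epochset):
        traces = np.zeros((5, 238))
        traces[:, 79:] = 1.0  # identical step in every trace
        res = ps.mean_window_change(make_epochset(traces))
        assert res.degenerate
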