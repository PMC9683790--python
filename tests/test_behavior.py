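"""Pupil normalization, arousal splits, and modulation statistics."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import vipmode as v
from vipmode import behavior as bh
from vipmode.preprocessing import AlignedTrials, TraceSet, align_trials, compute_dff


def _trials(rows):
    df = pd.DataFrame(rows)
    df["index"] = np.arange(len(df))
    return df


@pytest.fixture()
def simple_trials():
    return _trials([
        dict(type="Hit", tone_onset=10.0, reinforcement_onset=11.0),
        dict(type="Hit", tone_onset=25.0, reinforcement_onset=26.0),
        dict(type="CR", tone_onset=40.0, reinforcement_onset=np.nan),
        dict(type="CR", tone_onset=55.0, reinforcement_onset=np.nan),
    ])


class TestNormalizePupil:
    def test_constant_pupil_gives_zero_dpp(self, simple_trials):
        t = np.arange(0, 70, 0.05)
        out = bh.normalize_pupil(t, np.full_like(t, 2.0), simple_trials)
        np.testing.assert_allclose(out.dPP, 0.0, atol=1e-12)

    def test_doubling_after_event_gives_plateau_one(self, simple_trials):
        t = np.arange(0, 70, 0.05)
        p = np.where(t > 11.0, 2.0, 1.0)
        out = bh.normalize_pupil(t, p, simple_trials, sigma=0.0)
        sel = (t > 12.0) & (t < 20.0)
        np.testing.assert_allclose(out.dPP[sel], 1.0, atol=1e-9)

    def test_gap_over_linear_segment_interpolates_exactly(self, simple_trials):
        t = np.arange(0, 70, 0.05)
        p = 1.0 + 0.001 * t
        withgap = p.copy()
        gap = (t > 30.0) & (t < 30.4)
        withgap[gap] = np.nan
        out = bh.normalize_pupil(t, withgap, simple_trials, sigma=0.0)
        np.testing.assert_allclose(out.P[gap], p[gap], atol=1e-9)

    def test_long_gap_flags_trial(self, simple_trials):
        t = np.arange(0, 70, 0.05)
        p = np.ones_like(t) * 1.5
        p[(t > 40.5) & (t < 42.0)] = np.nan  # 1.5 s gap inside trial 2
        out = bh.normalize_pupil(t, p, simple_trials)
        assert 2 in out.dropped_trials


class TestAucSplit:
    def _pupil(self, t, dpp):
        return bh.PupilTrace(time=t, P=1 + dpp, P0=np.array([1.0]), dPP=dpp)

    def test_median_split_of_ordered_aucs(self):
        # trials with AUC 1..10 -> the top five are 'high'
        t = np.arange(0, 200, 0.1)
        dpp = np.zeros_like(t)
        trials = _trials([dict(type="Hit", tone_onset=10.0 + 15 * k,
                               reinforcement_onset=11.0 + 15 * k) for k in range(10)])
        for k in range(10):
            ev = 11.0 + 15 * k
            dpp[(t >= ev) & (t <= ev + 3.0)] = (k + 1) / 3.0  # AUC = k+1
        split = bh.auc_split(self._pupil(t, dpp), trials)
        assert list(split.labels) == ["low"] * 5 + ["high"] * 5

    def test_all_equal_aucs_all_low(self):
        t = np.arange(0, 100, 0.1)
        trials = _trials([dict(type="Hit", tone_onset=10.0 + 20 * k,
                               reinforcement_onset=11.0 + 20 * k) for k in range(4)])
        split = bh.auc_split(self._pupil(t, np.zeros_like(t)), trials)
        assert (split.labels == "low").all()

    def test_triangle_closed_form_auc(self):
        # triangular dP/P peaking at 0.2 over 3 s -> area 0.3
        t = np.arange(0, 40, 0.01)
        dpp = np.zeros_like(t)
        ev = 11.0
        up = (t >= ev) & (t < ev + 1.5)
        down = (t >= ev + 1.5) & (t <= ev + 3.0)
        dpp[up] = 0.2 * (t[up] - ev) / 1.5
        dpp[down] = 0.2 * (1 - (t[down] - ev - 1.5) / 1.5)
        trials = _trials([dict(type="Hit", tone_onset=10.0, reinforcement_onset=ev),
                          dict(type="Hit", tone_onset=30.0, reinforcement_onset=31.0)])
        split = bh.auc_split(self._pupil(t, dpp), trials)
        assert split.statistic.iloc[0] == pytest.approx(0.3, rel=1e-3)

    def test_constant_offset_invariance(self, simple_trials):
        # dP/P normalizes away any constant added to P
        t = np.arange(0, 70, 0.05)
        p = 2.0 + 0.1 * np.sin(0.2 * t)
        a = bh.auc_split(bh.normalize_pupil(t, p, simple_trials), simple_trials)
        b = bh.auc_split(bh.normalize_pupil(t, p + 5.0, simple_trials), simple_trials)
        assert list(a.labels) == list(b.labels)

    def test_split_sizes_differ_by_at_most_one(self, rng):
        t = np.arange(0, 500, 0.1)
        dpp = rng.standard_normal(len(t)) * 0.01
        for n in (7, 8):
            trials = _trials([dict(type="Hit", tone_onset=10.0 + 20 * k,
                                   reinforcement_onset=11.0 + 20 * k) for k in range(n)])
            split = bh.auc_split(bh.PupilTrace(time=t, P=1 + dpp, P0=np.array([1.0]),
                                               dPP=dpp), trials)
            hi, lo = (split.labels == "high").sum(), (split.labels == "low").sum()
            assert abs(hi - lo) <= 1
            assert hi + lo == n


class TestSpeedChange:
    def test_stationary_mouse_zero_delta(self, simple_trials):
        t = np.arange(0, 70, 0.05)
        split = bh.speed_change(t, np.zeros_like(t), simple_trials)
        np.testing.assert_allclose(split.statistic, 0.0, atol=1e-12)

    def test_step_to_two_cm_s_delta_two(self):
        t = np.arange(0, 70, 0.05)
        trials = _trials([dict(type="Hit", tone_onset=10.0, reinforcement_onset=11.0),
                          dict(type="Hit", tone_onset=40.0, reinforcement_onset=41.0)])
        speed = np.where((t >= 11.0) & (t < 14.0), 2.0, 0.0)
        split = bh.speed_change(t, speed, trials, sigma=0.0)
        assert split.statistic.iloc[0] == pytest.approx(2.0, rel=1e-6)

    def test_planted_bout_trials_labeled_high(self, rng):
        # running bouts on exactly half the trials: split recovers them
        t = np.arange(0, 500, 0.05)
        trials = _trials([dict(type="Hit", tone_onset=10.0 + 20 * k,
                               reinforcement_onset=11.0 + 20 * k) for k in range(20)])
        speed = 0.02 * np.abs(rng.standard_normal(len(t)))
        bout_trials = rng.permutation(20)[:10]
        for k in bout_trials:
            ev = 11.0 + 20 * k
            speed[(t >= ev) & (t < ev + 2.0)] += 3.0
        split = bh.speed_change(t, speed, trials)
        planted = np.zeros(20, dtype=bool)
        planted[bout_trials] = True
        agree = (split.labels.to_numpy() == np.where(planted, "high", "low")).mean()
        assert agree >= 0.95


class TestCompareSplitResponses:
    def _aligned_and_split(self, gain_high=1.0, n_neurons=50, seed=0):
        rng = np.random.default_rng(seed)
        fs = 10.0
        n_t = int(round(6 * fs))
        n_trials = 40
        tt = (np.arange(n_t) + round(-2 * fs)) / fs
        resp = np.where((tt >= 0) & (tt < 2), 0.3, 0.0)
        high = np.arange(n_trials) < n_trials // 2
        data = np.empty((n_neurons, n_t, n_trials))
        for k in range(n_trials):
            g = gain_high if high[k] else 1.0
            data[:, :, k] = g * resp[None, :] + 0.05 * rng.standard_normal((n_neurons, n_t))
        al = AlignedTrials(data=data, time=tt, window=(-2, 4), alignment_mode="cue",
                           trial_types=np.array(["Hit"] * n_trials), sample_rate=fs)
        labels = pd.Series(np.where(high, "high", "low"), index=np.arange(n_trials))
        split = bh.SplitResult(labels=labels, statistic=pd.Series(high.astype(float)),
                               trial_types=pd.Series(["Hit"] * n_trials))
        return al, split

    def test_identical_groups_no_difference(self):
        al, split = self._aligned_and_split(gain_high=1.0, seed=1)
        out = bh.compare_split_responses(al, split)
        assert abs(out["response"]["high_mean"] - out["response"]["low_mean"]) < 0.02

    def test_planted_gain_detected(self):
        al, split = self._aligned_and_split(gain_high=1.5, n_neurons=100, seed=2)
        out = bh.compare_split_responses(al, split)
        assert out["response"]["high_mean"] > out["response"]["low_mean"]
        assert out["response"]["p"] < 0.01

    def test_null_gain_p_uniform_over_seeds(self):
        ps = [bh.compare_split_responses(*self._aligned_and_split(1.0, 20, s))["response"]["p"]
              for s in range(40)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_arousal_gain_in_generator_detected(self, small_session, small_aligned):
        s = small_session
        pupil = bh.normalize_pupil(s.behavior.time, s.behavior.pupil, s.trials)
        hitfa = s.trials[s.trials["type"].isin(["Hit", "FA"])]
        split = bh.auc_split(pupil, hitfa)
        out = bh.compare_split_responses(small_aligned, split)
        assert out["response"]["high_mean"] > out["response"]["low_mean"]
        assert out["response"]["p"] < 0.01


class TestPercellCorrelation:
    def test_trace_equal_to_behavior_is_one(self):
        t = np.arange(0, 100, 0.1)
        x = np.sin(0.3 * t)
        out = bh.percell_behavior_correlation(x[None], t, t, x)
        assert out["coefficients"][0] == pytest.approx(1.0)

    def test_independent_traces_near_zero(self, rng):
        t = np.arange(0, 100, 0.1)
        n = len(t)
        dff = rng.standard_normal((30, n))
        out = bh.percell_behavior_correlation(dff, t, t, rng.standard_normal(n))
        assert np.mean(np.abs(out["coefficients"]) < 2 / np.sqrt(n)) > 0.9

    def test_coupling_tuned_to_target_median(self, rng):
        # shared-signal model with noise set for population r = 0.31
        t = np.arange(0, 300, 0.1)
        n = len(t)
        b = rng.standard_normal(n)
        rho = 0.31
        sd = np.sqrt(1 / rho**2 - 1)
        dff = np.vstack([b + sd * rng.standard_normal(n) for _ in range(41)])
        out = bh.percell_behavior_correlation(dff, t, t, b)
        assert out["median"] == pytest.approx(0.31, abs=0.05)


class TestNoArousalSubset:
    def test_no_arousal_generator_keeps_most_trials(self):
        cfg = v.SessionConfig(n_neurons=3, n_trials=40, seed=43, dilation_gain=0.0,
                              p_run=0.0)
        s = v.generate_session(cfg)
        pupil = bh.normalize_pupil(s.behavior.time, s.behavior.pupil, s.trials)
        out = bh.no_arousal_subset(s.trials, pupil, s.behavior.time, s.behavior.speed)
        assert out["fraction"] > 0.8

    def test_strong_dilation_empties_subset(self):
        cfg = v.SessionConfig(n_neurons=3, n_trials=40, seed=44, dilation_gain=1.0,
                              dilation_sd=0.0, p_run=0.0)
        s = v.generate_session(cfg)
        pupil = bh.normalize_pupil(s.behavior.time, s.behavior.pupil, s.trials)
        out = bh.no_arousal_subset(s.trials, pupil, s.behavior.time, s.behavior.speed)
        assert out["fraction"] < 0.2

    def test_arousal_independent_response_still_positive(self):
        cfg = v.SessionConfig(n_neurons=40, n_trials=60, seed=45, arousal_gain=0.0,
                              dilation_gain=0.0, p_run=0.0)
        s = v.generate_session(cfg)
        dff = compute_dff(TraceSet(s.traces, s.sample_rate))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            al = align_trials(dff, s.trials, "expected_reinforcement", (-2.0, 4.0))
        pupil = bh.normalize_pupil(s.behavior.time, s.behavior.pupil, s.trials)
        out = bh.no_arousal_subset(s.trials, pupil, s.behavior.time, s.behavior.speed,
                                   aligned=al)
        assert out["fraction"] > 0.5
        assert out["p"] < 0.01
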