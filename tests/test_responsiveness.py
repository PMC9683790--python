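"""Response classification and population statistics (synchronicity etc.)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from vipmode.preprocessing import AlignedTrials
from vipmode import responsiveness as rp


def make_aligned(data, trial_types, fs=10.0, window=(-2.0, 4.0)):
    n_t = int(round((window[1] - window[0]) * fs))
    assert data.shape[1] == n_t
    t = (np.arange(n_t) + round(window[0] * fs)) / fs
    return AlignedTrials(data=data, time=t, window=window, alignment_mode="cue",
                         trial_types=np.asarray(trial_types), sample_rate=fs)


def planted_aligned(step, n_trials=20, noise_sd=0.05, seed=0, fs=10.0):
    """One neuron with a plateau of height ``step`` over the response window."""
    rng = np.random.default_rng(seed)
    n_t = 60
    data = noise_sd * rng.standard_normal((1, n_t, n_trials))
    data[:, 20:40, :] += step  # [0, 2) s at fs=10 with window (-2, 4)
    return make_aligned(data, ["Hit"] * n_trials, fs=fs)


class TestClassifyResponse:
    def test_all_zero_responses_are_none(self):
        al = make_aligned(np.zeros((1, 60, 10)), ["Hit"] * 10)
        out = rp.classify_response(al, 0, "Hit")
        assert out["direction"] == "none"

    @pytest.mark.parametrize("step,expected", [(0.3, "activated"), (-0.3, "suppressed")])
    def test_planted_step_detected(self, step, expected):
        # oracle: t = mean/(sd/sqrt(n)) ~ 0.3/(0.05/sqrt(20)) >> t_crit
        out = rp.classify_response(planted_aligned(step), 0, "Hit")
        assert out["direction"] == expected
        assert out["amplitude"] == pytest.approx(step, abs=0.05)

    def test_under_three_trials_insufficient(self):
        al = make_aligned(np.zeros((1, 60, 2)), ["Hit"] * 2)
        assert rp.classify_response(al, 0, "Hit")["direction"] == "insufficient data"

    def test_lilliefors_recorded_not_gating(self):
        # strongly non-normal per-trial means still classify by the t-test
        rng = np.random.default_rng(1)
        n_trials = 40
        data = np.zeros((1, 60, n_trials))
        data[:, 20:40, :] = 0.5 + 2.0 * (rng.random(n_trials) < 0.2)
        out = rp.classify_response(make_aligned(data, ["Hit"] * n_trials), 0, "Hit")
        assert np.isfinite(out["normal_p"])
        assert out["direction"] == "activated"


class TestTrialActivity:
    def test_boundary_exactly_two_sd_inactive(self):
        # baseline sd exactly 1, peak excess exactly 2 -> strict > fails
        data = np.zeros((1, 60, 1))
        data[0, :20, 0] = np.resize([1.0, -1.0], 20)  # mean 0, sample sd ~1.0129
        sd = data[0, :20, 0].std(ddof=1)
        data[0, 20:40, 0] = 2.0 * sd
        act = rp.trial_activity(make_aligned(data, ["Hit"]))
        assert not act.matrix[0, 0]

    def test_zero_sd_baseline_with_response_active(self):
        data = np.zeros((1, 60, 1))
        data[0, 25, 0] = 0.1
        act = rp.trial_activity(make_aligned(data, ["Hit"]))
        assert act.matrix[0, 0]

    def test_all_zero_trial_inactive(self):
        act = rp.trial_activity(make_aligned(np.zeros((1, 60, 1)), ["Hit"]))
        assert not act.matrix[0, 0]

    def test_hand_enumerated_toy_pattern(self):
        # 5 neurons x 4 trials, planted excesses {3,3,0,0,3} x SD on trial 0
        rng = np.random.default_rng(2)
        data = 0.05 * rng.standard_normal((5, 60, 4))
        sds = data[:, :20, 0].std(ddof=1, axis=0)
        for i, mult in enumerate([3, 3, 0, 0, 3]):
            base_sd = data[i, :20, 0].std(ddof=1)
            data[i, 20:40, 0] += mult * 3 * base_sd  # comfortably above/below 2 SD
        act = rp.trial_activity(make_aligned(data, ["Hit", "FA", "Miss", "CR"]))
        np.testing.assert_array_equal(act.matrix[:, 0], [True, True, False, False, True])


class TestPopulationStatistics:
    @pytest.fixture()
    def toy_activity(self):
        m = np.array([[1, 1, 0, 0],
                      [1, 0, 1, 0],
                      [0, 0, 0, 0],
                      [0, 1, 0, 0],
                      [1, 1, 1, 1]])
        return rp.ActivityMatrix(matrix=m, trial_types=np.array(["Hit", "Hit", "FA", "FA"]))

    def test_synchronicity_hand_counts(self, toy_activity):
        frac = rp.synchronicity(toy_activity)["fraction"].to_numpy()
        np.testing.assert_allclose(frac, [3 / 5, 3 / 5, 2 / 5, 1 / 5])

    def test_synchronicity_extremes(self):
        allon = rp.ActivityMatrix(np.ones((3, 2)), np.array(["Hit", "Hit"]))
        alloff = rp.ActivityMatrix(np.zeros((3, 2)), np.array(["Hit", "Hit"]))
        assert rp.synchronicity(allon)["fraction"].tolist() == [1.0, 1.0]
        assert rp.synchronicity(alloff)["fraction"].tolist() == [0.0, 0.0]

    def test_reliability_hand_counts(self, toy_activity):
        rel = rp.reliability(toy_activity, "Hit")
        np.testing.assert_allclose(rel, [1.0, 0.5, 0.0, 0.5, 1.0])

    @given(hnp.arrays(bool, hnp.array_shapes(min_dims=2, max_dims=2, min_side=1,
                                             max_side=12)))
    @settings(max_examples=50, deadline=None)
    def test_double_counting_identity(self, m):
        """Sum of active cells counted by trial equals the count by neuron."""
        types = np.array(["Hit"] * m.shape[1])
        act = rp.ActivityMatrix(matrix=m.astype(int), trial_types=types)
        by_trial = rp.synchronicity(act)["fraction"].to_numpy() * m.shape[0]
        by_neuron = rp.reliability(act, "Hit") * m.shape[1]
        assert by_trial.sum() == pytest.approx(by_neuron.sum())

    def test_stability_slope_of_planted_decay(self):
        # activity fraction decaying linearly across trials -> negative slope
        rng = np.random.default_rng(3)
        n, k = 50, 30
        p = np.linspace(0.9, 0.1, k)
        m = rng.random((n, k)) < p
        act = rp.ActivityMatrix(m.astype(int), np.array(["Hit"] * k))
        out = rp.stability(act)
        assert out["slope"] < 0 and out["slope_p"] < 0.01

    def test_stability_single_trial_undefined(self):
        act = rp.ActivityMatrix(np.ones((2, 1)), np.array(["Hit"]))
        assert np.isnan(rp.stability(act)["slope"])


class TestCategoryTable:
    def _result(self, directions):
        rows = []
        for i, per_type in enumerate(directions):
            for tt, d in zip(rp.TRIAL_TYPES, per_type):
                rows.append(dict(neuron=i, trial_type=tt, direction=d))
        return rp.ResponsivenessResult(table=pd.DataFrame(rows))

    def test_all_responders_in_all_types(self):
        res = self._result([["activated"] * 4] * 7)
        c = rp.category_table(res)
        assert c["both"] == 7 and c["all_types"] == 7 and c["none"] == 0

    def test_zero_responders(self):
        res = self._result([["none"] * 4] * 5)
        c = rp.category_table(res)
        assert c["none"] == 5
        assert c["both"] == c["reward_only"] == c["punishment_only"] == 0

    def test_mixed_partition_sums(self):
        res = self._result([
            ["activated", "none", "none", "none"],       # reward only
            ["none", "activated", "none", "none"],       # punishment only
            ["activated", "suppressed", "none", "none"],  # both
            ["none", "none", "activated", "none"],       # none (Hit/FA-wise)
        ])
        c = rp.category_table(res)
        assert (c["reward_only"], c["punishment_only"], c["both"], c["none"]) == (1, 1, 1, 1)
        assert c["reward_only"] + c["punishment_only"] + c["both"] + c["none"] == c["n_neurons"]

    def test_planted_both_responder_fraction_recovered(self):
        # 73% of neurons respond to both reinforcers at high SNR
        rng = np.random.default_rng(4)
        n = 200
        both = rng.random(n) < 0.73
        dirs = [["activated", "activated", "none", "none"] if b else
                ["none"] * 4 for b in both]
        c = rp.category_table(self._result(dirs))
        # binomial 99% CI half-width at n=200 ~ 0.08
        assert c["both"] / n == pytest.approx(0.73, abs=0.09)


class TestAmplitudeStatistics:
    def test_proportional_amplitudes_perfectly_correlated(self):
        hit = np.array([0.1, 0.4, 0.2, 0.8, 0.3])
        r, _ = rp.amplitude_correlation(hit, 2 * hit)
        assert r == pytest.approx(1.0)

    def test_shared_gain_model_reaches_target_correlation(self):
        # x = g + e1, y = g + e2 with var(e) = var(g)(1-rho)/rho gives corr rho
        rho = 0.73
        rng = np.random.default_rng(5)
        n = 2000
        g = rng.standard_normal(n)
        sd_e = np.sqrt((1 - rho) / rho)
        r, _ = rp.amplitude_correlation(g + sd_e * rng.standard_normal(n),
                                        g + sd_e * rng.standard_normal(n))
        assert r == pytest.approx(0.73, abs=0.05)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(6)
        rs = [rp.amplitude_correlation(rng.standard_normal(100),
                                       rng.standard_normal(100))[0] for _ in range(20)]
        assert np.mean(np.abs(rs) < 2 / np.sqrt(100)) >= 0.9

    def test_zero_variance_sentinel(self):
        r, p = rp.amplitude_correlation(np.ones(5), np.arange(5.0))
        assert np.isnan(r)


class TestCvPartition:
    def test_identical_values_zero_cv(self):
        df = pd.DataFrame(dict(session=["a"] * 3 + ["b"] * 3, trial_type="Hit",
                               amplitude=[2.0] * 6))
        out = rp.cv_partition(df)
        assert out["cell_to_cell_cv"].iloc[0] == 0.0
        assert out["inter_individual_cv"].iloc[0] == 0.0

    def test_closed_form_pair(self):
        # values {1, 3}: sample SD sqrt(2), mean 2 -> CV = 0.7071
        df = pd.DataFrame(dict(session=["a", "a", "b", "b"], trial_type="Hit",
                               amplitude=[1.0, 3.0, 1.0, 3.0]))
        out = rp.cv_partition(df)
        assert out["cell_to_cell_cv"].iloc[0] == pytest.approx(np.sqrt(2) / 2, abs=1e-6)

    def test_equal_session_means_kill_inter_individual_cv(self):
        rng = np.random.default_rng(7)
        rows = []
        for sess in range(6):
            cells = 1.0 + 0.3 * rng.standard_normal(5000)
            rows.append(pd.DataFrame(dict(session=f"s{sess}", trial_type="Hit",
                                          amplitude=cells)))
        out = rp.cv_partition(pd.concat(rows))
        assert out["inter_individual_cv"].iloc[0] < 0.02
        assert out["cell_to_cell_cv"].iloc[0] > 0.2
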