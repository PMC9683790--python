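"""Pupil and locomotion preprocessing, arousal splits, and modulation tests.

Pupil diameter is blink-interpolated, Gaussian filtered, and expressed as
dP/P against a 2-s pre-tone baseline per trial. Trials are split at the
median of an arousal statistic (pupil AUC after the event, or the running
speed change) and neural responses compared between the high and low halves;
per-cell behavior correlations and the no-arousal-change trial subset round
out the analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import AlignedTrials, smooth_gaussian


@dataclass
class PupilTrace:
    """Normalized pupil trace with per-trial baselines."""

    time: np.ndarray
    P: np.ndarray  # interpolated + smoothed diameter
    P0: np.ndarray  # per-trial baseline
    dPP: np.ndarray  # (P - P0)/P0, piecewise per trial
    dropped_trials: list = field(default_factory=list)

    def __post_init__(self):
        if np.isnan(self.P).any():
            raise ValueError("pupil trace still contains missing samples")


@dataclass
class SplitResult:
    """Median split of trials by an arousal statistic."""

    labels: pd.Series  # 'high'/'low' per trial index
    statistic: pd.Series
    trial_types: pd.Series

    def __post_init__(self):
        if set(self.labels.unique()) - {"high", "low"}:
            raise ValueError("labels must be 'high' or 'low'")

    def trials(self, group: str) -> np.ndarray:
        return self.labels.index[self.labels == group].to_numpy()


def _event_times(trials: pd.DataFrame) -> np.ndarray:
    """Reinforcement onset for Hit/FA, tone onset for Miss/CR."""
    reinf = trials["reinforcement_onset"].to_numpy(dtype=float)
    tone = trials["tone_onset"].to_numpy(dtype=float)
    return np.where(np.isfinite(reinf), reinf, tone)


def interpolate_gaps(time: np.ndarray, x: np.ndarray,
                     max_gap: float = 0.5) -> tuple[np.ndarray, list]:
    """Linear interpolation across NaN gaps; returns (filled, long-gap spans).

    Gaps longer than ``max_gap`` seconds are still filled but their time
    spans are returned so callers can drop affected trials. Gaps touching a
    trace boundary are filled with the nearest valid value.
    """
    x = np.asarray(x, dtype=float).copy()
    bad = ~np.isfinite(x)
    long_spans = []
    if bad.any():
        if bad.all():
            raise ValueError("no valid samples to interpolate from")
        idx = np.flatnonzero(bad)
        splits = np.flatnonzero(np.diff(idx) > 1)
        runs = np.split(idx, splits + 1)
        dt = float(np.median(np.diff(time)))
        for run in runs:
            if len(run) * dt > max_gap:
                long_spans.append((float(time[run[0]]), float(time[run[-1]])))
        good = ~bad
        x[bad] = np.interp(time[bad], time[good], x[good])
        if bad[0] or bad[-1]:
            warnings.warn("gap at trace boundary filled with nearest value")
    return x, long_spans


def normalize_pupil(time: np.ndarray, P: np.ndarray, trials: pd.DataFrame,
                    sigma: float = 0.1, max_gap: float = 0.5,
                    baseline_window: tuple = (-2.0, 0.0)) -> PupilTrace:
    """Blink-interpolate, smooth, and normalize pupil diameter to dP/P.

    The per-trial baseline P0 is the mean over ``baseline_window`` relative
    to tone onset; dP/P is computed piecewise, each trial's baseline applying
    from its own baseline start to the next trial's. Trials overlapping a
    gap longer than ``max_gap`` seconds are listed in ``dropped_trials``.
    """
    time = np.asarray(time, dtype=float)
    fs = 1.0 / float(np.median(np.diff(time)))
    filled, long_spans = interpolate_gaps(time, P, max_gap)
    smoothed = smooth_gaussian(filled, sigma, fs)

    onsets = trials["tone_onset"].to_numpy(dtype=float)
    dropped = []
    for k, t0 in enumerate(onsets):
        t1 = onsets[k + 1] if k + 1 < len(onsets) else time[-1]
        for lo, hi in long_spans:
            if lo < t1 and hi > t0 + baseline_window[0]:
                dropped.append(k)
                break

    P0 = np.empty(len(onsets))
    dPP = np.empty_like(smoothed)
    starts = onsets + baseline_window[0]
    for k, t0 in enumerate(onsets):
        sel = (time >= t0 + baseline_window[0]) & (time < t0 + baseline_window[1])
        if not sel.any():
            raise ValueError(f"trial {k}: baseline window outside the recording")
        P0[k] = smoothed[sel].mean()
        if P0[k] <= 0:
            raise ValueError(f"trial {k}: non-positive pupil baseline")
        lo = starts[k] if k > 0 else time[0]
        hi = starts[k + 1] if k + 1 < len(onsets) else time[-1] + 1
        span = (time >= lo) & (time < hi)
        dPP[span] = (smoothed[span] - P0[k]) / P0[k]
    return PupilTrace(time=time, P=smoothed, P0=P0, dPP=dPP, dropped_trials=dropped)


def auc_split(pupil: PupilTrace, trials: pd.DataFrame, window: tuple = (0.0, 3.0),
              anchor: str = "event") -> SplitResult:
    """Median split of trials by pupil dP/P area under the curve.

    The AUC is the trapezoidal integral of dP/P over ``window`` relative to
    the trial's event (reinforcement for Hit/FA, tone for Miss/CR; pass
    ``anchor='baseline'`` with ``window=(-2, 0)`` relative to tone for the
    baseline-arousal variant). The split is taken separately within each
    outcome type; ties at the median go to 'low'.
    """
    events = _event_times(trials) if anchor == "event" else trials["tone_onset"].to_numpy(float)
    aucs = np.empty(len(trials))
    for k, ev in enumerate(events):
        sel = (pupil.time >= ev + window[0]) & (pupil.time <= ev + window[1])
        if sel.sum() < 2:
            raise ValueError(f"trial {k}: window has fewer than 2 pupil samples")
        aucs[k] = np.trapezoid(pupil.dPP[sel], pupil.time[sel])
    return _median_split(aucs, trials)


def speed_change(time: np.ndarray, speed: np.ndarray, trials: pd.DataFrame,
                 sigma: float = 0.1, event_window: tuple = (0.0, 2.0),
                 baseline_window: tuple = (-2.0, 0.0)) -> SplitResult:
    """Median split of trials by running-speed change around the event.

    Delta speed = mean absolute (Gauss-filtered) speed over the event window
    (after reinforcement for Hit/FA, after the tone for Miss/CR) minus the
    mean over the pre-tone baseline window.
    """
    time = np.asarray(time, dtype=float)
    fs = 1.0 / float(np.median(np.diff(time)))
    sp = smooth_gaussian(np.abs(np.asarray(speed, dtype=float)), sigma, fs)
    events = _event_times(trials)
    tones = trials["tone_onset"].to_numpy(dtype=float)
    deltas = np.empty(len(trials))
    for k in range(len(trials)):
        ev_sel = (time >= events[k] + event_window[0]) & (time < events[k] + event_window[1])
        b_sel = (time >= tones[k] + baseline_window[0]) & (time < tones[k] + baseline_window[1])
        if not ev_sel.any() or not b_sel.any():
            raise ValueError(f"trial {k}: speed windows outside the recording")
        deltas[k] = sp[ev_sel].mean() - sp[b_sel].mean()
    return _median_split(deltas, trials)


def _median_split(values: np.ndarray, trials: pd.DataFrame) -> SplitResult:
    idx = trials["index"].to_numpy() if "index" in trials else np.arange(len(trials))
    types = trials["type"].to_numpy()
    labels = np.empty(len(values), dtype=object)
    for tt in np.unique(types):
        sel = types == tt
        if sel.sum() < 2:
            raise ValueError(f"need at least 2 trials of type {tt!r} to split")
        med = np.median(values[sel])
        labels[sel] = np.where(values[sel] > med, "high", "low")
    return SplitResult(labels=pd.Series(labels, index=idx),
                       statistic=pd.Series(values, index=idx),
                       trial_types=pd.Series(types, index=idx))


def compare_split_responses(aligned: AlignedTrials, split: SplitResult,
                            response_window: tuple = (0.0, 2.0),
                            initial_window: tuple = (0.0, 1.0),
                            late_window: tuple = (2.0, 3.0)) -> dict:
    """High vs low group responses with a paired t-test across neurons.

    Per neuron, the mean dF/F over each window is averaged within the high
    and the low trial group; groups are compared with a paired t-test across
    neurons. Returns group means +/- SEM and p-values for the full response
    window plus the initial and late phase.
    """
    hi_trials = set(split.trials("high"))
    lo_trials = set(split.trials("low"))
    hi_mask = np.array([ti in hi_trials for ti in aligned.trial_index])
    lo_mask = np.array([ti in lo_trials for ti in aligned.trial_index])
    if hi_mask.sum() == 0 or lo_mask.sum() == 0:
        raise ValueError("both split groups must contain aligned trials")
    out = {}
    for name, win in (("response", response_window), ("initial", initial_window),
                      ("late", late_window)):
        tm = aligned.time_mask(*win)
        hi = aligned.data[:, tm, :][:, :, hi_mask].mean(axis=(1, 2))
        lo = aligned.data[:, tm, :][:, :, lo_mask].mean(axis=(1, 2))
        if np.allclose(hi, lo):
            p = 1.0
        else:
            p = float(stats.ttest_rel(hi, lo).pvalue)
        n = len(hi)
        out[name] = dict(high_mean=float(hi.mean()),
                         high_sem=float(hi.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                         low_mean=float(lo.mean()),
                         low_sem=float(lo.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                         p=p)
    return out


def percell_behavior_correlation(dff: np.ndarray, imaging_time: np.ndarray,
                                 behavior_time: np.ndarray,
                                 behavior: np.ndarray) -> dict:
    """Pearson correlation of each cell's dF/F with a behavior trace.

    The behavior trace is interpolated onto the imaging time base. Returns
    per-cell coefficients (NaN for zero-variance cells), the population
    median, and a median split of the cells by coefficient.
    """
    dff = np.atleast_2d(dff)
    beh = np.interp(imaging_time, behavior_time, behavior)
    if np.std(beh) == 0:
        coeffs = np.full(dff.shape[0], np.nan)
    else:
        coeffs = np.empty(dff.shape[0])
        for i in range(dff.shape[0]):
            coeffs[i] = np.nan if np.std(dff[i]) == 0 else stats.pearsonr(dff[i], beh)[0]
    med = np.nanmedian(coeffs) if np.isfinite(coeffs).any() else np.nan
    above = coeffs > med
    return dict(coefficients=coeffs, median=float(med) if np.isfinite(med) else np.nan,
                above_median=above)


def no_arousal_subset(trials: pd.DataFrame, pupil: PupilTrace, time: np.ndarray,
                      speed: np.ndarray, aligned: AlignedTrials | None = None,
                      window: tuple = (0.0, 1.0), baseline_window: tuple = (-2.0, 0.0),
                      sigma: float = 0.1, response_window: tuple = (0.0, 2.0)) -> dict:
    """Trials whose reinforcement evoked no detectable arousal change.

    A Hit/FA trial is kept when both its post-reinforcement pupil dP/P change
    and its absolute speed change (means over ``window`` after reinforcement,
    relative to the pre-tone baseline) stay within 2 SD of the session's
    baseline fluctuation. That fluctuation SD is estimated robustly across
    trials (1.4826 x the median absolute deviation of the change statistic),
    so that a shared arousal transient on every trial inflates the changes
    but not the threshold. When ``aligned`` is given, a one-sample t-test
    checks whether the subset's responses still exceed zero.
    """
    time = np.asarray(time, dtype=float)
    fs = 1.0 / float(np.median(np.diff(time)))
    sp = smooth_gaussian(np.abs(np.asarray(speed, dtype=float)), sigma, fs)
    hitfa = trials[trials["type"].isin(["Hit", "FA"])]
    idx, dpp_changes, sp_changes = [], [], []
    for row in hitfa.itertuples():
        ev = row.reinforcement_onset
        b_sel = (pupil.time >= row.tone_onset + baseline_window[0]) & \
                (pupil.time < row.tone_onset + baseline_window[1])
        w_sel = (pupil.time >= ev + window[0]) & (pupil.time < ev + window[1])
        if not b_sel.any() or not w_sel.any():
            continue
        idx.append(row.index)
        dpp_changes.append(pupil.dPP[w_sel].mean() - pupil.dPP[b_sel].mean())
        sp_changes.append(sp[w_sel].mean() - sp[b_sel].mean())
    dpp_changes = np.asarray(dpp_changes)
    sp_changes = np.asarray(sp_changes)

    def _robust_sd(x):
        return 1.4826 * np.median(np.abs(x - np.median(x))) if len(x) else 0.0

    dpp_sd, sp_sd = _robust_sd(dpp_changes), _robust_sd(sp_changes)
    keep = [i for i, dp, ds in zip(idx, dpp_changes, sp_changes)
            if abs(dp) <= 2 * dpp_sd and abs(ds) <= 2 * sp_sd]
    out = dict(trial_index=keep, n_total=len(hitfa), fraction=len(keep) / max(len(hitfa), 1))
    if aligned is not None and keep:
        mask = np.isin(aligned.trial_index, keep)
        tm = aligned.time_mask(*response_window)
        bm = aligned.time_mask(*baseline_window)
        per_trial = (aligned.data[:, tm, :][:, :, mask].mean(axis=1)
                     - aligned.data[:, bm, :][:, :, mask].mean(axis=1)).mean(axis=0)
        if len(per_trial) >= 2 and np.std(per_trial) > 0:
            out["p"] = float(stats.ttest_1samp(per_trial, 0.0, alternative="greater").pvalue)
            out["mean_response"] = float(per_trial.mean())
    elif not keep:
        out["p"] = None
    return out
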