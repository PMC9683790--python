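"""dF/F computation, event alignment, smoothing, and response kinetics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize


@dataclass
class TraceSet:
    """Fluorescence traces (neurons x samples) with their sample rate."""

    F: np.ndarray
    sample_rate: float
    is_dff: bool = False

    def __post_init__(self):
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))
        if not np.all(np.isfinite(self.F)):
            raise ValueError("traces must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_neurons(self) -> int:
        return self.F.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.F.shape[1]) / self.sample_rate


@dataclass
class AlignedTrials:
    """dF/F tensor (neurons x time x trials) cut around an alignment event.

    ``time`` is relative to the event; the event sample sits at relative
    t = 0 (on the grid of integer multiples of one sample period).
    """

    data: np.ndarray
    time: np.ndarray
    window: tuple
    alignment_mode: str
    trial_types: np.ndarray
    sample_rate: float
    trial_index: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.trial_types = np.asarray(self.trial_types)
        if self.trial_index is None:
            self.trial_index = np.arange(self.data.shape[2])
        expected = int(round((self.window[1] - self.window[0]) * self.sample_rate))
        if self.data.shape[1] != expected:
            raise ValueError(f"time axis length {self.data.shape[1]} != {expected}")

    @property
    def n_neurons(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def select(self, trial_type) -> "AlignedTrials":
        """Sub-tensor restricted to one trial type (or a list of types)."""
        types = [trial_type] if isinstance(trial_type, str) else list(trial_type)
        mask = np.isin(self.trial_types, types)
        return AlignedTrials(data=self.data[:, :, mask], time=self.time, window=self.window,
                             alignment_mode=self.alignment_mode,
                             trial_types=self.trial_types[mask],
                             sample_rate=self.sample_rate,
                             trial_index=self.trial_index[mask])

    def time_mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.time >= lo) & (self.time < hi)


def compute_dff(traces: TraceSet, method: str = "percentile", percentile: float = 20.0,
                trials: pd.DataFrame | None = None,
                baseline_window: tuple = (-2.0, 0.0)) -> TraceSet:
    """Convert raw fluorescence to dF/F = (F - F0) / F0.

    ``method='percentile'`` uses a global per-neuron percentile of the trace
    as F0 (suitable for continuous recordings). ``method='per_trial'``
    estimates F0 per trial as the mean over ``baseline_window`` relative to
    each tone onset and applies it piecewise from one trial's baseline start
    to the next.
    """
    if traces.is_dff:
        return traces
    F = traces.F
    if method == "percentile":
        f0 = np.percentile(F, percentile, axis=1)
        bad = np.flatnonzero(f0 <= 0)
        if bad.size:
            raise ValueError(f"non-positive baseline F0 for neuron(s) {bad.tolist()}")
        dff = (F - f0[:, None]) / f0[:, None]
    elif method == "per_trial":
        if trials is None:
            raise ValueError("per_trial mode requires the trial table")
        fs = traces.sample_rate
        onsets = trials["tone_onset"].to_numpy()
        starts = np.maximum(((onsets + baseline_window[0]) * fs).round().astype(int), 0)
        stops = np.minimum(((onsets + baseline_window[1]) * fs).round().astype(int), F.shape[1])
        dff = np.empty_like(F)
        edges = list(starts) + [F.shape[1]]
        for k in range(len(onsets)):
            f0 = F[:, starts[k]:stops[k]].mean(axis=1)
            bad = np.flatnonzero(f0 <= 0)
            if bad.size:
                raise ValueError(f"non-positive baseline F0 for neuron(s) {bad.tolist()} "
                                 f"in trial {k}")
            lo = starts[k] if k > 0 else 0
            dff[:, lo:edges[k + 1]] = (F[:, lo:edges[k + 1]] - f0[:, None]) / f0[:, None]
        return TraceSet(F=dff, sample_rate=fs, is_dff=True)
    else:
        raise ValueError(f"unknown dF/F method {method!r}")
    return TraceSet(F=dff, sample_rate=traces.sample_rate, is_dff=True)


def alignment_events(trials: pd.DataFrame, mode: str,
                     reinforcement_delay: float = 0.5) -> np.ndarray:
    """Absolute event time per trial for a given alignment mode.

    ``cue`` aligns every trial at tone onset. ``reinforcement`` aligns Hit/FA
    at the actual reinforcement onset and leaves Miss/CR undefined (NaN).
    ``expected_reinforcement`` additionally aligns Miss/CR at tone onset +
    session-mean reaction time (over Hit and FA) + the reinforcement delay.
    """
    onsets = trials["tone_onset"].to_numpy(dtype=float)
    if mode == "cue":
        return onsets
    reinf = trials["reinforcement_onset"].to_numpy(dtype=float)
    if mode == "reinforcement":
        return reinf
    if mode == "expected_reinforcement":
        rts = trials.loc[trials["type"].isin(["Hit", "FA"]), "reaction_time"].to_numpy(dtype=float)
        if len(rts) == 0:
            raise ValueError("expected_reinforcement needs at least one Hit or FA trial")
        expected = onsets + np.nanmean(rts) + reinforcement_delay
        return np.where(np.isfinite(reinf), reinf, expected)
    raise ValueError(f"unknown alignment mode {mode!r}")


def align_trials(traces: TraceSet, trials: pd.DataFrame, mode: str = "expected_reinforcement",
                 window: tuple = (-2.0, 4.0), reinforcement_delay: float = 0.5) -> AlignedTrials:
    """Cut dF/F traces into a neurons x time x trials tensor around an event.

    Fractional-sample offsets are handled by linear interpolation onto a grid
    of integer sample multiples relative to the event. Trials whose window
    falls outside the recording are dropped with a warning.
    """
    if not traces.is_dff:
        raise ValueError("align_trials expects dF/F input (run compute_dff first)")
    fs = traces.sample_rate
    events = alignment_events(trials, mode, reinforcement_delay)
    n_t = int(round((window[1] - window[0]) * fs))
    rel = (np.arange(n_t) + round(window[0] * fs)) / fs
    t_abs_max = (traces.F.shape[1] - 1) / fs

    keep, dropped = [], []
    for k, ev in enumerate(events):
        if not np.isfinite(ev):
            dropped.append(k)
        elif ev + rel[0] < 0 or ev + rel[-1] > t_abs_max:
            dropped.append(k)
        else:
            keep.append(k)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} trial(s) without a full window: {dropped}")
    if not keep:
        raise ValueError("no trial has a complete window inside the recording")

    t_src = traces.time
    data = np.empty((traces.n_neurons, n_t, len(keep)))
    for j, k in enumerate(keep):
        tq = events[k] + rel
        for i in range(traces.n_neurons):
            data[i, :, j] = np.interp(tq, t_src, traces.F[i])
    return AlignedTrials(data=data, time=rel, window=tuple(window), alignment_mode=mode,
                         trial_types=trials["type"].to_numpy()[keep], sample_rate=fs,
                         trial_index=trials["index"].to_numpy()[keep]
                         if "index" in trials else np.asarray(keep))


def smooth_gaussian(trace: np.ndarray, sigma: float, sample_rate: float = 1.0) -> np.ndarray:
    """Gaussian smoothing with reflective boundaries; ``sigma`` in seconds
    (samples when ``sample_rate`` is 1). ``sigma=0`` returns the input."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    trace = np.asarray(trace, dtype=float)
    if sigma == 0:
        return trace.copy()
    return ndimage.gaussian_filter1d(trace, sigma * sample_rate, mode="reflect")


def estimate_kinetics(mean_trace: np.ndarray, sample_rate: float,
                      t: np.ndarray | None = None) -> tuple[float, float]:
    """Peak time and decay time constant of an event-aligned mean response.

    ``t_peak`` is the time of the maximum after t = 0; ``tau_decay`` comes
    from a least-squares fit of ``a * exp(-t / tau)`` to the post-peak
    segment. A non-decaying post-peak segment yields ``tau = inf``.
    """
    y = np.asarray(mean_trace, dtype=float)
    if t is None:
        t = np.arange(len(y)) / sample_rate
    post = t >= 0
    if not post.any() or np.nanmax(y[post]) <= 0:
        raise ValueError("trace needs a positive maximum after t=0")
    ip = np.flatnonzero(post)[np.nanargmax(y[post])]
    t_peak = float(t[ip])
    ty, yy = t[ip:] - t[ip], y[ip:]
    if len(yy) < 3 or yy[-1] >= 0.95 * yy[0]:
        return t_peak, np.inf
    try:
        popt, _ = optimize.curve_fit(lambda tt, a, tau: a * np.exp(-tt / tau), ty, yy,
                                     p0=(yy[0], max(ty[-1] / 3, 1e-3)),
                                     bounds=([0, 1e-4], [np.inf, np.inf]), maxfev=10000)
    except RuntimeError:
        return t_peak, np.inf
    return t_peak, float(popt[1])
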