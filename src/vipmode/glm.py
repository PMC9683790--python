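"""Behavioral-kernel design matrix and cross-validated lasso regression.

The population calcium signal is modeled from five behavioral predictors:
an auditory-cue regressor, a water-availability kernel shaped by the average
lick rate, an air-puff kernel peaking 0.2 s after valve opening, the
Gauss-filtered pupil diameter, and the running speed. Predictors are
downsampled to the imaging rate and standardized; the penalty of the lasso
fit is tuned on contiguous-block cross-validation folds and the variance
explained reported as mean held-out R^2. An optional uniform-random column
serves as a negative control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.metrics import r2_score

from .preprocessing import smooth_gaussian


@dataclass
class DesignMatrix:
    """Standardized predictor matrix at the imaging sample rate."""

    X: np.ndarray
    columns: list
    sample_rate: float
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self):
        if np.isnan(self.X).any():
            raise ValueError("design matrix contains missing values")
        if self.X.size and (np.abs(self.X.mean(axis=0)).max() > 1e-9
                            or np.abs(self.X.std(axis=0) - 1).max() > 1e-6):
            raise ValueError("design matrix must be standardized")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.columns)


@dataclass
class GLMFit:
    weights: dict
    penalty: float
    variance_explained: float  # mean held-out R^2
    fold_r2: np.ndarray
    seed: int


def water_kernel(delivery_times: np.ndarray, time: np.ndarray,
                 lick_rate_curve: tuple | None = None) -> np.ndarray:
    """Water-availability regressor from delivery times and the lick profile.

    Each delivery contributes a kernel that rises as a Gaussian from the
    delivery time, peaks when the session-average lick rate peaks before its
    plateau, then decays linearly to baseline at the time the plateau has
    decayed 5% from its peak. ``lick_rate_curve`` is ``(t_rel, rate)``
    relative to delivery; without licks a fixed 2-s kernel (peak at 0.3 s)
    is used and a warning emitted. Overlapping kernels sum.
    """
    time = np.asarray(time, dtype=float)
    out = np.zeros_like(time)
    if len(delivery_times) == 0:
        return out
    if lick_rate_curve is None or np.asarray(lick_rate_curve[1]).max() <= 0:
        warnings.warn("no licks available; falling back to a fixed 2-s water kernel")
        t_peak, t_end = 0.3, 2.0
    else:
        t_rel, rate = (np.asarray(a, dtype=float) for a in lick_rate_curve)
        ip = int(np.argmax(rate))
        t_peak = max(float(t_rel[ip]), 1e-3)
        peak = rate[ip]
        below = np.flatnonzero((t_rel > t_rel[ip]) & (rate <= 0.95 * peak))
        t_end = float(t_rel[below[0]]) if below.size else float(t_rel[-1])
        t_end = max(t_end, t_peak + 1e-3)
    sigma = t_peak / 2.5  # rise ~zero at delivery, peak at t_peak
    for d in np.asarray(delivery_times, dtype=float):
        rel = time - d
        rise = (rel >= 0) & (rel <= t_peak)
        fall = (rel > t_peak) & (rel <= t_end)
        out[rise] += np.exp(-((rel[rise] - t_peak) ** 2) / (2 * sigma ** 2))
        out[fall] += 1.0 - (rel[fall] - t_peak) / (t_end - t_peak)
    return out


def airpuff_kernel(puff_times: np.ndarray, time: np.ndarray, peak: float = 0.2,
                   sigma: float = 0.06) -> np.ndarray:
    """Air-puff regressor: Gaussian starting at puff onset, peaking at +0.2 s.

    The default sigma (60 ms) puts the kernel value at onset below 1% of the
    peak, consistent with a kernel that 'starts' at the valve opening.
    """
    time = np.asarray(time, dtype=float)
    out = np.zeros_like(time)
    for p in np.asarray(puff_times, dtype=float):
        rel = time - p
        sup = (rel >= 0) & (rel <= peak + 3 * sigma)
        out[sup] += np.exp(-((rel[sup] - peak) ** 2) / (2 * sigma ** 2))
    return out


def _block_downsample(x: np.ndarray, factor: int) -> np.ndarray:
    n = (len(x) // factor) * factor
    return x[:n].reshape(-1, factor).mean(axis=1)


def build_design(events: dict, behavior_time: np.ndarray, pupil: np.ndarray,
                 speed: np.ndarray, imaging_rate: float, behavior_rate: float | None = None,
                 pupil_sigma: float = 0.1, include_random: bool = False,
                 seed: int = 0, lick_rate_curve: tuple | None = None) -> DesignMatrix:
    """Assemble and standardize the behavioral design matrix.

    ``events`` maps 'cue' -> tone onsets, 'water' -> water delivery times,
    'airpuff' -> puff times (seconds, on the behavior clock). Behavioral
    traces are Gauss-filtered (pupil), block-mean downsampled to the imaging
    rate, and z-scored; constant columns are excluded with a warning.
    """
    behavior_time = np.asarray(behavior_time, dtype=float)
    if behavior_rate is None:
        behavior_rate = 1.0 / float(np.median(np.diff(behavior_time)))
    factor = max(int(round(behavior_rate / imaging_rate)), 1)

    cue = np.zeros_like(behavior_time)
    for t0 in events.get("cue", []):
        cue[(behavior_time >= t0) & (behavior_time < t0 + 0.5)] = 1.0
    cols = {
        "cue": cue,
        "water": water_kernel(events.get("water", []), behavior_time, lick_rate_curve),
        "airpuff": airpuff_kernel(events.get("airpuff", []), behavior_time),
        "pupil": smooth_gaussian(np.asarray(pupil, dtype=float), pupil_sigma, behavior_rate),
        "speed": np.asarray(speed, dtype=float),
    }
    if include_random:
        cols["random"] = np.random.default_rng(seed).uniform(0, 1, size=len(behavior_time))

    names, data, means, sds = [], [], [], []
    for name, x in cols.items():
        ds = _block_downsample(x, factor)
        sd = ds.std()
        if sd == 0:
            warnings.warn(f"excluded constant predictor {name!r}")
            continue
        names.append(name)
        means.append(ds.mean())
        sds.append(sd)
        data.append((ds - ds.mean()) / sd)
    X = np.column_stack(data) if data else np.empty((0, 0))
    return DesignMatrix(X=X, columns=names, sample_rate=imaging_rate,
                        means=np.asarray(means), sds=np.asarray(sds))


def contiguous_folds(n: int, folds: int) -> list:
    """Contiguous-block fold index arrays (respects temporal autocorrelation)."""
    edges = np.linspace(0, n, folds + 1).astype(int)
    return [np.arange(edges[i], edges[i + 1]) for i in range(folds)]


def fit_lasso(design: DesignMatrix, y: np.ndarray, folds: int = 5, seed: int = 0,
              n_lambda: int = 25) -> GLMFit:
    """Cross-validated lasso of the population dF/F on the design matrix.

    The penalty grid spans 1e-4 to 1e1 times lambda_max (the smallest
    penalty zeroing all weights) on a log scale; the penalty maximizing the
    mean held-out R^2 over contiguous folds is selected and the model refit
    on all samples.
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("response contains non-finite values")
    X = design.X
    if X.shape[0] != len(y):
        raise ValueError("design and response lengths differ")
    if X.shape[0] < 10 * max(X.shape[1], 1):
        raise ValueError("need at least 10 rows per column")
    yc = y - y.mean()
    lam_max = np.max(np.abs(X.T @ yc)) / len(y)
    lambdas = lam_max * np.logspace(-4, 1, n_lambda)
    fold_idx = contiguous_folds(len(y), folds)
    mean_r2 = np.full(len(lambdas), -np.inf)
    all_r2 = np.zeros((len(lambdas), folds))
    for li, lam in enumerate(lambdas):
        for fi, test in enumerate(fold_idx):
            train = np.setdiff1d(np.arange(len(y)), test, assume_unique=True)
            model = Lasso(alpha=lam, max_iter=5000)
            model.fit(X[train], y[train])
            all_r2[li, fi] = r2_score(y[test], model.predict(X[test]))
        mean_r2[li] = all_r2[li].mean()
    best = int(np.argmax(mean_r2))
    final = Lasso(alpha=lambdas[best], max_iter=10000).fit(X, y)
    weights = dict(zip(design.columns, final.coef_))
    return GLMFit(weights=weights, penalty=float(lambdas[best]),
                  variance_explained=float(mean_r2[best]), fold_r2=all_r2[best], seed=seed)


def lick_rate_curve(trials: pd.DataFrame, window: tuple = (0.0, 4.0),
                    bin_width: float = 0.1) -> tuple:
    """Session-average lick rate around water delivery (Hit trials)."""
    edges = np.arange(window[0], window[1] + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros(len(centers))
    n = 0
    for row in trials[trials["type"] == "Hit"].itertuples():
        if not np.isfinite(row.reinforcement_onset):
            continue
        rel = np.asarray(row.lick_times, dtype=float) - row.reinforcement_onset
        counts += np.histogram(rel, bins=edges)[0]
        n += 1
    rate = counts / max(n, 1) / bin_width
    return centers, rate
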