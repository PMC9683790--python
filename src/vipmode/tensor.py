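"""Time-warped trial tensors and non-negative CP decomposition.

Single-trial responses are warped onto a fixed 30-sample axis (nominally
spanning 1.5 s) so that trials with different reaction times share one time
base, rendered non-negative per cell, normalized by the mean Hit-trial
maximum, and assembled into a neurons x time x trials tensor. The tensor is
factorized by non-negative canonical polyadic (CP) decomposition using HALS
(hierarchical alternating least squares), keeping the best of several random
initializations by relative reconstruction error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import TraceSet, compute_dff

TRIAL_TYPES = ("Hit", "FA", "Miss", "CR")


@dataclass
class TensorDataset:
    """Non-negative N x T x K trial tensor with its normalization constants."""

    tensor: np.ndarray
    trial_types: np.ndarray
    cell_session: np.ndarray
    offsets: np.ndarray  # per-cell subtracted minimum
    scales: np.ndarray  # per-cell Hit-maximum normalizer

    def __post_init__(self):
        if np.any(self.tensor < 0):
            raise ValueError("tensor entries must be non-negative")


@dataclass
class TensorFactors:
    """CP factors (all non-negative) and the relative reconstruction error."""

    rank: int
    neuron_factors: np.ndarray  # N x r
    temporal_factors: np.ndarray  # T x r
    trial_factors: np.ndarray  # K x r
    error: float

    def reconstruct(self) -> np.ndarray:
        return np.einsum("ir,jr,kr->ijk", self.neuron_factors, self.temporal_factors,
                         self.trial_factors)


def time_warp(segment: np.ndarray, target_len: int = 30) -> np.ndarray:
    """Linearly interpolate a segment onto ``target_len`` uniform samples.

    Endpoints are preserved exactly; a length-``target_len`` input is
    returned unchanged.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.ndim != 1 or len(seg) < 2:
        raise ValueError("segment must be a 1-D vector of length >= 2")
    if len(seg) == target_len:
        return seg.copy()
    x = np.linspace(0.0, len(seg) - 1.0, target_len)
    return np.interp(x, np.arange(len(seg)), seg)


def _trial_segment_bounds(row, mean_rt: float, delay: float, post_window: float):
    start = row.tone_onset
    if row.type in ("Hit", "FA"):
        end = row.reinforcement_onset
    else:
        end = row.tone_onset + mean_rt + delay
    return start, end + post_window


def build_tensor(sessions, trials_per_type: int = 10, target_len: int = 30,
                 post_window: float = 1.0, dff_percentile: float = 20.0) -> TensorDataset:
    """Assemble the warped, non-negative trial tensor from sessions.

    For each session the first ``trials_per_type`` trials of each type are
    kept (sessions lacking that many of any type are excluded with a
    warning). Each trial's segment runs from tone onset to its (expected)
    reinforcement plus ``post_window`` seconds and is warped to
    ``target_len`` samples. Per cell, the minimum over all entries is
    subtracted and the result divided by the mean over Hit trials of the
    per-trial maxima; cells whose Hit normalizer is non-positive are
    excluded. Cells from all sessions are concatenated along the neuron axis.
    """
    if not isinstance(sessions, (list, tuple)):
        sessions = [sessions]
    blocks, cell_sess, offsets, scales = [], [], [], []
    trial_types_ref = None
    for s_idx, sess in enumerate(sessions):
        trials = sess.trials
        picked = []
        ok = True
        for tt in TRIAL_TYPES:
            rows = trials[trials["type"] == tt].head(trials_per_type)
            if len(rows) < trials_per_type:
                warnings.warn(f"session {s_idx} excluded: only {len(rows)} {tt} trial(s)")
                ok = False
                break
            picked.append(rows)
        if not ok:
            continue
        picked = pd.concat(picked)
        dff = compute_dff(TraceSet(sess.traces, sess.sample_rate), percentile=dff_percentile)
        fs = sess.sample_rate
        rts = trials.loc[trials["type"].isin(["Hit", "FA"]), "reaction_time"]
        mean_rt = float(rts.mean())
        delay = getattr(sess.config, "reinforcement_delay", 0.5)
        n_cells = dff.n_neurons
        warped = np.empty((n_cells, target_len, len(picked)))
        for j, row in enumerate(picked.itertuples()):
            t0, t1 = _trial_segment_bounds(row, mean_rt, delay, post_window)
            i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
            i1 = min(i1, dff.F.shape[1])
            if i1 - i0 < 2:
                raise ValueError(f"trial {row.index} segment too short")
            for i in range(n_cells):
                warped[i, :, j] = time_warp(dff.F[i, i0:i1], target_len)
        ttypes = picked["type"].to_numpy()
        if trial_types_ref is None:
            trial_types_ref = ttypes
        elif not np.array_equal(trial_types_ref, ttypes):
            raise ValueError("sessions produced inconsistent trial-type orderings")
        mins = warped.min(axis=(1, 2))
        warped = warped - mins[:, None, None]
        hit_mask = ttypes == "Hit"
        norm = warped[:, :, hit_mask].max(axis=1).mean(axis=1)
        keep = norm > 0
        if (~keep).any():
            warnings.warn(f"session {s_idx}: excluded {int((~keep).sum())} cell(s) with "
                          "non-positive Hit normalizer")
        warped = warped[keep] / norm[keep, None, None]
        blocks.append(warped)
        cell_sess.extend([s_idx] * warped.shape[0])
        offsets.extend(mins[keep])
        scales.extend(norm[keep])
    if not blocks:
        raise ValueError("no session had enough trials of every type")
    return TensorDataset(tensor=np.concatenate(blocks, axis=0), trial_types=trial_types_ref,
                         cell_session=np.asarray(cell_sess), offsets=np.asarray(offsets),
                         scales=np.asarray(scales))


def _unfold(X: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(X, mode, 0).reshape(X.shape[mode], -1)


def _khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    r = a.shape[1]
    return (a[:, None, :] * b[None, :, :]).reshape(-1, r)


def _cp_error(norm_x: float, factors: list, mttkrp: np.ndarray) -> float:
    """Relative error ||X - Xhat||_F / ||X||_F from cached cross products."""
    gram = np.ones((factors[0].shape[1],) * 2)
    for f in factors:
        gram = gram * (f.T @ f)
    norm_hat_sq = float(gram.sum())
    inner = float(np.sum(mttkrp * factors[0]))
    diff_sq = max(norm_x ** 2 - 2 * inner + norm_hat_sq, 0.0)
    return np.sqrt(diff_sq) / norm_x


def _nncp_single(X: np.ndarray, rank: int, rng: np.random.Generator,
                 max_iter: int, tol: float) -> tuple[list, float]:
    dims = X.shape
    norm_x = float(np.linalg.norm(X))
    factors = [rng.uniform(0.1, 1.0, size=(d, rank)) for d in dims]
    unfolds = [_unfold(X, m) for m in range(3)]
    prev_err = np.inf
    err = np.inf
    for _ in range(max_iter):
        for m in range(3):
            others = [factors[i] for i in range(3) if i != m]
            # column order of the Khatri-Rao must match moveaxis flattening
            kr = _khatri_rao(others[0], others[1])
            mttkrp = unfolds[m] @ kr
            gram = (others[0].T @ others[0]) * (others[1].T @ others[1])
            A = factors[m]
            for j in range(rank):
                denom = gram[j, j]
                if denom <= 1e-12:
                    A[:, j] = rng.uniform(0.1, 1.0, size=dims[m])
                    continue
                resid = mttkrp[:, j] - A @ gram[:, j] + A[:, j] * denom
                A[:, j] = np.maximum(resid / denom, 0.0)
        kr = _khatri_rao(factors[1], factors[2])
        mttkrp0 = _unfold(X, 0) @ kr
        err = _cp_error(norm_x, factors, mttkrp0)
        if prev_err - err < tol:
            break
        prev_err = err
    return factors, err


def nncp_decompose(dataset, rank: int, n_init: int = 10, seed: int = 0,
                   max_iter: int = 500, tol: float = 1e-8) -> TensorFactors:
    """Non-negative CP decomposition, best of ``n_init`` HALS runs.

    The reported error is the relative Frobenius reconstruction error
    ``||X - Xhat||_F / ||X||_F``. Deterministic given ``seed``. A zero
    tensor is rejected as degenerate.
    """
    X = dataset.tensor if isinstance(dataset, TensorDataset) else np.asarray(dataset, float)
    if X.ndim != 3:
        raise ValueError("input must be a 3-way tensor")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if np.linalg.norm(X) == 0:
        raise ValueError("degenerate input: zero tensor")
    best = None
    for i in range(n_init):
        rng = np.random.default_rng((seed + 7919 * i) % (2 ** 31 - 1))
        factors, err = _nncp_single(X, rank, rng, max_iter, tol)
        if best is None or err < best[1]:
            best = (factors, err)
    factors, err = best
    return TensorFactors(rank=rank, neuron_factors=factors[0], temporal_factors=factors[1],
                         trial_factors=factors[2], error=float(err))


def error_vs_rank(dataset, ranks=(1, 2, 3, 4, 5), n_init: int = 10, seed: int = 0,
                  **kwargs) -> pd.DataFrame:
    """Reconstruction-error curve across candidate ranks."""
    rows = [dict(rank=r, error=nncp_decompose(dataset, r, n_init=n_init, seed=seed,
                                              **kwargs).error) for r in ranks]
    return pd.DataFrame(rows)


def trial_factor_separation(factors: TensorFactors, trial_types: np.ndarray) -> pd.DataFrame:
    """Mann-Whitney separation of reinforced vs unreinforced trial factors.

    Per component, a two-sided Mann-Whitney test compares the trial-factor
    loadings of {Hit, FA} against {Miss, CR}; the component with the minimal
    p-value is flagged as the reinforcement component.
    """
    trial_types = np.asarray(trial_types)
    reinf = np.isin(trial_types, ("Hit", "FA"))
    if reinf.sum() == 0 or (~reinf).sum() == 0:
        raise ValueError("both reinforced and unreinforced trials are required")
    rows = []
    for j in range(factors.rank):
        a = factors.trial_factors[reinf, j]
        b = factors.trial_factors[~reinf, j]
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(dict(component=j, U=float(u), p=float(p),
                         mean_reinforced=float(a.mean()), mean_unreinforced=float(b.mean())))
    df = pd.DataFrame(rows)
    df["is_reinforcement_component"] = df["p"] == df["p"].min()
    return df
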