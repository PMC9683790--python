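"""Orientation/direction selectivity of visually evoked responses.

Responses to eight drifting-grating directions (45 degree spacing) yield per
direction mean amplitudes; selectivity indices follow the standard forms
OSI = (R_pref - R_ortho)/(R_pref + R_ortho) and
DSI = (R_pref - R_opp)/(R_pref + R_opp), with R_ortho taken as the mean of
the two orthogonal directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import AlignedTrials

DIRECTIONS = np.arange(0, 360, 45)


@dataclass
class TuningResult:
    amplitudes: np.ndarray  # 8 mean amplitudes, clipped at 0
    raw_amplitudes: np.ndarray
    preferred_direction: int
    r_pref: float
    r_ortho: float
    r_opp: float
    osi: float
    dsi: float
    visually_responsive: bool = True


def direction_responses(aligned: AlignedTrials, neuron: int,
                        moving_window: tuple = (0.0, 6.0),
                        baseline_window: tuple = (-1.0, 0.0),
                        clip_negative: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-subtracted mean amplitude per grating direction.

    ``aligned.trial_types`` must carry the direction labels (degrees as
    strings); every direction needs at least 3 repeats. Negative means are
    clipped to 0 in the first returned vector (used for the indices); the
    raw means are returned second.
    """
    tm = aligned.time_mask(*moving_window)
    bm = aligned.time_mask(*baseline_window)
    raw = np.empty(len(DIRECTIONS))
    dirs_present = aligned.trial_types.astype(float).astype(int)
    for j, d in enumerate(DIRECTIONS):
        mask = dirs_present == d
        if mask.sum() < 3:
            raise ValueError(f"direction {d} deg has {int(mask.sum())} repeat(s); need >= 3")
        seg = aligned.data[neuron][:, mask]
        raw[j] = (seg[tm].mean(axis=0) - seg[bm].mean(axis=0)).mean()
    clipped = np.clip(raw, 0.0, None) if clip_negative else raw.copy()
    return clipped, raw


def osi(amplitudes: np.ndarray) -> float:
    """Orientation selectivity index from 8 direction amplitudes (>= 0)."""
    r_pref, _, r_ortho, _ = _tuning_amplitudes(amplitudes)
    denom = r_pref + r_ortho
    return np.nan if denom == 0 else float((r_pref - r_ortho) / denom)


def dsi(amplitudes: np.ndarray) -> float:
    """Direction selectivity index from 8 direction amplitudes (>= 0)."""
    r_pref, r_opp, _, _ = _tuning_amplitudes(amplitudes)
    denom = r_pref + r_opp
    return np.nan if denom == 0 else float((r_pref - r_opp) / denom)


def _tuning_amplitudes(amplitudes: np.ndarray):
    a = np.asarray(amplitudes, dtype=float)
    if a.shape != (8,):
        raise ValueError("expected 8 direction amplitudes")
    ip = int(np.argmax(a))
    r_pref = a[ip]
    r_opp = a[(ip + 4) % 8]
    r_ortho = 0.5 * (a[(ip + 2) % 8] + a[(ip + 6) % 8])
    return r_pref, r_opp, r_ortho, ip


def compute_tuning(aligned: AlignedTrials, neuron: int, **kwargs) -> TuningResult:
    """Full tuning summary for one neuron."""
    amps, raw = direction_responses(aligned, neuron, **kwargs)
    r_pref, r_opp, r_ortho, ip = _tuning_amplitudes(amps)
    return TuningResult(amplitudes=amps, raw_amplitudes=raw,
                        preferred_direction=int(DIRECTIONS[ip]), r_pref=float(r_pref),
                        r_ortho=float(r_ortho), r_opp=float(r_opp),
                        osi=osi(amps), dsi=dsi(amps))


def tuning_vs_reinforcement(tuning: pd.DataFrame,
                            reinforcement_amps: np.ndarray) -> pd.DataFrame:
    """Pearson correlations of tuning measures with reinforcement amplitudes.

    ``tuning`` holds per-cell columns among {'visual_max', 'osi', 'dsi'};
    each is correlated with the per-cell reinforcement response amplitude.
    """
    y = np.asarray(reinforcement_amps, dtype=float)
    if len(tuning) != len(y) or len(y) < 3:
        raise ValueError("need matched per-cell vectors of length >= 3")
    rows = []
    for col in tuning.columns:
        x = tuning[col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append(dict(measure=col, r=np.nan, p=np.nan))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append(dict(measure=col, r=float(r), p=float(p)))
    return pd.DataFrame(rows)
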