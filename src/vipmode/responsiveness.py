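"""Per-neuron responsiveness classification and population statistics.

A neuron is classified per trial type from baseline-subtracted per-trial
response means: a Lilliefors normality check is recorded, and two one-tailed
one-sample t-tests (each at p < 0.05) decide whether the neuron is activated
(positive tail) or suppressed (negative tail). The trial-level activity
criterion (peak excess > 2 baseline SD) feeds the synchronicity, reliability,
and stability statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .preprocessing import AlignedTrials

TRIAL_TYPES = ("Hit", "FA", "Miss", "CR")


@dataclass
class ResponsivenessResult:
    """Neuron x trial-type classification table.

    ``table`` has one row per (neuron, trial type) with the Lilliefors
    normality p-value, one-tailed t-test p-values for each direction, the
    resulting direction label, and the mean baseline-subtracted amplitude.
    """

    table: pd.DataFrame

    def direction(self, neuron: int, trial_type: str) -> str:
        row = self.table[(self.table.neuron == neuron) & (self.table.trial_type == trial_type)]
        return row["direction"].iloc[0]

    @property
    def responsive_any(self) -> pd.Series:
        resp = self.table.assign(r=self.table.direction.isin(["activated", "suppressed"]))
        return resp.groupby("neuron")["r"].any()


@dataclass
class ActivityMatrix:
    """Binary active/inactive matrix (neurons x trials)."""

    matrix: np.ndarray
    trial_types: np.ndarray
    trial_index: np.ndarray = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if not np.isin(self.matrix, [0, 1]).all():
            raise ValueError("activity matrix must be binary")
        self.matrix = self.matrix.astype(bool)
        self.trial_types = np.asarray(self.trial_types)
        if self.trial_index is None:
            self.trial_index = np.arange(self.matrix.shape[1])


def _trial_means(aligned: AlignedTrials, neuron: int, mask: np.ndarray,
                 baseline_window: tuple, response_window: tuple) -> np.ndarray:
    b = aligned.time_mask(*baseline_window)
    r = aligned.time_mask(*response_window)
    seg = aligned.data[neuron][:, mask]
    return seg[r].mean(axis=0) - seg[b].mean(axis=0)


def classify_response(aligned: AlignedTrials, neuron: int, trial_type: str,
                      baseline_window: tuple = (-2.0, 0.0),
                      response_window: tuple = (0.0, 2.0), alpha: float = 0.05) -> dict:
    """Classify one neuron for one trial type.

    Returns a dict with the per-trial-mean count, Lilliefors p (metadata, not
    a gate), one-tailed p-values, direction in {activated, suppressed, none,
    insufficient data}, and the mean amplitude.
    """
    mask = aligned.trial_types == trial_type
    n = int(mask.sum())
    out = dict(neuron=neuron, trial_type=trial_type, n_trials=n, normal_p=np.nan,
               p_greater=np.nan, p_less=np.nan, p_value=np.nan,
               direction="insufficient data", amplitude=np.nan)
    if n < 3:
        return out
    d = _trial_means(aligned, neuron, mask, baseline_window, response_window)
    out["amplitude"] = float(d.mean())
    if n >= 4 and np.std(d) > 0:
        out["normal_p"] = float(lilliefors(d, dist="norm")[1])
    if np.allclose(d, d[0]):
        # degenerate: constant differences carry no sampling variability
        out["direction"] = "none" if d[0] == 0 else ("activated" if d[0] > 0 else "suppressed")
        out["p_greater"] = out["p_less"] = out["p_value"] = 0.0 if d[0] != 0 else 1.0
        return out
    out["p_greater"] = float(stats.ttest_1samp(d, 0.0, alternative="greater").pvalue)
    out["p_less"] = float(stats.ttest_1samp(d, 0.0, alternative="less").pvalue)
    out["p_value"] = float(min(out["p_greater"], out["p_less"]))
    if out["p_greater"] < alpha:
        out["direction"] = "activated"
    elif out["p_less"] < alpha:
        out["direction"] = "suppressed"
    else:
        out["direction"] = "none"
    return out


def classify_all(aligned: AlignedTrials, trial_types=TRIAL_TYPES,
                 baseline_window: tuple = (-2.0, 0.0), response_window: tuple = (0.0, 2.0),
                 alpha: float = 0.05, fdr: bool = False) -> ResponsivenessResult:
    """Classification table for every neuron x trial type.

    ``fdr=True`` applies Benjamini-Hochberg across neurons within each trial
    type and tail (off by default; the classifier uses raw p < 0.05).
    """
    rows = [classify_response(aligned, i, tt, baseline_window, response_window, alpha)
            for i in range(aligned.n_neurons) for tt in trial_types]
    table = pd.DataFrame(rows)
    if fdr:
        for tt in trial_types:
            sel = (table.trial_type == tt) & table.p_greater.notna()
            if sel.sum() == 0:
                continue
            for col in ("p_greater", "p_less"):
                rej = multipletests(table.loc[sel, col], alpha=alpha, method="fdr_bh")[0]
                table.loc[sel, col + "_fdr"] = rej
            g = table.loc[sel, "p_greater_fdr"].astype(bool)
            l = table.loc[sel, "p_less_fdr"].astype(bool)
            table.loc[sel, "direction"] = np.where(g, "activated",
                                                   np.where(l, "suppressed", "none"))
    return ResponsivenessResult(table=table)


def trial_activity(aligned: AlignedTrials, baseline_window: tuple = (-2.0, 0.0),
                   response_window: tuple = (0.0, 2.0),
                   peak_halfwidth: float = 0.125) -> ActivityMatrix:
    """Binary per-trial activity: peak excess strictly above 2 baseline SD.

    The per-trial peak is the mean of the samples within ``peak_halfwidth``
    (250 ms total by default) around the maximum of the response window,
    truncated at the window edges; the SD is the sample SD of that trial's
    own baseline samples. A zero-SD baseline with a positive excess counts
    as active; zero excess with zero SD is inactive.
    """
    b = aligned.time_mask(*baseline_window)
    r = aligned.time_mask(*response_window)
    if not b.any() or not r.any():
        raise ValueError("baseline and response windows must lie inside the aligned window")
    n, _, k = aligned.data.shape
    half = max(int(round(peak_halfwidth * aligned.sample_rate)), 0)
    resp = aligned.data[:, r, :]
    base = aligned.data[:, b, :]
    bmean = base.mean(axis=1)
    bsd = base.std(axis=1, ddof=1) if base.shape[1] > 1 else np.zeros((n, k))
    active = np.zeros((n, k), dtype=bool)
    peak_idx = resp.argmax(axis=1)
    for i in range(n):
        for j in range(k):
            p = peak_idx[i, j]
            lo, hi = max(p - half, 0), min(p + half + 1, resp.shape[1])
            excess = resp[i, lo:hi, j].mean() - bmean[i, j]
            active[i, j] = excess > 2.0 * bsd[i, j]
    return ActivityMatrix(matrix=active, trial_types=aligned.trial_types,
                          trial_index=aligned.trial_index)


def synchronicity(activity: ActivityMatrix) -> pd.DataFrame:
    """Fraction of neurons active on each trial (with its trial type)."""
    if activity.matrix.shape[0] < 1:
        raise ValueError("need at least one neuron")
    frac = activity.matrix.mean(axis=0)
    return pd.DataFrame({"trial_index": activity.trial_index,
                         "trial_type": activity.trial_types, "fraction": frac})


def synchronicity_summary(activity: ActivityMatrix) -> pd.DataFrame:
    """Mean +/- SEM synchronicity per trial type."""
    df = synchronicity(activity)
    return df.groupby("trial_type")["fraction"].agg(
        mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan,
        n="count").reset_index()


def reliability(activity: ActivityMatrix, trial_type: str) -> np.ndarray:
    """Per-neuron fraction of active trials among trials of one type."""
    mask = activity.trial_types == trial_type
    if mask.sum() < 1:
        raise ValueError(f"no trials of type {trial_type!r}")
    return activity.matrix[:, mask].mean(axis=1)


def stability(activity: ActivityMatrix) -> dict:
    """Active fraction across trials (in time order) and its trend slope."""
    order = np.argsort(activity.trial_index)
    frac = activity.matrix.mean(axis=0)[order]
    x = np.asarray(activity.trial_index)[order].astype(float)
    if len(x) < 2:
        return dict(fraction=frac, slope=np.nan, slope_p=np.nan, intercept=np.nan)
    res = stats.linregress(x, frac)
    return dict(fraction=frac, slope=float(res.slope), slope_p=float(res.pvalue),
                intercept=float(res.intercept))


def category_table(result: ResponsivenessResult) -> dict:
    """Responder categories across trial types.

    ``reward_only`` / ``punishment_only`` / ``both`` partition the responders
    by Hit (reward) and FA (punishment) significance; ``all_types`` (subset
    of ``both``) marks neurons significant in all four types; ``none`` counts
    the rest.
    """
    t = result.table
    needed = {"Hit", "FA"}
    if not needed.issubset(set(t.trial_type)):
        raise ValueError("category_table needs Hit and FA classifications")
    sig = (t.assign(s=t.direction.isin(["activated", "suppressed"]))
           .pivot_table(index="neuron", columns="trial_type", values="s", aggfunc="first")
           .fillna(False).astype(bool))
    hit, fa = sig["Hit"], sig["FA"]
    both = hit & fa
    all_types = sig.all(axis=1) if set(TRIAL_TYPES).issubset(sig.columns) else both & False
    counts = dict(
        reward_only=int((hit & ~fa).sum()),
        punishment_only=int((fa & ~hit).sum()),
        both=int(both.sum()),
        all_types=int(all_types.sum()),
        none=int((~hit & ~fa).sum()),
        n_neurons=int(len(sig)),
    )
    return counts


def amplitude_correlation(hit_amps: np.ndarray, fa_amps: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of reward vs punishment response amplitudes."""
    x = np.asarray(hit_amps, dtype=float)
    y = np.asarray(fa_amps, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("amplitudes must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def cv_partition(amplitudes: pd.DataFrame) -> pd.DataFrame:
    """Cell-to-cell vs inter-individual coefficient of variation (SD/mean).

    ``amplitudes`` has columns ``session``, ``trial_type``, ``amplitude``
    (one row per cell). Per trial type: the cell-to-cell CV is computed over
    cells within each session (sample SD, n-1) and averaged across sessions;
    the inter-individual CV is computed over the session-mean amplitudes.
    Groups with non-positive means yield NaN.
    """
    req = {"session", "trial_type", "amplitude"}
    if not req.issubset(amplitudes.columns):
        raise ValueError(f"amplitudes must have columns {sorted(req)}")
    if amplitudes["session"].nunique() < 2:
        raise ValueError("need at least 2 sessions")

    def _cv(x):
        x = np.asarray(x, dtype=float)
        m = x.mean()
        if len(x) < 2 or m <= 0:
            return np.nan
        return x.std(ddof=1) / m

    rows = []
    for tt, g in amplitudes.groupby("trial_type"):
        per_sess = g.groupby("session")["amplitude"]
        if (per_sess.count() < 2).any():
            raise ValueError("need at least 2 cells per session")
        cell_cv = per_sess.apply(_cv).mean()
        inter_cv = _cv(per_sess.mean().to_numpy())
        rows.append(dict(trial_type=tt, cell_to_cell_cv=float(cell_cv),
                         inter_individual_cv=float(inter_cv)))
    return pd.DataFrame(rows)
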