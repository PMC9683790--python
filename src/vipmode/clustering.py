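"""Temporal-archetype clustering of reward responses and linear models.

Mean Hit-trial response profiles are z-scored against the first second of the
aligned segment, peak-normalized over the 0-4 s post-reward window, reduced
by PCA to the smallest number of components explaining 90% of the variance,
and clustered with k-means (k = 5, best of 5 replicate initializations).
Cluster mean profiles serve as feature vectors for projections and
area/depth comparisons; two OLS models relate cue-response size to hit rate
or to region identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .preprocessing import AlignedTrials


@dataclass
class ClusterModel:
    labels: np.ndarray
    n_components: int
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    cluster_profiles: np.ndarray  # k x time (on the clustering segment)
    feature_scores: np.ndarray | None = None
    kept_neurons: np.ndarray | None = None


def mean_hit_profiles(aligned: AlignedTrials, trial_type: str = "Hit") -> np.ndarray:
    """Per-neuron mean response profile over trials of one type."""
    sub = aligned.select(trial_type)
    if sub.n_trials == 0:
        raise ValueError(f"no {trial_type} trials")
    return sub.data.mean(axis=2)


def preprocess_profiles(profiles: np.ndarray, time: np.ndarray, baseline_sec: float = 1.0,
                        response_window: tuple = (0.0, 4.0),
                        outlier_factor: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Z-score by the first second, peak-normalize over the post-reward window.

    Each profile is z-scored using the mean and SD of its first ``baseline_sec``
    seconds of the segment, then divided by its maximum over
    ``response_window`` (relative to the alignment event). Neurons with a
    zero first-second SD, a non-positive post-reward maximum, or a profile
    norm exceeding ``outlier_factor`` times the median norm are excluded.

    Returns (normalized profiles, indices of kept neurons).
    """
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    t0 = time[0]
    base = (time >= t0) & (time < t0 + baseline_sec)
    resp = (time >= response_window[0]) & (time < response_window[1])
    if not base.any() or not resp.any():
        raise ValueError("profile window must cover the first second and the response window")
    mu = profiles[:, base].mean(axis=1)
    sd = profiles[:, base].std(axis=1)
    keep = sd > 0
    z = np.zeros_like(profiles)
    z[keep] = (profiles[keep] - mu[keep, None]) / sd[keep, None]
    peak = np.where(keep, z[:, resp].max(axis=1, initial=-np.inf), 0.0)
    keep &= peak > 0
    z[keep] = z[keep] / peak[keep, None]
    norms = np.linalg.norm(z[keep], axis=1)
    if norms.size:
        keep_idx = np.flatnonzero(keep)
        med = np.median(norms)
        ok = norms <= (np.inf if med == 0 else outlier_factor * med)
        dropped = keep_idx[~ok]
        if dropped.size:
            warnings.warn(f"excluded {dropped.size} outlier profile(s): {dropped.tolist()}")
        keep[dropped] = False
    excluded = np.flatnonzero(~keep)
    if excluded.size:
        warnings.warn(f"excluded {excluded.size} profile(s) during normalization")
    return z[keep], np.flatnonzero(keep)


def pca_reduce(profiles: np.ndarray, time: np.ndarray | None = None,
               response_window: tuple = (0.0, 4.0),
               var_threshold: float = 0.90) -> tuple[np.ndarray, PCA, int]:
    """PC scores on the post-reward segment, keeping the smallest number of
    components whose cumulative explained variance reaches the threshold."""
    profiles = np.atleast_2d(profiles)
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    if time is not None:
        seg = profiles[:, (time >= response_window[0]) & (time < response_window[1])]
    else:
        seg = profiles
    pca = PCA()
    scores = pca.fit_transform(seg)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    n_keep = min(n_keep, scores.shape[1])
    return scores[:, :n_keep], pca, n_keep


def kmeans_cluster(scores: np.ndarray, k: int = 5, replicates: int = 5,
                   seed: int = 0) -> np.ndarray:
    """K-means labels, best of ``replicates`` initializations (k-means++)."""
    scores = np.atleast_2d(scores)
    if scores.shape[0] < k:
        raise ValueError(f"need at least {k} points")
    if np.unique(scores, axis=0).shape[0] < k:
        raise ValueError(f"fewer than {k} distinct points")
    km = KMeans(n_clusters=k, n_init=replicates, init="k-means++", random_state=seed)
    return km.fit_predict(scores)


def cluster_mean_profiles(profiles: np.ndarray, labels: np.ndarray,
                          time: np.ndarray | None = None,
                          response_window: tuple = (0.0, 4.0)) -> np.ndarray:
    """Mean normalized profile per cluster (the feature vectors)."""
    if time is not None:
        seg = profiles[:, (time >= response_window[0]) & (time < response_window[1])]
    else:
        seg = profiles
    ks = np.unique(labels)
    return np.vstack([seg[labels == k].mean(axis=0) for k in ks])


def feature_projection(profiles: np.ndarray, features: np.ndarray,
                       time: np.ndarray | None = None,
                       response_window: tuple = (0.0, 4.0)) -> np.ndarray:
    """Inner products of each profile with each unit-normalized feature."""
    if time is not None:
        seg = profiles[:, (time >= response_window[0]) & (time < response_window[1])]
    else:
        seg = profiles
    f = np.atleast_2d(features)
    if f.shape[1] != seg.shape[1]:
        raise ValueError("profiles and features must share the time support")
    norms = np.linalg.norm(f, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return seg @ (f / norms).T


def compare_by_area(scores: np.ndarray, areas: np.ndarray, area_a: str,
                    area_b: str) -> pd.DataFrame:
    """Two-sided Mann-Whitney per feature between two areas, with mean diff."""
    areas = np.asarray(areas)
    a = scores[areas == area_a]
    b = scores[areas == area_b]
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ValueError("need at least 3 cells in each area")
    rows = []
    for j in range(scores.shape[1]):
        u, p = stats.mannwhitneyu(a[:, j], b[:, j], alternative="two-sided")
        rows.append(dict(feature=j, mean_diff=float(a[:, j].mean() - b[:, j].mean()),
                         U=float(u), p=float(p)))
    return pd.DataFrame(rows)


def depth_distribution(labels: np.ndarray, depths: np.ndarray) -> dict:
    """Per-cluster empirical depth CDFs and a one-way ANOVA across clusters.

    The homogeneity test across clusters is a one-way ANOVA on depths (the
    choice of test is an implementation decision; see docs/methods.md).
    """
    labels = np.asarray(labels)
    depths = np.asarray(depths, dtype=float)
    if not np.isfinite(depths).all():
        raise ValueError("depths must be finite")
    groups = {k: np.sort(depths[labels == k]) for k in np.unique(labels)}
    cdfs = {k: (v, np.arange(1, len(v) + 1) / len(v)) for k, v in groups.items()}
    if len(groups) < 2:
        return dict(cdfs=cdfs, F=np.nan, p=np.nan)
    F, p = stats.f_oneway(*groups.values())
    return dict(cdfs=cdfs, F=float(F), p=float(p))


def regress_cue_response(predictors: pd.DataFrame, y: np.ndarray) -> dict:
    """OLS of relative cue response on hit rate or region dummies.

    ``predictors`` contains either a numeric ``hit_rate`` column or a
    categorical ``region`` column (dummy coded, 4 categories in the study
    design). Returns R-squared and the overall F-test p-value.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 sessions")
    if "hit_rate" in predictors.columns:
        X = predictors[["hit_rate"]].astype(float)
    elif "region" in predictors.columns:
        X = pd.get_dummies(predictors["region"], drop_first=True, dtype=float)
    else:
        raise ValueError("predictors must contain 'hit_rate' or 'region'")
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    if np.var(y) == 0:
        return dict(r_squared=0.0, p=np.nan, model=None)
    fit = sm.OLS(y, X).fit()
    return dict(r_squared=float(fit.rsquared), p=float(fit.f_pvalue), model=fit)


def merge_indistinct_clusters(labels: np.ndarray, profiles: np.ndarray,
                              threshold: float = 0.95) -> np.ndarray:
    """Merge clusters whose mean profiles are temporally indistinguishable.

    When the underlying responses all share one temporal shape, k-means
    splits the residual noise into arbitrary groups whose mean profiles are
    nearly identical; merging components whose profile correlation exceeds
    ``threshold`` collapses such degenerate partitions while leaving genuine
    archetypes (pairwise correlations well below 0.95) untouched.
    """
    ks = np.unique(labels)
    if len(ks) < 2:
        return labels.copy()
    means = np.vstack([profiles[labels == k].mean(axis=0) for k in ks])
    c = np.corrcoef(means)
    parent = list(range(len(ks)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(ks)):
        for j in range(i + 1, len(ks)):
            if c[i, j] > threshold:
                parent[find(i)] = find(j)
    roots = {k: find(i) for i, k in enumerate(ks)}
    remap = {r: n for n, r in enumerate(sorted(set(roots.values())))}
    return np.array([remap[roots[l]] for l in labels])


def cluster_reward_responses(aligned: AlignedTrials, k: int = 5, replicates: int = 5,
                             var_threshold: float = 0.90, seed: int = 0,
                             merge_threshold: float = 0.95) -> ClusterModel:
    """Full clustering pipeline on Hit-trial mean profiles."""
    profiles = mean_hit_profiles(aligned)
    normed, kept = preprocess_profiles(profiles, aligned.time)
    scores, pca, n_keep = pca_reduce(normed, aligned.time, var_threshold=var_threshold)
    labels = kmeans_cluster(scores, k=k, replicates=replicates, seed=seed)
    seg_mask = (aligned.time >= 0) & (aligned.time < 4)
    labels = merge_indistinct_clusters(labels, normed[:, seg_mask], merge_threshold)
    feats = cluster_mean_profiles(normed, labels, aligned.time)
    proj = feature_projection(normed, feats, aligned.time)
    return ClusterModel(labels=labels, n_components=n_keep, scores=scores,
                        explained_variance_ratio=pca.explained_variance_ratio_,
                        cluster_profiles=feats, feature_scores=proj, kept_neurons=kept)
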