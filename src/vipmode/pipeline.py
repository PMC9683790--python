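"""Pipeline orchestration: run the analysis stages on one configuration.

A run config (JSON-serializable dict) names the stages to execute, the seed,
and per-stage parameter overrides. Stages execute in dependency order, every
output directory carries the config hash, and the machine-readable
``summary.json`` collects each stage's headline numbers. Runs are
deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import clustering, glm, io, responsiveness, tensor
from .preprocessing import TraceSet, align_trials, compute_dff
from .synthetic import SessionConfig, generate_session

STAGES = ("generate", "align", "respond", "cluster", "tca", "arousal", "glm")


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:12]


def _session_config(config: dict) -> SessionConfig:
    params = dict(config.get("session", {}))
    params.setdefault("seed", config.get("seed", 0))
    if "archetype_mix" in params:
        params["archetype_mix"] = tuple(params["archetype_mix"])
    return SessionConfig(**params)


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the configured stages and write per-stage outputs.

    Returns the summary dict (also written to ``summary.json``). Unknown
    stage names are rejected; stages that need an upstream product raise a
    clear error naming the missing stage.
    """
    stages = list(config.get("stages", STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}; valid: {list(STAGES)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    summary = {"config_hash": config_hash(config), "seed": seed, "stages": {}}
    state: dict = {}

    def _need(name):
        if name not in state:
            raise RuntimeError(f"stage requires missing upstream output from {name!r}")
        return state[name]

    for stage in stages:
        if stage == "generate":
            sess = generate_session(_session_config(config))
            io.save_session(sess, out / "session")
            state["generate"] = sess
            summary["stages"]["generate"] = dict(
                n_neurons=int(sess.traces.shape[0]), n_trials=int(len(sess.trials)),
                n_responsive=int(sess.truth.responsive.sum()))
        elif stage == "align":
            sess = _need("generate")
            p = config.get("align", {})
            dff = compute_dff(TraceSet(sess.traces, sess.sample_rate))
            aligned = align_trials(dff, sess.trials, p.get("mode", "expected_reinforcement"),
                                   tuple(p.get("window", (-2.0, 4.0))),
                                   sess.config.reinforcement_delay)
            io.save_aligned(aligned, out / "aligned.h5")
            state["align"] = aligned
            state["dff"] = dff
            summary["stages"]["align"] = dict(n_trials=int(aligned.n_trials),
                                              window=list(aligned.window))
        elif stage == "respond":
            aligned = _need("align")
            res = responsiveness.classify_all(aligned)
            res.table.to_csv(out / "responsiveness.csv", index=False)
            activity = responsiveness.trial_activity(aligned)
            cats = responsiveness.category_table(res)
            sync = responsiveness.synchronicity_summary(activity)
            stats_json = dict(categories=cats,
                              synchronicity={r.trial_type: r.mean
                                             for r in sync.itertuples()})
            (out / "responsiveness.json").write_text(json.dumps(stats_json, indent=2))
            state["respond"] = res
            summary["stages"]["respond"] = dict(
                frac_responsive=float(res.responsive_any.mean()),
                both=cats["both"], n=cats["n_neurons"])
        elif stage == "cluster":
            aligned = _need("align")
            p = config.get("cluster", {})
            model = clustering.cluster_reward_responses(
                aligned, k=p.get("k", 5), var_threshold=p.get("var_threshold", 0.9),
                seed=seed)
            pd.DataFrame({"neuron": model.kept_neurons, "label": model.labels}).to_csv(
                out / "clusters.csv", index=False)
            state["cluster"] = model
            summary["stages"]["cluster"] = dict(
                n_components=int(model.n_components),
                sizes=np.bincount(model.labels).tolist())
        elif stage == "tca":
            sess = _need("generate")
            p = config.get("tca", {})
            try:
                ds = tensor.build_tensor([sess], trials_per_type=p.get("trials_per_type", 10))
            except ValueError as exc:
                warnings.warn(f"tca skipped: {exc}")
                summary["stages"]["tca"] = dict(skipped=str(exc))
                continue
            factors = tensor.nncp_decompose(ds, rank=p.get("rank", 3),
                                            n_init=p.get("n_init", 10), seed=seed)
            sep = tensor.trial_factor_separation(factors, ds.trial_types)
            sep.to_csv(out / "tca_separation.csv", index=False)
            for name, mat in (("neuron", factors.neuron_factors),
                              ("temporal", factors.temporal_factors),
                              ("trial", factors.trial_factors)):
                pd.DataFrame(mat).to_csv(out / f"tca_{name}_factors.csv", index=False)
            state["tca"] = factors
            summary["stages"]["tca"] = dict(rank=factors.rank, error=factors.error,
                                            min_sep_p=float(sep["p"].min()))
        elif stage == "arousal":
            sess = _need("generate")
            aligned = _need("align")
            pupil = beh.normalize_pupil(sess.behavior.time, sess.behavior.pupil, sess.trials)
            hitfa = sess.trials[sess.trials["type"].isin(["Hit", "FA"])]
            split = beh.auc_split(pupil, hitfa)
            comp = beh.compare_split_responses(aligned, split)
            (out / "arousal.json").write_text(json.dumps(comp, indent=2))
            summary["stages"]["arousal"] = dict(
                high=comp["response"]["high_mean"], low=comp["response"]["low_mean"],
                p=comp["response"]["p"])
        elif stage == "glm":
            sess = _need("generate")
            dff = state.get("dff") or compute_dff(TraceSet(sess.traces, sess.sample_rate))
            events = dict(
                cue=sess.trials["tone_onset"].tolist(),
                water=sess.trials.loc[sess.trials["type"] == "Hit",
                                      "reinforcement_onset"].dropna().tolist(),
                airpuff=sess.trials.loc[sess.trials["type"] == "FA",
                                        "reinforcement_onset"].dropna().tolist(),
            )
            lick = glm.lick_rate_curve(sess.trials)
            design = glm.build_design(events, sess.behavior.time, sess.behavior.pupil,
                                      sess.behavior.speed, imaging_rate=sess.sample_rate,
                                      behavior_rate=sess.sample_rate, seed=seed,
                                      lick_rate_curve=lick)
            y = dff.F.mean(axis=0)[:design.X.shape[0]]
            fit = glm.fit_lasso(design, y, seed=seed)
            (out / "glm.json").write_text(json.dumps(
                dict(weights={k: float(v) for k, v in fit.weights.items()},
                     penalty=fit.penalty, variance_explained=fit.variance_explained),
                indent=2))
            summary["stages"]["glm"] = dict(variance_explained=fit.variance_explained)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
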