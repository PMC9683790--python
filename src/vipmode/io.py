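"""Session persistence: trial CSV, HDF5 traces, JSON config, TIFF tiles."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .preprocessing import AlignedTrials
from .synthetic import (BehaviorTraces, SessionConfig, SessionData, SessionTruth,
                        TileStack)


def save_session(session: SessionData, directory) -> Path:
    """Persist a session as trials.csv + session.h5 + config.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    trials = session.trials.copy()
    trials["lick_times"] = trials["lick_times"].apply(json.dumps)
    trials.to_csv(d / "trials.csv", index=False, float_format="%.17g")
    with h5py.File(d / "session.h5", "w") as f:
        f.create_dataset("traces", data=session.traces, compression="gzip")
        f["traces"].attrs["sample_rate"] = session.sample_rate
        b = f.create_group("behavior")
        for name in ("time", "pupil", "speed", "lick_raster"):
            b.create_dataset(name, data=getattr(session.behavior, name))
        t = f.create_group("truth")
        t.create_dataset("archetype", data=np.array(session.truth.archetype, dtype="S16"))
        for name in ("responsive", "soma_diameter", "amplitude", "trial_arousal",
                     "cue_responsive", "depth"):
            t.create_dataset(name, data=getattr(session.truth, name))
        f.attrs["seed"] = session.seed
    with open(d / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(session.config), fh, indent=2, default=list)
    return d


def load_session(directory) -> SessionData:
    d = Path(directory)
    with open(d / "config.json") as fh:
        cfg = json.load(fh)
    cfg["archetype_mix"] = tuple(cfg["archetype_mix"])
    cfg["soma_means"] = tuple(cfg["soma_means"])
    config = SessionConfig(**cfg)
    trials = pd.read_csv(d / "trials.csv", float_precision="round_trip")
    trials["lick_times"] = trials["lick_times"].apply(json.loads)
    with h5py.File(d / "session.h5", "r") as f:
        traces = f["traces"][...]
        fs = float(f["traces"].attrs["sample_rate"])
        beh = BehaviorTraces(**{k: f["behavior"][k][...]
                                for k in ("time", "pupil", "speed", "lick_raster")})
        tr = f["truth"]
        truth = SessionTruth(
            archetype=np.array([s.decode() for s in tr["archetype"][...]], dtype=object),
            responsive=tr["responsive"][...].astype(bool),
            soma_diameter=tr["soma_diameter"][...],
            amplitude=tr["amplitude"][...],
            trial_arousal=tr["trial_arousal"][...],
            cue_responsive=tr["cue_responsive"][...].astype(bool),
            depth=tr["depth"][...],
        )
        seed = int(f.attrs["seed"])
    return SessionData(config=config, trials=trials, traces=traces, sample_rate=fs,
                       behavior=beh, truth=truth, seed=seed)


def save_aligned(aligned: AlignedTrials, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=aligned.data, compression="gzip")
        f.create_dataset("time", data=aligned.time)
        f.create_dataset("trial_types", data=np.array(aligned.trial_types, dtype="S8"))
        f.create_dataset("trial_index", data=np.asarray(aligned.trial_index))
        f.attrs["window"] = aligned.window
        f.attrs["alignment_mode"] = aligned.alignment_mode
        f.attrs["sample_rate"] = aligned.sample_rate
    return path


def load_aligned(path) -> AlignedTrials:
    with h5py.File(path, "r") as f:
        return AlignedTrials(
            data=f["data"][...], time=f["time"][...],
            window=tuple(f.attrs["window"]), alignment_mode=str(f.attrs["alignment_mode"]),
            trial_types=np.array([s.decode() for s in f["trial_types"][...]]),
            sample_rate=float(f.attrs["sample_rate"]),
            trial_index=f["trial_index"][...],
        )


def save_tile_stack(stack: TileStack, path) -> Path:
    """Multi-page TIFF, tiles stacked along a leading axis."""
    path = Path(path)
    tifffile.imwrite(path, np.stack(stack.tiles).astype(np.float32))
    return path


def load_tile_stack(path) -> TileStack:
    arr = tifffile.imread(path)
    if arr.ndim == 3:
        arr = arr[None]
    return TileStack(tiles=[arr[i].astype(float) for i in range(arr.shape[0])])
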