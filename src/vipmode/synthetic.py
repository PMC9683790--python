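"""Synthetic go/no-go imaging sessions with full ground truth.

Emulates the statistical structure of a head-fixed auditory discrimination
session recorded with fast 3-D two-photon imaging: Hit/FA/Miss/CR trial
outcomes with log-normal reaction times and a 0.5 s reinforcement delay,
GCaMP6f-like double-exponential calcium transients drawn from five temporal
archetypes, arousal-coupled response gain, a mean-reverting pupil trace with
event-evoked dilation, sparse locomotion bouts, bimodal soma diameters, and
translating tile stacks for motion-correction fixtures.

Every generator is deterministic given the seed carried by its config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

TRIAL_TYPES = ("Hit", "FA", "Miss", "CR")

ARCHETYPES = ("fast", "delayed", "sustained", "biphasic", "slow")

#: double-exponential (rise, decay) time constants in seconds, plus onset latency
_KERNEL_PARAMS = {
    "fast": dict(tau_rise=0.1, tau_decay=0.5, latency=0.0),
    "delayed": dict(tau_rise=0.1, tau_decay=0.5, latency=0.5),
    "sustained": dict(tau_rise=0.1, tau_decay=3.0, latency=0.0),
    "slow": dict(tau_rise=1.0, tau_decay=5.0, latency=0.0),
}


def _double_exp(t: np.ndarray, tau_rise: float, tau_decay: float, latency: float = 0.0) -> np.ndarray:
    """Causal difference-of-exponentials transient; zero before ``latency``."""
    ts = t - latency
    out = np.where(ts > 0, np.exp(-np.maximum(ts, 0) / tau_decay) - np.exp(-np.maximum(ts, 0) / tau_rise), 0.0)
    return out


def archetype_kernel(name: str, t: np.ndarray) -> np.ndarray:
    """Peak-normalized response waveform of one of the five temporal archetypes.

    Parameters
    ----------
    name : one of ``fast``, ``delayed``, ``sustained``, ``biphasic``, ``slow``
    t : uniformly sampled, non-negative time vector in seconds

    Returns
    -------
    Non-negative waveform with its peak normalized to 1 (when the peak lies
    inside ``t``). ``fast`` rises with tau 0.1 s and decays with tau 0.5 s;
    ``delayed`` is the same shape with a 0.5 s onset latency; ``sustained``
    decays with tau 3 s; ``biphasic`` adds a second lobe peaking near 2 s;
    ``slow`` rises with tau 1 s and decays with tau 5 s.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("kernel time axis must be non-negative")
    if name == "biphasic":
        lobe1 = _double_exp(t, 0.1, 0.5)
        # second lobe: rise 0.3 s / decay 1.0 s shifted so its own peak sits near 2 s
        lobe2 = _double_exp(t, 0.3, 1.0, latency=1.5)
        raw = lobe1 + 0.8 * lobe2 / max(lobe2.max(), 1e-30) * lobe1.max() if lobe1.max() > 0 else lobe2
    elif name in _KERNEL_PARAMS:
        raw = _double_exp(t, **_KERNEL_PARAMS[name])
    else:
        raise ValueError(f"unknown archetype {name!r}; valid labels: {', '.join(ARCHETYPES)}")
    peak = raw.max()
    if peak > 0:
        raw = raw / peak
    return raw


@dataclass(frozen=True)
class SessionConfig:
    """Parameters of one synthetic go/no-go session.

    Defaults mirror a typical early-training session: 120 simultaneously
    imaged neurons, 128 trials, 27.8 Hz sampling, ~80% lick rate on go tones,
    a 0.5 s delay between the triggering lick and reinforcement delivery, and
    an archetype mixture proportional to the five reported cluster sizes.
    """

    n_neurons: int = 120
    n_trials: int = 128
    p_go: float = 0.5
    p_lick_go: float = 0.8
    p_lick_nogo: float = 0.3
    sample_rate: float = 27.8
    reinforcement_delay: float = 0.5
    reaction_time_mean: float = 0.5
    reaction_time_sd: float = 0.2
    archetype_mix: tuple = (109 / 606, 88 / 606, 177 / 606, 120 / 606, 112 / 606)
    response_gain: float = 0.3
    noise_sd: float = 0.05
    arousal_gain: float = 3.0
    seed: int = 0
    # secondary structure
    p_responsive: float = 0.92
    p_cue_responsive: float = 0.15
    cue_gain: float = 0.1
    iti_mean: float = 7.0
    iti_jitter: float = 1.0
    f0_mean: float = 100.0
    f0_sd: float = 10.0
    pupil_baseline: float = 1.0
    dilation_gain: float = 0.12
    dilation_sd: float = 0.6
    blink_rate: float = 0.0
    p_run: float = 0.3
    run_speed: float = 3.0
    soma_means: tuple = (8.0, 11.0)
    soma_sd: float = 0.8
    area_label: str = "MPta"
    session_id: str = "synthetic-0"
    ensure_all_types: bool = True

    def __post_init__(self):
        for p in (self.p_go, self.p_lick_go, self.p_lick_nogo, self.p_responsive, self.p_cue_responsive):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if abs(sum(self.archetype_mix) - 1.0) > 1e-9 or any(w < 0 for w in self.archetype_mix):
            raise ValueError("archetype_mix must be 5 non-negative weights summing to 1")
        if len(self.archetype_mix) != 5:
            raise ValueError("archetype_mix must have 5 entries")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.n_trials < 4:
            raise ValueError("need at least 4 trials")


@dataclass
class BehaviorTraces:
    """Pupil, running-speed, and lick traces sharing one time base."""

    time: np.ndarray
    pupil: np.ndarray
    speed: np.ndarray
    lick_raster: np.ndarray

    def __post_init__(self):
        n = len(self.time)
        if not (len(self.pupil) == len(self.speed) == len(self.lick_raster) == n):
            raise ValueError("behavior traces must share one length")


@dataclass
class SessionTruth:
    """Planted ground truth carried alongside a synthetic session."""

    archetype: np.ndarray  # per-neuron label, "" for non-responsive cells
    responsive: np.ndarray  # bool per neuron
    soma_diameter: np.ndarray  # um per neuron
    amplitude: np.ndarray  # per-neuron planted response gain (dF/F)
    trial_arousal: np.ndarray  # planted per-trial dP/P used for gain coupling
    cue_responsive: np.ndarray  # bool per neuron
    depth: np.ndarray  # um per neuron
    glm_weights: dict | None = None


@dataclass
class SessionData:
    """One synthetic session: trial table, raw traces, behavior, and truth."""

    config: SessionConfig
    trials: pd.DataFrame
    traces: np.ndarray  # neurons x samples, raw fluorescence (a.u.)
    sample_rate: float
    behavior: BehaviorTraces
    truth: SessionTruth
    seed: int

    def __post_init__(self):
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces must be finite")
        onsets = self.trials["tone_onset"].to_numpy()
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("trial onsets must be strictly increasing")
        if len(self.truth.archetype) != self.traces.shape[0]:
            raise ValueError("truth arrays must have length n_neurons")


def draw_trial_types(n_trials: int, p_go: float, p_lick_go: float, p_lick_nogo: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw Hit/FA/Miss/CR outcome labels from the go/lick probabilities."""
    go = rng.random(n_trials) < p_go
    lick = np.where(go, rng.random(n_trials) < p_lick_go, rng.random(n_trials) < p_lick_nogo)
    types = np.where(go, np.where(lick, "Hit", "Miss"), np.where(lick, "FA", "CR"))
    return types.astype(object)


def _draw_reaction_times(n: int, mean: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Log-normal reaction times truncated to [0.1, 1.5] s by resampling."""
    sigma2 = np.log(1 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    out = rng.lognormal(mu, np.sqrt(sigma2), size=n)
    for _ in range(50):
        bad = (out < 0.1) | (out > 1.5)
        if not bad.any():
            break
        out[bad] = rng.lognormal(mu, np.sqrt(sigma2), size=bad.sum())
    return np.clip(out, 0.1, 1.5)


def generate_trials(config: SessionConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Trial table with tone onsets, outcomes, reaction times and lick times."""
    types = draw_trial_types(config.n_trials, config.p_go, config.p_lick_go, config.p_lick_nogo, rng)
    if config.ensure_all_types:
        for _ in range(200):
            if all(t in set(types) for t in TRIAL_TYPES):
                break
            types = draw_trial_types(config.n_trials, config.p_go, config.p_lick_go,
                                     config.p_lick_nogo, rng)
        else:
            raise RuntimeError("could not draw all four trial types; adjust probabilities")
    itis = config.iti_mean + rng.uniform(-config.iti_jitter, config.iti_jitter, size=config.n_trials)
    tone_onsets = 5.0 + np.cumsum(itis) - itis[0]
    lick_trial = np.isin(types.astype(str), ("Hit", "FA"))
    rts = np.full(config.n_trials, np.nan)
    rts[lick_trial] = _draw_reaction_times(int(lick_trial.sum()), config.reaction_time_mean,
                                           config.reaction_time_sd, rng)
    reinf = np.where(lick_trial, tone_onsets + rts + config.reinforcement_delay, np.nan)
    lick_times = []
    for i in range(config.n_trials):
        if lick_trial[i]:
            first = tone_onsets[i] + rts[i]
            bout = first + np.arange(0, 1.5, 1 / 7.0)  # ~7 Hz lick bout
            lick_times.append(bout.tolist())
        else:
            lick_times.append([])
    return pd.DataFrame({
        "index": np.arange(config.n_trials),
        "type": types.astype(str),
        "tone_onset": tone_onsets,
        "reaction_time": rts,
        "reinforcement_onset": reinf,
        "lick_times": lick_times,
        "area_label": config.area_label,
        "session_id": config.session_id,
    })


def _dilation_kernel(t: np.ndarray) -> np.ndarray:
    """Pupil dilation impulse response peaking ~1 s after the event."""
    k = _double_exp(t, 0.4, 2.5)
    return k / max(k.max(), 1e-30)


def generate_behavior(trials: pd.DataFrame, config: SessionConfig,
                      rng: np.random.Generator | None = None,
                      duration: float | None = None) -> tuple[BehaviorTraces, np.ndarray]:
    """Pupil/speed/lick traces; returns (behavior, planted per-trial dP/P).

    Pupil is an Ornstein-Uhlenbeck baseline around ``pupil_baseline`` plus an
    event-evoked dilation kernel at each reinforcement whose per-trial
    amplitude (in dP/P units) is the planted arousal level; Miss/CR trials
    receive a smaller cue-evoked dilation. Speed is sparse running bouts on a
    random subset of trials. Blink gaps are inserted as NaN when
    ``blink_rate`` > 0.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    fs = config.sample_rate
    if duration is None:
        last = trials["tone_onset"].max() if len(trials) else 0.0
        duration = float(last) + 10.0
    n = int(round(duration * fs))
    time = np.arange(n) / fs

    # mean-reverting baseline: theta = 0.5 1/s, sigma chosen small vs baseline
    theta, sig = 0.5, 0.02
    dt = 1 / fs
    pupil = np.empty(n)
    pupil[0] = config.pupil_baseline
    eps = rng.standard_normal(n - 1)
    for i in range(1, n):
        pupil[i] = pupil[i - 1] + theta * (config.pupil_baseline - pupil[i - 1]) * dt \
            + sig * np.sqrt(dt) * eps[i - 1]

    kern_t = np.arange(0, 8.0, dt)
    kern = _dilation_kernel(kern_t)
    arousal = np.zeros(len(trials))
    dil = np.zeros(n)
    for i, row in enumerate(trials.itertuples()):
        if row.type in ("Hit", "FA"):
            amp = config.dilation_gain * rng.lognormal(0.0, config.dilation_sd)
            onset = row.reinforcement_onset
        else:
            amp = 0.3 * config.dilation_gain * rng.lognormal(0.0, config.dilation_sd)
            onset = row.tone_onset
        arousal[i] = amp
        j = int(round(onset * fs))
        if 0 <= j < n:
            m = min(len(kern), n - j)
            dil[j:j + m] += amp * config.pupil_baseline * kern[:m]
    pupil = pupil + dil

    speed = 0.02 * np.abs(rng.standard_normal(n))
    bout = np.exp(-((np.arange(0, 3.0, dt) - 1.0) ** 2) / (2 * 0.5 ** 2))
    run_trials = np.zeros(len(trials), dtype=bool)
    for i, row in enumerate(trials.itertuples()):
        if rng.random() < config.p_run:
            run_trials[i] = True
            onset = row.reinforcement_onset if row.type in ("Hit", "FA") else row.tone_onset
            j = int(round(onset * fs))
            if 0 <= j < n:
                m = min(len(bout), n - j)
                speed[j:j + m] += config.run_speed * bout[:m]

    lick_raster = np.zeros(n)
    for licks in trials["lick_times"]:
        for lt in licks:
            j = int(round(lt * fs))
            if 0 <= j < n:
                lick_raster[j] = 1.0

    if config.blink_rate > 0:
        n_blinks = rng.poisson(config.blink_rate * duration / 60.0)
        for _ in range(n_blinks):
            j = rng.integers(1, max(n - int(0.2 * fs) - 1, 2))
            pupil[j:j + max(int(0.2 * fs), 1)] = np.nan

    return BehaviorTraces(time=time, pupil=pupil, speed=speed, lick_raster=lick_raster), arousal


def generate_session(config: SessionConfig) -> SessionData:
    """Generate one full synthetic session (deterministic given ``config.seed``).

    Each responsive neuron's raw trace is ``F0 * (1 + dF/F)`` where dF/F is
    its archetype kernel placed at every reinforcement (Hit/FA), scaled by the
    neuron's planted amplitude and by ``1 + arousal_gain * dP/P`` of the
    trial, plus Gaussian noise of ``noise_sd`` (dF/F units). A subset of
    responsive neurons additionally responds to the cue on every trial.
    """
    rng = np.random.default_rng(config.seed)
    trials = generate_trials(config, rng)
    behavior, arousal = generate_behavior(trials, config, rng)
    fs = config.sample_rate
    n = len(behavior.time)
    nn = config.n_neurons

    responsive = rng.random(nn) < config.p_responsive
    arch_idx = rng.choice(5, size=nn, p=np.asarray(config.archetype_mix))
    archetype = np.where(responsive, np.array(ARCHETYPES, dtype=object)[arch_idx], "")
    cue_resp = responsive & (rng.random(nn) < config.p_cue_responsive)
    amp = np.where(responsive, config.response_gain * rng.lognormal(0.0, 0.25, size=nn), 0.0)
    f0 = np.maximum(rng.normal(config.f0_mean, config.f0_sd, size=nn), 1.0)
    comp = rng.random(nn) < 0.5
    soma = np.where(comp, rng.normal(config.soma_means[0], config.soma_sd, size=nn),
                    rng.normal(config.soma_means[1], config.soma_sd, size=nn))
    depth = rng.uniform(100.0, 350.0, size=nn)

    kern_t = np.arange(0, 12.0, 1 / fs)
    kernels = {name: archetype_kernel(name, kern_t) for name in ARCHETYPES}

    reinf_idx = np.array([int(round(r * fs)) if np.isfinite(r) else -1
                          for r in trials["reinforcement_onset"]])
    tone_idx = np.array([int(round(t * fs)) for t in trials["tone_onset"]])
    gain_per_trial = 1.0 + config.arousal_gain * arousal

    dff = np.zeros((nn, n))
    for i in range(nn):
        if not responsive[i]:
            continue
        impulses = np.zeros(n)
        for k in range(len(trials)):
            j = reinf_idx[k]
            if j >= 0 and j < n:
                impulses[j] += amp[i] * gain_per_trial[k]
        if cue_resp[i]:
            for k in range(len(trials)):
                j = tone_idx[k]
                if 0 <= j < n:
                    impulses[j] += config.cue_gain * gain_per_trial[k]
        kern = kernels[str(archetype[i])]
        dff[i] = np.convolve(impulses, kern)[:n]

    noise = config.noise_sd * rng.standard_normal((nn, n)) if config.noise_sd > 0 else 0.0
    traces = f0[:, None] * (1.0 + dff + noise)

    truth = SessionTruth(archetype=archetype, responsive=responsive, soma_diameter=soma,
                         amplitude=amp, trial_arousal=arousal, cue_responsive=cue_resp,
                         depth=depth)
    return SessionData(config=config, trials=trials, traces=traces, sample_rate=fs,
                       behavior=behavior, truth=truth, seed=config.seed)


@dataclass
class TileStack:
    """Per-soma image tiles sharing one frame clock."""

    tiles: list  # list of (n_frames, h, w) arrays
    pixel_size: float = 1.0
    frame_times: np.ndarray | None = None
    true_shifts: np.ndarray | None = None  # planted (dy, dx) per frame

    def __post_init__(self):
        counts = {t.shape[0] for t in self.tiles}
        if len(counts) > 1:
            raise ValueError("all tiles must share the frame count")


def _tile_template(shape: tuple, rng: np.random.Generator) -> np.ndarray:
    """Smoothed random scene with a bright central blob (a soma-like tile)."""
    img = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    cy, cx = (shape[0] - 1) / 2 + rng.uniform(-3, 3), (shape[1] - 1) / 2 + rng.uniform(-3, 3)
    r = rng.uniform(4, 7)
    img = img + 4.0 * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * r ** 2)))
    return img


def generate_tile_stack(n_tiles: int, n_frames: int, shifts, noise_sd: float = 0.0,
                        seed: int = 0, tile_shape: tuple = (64, 64)) -> TileStack:
    """Translate a fixed template scene by per-frame (dy, dx) shifts plus noise.

    ``shifts`` has one (dy, dx) pair per frame, in pixels; sub-pixel shifts
    are realized by linear interpolation. Shifts larger than a quarter of the
    tile are rejected.
    """
    shifts = np.asarray(shifts, dtype=float)
    if shifts.shape != (n_frames, 2):
        raise ValueError("shifts must be (n_frames, 2)")
    margin = min(tile_shape) / 4
    if np.any(np.abs(shifts) > margin):
        raise ValueError(f"shift exceeds tile margin of {margin} px")
    rng = np.random.default_rng(seed)
    tiles = []
    for _ in range(n_tiles):
        template = _tile_template(tile_shape, rng)
        frames = np.empty((n_frames,) + tuple(tile_shape))
        for f in range(n_frames):
            frames[f] = ndimage.shift(template, shifts[f], order=1, mode="nearest")
            if noise_sd > 0:
                frames[f] += noise_sd * rng.standard_normal(tile_shape)
        tiles.append(frames)
    return TileStack(tiles=tiles, frame_times=np.arange(n_frames, dtype=float),
                     true_shifts=shifts)


def generate_tuning_session(n_neurons: int = 50, n_repeats: int = 10, base_amp: float = 0.3,
                            dsi: float = 0.3, noise_sd: float = 0.02, seed: int = 0,
                            sharp: bool = False, sample_rate: float = 27.8):
    """Visually evoked responses to 8 drifting-grating directions.

    Each cell is cosine tuned, ``r(theta) = a + b cos(theta - theta_pref)``
    with ``b/a`` equal to the requested DSI (``sharp=True`` emulates a
    narrowly tuned pyramidal-like population with a wrapped-Gaussian profile).
    Returns an :class:`~vipmode.preprocessing.AlignedTrials` whose trial types
    are the direction labels, plus the planted preferred directions (deg) and
    per-cell gains.
    """
    from .preprocessing import AlignedTrials  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    directions = np.arange(0, 360, 45)
    pref = rng.choice(directions, size=n_neurons)
    gains = base_amp * rng.lognormal(0.0, 0.3, size=n_neurons)
    window = (-1.0, 7.0)
    n_t = int(round((window[1] - window[0]) * sample_rate))
    t = (np.arange(n_t) + round(window[0] * sample_rate)) / sample_rate
    envelope = np.clip(np.where((t >= 0) & (t <= 6.0), 1.0, 0.0), 0, None)
    trial_dirs = np.repeat(directions, n_repeats)
    rng.shuffle(trial_dirs)
    data = np.empty((n_neurons, n_t, len(trial_dirs)))
    for i in range(n_neurons):
        delta = np.deg2rad(trial_dirs - pref[i])
        if sharp:
            resp = gains[i] * (0.1 + 0.9 * np.exp(-(np.minimum(np.abs(delta),
                               2 * np.pi - np.abs(delta)) ** 2) / (2 * 0.5 ** 2)))
        else:
            resp = gains[i] * (1.0 + dsi * np.cos(delta))
        data[i] = envelope[:, None] * resp[None, :] + noise_sd * rng.standard_normal((n_t, len(trial_dirs)))
    aligned = AlignedTrials(data=data, time=t, window=window, alignment_mode="cue",
                            trial_types=trial_dirs.astype(str), sample_rate=sample_rate,
                            trial_index=np.arange(len(trial_dirs)))
    return aligned, pref, gains


def with_seed(config: SessionConfig, seed: int) -> SessionConfig:
    """Copy of ``config`` with a new seed (convenience for seed ensembles)."""
    return replace(config, seed=seed, session_id=f"{config.session_id}-s{seed}")
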