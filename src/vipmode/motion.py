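"""Tile-wise FFT registration with robust consensus displacement.

Each soma tile is registered against a template (the mean of its best
mutually correlating frames) by windowed normalized cross-correlation
computed in the frequency domain, with sub-pixel refinement by a local
quadratic fit of the correlation peak. The final per-frame displacement is
the component-wise median over the tiles with the smallest matching errors.
The motion model is translation only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import exposure


@dataclass
class ShiftEstimate:
    """Estimated (dy, dx) mapping the moving image onto the template."""

    dy: float
    dx: float
    error: float
    integer: tuple = (0, 0)


@dataclass
class DisplacementEstimate:
    """Per-tile shifts plus the robust consensus for one frame."""

    tile_shifts: np.ndarray  # n_tiles x 2 (dy, dx)
    tile_errors: np.ndarray
    consensus: tuple
    fraction_used: float


def _window(shape: tuple) -> np.ndarray:
    wy = np.hanning(shape[0])
    wx = np.hanning(shape[1])
    return np.outer(wy, wx)


def register_tile(moving: np.ndarray, template: np.ndarray,
                  window: bool = False) -> ShiftEstimate:
    """Translation estimate via FFT cross-correlation with sub-pixel fit.

    The returned (dy, dx) is the shift that maps ``moving`` onto
    ``template`` (i.e. ``ndimage.shift(moving, (dy, dx)) ~ template``).
    ``error`` is 1 minus the normalized correlation peak; 0 for identical
    images. Sub-pixel refinement fits a parabola through the correlation
    peak and its neighbors along each axis. ``window=True`` applies a Hann
    window first (useful for strong periodic edge content, at the cost of a
    small peak bias on small tiles).
    """
    moving = np.asarray(moving, dtype=float)
    template = np.asarray(template, dtype=float)
    if moving.shape != template.shape:
        raise ValueError("moving and template must share the same shape")
    if moving.std() == 0 or template.std() == 0:
        raise ValueError("zero-variance image cannot be registered")
    m = moving - moving.mean()
    t = template - template.mean()
    if window:
        w = _window(moving.shape)
        m, t = m * w, t * w
    corr = np.fft.ifft2(np.fft.fft2(t) * np.conj(np.fft.fft2(m))).real
    corr = corr / (np.linalg.norm(m) * np.linalg.norm(t))
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    shifts_int = []
    for ax, p in enumerate(peak):
        n = corr.shape[ax]
        shifts_int.append(p - n if p > n // 2 else p)

    def _quad(cm, c0, cp):
        denom = cm - 2 * c0 + cp
        if denom >= 0:  # not a local max; skip refinement
            return 0.0
        return 0.5 * (cm - cp) / denom

    dy0, dx0 = shifts_int
    py, px = peak
    ny, nx = corr.shape
    dy = dy0 + _quad(corr[(py - 1) % ny, px], corr[py, px], corr[(py + 1) % ny, px])
    dx = dx0 + _quad(corr[py, (px - 1) % nx], corr[py, px], corr[py, (px + 1) % nx])
    error = float(1.0 - corr[py, px])
    return ShiftEstimate(dy=float(dy), dx=float(dx), error=error, integer=(dy0, dx0))


def select_templates(frames: np.ndarray, fraction: float = 0.20,
                     manual_template: np.ndarray | None = None) -> np.ndarray:
    """Template = mean of the top ``fraction`` of frames by mutual correlation.

    Frames are ranked by their mean Pearson correlation with every other
    frame; the best-correlating fraction (at least one frame) is averaged.
    A manually supplied template bypasses the selection.
    """
    if manual_template is not None:
        return np.asarray(manual_template, dtype=float)
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[0]
    if n < 5:
        raise ValueError("need at least 5 frames for template selection")
    flat = frames.reshape(n, -1)
    flat = flat - flat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(flat, axis=1)
    norms[norms == 0] = 1.0
    c = (flat @ flat.T) / np.outer(norms, norms)
    mean_corr = (c.sum(axis=1) - 1.0) / (n - 1)
    k = max(int(math.ceil(fraction * n)), 1)
    best = np.argsort(mean_corr)[::-1][:k]
    return frames[best].mean(axis=0)


def consensus_shift(shifts: np.ndarray, errors: np.ndarray,
                    fraction: float = 0.20) -> tuple:
    """Component-wise median shift over the lowest-error fraction of tiles.

    At least 3 tiles are always used (and required).
    """
    shifts = np.atleast_2d(np.asarray(shifts, dtype=float))
    errors = np.asarray(errors, dtype=float)
    n = shifts.shape[0]
    if n < 3:
        raise ValueError("need at least 3 tiles for a consensus shift")
    k = max(int(math.ceil(fraction * n)), 3)
    best = np.argsort(errors)[:k]
    med = np.median(shifts[best], axis=0)
    return float(med[0]), float(med[1])


def preprocess_tile(image: np.ndarray, mode: str = "none") -> np.ndarray:
    """Optional tile preprocessing before registration.

    ``median3`` applies a 3x3 median filter; ``adaptive_hist_eq`` applies
    CLAHE on an 8x8 tile grid (image rescaled to [0, 1] first).
    """
    image = np.asarray(image, dtype=float)
    if mode == "none":
        return image.copy()
    if mode == "median3":
        return ndimage.median_filter(image, size=3, mode="reflect")
    if mode == "adaptive_hist_eq":
        lo, hi = image.min(), image.max()
        if hi == lo:
            return image.copy()
        scaled = (image - lo) / (hi - lo)
        ks = tuple(max(s // 8, 1) for s in image.shape)
        return exposure.equalize_adapthist(scaled, kernel_size=ks, clip_limit=0.02)
    raise ValueError(f"unknown preprocessing mode {mode!r}")


def register_stack(stack, fraction: float = 0.20, preprocess: str = "none",
                   template_fraction: float = 0.20,
                   templates: list | None = None) -> list:
    """Per-frame displacement estimates for a multi-tile stack.

    ``stack`` is a :class:`~vipmode.synthetic.TileStack` (or any object with
    a ``tiles`` list of (frames, h, w) arrays). Returns one
    :class:`DisplacementEstimate` per frame.
    """
    tiles = [np.asarray(t, dtype=float) for t in stack.tiles]
    if preprocess != "none":
        tiles = [np.stack([preprocess_tile(f, preprocess) for f in t]) for t in tiles]
    if templates is None:
        templates = [select_templates(t, template_fraction) for t in tiles]
    n_frames = tiles[0].shape[0]
    out = []
    for f in range(n_frames):
        shifts = np.empty((len(tiles), 2))
        errors = np.empty(len(tiles))
        for i, t in enumerate(tiles):
            est = register_tile(t[f], templates[i])
            shifts[i] = (est.dy, est.dx)
            errors[i] = est.error
        cons = consensus_shift(shifts, errors, fraction)
        out.append(DisplacementEstimate(tile_shifts=shifts, tile_errors=errors,
                                        consensus=cons,
                                        fraction_used=max(fraction, 3 / len(tiles))))
    return out


def shifts_table(estimates: list) -> pd.DataFrame:
    """Per-frame consensus shifts as a tidy table (for CSV export)."""
    return pd.DataFrame([dict(frame=i, dy=e.consensus[0], dx=e.consensus[1],
                              fraction_used=e.fraction_used)
                         for i, e in enumerate(estimates)])
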