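"""Closed-form scan-rate and SNR-gain arithmetic for scanning strategies.

Compares ROI-restricted (chessboard) acousto-optic scanning against
point-by-point volume scanning and resonant-mirror scanning: volume rates
from pixel counts and dwell times, and the combined (SNR gain)^2 x speed
gain from the ratio of the total scanned volume (or field area, in 2-D) to
the summed ROI volumes (areas).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ScanGeometry:
    """Pixel counts and timing of a scanning configuration."""

    nx: int = 548
    ny: int = 507
    nz: int = 193
    dwell_time: float = 30e-6  # s per pixel
    line_rate: float | None = 16000.0  # Hz, resonant scanner
    n_layers: int | None = None
    settle_per_layer: float = 0.0  # s, z-drive settling
    roi_volumes: tuple = ()
    total_volume: float | None = None
    roi_areas: tuple = ()
    total_area: float | None = None

    def __post_init__(self):
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("pixel counts must be >= 1")
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be positive")
        if self.total_volume is not None and sum(self.roi_volumes) > self.total_volume * (1 + 1e-9):
            raise ValueError("ROI volumes exceed the total volume")
        if self.total_area is not None and sum(self.roi_areas) > self.total_area * (1 + 1e-9):
            raise ValueError("ROI areas exceed the total area")


def point_scan_rate(geometry: ScanGeometry) -> float:
    """Volume rate (Hz) of point-by-point scanning: 1 / (nx ny nz dwell)."""
    return 1.0 / (geometry.nx * geometry.ny * geometry.nz * geometry.dwell_time)


def resonant_volume_rate(line_rate: float, n_lines: int, n_planes: int,
                         settle_per_plane: float = 0.0) -> float:
    """Volume rate (Hz) of a resonant scanner with an optional z settle time."""
    if line_rate <= 0:
        raise ValueError("line_rate must be positive")
    return 1.0 / (n_lines * n_planes / line_rate + n_planes * settle_per_plane)


def roi_gain(total: float, roi_sizes) -> float:
    """Combined (SNR gain)^2 x speed gain of ROI-restricted scanning.

    ``total / sum(roi_sizes)`` with volumes in 3-D or areas in 2-D; the
    ratio is dimensionless, so any consistent unit works.
    """
    s = float(np.sum(roi_sizes))
    if s <= 0:
        raise ValueError("summed ROI size must be positive")
    return float(total) / s


def speed_gain_ratio(rate_a: float, rate_b: float) -> float:
    """Fold increase of rate_a over rate_b."""
    if rate_b <= 0:
        raise ValueError("reference rate must be positive")
    return rate_a / rate_b


def comparison_table(geometry: ScanGeometry, chessboard_rate: float = 27.8,
                     multilayer_layers: int = 19,
                     multilayer_settle: float = 0.020) -> pd.DataFrame:
    """Rate comparison of chessboard vs point and resonant scanning modes."""
    rows = [
        dict(mode="chessboard", rate_hz=chessboard_rate, fold_vs_chessboard=1.0),
        dict(mode="point_volume", rate_hz=point_scan_rate(geometry)),
        dict(mode="resonant_volume",
             rate_hz=resonant_volume_rate(geometry.line_rate, geometry.ny, geometry.nz)),
        dict(mode="resonant_multilayer",
             rate_hz=resonant_volume_rate(geometry.line_rate, geometry.ny,
                                          multilayer_layers, multilayer_settle)),
    ]
    for r in rows[1:]:
        r["fold_vs_chessboard"] = speed_gain_ratio(chessboard_rate, r["rate_hz"])
    return pd.DataFrame(rows)
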