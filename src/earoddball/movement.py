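"""Gyroscope-based gross-movement quantification.

The neck-worn amplifier's 3-axis gyroscope captures gross body movement
(shoulder-involving movement; isolated head rotations may escape it).
Per-sample *displacement* is the Euclidean magnitude of the three axes,
sqrt(yaw^2 + pitch^2 + roll^2) — a direction-free movement index whose
units cancel in all downstream thresholding.  Each participant's
movement-free threshold is the median displacement plus four times the
interquartile range, computed over all their rapid (seated) blocks;
values below it are typical of sitting quietly, so the fraction of
below-threshold samples measures how much of a block is effectively
movement-free.  For the day-long time course, displacement is categorized
per participant into SD bins above the rapid-block mean (0, 1, 2, 3+),
smoothed with a 10-s moving median, and grand-averaged across
participants on a common 1-Hz clock.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DisplacementSeries",
    "MovementThreshold",
    "displacement",
    "individual_threshold",
    "percent_below",
    "percentile_profile",
    "categorize_timecourse",
    "moving_median",
]


@dataclass
class DisplacementSeries:
    t: np.ndarray  # seconds
    d: np.ndarray  # per-sample magnitude, >= 0
    block_id: int | str = ""

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t))) if len(self.t) > 1 else np.nan


@dataclass(frozen=True)
class MovementThreshold:
    participant: int | str
    threshold: float


def displacement(
    gyro: np.ndarray, rate_hz: float = 250.0, block_id: int | str = ""
) -> DisplacementSeries:
    """Per-sample magnitude sqrt(yaw^2 + pitch^2 + roll^2)."""
    gyro = np.asarray(gyro, dtype=float)
    if gyro.ndim != 2 or gyro.shape[0] != 3:
        raise ValueError("gyro must be a 3 x samples array of aligned axes")
    d = np.sqrt((gyro**2).sum(axis=0))
    t = np.arange(gyro.shape[1]) / rate_hz
    return DisplacementSeries(t, d, block_id)


def individual_threshold(
    rapid_blocks: list[DisplacementSeries], participant: int | str = ""
) -> MovementThreshold:
    """Movement-free cutoff: median + 4 x IQR over concatenated rapid blocks.

    Quartiles use the linear-interpolation (type-7) convention.
    """
    if not rapid_blocks:
        raise ValueError("need at least one rapid block")
    d = np.concatenate([b.d for b in rapid_blocks])
    if d.size == 0:
        raise ValueError("empty displacement data")
    q1, med, q3 = np.quantile(d, [0.25, 0.5, 0.75])
    return MovementThreshold(participant, float(med + 4.0 * (q3 - q1)))


def percent_below(series: DisplacementSeries, thr: MovementThreshold) -> float:
    """Fraction of samples strictly below the movement-free threshold."""
    return float((series.d < thr.threshold).mean())


def percentile_profile(
    blocks: dict[int | str, list[DisplacementSeries]],
    percentiles: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-block displacement percentile curves averaged across participants.

    ``blocks`` maps block id -> one DisplacementSeries per participant.
    Returns a long table (block, percentile, displacement) where the
    displacement at each percentile (default 1..99) is first computed per
    participant and then averaged.
    """
    if percentiles is None:
        percentiles = np.arange(1, 100)
    rows = []
    for block, series_list in blocks.items():
        if not series_list:
            raise ValueError(f"block {block!r} has no participants")
        curves = np.stack(
            [np.percentile(s.d, percentiles) for s in series_list]
        )
        for p, v in zip(percentiles, curves.mean(axis=0)):
            rows.append({"block": block, "percentile": p, "displacement": v})
    return pd.DataFrame(rows)


def moving_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving median with edge truncation."""
    s = pd.Series(x)
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def categorize_timecourse(
    series: list[DisplacementSeries],
    rapid_stats: dict[int | str, tuple[float, float]],
    participants: list[int | str],
    *,
    smooth_s: float = 10.0,
    out_rate_hz: float = 1.0,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """SD-binned movement categories, smoothed and grand-averaged.

    Per sample, category = how many participant SDs the displacement sits
    above the participant's rapid-block mean, floored and clipped to
    0..3 ('3' = three or more).  The per-participant category trace is
    smoothed with a centered ``smooth_s`` moving median, resampled to
    ``out_rate_hz``, and averaged across participants over the clock span
    covered by at least ``min_coverage`` of them.  Returns a long table
    (t_s, participant, category) plus rows with participant='grand'
    carrying the average.
    """
    rows = []
    per_part: dict[int | str, tuple[np.ndarray, np.ndarray]] = {}
    for s, p in zip(series, participants):
        mean, sd = rapid_stats[p]
        if sd <= 0:
            warnings.warn(f"participant {p!r}: zero rapid-block SD; all category 0")
            cat = np.zeros_like(s.d)
        else:
            cat = np.clip(np.floor(np.maximum(s.d - mean, 0.0) / sd), 0, 3)
        win = max(int(round(smooth_s * s.rate_hz)), 1)
        cat = moving_median(cat, win)
        # resample to the common clock by block-averaging
        step = max(int(round(s.rate_hz / out_rate_hz)), 1)
        n_out = len(cat) // step
        t_out = s.t[: n_out * step : step]
        c_out = cat[: n_out * step].reshape(n_out, step).mean(axis=1)
        if p in per_part:  # concatenate multiple blocks of one participant
            t_prev, c_prev = per_part[p]
            t_out = np.concatenate([t_prev, t_out])
            c_out = np.concatenate([c_prev, c_out])
        per_part[p] = (t_out, c_out)

    for p, (t_out, c_out) in per_part.items():
        for t, c in zip(t_out, c_out):
            rows.append({"t_s": float(t), "participant": p, "category": float(c)})
    frame = pd.DataFrame(rows)

    # grand average over the span covered by enough participants
    pivot = frame.pivot_table(index="t_s", columns="participant", values="category")
    coverage = pivot.notna().mean(axis=1)
    grand = pivot[coverage >= min_coverage].mean(axis=1)
    grand_rows = pd.DataFrame(
        {"t_s": grand.index, "participant": "grand", "category": grand.values}
    )
    return pd.concat([frame, grand_rows], ignore_index=True)
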