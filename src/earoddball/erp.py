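"""Stimulus-locked epoching and P3 amplitude extraction.

Epochs run from -0.2 to 0.8 s around the onset of the first tone of each
double tone (half-open on the right, so exactly 250 samples at 250 Hz) and
are baseline-corrected to the -200-0 ms mean.  Exclusions mirror the
analysis protocol: the first two epochs of every block, missed targets,
and familiarization trials.  Remaining epochs pass a single-pass
joint-probability rejection (local and global threshold of two SDs).  The
single analysis channel is the vertical bipolar cEEGrid derivation
(R2+R3)/2 - (R6+R7)/2; the per-trial P3 amplitude is the mean within the
grand-average peak latency +/- 100 ms, the peak searched between 200 and
600 ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from earoddball.paradigm import Schedule
from earoddball.synthgen import Recording

__all__ = [
    "EpochSet",
    "P3Window",
    "extract_epochs",
    "reject_jointprob",
    "derive_bipolar",
    "grand_average",
    "find_p3_window",
    "extract_amplitudes",
]

EPOCH_START_S = -0.2
EPOCH_STOP_S = 0.8
BASELINE_S = (-0.2, 0.0)
P3_SEARCH_MS = (200.0, 600.0)


@dataclass
class EpochSet:
    """Baseline-corrected stimulus-locked segments with bookkeeping.

    ``epochs`` is trials x channels x samples; ``kept`` marks epochs that
    survive all exclusions so far; ``rejection_reason`` is one of none,
    first_two, missed_target, out_of_bounds, jointprob_local,
    jointprob_global.
    """

    epochs: np.ndarray
    roles: np.ndarray  # per-epoch "standard" | "target"
    kept: np.ndarray  # bool per epoch
    rejection_reason: np.ndarray  # str per epoch
    times: np.ndarray  # seconds relative to stimulus onset
    labels: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def subset(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(
            self.epochs[mask],
            self.roles[mask],
            self.kept[mask],
            self.rejection_reason[mask],
            self.times,
            self.labels,
            dict(self.meta),
        )


@dataclass(frozen=True)
class P3Window:
    peak_latency_ms: float
    window_ms: tuple[float, float]
    search_range_ms: tuple[float, float] = P3_SEARCH_MS


def extract_epochs(
    rec: Recording,
    schedule: Schedule | None = None,
    behavior: pd.DataFrame | None = None,
    *,
    participant: int | None = None,
) -> EpochSet:
    """Cut, baseline-correct, and book-keep epochs for one block.

    Stimulus events come from ``rec.events``.  Familiarization
    (unscored) trials are dropped outright; the first two scored epochs
    and targets marked missed in ``behavior`` (matched by trial index,
    and by participant when given) stay in the set but are flagged
    unkept with their reason.  Events whose epoch would leave the
    recording are flagged ``out_of_bounds``.
    """
    rate = rec.eeg_rate_hz
    n0 = int(round(EPOCH_START_S * rate))
    n1 = int(round(EPOCH_STOP_S * rate))
    times = np.arange(n0, n1) / rate
    base = times < BASELINE_S[1]

    ev = rec.events
    ev = ev[ev.role.isin(["standard", "target"])].reset_index(drop=True)
    scored = ev[ev.scored].reset_index(drop=True)

    missed: set[int] = set()
    if behavior is not None:
        b = behavior
        if participant is not None and "participant" in b:
            b = b[b.participant == participant]
        if "block" in b and "block" in rec.meta:
            b = b[b.block == rec.meta["block"]]
        missed = set(b[b.miss].trial.astype(int))

    n_samp = rec.eeg.shape[1]
    epochs, roles, kept, reasons = [], [], [], []
    for k, row in scored.iterrows():
        center = int(round(row.t_s * rate))
        a, b_ = center + n0, center + n1
        if a < 0 or b_ > n_samp:
            seg = np.zeros((rec.eeg.shape[0], n1 - n0))
            reason, keep = "out_of_bounds", False
        else:
            seg = rec.eeg[:, a:b_].astype(float)
            seg = seg - seg[:, base].mean(axis=1, keepdims=True)
            if k < 2:
                reason, keep = "first_two", False
            elif row.role == "target" and int(row.trial_index) in missed:
                reason, keep = "missed_target", False
            else:
                reason, keep = "none", True
        epochs.append(seg)
        roles.append(row.role)
        kept.append(keep)
        reasons.append(reason)

    return EpochSet(
        np.asarray(epochs),
        np.asarray(roles, dtype=object),
        np.asarray(kept, dtype=bool),
        np.asarray(reasons, dtype=object),
        times,
        tuple(rec.labels),
        {k: rec.meta[k] for k in ("participant", "block", "variant") if k in rec.meta},
    )


def reject_jointprob(
    eset: EpochSet, z_thresh: float = 2.0, *, n_bins: int = 100
) -> EpochSet:
    """Single-pass joint-probability epoch rejection.

    Per channel, the empirical distribution of all kept epochs' sample
    values is estimated with a fixed-bin histogram over the pooled range;
    each epoch's joint log-probability per channel is the sum of log
    densities of its samples.  An epoch is rejected when its
    improbability — the negative z-score of that statistic across epochs —
    exceeds ``z_thresh`` on any single channel (local) or on the channel
    average (global), the one-sided convention of the standard tool:
    only improbable epochs are artifacts, never unusually typical ones.
    """
    out = eset.subset(np.ones(len(eset.epochs), dtype=bool))
    kept_idx = np.flatnonzero(out.kept)
    if kept_idx.size < 10:
        return out
    data = out.epochs[kept_idx]  # kept x channels x samples
    n_kept, n_ch, _ = data.shape
    logp = np.zeros((n_kept, n_ch))
    for c in range(n_ch):
        pooled = data[:, c, :].ravel()
        lo, hi = pooled.min(), pooled.max()
        if hi <= lo:  # degenerate: all values equal
            continue
        hist, edges = np.histogram(pooled, bins=n_bins, range=(lo, hi), density=True)
        which = np.clip(np.searchsorted(edges, data[:, c, :], "right") - 1, 0, n_bins - 1)
        logp[:, c] = np.log(hist[which] + 1e-12).sum(axis=1)

    def zscore(v: np.ndarray) -> np.ndarray:
        sd = v.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return (v - v.mean(axis=0)) / sd

    local = (-zscore(logp)).max(axis=1) > z_thresh
    global_ = -zscore(logp.mean(axis=1)) > z_thresh
    for i, (loc, glo) in zip(kept_idx, zip(local, global_)):
        if loc or glo:
            out.kept[i] = False
            out.rejection_reason[i] = (
                "jointprob_local" if loc else "jointprob_global"
            )
    return out


def derive_bipolar(eset: EpochSet) -> EpochSet:
    """Vertical bipolar cEEGrid channel: (R2+R3)/2 - (R6+R7)/2."""
    need = ("R2", "R3", "R6", "R7")
    missing = [lab for lab in need if lab not in eset.labels]
    if missing:
        raise ValueError(f"bipolar derivation requires channels {missing}")
    i = {lab: eset.labels.index(lab) for lab in need}
    y = 0.5 * (eset.epochs[:, i["R2"]] + eset.epochs[:, i["R3"]]) - 0.5 * (
        eset.epochs[:, i["R6"]] + eset.epochs[:, i["R7"]]
    )
    return EpochSet(
        y[:, None, :],
        eset.roles.copy(),
        eset.kept.copy(),
        eset.rejection_reason.copy(),
        eset.times,
        ("bipolar",),
        dict(eset.meta),
    )


def grand_average(
    esets: list[EpochSet], role: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Participant-weighted grand average of kept bipolar epochs.

    Each epoch set (one participant-block) contributes its own kept-epoch
    average; those averages are averaged with equal weight so participants
    with unequal trial counts count equally.  Returns (times, waveform).
    """
    waves = []
    times = None
    for es in esets:
        mask = es.kept if role is None else es.kept & (es.roles == role)
        if not mask.any():
            continue
        waves.append(es.epochs[mask, 0, :].mean(axis=0))
        times = es.times
    if not waves:
        raise ValueError("no kept epochs to average")
    return times, np.mean(waves, axis=0)


def find_p3_window(
    times: np.ndarray,
    grand_avg: np.ndarray,
    search_range_ms: tuple[float, float] = P3_SEARCH_MS,
) -> P3Window:
    """Peak-latency +/- 100 ms extraction window from a grand average.

    The peak is the maximum (the P3 is a positivity) within the search
    range; ties break to the earliest latency, with a warning for a
    perfectly flat waveform.
    """
    t_ms = np.asarray(times) * 1000.0
    mask = (t_ms >= search_range_ms[0]) & (t_ms <= search_range_ms[1])
    if not mask.any():
        raise ValueError("grand average does not cover the search range")
    seg = np.asarray(grand_avg)[mask]
    if np.allclose(seg, seg[0]):
        warnings.warn("flat waveform in search range; peak set to range start")
    peak_ms = float(t_ms[mask][np.argmax(seg)])
    return P3Window(peak_ms, (peak_ms - 100.0, peak_ms + 100.0), search_range_ms)


def extract_amplitudes(eset: EpochSet, window: P3Window) -> pd.DataFrame:
    """Per-trial mean bipolar amplitude inside the extraction window.

    One row per kept epoch: (participant, block, condition, role, trial,
    amplitude_uv).  Raises if the window leaves the epoch support.
    """
    t_ms = eset.times * 1000.0
    lo, hi = window.window_ms
    if lo < t_ms[0] or hi > t_ms[-1] + 1e-9:
        raise ValueError("extraction window outside epoch support")
    sel = (t_ms >= lo - 1e-9) & (t_ms <= hi + 1e-9)
    rows = []
    for i in np.flatnonzero(eset.kept):
        rows.append(
            {
                "participant": eset.meta.get("participant", 0),
                "block": eset.meta.get("block", 0),
                "condition": eset.meta.get("variant", ""),
                "role": eset.roles[i],
                "trial": i,
                "amplitude_uv": float(eset.epochs[i, 0, sel].mean()),
            }
        )
    return pd.DataFrame(rows)
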