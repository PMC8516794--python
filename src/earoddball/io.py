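"""Session persistence, configuration, and the run manifest.

The canonical on-disk layout for one session is::

    session_dir/
      manifest.json                 seeds, config hash, stage status
      schedules/block-<b>.tsv(.json)  event tables + sidecars
      behavior.tsv
      sub-<p>/block-<b>/
        header.json                 labels, rates, shapes, meta
        eeg.bin                     float32, channels x samples, C order
        gyro.tsv                    t_s, yaw, pitch, roll (optional)
        events.tsv
        ground_truth.json           artifact log + run-length gyro states

EEG is stored as raw float32, so a write/read round trip reproduces the
written stream bit-exactly.  A missing gyro stream is tolerated: the EEG
pipeline runs and the movement stage is skipped with a logged reason.
All stage parameters live in a flat TOML config whose defaults are the
published analysis values.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from earoddball.paradigm import Schedule, read_schedule, write_schedule
from earoddball.synthgen import Recording

__all__ = [
    "default_config",
    "load_config",
    "config_hash",
    "write_recording",
    "read_recording",
    "write_session",
    "read_session",
    "Manifest",
]


def default_config() -> dict:
    """All stage parameters with the published analysis values as defaults."""
    return {
        "paradigm": {
            "n_trials": 160,
            "target_fraction": 0.3,
            "rapid_isi_s": [0.5, 0.9],
            "sporadic_isi_s": [56.2, 61.2],
        },
        "filter": {
            "lowpass_hz": 10.0,
            "lowpass_order": 330,
            "highpass_hz": 0.1,
            "highpass_order": 8250,
        },
        "asr": {"flatline_s": 60.0, "burst_cutoff_k": 20.0, "highpass_band_hz": [0.25, 0.75]},
        "rejection": {"amp_limit_uv": 500.0, "spectral_z": 2.0, "jointprob_z": 2.0},
        "erp": {
            "epoch_s": [-0.2, 0.8],
            "baseline_s": [-0.2, 0.0],
            "search_range_ms": [200.0, 600.0],
            "window_halfwidth_ms": 100.0,
        },
        "movement": {"threshold_iqr_multiplier": 4.0, "smooth_s": 10.0},
        "stats": {"alpha": 0.05, "correction": "bonferroni"},
    }


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, with any TOML file entries overriding (overrides logged)."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    for section, values in user.items():
        cfg.setdefault(section, {}).update(values)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha1(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


def _rle(values: np.ndarray) -> list[list]:
    """Run-length encode a vector of labels."""
    out = []
    for v in values:
        if out and out[-1][0] == v:
            out[-1][1] += 1
        else:
            out.append([v, 1])
    return [[str(v), int(n)] for v, n in out]


def _unrle(runs: list[list]) -> np.ndarray:
    return np.concatenate([[v] * n for v, n in runs]) if runs else np.array([])


def write_recording(rec: Recording, path: str | Path, ground_truth: list | None = None):
    """Write one block recording in the native layout."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    eeg32 = np.ascontiguousarray(rec.eeg, dtype=np.float32)
    eeg32.tofile(path / "eeg.bin")
    meta = {k: v for k, v in rec.meta.items() if k != "gyro_states"}
    header = {
        "labels": list(rec.labels),
        "eeg_rate_hz": rec.eeg_rate_hz,
        "gyro_rate_hz": rec.gyro_rate_hz,
        "eeg_shape": list(eeg32.shape),
        "has_gyro": rec.gyro is not None,
        "meta": meta,
    }
    (path / "header.json").write_text(json.dumps(header, indent=1))
    rec.events.to_csv(path / "events.tsv", sep="\t", index=False)
    if rec.gyro is not None:
        t = np.arange(rec.gyro.shape[1]) / rec.gyro_rate_hz
        pd.DataFrame(
            {"t_s": t, "yaw": rec.gyro[0], "pitch": rec.gyro[1], "roll": rec.gyro[2]}
        ).to_csv(path / "gyro.tsv", sep="\t", index=False, float_format="%.4f")
    truth = {"artifact_log": ground_truth or []}
    if "gyro_states" in rec.meta:
        truth["gyro_states_rle"] = _rle(np.asarray(rec.meta["gyro_states"]))
    (path / "ground_truth.json").write_text(json.dumps(truth))


def read_recording(path: str | Path) -> Recording:
    """Read one block recording; raises naming any missing required stream."""
    path = Path(path)
    for required in ("header.json", "eeg.bin", "events.tsv"):
        if not (path / required).exists():
            raise FileNotFoundError(f"missing stream {required!r} in {path}")
    header = json.loads((path / "header.json").read_text())
    eeg = np.fromfile(path / "eeg.bin", dtype=np.float32).reshape(header["eeg_shape"])
    events = pd.read_csv(path / "events.tsv", sep="\t")
    gyro = None
    if header.get("has_gyro") and (path / "gyro.tsv").exists():
        g = pd.read_csv(path / "gyro.tsv", sep="\t")
        gyro = np.vstack([g.yaw, g.pitch, g.roll])
    meta = dict(header.get("meta", {}))
    truth_path = path / "ground_truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        meta["artifact_log"] = truth.get("artifact_log", [])
        if "gyro_states_rle" in truth:
            meta["gyro_states"] = _unrle(truth["gyro_states_rle"])
    return Recording(
        eeg.astype(np.float32),
        gyro,
        events,
        header["eeg_rate_hz"],
        header["gyro_rate_hz"],
        tuple(header["labels"]),
        meta,
    )


class Manifest:
    """Session bookkeeping: seeds, config hash, per-stage status, files."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.path = self.root / "manifest.json"
        self.data = (
            json.loads(self.path.read_text())
            if self.path.exists()
            else {"seeds": {}, "stages": {}, "files": {}, "config_hash": ""}
        )

    def update(self, **kwargs) -> None:
        self.data.update(kwargs)
        self.save()

    def set_stage(self, stage: str, status: str, **extra) -> None:
        self.data["stages"][stage] = {"status": status, **extra}
        self.save()

    def save(self) -> None:
        self.root.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.data, indent=1, default=str))


def write_session(session: dict, root: str | Path, *, seed: int | None = None) -> None:
    """Persist a simulated session (output of synthgen.simulate_session)."""
    root = Path(root)
    (root / "schedules").mkdir(parents=True, exist_ok=True)
    for b, sched in session["schedules"].items():
        write_schedule(sched, root / "schedules" / f"block-{b}.tsv")
    session["behavior"].to_csv(root / "behavior.tsv", sep="\t", index=False)
    for (p, b), rec in session["recordings"].items():
        write_recording(
            rec,
            root / f"sub-{p:02d}" / f"block-{b}",
            session["artifact_logs"].get((p, b)),
        )
    man = Manifest(root)
    man.update(seeds={"session": seed}, config_hash=config_hash(default_config()))
    man.set_stage("simulate", "done", n_recordings=len(session["recordings"]))


def read_session(root: str | Path) -> dict:
    """Reconstruct a session dict from the native layout."""
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(root)
    schedules: dict[int, Schedule] = {}
    for f in sorted((root / "schedules").glob("block-*.tsv")):
        b = int(f.stem.split("-")[1])
        schedules[b] = read_schedule(f)
    behavior = pd.read_csv(root / "behavior.tsv", sep="\t")
    recordings, logs = {}, {}
    for sub in sorted(root.glob("sub-*")):
        p = int(sub.name.split("-")[1])
        for blk in sorted(sub.glob("block-*")):
            b = int(blk.name.split("-")[1])
            rec = read_recording(blk)
            recordings[(p, b)] = rec
            logs[(p, b)] = rec.meta.get("artifact_log", [])
    return {
        "recordings": recordings,
        "schedules": schedules,
        "behavior": behavior,
        "artifact_logs": logs,
    }
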