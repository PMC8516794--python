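"""Auditory oddball paradigm: trial sequences, block schedules, double tones.

Two block variants are supported.  The *rapid* variant is a classical
oddball: 160 double tones in quick succession (inter-trial interval, ITI,
drawn uniformly from 0.5-0.9 s, offset-to-onset), lasting about five
minutes.  The *sporadic* variant spreads the same 160 trials over roughly
160 minutes (ITI uniform on 56.2-61.2 s) so the task can run in the
background of normal office work.  Both variants present 112 standards
(70%) and 48 targets (30%); the first four trials are always standards and
targets never occur more than twice in a row.

Each trial is a *double tone*: a 700-ms tone, 100 ms of silence, then a
500-ms tone of the same pitch, 1300 ms in total.  One pitch (100 Hz
fundamental, oboe-like) serves as standard and the other (300 Hz,
clarinet-like) as target, or vice versa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DoubleToneSpec",
    "Trial",
    "Schedule",
    "generate_sequence",
    "generate_schedule",
    "render_double_tone",
    "write_schedule",
    "read_schedule",
    "RAPID_ISI_RANGE_S",
    "SPORADIC_ISI_RANGE_S",
]

#: Offset-to-onset inter-trial interval ranges, seconds.
RAPID_ISI_RANGE_S = (0.5, 0.9)
SPORADIC_ISI_RANGE_S = (56.2, 61.2)

#: Number of familiarization trials at each end of a sporadic block.
N_FAMILIARIZATION = 10

#: Scored trials after which the sporadic block pauses for a rest break.
REST_BREAK_AFTER = 80


class ConstraintError(ValueError):
    """Raised when a requested trial sequence is infeasible."""


@dataclass(frozen=True)
class DoubleToneSpec:
    """Timing and pitch parameters of the double-tone stimuli."""

    f0_standard_hz: float = 100.0
    f0_target_hz: float = 300.0
    tone1_ms: float = 700.0
    gap_ms: float = 100.0
    tone2_ms: float = 500.0
    ramp_ms: float = 5.0
    audio_rate_hz: float = 44100.0

    def __post_init__(self) -> None:
        if self.ramp_ms >= min(self.tone1_ms, self.tone2_ms):
            raise ValueError("ramp must be shorter than each tone")

    @property
    def total_ms(self) -> float:
        return self.tone1_ms + self.gap_ms + self.tone2_ms

    @property
    def duration_s(self) -> float:
        return self.total_ms / 1000.0


@dataclass(frozen=True)
class Trial:
    """One double-tone presentation within a block."""

    index: int
    role: str  # "standard" | "target"
    onset_s: float
    stimulus_duration_s: float
    scored: bool = True


@dataclass
class Schedule:
    """Ordered trials of one oddball block plus its generation parameters."""

    variant: str  # "rapid" | "sporadic"
    trials: list[Trial]
    isi_range_s: tuple[float, float]
    seed: int
    spec: DoubleToneSpec = field(default_factory=DoubleToneSpec)
    rest_break_s: float | None = None  # onset of the mid-block rest marker

    @property
    def scored_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.scored]

    @property
    def n_standards(self) -> int:
        return sum(1 for t in self.scored_trials if t.role == "standard")

    @property
    def n_targets(self) -> int:
        return sum(1 for t in self.scored_trials if t.role == "target")

    @property
    def duration_s(self) -> float:
        """First scored onset to last scored tone offset."""
        sc = self.scored_trials
        return sc[-1].onset_s + sc[-1].stimulus_duration_s - sc[0].onset_s

    @property
    def span_s(self) -> float:
        """Full span including familiarization trials."""
        return self.trials[-1].onset_s + self.trials[-1].stimulus_duration_s

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "onset_s": t.onset_s,
                "role": t.role,
                "scored": t.scored,
                "marker": f"{'T' if t.role == 'target' else 'S'}",
            }
            for t in self.trials
        ]
        return pd.DataFrame(rows)


def generate_sequence(
    n_trials: int,
    target_fraction: float,
    seed: int | np.random.Generator,
    *,
    n_leading_standards: int = 4,
    max_run: int = 2,
    max_attempts: int = 100_000,
) -> list[str]:
    """Randomize trial roles under the oddball sequencing constraints.

    Returns a list of ``n_trials`` roles with exactly
    ``round(n_trials * target_fraction)`` targets, the first
    ``n_leading_standards`` trials all standards, and never more than
    ``max_run`` targets in succession.  Sampling is by rejection from
    uniform shuffles, so every admissible order is equally likely.
    """
    if n_trials < n_leading_standards:
        raise ConstraintError(
            f"need at least {n_leading_standards} trials, got {n_trials}"
        )
    n_targets = int(round(n_trials * target_fraction))
    n_rest = n_trials - n_leading_standards
    if n_targets > n_rest:
        raise ConstraintError("too many targets for the free positions")
    # max_run targets per (standard-separated) slot bounds feasibility
    n_standards_rest = n_rest - n_targets
    if n_targets > max_run * (n_standards_rest + 1):
        raise ConstraintError(
            f"{n_targets} targets cannot be placed with runs <= {max_run}"
        )
    rng = np.random.default_rng(seed)
    rest = np.zeros(n_rest, dtype=np.int8)
    rest[:n_targets] = 1
    for _ in range(max_attempts):
        rng.shuffle(rest)
        if n_targets == 0 or not _has_long_run(rest, max_run):
            roles = np.concatenate([np.zeros(n_leading_standards, np.int8), rest])
            return ["target" if r else "standard" for r in roles]
    raise ConstraintError("rejection sampling failed to find a valid order")


def _has_long_run(x: np.ndarray, max_run: int) -> bool:
    """True if ``x`` (0/1) contains a run of >max_run ones."""
    if len(x) <= max_run:
        return False
    window = np.ones(max_run + 1, dtype=np.int8)
    return bool(np.convolve(x, window, mode="valid").max() > max_run)


def generate_schedule(
    variant: str,
    seed: int,
    *,
    spec: DoubleToneSpec | None = None,
    n_trials: int = 160,
    target_fraction: float = 0.3,
    isi_range_s: tuple[float, float] | None = None,
) -> Schedule:
    """Generate one block schedule (trial roles and onset times).

    ``isi_range_s`` overrides the variant's default inter-trial interval
    range; this is how time-compressed sporadic-parameter blocks are
    produced for simulation studies.
    """
    if variant not in ("rapid", "sporadic"):
        raise ValueError(f"unknown variant {variant!r}")
    spec = spec or DoubleToneSpec()
    if isi_range_s is None:
        isi_range_s = RAPID_ISI_RANGE_S if variant == "rapid" else SPORADIC_ISI_RANGE_S
    rng = np.random.default_rng(seed)
    roles = generate_sequence(n_trials, target_fraction, rng)
    dur = spec.duration_s

    trials: list[Trial] = []
    t = 0.0
    index = 0

    def emit(role: str, scored: bool, isi: float) -> None:
        nonlocal t, index
        trials.append(Trial(index, role, round(t, 6), dur, scored))
        index += 1
        t += dur + isi

    def familiarization() -> None:
        # alternating standard/target at rapid pacing, unscored
        for k in range(N_FAMILIARIZATION):
            role = "standard" if k % 2 == 0 else "target"
            emit(role, False, rng.uniform(*RAPID_ISI_RANGE_S))

    rest_break_s: float | None = None
    if variant == "sporadic":
        familiarization()
    for k, role in enumerate(roles):
        emit(role, True, rng.uniform(*isi_range_s))
        if variant == "sporadic" and k + 1 == REST_BREAK_AFTER:
            rest_break_s = t  # one-minute eyes-closed rest marker
            t += 60.0
    if variant == "sporadic":
        familiarization()
    return Schedule(variant, trials, isi_range_s, seed, spec, rest_break_s)


def _tone(
    f0: float, dur_ms: float, ramp_ms: float, rate: float, harmonics: tuple[int, ...]
) -> np.ndarray:
    n = int(round(dur_ms / 1000.0 * rate))
    t = np.arange(n) / rate
    y = sum((1.0 / k) * np.sin(2 * np.pi * k * f0 * t) for k in harmonics)
    n_ramp = int(round(ramp_ms / 1000.0 * rate))
    env = np.ones(n)
    env[:n_ramp] = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
    env[n - n_ramp :] = np.linspace(1.0, 0.0, n_ramp)
    return np.asarray(y) * env


# fixed harmonic recipes: all harmonics decaying 1/k (oboe-like) vs
# odd-dominant (clarinet-like); exact timbre never enters the analysis
_OBOE = tuple(range(1, 11))
_CLARINET = (1, 3, 5, 7, 9)


def render_double_tone(spec: DoubleToneSpec, role: str) -> np.ndarray:
    """Synthesize the double-tone waveform for one role, RMS-normalized.

    The standard uses an all-harmonic (oboe-like) timbre at the standard
    fundamental; the target an odd-dominant (clarinet-like) timbre at the
    target fundamental.  Both waveforms are normalized to unit RMS over the
    sounding samples so the two roles have identical intensity.
    """
    if role == "standard":
        f0, harmonics = spec.f0_standard_hz, _OBOE
    elif role == "target":
        f0, harmonics = spec.f0_target_hz, _CLARINET
    else:
        raise ValueError(f"unknown role {role!r}")
    rate = spec.audio_rate_hz
    tone1 = _tone(f0, spec.tone1_ms, spec.ramp_ms, rate, harmonics)
    tone2 = _tone(f0, spec.tone2_ms, spec.ramp_ms, rate, harmonics)
    gap = np.zeros(int(round(spec.gap_ms / 1000.0 * rate)))
    y = np.concatenate([tone1, gap, tone2])
    sounding = np.concatenate([tone1, tone2])
    return y / np.sqrt(np.mean(sounding**2))


def write_wav(waveform: np.ndarray, path: str | Path, rate_hz: float = 44100.0) -> None:
    """Write a waveform as 16-bit PCM WAV, peak-normalized to -1 dBFS."""
    from scipy.io import wavfile

    peak = np.abs(waveform).max() or 1.0
    scaled = np.round(waveform / peak * 0.891 * 32767).astype(np.int16)
    wavfile.write(str(path), int(rate_hz), scaled)


def write_schedule(schedule: Schedule, path: str | Path) -> None:
    """Serialize a schedule as a TSV event table plus a JSON sidecar."""
    path = Path(path)
    schedule.to_frame().to_csv(path, sep="\t", index=False)
    sidecar = {
        "variant": schedule.variant,
        "isi_range_s": list(schedule.isi_range_s),
        "seed": schedule.seed,
        "rest_break_s": schedule.rest_break_s,
        "spec": {
            "f0_standard_hz": schedule.spec.f0_standard_hz,
            "f0_target_hz": schedule.spec.f0_target_hz,
            "tone1_ms": schedule.spec.tone1_ms,
            "gap_ms": schedule.spec.gap_ms,
            "tone2_ms": schedule.spec.tone2_ms,
            "ramp_ms": schedule.spec.ramp_ms,
            "audio_rate_hz": schedule.spec.audio_rate_hz,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_schedule(path: str | Path) -> Schedule:
    """Read a schedule written by :func:`write_schedule`."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = DoubleToneSpec(**meta["spec"])
    trials = [
        Trial(i, row.role, float(row.onset_s), spec.duration_s, bool(row.scored))
        for i, row in enumerate(table.itertuples())
    ]
    return Schedule(
        meta["variant"],
        trials,
        tuple(meta["isi_range_s"]),
        meta["seed"],
        spec,
        meta.get("rest_break_s"),
    )
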