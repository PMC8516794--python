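#!/usr/bin/env python
"""Simulate the study's synthetic stand-in dataset.

Eight participants, five blocks (rapid / sporadic / rapid / sporadic /
rapid), behavioral responses from the published GLMM estimates, EEG with
the published ERP amplitudes and latencies, and a modest artifact mix
(movement-locked bursts, one flatline channel, one drift-heavy channel,
sparse large transients).  Sporadic blocks are generated at rapid pacing
(identical trial counts/roles; see docs/methods.md).  The session is
written to scratch/session/ in the native layout; summary counts go to
results/session_summary.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from earoddball import pipeline, synthgen  # noqa: E402

ROOT = Path(__file__).resolve().parents[1]
SESSION = ROOT / "scratch" / "session"
SEED = 2024

plan = synthgen.ArtifactPlan(
    bursts_per_min=0.5,
    burst_amp_factor=20.0,
    movement_coupling_gain=1.0,
    flatlines=(("L5", 120.0, 90.0),),
    noisy_channels=(("L8", 12.0),),
    transients_per_min=0.3,
)

session = pipeline.stage_simulate(SESSION, SEED, artifact_plan=plan)

beh = session["behavior"]
summary = {
    "n_participants": 8,
    "n_blocks": len(session["schedules"]),
    "block_variants": {b: s.variant for b, s in session["schedules"].items()},
    "n_targets_total": int(len(beh)),
    "observed_miss_rate_rapid": float(beh[beh.condition == "rapid"].miss.mean()),
    "observed_miss_rate_sporadic": float(beh[beh.condition == "sporadic"].miss.mean()),
    "observed_median_rt_rapid_s": float(
        beh[(beh.condition == "rapid") & ~beh.miss].rt_s.median()
    ),
    "observed_median_rt_sporadic_s": float(
        beh[(beh.condition == "sporadic") & ~beh.miss].rt_s.median()
    ),
    "n_artifacts_injected": sum(len(v) for v in session["artifact_logs"].values()),
    "seed": SEED,
}
(ROOT / "results").mkdir(exist_ok=True)
(ROOT / "results" / "session_summary.json").write_text(json.dumps(summary, indent=1))
print(json.dumps(summary, indent=1))
print(f"\nsession written to {SESSION}")
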