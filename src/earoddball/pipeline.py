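"""End-to-end session pipeline stages over the native on-disk layout.

Each stage reads what the previous one wrote, updates the run manifest,
and is a no-op-equivalent on re-run with unchanged inputs (outputs are
rewritten deterministically).  The `analysis/` drivers and the command
line both call these functions.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from earoddball import erp as erp_mod
from earoddball import movement as mov
from earoddball import sigproc
from earoddball import stats as stats_mod
from earoddball.io import Manifest, read_recording, read_session, write_session
from earoddball.synthgen import (
    ArtifactPlan,
    ParticipantProfile,
    SessionConfig,
    simulate_session,
)

__all__ = [
    "stage_simulate",
    "stage_preprocess",
    "stage_erp",
    "stage_movement",
    "stage_stats",
    "run_all",
]

#: Sporadic blocks time-compressed to rapid pacing for EEG simulation runs;
#: epoch content is unaffected (epochs never overlap at either pacing).
COMPRESSED_SPORADIC_ISI_S = (0.5, 0.9)


def stage_simulate(
    root: str | Path,
    seed: int,
    *,
    n_participants: int = 8,
    compress_sporadic: bool = True,
    artifact_plan: ArtifactPlan | None = None,
    profile: ParticipantProfile | None = None,
) -> dict:
    """Simulate and persist a full synthetic session."""
    root = Path(root)
    config = SessionConfig(
        n_participants=n_participants,
        artifact_plan=artifact_plan or ArtifactPlan(),
    )
    session = simulate_session(
        config,
        seed,
        profile=profile,
        sporadic_isi_range_s=COMPRESSED_SPORADIC_ISI_S if compress_sporadic else None,
    )
    write_session(session, root, seed=seed)
    return session


def stage_preprocess(root: str | Path) -> dict:
    """Clean every block recording; write cleaned EEG and channel reports."""
    root = Path(root)
    man = Manifest(root)
    reports = {}
    for sub in sorted(root.glob("sub-*")):
        for blk in sorted(sub.glob("block-*")):
            rec = read_recording(blk)
            cleaned, report = sigproc.clean_recording(rec)
            reports[f"{sub.name}/{blk.name}"] = report.to_dict()
            out = blk / "cleaned"
            out.mkdir(exist_ok=True)
            np.ascontiguousarray(cleaned.eeg, dtype=np.float32).tofile(
                out / "eeg.bin"
            )
            (out / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
    (root / "channel_reports.json").write_text(json.dumps(reports, indent=1))
    n_discarded = sum(r["block_discarded"] for r in reports.values())
    man.set_stage("preprocess", "done", n_blocks=len(reports), n_discarded=n_discarded)
    return reports


def _load_cleaned(blk: Path):
    rec = read_recording(blk)
    cleaned_bin = blk / "cleaned" / "eeg.bin"
    if cleaned_bin.exists():
        rec.eeg = np.fromfile(cleaned_bin, dtype=np.float32).reshape(rec.eeg.shape)
        report = json.loads((blk / "cleaned" / "report.json").read_text())
        if report["block_discarded"]:
            return None
    return rec


def stage_erp(root: str | Path, jointprob_z: float = 2.0) -> pd.DataFrame:
    """Epoch, reject, window and score P3 amplitudes for every condition.

    Writes the per-trial amplitude table, the per-condition extraction
    windows, grand-average waveforms, and rejection bookkeeping.
    """
    root = Path(root)
    man = Manifest(root)
    behavior = pd.read_csv(root / "behavior.tsv", sep="\t")
    esets: dict[str, list] = {"rapid": [], "sporadic": []}
    for sub in sorted(root.glob("sub-*")):
        p = int(sub.name.split("-")[1])
        for blk in sorted(sub.glob("block-*")):
            rec = _load_cleaned(blk)
            if rec is None:
                continue
            es = erp_mod.extract_epochs(rec, behavior=behavior, participant=p)
            es = erp_mod.reject_jointprob(es, jointprob_z)
            esets[rec.meta["variant"]].append(erp_mod.derive_bipolar(es))

    tables, windows, waves = [], {}, []
    for cond, sets in esets.items():
        if not sets:
            continue
        times, ga = erp_mod.grand_average(sets)
        win = erp_mod.find_p3_window(times, ga)
        windows[cond] = {
            "peak_latency_ms": win.peak_latency_ms,
            "window_ms": list(win.window_ms),
        }
        for role in ("standard", "target"):
            _, w = erp_mod.grand_average(sets, role)
            waves.append(
                pd.DataFrame(
                    {"condition": cond, "role": role, "t_s": times, "uv": w}
                )
            )
        for es in sets:
            tables.append(erp_mod.extract_amplitudes(es, win))

    amplitudes = pd.concat(tables, ignore_index=True)
    amplitudes.to_csv(root / "p3_amplitudes.tsv", sep="\t", index=False)
    pd.concat(waves, ignore_index=True).to_csv(
        root / "grand_averages.tsv", sep="\t", index=False
    )
    (root / "p3_windows.json").write_text(json.dumps(windows, indent=1))
    rejection = pd.DataFrame(
        [
            {
                "condition": cond,
                "participant": es.meta.get("participant"),
                "block": es.meta.get("block"),
                "n_epochs": len(es.kept),
                "n_kept": es.n_kept,
                "pct_rejected": 100.0 * (1 - es.n_kept / max(len(es.kept), 1)),
            }
            for cond, sets in esets.items()
            for es in sets
        ]
    )
    rejection.to_csv(root / "epoch_rejection.tsv", sep="\t", index=False)
    man.set_stage("erp", "done", windows=windows)
    return amplitudes


def stage_movement(root: str | Path) -> dict | None:
    """Displacement thresholds, movement-free fractions, profiles, timecourse."""
    root = Path(root)
    man = Manifest(root)
    session = read_session(root)
    if any(rec.gyro is None for rec in session["recordings"].values()):
        man.set_stage("movement", "skipped", reason="missing gyro stream")
        return None

    variants = {b: s.variant for b, s in session["schedules"].items()}
    series: dict[tuple[int, int], mov.DisplacementSeries] = {}
    for (p, b), rec in session["recordings"].items():
        series[(p, b)] = mov.displacement(rec.gyro, rec.gyro_rate_hz, block_id=b)

    participants = sorted({p for p, _ in series})
    thresholds, fractions, stats_rows = [], [], []
    rapid_stats = {}
    for p in participants:
        rapid = [series[(p, b)] for b in variants if variants[b] == "rapid"]
        thr = mov.individual_threshold(rapid, participant=p)
        d_rapid = np.concatenate([s.d for s in rapid])
        rapid_stats[p] = (float(d_rapid.mean()), float(d_rapid.std()))
        thresholds.append({"participant": p, "threshold": thr.threshold})
        for b in variants:
            fractions.append(
                {
                    "participant": p,
                    "block": b,
                    "condition": variants[b],
                    "fraction_below": mov.percent_below(series[(p, b)], thr),
                    "mean_displacement": float(series[(p, b)].d.mean()),
                }
            )
    frac = pd.DataFrame(fractions)
    pd.DataFrame(thresholds).to_csv(root / "movement_thresholds.tsv", sep="\t", index=False)
    frac.to_csv(root / "movement_fractions.tsv", sep="\t", index=False)

    profile = mov.percentile_profile(
        {b: [series[(p, b)] for p in participants] for b in variants}
    )
    profile.to_csv(root / "movement_profile.tsv", sep="\t", index=False)

    # categorized day time course over the sporadic blocks
    spor_blocks = [b for b in variants if variants[b] == "sporadic"]
    tc_series = [series[(p, b)] for p in participants for b in spor_blocks]
    tc_parts = [p for p in participants for _ in spor_blocks]
    timecourse = mov.categorize_timecourse(tc_series, rapid_stats, tc_parts)
    timecourse.to_csv(root / "movement_timecourse.tsv", sep="\t", index=False)

    summary = {
        "fraction_below_rapid": float(
            frac[frac.condition == "rapid"].fraction_below.mean()
        ),
        "fraction_below_sporadic": float(
            frac[frac.condition == "sporadic"].fraction_below.mean()
        ),
        "global_threshold": float(np.mean([t["threshold"] for t in thresholds])),
    }
    man.set_stage("movement", "done", **summary)
    return summary


def stage_stats(root: str | Path, alpha: float = 0.05) -> dict:
    """Mixed models, Wald tests and the movement ANOVA; writes report.json."""
    root = Path(root)
    man = Manifest(root)
    behavior = pd.read_csv(root / "behavior.tsv", sep="\t")
    out: dict = {}

    rt_fit = stats_mod.fit_glmm(
        behavior[~behavior.miss],
        stats_mod.GlmmSpec(
            "rt_s", "condition", "inverse_gaussian", "inverse", reference="rapid"
        ),
    )
    miss_fit = stats_mod.fit_glmm(
        behavior.assign(miss=behavior.miss.astype(float)),
        stats_mod.GlmmSpec("miss", "condition", "binomial", "logit", reference="rapid"),
    )
    for name, fit in (("reaction_time", rt_fit), ("miss", miss_fit)):
        chi2, df, p = stats_mod.wald_chisq(fit, "slope")
        out[name] = {
            "beta_link": fit.beta_link.tolist(),
            "se_link": fit.se_link.tolist(),
            "loglik": fit.loglik,
            "response_scale": fit.response_scale_summary,
            "wald_chi2": chi2,
            "wald_p": p,
            "significant": p < alpha,
            "converged": fit.converged,
        }

    amp_path = root / "p3_amplitudes.tsv"
    if amp_path.exists():
        amps = pd.read_csv(amp_path, sep="\t")
        out["erp"] = {}
        for cond, sub in amps.groupby("condition"):
            fit = stats_mod.fit_glmm(
                sub.rename(columns={"amplitude_uv": "uv"}),
                stats_mod.GlmmSpec("uv", "role", "gaussian", "identity",
                                   reference="standard"),
            )
            chi2, df, p = stats_mod.wald_chisq(fit, "slope")
            out["erp"][cond] = {
                "standard_uv": fit.response_scale_summary["mean_standard"],
                "target_increase_uv": fit.beta_link[1],
                "se_link": fit.se_link.tolist(),
                "wald_chi2": chi2,
                "wald_p": p,
                "significant": p < alpha,
                "converged": fit.converged,
            }

    frac_path = root / "movement_fractions.tsv"
    if frac_path.exists():
        frac = pd.read_csv(frac_path, sep="\t")
        aov = stats_mod.rm_anova(
            frac.rename(columns={"mean_displacement": "value"}),
            dv="value",
            within="block",
            subject="participant",
        )
        out["movement_anova"] = {
            "F": aov.F,
            "df": list(aov.df),
            "p": aov.p,
            "ges": aov.ges,
            "posthoc": aov.posthoc.to_dict(orient="records")
            if not aov.posthoc.empty
            else [],
        }

    (root / "report.json").write_text(json.dumps(out, indent=1, default=float))
    man.set_stage("stats", "done")
    return out


def run_all(root: str | Path, seed: int, *, n_participants: int = 8) -> dict:
    """simulate -> preprocess -> erp -> movement -> stats."""
    stage_simulate(root, seed, n_participants=n_participants)
    stage_preprocess(root)
    stage_erp(root)
    stage_movement(root)
    return stage_stats(root)
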