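"""Parameter-recovery simulations at the published model estimates.

These routines close the loop that stands in for the unavailable raw
recordings: simulate data from the fitted published models (the
generators' defaults), refit the same models with this package's
estimators, and summarize the recovered quantities over replicates.
Unbiased recovery of every fixed effect is the package's acceptance
standard for the statistical machinery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from earoddball import erp as erp_mod
from earoddball import stats as stats_mod
from earoddball.paradigm import generate_schedule
from earoddball.synthgen import (
    ParticipantProfile,
    SessionConfig,
    realize_participant,
    simulate_behavior,
    simulate_eeg,
)

__all__ = [
    "study_schedules",
    "recover_rt",
    "recover_miss",
    "recover_erp",
    "recover_erp_amplitudes",
    "null_type1_rate",
]

#: Single-trial bipolar window-mean amplitude SD implied by the EEG
#: generator's background-noise defaults (3 uV 1/f + 0.5 uV white,
#: spatially correlated), measured once on noise-only epochs.
TRIAL_AMPLITUDE_SD_UV = 1.7

#: The study design: rapid blocks 1/3/5, sporadic blocks 2/4.
BLOCK_PLAN = ("rapid", "sporadic", "rapid", "sporadic", "rapid")


def study_schedules(seed: int, *, compress_sporadic: bool = True):
    """One set of five block schedules following the study block plan.

    Sporadic blocks may be generated at rapid pacing (identical trial
    counts and roles); only event counts and roles enter the behavioral
    models, so pacing is irrelevant there.
    """
    rng = np.random.default_rng(seed)
    out = []
    for b, variant in enumerate(BLOCK_PLAN):
        kwargs = {}
        if variant == "sporadic" and compress_sporadic:
            kwargs["isi_range_s"] = (0.5, 0.9)
        out.append((b, generate_schedule(variant, int(rng.integers(2**31)), **kwargs)))
    return out


def recover_rt(
    n_reps: int = 100,
    seed: int = 0,
    *,
    n_participants: int = 8,
    profile: ParticipantProfile | None = None,
) -> pd.DataFrame:
    """Simulate-and-refit the reaction-time GLMM (inverse Gaussian, inverse link).

    Returns one row per replicate with the link-scale estimates and the
    response-scale rapid mean and sporadic increase.
    """
    profile = profile or ParticipantProfile()
    schedules = study_schedules(seed)
    rng = np.random.default_rng(seed)
    spec = stats_mod.GlmmSpec(
        "rt_s", "condition", "inverse_gaussian", "inverse", reference="rapid"
    )
    rows = []
    for rep in range(n_reps):
        behavior = simulate_behavior(
            profile, schedules, int(rng.integers(2**31)), n_participants=n_participants
        )
        fit = stats_mod.fit_glmm(behavior[~behavior.miss], spec)
        s = fit.response_scale_summary
        rows.append(
            {
                "rep": rep,
                "beta0": fit.beta_link[0],
                "beta1": fit.beta_link[1],
                "rapid_mean_s": s["mean_rapid"],
                "increase_s": s["difference"],
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def recover_miss(
    n_reps: int = 100,
    seed: int = 0,
    *,
    n_participants: int = 8,
    profile: ParticipantProfile | None = None,
) -> pd.DataFrame:
    """Simulate-and-refit the accuracy GLMM (binomial, logit link)."""
    profile = profile or ParticipantProfile()
    schedules = study_schedules(seed)
    rng = np.random.default_rng(seed)
    spec = stats_mod.GlmmSpec(
        "miss", "condition", "binomial", "logit", reference="rapid"
    )
    rows = []
    for rep in range(n_reps):
        behavior = simulate_behavior(
            profile, schedules, int(rng.integers(2**31)), n_participants=n_participants
        )
        fit = stats_mod.fit_glmm(
            behavior.assign(miss=behavior.miss.astype(float)), spec
        )
        s = fit.response_scale_summary
        rows.append(
            {
                "rep": rep,
                "beta0": fit.beta_link[0],
                "beta1": fit.beta_link[1],
                "rapid_miss_pct": 100.0 * s["mean_rapid"],
                "increase_pct": 100.0 * s["difference"],
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def recover_erp(
    variant: str = "rapid",
    n_reps: int = 100,
    seed: int = 0,
    *,
    n_participants: int = 8,
    profile: ParticipantProfile | None = None,
    jointprob_z: float = 2.0,
) -> pd.DataFrame:
    """Full ERP pipeline recovery for one condition.

    Per replicate: simulate one block per participant at the published
    generative amplitudes (time-compressed pacing for the sporadic
    condition), run epoching, joint-probability rejection, bipolar
    derivation, data-driven window search and the per-condition LMM with
    independent random intercepts and slopes.  Returns per-replicate
    fitted standard amplitude and target increase.
    """
    profile = profile or ParticipantProfile()
    config = SessionConfig(n_participants=n_participants)
    rng = np.random.default_rng(seed)
    spec = stats_mod.GlmmSpec(
        "uv", "role", "gaussian", "identity", reference="standard"
    )
    rows = []
    for rep in range(n_reps):
        schedule = generate_schedule(
            variant, int(rng.integers(2**31)), isi_range_s=(0.5, 0.9)
        )
        esets = []
        for p in range(n_participants):
            realized = realize_participant(profile, rng)
            rec = simulate_eeg(realized, schedule, config, int(rng.integers(2**31)))
            rec.meta.update({"participant": p, "block": 0})
            es = erp_mod.extract_epochs(rec, participant=p)
            es = erp_mod.reject_jointprob(es, jointprob_z)
            esets.append(erp_mod.derive_bipolar(es))
        times, ga = erp_mod.grand_average(esets)
        win = erp_mod.find_p3_window(times, ga)
        amps = pd.concat(
            [erp_mod.extract_amplitudes(es, win) for es in esets], ignore_index=True
        ).rename(columns={"amplitude_uv": "uv"})
        fit = stats_mod.fit_glmm(amps, spec)
        rows.append(
            {
                "rep": rep,
                "standard_uv": fit.beta_link[0],
                "delta_uv": fit.beta_link[1],
                "peak_ms": win.peak_latency_ms,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def recover_erp_amplitudes(
    variant: str = "rapid",
    n_reps: int = 100,
    seed: int = 0,
    *,
    n_participants: int = 8,
    profile: ParticipantProfile | None = None,
    residual_sd_uv: float = TRIAL_AMPLITUDE_SD_UV,
) -> pd.DataFrame:
    """Model-level ERP LMM recovery at the published amplitude estimates.

    Simulates per-trial amplitude tables directly from the linear mixed
    model (fixed effects = the condition's published standard amplitude
    and target increase; independent participant random intercepts and
    slopes; Gaussian trial noise at the generator-implied single-trial
    SD), then refits the same LMM.  Trial counts per participant follow
    the design (112 standards + 48 targets per block, three rapid or two
    sporadic blocks).
    """
    profile = profile or ParticipantProfile()
    amp_std, amp_delta, _ = profile.erp_params(variant)
    n_blocks = 3 if variant == "rapid" else 2
    n_std, n_tgt = 112 * n_blocks, 48 * n_blocks
    rng = np.random.default_rng(seed)
    spec = stats_mod.GlmmSpec(
        "uv", "role", "gaussian", "identity", reference="standard"
    )
    rows = []
    for rep in range(n_reps):
        frames = []
        for p in range(n_participants):
            b0, b1 = rng.normal(0.0, profile.erp_random_sds)
            x = np.r_[np.zeros(n_std), np.ones(n_tgt)]
            uv = (
                amp_std
                + b0
                + (amp_delta + b1) * x
                + rng.normal(0.0, residual_sd_uv, x.size)
            )
            frames.append(
                pd.DataFrame(
                    {
                        "participant": p,
                        "role": np.where(x > 0, "target", "standard"),
                        "uv": uv,
                    }
                )
            )
        fit = stats_mod.fit_glmm(pd.concat(frames, ignore_index=True), spec)
        rows.append(
            {
                "rep": rep,
                "standard_uv": fit.beta_link[0],
                "delta_uv": fit.beta_link[1],
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def null_type1_rate(
    n_reps: int = 500,
    seed: int = 0,
    *,
    alpha: float = 0.05,
    n_participants: int = 8,
) -> float:
    """Wald-test rejection rate under a zero condition effect.

    Reaction times are simulated with a zero link-scale slope and zero
    slope random SD; returns the fraction of replicates whose Wald test
    on the slope rejects at ``alpha``.
    """
    profile = ParticipantProfile(rt_slope_link=0.0, rt_random_sds=(0.06, 0.0))
    schedules = study_schedules(seed)
    rng = np.random.default_rng(seed)
    spec = stats_mod.GlmmSpec(
        "rt_s", "condition", "inverse_gaussian", "inverse", reference="rapid"
    )
    hits = 0
    n_ok = 0
    for _ in range(n_reps):
        behavior = simulate_behavior(
            profile, schedules, int(rng.integers(2**31)), n_participants=n_participants
        )
        fit = stats_mod.fit_glmm(behavior[~behavior.miss], spec)
        if not np.isfinite(fit.se_link[1]):
            continue
        _, _, p = stats_mod.wald_chisq(fit, "slope")
        n_ok += 1
        hits += p < alpha
    return hits / max(n_ok, 1)
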