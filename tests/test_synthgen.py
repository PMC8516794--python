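"""Synthetic session generator: closed-form behavior, ERP construction,
artifact logging, gyroscope states, and seed determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from earoddball import erp, movement, paradigm, synthgen
from earoddball.synthgen import (
    ActivityPlan,
    ArtifactPlan,
    ParticipantProfile,
    SessionConfig,
    inject_artifacts,
    simulate_behavior,
    simulate_eeg,
    simulate_gyro,
)


@pytest.fixture(scope="module")
def schedules():
    rng = np.random.default_rng(0)
    plan = ("rapid", "sporadic", "rapid", "sporadic", "rapid")
    return [
        (b, paradigm.generate_schedule(v, int(rng.integers(2**31)), isi_range_s=(0.5, 0.9)))
        for b, v in enumerate(plan)
    ]


class TestBehavior:
    def test_miss_rate_matches_inverse_logit(self, schedules):
        # intercept -3.31 on the logit scale -> 3.52% rapid miss chance
        prof = ParticipantProfile(miss_random_sds=(0.0, 0.0), rt_random_sds=(0.0, 0.0))
        beh = simulate_behavior(prof, schedules, seed=1, n_participants=60)
        rapid = beh[beh.condition == "rapid"]
        expected = 1 / (1 + np.exp(3.31))
        assert rapid.miss.mean() == pytest.approx(expected, abs=0.006)

    def test_rt_mean_matches_inverse_link(self, schedules):
        prof = ParticipantProfile(miss_random_sds=(0.0, 0.0), rt_random_sds=(0.0, 0.0))
        beh = simulate_behavior(prof, schedules, seed=2, n_participants=60)
        rapid = beh[(beh.condition == "rapid") & ~beh.miss]
        assert rapid.rt_s.mean() == pytest.approx(1 / 0.91, rel=0.02)

    def test_rows_only_for_targets(self, schedules):
        beh = simulate_behavior(ParticipantProfile(), schedules, seed=3)
        n_targets = sum(s.n_targets for _, s in schedules)
        assert len(beh) == 8 * n_targets
        assert (beh.rt_s.isna() == beh.miss).all()
        assert (beh[~beh.miss].rt_s > 0).all()

    def test_zero_slope_makes_conditions_indistinguishable(self, schedules):
        prof = ParticipantProfile(
            rt_slope_link=0.0,
            rt_random_sds=(0.0, 0.0),
            miss_random_sds=(0.0, 0.0),
        )
        beh = simulate_behavior(prof, schedules, seed=4, n_participants=30)
        ok = beh[~beh.miss]
        _, p = sps.ks_2samp(
            ok[ok.condition == "rapid"].rt_s, ok[ok.condition == "sporadic"].rt_s
        )
        assert p > 0.01

    def test_nonpositive_mean_raises(self, schedules):
        prof = ParticipantProfile(rt_intercept_link=-0.1, rt_random_sds=(0.0, 0.0))
        with pytest.raises(ValueError, match="non-positive"):
            simulate_behavior(prof, schedules, seed=5, n_participants=1)

    def test_seed_determinism(self, schedules):
        a = simulate_behavior(ParticipantProfile(), schedules, seed=9)
        b = simulate_behavior(ParticipantProfile(), schedules, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestEEG:
    def test_noise_free_standard_amplitude_exact(self, quiet_recording):
        es = erp.derive_bipolar(erp.extract_epochs(quiet_recording))
        win = erp.P3Window(312.0, (212.0, 412.0))
        amps = erp.extract_amplitudes(es, win)
        std = amps[amps.role == "standard"].amplitude_uv
        tgt = amps[amps.role == "target"].amplitude_uv
        assert np.allclose(std, 1.07, atol=1e-9)
        assert np.allclose(tgt, 1.07 + 1.75, atol=1e-9)

    def test_grand_average_peak_latency_near_configured(self, short_schedule):
        cfg = SessionConfig()
        peaks = []
        for seed in range(6):
            rec = simulate_eeg(ParticipantProfile(), short_schedule, cfg, seed)
            es = erp.derive_bipolar(erp.extract_epochs(rec))
            t, ga = erp.grand_average([es])
            peaks.append(erp.find_p3_window(t, ga).peak_latency_ms)
        # single short blocks are noisy; the average peak stays near 312 ms
        assert np.mean(peaks) == pytest.approx(312.0, abs=16.0)

    def test_amplitude_se_shrinks_with_sqrt_event_count(self, quiet_profile):
        # doubling the number of events should shrink the SE of the
        # window-mean amplitude by about sqrt(2)
        prof = ParticipantProfile(erp_random_sds=(0.0, 0.0))
        cfg = SessionConfig()
        win = erp.P3Window(312.0, (212.0, 412.0))

        def se_of_mean(n_trials, seeds):
            sched = paradigm.generate_schedule(
                "rapid", 5, n_trials=n_trials, target_fraction=0.3
            )
            means = []
            for seed in seeds:
                rec = simulate_eeg(prof, sched, cfg, seed)
                es = erp.derive_bipolar(erp.extract_epochs(rec))
                amps = erp.extract_amplitudes(es, win)
                means.append(amps.amplitude_uv.mean())
            return np.std(means)

        se_small = se_of_mean(40, range(20))
        se_big = se_of_mean(80, range(20, 40))
        assert se_small / se_big == pytest.approx(np.sqrt(2), rel=0.45)

    def test_event_times_on_sample_grid(self, noisy_recording):
        t = noisy_recording.events.t_s.to_numpy()
        np.testing.assert_allclose(t * 250, np.round(t * 250), atol=1e-9)

    def test_seed_determinism(self, short_schedule, small_config):
        a = simulate_eeg(ParticipantProfile(), short_schedule, small_config, 77)
        b = simulate_eeg(ParticipantProfile(), short_schedule, small_config, 77)
        np.testing.assert_array_equal(a.eeg, b.eeg)
        np.testing.assert_array_equal(a.gyro, b.gyro)


class TestArtifacts:
    def test_empty_plan_is_identity(self, noisy_recording):
        out, log = inject_artifacts(noisy_recording, ArtifactPlan(), seed=0)
        assert log == []
        np.testing.assert_array_equal(out.eeg, noisy_recording.eeg)

    def test_flatline_logged_and_planted(self, noisy_recording):
        plan = ArtifactPlan(flatlines=(("L5", 70.0, 30.0),))
        out, log = inject_artifacts(noisy_recording, plan, seed=0)
        assert log[0]["kind"] == "flatline" and log[0]["channels"] == ["L5"]
        i = out.labels.index("L5")
        seg = out.eeg[i, int(70 * 250) : int(100 * 250)]
        assert np.ptp(seg) == 0

    def test_flatline_beyond_span_raises(self, noisy_recording):
        plan = ArtifactPlan(flatlines=(("L5", 1e5, 60.0),))
        with pytest.raises(ValueError, match="span"):
            inject_artifacts(noisy_recording, plan, seed=0)

    def test_burst_log_locates_high_variance(self, noisy_recording):
        plan = ArtifactPlan(bursts_per_min=6.0, burst_amp_factor=20.0)
        out, log = inject_artifacts(noisy_recording, plan, seed=1)
        bursts = [e for e in log if e["kind"] == "burst"]
        assert bursts
        rate = out.eeg_rate_hz
        for e in bursts:
            a = int(e["start_s"] * rate)
            b = int((e["start_s"] + e["dur_s"]) * rate)
            inside = out.eeg[:, a:b].std()
            assert inside > 5 * noisy_recording.eeg.std()

    def test_calibration_left_untouched(self, noisy_recording):
        plan = ArtifactPlan(bursts_per_min=10.0, transients_per_min=10.0)
        out, _ = inject_artifacts(noisy_recording, plan, seed=2)
        n_cal = int(60.0 * out.eeg_rate_hz)
        np.testing.assert_array_equal(
            out.eeg[:, :n_cal], noisy_recording.eeg[:, :n_cal]
        )


class TestGyro:
    def test_all_still_zero_noise_displacement_is_zero(self, short_schedule):
        plan = ActivityPlan(
            sigma_still=0.0, rapid_fractions=(1.0, 0.0, 0.0), sporadic_fractions=(1.0, 0.0, 0.0)
        )
        cfg = SessionConfig(activity_plan=plan)
        gyro, states = simulate_gyro(cfg, short_schedule, seed=0)
        assert np.all(movement.displacement(gyro).d == 0)

    def test_state_displacement_ordering(self, sporadic_schedule):
        cfg = SessionConfig()
        for seed in range(3):
            gyro, states = simulate_gyro(cfg, sporadic_schedule, seed=seed)
            d = movement.displacement(gyro).d
            means = {s: d[states == s].mean() for s in np.unique(states)}
            assert means["ambulatory"] > means["fidget"] > means["still"]

    def test_sporadic_has_contiguous_lunch_bout(self, sporadic_schedule):
        cfg = SessionConfig()
        gyro, states = simulate_gyro(cfg, sporadic_schedule, seed=4)
        amb = (states == "ambulatory").astype(int)
        runs = np.diff(np.flatnonzero(np.diff(np.r_[0, amb, 0])))[::2]
        assert runs.max() >= cfg.activity_plan.lunch_s * cfg.gyro_rate_hz

    def test_calibration_segment_still(self, sporadic_schedule):
        cfg = SessionConfig()
        _, states = simulate_gyro(cfg, sporadic_schedule, seed=5)
        n_cal = int(cfg.calibration_s * cfg.gyro_rate_hz)
        assert set(states[:n_cal]) == {"still"}


def test_movement_free_fractions_near_published(sporadic_schedule):
    """Generator calibration: ~95% of rapid and ~75% of sporadic samples
    fall below the individual movement-free threshold."""
    cfg = SessionConfig()
    rng = np.random.default_rng(6)
    rapid_sched = paradigm.generate_schedule("rapid", 1)
    rapid = [
        movement.displacement(simulate_gyro(cfg, rapid_sched, int(rng.integers(2**31)))[0])
        for _ in range(3)
    ]
    thr = movement.individual_threshold(rapid)
    spor = movement.displacement(simulate_gyro(cfg, sporadic_schedule, 9)[0])
    frac_rapid = np.mean([movement.percent_below(s, thr) for s in rapid])
    frac_spor = movement.percent_below(spor, thr)
    assert frac_rapid == pytest.approx(0.95, abs=0.05)
    assert frac_spor == pytest.approx(0.75, abs=0.10)
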