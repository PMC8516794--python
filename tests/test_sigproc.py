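"""Cleaning chain: FIR responses, zero-phase application, flatline and
channel rejection, ASR calibration/correction, spherical interpolation."""

import numpy as np
import pytest
from scipy import signal

from earoddball import sigproc
from earoddball.montage import CEEGRID_CHANNELS, ceegrid_positions
from earoddball.sigproc import (
    ASRModel,
    FilterSpec,
    apply_zero_phase,
    asr_apply,
    asr_calibrate,
    clean_recording,
    design_fir,
    detect_flatlines,
    interpolate_spherical,
    reject_channels,
)
from earoddball.synthgen import (
    ArtifactPlan,
    ParticipantProfile,
    Recording,
    inject_artifacts,
    simulate_eeg,
)

RATE = 250.0


def freq_response(kernel, f, rate=RATE):
    w, h = signal.freqz(kernel, worN=[2 * np.pi * f / rate])
    return np.abs(h[0])


class TestFIR:
    def test_lowpass_response(self):
        k = design_fir(FilterSpec("lowpass", 10.0, 330), RATE)
        assert 0.99 < freq_response(k, 5.0) < 1.01
        assert freq_response(k, 20.0) < 0.01

    def test_minus6db_at_cutoff(self):
        k = design_fir(FilterSpec("lowpass", 10.0, 330), RATE)
        assert freq_response(k, 10.0) == pytest.approx(0.5, rel=0.05)

    def test_kernel_symmetric(self):
        k = design_fir(FilterSpec("lowpass", 10.0, 330), RATE)
        np.testing.assert_allclose(k, k[::-1])

    def test_highpass_blocks_dc(self):
        k = design_fir(FilterSpec("highpass", 0.1, 8250), RATE)
        assert abs(k.sum()) < 1e-3  # DC gain is the tap sum

    def test_invalid_specs_raise(self):
        with pytest.raises(ValueError):
            FilterSpec("lowpass", 10.0, 331)  # odd order
        with pytest.raises(ValueError):
            design_fir(FilterSpec("lowpass", 200.0, 330), RATE)  # above Nyquist


class TestZeroPhase:
    def test_passband_sinusoid_not_shifted(self):
        k = design_fir(FilterSpec("lowpass", 10.0, 330), RATE)
        t = np.arange(5000) / RATE
        x = np.sin(2 * np.pi * 5.0 * t)
        y = apply_zero_phase(x, k)
        xc = np.correlate(y[500:-500], x[500:-500], "full")
        lag = np.argmax(xc) - (len(x) - 1000 - 1)
        assert lag == 0

    def test_impulse_stays_in_place(self):
        k = design_fir(FilterSpec("lowpass", 10.0, 330), RATE)
        x = np.zeros(3000)
        x[1700] = 1.0
        assert np.argmax(apply_zero_phase(x, k)) == 1700

    def test_linearity(self, rng):
        k = design_fir(FilterSpec("lowpass", 10.0, 330), RATE)
        x, y = rng.standard_normal((2, 2000))
        lhs = apply_zero_phase(2.0 * x + 3.0 * y, k)
        rhs = 2.0 * apply_zero_phase(x, k) + 3.0 * apply_zero_phase(y, k)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_white_noise_spectrum_shaped_by_kernel(self, rng):
        k = design_fir(FilterSpec("lowpass", 10.0, 330), RATE)
        x = rng.standard_normal(200_000)
        y = apply_zero_phase(x, k)
        f, pxx = signal.welch(y, fs=RATE, nperseg=4096)
        gain2 = np.array([freq_response(k, ff) ** 2 for ff in (2.0, 5.0)])
        measured = np.array(
            [pxx[np.argmin(np.abs(f - ff))] for ff in (2.0, 5.0)]
        ) / (2 / RATE)  # white-noise PSD level
        np.testing.assert_allclose(measured, gain2, rtol=0.2)

    def test_short_signal_raises(self):
        k = design_fir(FilterSpec("lowpass", 10.0, 330), RATE)
        with pytest.raises(ValueError):
            apply_zero_phase(np.zeros(100), k)


def _recording(eeg, labels=None, rate=RATE, calibration_s=0.0):
    import pandas as pd

    labels = labels or tuple(f"ch{i}" for i in range(eeg.shape[0]))
    return Recording(
        eeg,
        None,
        pd.DataFrame(columns=["t_s", "role", "scored", "trial_index", "marker"]),
        rate,
        rate,
        tuple(labels),
        {"calibration_s": calibration_s},
    )


class TestFlatlines:
    def test_planted_flat_detected(self, rng):
        eeg = rng.standard_normal((3, int(200 * RATE)))
        eeg[1, int(30 * RATE) : int(150 * RATE)] = 0.5  # 120 s flat
        rec = _recording(eeg, ("L4a", "L5", "L6"))
        assert detect_flatlines(rec) == {"L5"}

    def test_59s_run_not_flagged(self, rng):
        eeg = rng.standard_normal((1, int(120 * RATE)))
        eeg[0, 0 : int(59 * RATE)] = 1.0
        assert detect_flatlines(_recording(eeg)) == set()

    def test_exactly_60s_run_flagged(self, rng):
        eeg = rng.standard_normal((1, int(120 * RATE)))
        eeg[0, 0 : int(60 * RATE)] = 1.0
        assert detect_flatlines(_recording(eeg)) == {"ch0"}

    def test_no_flat_runs(self, rng):
        eeg = rng.standard_normal((2, int(70 * RATE)))
        assert detect_flatlines(_recording(eeg)) == set()


class TestChannelRejection:
    def test_amplitude_criterion(self, rng):
        eeg = 10 * rng.standard_normal((6, 20000))
        eeg[2] = 600 * rng.standard_normal(20000)  # exceeds +-500 uV often
        report = reject_channels(_recording(eeg))
        assert "ch2" in report.amplitude_bad

    def test_noisy_channel_spectrally_rejected(self, rng):
        eeg = np.vstack(
            [np.sin(2 * np.pi * 5 * np.arange(50000) / RATE) + 0.1 * rng.standard_normal(50000)
             for _ in range(8)]
        )
        eeg[3] += 10 * rng.standard_normal(50000)
        report = reject_channels(_recording(eeg))
        assert "ch3" in report.spectral_bad

    def test_identical_channels_no_spectral_rejection(self):
        base = np.sin(2 * np.pi * 3 * np.arange(30000) / RATE)
        eeg = np.tile(base, (5, 1))
        report = reject_channels(_recording(eeg))
        assert report.spectral_bad == set()
        assert not report.block_discarded

    def test_block_discard_at_half_bad(self, rng):
        eeg = rng.standard_normal((18, 20000))
        eeg[:9] = 700 * rng.standard_normal((9, 20000))
        report = reject_channels(_recording(eeg))
        assert report.block_discarded


@pytest.fixture(scope="module")
def calib():
    return np.random.default_rng(5).standard_normal((6, int(60 * RATE)))


class TestASR:
    def test_thresholds_increase_with_cutoff(self, calib):
        t20 = asr_calibrate(calib, RATE, cutoff_k=20, highpass_hz=None)
        t40 = asr_calibrate(calib, RATE, cutoff_k=40, highpass_hz=None)
        assert np.all(t40.component_thresholds > t20.component_thresholds)

    def test_rank_deficiency_raises(self, calib):
        bad = calib.copy()
        bad[1] = bad[0]
        with pytest.raises(ValueError, match="rank-deficient"):
            asr_calibrate(bad, RATE, highpass_hz=None)

    def test_white_noise_thresholds_match_rms_statistics(self, calib):
        model = asr_calibrate(calib, RATE, cutoff_k=20, highpass_hz=None)
        # for iid noise each component's windowed RMS has mean ~sigma and
        # cv ~ 1/sqrt(2*win): threshold ~ (1 + 20*cv) * mean RMS
        win = int(0.5 * RATE)
        cv = 1 / np.sqrt(2 * win)
        ratio = model.component_thresholds / np.sqrt(
            np.sort(np.linalg.eigvalsh(calib @ calib.T / calib.shape[1]))
        )
        assert np.allclose(ratio, 1 + 20 * cv, rtol=0.25)

    def test_self_application_near_identity(self, calib):
        model = asr_calibrate(calib, RATE, highpass_hz=None)
        rec = _recording(calib, model.labels)
        out = asr_apply(rec, model)
        rel = np.abs(out.eeg.std(axis=1) - calib.std(axis=1)) / calib.std(axis=1)
        assert np.all(rel < 0.05)

    def test_infinite_cutoff_is_identity(self, calib):
        model = asr_calibrate(calib, RATE, highpass_hz=None)
        model.component_thresholds[:] = np.inf
        rec = _recording(calib, model.labels)
        out = asr_apply(rec, model)
        np.testing.assert_array_equal(out.eeg, calib)

    def test_burst_rms_suppressed_by_half(self, rng):
        n = int(120 * RATE)
        eeg = rng.standard_normal((6, n))
        a, b = int(80 * RATE), int(81 * RATE)
        dirty = eeg.copy()
        dirty[:, a:b] += 20 * rng.standard_normal((6, b - a))
        model = asr_calibrate(eeg[:, : int(60 * RATE)], RATE, highpass_hz=None)
        out = asr_apply(_recording(dirty), model)
        rms_before = np.sqrt((dirty[:, a:b] ** 2).mean())
        rms_after = np.sqrt((out.eeg[:, a:b] ** 2).mean())
        assert rms_after < 0.5 * rms_before

    def test_channel_mismatch_raises(self, calib):
        model = asr_calibrate(calib, RATE, highpass_hz=None)
        rec = _recording(calib[:5], model.labels[:5])
        with pytest.raises(ValueError, match="channel"):
            asr_apply(rec, model)


class TestSphericalInterpolation:
    def test_constant_topography_reproduced(self, rng):
        coords = ceegrid_positions()
        eeg = np.ones((len(CEEGRID_CHANNELS), 1000)) * 3.7
        eeg[2] = rng.standard_normal(1000)  # corrupt L3
        rec = _recording(eeg, CEEGRID_CHANNELS)
        out = interpolate_spherical(rec, {"L3"}, coords)
        np.testing.assert_allclose(out.eeg[2], 3.7, atol=1e-6)

    def test_leave_one_out_correlation(self, rng):
        coords = ceegrid_positions()
        pos = np.array([coords[lab] for lab in CEEGRID_CHANNELS])
        t = rng.standard_normal(500)
        # smooth topography: linear-in-position source pattern
        gain = pos @ np.array([0.3, -0.5, 0.8])
        eeg = gain[:, None] * t[None, :]
        rec = _recording(eeg.copy(), CEEGRID_CHANNELS)
        i = CEEGRID_CHANNELS.index("R6")
        out = interpolate_spherical(rec, {"R6"}, coords)
        r = np.corrcoef(out.eeg[i], eeg[i])[0, 1]
        assert r >= 0.9

    def test_no_bad_channels_is_identity(self, rng):
        coords = ceegrid_positions()
        eeg = rng.standard_normal((len(CEEGRID_CHANNELS), 200))
        rec = _recording(eeg, CEEGRID_CHANNELS)
        out = interpolate_spherical(rec, set(), coords)
        np.testing.assert_array_equal(out.eeg, eeg)

    def test_too_few_good_channels_raises(self, rng):
        coords = ceegrid_positions()
        eeg = rng.standard_normal((len(CEEGRID_CHANNELS), 200))
        rec = _recording(eeg, CEEGRID_CHANNELS)
        with pytest.raises(ValueError, match="good channels"):
            interpolate_spherical(rec, set(CEEGRID_CHANNELS[:-3]), coords)


class TestCleanRecording:
    def test_flatline_channel_flagged_and_interpolated(self, small_config):
        from earoddball import paradigm

        sched = paradigm.generate_schedule("rapid", 9, n_trials=40)
        rec = simulate_eeg(ParticipantProfile(), sched, small_config, 21)
        plan = ArtifactPlan(flatlines=(("L5", 65.0, 61.0),))
        dirty, _ = inject_artifacts(rec, plan, seed=0)
        cleaned, report = clean_recording(dirty)
        assert "L5" in report.flatline_bad
        assert "L5" in report.interpolated

    def test_erp_survives_cleaning_on_clean_data(self, short_schedule, small_config):
        """End to end: window-mean amplitudes before vs after cleaning on
        artifact-free data differ by < 0.2 uV."""
        from earoddball import erp as erp_mod

        rec = simulate_eeg(ParticipantProfile(), short_schedule, small_config, 33)
        cleaned, report = clean_recording(rec)
        assert not report.block_discarded
        win = erp_mod.P3Window(312.0, (212.0, 412.0))

        def mean_amp(r):
            es = erp_mod.derive_bipolar(erp_mod.extract_epochs(r))
            return erp_mod.extract_amplitudes(es, win).amplitude_uv.mean()

        assert abs(mean_amp(cleaned) - mean_amp(rec)) < 0.2
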