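"""Synthetic cohort generator: IBI statistics, waveform, noise, cohort shape."""

import numpy as np
import pytest

from ppgstress import (
    CONDITIONS, PPGRecording, SynthConfig, add_noise, generate_cohort,
    generate_ibi_sequence, render_pulse_train,
)
from ppgstress.hrv import compute_hrv_table


class TestIBISequence:
    def test_zero_jitter_limit_gives_equal_intervals_and_zero_rmssd(self):
        ibis = generate_ibi_sequence(75.0, 0.0, 20.0, seed=0)
        assert np.allclose(ibis, 60.0 / 75.0)
        assert np.allclose(np.diff(ibis), 0.0)

    def test_sum_covers_duration(self, rng):
        for _ in range(10):
            hr = rng.uniform(40, 180)
            ibis = generate_ibi_sequence(hr, 30.0, 20.0, rng)
            assert ibis.sum() >= 20.0

    def test_realized_mean_hr_within_5pct_over_300s(self):
        ibis = generate_ibi_sequence(76.0, 40.0, 300.0, seed=11)
        realized = 60.0 / ibis.mean()
        assert 72.2 <= realized <= 79.8

    def test_realized_rmssd_near_target_on_long_sequence(self):
        ibis = generate_ibi_sequence(70.0, 40.0, 600.0, seed=5)
        r = np.sqrt(np.mean(np.diff(ibis) ** 2)) * 1000.0
        assert abs(r - 40.0) / 40.0 < 0.15

    def test_seeded_determinism(self):
        a = generate_ibi_sequence(80.0, 25.0, 20.0, seed=9)
        b = generate_ibi_sequence(80.0, 25.0, 20.0, seed=9)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("hr,rmssd", [(25.0, 40.0), (76.0, -1.0)])
    def test_invalid_parameters_rejected(self, hr, rmssd):
        with pytest.raises(ValueError):
            generate_ibi_sequence(hr, rmssd, 20.0, seed=0)


class TestPulseTrain:
    def test_equal_intervals_give_annotations_at_interval_spacing(self):
        ibis = np.full(25, 0.8)
        sig, peaks = render_pulse_train(ibis, 367.0)
        assert len(peaks) == 25
        # spacing within one sample of the configured interval
        assert np.all(np.abs(np.diff(peaks) - 0.8) <= 1.0 / 367.0 + 1e-12)
        assert len(sig) == int(round((0.3 + 25 * 0.8 + 2 * 0.05) * 367.0))

    def test_zero_dicrotic_amplitude_gives_unimodal_beats(self):
        ibis = np.full(10, 0.9)
        sig, peaks = render_pulse_train(ibis, 367.0, dicrotic_amplitude=0.0)
        # between consecutive annotated peaks the signal has a single maximum
        for a, b in zip(peaks[:-1], peaks[1:]):
            lo, hi = int(a * 367) + 3, int(b * 367) - 3
            seg = sig[lo:hi]
            interior = (seg[1:-1] > seg[:-2]) & (seg[1:-1] > seg[2:])
            assert interior.sum() <= 1

    def test_amplitude_linearity(self):
        ibis = np.full(8, 0.75)
        s1, _ = render_pulse_train(ibis, 367.0, amplitude=1.0)
        s2, _ = render_pulse_train(ibis, 367.0, amplitude=2.0)
        np.testing.assert_allclose(s2, 2.0 * s1, rtol=1e-12)

    def test_annotations_sit_on_local_maxima(self):
        ibis = generate_ibi_sequence(70.0, 40.0, 21.0, seed=2)
        sig, peaks = render_pulse_train(ibis, 367.0, duration=20.0)
        assert len(peaks) > 0
        for p in peaks:
            k = int(round(p * 367.0))
            lo, hi = max(0, k - 2), min(len(sig), k + 3)
            assert abs(lo + int(np.argmax(sig[lo:hi])) - k) <= 1

    def test_empty_interval_sequence_rejected(self):
        with pytest.raises(ValueError):
            render_pulse_train(np.asarray([]), 367.0)


class TestNoise:
    def test_all_zero_amplitudes_is_identity(self, rng):
        clean = rng.normal(size=1000)
        out = add_noise(clean, 367.0, seed=1)
        np.testing.assert_array_equal(out, clean)

    def test_powerline_peak_at_50hz_with_matching_amplitude(self):
        clean = np.zeros(7340)
        out = add_noise(clean, 367.0, powerline_amp=0.5, seed=2)
        spec = np.abs(np.fft.rfft(out)) * 2.0 / len(out)
        freqs = np.fft.rfftfreq(len(out), 1.0 / 367.0)
        k = int(np.argmax(spec))
        assert abs(freqs[k] - 50.0) < 0.1
        assert abs(spec[k] - 0.5) / 0.5 < 0.10

    def test_seeded_noise_realization_is_reproducible(self, rng):
        clean = rng.normal(size=500)
        a = add_noise(clean, 367.0, baseline_amp=0.2, white_sigma=0.05, seed=4)
        b = add_noise(clean, 367.0, baseline_amp=0.2, white_sigma=0.05, seed=4)
        np.testing.assert_array_equal(a, b)


class TestCohort:
    def test_cohort_shape_and_uniqueness(self, default_cohort):
        assert len(default_cohort) == 160
        assert len(default_cohort.subjects) == 40
        for cond in CONDITIONS:
            assert len(default_cohort.by_condition(cond)) == 40

    def test_recording_lengths_match_config(self, default_cohort):
        n = int(round(367.0 * 20.0))
        assert all(len(r.samples) == n for r in default_cohort)

    def test_rest_median_detected_hr_near_target(self, default_cohort):
        hrv = compute_hrv_table(default_cohort)
        med = hrv[hrv.condition == "BE"]["mean_hr_bpm"].median()
        assert 66.0 <= med <= 86.0

    def test_stress_suppresses_cohort_median_rmssd(self, default_cohort):
        hrv = compute_hrv_table(default_cohort)
        med = hrv.groupby("condition")["rmssd_ms"].median()
        assert med["E3"] < med["BE"]

    def test_seed_determinism_bit_identical(self):
        a = generate_cohort(SynthConfig(n_subjects=3, seed=12))
        b = generate_cohort(SynthConfig(n_subjects=3, seed=12))
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.samples, rb.samples)
            np.testing.assert_array_equal(ra.true_peak_times, rb.true_peak_times)

    def test_raising_stress_rmssd_shrinks_the_gap_monotonically(self):
        gaps = []
        for rmssd_stress in (10.0, 25.0, 40.0):
            ds = generate_cohort(SynthConfig(
                n_subjects=8, seed=21, rmssd_stress=rmssd_stress,
                noise_baseline_amp=0.0, noise_powerline_amp=0.0,
                noise_white_sigma=0.0))
            hrv = compute_hrv_table(ds)
            med = hrv.groupby("condition")["rmssd_ms"].median()
            gaps.append(med["BE"] - med[["E1", "E2", "E3"]].mean())
        assert gaps[0] > gaps[1] > gaps[2]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(n_subjects=1)
        with pytest.raises(ValueError):
            SynthConfig(hr_rest=250.0)
        with pytest.raises(ValueError):
            SynthConfig(rmssd_rest=-5.0)

    def test_csv_roundtrip(self, tmp_path):
        ds = generate_cohort(SynthConfig(n_subjects=2, seed=5))
        ds.to_dir(tmp_path / "cohort")
        back = __import__("ppgstress").CohortDataset.from_dir(tmp_path / "cohort")
        assert len(back) == len(ds)
        for r in ds:
            rb = back.get(r.subject_id, r.condition)
            np.testing.assert_allclose(rb.samples, r.samples, rtol=1e-9)


def test_recording_validation():
    with pytest.raises(ValueError):
        PPGRecording(np.asarray([0.0, np.nan]), 367.0)
    with pytest.raises(ValueError):
        PPGRecording(np.zeros(10), -1.0)
    with pytest.raises(ValueError):
        PPGRecording(np.zeros(10), 367.0, condition="XX")
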