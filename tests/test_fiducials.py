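import numpy as np
import pytest

from bpfusion.fiducials import (
    BeatFiducials,
    InsufficientBeatsError,
    delineate_record,
    detect_max_slope,
    detect_ppg_peaks,
    detect_r_peaks,
    detect_second_peak,
    detect_valley,
    extract_bp_labels,
    pair_beats,
)
from bpfusion.synthetic import GeneratorConfig, generate_record

FS = 125.0


def nearest_errors(detected, truth):
    return np.array([np.min(np.abs(np.asarray(truth) - d)) for d in detected])


class TestBeatFiducials:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError, match="ordering"):
            BeatFiducials(r_peak=100, ppg_valley=90, ppg_max_slope=110, ppg_peak=120)

    def test_second_peak_after_peak(self):
        with pytest.raises(ValueError, match="second peak"):
            BeatFiducials(100, 110, 115, 130, ppg_second_peak=125)


class TestRPeaks:
    def test_recovery_on_noisy_synthetic(self):
        """>= 99% sensitivity within +/-20 ms at 20 dB SNR (60 bpm)."""
        hits = total = 0
        for seed in range(5):
            cfg = GeneratorConfig(hr_bpm=60, ecg_snr_db=20, ppg_snr_db=20, seed=seed)
            rec, truth = generate_record(cfg)
            det = detect_r_peaks(rec.ecg, FS)
            tol = int(0.020 * FS)
            hits += np.sum(nearest_errors(truth.r_idx, det) <= tol)
            total += len(truth.r_idx)
        assert hits / total >= 0.99

    def test_flat_signal_insufficient_beats(self):
        with pytest.raises(InsufficientBeatsError):
            detect_r_peaks(np.zeros(int(30 * FS)), FS)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError, match="fs"):
            detect_r_peaks(np.zeros(3000), 80.0)

    def test_time_reversal_symmetry(self, clean_record):
        rec, truth = clean_record
        fwd = detect_r_peaks(rec.ecg, FS)
        rev = detect_r_peaks(rec.ecg[::-1], FS)
        rev_mapped = np.sort(len(rec.ecg) - 1 - rev)
        matched = nearest_errors(fwd, rev_mapped)
        assert np.median(matched) <= 1

    def test_translation_equivariance(self, clean_record):
        rec, _ = clean_record
        k = 50
        shifted = np.concatenate([rec.ecg[-k:], rec.ecg[:-k]])
        base = detect_r_peaks(rec.ecg, FS)
        moved = detect_r_peaks(shifted, FS)
        core = [p for p in base if 2 * FS < p < len(rec.ecg) - 2 * FS]
        assert all(np.min(np.abs(moved - (p + k))) == 0 for p in core)


class TestPpgPeaks:
    def test_one_peak_per_beat_clean(self):
        cfg = GeneratorConfig(hr_bpm=75, ecg_noise_sd=0, ppg_noise_sd=0,
                              ecg_drift_amp=0, ppg_drift_amp=0, seed=2)
        rec, truth = generate_record(cfg)
        det = detect_ppg_peaks(rec.ppg, FS)
        assert len(det) == len(truth.peak_idx)
        assert np.max(nearest_errors(det, truth.peak_idx)) <= int(0.016 * FS)

    def test_dicrotic_peaks_rejected(self):
        cfg = GeneratorConfig(dicrotic_frac=0.40, ecg_noise_sd=0, ppg_noise_sd=0,
                              ecg_drift_amp=0, ppg_drift_amp=0, seed=2)
        rec, truth = generate_record(cfg)
        det = detect_ppg_peaks(rec.ppg, FS)
        assert len(det) == len(truth.peak_idx)  # no extra dicrotic detections

    def test_constant_signal_empty(self):
        assert len(detect_ppg_peaks(np.full(1000, 2.0), FS)) == 0


class TestValley:
    def test_raised_cosine_onset(self):
        cfg = GeneratorConfig(ecg_noise_sd=0, ppg_noise_sd=0,
                              ecg_drift_amp=0, ppg_drift_amp=0, seed=4)
        rec, truth = generate_record(cfg)
        for k in range(1, len(truth) - 1):
            p = truth.peak_idx[k]
            interval = truth.peak_idx[k] - truth.peak_idx[k - 1]
            v = detect_valley(rec.ppg, FS, int(p), int(interval))
            assert abs(v - truth.valley_idx[k]) <= 1

    def test_monotone_ramp_falls_back_to_window_minimum(self):
        x = np.arange(200, dtype=float)
        v = detect_valley(x, FS, peak=150, peak_interval=100)
        assert v == 150 - 40  # left edge of the 0.4*interval window

    def test_window_before_start_rejected(self):
        with pytest.raises(ValueError, match="before the record start"):
            detect_valley(np.zeros(100), FS, peak=10, peak_interval=100)


class TestMaxSlope:
    def test_cosine_rise_midpoint(self):
        t = np.arange(200)
        rise = 50
        x = np.where(t < 100, 0.0,
                     np.where(t < 100 + rise,
                              0.5 * (1 - np.cos(np.pi * (t - 100) / rise)), 1.0))
        ms = detect_max_slope(x, valley=100, peak=150)
        assert abs(ms - 125) <= 1

    def test_linear_ramp_earliest_tie(self):
        x = np.concatenate([np.zeros(50), np.arange(50, dtype=float)])
        # the constant-slope run starts with the step from sample 50 to 51
        assert detect_max_slope(x, valley=45, peak=90) == 50

    def test_sigmoid_inflection(self):
        t = np.arange(300, dtype=float)
        x = 1 / (1 + np.exp(-(t - 150) / 12))
        assert abs(detect_max_slope(x, valley=60, peak=250) - 150) <= 1

    def test_invalid_beat(self):
        with pytest.raises(ValueError, match="precede"):
            detect_max_slope(np.zeros(100), valley=50, peak=50)


class TestSecondPeak:
    def test_dicrotic_bump_apex(self):
        t = np.arange(200, dtype=float)
        x = np.exp(-0.5 * ((t - 50) / 12) ** 2) + 0.4 * np.exp(-0.5 * ((t - 110) / 10) ** 2)
        sp = detect_second_peak(x, FS, peak=50, next_valley=180)
        assert abs(sp - 110) <= 1

    def test_gaussian_inflection_at_sigma(self):
        t = np.arange(300, dtype=float)
        sigma = 20.0
        x = np.exp(-0.5 * ((t - 100) / sigma) ** 2)
        sp = detect_second_peak(x, FS, peak=100, next_valley=250)
        assert abs(sp - 120) <= 1  # descending inflection at +sigma

    def test_convex_decay_gives_none(self):
        x = 1.0 / (1.0 + np.arange(200) / 10.0)
        assert detect_second_peak(x, FS, peak=0, next_valley=199) is None


class TestPairing:
    def _detections(self, rec, truth):
        return (truth.r_idx, truth.peak_idx, truth.valley_idx)

    def test_clean_record_zero_rejections(self, clean_record):
        rec, truth = clean_record
        fids = pair_beats(truth.r_idx, truth.peak_idx, truth.valley_idx, FS, ppg=rec.ppg)
        assert fids.n_rejected == 0
        assert len(fids) == len(truth)

    def test_missing_pulse_rejects_exactly_one_beat(self, clean_record):
        rec, truth = clean_record
        drop = len(truth) // 2
        peaks = np.delete(truth.peak_idx, drop)
        valleys = np.delete(truth.valley_idx, drop)
        fids = pair_beats(truth.r_idx, peaks, valleys, FS, ppg=rec.ppg)
        assert fids.n_rejected == 1

    def test_out_of_range_pat_rejected(self):
        # valleys 0.68 s after each R: outside the 0.6 s pairing window
        r = np.arange(10) * 100 + 50
        valleys = r + 85
        peaks = valleys + 20
        with pytest.raises(InsufficientBeatsError):
            pair_beats(r, peaks, valleys, FS, ppg=np.zeros(1300))

    def test_ordering_invariant_on_noisy_records(self):
        for seed in range(5):
            rec, _ = generate_record(GeneratorConfig(ecg_snr_db=20, ppg_snr_db=20, seed=seed))
            from bpfusion.preprocess import preprocess_record
            fids = delineate_record(preprocess_record(rec))
            for b in fids.beats:
                assert b.r_peak <= b.ppg_valley < b.ppg_max_slope < b.ppg_peak


class TestBpLabels:
    @staticmethod
    def _pulse_train(n_s=20.0, hr_hz=1.25):
        """Asymmetric pressure pulse: fast rise (25% of the period), slow fall."""
        t = np.arange(int(n_s * FS)) / FS
        phase = (t * hr_hz) % 1.0
        x = np.where(phase < 0.25,
                     0.5 - 0.5 * np.cos(np.pi * phase / 0.25),
                     0.5 + 0.5 * np.cos(np.pi * (phase - 0.25) / 0.75))
        return t, 80.0 + 40.0 * x

    def test_oscillating_abp(self):
        _, abp = self._pulse_train()
        sbp, dbp = extract_bp_labels(abp, FS)
        assert abs(sbp - 120) <= 0.5 and abs(dbp - 80) <= 0.5

    def test_linear_drift_labels_mean_of_extremes(self):
        t, abp = self._pulse_train()
        sbp, dbp = extract_bp_labels(abp + 5.0 * t / t[-1], FS)
        assert abs(sbp - 122.5) <= 1.0 and abs(dbp - 82.5) <= 1.0

    def test_constant_abp_unusable(self):
        with pytest.raises(ValueError, match="unusable ABP"):
            extract_bp_labels(np.full(int(20 * FS), 90.0), FS)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            extract_bp_labels(np.zeros(int(5 * FS)), FS)

    def test_synthetic_abp_channel(self):
        cfg = GeneratorConfig(include_abp=True, sbp_mmhg=120, dbp_mmhg=80,
                              ecg_noise_sd=0, ppg_noise_sd=0,
                              ecg_drift_amp=0, ppg_drift_amp=0, seed=5)
        rec, _ = generate_record(cfg)
        sbp, dbp = extract_bp_labels(rec.abp, FS)
        # ABP synthesis is a monotone remap of the PPG pulse; the diastolic
        # tail does not fully settle, so the foot sits a little above DBP
        assert abs(sbp - 120) <= 1.0 and abs(dbp - 80) <= 2.0
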