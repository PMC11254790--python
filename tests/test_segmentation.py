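"""Detector, rigid thresholding and clipping against ground-truth oracles."""

import logging

import numpy as np
import pytest

from heartbeat_id import (
    SegmentationConfig,
    clip_beats,
    compute_thresholds,
    detect_r_peaks,
    preprocess,
    rr_lengths,
    segment_record,
    select_reference_rr,
)
from heartbeat_id.records import EcgRecord
from heartbeat_id.segmentation import (
    RecordRejectedError,
    RPeakList,
    ThresholdStats,
    TooShortError,
    interpolate_beat,
)
from heartbeat_id.synthetic import (
    NoiseSpec,
    SubjectPhysiology,
    generate_record,
    inject_artifacts,
    sample_subject,
)


def _match(detected: np.ndarray, true: np.ndarray, tol: int = 10) -> int:
    used, tp = set(), 0
    for p in detected:
        d = np.abs(true - p)
        j = int(np.argmin(d))
        if d[j] <= tol and j not in used:
            used.add(j)
            tp += 1
    return tp


class TestDetectRPeaks:
    def test_clean_60bpm_record_fully_detected(self):
        rec = generate_record(
            sample_subject(1), SubjectPhysiology(1000.0, 0.0, 500.0),
            NoiseSpec.silent(), duration_s=60, fs=250, seed=1,
        )
        clean = preprocess(rec.record)
        peaks = detect_r_peaks(clean)
        true = rec.true_r_indices
        assert len(peaks) == len(true)
        assert _match(peaks.indices, true) == len(true)

    def test_all_zero_signal_yields_no_peaks(self):
        rec = EcgRecord(np.zeros(2500) + 1e-12, fs=250.0)
        rec.samples[:] = 0.0
        assert len(detect_r_peaks(rec)) == 0

    def test_dropped_beat_does_not_invent_peaks(self, constant_rr_record):
        injected = inject_artifacts(
            constant_rr_record, ("dropped_beat",), count=2, seed=4
        )
        clean = preprocess(injected.record)
        peaks = detect_r_peaks(clean)
        true = np.round(injected.true_r_indices * 250.0 / 500.0).astype(int)
        # every detection corresponds to a true R peak: no hallucinations
        assert _match(peaks.indices, true) == len(peaks)

    def test_too_short_record_rejected(self, rng):
        rec = EcgRecord(rng.normal(size=200), fs=250.0)
        with pytest.raises(TooShortError):
            detect_r_peaks(rec)


class TestRrLengths:
    def test_direct_differencing(self):
        peaks = RPeakList(np.array([100, 300, 520]), fs=250.0)
        assert rr_lengths(peaks).tolist() == [200.0, 220.0]

    def test_single_peak_gives_empty(self):
        assert rr_lengths(RPeakList(np.array([42]), fs=250.0)).size == 0

    def test_constant_spacing(self):
        peaks = RPeakList(np.arange(11) * 250, fs=250.0)
        assert np.all(rr_lengths(peaks) == 250.0)


def _median_nearest_oracle(rr: list[float], k: int = 8) -> list[float]:
    """Brute-force ranking by |Δx − median|, ties by earliest occurrence."""
    med = float(np.median(rr))
    ranked = sorted(range(len(rr)), key=lambda i: (abs(rr[i] - med), i))
    return [rr[i] for i in sorted(ranked[:k])]


class TestSelectReferenceRr:
    def test_uniform_input_is_identity(self):
        rr = np.array([200.0] * 8)
        assert select_reference_rr(rr).tolist() == [200.0] * 8

    def test_outliers_excluded(self):
        rr = np.array([200.0] * 8 + [400.0, 90.0])
        assert select_reference_rr(rr).tolist() == [200.0] * 8

    def test_matches_brute_force_ranking(self):
        rr = [196.0, 198.0, 200.0, 202.0, 204.0, 196.0, 198.0, 206.0, 400.0]
        got = select_reference_rr(np.array(rr)).tolist()
        assert got == _median_nearest_oracle(rr)
        assert got == rr[:8]  # the eight non-outlier values, original order

    @pytest.mark.parametrize("seed", range(5))
    def test_random_inputs_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rr = rng.integers(150, 260, size=20).astype(float)
        got = select_reference_rr(rr).tolist()
        assert got == _median_nearest_oracle(rr.tolist())

    def test_first_k_rule(self):
        rr = np.arange(12, dtype=float) + 100
        cfg = SegmentationConfig(ref_rule="first-k")
        assert select_reference_rr(rr, cfg).tolist() == rr[:8].tolist()

    def test_too_few_intervals_rejected(self):
        with pytest.raises(RecordRejectedError):
            select_reference_rr(np.array([200.0] * 7))


class TestComputeThresholds:
    def test_zero_variance(self):
        s = compute_thresholds(np.array([200.0] * 8))
        assert (s.mu, s.sigma, s.th1, s.th2) == (200.0, 0.0, 200.0, 200.0)

    def test_worked_example_population_sd(self):
        rr = np.array([196.0, 198.0, 200.0, 202.0, 204.0, 196.0, 198.0, 206.0])
        s = compute_thresholds(rr)
        assert s.mu == pytest.approx(200.0)
        assert s.sigma == pytest.approx(np.sqrt(12.0))  # divisor N = 8
        assert s.th1 == pytest.approx(200.0 - np.sqrt(12.0))
        assert s.th2 == pytest.approx(200.0 + np.sqrt(12.0))

    @pytest.mark.parametrize("seed", range(3))
    def test_band_width_is_two_sigma(self, seed):
        rng = np.random.default_rng(seed)
        rr = rng.uniform(150, 250, size=8)
        s = compute_thresholds(rr)
        assert s.th2 - s.th1 == pytest.approx(2 * s.sigma)

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError, match="8"):
            compute_thresholds(np.array([200.0] * 7))


class TestClipBeats:
    def test_length_150_segment_is_unchanged(self, rng):
        seg = rng.normal(size=150)
        assert np.array_equal(interpolate_beat(seg, 150), seg)

    def test_linear_ramp_interpolates_exactly(self):
        seg = np.linspace(0.0, 1.0, 200)
        out = interpolate_beat(seg, 150)
        assert np.max(np.abs(out - np.linspace(0.0, 1.0, 150))) < 1e-9

    def test_endpoints_preserved(self, rng):
        seg = rng.normal(size=173)
        for kind in ("linear", "cubic"):
            out = interpolate_beat(seg, 150, kind)
            assert out[0] == pytest.approx(seg[0])
            assert out[-1] == pytest.approx(seg[-1])

    def test_only_in_band_segments_emitted(self, rng):
        stats = ThresholdStats(
            rr_all=np.array([]), rr_ref=np.array([]),
            mu=200.0, sigma=3.4641, th1=196.54, th2=203.46,
        )
        idx = np.array([0, 195, 395, 599])  # RR = 195, 200, 204
        rec = EcgRecord(rng.normal(size=700), fs=250.0, subject_id="s")
        beats = clip_beats(rec, RPeakList(idx, 250.0), stats)
        assert len(beats) == 1
        assert beats[0].rr_samples == 200.0
        assert np.array_equal(beats[0].values, interpolate_beat(rec.samples[195:395], 150))


class TestSegmentRecord:
    def test_clean_constant_rr_keeps_almost_all_beats(self):
        rec = generate_record(
            sample_subject(6), SubjectPhysiology(800.0, 0.0, 400.0),
            NoiseSpec.silent(), duration_s=41, fs=250, seed=2,
        )
        n_true = len(rec.true_r_indices) - 1
        assert n_true >= 50
        beats = segment_record(preprocess(rec.record))
        assert abs(len(beats) - n_true) <= 1
        assert all(b.values.size == 150 for b in beats)

    def test_aberrant_rr_pairs_are_absent(self, constant_rr_record):
        injected = inject_artifacts(
            constant_rr_record, ("ectopic_short_rr", "dropped_beat"),
            count=5, seed=6,
        )
        clean = preprocess(injected.record)
        beats = segment_record(clean)
        nominal = 200.0  # samples at 250 Hz
        margin = 0.1 * nominal
        assert all(abs(b.rr_samples - nominal) < margin for b in beats)

    def test_every_beat_rr_inside_band(self, hrv_record):
        clean = preprocess(hrv_record.record)
        peaks = detect_r_peaks(clean)
        rr = rr_lengths(peaks)
        stats = compute_thresholds(select_reference_rr(rr), rr_all=rr)
        for b in segment_record(clean):
            assert stats.th1 <= b.rr_samples <= stats.th2

    def test_all_zero_record_logs_and_yields_nothing(self, caplog):
        rec = EcgRecord(np.zeros(2500) + 0.0, fs=250.0, record_id="flat")
        rec.samples[:] = 0.0
        with caplog.at_level(logging.WARNING):
            beats = segment_record(rec)
        assert beats == []
        assert any("rejected" in m for m in caplog.messages)
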