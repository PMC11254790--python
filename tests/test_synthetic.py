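"""Generator contracts: determinism, ground truth, morphology separation."""

import numpy as np
import pytest

from heartbeat_id.synthetic import (
    DEFAULT_WAVE_RANGES,
    NoiseSpec,
    SubjectPhysiology,
    SubjectTemplate,
    WaveComponent,
    generate_cohort,
    generate_record,
    inject_artifacts,
    render_beat,
    sample_subject,
)

POINT_RANGES = {
    "P": ((-160.0, -160.0), (0.15, 0.15), (25.0, 25.0)),
    "Q": ((-25.0, -25.0), (-0.1, -0.1), (8.0, 8.0)),
    "R": ((0.0, 0.0), (1.0, 1.0), (10.0, 10.0)),
    "S": ((30.0, 30.0), (-0.2, -0.2), (8.0, 8.0)),
    "T": ((300.0, 300.0), (0.3, 0.3), (45.0, 45.0)),
}


class TestSampleSubject:
    def test_same_seed_identical(self):
        assert sample_subject(7) == sample_subject(7)

    def test_templates_are_morphologically_distinct(self):
        # canonical beats of 50 random subjects are pairwise distinct
        beats = [render_beat(sample_subject(s), 800.0, 250.0) for s in range(50)]
        for i in range(len(beats)):
            for j in range(i + 1, len(beats)):
                assert np.linalg.norm(beats[i] - beats[j]) > 0

    def test_degenerate_ranges_give_point_values(self):
        t = sample_subject(0, ranges=POINT_RANGES)
        for comp, name in zip(t.components, "PQRST"):
            lo_c = POINT_RANGES[name][0][0]
            assert comp.center_ms == lo_c
            assert comp.amplitude_mv == POINT_RANGES[name][1][0]
            assert comp.width_ms == POINT_RANGES[name][2][0]

    def test_overlapping_offset_ranges_rejected(self):
        bad = dict(POINT_RANGES)
        bad["Q"] = ((-200.0, -150.0), (-0.1, -0.1), (8.0, 8.0))  # overlaps P
        with pytest.raises(ValueError, match="overlap"):
            sample_subject(0, ranges=bad)

    def test_sampled_template_satisfies_invariants(self):
        t = sample_subject(12, ranges=DEFAULT_WAVE_RANGES)
        centers = [c.center_ms for c in t.components]
        assert centers == sorted(centers)
        r_amp = abs(t.components[2].amplitude_mv)
        assert all(
            abs(c.amplitude_mv) < r_amp for c in t.components if c.name != "R"
        )


def _template(amplitudes: dict[str, float]) -> SubjectTemplate:
    base = {"P": -160.0, "Q": -25.0, "R": 0.0, "S": 30.0, "T": 300.0}
    widths = {"P": 25.0, "Q": 8.0, "R": 10.0, "S": 8.0, "T": 45.0}
    return SubjectTemplate(
        subject_id="t",
        components=tuple(
            WaveComponent(n, base[n], amplitudes.get(n, 0.0), widths[n])
            for n in "PQRST"
        ),
    )


class TestRenderBeat:
    def test_single_r_component_peaks_at_one_mv(self):
        t = _template({"R": 1.0})
        v = render_beat(t, 800.0, 250.0)
        assert v.max() == pytest.approx(1.0, abs=1e-3)
        assert np.argmax(v) == 0  # R center opens the segment

    def test_all_zero_amplitudes_render_silence(self):
        v = render_beat(_template({}), 800.0, 250.0)
        assert np.all(v == 0.0)

    def test_sample_count_is_rr_times_fs(self):
        assert render_beat(sample_subject(1), 800.0, 250.0).size == 200

    def test_rr_shorter_than_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            render_beat(sample_subject(1), 300.0, 250.0)


class TestGenerateRecord:
    def test_constant_rr_spacing_is_exact(self):
        t = sample_subject(3)
        rec = generate_record(
            t, SubjectPhysiology(1000.0, 0.0, 400.0), NoiseSpec.silent(),
            duration_s=10, fs=250, seed=1,
        )
        assert np.all(np.diff(rec.true_r_indices) == 250)
        assert len(rec.true_r_indices) - 1 in (9, 10, 11)

    def test_same_seed_bit_identical(self):
        t = sample_subject(3)
        a = generate_record(t, duration_s=10, fs=500, seed=4)
        b = generate_record(t, duration_s=10, fs=500, seed=4)
        assert np.array_equal(a.record.samples, b.record.samples)
        assert np.array_equal(a.true_r_indices, b.true_r_indices)

    def test_true_r_indices_are_local_maxima_of_clean_signal(self):
        t = sample_subject(9)
        rec = generate_record(
            t, SubjectPhysiology(800.0, 40.0, 400.0), NoiseSpec.silent(),
            duration_s=30, fs=500, seed=5,
        )
        x = rec.record.samples
        for idx in rec.true_r_indices:
            lo, hi = max(0, idx - 2), min(x.size, idx + 3)
            assert x[idx] >= np.max(x[lo:hi]) - 1e-9

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            generate_record(sample_subject(1), duration_s=1.0, fs=250, seed=0)


class TestInjectArtifacts:
    def test_count_zero_is_identity(self, constant_rr_record):
        assert inject_artifacts(constant_rr_record, count=0) is constant_rr_record

    def test_dropped_beat_doubles_one_rr(self, constant_rr_record):
        out = inject_artifacts(constant_rr_record, ("dropped_beat",), count=1, seed=2)
        nominal = constant_rr_record.physiology.mean_rr_ms
        doubled = np.isclose(out.rr_ms, 2 * nominal)
        assert doubled.sum() == 1
        assert len(out.artifact_intervals) == 1

    def test_rhythm_artifacts_exceed_deviation_margin(self, constant_rr_record):
        out = inject_artifacts(
            constant_rr_record, ("ectopic_short_rr", "dropped_beat"), count=5, seed=3
        )
        phys = out.physiology
        margin = 3 * phys.sdnn_ms + 0.1 * phys.mean_rr_ms
        devs = np.abs(out.rr_ms[out.artifact_intervals] - phys.mean_rr_ms)
        assert np.all(devs > margin)

    def test_deterministic_per_seed(self, constant_rr_record):
        a = inject_artifacts(constant_rr_record, ("burst_noise",), 2, seed=5)
        b = inject_artifacts(constant_rr_record, ("burst_noise",), 2, seed=5)
        assert np.array_equal(a.record.samples, b.record.samples)

    def test_unknown_kind_rejected(self, constant_rr_record):
        with pytest.raises(ValueError, match="unknown artifact"):
            inject_artifacts(constant_rr_record, ("flutter",), 1, seed=0)


class TestGenerateCohort:
    def test_requested_beat_counts_are_met(self):
        cohort = generate_cohort(3, [20, 40, 60], seed=1)
        for rec, want in zip(cohort, [20, 40, 60]):
            assert len(rec.true_r_indices) - 1 >= want

    def test_subject_ids_disjoint_and_deterministic(self):
        a = generate_cohort(4, 30, seed=9)
        b = generate_cohort(4, 30, seed=9)
        ids = [r.record.subject_id for r in a]
        assert len(set(ids)) == 4
        for x, y in zip(a, b):
            assert np.array_equal(x.record.samples, y.record.samples)

    def test_constant_sampler_meets_floor(self):
        cohort = generate_cohort(2, 50, seed=2)
        assert all(len(r.true_r_indices) - 1 >= 50 for r in cohort)

    def test_identity_signal_dominates_noise(self):
        """Inter-subject beat distance exceeds intra-subject noisy spread.

        Both distances are measured on band-passed beats — the
        representation identification actually runs on — because raw beats
        are dominated by baseline wander that the pipeline removes.
        """
        from heartbeat_id import preprocess

        n = 20
        win = 100  # samples at 250 Hz, safely below the 400 ms RR floor
        cohort = generate_cohort(n, 12, seed=4)
        per_subject = []
        for rec in cohort:
            clean = preprocess(rec.record)
            idx = np.round(rec.true_r_indices * 250.0 / rec.record.fs).astype(int)
            beats = [
                clean.samples[a:a + win]
                for a in idx[:-1] if a + win <= clean.n_samples
            ]
            per_subject.append(np.stack(beats))
        canon = [b.mean(axis=0) for b in per_subject]
        inter = [
            np.linalg.norm(canon[i] - canon[j])
            for i in range(n) for j in range(i + 1, n)
        ]
        intra = [
            np.linalg.norm(b - beats[0])
            for beats in per_subject for b in beats[1:]
        ]
        assert np.mean(inter) > np.mean(intra)
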