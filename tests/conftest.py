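"""Shared fixtures: small synthetic cohorts and separable beat datasets."""

from __future__ import annotations

import numpy as np
import pytest

from heartbeat_id import (
    BeatDataset,
    render_beat,
    sample_subject,
)
from heartbeat_id.synthetic import NoiseSpec, SubjectPhysiology, generate_record


@pytest.fixture(scope="session")
def constant_rr_record():
    """Noise-free constant-rhythm record: 80 s at 800 ms R-R, 500 Hz."""
    template = sample_subject(5)
    phys = SubjectPhysiology(mean_rr_ms=800.0, sdnn_ms=0.0, rr_floor_ms=400.0)
    return generate_record(
        template, phys, NoiseSpec.silent(), duration_s=80, fs=500, seed=3
    )


@pytest.fixture(scope="session")
def hrv_record():
    """Physiological-variability record with default noise, 60 s."""
    template = sample_subject(8)
    phys = SubjectPhysiology(mean_rr_ms=800.0, sdnn_ms=40.0, rr_floor_ms=400.0)
    return generate_record(template, phys, None, duration_s=60, fs=500, seed=11)


def _beat_matrix(seed: int, n: int, noise_sd: float = 0.02) -> np.ndarray:
    """n noisy copies of one subject's canonical 150-sample beat."""
    template = sample_subject(seed)
    base = render_beat(template, 750.0, 200.0)  # exactly 150 samples
    rng = np.random.default_rng(seed + 1000)
    return base[None, :] + rng.normal(0.0, noise_sd, size=(n, base.size))


@pytest.fixture(scope="session")
def separable_dataset() -> BeatDataset:
    """Three well-separated subjects with imbalanced counts 24/12/40."""
    parts, labels = [], []
    for seed, n in ((21, 24), (22, 12), (23, 40)):
        parts.append(_beat_matrix(seed, n))
        labels += [f"subj{seed}"] * n
    return BeatDataset(np.vstack(parts), np.array(labels, dtype=object))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
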