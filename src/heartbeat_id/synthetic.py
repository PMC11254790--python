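"""Synthetic multi-subject ECG generation with known ground truth.

Each subject is a :class:`SubjectTemplate`: five Gaussian wave components
(P, Q, R, S, T) parameterized by center offset relative to the R peak (ms),
signed amplitude (mV) and Gaussian width (ms).  Beats are rendered as R-R
segments — the R wave opens the segment, S and T follow, and the P and Q of
the *next* beat sit near its end — so concatenated beats tile into a
continuous trace whose R peaks are known exactly.

Heart-rate variability is a truncated normal law on the R-R interval;
noise is the classic ECG catalogue: sinusoidal baseline wander, power-line
interference and broadband (white) noise.  Artifacts that break the R-R
rhythm (ectopic short intervals, dropped beats) or the waveform (noise
bursts) can be injected on demand to exercise downstream rejection logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import EcgRecord

WAVE_NAMES = ("P", "Q", "R", "S", "T")

#: Per-wave sampling intervals (lo, hi) for (offset ms, amplitude mV, width ms).
#: Offsets are relative to the R peak; P and Q precede it.  Ranges are kept
#: physiologically disjoint so sampled templates are always ordered P<Q<R<S<T.
DEFAULT_WAVE_RANGES: dict[str, tuple[tuple[float, float], ...]] = {
    "P": ((-220.0, -140.0), (0.05, 0.25), (15.0, 30.0)),
    "Q": ((-45.0, -20.0), (-0.20, -0.05), (5.0, 12.0)),
    "R": ((0.0, 0.0), (0.8, 1.6), (8.0, 16.0)),
    "S": ((20.0, 45.0), (-0.35, -0.08), (5.0, 12.0)),
    "T": ((220.0, 340.0), (0.15, 0.45), (30.0, 60.0)),
}


@dataclass(frozen=True)
class WaveComponent:
    """One Gaussian wave: ``amp * exp(-(t - center)^2 / (2 width^2))``."""

    name: str
    center_ms: float
    amplitude_mv: float
    width_ms: float


@dataclass(frozen=True)
class SubjectTemplate:
    """Subject-specific beat morphology as a sum of five Gaussians."""

    subject_id: str
    components: tuple[WaveComponent, ...]

    def __post_init__(self) -> None:
        if len(self.components) != 5:
            raise ValueError("template needs exactly five components (P,Q,R,S,T)")
        names = tuple(c.name for c in self.components)
        if names != WAVE_NAMES:
            raise ValueError(f"components must be named {WAVE_NAMES} in order, got {names}")
        centers = [c.center_ms for c in self.components]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("component centers must be strictly increasing (P<Q<R<S<T)")
        r_amp = abs(self.components[2].amplitude_mv)
        silent = all(c.amplitude_mv == 0 for c in self.components)
        for c in self.components:
            if c.width_ms <= 0:
                raise ValueError(f"{c.name} width must be positive")
            if not silent and c.name != "R" and abs(c.amplitude_mv) >= r_amp:
                raise ValueError("R amplitude must dominate all other components")

    @property
    def span_ms(self) -> float:
        """Extent from the earliest to the latest component center."""
        return self.components[-1].center_ms - self.components[0].center_ms


@dataclass(frozen=True)
class SubjectPhysiology:
    """R-R interval law: truncated normal (mean_rr, sdnn), floor at rr_floor."""

    mean_rr_ms: float = 800.0
    sdnn_ms: float = 40.0
    rr_floor_ms: float = 400.0

    def __post_init__(self) -> None:
        if self.mean_rr_ms <= 0:
            raise ValueError("mean_rr must be positive")
        if self.sdnn_ms < 0:
            raise ValueError("sdnn must be non-negative")
        if not 0 < self.rr_floor_ms < self.mean_rr_ms:
            raise ValueError("rr_floor must satisfy 0 < rr_floor < mean_rr")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise: baseline wander + power-line + broadband white noise.

    Defaults are visibly attenuated by the 0.6–40 Hz band-pass of the
    preprocessing stage: wander sits below the low cutoff, power-line above
    the high cutoff.
    """

    baseline_amp_mv: float = 0.1
    baseline_freq_hz: float = 0.25
    powerline_amp_mv: float = 0.05
    powerline_freq_hz: float = 50.0
    broadband_sd_mv: float = 0.02

    def __post_init__(self) -> None:
        for amp in (self.baseline_amp_mv, self.powerline_amp_mv, self.broadband_sd_mv):
            if amp < 0:
                raise ValueError("noise amplitudes must be non-negative")
        for f in (self.baseline_freq_hz, self.powerline_freq_hz):
            if f <= 0:
                raise ValueError("noise frequencies must be positive")

    @staticmethod
    def silent() -> "NoiseSpec":
        return NoiseSpec(0.0, 0.25, 0.0, 50.0, 0.0)


@dataclass
class SyntheticRecord:
    """A generated record plus its ground truth.

    ``true_r_indices`` are the sample positions of the rendered R centers.
    ``rr_ms`` keeps the interval sequence the record was rendered from so
    artifact injection can re-render deterministically; ``artifact_intervals``
    lists the indices (into ``rr_ms``) of injected perturbed intervals.
    """

    record: EcgRecord
    true_r_indices: np.ndarray
    template: SubjectTemplate
    physiology: SubjectPhysiology = field(default_factory=SubjectPhysiology)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    noise_seed: int = 0
    rr_ms: np.ndarray = field(default_factory=lambda: np.array([]))
    artifact_intervals: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.true_r_indices = np.asarray(self.true_r_indices, dtype=int)
        if np.any(np.diff(self.true_r_indices) <= 0):
            raise ValueError("true_r_indices must be strictly increasing")
        if self.true_r_indices.size and (
            self.true_r_indices[0] < 0
            or self.true_r_indices[-1] >= self.record.n_samples
        ):
            raise ValueError("true_r_indices out of signal bounds")


def sample_subject(
    seed: int,
    ranges: dict[str, tuple[tuple[float, float], ...]] | None = None,
    subject_id: str | None = None,
) -> SubjectTemplate:
    """Draw a random subject morphology from per-wave parameter intervals.

    Deterministic for a fixed seed.  ``ranges`` maps wave name to three
    ``(lo, hi)`` intervals for center offset (ms), amplitude (mV) and width
    (ms); degenerate intervals (lo == hi) pin the parameter.
    """
    if ranges is None:
        ranges = DEFAULT_WAVE_RANGES
    if set(ranges) != set(WAVE_NAMES):
        raise ValueError(f"ranges must cover exactly the waves {WAVE_NAMES}")
    # Offset intervals must be disjoint and ordered P<Q<R<S<T, otherwise a
    # draw could violate the template ordering invariant.
    prev_hi = -np.inf
    for name in WAVE_NAMES:
        lo, hi = ranges[name][0]
        if lo > hi:
            raise ValueError(f"{name}: empty offset interval ({lo}, {hi})")
        if lo <= prev_hi:
            raise ValueError(f"{name}: offset interval overlaps the preceding wave's")
        prev_hi = hi
    rng = np.random.default_rng(seed)
    comps = []
    for name in WAVE_NAMES:
        (c_lo, c_hi), (a_lo, a_hi), (w_lo, w_hi) = ranges[name]
        comps.append(
            WaveComponent(
                name=name,
                center_ms=float(rng.uniform(c_lo, c_hi)) if c_lo != c_hi else c_lo,
                amplitude_mv=float(rng.uniform(a_lo, a_hi)) if a_lo != a_hi else a_lo,
                width_ms=float(rng.uniform(w_lo, w_hi)) if w_lo != w_hi else w_lo,
            )
        )
    return SubjectTemplate(
        subject_id=subject_id if subject_id is not None else f"synth-{seed}",
        components=tuple(comps),
    )


def _gauss(t_ms: np.ndarray, c: WaveComponent) -> np.ndarray:
    return c.amplitude_mv * np.exp(-0.5 * ((t_ms - c.center_ms) / c.width_ms) ** 2)


def render_beat(template: SubjectTemplate, rr_ms: float, fs: float) -> np.ndarray:
    """Render one R-R segment of ``round(rr * fs / 1000)`` samples.

    The segment starts at the R center (t = 0).  Components with
    non-negative offsets (R, S, T) are placed in this beat; components with
    negative offsets (P, Q) belong to the *next* beat and are rendered near
    the end of the segment at ``t = rr + offset``, so concatenating beats
    produces a seamless trace.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if rr_ms < template.span_ms:
        raise ValueError(
            f"rr ({rr_ms} ms) shorter than template span ({template.span_ms} ms)"
        )
    n = int(round(rr_ms * fs / 1000.0))
    t = np.arange(n) * 1000.0 / fs
    out = np.zeros(n)
    for c in template.components:
        if c.center_ms >= 0:
            out += _gauss(t, c)
        else:
            out += _gauss(t, WaveComponent(c.name, rr_ms + c.center_ms,
                                           c.amplitude_mv, c.width_ms))
    return out


def _render_rr_sequence(
    template: SubjectTemplate, rr_ms: np.ndarray, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate rendered beats; return (signal, R indices).

    A short lead-in (the diastolic tail of a beat, carrying the first
    beat's P and Q) precedes the first R so that every R peak, including
    the first, is an interior local maximum; a symmetric tail closes the
    last interval.
    """
    lead_beat = render_beat(template, float(rr_ms[0]), fs)
    n_lead = min(lead_beat.size - 1, int(round(0.30 * float(rr_ms[0]) * fs / 1000.0)))
    pieces = [lead_beat[lead_beat.size - n_lead:]]
    r_idx = []
    pos = n_lead
    for rr in rr_ms:
        beat = render_beat(template, float(rr), fs)
        r_idx.append(pos)
        pieces.append(beat)
        pos += beat.size
    # closing R peak so the last interval is bounded on both sides
    tail = render_beat(template, float(rr_ms[-1]), fs)
    r_idx.append(pos)
    pieces.append(tail[: max(1, int(round(0.35 * template.span_ms * fs / 1000.0)))])
    return np.concatenate(pieces), np.asarray(r_idx, dtype=int)


def _draw_rr(
    rng: np.random.Generator, physiology: SubjectPhysiology, n: int
) -> np.ndarray:
    rr = rng.normal(physiology.mean_rr_ms, physiology.sdnn_ms, size=n)
    return np.maximum(rr, physiology.rr_floor_ms)


def _apply_noise(
    clean: np.ndarray, fs: float, noise: NoiseSpec, seed: int
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    t = np.arange(clean.size) / fs
    out = clean.copy()
    if noise.baseline_amp_mv > 0:
        out += noise.baseline_amp_mv * np.sin(2 * np.pi * noise.baseline_freq_hz * t)
    if noise.powerline_amp_mv > 0:
        out += noise.powerline_amp_mv * np.sin(2 * np.pi * noise.powerline_freq_hz * t)
    if noise.broadband_sd_mv > 0:
        out += rng.normal(0.0, noise.broadband_sd_mv, size=clean.size)
    return out


def generate_record(
    template: SubjectTemplate,
    physiology: SubjectPhysiology | None = None,
    noise: NoiseSpec | None = None,
    duration_s: float = 60.0,
    fs: float = 500.0,
    seed: int = 0,
    record_id: str = "",
) -> SyntheticRecord:
    """Generate one subject's record of roughly ``duration_s`` seconds.

    R-R intervals are drawn from the truncated normal law of ``physiology``
    until the cumulative duration covers ``duration_s``; beats are rendered,
    concatenated, and noise added per ``noise``.  Deterministic per seed.
    """
    physiology = physiology or SubjectPhysiology()
    noise = noise if noise is not None else NoiseSpec()
    if duration_s * 1000.0 < 2 * physiology.mean_rr_ms:
        raise ValueError("duration too short for at least two beats")
    rng = np.random.default_rng(seed)
    n_beats = int(np.ceil(duration_s * 1000.0 / physiology.mean_rr_ms)) + 3
    rr = _draw_rr(rng, physiology, n_beats)
    # trim to requested duration (keep at least 2 intervals)
    cum = np.cumsum(rr)
    keep = max(2, int(np.searchsorted(cum, duration_s * 1000.0)) + 1)
    rr = rr[:keep]
    clean, r_idx = _render_rr_sequence(template, rr, fs)
    noise_seed = int(rng.integers(0, 2**31 - 1))
    samples = _apply_noise(clean, fs, noise, noise_seed)
    rec = EcgRecord(
        samples=samples,
        fs=fs,
        subject_id=template.subject_id,
        record_id=record_id or f"{template.subject_id}-r0",
        lead="ECG1",
        session="synthetic",
    )
    return SyntheticRecord(
        record=rec,
        true_r_indices=r_idx,
        template=template,
        physiology=physiology,
        noise=noise,
        noise_seed=noise_seed,
        rr_ms=rr,
    )


ARTIFACT_KINDS = ("ectopic_short_rr", "dropped_beat", "burst_noise")


def inject_artifacts(
    rec: SyntheticRecord,
    kinds: tuple[str, ...] | list[str] = ("ectopic_short_rr",),
    count: int = 1,
    seed: int = 0,
) -> SyntheticRecord:
    """Perturb ``count`` inter-beat intervals and re-render the record.

    Rhythm artifacts guarantee an R-R deviation from the subject's mean
    exceeding ``3·sdnn + 10%·mean_rr``: *ectopic_short_rr* shortens an
    interval toward the physiological floor, *dropped_beat* merges two
    intervals into one of double length.  *burst_noise* superimposes a
    high-amplitude broadband burst over an interval without changing the
    rhythm.  Perturbed interval indices are recorded in
    ``artifact_intervals`` of the returned record.
    """
    for k in kinds:
        if k not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {k!r}; choose from {ARTIFACT_KINDS}")
    if count == 0:
        return rec
    n_intervals = len(rec.rr_ms)
    if count >= n_intervals:
        raise ValueError("count must be smaller than the number of beats")
    rng = np.random.default_rng(seed)
    rr = np.array(rec.rr_ms, dtype=float)
    phys = rec.physiology
    margin = 3.0 * phys.sdnn_ms + 0.1 * phys.mean_rr_ms
    # choose interior intervals to perturb (avoid first/last for clean edges)
    candidates = np.arange(1, n_intervals - 1)
    if candidates.size < count:
        candidates = np.arange(n_intervals)
    chosen = rng.choice(candidates, size=count, replace=False)
    chosen_kinds = [kinds[int(rng.integers(0, len(kinds)))] for _ in chosen]

    bursts: list[int] = []
    drop_mask = np.zeros(n_intervals, dtype=bool)
    for idx, kind in zip(chosen, chosen_kinds):
        if kind == "ectopic_short_rr":
            target = phys.mean_rr_ms - 1.5 * margin
            rr[idx] = max(phys.rr_floor_ms, target)
            if phys.mean_rr_ms - rr[idx] <= margin:  # floor too high: go long instead
                rr[idx] = phys.mean_rr_ms + 1.5 * margin
        elif kind == "dropped_beat":
            rr[idx] = 2.0 * rr[idx]
        else:  # burst_noise: rhythm untouched, flag for post-render corruption
            bursts.append(int(idx))
    rr = rr[~drop_mask]
    clean, r_idx = _render_rr_sequence(rec.template, rr, rec.record.fs)
    samples = _apply_noise(clean, rec.record.fs, rec.noise, rec.noise_seed)
    for idx in bursts:
        a, b = r_idx[idx], r_idx[idx + 1]
        samples[a:b] += rng.normal(0.0, 0.8, size=b - a)
    new_rec = EcgRecord(
        samples=samples,
        fs=rec.record.fs,
        subject_id=rec.record.subject_id,
        record_id=rec.record.record_id,
        lead=rec.record.lead,
        session=rec.record.session,
    )
    return SyntheticRecord(
        record=new_rec,
        true_r_indices=r_idx,
        template=rec.template,
        physiology=phys,
        noise=rec.noise,
        noise_seed=rec.noise_seed,
        rr_ms=rr,
        artifact_intervals=sorted(int(i) for i in chosen),
    )


def generate_cohort(
    n_subjects: int,
    beats_per_subject: int | list[int] | None = None,
    fs: float = 500.0,
    seed: int = 0,
    physiology: SubjectPhysiology | None = None,
    noise: NoiseSpec | None = None,
) -> list[SyntheticRecord]:
    """Generate one record per subject with at least the requested beat count.

    ``beats_per_subject`` may be a constant, a per-subject list, or None
    (default 60).  Templates are drawn from a seed-derived stream, so the
    cohort is fully reproducible from (n_subjects, counts, fs, seed).
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least two subjects")
    if beats_per_subject is None:
        counts = [60] * n_subjects
    elif isinstance(beats_per_subject, int):
        counts = [beats_per_subject] * n_subjects
    else:
        counts = list(beats_per_subject)
        if len(counts) != n_subjects:
            raise ValueError("beats_per_subject list length must equal n_subjects")
    physiology = physiology or SubjectPhysiology()
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2 * n_subjects)]
    cohort = []
    for i in range(n_subjects):
        template = sample_subject(child_seeds[2 * i], subject_id=f"S{i:03d}")
        # duration sized with margin so that >= counts[i] beats are rendered
        duration_s = (counts[i] + 2) * physiology.mean_rr_ms / 1000.0 * 1.05
        cohort.append(
            generate_record(
                template,
                physiology=physiology,
                noise=noise,
                duration_s=duration_s,
                fs=fs,
                seed=child_seeds[2 * i + 1],
                record_id=f"S{i:03d}-r0",
            )
        )
    return cohort
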