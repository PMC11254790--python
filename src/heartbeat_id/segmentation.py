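"""R-peak detection, rigid R-R length thresholding, and beat clipping.

The detector is the classic Pan–Tompkins cascade: band-pass (5–15 Hz),
five-point derivative, squaring, 150 ms moving-window integration, then
adaptive dual thresholds with running signal/noise peak estimates, a 200 ms
refractory period, T-wave rejection by slope comparison, and a search-back
pass with halved thresholds when an expected beat is missed.  Reported
indices are refined to the local maximum of the preprocessed signal.

Detected R-R intervals then pass through rigid length thresholding: eight
reference intervals from the record's normal range define a mean μ and
population standard deviation σ, and only intervals within [μ−σ, μ+σ] are
kept.  Surviving R-R segments are interpolated to exactly 150 samples each,
one segment per heartbeat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import interpolate as spi
from scipy import signal as sps

from .records import Beat, EcgRecord

logger = logging.getLogger(__name__)


class TooShortError(ValueError):
    """Record too short for QRS detection."""


class RecordRejectedError(ValueError):
    """Record yields too few R-R intervals for reference selection."""


@dataclass(frozen=True)
class RPeakList:
    """Strictly increasing 0-based sample indices of detected R peaks."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=int))
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass(frozen=True)
class ThresholdStats:
    """Rigid-thresholding statistics of one record.

    ``rr_ref`` holds the eight reference R-R lengths (samples); ``mu`` and
    ``sigma`` their mean and population standard deviation; the retention
    band is [``th1``, ``th2``] = [μ−σ, μ+σ].
    """

    rr_all: np.ndarray
    rr_ref: np.ndarray
    mu: float
    sigma: float
    th1: float
    th2: float


@dataclass(frozen=True)
class SegmentationConfig:
    beat_length: int = 150
    n_ref: int = 8
    ref_rule: str = "median-nearest"  # or "first-k"
    interp: str = "linear"  # or "cubic"
    inclusive_bounds: bool = True

    def __post_init__(self) -> None:
        if self.beat_length < 2:
            raise ValueError("beat_length must be >= 2")
        if self.n_ref < 2:
            raise ValueError("n_ref must be >= 2")
        if self.ref_rule not in ("median-nearest", "first-k"):
            raise ValueError("ref_rule must be 'median-nearest' or 'first-k'")
        if self.interp not in ("linear", "cubic"):
            raise ValueError("interp must be 'linear' or 'cubic'")


# ---------------------------------------------------------------------------
# Pan–Tompkins detector
# ---------------------------------------------------------------------------

def _pt_stages(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (band-passed, integrated) stage outputs.

    The band-pass is applied zero-phase so stage outputs stay aligned with
    the input; the five-point derivative and squaring emphasise QRS slopes,
    and the 150 ms moving window integrates them into one hump per beat.
    """
    sos = sps.butter(1, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    # five-point derivative: (1/8)(2x[n] + x[n-1] - x[n-3] - 2x[n-4])
    kernel = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) / 8.0
    deriv = np.convolve(bp, kernel, mode="same")
    sq = deriv * deriv
    n_int = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(sq, np.ones(n_int) / n_int, mode="same")
    return bp, mwi


def _mean_abs_slope(bp: np.ndarray, idx: int, half: int) -> float:
    a, b = max(0, idx - half), min(bp.size, idx + half + 1)
    if b - a < 2:
        return 0.0
    return float(np.mean(np.abs(np.diff(bp[a:b]))))


def detect_r_peaks(rec: EcgRecord) -> RPeakList:
    """Pan–Tompkins R-peak detection on a preprocessed record.

    Designed for 250 Hz input, but all internal windows scale with the
    record's sampling rate.  Raises :class:`TooShortError` below 2 s.
    """
    fs = rec.fs
    if rec.duration_s < 2.0:
        raise TooShortError(f"record of {rec.duration_s:.2f} s is too short (< 2 s)")
    x = rec.samples
    bp, mwi = _pt_stages(x, fs)

    refractory = int(round(0.200 * fs))
    twave_win = int(round(0.360 * fs))
    slope_half = max(2, int(round(0.075 * fs)))

    # candidate peaks: local maxima of the integrated signal
    cand, _ = sps.find_peaks(mwi, distance=max(1, refractory // 2))
    if cand.size == 0:
        return RPeakList(np.array([], dtype=int), fs)

    # learning phase over the first two seconds
    n0 = int(2 * fs)
    spki = 0.25 * float(np.max(mwi[:n0]))
    npki = 0.5 * float(np.mean(mwi[:n0]))
    spkf = 0.25 * float(np.max(np.abs(bp[:n0])))
    npkf = 0.5 * float(np.mean(np.abs(bp[:n0])))

    def thr_i() -> float:
        return npki + 0.25 * (spki - npki)

    def thr_f() -> float:
        return npkf + 0.25 * (spkf - npkf)

    qrs: list[int] = []
    qrs_slopes: list[float] = []
    rr_hist: list[float] = []
    noise_cand: list[int] = []

    def rr_average() -> float:
        if not rr_hist:
            return 0.0
        return float(np.mean(rr_hist[-8:]))

    def accept(peak: int, searchback: bool = False) -> None:
        nonlocal spki, npki, spkf, npkf
        pki = float(mwi[peak])
        pkf = float(np.abs(bp[peak]))
        if searchback:
            spki = 0.25 * pki + 0.75 * spki
            spkf = 0.25 * pkf + 0.75 * spkf
        else:
            spki = 0.125 * pki + 0.875 * spki
            spkf = 0.125 * pkf + 0.875 * spkf
        if qrs:
            rr_hist.append(peak - qrs[-1])
        qrs.append(peak)
        qrs_slopes.append(_mean_abs_slope(bp, peak, slope_half))

    for peak in cand:
        pki = float(mwi[peak])
        pkf = float(np.abs(bp[peak]))
        since_last = peak - qrs[-1] if qrs else np.inf

        if since_last < refractory:
            continue

        is_qrs = pki > thr_i() and pkf > thr_f()
        if is_qrs and qrs and since_last < twave_win:
            # candidate close after a QRS: T wave if its slope is less than
            # half the slope of the preceding QRS
            if _mean_abs_slope(bp, peak, slope_half) < 0.5 * qrs_slopes[-1]:
                is_qrs = False

        if is_qrs:
            accept(peak)
        else:
            npki = 0.125 * pki + 0.875 * npki
            npkf = 0.125 * pkf + 0.875 * npkf
            noise_cand.append(peak)

        # search-back: no QRS within 166% of the running RR average
        rr_avg = rr_average()
        if qrs and rr_avg > 0 and (peak - qrs[-1]) > 1.66 * rr_avg:
            lo = qrs[-1] + refractory
            a = int(np.searchsorted(cand, lo))
            b = int(np.searchsorted(cand, peak))
            qrs_set = set(qrs)
            window = [
                int(c) for c in cand[a:b]
                if c not in qrs_set
                and float(mwi[c]) > 0.5 * thr_i()
                and float(np.abs(bp[c])) > 0.5 * thr_f()
            ]
            if window:
                best = max(window, key=lambda c: mwi[c])
                accept(int(best), searchback=True)
                qrs.sort()

    if not qrs:
        return RPeakList(np.array([], dtype=int), fs)

    # Refinement: an integration-hump maximum can sit tens of ms off the R
    # wave, so first snap to the band-passed QRS peak within half the
    # integration window, then to the maximum of the preprocessed signal
    # within ±40 ms of it.
    half_bp = max(1, int(round(0.075 * fs)))
    half = int(round(0.040 * fs))
    refined = []
    for peak in sorted(qrs):
        a, b = max(0, peak - half_bp), min(x.size, peak + half_bp + 1)
        anchor = a + int(np.argmax(np.abs(bp[a:b])))
        a, b = max(0, anchor - half), min(x.size, anchor + half + 1)
        refined.append(a + int(np.argmax(x[a:b])))
    refined = np.unique(np.asarray(refined, dtype=int))
    # drop refined duplicates closer than the refractory period
    keep = [int(refined[0])]
    for r in refined[1:]:
        if r - keep[-1] >= refractory:
            keep.append(int(r))
    return RPeakList(np.asarray(keep, dtype=int), fs)


# ---------------------------------------------------------------------------
# Rigid R-R length thresholding
# ---------------------------------------------------------------------------

def rr_lengths(peaks: RPeakList) -> np.ndarray:
    """Consecutive R-R lengths Δx_i = x_i − x_{i−1}, in samples."""
    if len(peaks) < 2:
        return np.array([], dtype=float)
    return np.diff(peaks.indices).astype(float)


def select_reference_rr(
    rr: np.ndarray, cfg: SegmentationConfig | None = None
) -> np.ndarray:
    """Pick the reference "normal range" R-R lengths (default eight).

    ``median-nearest``: the n_ref values closest to the median of all
    intervals, ties broken by earliest occurrence, returned in original
    order.  ``first-k``: simply the first n_ref values.
    """
    cfg = cfg or SegmentationConfig()
    rr = np.asarray(rr, dtype=float)
    if rr.size < cfg.n_ref:
        raise RecordRejectedError(
            f"only {rr.size} R-R intervals; need at least {cfg.n_ref}"
        )
    if cfg.ref_rule == "first-k":
        return rr[: cfg.n_ref].copy()
    med = float(np.median(rr))
    order = np.lexsort((np.arange(rr.size), np.abs(rr - med)))
    chosen = np.sort(order[: cfg.n_ref])
    return rr[chosen]


def compute_thresholds(
    rr_ref: np.ndarray, rr_all: np.ndarray | None = None, n_ref: int = 8
) -> ThresholdStats:
    """Mean, population standard deviation, and the μ±σ retention band."""
    rr_ref = np.asarray(rr_ref, dtype=float)
    if rr_ref.size != n_ref:
        raise ValueError(f"expected exactly {n_ref} reference R-R lengths, got {rr_ref.size}")
    mu = float(np.mean(rr_ref))
    sigma = float(np.sqrt(np.mean((rr_ref - mu) ** 2)))  # divisor N
    return ThresholdStats(
        rr_all=np.asarray(rr_all, dtype=float) if rr_all is not None else rr_ref.copy(),
        rr_ref=rr_ref,
        mu=mu,
        sigma=sigma,
        th1=mu - sigma,
        th2=mu + sigma,
    )


def interpolate_beat(
    segment: np.ndarray, beat_length: int = 150, kind: str = "linear"
) -> np.ndarray:
    """Map a segment onto ``beat_length`` points over normalized time."""
    segment = np.asarray(segment, dtype=float)
    if segment.size < 2:
        raise ValueError("segment must have at least 2 samples")
    src = np.linspace(0.0, 1.0, segment.size)
    dst = np.linspace(0.0, 1.0, beat_length)
    if kind == "linear":
        return np.interp(dst, src, segment)
    return spi.CubicSpline(src, segment)(dst)


def clip_beats(
    rec: EcgRecord,
    peaks: RPeakList,
    stats: ThresholdStats,
    cfg: SegmentationConfig | None = None,
) -> list[Beat]:
    """Clip retained R-R segments and interpolate each to the beat length.

    A consecutive peak pair (x_{i−1}, x_i) is retained when its length lies
    inside the record's [th1, th2] band (inclusive by default); the half-open
    segment [x_{i−1}, x_i) is then interpolated to ``cfg.beat_length``
    samples and labeled with the record's subject.
    """
    cfg = cfg or SegmentationConfig()
    beats: list[Beat] = []
    idx = peaks.indices
    for a, b in zip(idx[:-1], idx[1:]):
        dx = float(b - a)
        if cfg.inclusive_bounds:
            ok = stats.th1 <= dx <= stats.th2
        else:
            ok = stats.th1 < dx < stats.th2
        if not ok:
            continue
        segment = rec.samples[a:b]
        values = interpolate_beat(segment, cfg.beat_length, cfg.interp)
        beats.append(
            Beat(
                values=values,
                subject_id=rec.subject_id,
                record_id=rec.record_id,
                rr_samples=dx,
            )
        )
    return beats


def segment_record(
    rec: EcgRecord, cfg: SegmentationConfig | None = None
) -> list[Beat]:
    """Full segmentation: detect → R-R lengths → reference → thresholds → clip.

    A record that yields fewer reference intervals than required produces no
    beats (with a warning) rather than an exception, so cohort runs degrade
    gracefully.
    """
    cfg = cfg or SegmentationConfig()
    peaks = detect_r_peaks(rec)
    rr = rr_lengths(peaks)
    try:
        rr_ref = select_reference_rr(rr, cfg)
    except RecordRejectedError as e:
        logger.warning("record %s rejected: %s", rec.record_id, e)
        return []
    stats = compute_thresholds(rr_ref, rr_all=rr, n_ref=cfg.n_ref)
    beats = clip_beats(rec, peaks, stats, cfg)
    logger.info(
        "record %s: %d peaks, %d RR, %d retained, %d beats",
        rec.record_id, len(peaks), rr.size,
        int(np.sum((rr >= stats.th1) & (rr <= stats.th2))), len(beats),
    )
    return beats
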