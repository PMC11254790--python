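"""Sampling-rate standardization and band-pass denoising.

Raw records from different sources arrive at different rates; all are
resampled to a common 250 Hz by rational-factor polyphase filtering, then
band-pass filtered with a 3rd-order Butterworth (0.6–40 Hz) to remove
baseline wander below the band and power-line / muscle noise above it.
The filter is applied forward-backward by default (zero phase), so QRS
timing is preserved at the cost of squaring the magnitude response.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .records import EcgRecord


@dataclass(frozen=True)
class PreprocessConfig:
    target_fs: float = 250.0
    filter_order: int = 3
    low_cut: float = 0.6
    high_cut: float = 40.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError("need 0 < low_cut < high_cut")
        if self.high_cut >= self.target_fs / 2:
            raise ValueError("high_cut must be below the Nyquist frequency")


def design_bandpass(cfg: PreprocessConfig, fs: float) -> np.ndarray:
    """Second-order sections of the configured Butterworth band-pass."""
    if cfg.high_cut >= fs / 2:
        raise ValueError(
            f"high_cut {cfg.high_cut} Hz >= Nyquist {fs / 2} Hz at fs={fs}"
        )
    return sps.butter(
        cfg.filter_order, [cfg.low_cut, cfg.high_cut], btype="bandpass",
        fs=fs, output="sos",
    )


def bandpass_gain(cfg: PreprocessConfig, fs: float, freq: float) -> float:
    """Analytic magnitude response |H(f)| of the designed filter.

    Squared when ``zero_phase`` since forward-backward filtering applies the
    transfer function twice.
    """
    sos = design_bandpass(cfg, fs)
    _, h = sps.sosfreqz(sos, worN=[freq], fs=fs)
    g = float(np.abs(h[0]))
    return g * g if cfg.zero_phase else g


def resample_record(rec: EcgRecord, target_fs: float) -> EcgRecord:
    """Resample to ``target_fs`` by polyphase rational-factor filtering.

    Identity when the rate already matches.  Duration is preserved to within
    one output sample.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if rec.fs == target_fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = sps.resample_poly(rec.samples, frac.numerator, frac.denominator)
    n_expected = int(round(rec.n_samples * target_fs / rec.fs))
    if out.size > n_expected:
        out = out[:n_expected]
    elif out.size < n_expected:
        out = np.pad(out, (0, n_expected - out.size), mode="edge")
    return rec.with_samples(out, fs=target_fs)


def bandpass_record(rec: EcgRecord, cfg: PreprocessConfig | None = None) -> EcgRecord:
    """Apply the configured band-pass; same length as the input."""
    cfg = cfg or PreprocessConfig()
    sos = design_bandpass(cfg, rec.fs)
    if cfg.zero_phase:
        out = sps.sosfiltfilt(sos, rec.samples)
    else:
        out = sps.sosfilt(sos, rec.samples)
    return rec.with_samples(out)


def preprocess(rec: EcgRecord, cfg: PreprocessConfig | None = None) -> EcgRecord:
    """Resample to the target rate, then band-pass filter."""
    cfg = cfg or PreprocessConfig()
    return bandpass_record(resample_record(rec, cfg.target_fs), cfg)
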