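"""Signal conditioning: resampling, bandpass filtering, normalization, trimming.

The working sampling rate is 256 Hz.  Out-of-band noise — baseline wander
around 0.15–0.3 Hz, 60 Hz mains interference and its harmonics, broadband
muscle and instrumentation noise — is rejected with a zero-phase Butterworth
bandpass (default 0.5–40 Hz, order 4, applied forward-backward).  Amplitude
is normalized to unit maximum absolute value, and 1% of the record is
trimmed from each end to discard acquisition edge artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .ecg_io import ECGRecord

__all__ = [
    "PreprocessConfig",
    "resample",
    "bandpass",
    "normalize_amplitude",
    "trim_edges",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Conditioning parameters.

    target_fs : working sampling rate, Hz.
    bandpass_low, bandpass_high : Butterworth corner frequencies, Hz;
        must satisfy 0 < low < high < target_fs / 2.
    filter_order : Butterworth order (effective order doubles under the
        forward-backward application).
    edge_trim_fraction : fraction of the record removed from each end.
    normalization : "max_abs" scales the peak absolute amplitude to 1;
        "none" leaves amplitudes untouched.
    """

    target_fs: float = 256.0
    bandpass_low: float = 0.5
    bandpass_high: float = 40.0
    filter_order: int = 4
    edge_trim_fraction: float = 0.01
    normalization: str = "max_abs"

    def __post_init__(self) -> None:
        if not (0 < self.bandpass_low < self.bandpass_high < self.target_fs / 2):
            raise ValueError(
                "require 0 < bandpass_low < bandpass_high < target_fs/2, got "
                f"({self.bandpass_low}, {self.bandpass_high}) at fs {self.target_fs}"
            )
        if not (0 <= self.edge_trim_fraction < 0.5):
            raise ValueError("edge_trim_fraction must be in [0, 0.5)")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.normalization not in ("max_abs", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


def resample(rec: ECGRecord, target_fs: float) -> ECGRecord:
    """Resample to ``target_fs`` with polyphase anti-aliased resampling.

    Annotated R-peak indices are rescaled by the rate ratio and rounded to
    the nearest sample.  A record already at the target rate is returned
    unchanged.
    """
    if target_fs <= 0:
        raise ValueError(f"target_fs must be > 0, got {target_fs}")
    if rec.fs == target_fs:
        return rec
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    up, down = ratio.numerator, ratio.denominator
    samples = sps.resample_poly(rec.samples, up, down)
    r_peaks = None
    if rec.r_peaks is not None:
        scaled = np.round(rec.r_peaks * (target_fs / rec.fs)).astype(np.int64)
        r_peaks = np.unique(scaled[(scaled >= 0) & (scaled < samples.size)])
    return rec.with_(samples=samples, fs=float(target_fs), r_peaks=r_peaks)


def _sos(cfg: PreprocessConfig, fs: float):
    return sps.butter(
        cfg.filter_order,
        [cfg.bandpass_low, cfg.bandpass_high],
        btype="bandpass",
        fs=fs,
        output="sos",
    )


def bandpass(rec: ECGRecord, cfg: PreprocessConfig | None = None) -> ECGRecord:
    """Zero-phase Butterworth bandpass (forward-backward ``sosfiltfilt``)."""
    cfg = cfg or PreprocessConfig()
    if cfg.bandpass_high >= rec.fs / 2:
        raise ValueError(
            f"bandpass_high {cfg.bandpass_high} Hz is not below Nyquist ({rec.fs / 2} Hz)"
        )
    filtered = sps.sosfiltfilt(_sos(cfg, rec.fs), rec.samples)
    return rec.with_(samples=filtered)


def normalize_amplitude(rec: ECGRecord) -> ECGRecord:
    """Scale so the maximum absolute amplitude is exactly 1."""
    peak = float(np.max(np.abs(rec.samples)))
    if peak == 0.0:
        raise ValueError("cannot normalize an all-zero signal")
    if peak == 1.0:
        return rec
    return rec.with_(samples=rec.samples / peak)


def trim_edges(rec: ECGRecord, fraction: float = 0.01) -> ECGRecord:
    """Drop ``floor(fraction * n)`` samples from each end of the record.

    R-peak annotations are shifted into the new coordinate frame; peaks
    falling inside a trimmed region are dropped.
    """
    if not (0 <= fraction < 0.5):
        raise ValueError("fraction must be in [0, 0.5)")
    n = rec.n_samples
    cut = int(np.floor(fraction * n))
    if cut == 0:
        return rec
    if n - 2 * cut <= 0:
        raise ValueError("trimming would leave an empty record")
    samples = rec.samples[cut : n - cut]
    r_peaks = None
    if rec.r_peaks is not None:
        kept = rec.r_peaks[(rec.r_peaks >= cut) & (rec.r_peaks < n - cut)]
        r_peaks = kept - cut
    return rec.with_(samples=samples, r_peaks=r_peaks)


def preprocess(rec: ECGRecord, cfg: PreprocessConfig | None = None) -> ECGRecord:
    """Full conditioning chain: resample, bandpass, normalize, trim."""
    cfg = cfg or PreprocessConfig()
    rec = resample(rec, cfg.target_fs)
    rec = bandpass(rec, cfg)
    if cfg.normalization == "max_abs":
        rec = normalize_amplitude(rec)
    rec = trim_edges(rec, cfg.edge_trim_fraction)
    return rec
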