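"""Pan-Tompkins QRS detection.

The classic real-time detector: bandpass (5–15 Hz), derivative, squaring,
moving-window integration (150 ms) and an adaptive dual-threshold decision
rule with search-back for missed beats.  Constants follow the published
algorithm: 200 ms refractory period, T-wave rejection by slope comparison
for candidates within 360 ms of the previous beat, and a search-back
trigger at 1.66 times the running RR average.  The reported R-peak
position is refined to the maximum of the detector's bandpassed signal in
a window around each integrator peak, so indices are R-wave aligned and
directly usable for segmentation.

The first two seconds are used only for threshold initialization;
detections there are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .ecg_io import ECGRecord

__all__ = ["QRSDetection", "pan_tompkins", "get_r_peaks"]

# classic constants (seconds)
_BAND = (5.0, 15.0)
_INTEGRATION_WINDOW = 0.150
_REFRACTORY = 0.200
_TWAVE_WINDOW = 0.360
_SEARCHBACK_FACTOR = 1.66
_BURN_IN = 2.0


@dataclass(frozen=True)
class QRSDetection:
    """Detector output: R-peak indices plus optional per-stage traces."""

    r_peaks: np.ndarray
    stage_traces: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "r_peaks", np.asarray(self.r_peaks, dtype=np.int64)
        )


def _stages(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    sos = sps.butter(2, _BAND, btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, x)
    derivative = np.gradient(filtered) * fs
    squared = derivative ** 2
    w = max(1, int(round(_INTEGRATION_WINDOW * fs)))
    integrated = np.convolve(squared, np.ones(w) / w, mode="same")
    return filtered, integrated


def _refine(filtered: np.ndarray, idx: int, half: int) -> int:
    lo = max(0, idx - half)
    hi = min(filtered.size, idx + half + 1)
    return lo + int(np.argmax(filtered[lo:hi]))


def _max_slope(filtered: np.ndarray, idx: int, half: int) -> float:
    lo = max(1, idx - half)
    hi = min(filtered.size, idx + half)
    if hi <= lo:
        return 0.0
    return float(np.max(np.abs(np.diff(filtered[lo:hi]))))


def pan_tompkins(rec: ECGRecord, fs: Optional[float] = None, keep_traces: bool = False) -> QRSDetection:
    """Detect QRS complexes; returns R-wave-aligned sample indices.

    Raises on records shorter than two seconds.  A flat (zero-energy)
    signal yields an empty detection rather than an error.
    """
    fs = float(fs or rec.fs)
    x = rec.samples
    if x.size < 2 * fs:
        raise ValueError("record must be at least 2 s long for QRS detection")
    if np.ptp(x) == 0:
        traces = None
        return QRSDetection(r_peaks=np.empty(0, dtype=np.int64), stage_traces=traces)

    filtered, integrated = _stages(x, fs)
    refractory = int(round(_REFRACTORY * fs))
    half_search = int(round(0.100 * fs))
    slope_half = int(round(0.075 * fs))

    # candidate peaks of the integrated signal
    cand, _ = sps.find_peaks(integrated, distance=refractory)
    if cand.size == 0:
        return QRSDetection(r_peaks=np.empty(0, dtype=np.int64))

    burn = int(_BURN_IN * fs)
    init = integrated[:burn]
    spki = 0.25 * float(np.max(init)) if init.size else 0.25 * float(np.max(integrated))
    npki = 0.5 * float(np.mean(init)) if init.size else 0.0

    accepted: list[int] = []       # refined R indices
    accepted_slope: list[float] = []
    rr_history: list[float] = []
    threshold = npki + 0.25 * (spki - npki)

    def rr_avg() -> float:
        if not rr_history:
            return 0.0
        return float(np.mean(rr_history[-8:]))

    noise_peaks: list[int] = []

    for c in cand:
        peak_val = float(integrated[c])
        is_signal = peak_val > threshold
        if is_signal and accepted:
            r_guess = _refine(filtered, c, half_search)
            since = r_guess - accepted[-1]
            if since < refractory:
                is_signal = False
            elif since < int(_TWAVE_WINDOW * fs):
                # T-wave discrimination: a T wave has less than half the
                # slope of the preceding QRS
                slope = _max_slope(filtered, r_guess, slope_half)
                if slope < 0.5 * accepted_slope[-1]:
                    is_signal = False
        if is_signal:
            r = _refine(filtered, c, half_search)
            if accepted and r - accepted[-1] < refractory:
                is_signal = False
            else:
                spki = 0.125 * peak_val + 0.875 * spki
                if accepted:
                    rr_history.append(r - accepted[-1])
                accepted.append(r)
                accepted_slope.append(_max_slope(filtered, r, slope_half))
        if not is_signal:
            npki = 0.125 * peak_val + 0.875 * npki
            noise_peaks.append(c)
        threshold = npki + 0.25 * (spki - npki)

        # search-back: a long gap suggests a missed beat below threshold
        avg = rr_avg()
        if accepted and avg > 0 and (c - _last_integr(accepted, half_search)) > _SEARCHBACK_FACTOR * avg:
            lo = accepted[-1] + refractory
            hi = c
            if hi > lo:
                seg = integrated[lo:hi]
                back_threshold = npki + 0.125 * (spki - npki)
                j = int(np.argmax(seg))
                if seg[j] > back_threshold:
                    r = _refine(filtered, lo + j, half_search)
                    if r - accepted[-1] >= refractory and (c - r) >= 0:
                        spki = 0.25 * float(seg[j]) + 0.75 * spki
                        rr_history.append(r - accepted[-1])
                        accepted.append(r)
                        accepted_slope.append(_max_slope(filtered, r, slope_half))

    peaks = np.asarray(sorted(set(accepted)), dtype=np.int64)
    peaks = peaks[peaks >= burn]
    # enforce refractory after refinement
    if peaks.size:
        kept = [int(peaks[0])]
        for p in peaks[1:]:
            if p - kept[-1] >= refractory:
                kept.append(int(p))
        peaks = np.asarray(kept, dtype=np.int64)

    traces = None
    if keep_traces:
        traces = {"filtered": filtered, "integrated": integrated}
    return QRSDetection(r_peaks=peaks, stage_traces=traces)


def _last_integr(accepted: list[int], half_search: int) -> int:
    return accepted[-1]


def get_r_peaks(rec: ECGRecord, policy: str = "annotations_first") -> np.ndarray:
    """Return R-peak indices for a record.

    ``annotations_first`` uses ``rec.r_peaks`` when present, falling back
    to Pan-Tompkins; ``always_detect`` always runs the detector.
    """
    if policy not in ("annotations_first", "always_detect"):
        raise ValueError(f"unknown policy {policy!r}")
    if policy == "annotations_first" and rec.r_peaks is not None:
        return np.asarray(rec.r_peaks, dtype=np.int64)
    return pan_tompkins(rec).r_peaks
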