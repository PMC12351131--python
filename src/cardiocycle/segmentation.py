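"""Fixed-window "statistical cycle" segmentation around R-peaks.

Each heartbeat is represented by a fixed 1-second window spanning λ = 0.4 s
before to θ = 0.6 s after the R-peak (λ + θ ≤ 1).  Windows are half-open,
0-based sample ranges ``[PR - round(fs·λ), PR - round(fs·λ) + L)`` with
``L = round(fs·(λ+θ))``; the cycle length L is fixed first and the
post-window is L minus the pre-window, so every row of the resulting
matrix has identical length even when ``fs·λ`` is not an integer
(rounding is half-away-from-zero).  Windows extending past either end of
the record are dropped and counted.  When the RR interval is shorter than
the window, consecutive cycles overlap; overlap is retained since the
window length is fixed irrespective of heart rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ecg_io import ECGRecord

__all__ = ["SegmentationConfig", "CycleSet", "segment_cycles", "round_half_away"]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


@dataclass(frozen=True)
class SegmentationConfig:
    """Cycle-window geometry: λ seconds before and θ seconds after R."""

    lambda_pre: float = 0.4
    theta_post: float = 0.6
    fs: float = 256.0

    def __post_init__(self) -> None:
        if self.lambda_pre < 0 or self.theta_post <= 0:
            raise ValueError("window extents must be positive")
        if self.lambda_pre + self.theta_post > 1.0 + 1e-12:
            raise ValueError(
                f"lambda_pre + theta_post must be <= 1 s, got {self.lambda_pre + self.theta_post}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be > 0")

    @property
    def cycle_length(self) -> int:
        """Samples per cycle, L = round(fs·(λ+θ))."""
        return round_half_away(self.fs * (self.lambda_pre + self.theta_post))

    @property
    def r_offset(self) -> int:
        """Sample index of the R-peak within each cycle, round(fs·λ)."""
        return round_half_away(self.fs * self.lambda_pre)


@dataclass(frozen=True)
class CycleSet:
    """An n×L matrix of statistical cycles from one recording."""

    cycles: np.ndarray
    L: int
    r_offset: int
    subject_id: str
    label: str
    source_peaks: np.ndarray
    n_dropped: int = 0
    config: SegmentationConfig = field(default_factory=SegmentationConfig)

    def __post_init__(self) -> None:
        cycles = np.asarray(self.cycles, dtype=float)
        if cycles.ndim != 2 or cycles.shape[1] != self.L:
            raise ValueError(f"cycles must be n×{self.L}")
        peaks = np.asarray(self.source_peaks, dtype=np.int64)
        if peaks.size != cycles.shape[0]:
            raise ValueError("one source peak per cycle row required")
        object.__setattr__(self, "cycles", cycles)
        object.__setattr__(self, "source_peaks", peaks)

    @property
    def n_cycles(self) -> int:
        return int(self.cycles.shape[0])


def segment_cycles(
    rec: ECGRecord,
    peaks: np.ndarray,
    cfg: SegmentationConfig | None = None,
) -> CycleSet:
    """Cut one fixed-length cycle per in-bounds R-peak.

    Peaks whose full window ``[PR - r_offset, PR - r_offset + L)`` falls
    outside the record are dropped (counted in ``n_dropped``).  Raises if
    no cycle can be retained.
    """
    cfg = cfg or SegmentationConfig(fs=rec.fs)
    peaks = np.asarray(peaks, dtype=np.int64)
    if peaks.size and np.any(np.diff(peaks) <= 0):
        raise ValueError("peaks must be strictly increasing")
    if peaks.size and (peaks[0] < 0 or peaks[-1] >= rec.n_samples):
        raise ValueError("peaks out of record bounds")
    L = cfg.cycle_length
    r_off = cfg.r_offset
    starts = peaks - r_off
    ok = (starts >= 0) & (starts + L <= rec.n_samples)
    kept = peaks[ok]
    if kept.size == 0:
        raise ValueError("no peak admits a full in-bounds cycle window")
    rows = np.stack([rec.samples[s : s + L] for s in kept - r_off])
    return CycleSet(
        cycles=rows,
        L=L,
        r_offset=r_off,
        subject_id=rec.subject_id,
        label=rec.label,
        source_peaks=kept,
        n_dropped=int(peaks.size - kept.size),
        config=cfg,
    )
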