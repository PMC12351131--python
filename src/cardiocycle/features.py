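"""Per-cycle moment features about the mean or the median.

Classical per-cycle features take deviations from the sample mean; the
median-centered variants replace the center with the sample median η,
trading a little statistical efficiency for robustness: a single
arbitrarily large outlier moves the mean without bound but moves the
median by at most the gap to a neighbouring order statistic.

For a cycle x₁…x_N the median-centered moments are

    σ_η² = (1/N) Σ (xᵢ − η)²            (median variance)
    σ_η  = sqrt(σ_η²)                   (median standard deviation)
    ψ_η  = (1/N) Σ (xᵢ − η)³ / σ_η³     (median skewness)
    κ_η  = (1/N) Σ (xᵢ − η)⁴ / σ_η⁴     (median kurtosis)

All denominators use the population convention (1/N).  The standardized
third and fourth moments are normalized by 1/N by default so that the
median and classical features share a convention and κ_η of a large
normal sample is ≈ 3; ``raw=True`` drops the 1/N from ψ_η and κ_η (the
un-normalized sums grow linearly with N and are only meaningful at a
fixed cycle length).

Since the mean minimizes the sum of squared deviations, σ_η² ≥ σ² for
every sample, with equality when mean = median.  With the 1/N
convention, κ ≥ 1 by the power-mean inequality (minimum attained by a
symmetric two-point mass).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import CycleSet

__all__ = [
    "median_center",
    "median_variance",
    "median_std",
    "median_skewness",
    "median_kurtosis",
    "classical_moments",
    "CycleFeatures",
    "extract_features",
]

logger = logging.getLogger(__name__)


def _as_array(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError("input sequence must be non-empty")
    return arr.ravel()


def median_center(x) -> float:
    """Sample median: middle element for odd N, mean of the two middle for even N."""
    return float(np.median(_as_array(x)))


def median_variance(x) -> float:
    """Mean squared deviation from the median, σ_η² = (1/N) Σ (xᵢ − η)²."""
    arr = _as_array(x)
    d = arr - np.median(arr)
    return float(np.mean(d * d))


def median_std(x) -> float:
    """σ_η = sqrt(σ_η²)."""
    return float(np.sqrt(median_variance(x)))


def median_skewness(x, raw: bool = False) -> float:
    """Third standardized moment about the median.

    Default: (1/N) Σ (xᵢ − η)³ / σ_η³.  ``raw=True`` omits the 1/N.
    Raises when σ_η = 0 (moment undefined).
    """
    arr = _as_array(x)
    d = arr - np.median(arr)
    var = float(np.mean(d * d))
    if var == 0.0:
        raise ValueError("median skewness undefined for zero-dispersion input")
    s = float(np.sum(d ** 3)) / var ** 1.5
    return s if raw else s / arr.size


def median_kurtosis(x, raw: bool = False) -> float:
    """Fourth standardized moment about the median (not excess).

    Default: (1/N) Σ (xᵢ − η)⁴ / σ_η⁴ — ≈ 3 for a large normal sample.
    ``raw=True`` omits the 1/N.  Raises when σ_η = 0.
    """
    arr = _as_array(x)
    d = arr - np.median(arr)
    var = float(np.mean(d * d))
    if var == 0.0:
        raise ValueError("median kurtosis undefined for zero-dispersion input")
    k = float(np.sum(d ** 4)) / var ** 2
    return k if raw else k / arr.size


def classical_moments(x) -> tuple[float, float, float, float]:
    """(mean, variance, skewness, kurtosis) with population (1/N) conventions.

    Kurtosis is the plain fourth standardized moment (normal ≈ 3, not
    excess).  Raises when σ = 0 since the standardized moments are then
    undefined.
    """
    arr = _as_array(x)
    m = float(np.mean(arr))
    d = arr - m
    var = float(np.mean(d * d))
    if var == 0.0:
        raise ValueError("standardized moments undefined for zero-dispersion input")
    skew = float(np.mean(d ** 3)) / var ** 1.5
    kurt = float(np.mean(d ** 4)) / var ** 2
    return m, var, skew, kurt


@dataclass(frozen=True)
class CycleFeatures:
    """Per-cycle moment features under one center statistic."""

    center_kind: str  # "mean" or "median"
    center: np.ndarray
    variance: np.ndarray
    skewness: np.ndarray
    kurtosis: np.ndarray
    subject_id: str
    label: str
    n_excluded: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "label": self.label,
                "center_kind": self.center_kind,
                "center": self.center,
                "variance": self.variance,
                "skewness": self.skewness,
                "kurtosis": self.kurtosis,
            }
        )

    @property
    def n_cycles(self) -> int:
        return int(self.variance.size)


def extract_features(cs: CycleSet, center_kind: str = "median", raw: bool = False) -> CycleFeatures:
    """Compute per-cycle moments for every row of a :class:`CycleSet`.

    ``center_kind`` selects mean- or median-centered moments.  Cycles with
    zero dispersion (undefined standardized moments) are excluded with a
    logged count rather than poisoning the feature table.
    """
    if center_kind not in ("mean", "median"):
        raise ValueError(f"center_kind must be 'mean' or 'median', got {center_kind!r}")
    rows = cs.cycles
    n, L = rows.shape
    if center_kind == "median":
        center = np.median(rows, axis=1)
    else:
        center = np.mean(rows, axis=1)
    d = rows - center[:, None]
    var = np.mean(d * d, axis=1)
    ok = var > 0.0
    n_excluded = int(n - ok.sum())
    if n_excluded:
        logger.warning(
            "excluded %d zero-dispersion cycle(s) from %s", n_excluded, cs.subject_id
        )
    d, var, center = d[ok], var[ok], center[ok]
    skew = np.sum(d ** 3, axis=1) / var ** 1.5
    kurt = np.sum(d ** 4, axis=1) / var ** 2
    if not raw:
        skew = skew / L
        kurt = kurt / L
    return CycleFeatures(
        center_kind=center_kind,
        center=center,
        variance=var,
        skewness=skew,
        kurtosis=kurt,
        subject_id=cs.subject_id,
        label=cs.label,
        n_excluded=n_excluded,
    )
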