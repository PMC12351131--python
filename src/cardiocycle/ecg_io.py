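"""Reading and writing single-lead ECG recordings.

Two on-disk layouts are supported:

* a minimal WFDB-style triplet (``<base>.hea`` header, ``<base>.dat`` signal,
  optional ``<base>.rpeaks`` annotation sidecar).  Signal format 16
  (little-endian int16) is read and written; the packed 12-bit format 212
  used by the historical MIT-BIH distributions is read as well.
* plain CSV with two columns (time-or-index, amplitude), an optional header
  line and ``#``-prefixed metadata comments.

Annotation sidecars are plain text: one 0-based R-peak sample index per
line; ``#`` starts a comment.  Files written with 1-based indices by other
software can be converted on read with ``one_based=True``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ECGRecord",
    "FormatError",
    "read_record",
    "write_record",
    "read_rpeaks",
    "write_rpeaks",
]

LABELS = ("healthy", "epilepsy", "unknown")


class FormatError(ValueError):
    """Raised when an on-disk record violates the expected layout."""


@dataclass(frozen=True)
class ECGRecord:
    """A sampled single-lead voltage trace.

    Parameters
    ----------
    samples : ndarray of float
        Amplitudes — millivolts before normalization, arbitrary units after.
    fs : float
        Sampling rate in Hz, strictly positive.
    subject_id : str
        Opaque identifier of the recorded subject.
    label : {"healthy", "epilepsy", "unknown"}
        Class label of the recording.
    r_peaks : ndarray of int, optional
        Strictly increasing 0-based sample indices of annotated R-peaks.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    label: str = "unknown"
    r_peaks: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            bad = int(np.flatnonzero(~np.isfinite(samples))[0])
            raise ValueError(f"non-finite amplitude at sample {bad}")
        if not self.fs > 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        object.__setattr__(self, "samples", samples)
        if self.r_peaks is not None:
            peaks = np.asarray(self.r_peaks, dtype=np.int64)
            if peaks.ndim != 1:
                raise ValueError("r_peaks must be 1-D")
            if peaks.size and (np.any(np.diff(peaks) <= 0)):
                raise ValueError("r_peaks must be strictly increasing")
            if peaks.size and (peaks[0] < 0 or peaks[-1] >= samples.size):
                raise ValueError("r_peaks indices out of signal bounds")
            object.__setattr__(self, "r_peaks", peaks)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.samples.size / self.fs

    def with_(self, **kwargs) -> "ECGRecord":
        """Return a copy with the given fields replaced (validated)."""
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# annotation sidecars

def _rpeaks_path(base: str) -> str:
    return base + ".rpeaks"


def write_rpeaks(peaks: np.ndarray, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# R-peak sample indices, 0-based\n")
        for p in np.asarray(peaks, dtype=np.int64):
            fh.write(f"{int(p)}\n")


def read_rpeaks(path: str, one_based: bool = False) -> np.ndarray:
    indices = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                indices.append(int(line))
    peaks = np.asarray(indices, dtype=np.int64)
    if one_based:
        peaks = peaks - 1
    return peaks


# ---------------------------------------------------------------------------
# CSV

def _write_csv(rec: ECGRecord, base: str) -> None:
    path = base + ".csv"
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:.12g}\n")
        if rec.subject_id:
            fh.write(f"# subject_id={rec.subject_id}\n")
        if rec.label != "unknown":
            fh.write(f"# label={rec.label}\n")
        fh.write("time,amplitude\n")
        for i, x in enumerate(rec.samples):
            fh.write(f"{i / rec.fs:.9f},{x:.17g}\n")


def _read_csv(base: str, fs: Optional[float], one_based: bool) -> ECGRecord:
    path = base if base.endswith(".csv") else base + ".csv"
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    meta = {}
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            parts = line.split(",")
            if len(parts) < 2:
                raise FormatError(f"{path}: expected two columns, got {line!r}")
            rows.append((parts[0].strip(), parts[1].strip()))
    # optional single header line
    start = 0
    try:
        float(rows[0][0])
    except (ValueError, IndexError):
        start = 1
    if len(rows) <= start:
        raise FormatError(f"{path}: no data rows")
    times = np.empty(len(rows) - start)
    amps = np.empty(len(rows) - start)
    for i, (t, a) in enumerate(rows[start:]):
        times[i] = float(t)
        amps[i] = float(a)
        if not np.isfinite(amps[i]):
            raise FormatError(f"{path}: non-finite amplitude at data row {i}")
    if times.size > 1 and np.any(np.diff(times) <= 0):
        bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
        raise FormatError(f"{path}: time column not strictly increasing at row {bad}")
    if fs is None:
        if "fs" in meta:
            fs = float(meta["fs"])
        elif times.size > 1:
            dt = np.median(np.diff(times))
            if dt <= 0:
                raise FormatError(f"{path}: cannot infer sampling rate")
            fs = 1.0 / dt
        else:
            raise FormatError(f"{path}: sampling rate unknown; pass fs=")
    stem = path[:-4]
    r_peaks = None
    ann = _rpeaks_path(stem)
    if os.path.exists(ann):
        r_peaks = read_rpeaks(ann, one_based=one_based)
    return ECGRecord(
        samples=amps,
        fs=float(fs),
        subject_id=meta.get("subject_id", os.path.basename(stem)),
        label=meta.get("label", "unknown"),
        r_peaks=r_peaks,
    )


# ---------------------------------------------------------------------------
# minimal WFDB-style triplet

def _write_wfdb(rec: ECGRecord, base: str, adc_bits: int, adc_range: float) -> None:
    name = os.path.basename(base)
    gain = (2 ** adc_bits) / adc_range  # ADC units per signal unit
    stored = np.round(rec.samples * gain)
    lim = 2 ** 15 - 1
    if np.any(np.abs(stored) > lim):
        raise FormatError(
            f"amplitudes exceed the {adc_bits}-bit/{adc_range:g}-unit ADC span"
        )
    stored = stored.astype("<i2")
    with open(base + ".dat", "wb") as fh:
        fh.write(stored.tobytes())
    comments = []
    if rec.subject_id:
        comments.append(f"# subject_id: {rec.subject_id}")
    if rec.label != "unknown":
        comments.append(f"# label: {rec.label}")
    with open(base + ".hea", "w") as fh:
        fh.write(f"{name} 1 {rec.fs:.12g} {rec.n_samples}\n")
        fh.write(f"{name}.dat 16 {gain:.12g}(0)/mV {adc_bits} 0 {int(stored[0])} 0 0 ECG\n")
        for c in comments:
            fh.write(c + "\n")
    if rec.r_peaks is not None:
        write_rpeaks(rec.r_peaks, _rpeaks_path(base))


def _parse_gain(token: str) -> tuple[float, float]:
    """Parse a WFDB gain spec ``gain(baseline)/units`` -> (gain, baseline)."""
    token = token.split("/", 1)[0]
    baseline = 0.0
    if "(" in token:
        token, rest = token.split("(", 1)
        baseline = float(rest.rstrip(")"))
    gain = float(token) if token else 200.0
    if gain == 0:
        gain = 200.0  # WFDB convention: 0 means the default gain
    return gain, baseline


def _read_dat(path: str, fmt: int, n_samples: int) -> np.ndarray:
    with open(path, "rb") as fh:
        raw = fh.read()
    if fmt == 16:
        data = np.frombuffer(raw, dtype="<i2")
        return data[:n_samples].astype(float)
    if fmt == 212:
        # pairs of 12-bit samples packed into 3 bytes
        b = np.frombuffer(raw, dtype=np.uint8)
        n_tri = b.size // 3
        b = b[: n_tri * 3].reshape(-1, 3).astype(np.int32)
        s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        s0 = np.where(s0 > 2047, s0 - 4096, s0)
        s1 = np.where(s1 > 2047, s1 - 4096, s1)
        out = np.empty(2 * n_tri, dtype=float)
        out[0::2] = s0
        out[1::2] = s1
        return out[:n_samples]
    raise FormatError(f"unsupported WFDB signal format {fmt}")


def _read_wfdb(base: str, channel: int, one_based: bool) -> ECGRecord:
    hea = base + ".hea"
    if not os.path.exists(hea):
        raise FileNotFoundError(hea)
    meta = {}
    lines = []
    with open(hea) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            lines.append(line)
    if not lines:
        raise FormatError(f"{hea}: empty header")
    head = lines[0].split()
    if len(head) < 3:
        raise FormatError(f"{hea}: malformed record line")
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0])
    n_samples = int(head[3]) if len(head) > 3 else -1
    if channel >= n_sig:
        raise FormatError(f"{hea}: channel {channel} but only {n_sig} signals")
    sig_line = lines[1 + channel].split()
    dat_name, fmt_token = sig_line[0], sig_line[1]
    fmt = int(fmt_token.split("x")[0].split(":")[0].split("+")[0])
    gain, baseline = _parse_gain(sig_line[2]) if len(sig_line) > 2 else (200.0, 0.0)
    dat_path = os.path.join(os.path.dirname(base) or ".", dat_name)
    if n_sig > 1 and fmt == 16:
        # interleaved multiplexed frames: take the requested channel
        all_data = _read_dat(dat_path, fmt, -1 if n_samples < 0 else n_samples * n_sig)
        data = all_data[channel::n_sig]
        if n_samples >= 0:
            data = data[:n_samples]
    else:
        data = _read_dat(dat_path, fmt, n_samples if n_samples >= 0 else 2 ** 62)
    samples = (data - baseline) / gain
    r_peaks = None
    ann = _rpeaks_path(base)
    if os.path.exists(ann):
        r_peaks = read_rpeaks(ann, one_based=one_based)
    return ECGRecord(
        samples=samples,
        fs=fs,
        subject_id=meta.get("subject_id", os.path.basename(base)),
        label=meta.get("label", "unknown"),
        r_peaks=r_peaks,
    )


# ---------------------------------------------------------------------------
# public dispatch

def read_record(
    path: str,
    format: str = "wfdb",
    fs: Optional[float] = None,
    channel: int = 0,
    one_based: bool = False,
) -> ECGRecord:
    """Read an ECG recording from disk.

    Parameters
    ----------
    path : str
        Record base path (without extension) or, for CSV, the ``.csv`` file.
    format : {"wfdb", "csv"}
    fs : float, optional
        Sampling rate override for CSV files whose time column is an index.
    channel : int
        Signal channel to extract from multi-signal WFDB records.
    one_based : bool
        Treat sidecar annotation indices as 1-based and convert.
    """
    base = path
    for ext in (".csv", ".hea", ".dat"):
        if base.endswith(ext):
            base = base[: -len(ext)]
    if format == "csv":
        return _read_csv(base, fs=fs, one_based=one_based)
    if format == "wfdb":
        return _read_wfdb(base, channel=channel, one_based=one_based)
    raise ValueError(f"unknown format {format!r}")


def write_record(
    rec: ECGRecord,
    path: str,
    format: str = "wfdb",
    adc_bits: int = 12,
    adc_range: float = 10.0,
) -> None:
    """Write an ECG recording.

    WFDB output quantizes amplitudes to ``adc_bits`` over ``adc_range``
    signal units (defaults mirror a 12-bit ADC spanning 10 mV), so a
    round-trip restores samples within half a quantization step,
    ``adc_range / 2**adc_bits / 2``.  CSV output is full precision.
    An annotation sidecar is written iff ``rec.r_peaks`` is present.
    """
    base = path
    for ext in (".csv", ".hea", ".dat"):
        if base.endswith(ext):
            base = base[: -len(ext)]
    d = os.path.dirname(base)
    if d and not os.path.isdir(d):
        raise IOError(f"directory does not exist: {d}")
    if format == "csv":
        _write_csv(rec, base)
        if rec.r_peaks is not None:
            write_rpeaks(rec.r_peaks, _rpeaks_path(base))
        return
    if format == "wfdb":
        _write_wfdb(rec, base, adc_bits=adc_bits, adc_range=adc_range)
        return
    raise ValueError(f"unknown format {format!r}")
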