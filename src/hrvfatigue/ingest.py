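"""ECG / RR-interval ingestion.

Containers for single-lead ECG records and RR (inter-beat) interval series,
a Pan-Tompkins-style R-peak detector, and an optional median-filter artifact
corrector.  All file formats are plain delimited text so that fixtures and
pipeline artifacts stay human-readable: ECG as one sample per line with a
YAML sidecar header, RR as two columns (interval onset time in seconds,
interval length in ms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import signal as sps
from scipy.interpolate import interp1d

__all__ = [
    "EcgRecord",
    "RPeakSeries",
    "RRSeries",
    "read_ecg",
    "write_ecg",
    "read_rr",
    "write_rr",
    "detect_r_peaks",
    "rr_from_peaks",
    "correct_artifacts",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EcgRecord:
    """Single-lead ECG: voltage samples (mV) at a fixed sampling rate."""

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    sex: str = ""

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("ECG samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class RPeakSeries:
    """0-based sample indices of detected R peaks."""

    peak_indices: np.ndarray
    fs: float

    def __post_init__(self):
        idx = np.asarray(self.peak_indices, dtype=np.int64)
        object.__setattr__(self, "peak_indices", idx)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if idx.size > 1 and np.any(np.diff(idx) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return self.peak_indices.size

    @property
    def times_s(self) -> np.ndarray:
        return self.peak_indices / self.fs


@dataclass(frozen=True)
class RRSeries:
    """Successive inter-beat intervals (ms) with cumulative beat timestamps (s).

    For ``n`` intervals there are ``n + 1`` beat timestamps; ``timestamps[i]``
    is the onset of interval ``i`` and ``timestamps[-1]`` the final beat.
    The degenerate empty series (no intervals, no timestamps) is permitted so
    that generators and windowing can represent beat-free spans.
    """

    intervals: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self):
        iv = np.asarray(self.intervals, dtype=float)
        ts = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "intervals", iv)
        object.__setattr__(self, "timestamps", ts)
        if iv.size == 0 and ts.size == 0:
            return
        if ts.size != iv.size + 1:
            raise ValueError(
                f"need n+1 timestamps for n intervals, got {ts.size} for {iv.size}"
            )
        if np.any(iv <= 0):
            raise ValueError("RR intervals must be positive")
        if np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @classmethod
    def from_intervals(cls, intervals_ms, t0_s: float = 0.0) -> "RRSeries":
        iv = np.asarray(intervals_ms, dtype=float)
        if iv.size == 0:
            return cls(np.empty(0), np.empty(0))
        ts = t0_s + np.concatenate(([0.0], np.cumsum(iv) / 1000.0))
        return cls(iv, ts)

    @property
    def onsets_s(self) -> np.ndarray:
        """Onset time of each interval (all timestamps but the last)."""
        return self.timestamps[:-1] if self.timestamps.size else self.timestamps

    @property
    def duration_s(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0]) if self.timestamps.size else 0.0

    def __len__(self) -> int:
        return self.intervals.size


# ---------------------------------------------------------------------------
# text I/O
# ---------------------------------------------------------------------------

def write_ecg(record: EcgRecord, path) -> None:
    """One sample per line plus a ``<path>.hdr`` YAML sidecar (fs, subject, sex)."""
    path = Path(path)
    np.savetxt(path, record.samples, fmt="%.17g")
    header = {
        "fs": float(record.fs),
        "subject_id": record.subject_id,
        "sex": record.sex,
        "n_samples": int(record.samples.size),
    }
    path.with_suffix(path.suffix + ".hdr").write_text(yaml.safe_dump(header))


def read_ecg(path, fs: float | None = None) -> EcgRecord:
    """Read a single-column delimited ECG file.

    ``fs`` may be omitted when a ``<path>.hdr`` sidecar written by
    :func:`write_ecg` is present.  Non-numeric rows are rejected with their
    1-based row number in the error message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ECG file not found: {path}")
    subject_id, sex = "", ""
    hdr = path.with_suffix(path.suffix + ".hdr")
    if hdr.exists():
        meta = yaml.safe_load(hdr.read_text())
        fs = fs if fs is not None else meta.get("fs")
        subject_id = meta.get("subject_id", "")
        sex = meta.get("sex", "")
    if fs is None:
        raise ValueError(f"no sampling rate given and no sidecar header for {path}")
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                values.append(float(line.split()[0]))
            except ValueError:
                raise ValueError(f"{path}: non-numeric content at row {lineno}: {line!r}")
    if not values:
        raise ValueError(f"{path}: empty ECG file")
    return EcgRecord(np.asarray(values), fs=float(fs), subject_id=subject_id, sex=sex)


def write_rr(rr: RRSeries, path) -> None:
    """Two columns: interval onset time (s), interval (ms)."""
    data = np.column_stack([rr.onsets_s, rr.intervals]) if len(rr) else np.empty((0, 2))
    np.savetxt(path, data, fmt="%.17g", header="onset_s\trr_ms", delimiter="\t")


def read_rr(path) -> RRSeries:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"RR file not found: {path}")
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        return RRSeries(np.empty(0), np.empty(0))
    onsets, intervals = data[:, 0], data[:, 1]
    ts = np.concatenate([onsets, [onsets[-1] + intervals[-1] / 1000.0]])
    return RRSeries(intervals, ts)


# ---------------------------------------------------------------------------
# R-peak detection (Pan-Tompkins-style chain)
# ---------------------------------------------------------------------------

def _preprocess(record: EcgRecord) -> tuple[np.ndarray, np.ndarray]:
    """Band-pass 5-15 Hz, differentiate, square, 150 ms moving-window integrate."""
    fs = record.fs
    nyq = fs / 2.0
    hi = min(15.0, 0.9 * nyq)
    b, a = sps.butter(2, [5.0 / nyq, hi / nyq], btype="band")
    filtered = sps.filtfilt(b, a, record.samples)
    deriv = np.gradient(filtered)
    squared = deriv * deriv
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")
    return filtered, mwi


def detect_r_peaks(record: EcgRecord) -> RPeakSeries:
    """Detect R peaks with a Pan-Tompkins-style chain.

    Band-pass (5-15 Hz) -> derivative -> squaring -> 150 ms moving-window
    integration -> adaptive signal/noise thresholds with a 200 ms refractory
    period.  Peak positions are refined to the band-passed-signal maximum in a
    +/-100 ms neighbourhood, which keeps the detector invariant to constant
    offsets and positive amplitude rescaling of the input.
    """
    if record.duration_s < 2.0:
        raise ValueError(
            f"record of {record.duration_s:.2f} s is too short; need >= 2 s"
        )
    filtered, mwi = _preprocess(record)
    fs = record.fs
    refractory = int(round(0.200 * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if cand.size == 0 or np.max(mwi) <= 0 or np.ptp(record.samples) == 0:
        warnings.warn("no R peaks detected", stacklevel=2)
        return RPeakSeries(np.empty(0, dtype=np.int64), fs)

    # adaptive thresholds seeded from the first 2 s
    head = mwi[: int(2 * fs)]
    spki = float(np.max(head))
    npki = float(np.mean(head)) * 0.5
    accepted = []
    for i in cand:
        h = mwi[i]
        thr = npki + 0.25 * (spki - npki)
        if h >= thr:
            accepted.append(i)
            spki = 0.125 * h + 0.875 * spki
        else:
            npki = 0.125 * h + 0.875 * npki
    if not accepted:
        warnings.warn("no R peaks detected", stacklevel=2)
        return RPeakSeries(np.empty(0, dtype=np.int64), fs)

    # refine to the local max of the band-passed signal
    half = int(round(0.100 * fs))
    refined = []
    for i in accepted:
        lo, hi = max(0, i - half), min(len(filtered), i + half + 1)
        refined.append(lo + int(np.argmax(filtered[lo:hi])))
    refined = np.asarray(sorted(set(refined)), dtype=np.int64)

    # enforce refractory on refined positions, keeping the larger peak
    keep: list[int] = []
    for i in refined:
        if keep and i - keep[-1] < refractory:
            if filtered[i] > filtered[keep[-1]]:
                keep[-1] = int(i)
        else:
            keep.append(int(i))
    return RPeakSeries(np.asarray(keep, dtype=np.int64), fs)


def rr_from_peaks(peaks: RPeakSeries) -> RRSeries:
    """RR intervals (ms) from successive peak indices; n peaks -> n-1 intervals."""
    if len(peaks) < 2:
        raise ValueError(f"need >= 2 peaks to form RR intervals, got {len(peaks)}")
    times = peaks.times_s
    intervals = np.diff(peaks.peak_indices) / peaks.fs * 1000.0
    return RRSeries(intervals, times)


# ---------------------------------------------------------------------------
# optional artifact correction (off by default in the pipeline)
# ---------------------------------------------------------------------------

def correct_artifacts(rr: RRSeries, rel_threshold: float = 0.3) -> tuple[RRSeries, int]:
    """Replace intervals deviating > ``rel_threshold`` from an 11-beat local
    median by cubic interpolation of the surrounding good beats.

    Returns the corrected series and the number of corrected intervals.
    """
    if not 0 < rel_threshold <= 1:
        raise ValueError("rel_threshold must lie in (0, 1]")
    iv = rr.intervals
    if iv.size < 3:
        return rr, 0
    from scipy.ndimage import median_filter

    local_med = median_filter(iv, size=11, mode="nearest")
    bad = np.abs(iv - local_med) > rel_threshold * local_med
    n_bad = int(bad.sum())
    if n_bad == 0 or n_bad == iv.size:
        return rr, 0
    good = ~bad
    kind = "cubic" if good.sum() >= 4 else "linear"
    f = interp1d(
        np.flatnonzero(good), iv[good], kind=kind, fill_value="extrapolate"
    )
    fixed = iv.copy()
    fixed[bad] = f(np.flatnonzero(bad))
    return RRSeries.from_intervals(fixed, t0_s=rr.timestamps[0]), n_bad
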