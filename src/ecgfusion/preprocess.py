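"""Baseline-wander removal and R-peak-anchored heartbeat segmentation.

Raw ambulatory ECG carries low-frequency baseline drift (respiration,
electrode motion).  The drift is estimated with two cascaded median
filters — a short window that flattens the QRS complexes followed by a
longer window that flattens P/T waves — and subtracted from the signal.
Beats are then cut around annotated R-peaks: ``dt1`` seconds before the
peak through ``dt2`` seconds after, giving ``(dt1 + dt2) * fs + 1`` raw
samples, and resampled to a fixed network input length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import median_filter

__all__ = [
    "EcgRecord",
    "SegmentationConfig",
    "HeartbeatSegment",
    "SegmentationResult",
    "remove_baseline",
    "segment_heartbeats",
    "resample_segment",
    "raw_window_length",
    "load_record_csv",
]

#: sd floor used when z-scoring a segment, so flat segments map to zero.
_SD_FLOOR = 1e-8


@dataclass
class EcgRecord:
    """A single-lead ECG trace with beat annotations.

    Parameters
    ----------
    record_id : str
        Identifier (e.g. the WFDB record name).
    samples : ndarray of float
        Signal amplitudes in mV.
    fs : float
        Sampling rate in Hz.
    lead : str
        Lead name; the reference data uses modified limb lead II.
    annotations : list of (int, str)
        ``(sample_index, symbol)`` pairs marking R-peaks, ordered by index.
    """

    record_id: str
    samples: np.ndarray
    fs: float
    lead: str = "MLII"
    annotations: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError(f"record {self.record_id!r}: samples must be 1-D")
        if not self.fs > 0:
            raise ValueError(f"record {self.record_id!r}: fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"record {self.record_id!r}: samples must be finite")
        idx = np.array([i for i, _ in self.annotations], dtype=int)
        if idx.size:
            if np.any(np.diff(idx) <= 0):
                raise ValueError(
                    f"record {self.record_id!r}: annotation indices must be "
                    "strictly increasing"
                )
            if idx[0] < 0 or idx[-1] >= self.samples.size:
                raise ValueError(
                    f"record {self.record_id!r}: annotation index out of range"
                )

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class SegmentationConfig:
    """Window geometry for beat extraction.

    ``dt1``/``dt2`` are the seconds kept before/after each R-peak;
    ``target_len`` is the length every raw window is resampled to before
    entering the network.  ``normalize`` z-scores each segment (mean 0,
    sd 1) — flat segments map to all-zero.
    """

    dt1: float = 0.3
    dt2: float = 0.5
    target_len: int = 200
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.dt1 < 0 or self.dt2 < 0:
            raise ValueError("dt1 and dt2 must be non-negative")
        if self.dt1 + self.dt2 <= 0:
            raise ValueError("dt1 + dt2 must be positive")
        if self.target_len < 2:
            raise ValueError("target_len must be at least 2")


@dataclass(frozen=True)
class HeartbeatSegment:
    """A fixed-length beat waveform with its label and provenance."""

    samples: np.ndarray
    label: str | None
    record_id: str
    r_peak_index: int


@dataclass
class SegmentationResult:
    """Segments plus a drop report (beats whose window left the record)."""

    segments: list[HeartbeatSegment]
    n_dropped: int
    n_annotations: int

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)


def raw_window_length(cfg: SegmentationConfig, fs: float) -> int:
    """Number of raw samples per beat window: ``(dt1 + dt2) * fs + 1``."""
    return int(round((cfg.dt1 + cfg.dt2) * fs)) + 1


def _odd_window(width_s: float, fs: float) -> int:
    n = int(round(width_s * fs))
    return n + 1 if n % 2 == 0 else n


def remove_baseline(record: EcgRecord, w1: float = 0.2, w2: float = 0.6) -> EcgRecord:
    """Subtract the cascaded-median-filter baseline estimate.

    The baseline is ``median_w2(median_w1(x))`` where the window widths
    (0.2 s and 0.6 s by default) are converted to odd sample counts so the
    median is always an actual sample value; edges use reflection padding.
    Annotations are unchanged.
    """
    if w1 <= 0 or w2 <= 0:
        raise ValueError(
            f"record {record.record_id!r}: median windows must be positive"
        )
    if record.samples.size == 0:
        raise ValueError(f"record {record.record_id!r}: empty signal")
    n1 = _odd_window(w1, record.fs)
    n2 = _odd_window(w2, record.fs)
    if max(n1, n2) > record.samples.size:
        raise ValueError(
            f"record {record.record_id!r}: median window ({max(n1, n2)} samples) "
            f"longer than signal ({record.samples.size} samples)"
        )
    baseline = median_filter(record.samples, size=n1, mode="reflect")
    baseline = median_filter(baseline, size=n2, mode="reflect")
    return replace(record, samples=record.samples - baseline)


def resample_segment(samples: np.ndarray, target_len: int) -> np.ndarray:
    """Resample a beat window to ``target_len`` samples.

    Linear interpolation over the same time support; endpoints are
    preserved and the operation is the identity when lengths already
    match.  Linear interpolation maps affine signals to affine signals,
    which keeps ramp-like ECG segments undistorted.
    """
    samples = np.asarray(samples, dtype=float)
    if target_len < 2:
        raise ValueError("target_len must be at least 2")
    if samples.size < 2:
        raise ValueError("input must have at least 2 samples")
    if samples.size == target_len:
        return samples.copy()
    src = np.linspace(0.0, 1.0, samples.size)
    dst = np.linspace(0.0, 1.0, target_len)
    return np.interp(dst, src, samples)


def _normalize(seg: np.ndarray) -> np.ndarray:
    sd = seg.std()
    return (seg - seg.mean()) / max(sd, _SD_FLOOR)


def segment_heartbeats(
    record: EcgRecord, cfg: SegmentationConfig | None = None
) -> SegmentationResult:
    """Cut one fixed-length segment per annotated R-peak.

    Each window spans ``dt1*fs`` samples before the peak through
    ``dt2*fs`` after (inclusive) and is resampled to ``cfg.target_len``.
    Beats whose window would cross a record boundary are dropped and
    counted in the result's drop report rather than padded.
    """
    cfg = cfg or SegmentationConfig()
    if not record.annotations:
        warnings.warn(
            f"record {record.record_id!r}: no annotations; nothing to segment",
            stacklevel=2,
        )
        return SegmentationResult([], 0, 0)
    before = int(round(cfg.dt1 * record.fs))
    after = int(round(cfg.dt2 * record.fs))
    n = record.samples.size
    segments: list[HeartbeatSegment] = []
    dropped = 0
    for peak, symbol in record.annotations:
        lo, hi = peak - before, peak + after
        if lo < 0 or hi >= n:
            dropped += 1
            continue
        raw = record.samples[lo : hi + 1]
        seg = resample_segment(raw, cfg.target_len)
        if cfg.normalize:
            seg = _normalize(seg)
        segments.append(
            HeartbeatSegment(
                samples=seg, label=symbol, record_id=record.record_id,
                r_peak_index=peak,
            )
        )
    return SegmentationResult(segments, dropped, len(record.annotations))


def load_record_csv(
    signal_path, annotation_path=None, fs: float = 360.0,
    record_id: str | None = None, lead: str = "MLII",
) -> EcgRecord:
    """Read a record from the plain CSV dialect.

    ``signal_path`` holds one sample value per line (first column);
    ``annotation_path`` holds ``sample_index,symbol`` rows.
    """
    samples = np.loadtxt(signal_path, delimiter=",", usecols=0, ndmin=1)
    annotations: list[tuple[int, str]] = []
    if annotation_path is not None:
        with open(annotation_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                idx, sym = line.split(",")[:2]
                annotations.append((int(idx), sym.strip()))
    rid = record_id or str(signal_path)
    return EcgRecord(rid, samples, fs, lead=lead, annotations=annotations)
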