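"""Pre-processing chain: band-pass filter, fixed-length segmentation, z-normalization.

The chain is applied per record in the order *filter → segment → normalize*:
filtering first keeps window-edge transients out of the segments, and
normalization is per segment (each model input has zero mean and unit
standard deviation, so no statistics leak between training and test folds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .bonn import EEGRecord

__all__ = ["PreprocessConfig", "SegmentSet", "bandpass", "segment", "znormalize", "preprocess_dataset"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Band edges in Hz, Butterworth order, and segmentation/normalization flags.

    Defaults follow the common EEG passband 0.5-50 Hz with a 4th-order
    zero-phase Butterworth, and a segment length of 4096 samples (one Bonn
    record; 23.6 s at 173.61 Hz is 4097.2 samples — the corpus itself stores
    4096-point segments, and 4096 divides cleanly through pooling).
    """

    low_hz: float = 0.5
    high_hz: float = 50.0
    filter_order: int = 4
    zero_phase: bool = True
    segment_len_samples: int = 4096
    normalize: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("require 0 < low_hz < high_hz")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.segment_len_samples < 2:
            raise ValueError("segment_len_samples must be >= 2")


@dataclass
class SegmentSet:
    """Fixed-length preprocessed segments with labels and provenance.

    ``segments`` has shape ``(n_segments, segment_len)``; ``provenance[i]`` is
    ``(source_id, sample_offset)`` of segment i within its source record.
    """

    segments: np.ndarray
    labels: np.ndarray
    provenance: list[tuple[str, int]]
    fs: float

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.segments.ndim != 2:
            raise ValueError("segments must be a 2-D array (n_segments, segment_len)")
        if self.labels.shape[0] != self.segments.shape[0]:
            raise ValueError("labels must align with segments")

    def __len__(self) -> int:
        return int(self.segments.shape[0])


def bandpass(signal: np.ndarray, fs: float, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Butterworth band-pass of the configured order; zero-phase when requested.

    Zero-phase filtering runs the filter forward and backward (``sosfiltfilt``),
    which squares the magnitude response and cancels phase distortion.
    Output length equals input length.
    """
    x = np.asarray(signal, dtype=float)
    if not 0 < cfg.low_hz < cfg.high_hz < fs / 2.0:
        raise ValueError(
            f"band edges ({cfg.low_hz}, {cfg.high_hz}) Hz must lie strictly inside (0, fs/2)=(0, {fs/2})"
        )
    if x.size <= 3 * cfg.filter_order:
        raise ValueError(f"signal of length {x.size} too short for order-{cfg.filter_order} filter")
    sos = sps.butter(cfg.filter_order, [cfg.low_hz, cfg.high_hz], btype="bandpass", fs=fs, output="sos")
    if cfg.zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def segment(signal: np.ndarray, segment_len_samples: int) -> list[np.ndarray]:
    """Cut a signal into consecutive non-overlapping windows of fixed length.

    A trailing remainder shorter than one window is discarded.  A signal
    shorter than one window yields an empty list.
    """
    if segment_len_samples < 2:
        raise ValueError("segment_len_samples must be >= 2")
    x = np.asarray(signal, dtype=float)
    n_seg = x.size // segment_len_samples
    if n_seg == 0:
        log.debug("signal of length %d shorter than one window (%d); no segments", x.size, segment_len_samples)
    return [x[i * segment_len_samples : (i + 1) * segment_len_samples].copy() for i in range(n_seg)]


def znormalize(seg: np.ndarray, name: str | None = None) -> np.ndarray:
    """Shift/scale to zero mean and unit population standard deviation."""
    x = np.asarray(seg, dtype=float)
    if x.size < 2:
        raise ValueError("znormalize requires at least 2 samples")
    mu = x.mean()
    sd = x.std()  # population std
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"zero-variance segment cannot be normalized ({name or 'unnamed segment'})")
    return (x - mu) / sd


def preprocess_dataset(
    records: Sequence[tuple[EEGRecord, int]],
    cfg: PreprocessConfig = PreprocessConfig(),
) -> SegmentSet:
    """Apply *bandpass → segment → znormalize* to labelled records.

    Every segment inherits the label of its source record.  All records must
    share a sampling rate.
    """
    if len(records) == 0:
        return SegmentSet(
            np.empty((0, cfg.segment_len_samples)), np.empty(0, dtype=int), [], 0.0
        )
    fs_values = {rec.fs for rec, _ in records}
    if len(fs_values) != 1:
        raise ValueError(f"mixed sampling rates in dataset: {sorted(fs_values)}")
    fs = fs_values.pop()

    segs: list[np.ndarray] = []
    labels: list[int] = []
    provenance: list[tuple[str, int]] = []
    for rec, label in records:
        filtered = bandpass(rec.samples, fs, cfg)
        for i, win in enumerate(segment(filtered, cfg.segment_len_samples)):
            offset = i * cfg.segment_len_samples
            if cfg.normalize:
                win = znormalize(win, name=f"{rec.source_id}@{offset}")
            segs.append(win)
            labels.append(label)
            provenance.append((rec.source_id, offset))
    if not segs:
        return SegmentSet(np.empty((0, cfg.segment_len_samples)), np.empty(0, dtype=int), [], fs)
    return SegmentSet(np.stack(segs), np.array(labels), provenance, fs)
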