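"""Tap landmark detection with threshold-plus-refractory rules.

A tap *onset* (a sudden impact) fires at the first sample where the
smoothed force exceeds the detection threshold (0.05 N by default),
provided at least 75 ms have elapsed since the previous tap's offset.
The matching *offset* (release of contact) fires at the first sample
where the force is back below threshold, at least 40 ms after that
onset.  A trailing onset with no qualifying offset before the end of the
trace is discarded.

Inter-tap intervals (ITIs) are onset-to-onset differences; physiological
plausibility is enforced by :func:`filter_itis`, which discards intervals
longer than 2000 ms (pauses/interruptions) or shorter than 120 ms
(double-tap artifacts).  The detector itself does not enforce the ITI
bounds: double taps with legal refractory spacing are detected as taps
and removed at the interval stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .trace_io import ForceTrace, TraceFormatError

__all__ = [
    "DetectionConfig",
    "TapEvent",
    "ITISeries",
    "detect_taps",
    "extract_itis",
    "filter_itis",
    "taps_to_frame",
    "iti_audit_frame",
]

KEPT = "kept"
TOO_SHORT = "too_short"
TOO_LONG = "too_long"


@dataclass(frozen=True)
class DetectionConfig:
    """Landmark detection parameters.

    ``threshold_override_n`` reproduces the manual per-recording
    threshold adjustment used for patients who tapped too softly or off
    the sensor surface; when set, it replaces ``threshold_n`` and
    ``override_note`` records the provenance of the adjustment.
    """

    threshold_n: float = 0.05
    min_offset_after_onset_ms: float = 40.0
    min_onset_after_offset_ms: float = 75.0
    threshold_override_n: Optional[float] = None
    override_note: str = ""

    def __post_init__(self) -> None:
        if not self.threshold_n > 0:
            raise ValueError("threshold_n must be positive")
        if self.min_offset_after_onset_ms < 0 or self.min_onset_after_offset_ms < 0:
            raise ValueError("refractory times must be non-negative")
        if self.threshold_override_n is not None and not self.threshold_override_n > 0:
            raise ValueError("threshold override must be positive")

    @property
    def effective_threshold_n(self) -> float:
        if self.threshold_override_n is not None:
            return self.threshold_override_n
        return self.threshold_n


@dataclass(frozen=True)
class TapEvent:
    """One detected tap: landmark times (ms, original-recording
    coordinates), peak force between the landmarks, and dwell duration."""

    onset_ms: float
    offset_ms: float
    peak_force_n: float

    def __post_init__(self) -> None:
        if not self.offset_ms > self.onset_ms:
            raise ValueError("tap offset must follow its onset")

    @property
    def dwell_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class ITISeries:
    """Ordered onset-to-onset intervals with per-interval audit flags."""

    intervals_ms: np.ndarray
    flags: np.ndarray

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals_ms, dtype=float)
        fl = np.asarray(self.flags, dtype=object)
        if iv.shape != fl.shape:
            raise ValueError("intervals and flags must have equal length")
        object.__setattr__(self, "intervals_ms", iv)
        object.__setattr__(self, "flags", fl)

    @classmethod
    def from_intervals(cls, intervals_ms: Sequence[float]) -> "ITISeries":
        iv = np.asarray(intervals_ms, dtype=float)
        return cls(intervals_ms=iv, flags=np.full(iv.shape, KEPT, dtype=object))

    @property
    def kept_ms(self) -> np.ndarray:
        return self.intervals_ms[self.flags == KEPT]

    def __len__(self) -> int:
        return self.intervals_ms.size


def detect_taps(trace: ForceTrace, config: DetectionConfig = DetectionConfig()) -> list[TapEvent]:
    """Scan a preprocessed (Newton-unit) trace for tap landmarks.

    Implements a forward scan: onsets are first supra-threshold samples
    satisfying the 75 ms post-offset refractory rule; offsets are first
    sub-threshold samples satisfying the 40 ms post-onset rule.  A sample
    exactly at threshold neither fires an onset (strict ``>``) nor an
    offset (strict ``<``).
    """
    if trace.units != "newton":
        raise TraceFormatError("detect_taps requires a calibrated trace (units='newton')")
    thr = config.effective_threshold_n
    rate = trace.sample_rate_hz
    ms_per_sample = 1000.0 / rate
    above_idx = np.flatnonzero(trace.samples > thr)
    below_idx = np.flatnonzero(trace.samples < thr)
    min_off = math.ceil(config.min_offset_after_onset_ms / ms_per_sample)
    min_on = math.ceil(config.min_onset_after_offset_ms / ms_per_sample)

    taps: list[TapEvent] = []
    search_from = 0  # earliest sample index allowed to fire the next onset
    while True:
        k = np.searchsorted(above_idx, search_from)
        if k == above_idx.size:
            break
        onset = int(above_idx[k])
        m = np.searchsorted(below_idx, onset + min_off)
        if m == below_idx.size:
            break  # trailing onset without qualifying offset: discarded
        offset = int(below_idx[m])
        peak = float(trace.samples[onset:offset].max())
        taps.append(
            TapEvent(
                onset_ms=trace.t0_ms + onset * ms_per_sample,
                offset_ms=trace.t0_ms + offset * ms_per_sample,
                peak_force_n=peak,
            )
        )
        search_from = offset + min_on
    return taps


def extract_itis(taps: Sequence[TapEvent]) -> ITISeries:
    """Onset-to-onset intervals from a chronologically sorted tap list.

    Fewer than two taps yield an empty series (a metric computed on it
    propagates as missing, never as zero).
    """
    onsets = np.array([t.onset_ms for t in taps], dtype=float)
    if onsets.size and np.any(np.diff(onsets) <= 0):
        raise ValueError("taps must be sorted by onset with strictly increasing times")
    if onsets.size < 2:
        return ITISeries.from_intervals([])
    return ITISeries.from_intervals(np.diff(onsets))


def filter_itis(series: ITISeries, min_ms: float = 120.0, max_ms: float = 2000.0) -> ITISeries:
    """Flag implausible intervals; keep the closed interval [min, max].

    Intervals strictly shorter than ``min_ms`` are double-tap artifacts;
    strictly longer than ``max_ms`` are pauses.  Exactly 120 or 2000 ms
    is kept.  Discarded intervals retain their flag for audit; ordering
    is preserved.
    """
    if min_ms >= max_ms:
        raise ValueError("min_ms must be smaller than max_ms")
    flags = np.where(
        series.intervals_ms < min_ms,
        TOO_SHORT,
        np.where(series.intervals_ms > max_ms, TOO_LONG, KEPT),
    ).astype(object)
    return ITISeries(intervals_ms=series.intervals_ms.copy(), flags=flags)


def taps_to_frame(taps: Sequence[TapEvent], recording_id: str = "") -> pd.DataFrame:
    """Detection results as a tidy table (one row per tap)."""
    return pd.DataFrame(
        {
            "recording_id": recording_id,
            "onset_ms": [t.onset_ms for t in taps],
            "offset_ms": [t.offset_ms for t in taps],
            "peak_force_n": [t.peak_force_n for t in taps],
            "dwell_ms": [t.dwell_ms for t in taps],
        }
    )


def iti_audit_frame(series: ITISeries, recording_id: str = "") -> pd.DataFrame:
    """Interval audit table: every interval with its keep/discard flag."""
    return pd.DataFrame(
        {
            "recording_id": recording_id,
            "interval_ms": series.intervals_ms,
            "flag": series.flags,
        }
    )
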