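"""Per-block and per-session tapping speed and variability.

Speed is the median of the kept inter-tap intervals (ms); variability is
the coefficient of variation (CV, %) computed after a single 3-SD trim:
intervals more than 3 sample SDs from the block mean are discarded once,
then CV = 100 × SD / mean of the remaining intervals.  Blocks recorded
before and after a therapy session are pooled (interval concatenation —
no interval is ever formed across a block boundary) before metrics are
computed.

Missing data propagate as NaN, never as zero: a median needs at least
one kept interval, a CV at least two intervals surviving the trim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .detection import ITISeries, TapEvent

__all__ = [
    "TappingSummary",
    "pool_session_blocks",
    "speed_median",
    "variability_cv",
    "window_taps",
    "summarize_session",
]


@dataclass(frozen=True)
class TappingSummary:
    """Session-level tapping outcome row."""

    session_label: str
    n_taps: int
    median_iti_ms: float
    cv_percent: float
    mean_peak_force_n: float
    mean_dwell_ms: float


def pool_session_blocks(blocks: Sequence[ITISeries]) -> ITISeries:
    """Concatenate kept intervals of same-session blocks, in block order.

    Only intervals formed within a block are pooled; the boundary between
    the last tap of one block and the first tap of the next never forms
    an interval.
    """
    if len(blocks) == 0:
        raise ValueError("pool_session_blocks requires at least one block")
    kept = [b.kept_ms for b in blocks]
    return ITISeries.from_intervals(np.concatenate(kept) if kept else np.array([]))


def speed_median(series: ITISeries) -> float:
    """Tapping speed: median of the kept intervals in ms (NaN if empty)."""
    kept = series.kept_ms
    if kept.size == 0:
        return float("nan")
    return float(np.median(kept))


def variability_cv(series: ITISeries, trim_sd: float = 3.0, post_trim_mean: bool = True) -> float:
    """Tapping variability: CV in percent after a single 3-SD trim.

    The trim is one pass: mean and sample SD of the kept intervals define
    the band mean ± ``trim_sd``·SD; intervals outside are discarded once
    (no iteration).  With ``post_trim_mean`` (default) the CV denominator
    is the mean of the remaining intervals, matching the SD's sample; set
    it False to divide by the pre-trim block mean instead.
    """
    kept = series.kept_ms
    if kept.size < 2:
        return float("nan")
    mean = kept.mean()
    sd = kept.std(ddof=1)
    remaining = kept[np.abs(kept - mean) <= trim_sd * sd]
    if remaining.size < 2:
        return float("nan")
    denom = remaining.mean() if post_trim_mean else mean
    return float(100.0 * remaining.std(ddof=1) / denom)


def window_taps(taps: Sequence[TapEvent], window_s: float) -> list[TapEvent]:
    """Restrict taps to a window measured from the first tap onset.

    Speed-tapping trials run ~14 s and paced trials 60 s from the first
    tap; taps whose onset falls after first_onset + window are dropped.
    """
    if not taps:
        return []
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    limit = taps[0].onset_ms + window_s * 1000.0
    return [t for t in taps if t.onset_ms <= limit]


def summarize_session(
    session_label: str,
    blocks: Sequence[Sequence[TapEvent]],
    iti_blocks: Sequence[ITISeries],
) -> TappingSummary:
    """Build the per-session outcome row from pooled blocks."""
    pooled = pool_session_blocks(iti_blocks)
    all_taps = [t for block in blocks for t in block]
    peaks = np.array([t.peak_force_n for t in all_taps], dtype=float)
    dwells = np.array([t.dwell_ms for t in all_taps], dtype=float)
    return TappingSummary(
        session_label=session_label,
        n_taps=len(all_taps),
        median_iti_ms=speed_median(pooled),
        cv_percent=variability_cv(pooled),
        mean_peak_force_n=float(peaks.mean()) if peaks.size else float("nan"),
        mean_dwell_ms=float(dwells.mean()) if dwells.size else float("nan"),
    )
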