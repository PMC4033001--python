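"""Circular statistics for metronome-paced tapping.

Synchronization between tap onsets and metronome clicks is quantified on
the circle: each onset is mapped to a phase angle relative to its
nearest click (full metronome cycle = 2π), and the phase sample is
summarized by the mean resultant length R (1 = perfect phase locking,
0 = no locking), the circular mean phase, the circular angular SD
√(−2·ln R), and the Rayleigh test of uniformity.

The paced task uses a 69 BPM metronome (1.15 Hz, inter-click interval
60000/69 ≈ 869.57 ms) for 60 s from the first tap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MetronomeSchedule",
    "SyncSummary",
    "compute_phases",
    "resultant_length",
    "angular_sd",
    "rayleigh_test",
    "summarize_sync",
]


@dataclass(frozen=True)
class MetronomeSchedule:
    """Uniformly spaced metronome click times."""

    tempo_bpm: float
    click_times_ms: np.ndarray

    def __post_init__(self) -> None:
        if not self.tempo_bpm > 0:
            raise ValueError("tempo_bpm must be positive")
        clicks = np.asarray(self.click_times_ms, dtype=float)
        object.__setattr__(self, "click_times_ms", clicks)
        if clicks.size < 1:
            raise ValueError("schedule needs at least one click")
        if clicks.size > 1:
            spacing = np.diff(clicks)
            if not np.allclose(spacing, self.inter_click_ms, rtol=1e-9, atol=1e-6):
                raise ValueError("clicks must be uniformly spaced at 60000/tempo_bpm ms")

    @property
    def inter_click_ms(self) -> float:
        return 60000.0 / self.tempo_bpm

    @property
    def rate_hz(self) -> float:
        return self.tempo_bpm / 60.0

    @classmethod
    def from_tempo(
        cls, tempo_bpm: float, duration_s: float, start_ms: float = 0.0
    ) -> "MetronomeSchedule":
        """Clicks at ``start_ms + k·60000/tempo`` covering ``duration_s``."""
        if duration_s <= 0:
            raise ValueError("duration_s must be positive")
        inter = 60000.0 / tempo_bpm
        n = int(math.floor(duration_s * 1000.0 / inter)) + 1
        return cls(tempo_bpm=tempo_bpm, click_times_ms=start_ms + inter * np.arange(n))


@dataclass(frozen=True)
class SyncSummary:
    """Circular summary of tap-to-click synchronization."""

    n: int
    R: float
    mean_phase_rad: float
    angular_sd_rad: float
    rayleigh_p: float


def compute_phases(onsets_ms: Sequence[float], schedule: MetronomeSchedule) -> np.ndarray:
    """Phase of each onset relative to its nearest click, in (−π, π].

    phase = 2π · (onset − nearest click) / inter-click interval.  An
    onset exactly halfway between clicks maps to +π by convention.
    Onsets are referenced to the nearest *scheduled* click (clamped to
    the first/last click beyond the clicked span).
    """
    onsets = np.asarray(onsets_ms, dtype=float)
    if onsets.size == 0:
        return np.array([])
    clicks = schedule.click_times_ms
    inter = schedule.inter_click_ms
    k = np.clip(np.round((onsets - clicks[0]) / inter).astype(int), 0, clicks.size - 1)
    delta = onsets - clicks[k]
    phi = 2.0 * np.pi * delta / inter
    # wrap into (−π, π], ties at half-cycle to +π
    phi = np.mod(-phi + np.pi, 2.0 * np.pi)
    return np.pi - phi


def resultant_length(phases: Sequence[float]) -> tuple[float, float]:
    """Mean resultant length R and circular mean phase of a phase sample.

    R = |n⁻¹ Σ e^{iθ}| ∈ [0, 1]; mean phase is the argument of the mean
    resultant vector (NaN when R is numerically zero).
    """
    theta = np.asarray(phases, dtype=float)
    if theta.size == 0:
        raise ValueError("resultant_length requires at least one phase")
    mean_vec = np.exp(1j * theta).mean()
    R = float(np.abs(mean_vec))
    mean_phase = float(np.angle(mean_vec)) if R > 1e-12 else float("nan")
    return R, mean_phase


def angular_sd(R: float) -> float:
    """Circular standard deviation √(−2·ln R), in radians."""
    if not 0 < R <= 1:
        return float("inf") if R == 0 else float("nan")
    return math.sqrt(-2.0 * math.log(R))


def rayleigh_test(phases: Sequence[float]) -> float:
    """Rayleigh test of circular uniformity; returns the p value.

    Uses Z = n·R² with the standard series approximation
    p ≈ e^{−Z} [1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²)],
    clamped into (0, 1].
    """
    theta = np.asarray(phases, dtype=float)
    n = theta.size
    if n < 2:
        raise ValueError("rayleigh_test requires at least two phases")
    R, _ = resultant_length(theta)
    Z = n * R * R
    p = math.exp(-Z) * (
        1.0
        + (2.0 * Z - Z * Z) / (4.0 * n)
        - (24.0 * Z - 132.0 * Z**2 + 76.0 * Z**3 - 9.0 * Z**4) / (288.0 * n * n)
    )
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def summarize_sync(
    onsets_ms: Sequence[float], schedule: MetronomeSchedule
) -> Optional[SyncSummary]:
    """Full circular summary for one recording (None if no onsets)."""
    phases = compute_phases(onsets_ms, schedule)
    if phases.size == 0:
        return None
    R, mean_phase = resultant_length(phases)
    p = rayleigh_test(phases) if phases.size >= 2 else float("nan")
    return SyncSummary(
        n=int(phases.size),
        R=R,
        mean_phase_rad=mean_phase,
        angular_sd_rad=angular_sd(R),
        rayleigh_p=p,
    )
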