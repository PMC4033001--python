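"""Synthetic tapping recordings and cohorts with known ground truth.

No raw patient data accompany the study design this package analyses,
so every downstream stage is exercised against simulated inputs whose
ground truth is known exactly:

* :func:`generate_unpaced_trace` — a speed-tapping force trace (3 kHz)
  with log-normal inter-tap intervals, piecewise-linear tap pulses,
  additive Gaussian sensor noise (clipped at 0 N), and the artifact
  classes real recordings contain: sub-threshold "soft" taps, double-tap
  re-contacts within 120 ms, and pauses longer than 2 s;
* :func:`generate_paced_trace` — metronome-paced tapping (69 BPM
  default) with wrapped-normal asynchronies around the click times;
* :func:`generate_cohort` — a two-group cohort (together / in-turn)
  carrying 9HPT times at PRE/POST, 35-item POMS ratings at PRE/POST and
  faces-scale ratings over twelve time points, with configurable
  group-level PRE→POST effects.

Ground-truth landmark semantics: each generated contact is recorded
with the exact sample indices at which the *clean* (noise-free,
unsmoothed) force signal crosses the detection threshold, so detector
output can be compared landmark-for-landmark.  Soft taps never cross
the threshold; their nominal pulse extent is recorded instead and they
are flagged ``kind="soft"``.

Identical (params, seed) always reproduce bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .clinical import PatientRecord, POMS_SUBSCALES
from .sync import MetronomeSchedule
from .trace_io import ForceTrace

__all__ = [
    "TapGenParams",
    "PacedGenParams",
    "CohortGenParams",
    "GroundTruthTap",
    "Cohort",
    "generate_unpaced_trace",
    "generate_paced_trace",
    "generate_cohort",
]

GROUPS = ("together", "in_turn")

#: Faces-scale session labels: baseline, ten therapy sessions, post.
FACES_TIMEPOINTS = ("PRE",) + tuple(f"S{i}" for i in range(1, 11)) + ("POST",)


@dataclass(frozen=True)
class GroundTruthTap:
    """One generated contact with its exact landmark samples."""

    onset_sample: int
    offset_sample: int
    onset_ms: float
    offset_ms: float
    peak_force_n: float
    kind: str = "normal"  # "normal" | "soft" | "double"
    after_pause: bool = False

    @property
    def dwell_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class TapGenParams:
    """Unpaced (speed-tapping) generator settings.

    Defaults emulate an index-finger speed-tapping block: 3 kHz
    sampling, ~300 ms mean inter-tap interval with 15% CV, ~1 N peaks
    with an 80 ms dwell, plus low rates of soft taps (peak below the
    0.05 N detection threshold), double-tap re-contacts (<120 ms) and
    pauses (>2 s).
    """

    mean_iti_ms: float = 300.0
    iti_cv: float = 0.15
    peak_force_n: float = 1.0
    dwell_ms: float = 80.0
    pulse_rise_ms: float = 5.0
    pulse_fall_ms: float = 10.0
    noise_sd_n: float = 0.005
    soft_tap_rate: float = 0.02
    double_tap_rate: float = 0.03
    pause_rate: float = 0.01
    duration_s: float = 16.0
    sample_rate_hz: float = 3000.0
    detection_threshold_n: float = 0.05

    def __post_init__(self) -> None:
        if not self.mean_iti_ms > 0:
            raise ValueError("mean_iti_ms must be positive")
        if not self.peak_force_n > 0:
            raise ValueError("peak_force_n must be positive")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        for name in ("soft_tap_rate", "double_tap_rate", "pause_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.iti_cv < 0 or self.noise_sd_n < 0:
            raise ValueError("iti_cv and noise_sd_n must be non-negative")
        if min(self.dwell_ms, self.pulse_rise_ms, self.pulse_fall_ms) <= 0:
            raise ValueError("pulse timing fields must be positive")


@dataclass(frozen=True)
class PacedGenParams:
    """Metronome-paced generator settings: 69 BPM (1.15 Hz) for 60 s,
    taps offset from clicks by wrapped-normal asynchronies."""

    tempo_bpm: float = 69.0
    mean_asynchrony_ms: float = 0.0
    asynchrony_sd_ms: float = 20.0
    duration_s: float = 60.0
    peak_force_n: float = 1.0
    dwell_ms: float = 80.0
    pulse_rise_ms: float = 5.0
    pulse_fall_ms: float = 10.0
    noise_sd_n: float = 0.005
    sample_rate_hz: float = 3000.0
    detection_threshold_n: float = 0.05

    def __post_init__(self) -> None:
        if not self.tempo_bpm > 0:
            raise ValueError("tempo_bpm must be positive")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if self.asynchrony_sd_ms < 0 or self.noise_sd_n < 0:
            raise ValueError("spread fields must be non-negative")


# ---------------------------------------------------------------------------
# Pulse construction helpers

_EDGE_MARGIN_S = 1.0  # pulse-free head/tail so the 0.5 s trim is harmless
_DOUBLE_HOST_DWELL_MS = 42.0  # shortened host dwell so a <120 ms re-contact
_DOUBLE_GAP_MS = (75.5, 77.0)  # can respect the 75/40 ms refractory rules
_DOUBLE_DWELL_MS = 42.0


def _pulse_breakpoints(onset_ms, peak, dwell_ms, rise_ms, fall_ms, thr):
    """Piecewise-linear pulse whose threshold crossings sit at
    ``onset_ms`` and ``onset_ms + dwell_ms`` (for peak > thr)."""
    frac = min(thr / peak, 1.0)
    rise_to_thr = rise_ms * frac
    plateau = dwell_ms - (rise_ms + fall_ms) * (1.0 - frac)
    if peak <= thr or plateau <= 0:  # soft tap: nominal extent only
        plateau = max(dwell_ms - rise_ms - fall_ms, 1.0)
        start = onset_ms
    else:
        start = onset_ms - rise_to_thr
    t = np.array([start, start + rise_ms, start + rise_ms + plateau,
                  start + rise_ms + plateau + fall_ms])
    v = np.array([0.0, peak, peak, 0.0])
    return t, v


def _add_pulse(clean: np.ndarray, t_ms: np.ndarray, v: np.ndarray, rate: float) -> tuple[int, int]:
    """Render a pulse onto the clean trace; returns its sample support."""
    s0 = max(int(math.floor(t_ms[0] * rate / 1000.0)), 0)
    s1 = min(int(math.ceil(t_ms[-1] * rate / 1000.0)) + 1, clean.size)
    idx = np.arange(s0, s1)
    clean[idx] += np.interp(idx * 1000.0 / rate, t_ms, v)
    return s0, s1


def _crossings(clean: np.ndarray, s0: int, s1: int, thr: float) -> Optional[tuple[int, int]]:
    """First supra-threshold and first subsequent sub-threshold sample
    within a pulse's support, or None if the pulse never crosses."""
    seg = clean[s0:s1]
    above = np.flatnonzero(seg > thr)
    if above.size == 0:
        return None
    onset = s0 + int(above[0])
    below = np.flatnonzero(seg[above[0]:] < thr)
    if below.size == 0:
        return None
    offset = onset + int(below[0])
    return onset, offset


def _ground_truth_from_schedule(clean, schedule, params, rate):
    """Resolve every scheduled pulse to its clean-signal landmarks."""
    taps = []
    for onset_ms, peak, dwell, kind, after_pause in schedule:
        t, v = _pulse_breakpoints(
            onset_ms, peak, dwell, params.pulse_rise_ms, params.pulse_fall_ms,
            params.detection_threshold_n,
        )
        s0, s1 = _add_pulse(clean, t, v, rate)
        cross = _crossings(clean, s0, s1, params.detection_threshold_n)
        if cross is None:  # soft tap: record nominal pulse extent
            taps.append(
                GroundTruthTap(
                    onset_sample=s0, offset_sample=s1 - 1,
                    onset_ms=s0 * 1000.0 / rate, offset_ms=(s1 - 1) * 1000.0 / rate,
                    peak_force_n=peak, kind="soft", after_pause=after_pause,
                )
            )
        else:
            on, off = cross
            taps.append(
                GroundTruthTap(
                    onset_sample=on, offset_sample=off,
                    onset_ms=on * 1000.0 / rate, offset_ms=off * 1000.0 / rate,
                    peak_force_n=peak, kind=kind, after_pause=after_pause,
                )
            )
    return taps


def _finalize_trace(clean, params, rng, recording_id):
    samples = clean
    if params.noise_sd_n > 0:
        samples = samples + rng.normal(0.0, params.noise_sd_n, size=clean.size)
    samples = np.clip(samples, 0.0, None)  # a resistive sensor reads >= 0 N
    return ForceTrace(
        samples=samples, sample_rate_hz=params.sample_rate_hz,
        units="newton", recording_id=recording_id,
    )


def generate_unpaced_trace(
    params: TapGenParams, seed: int
) -> tuple[ForceTrace, list[GroundTruthTap]]:
    """Simulate one speed-tapping block with exact ground truth.

    Inter-tap intervals are log-normal with the requested mean and CV
    (strictly positive and right-skewed, like real tapping).  Intervals
    are clipped from below so that consecutive pulses always respect the
    detector's refractory geometry (offset + 75 ms before the next
    onset); a pause event replaces the drawn interval with a gap drawn
    uniformly in 2.2–4 s.  A double-tap event shortens the host tap's
    dwell and inserts a spurious re-contact 117–119 ms after the host
    onset — detectable, but removed later by the ITI filter.
    """
    rng = np.random.default_rng(seed)
    rate = params.sample_rate_hz
    n_samples = int(round(params.duration_s * rate))
    clean = np.zeros(n_samples)
    thr = params.detection_threshold_n

    if params.iti_cv > 0:
        sigma2 = math.log(1.0 + params.iti_cv**2)
        mu = math.log(params.mean_iti_ms) - sigma2 / 2.0
    else:
        sigma2, mu = 0.0, math.log(params.mean_iti_ms)

    min_gap_ms = 76.0 + params.pulse_rise_ms + params.pulse_fall_ms
    t_end_ms = (params.duration_s - _EDGE_MARGIN_S) * 1000.0
    schedule: list[tuple[float, float, float, str, bool]] = []
    onset = _EDGE_MARGIN_S * 1000.0
    after_pause = False
    while onset < t_end_ms:
        is_soft = rng.random() < params.soft_tap_rate
        is_double = (not is_soft) and rng.random() < params.double_tap_rate
        if is_soft:
            peak = rng.uniform(0.05 * thr, 0.95 * thr)
            dwell = params.dwell_ms
        else:
            peak = params.peak_force_n
            dwell = _DOUBLE_HOST_DWELL_MS if is_double else params.dwell_ms
        schedule.append((onset, peak, dwell, "soft" if is_soft else "normal", after_pause))
        last_end = onset + dwell
        if is_double:
            gap = rng.uniform(*_DOUBLE_GAP_MS)
            d_onset = onset + dwell + gap  # 117.5–119 ms after the host onset
            schedule.append((d_onset, params.peak_force_n, _DOUBLE_DWELL_MS, "double", False))
            last_end = d_onset + _DOUBLE_DWELL_MS
        if params.pause_rate > 0 and rng.random() < params.pause_rate:
            iti = rng.uniform(2200.0, 4000.0)
            after_pause = True
        else:
            iti = float(rng.lognormal(mu, math.sqrt(sigma2))) if sigma2 > 0 else params.mean_iti_ms
            after_pause = False
        onset = max(onset + iti, last_end + min_gap_ms)

    taps = _ground_truth_from_schedule(clean, schedule, params, rate)
    trace = _finalize_trace(clean, params, rng, recording_id=f"unpaced-seed{seed}")
    return trace, taps


def generate_paced_trace(
    params: PacedGenParams, seed: int
) -> tuple[ForceTrace, MetronomeSchedule, list[GroundTruthTap]]:
    """Simulate metronome-paced tapping with exact ground truth.

    Clicks are spaced exactly ``60000 / tempo_bpm`` ms; each tap onset
    is its click time plus an asynchrony drawn normal(mean, sd) and
    wrapped onto the click cycle (−T/2, T/2].  Taps whose wrapped onset
    would violate the refractory geometry against the previous tap are
    skipped (vanishingly rare at realistic asynchrony spreads).
    """
    rng = np.random.default_rng(seed)
    rate = params.sample_rate_hz
    inter = 60000.0 / params.tempo_bpm
    head_ms = _EDGE_MARGIN_S * 1000.0
    n_samples = int(round((params.duration_s + 2 * _EDGE_MARGIN_S) * rate))
    clean = np.zeros(n_samples)

    n_clicks = int(math.floor(params.duration_s * 1000.0 / inter)) + 1
    clicks = head_ms + inter * np.arange(n_clicks)
    schedule_obj = MetronomeSchedule(tempo_bpm=params.tempo_bpm, click_times_ms=clicks)

    asyn = rng.normal(params.mean_asynchrony_ms, params.asynchrony_sd_ms, size=n_clicks)
    asyn = np.mod(asyn + inter / 2.0, inter) - inter / 2.0  # wrap to (−T/2, T/2]
    onsets = clicks + asyn

    min_gap_ms = 76.0 + params.pulse_rise_ms + params.pulse_fall_ms
    tap_schedule = []
    prev_offset = -np.inf
    for t in onsets:
        if t - prev_offset < min_gap_ms or t < head_ms / 2:
            continue
        tap_schedule.append((float(t), params.peak_force_n, params.dwell_ms, "normal", False))
        prev_offset = t + params.dwell_ms

    # reuse the unpaced pulse geometry/threshold fields
    pulse_params = TapGenParams(
        mean_iti_ms=inter, iti_cv=0.0, peak_force_n=params.peak_force_n,
        dwell_ms=params.dwell_ms, pulse_rise_ms=params.pulse_rise_ms,
        pulse_fall_ms=params.pulse_fall_ms, noise_sd_n=params.noise_sd_n,
        soft_tap_rate=0.0, double_tap_rate=0.0, pause_rate=0.0,
        duration_s=n_samples / rate, sample_rate_hz=rate,
        detection_threshold_n=params.detection_threshold_n,
    )
    taps = _ground_truth_from_schedule(clean, tap_schedule, pulse_params, rate)
    trace = _finalize_trace(clean, pulse_params, rng, recording_id=f"paced-seed{seed}")
    return trace, schedule_obj, taps


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class CohortGenParams:
    """Two-group cohort generator settings.

    Defaults emulate the structure of a 2 × 14 stroke cohort: ages in
    the mid-60s, Barthel around 48, 9HPT completion times log-normal
    around ~57 s, therapy improvements (POST − PRE, negative = faster)
    normal per group, POMS items driven by per-subscale latent means
    with a PRE→POST shift, and faces ratings drifting linearly over the
    twelve rating time points.  Setting both improvement means equal and
    all shifts/trends to zero yields an exact null cohort.
    """

    n_per_group: int = 14
    age_mean: float = 66.0
    age_sd: float = 11.0
    female_prop: float = 0.5
    barthel_mean: float = 48.5
    barthel_sd: float = 13.0
    days_since_stroke_mean: float = 43.0
    days_since_stroke_sd: float = 27.0
    pegboard_pre_mean_s: float = 57.0
    pegboard_pre_sd_s: float = 35.0
    pegboard_improvement_mean_s: Dict[str, float] = field(
        default_factory=lambda: {"together": -8.0, "in_turn": -14.0}
    )
    pegboard_improvement_sd_s: Dict[str, float] = field(
        default_factory=lambda: {"together": 12.0, "in_turn": 12.0}
    )
    poms_baseline: Dict[str, float] = field(
        default_factory=lambda: {
            "depression_anxiety": 2.6, "fatigue": 3.0, "vigor": 2.5, "hostility": 2.2,
        }
    )
    poms_shift: Dict[str, float] = field(
        default_factory=lambda: {
            "depression_anxiety": -0.5, "fatigue": -0.4, "vigor": 0.1, "hostility": -0.25,
        }
    )
    poms_item_sd: float = 1.0
    poms_subject_sd: float = 0.5
    faces_baseline: float = 2.0
    faces_trend: Dict[str, float] = field(
        default_factory=lambda: {"together": 0.12, "in_turn": 0.12}
    )
    faces_sd: float = 1.2
    n_faces: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        for name in ("age_sd", "barthel_sd", "pegboard_pre_sd_s", "poms_item_sd",
                     "poms_subject_sd", "faces_sd", "days_since_stroke_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for d in (self.pegboard_improvement_mean_s, self.pegboard_improvement_sd_s,
                  self.faces_trend):
            if set(d) != set(GROUPS):
                raise ValueError(f"per-group dicts must have exactly the keys {GROUPS}")
        for d in (self.poms_baseline, self.poms_shift):
            if set(d) != set(POMS_SUBSCALES):
                raise ValueError(f"per-subscale dicts need exactly the keys {POMS_SUBSCALES}")
        if any(v < 0 for v in self.pegboard_improvement_sd_s.values()):
            raise ValueError("improvement SDs must be non-negative")

    def null(self) -> "CohortGenParams":
        """Copy with all group-level and PRE→POST effects removed."""
        return CohortGenParams(
            **{
                **{f.name: getattr(self, f.name) for f in dc_fields(self)},
                "pegboard_improvement_mean_s": {g: 0.0 for g in GROUPS},
                "poms_shift": {s: 0.0 for s in POMS_SUBSCALES},
                "faces_trend": {g: 0.0 for g in GROUPS},
            }
        )


@dataclass
class Cohort:
    """Generated patients plus tidy-table exports."""

    patients: list
    params: CohortGenParams

    def pegboard_frame(self) -> pd.DataFrame:
        """Long table: one row per patient × {PRE, POST} with 9HPT time."""
        rows = []
        for p in self.patients:
            for session, t in (("PRE", p.pegboard_pre_s), ("POST", p.pegboard_post_s)):
                rows.append(
                    {"patient_id": p.patient_id, "group": p.group,
                     "session": session, "time_s": t}
                )
        return pd.DataFrame(rows)

    def poms_wide_frame(self) -> pd.DataFrame:
        """Wide table: 35 item columns per patient × {PRE, POST}."""
        rows = []
        for p in self.patients:
            for session, items in (("PRE", p.poms_pre), ("POST", p.poms_post)):
                row = {"patient_id": p.patient_id, "group": p.group, "session": session}
                row.update({f"item_{i + 1}": int(v) for i, v in enumerate(items)})
                rows.append(row)
        return pd.DataFrame(rows)

    def faces_long_frame(self) -> pd.DataFrame:
        """Long table: one row per patient × rating time point."""
        rows = []
        for p in self.patients:
            for tp in FACES_TIMEPOINTS:
                rows.append(
                    {"patient_id": p.patient_id, "group": p.group,
                     "timepoint": tp, "rating": p.faces[tp]}
                )
        return pd.DataFrame(rows)

    def group(self, name: str) -> list:
        return [p for p in self.patients if p.group == name]


def generate_cohort(params: CohortGenParams) -> Cohort:
    """Generate the two-group cohort described by ``params``.

    9HPT PRE times are log-normal (positive, right-skewed, like timed
    motor tasks); POST = PRE + a normal per-group improvement.  POMS
    items are latent-normal ratings rounded and clipped into 1..5 with a
    per-subject random effect shared between PRE and POST (paired
    structure).  Faces ratings follow a per-group linear trend over the
    twelve time points, rounded and clipped onto the ordinal scale.
    """
    rng = np.random.default_rng(params.seed)
    patients = []
    from .clinical import DEFAULT_POMS_MAPPING  # local to avoid cycle at import

    lg_sigma2 = math.log(1.0 + (params.pegboard_pre_sd_s / params.pegboard_pre_mean_s) ** 2)
    lg_mu = math.log(params.pegboard_pre_mean_s) - lg_sigma2 / 2.0

    for group in GROUPS:
        for i in range(params.n_per_group):
            pid = f"{group[:2]}{i + 1:02d}"
            age = float(np.clip(rng.normal(params.age_mean, params.age_sd), 30, 75))
            sex = "F" if rng.random() < params.female_prop else "M"
            barthel = float(np.clip(rng.normal(params.barthel_mean, params.barthel_sd), 0, 100))
            days = float(max(rng.normal(params.days_since_stroke_mean,
                                        params.days_since_stroke_sd), 1.0))
            peg_pre = float(rng.lognormal(lg_mu, math.sqrt(lg_sigma2)))
            improvement = rng.normal(
                params.pegboard_improvement_mean_s[group],
                params.pegboard_improvement_sd_s[group],
            )
            peg_post = float(max(peg_pre + improvement, 1.0))

            subj_effect = rng.normal(0.0, params.poms_subject_sd)
            poms = {}
            for session, shifted in (("PRE", False), ("POST", True)):
                items = np.empty(35, dtype=int)
                for sub in POMS_SUBSCALES:
                    latent = params.poms_baseline[sub] + subj_effect
                    if shifted:
                        latent += params.poms_shift[sub]
                    idx = [j - 1 for j in DEFAULT_POMS_MAPPING[sub]]
                    draws = rng.normal(latent, params.poms_item_sd, size=len(idx))
                    items[idx] = np.clip(np.round(draws), 1, 5).astype(int)
                poms[session] = items

            faces_subj = rng.normal(0.0, 0.6)
            faces = {}
            for t, tp in enumerate(FACES_TIMEPOINTS):
                latent = (params.faces_baseline + faces_subj
                          + params.faces_trend[group] * t
                          + rng.normal(0.0, params.faces_sd))
                faces[tp] = int(np.clip(round(latent), 0, params.n_faces - 1))

            patients.append(
                PatientRecord(
                    patient_id=pid, group=group, age=age, sex=sex,
                    affected_hand="R" if rng.random() < 0.6 else "L",
                    days_since_stroke=days, barthel_pre=barthel,
                    barthel_post=float(np.clip(barthel + rng.normal(21, 8), 0, 100)),
                    pegboard_pre_s=peg_pre, pegboard_post_s=peg_post,
                    poms_pre=poms["PRE"], poms_post=poms["POST"], faces=faces,
                )
            )
    return Cohort(patients=patients, params=params)
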