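"""Clinical outcome scoring: 9HPT, POMS subscales, faces scale.

* Nine-hole pegboard test (9HPT): time to place and remove nine pegs;
  the outcome is POST − PRE completion time in seconds, so a negative
  improvement means faster (better) performance after therapy.
* Profile of Mood States (POMS), 35-item short form: each adjective is
  rated 1 (not at all) … 5 (very strongly); items load onto four
  subscales (depression/anxiety, fatigue, vigor, hostility) scored as
  item sums.  The item→subscale mapping ships as an editable config —
  the default follows the 35-item short-form convention (14 depression/
  anxiety items, 7 each for fatigue, vigor, hostility), which is a
  scoring convention, not a fixed property of the instrument.
* Faces scale: a single ordinal mood rating chosen from a row of face
  drawings; the therapist records a letter code which is mapped to an
  integer with higher = happier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "POMS_SUBSCALES",
    "DEFAULT_POMS_MAPPING",
    "PomsScores",
    "FacesScale",
    "DEFAULT_FACES_SCALE",
    "PatientRecord",
    "pegboard_improvement",
    "score_poms",
]

POMS_SUBSCALES = ("depression_anxiety", "fatigue", "vigor", "hostility")

#: Default item→subscale mapping for the 35-item short form (1-based
#: item numbers).  Editable: pass any complete, non-overlapping mapping.
DEFAULT_POMS_MAPPING: Dict[str, tuple[int, ...]] = {
    "depression_anxiety": tuple(range(1, 15)),  # 14 items
    "fatigue": tuple(range(15, 22)),  # 7 items
    "vigor": tuple(range(22, 29)),  # 7 items
    "hostility": tuple(range(29, 36)),  # 7 items
}


@dataclass(frozen=True)
class PomsScores:
    """POMS subscale sums."""

    depression_anxiety: float
    fatigue: float
    vigor: float
    hostility: float

    def as_dict(self) -> Dict[str, float]:
        return {k: getattr(self, k) for k in POMS_SUBSCALES}


def score_poms(
    items: Sequence[int],
    mapping: Mapping[str, Sequence[int]] = DEFAULT_POMS_MAPPING,
) -> PomsScores:
    """Score 35 item ratings (1–5) into the four subscale sums.

    The mapping must cover items 1..35 exactly once; ratings outside
    1..5 or a mapping gap/overlap raise a validation error.
    """
    ratings = np.asarray(items)
    if ratings.shape != (35,):
        raise ValueError(f"expected exactly 35 item ratings, got {ratings.shape}")
    if not np.all((ratings >= 1) & (ratings <= 5)):
        bad = np.flatnonzero((ratings < 1) | (ratings > 5))[0]
        raise ValueError(f"item {bad + 1} rating {ratings[bad]} outside 1..5")
    if set(mapping) != set(POMS_SUBSCALES):
        raise ValueError(f"mapping must define exactly the subscales {POMS_SUBSCALES}")
    covered = [i for sub in POMS_SUBSCALES for i in mapping[sub]]
    if sorted(covered) != list(range(1, 36)):
        raise ValueError("mapping must cover items 1..35 exactly once (no gaps/overlaps)")
    sums = {
        sub: float(sum(ratings[i - 1] for i in mapping[sub])) for sub in POMS_SUBSCALES
    }
    return PomsScores(**sums)


@dataclass(frozen=True)
class FacesScale:
    """Ordered faces-scale letter codes, saddest first.

    ``to_numeric`` maps a letter to its 0-based ordinal with higher =
    happier; the cardinality is configurable (default 7 faces).
    """

    letters: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "G")

    def __post_init__(self) -> None:
        if len(self.letters) < 2 or len(set(self.letters)) != len(self.letters):
            raise ValueError("faces scale needs >= 2 distinct letter codes")

    def to_numeric(self, letter: str) -> int:
        try:
            return self.letters.index(letter)
        except ValueError:
            raise ValueError(
                f"unknown faces-scale letter {letter!r}; expected one of {self.letters}"
            ) from None

    def to_letter(self, value: int) -> str:
        if not 0 <= value < len(self.letters):
            raise ValueError(f"ordinal {value} outside 0..{len(self.letters) - 1}")
        return self.letters[value]

    @property
    def happiest(self) -> int:
        return len(self.letters) - 1

    @property
    def saddest(self) -> int:
        return 0


DEFAULT_FACES_SCALE = FacesScale()


@dataclass
class PatientRecord:
    """One patient's covariates and outcomes across the study.

    ``faces`` maps a session label (e.g. ``"PRE"``, ``"S1"`` … ``"S10"``,
    ``"POST"``) to an ordinal rating; ``poms_pre``/``poms_post`` hold the
    35 raw item ratings.  Barthel index arrives pre-scored and is carried
    as a covariate only.
    """

    patient_id: str
    group: str  # "together" | "in_turn"
    age: float
    sex: str  # "F" | "M"
    affected_hand: str = ""
    days_since_stroke: float = float("nan")
    barthel_pre: float = float("nan")
    barthel_post: float = float("nan")
    pegboard_pre_s: Optional[float] = None
    pegboard_post_s: Optional[float] = None
    poms_pre: Optional[np.ndarray] = None
    poms_post: Optional[np.ndarray] = None
    faces: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("together", "in_turn"):
            raise ValueError("group must be 'together' or 'in_turn'")
        for t in (self.pegboard_pre_s, self.pegboard_post_s):
            if t is not None and not t > 0:
                raise ValueError("pegboard times must be positive")


def pegboard_improvement(record: PatientRecord) -> float:
    """9HPT improvement: POST − PRE time in seconds (negative = faster
    after therapy).  Missing either time propagates as NaN."""
    if record.pegboard_pre_s is None or record.pegboard_post_s is None:
        return float("nan")
    return record.pegboard_post_s - record.pegboard_pre_s
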