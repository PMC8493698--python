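"""Composite radiological osteoarthritis score for the gleno-humeral joint.

Three established radiological classifications are each mapped to 0-3 points
and summed to a 0-9 composite:

* Kellgren-Lawrence: osteophytes, joint-space narrowing, sclerosis.  A row is
  satisfied when *any* of its criteria is met at the stated severity; the
  sub-score is the highest satisfied row.
* Samilson-Prieto: height of the inferior humeral and/or glenoid exostosis,
  with intervals 0 mm -> 0, (0, 3) mm -> 1, [3, 7] mm -> 2, > 7 mm -> 3.
* Larsen: destructive abnormality ladder (none / definite early / medium to
  severe / mutilating), with erosion contributing at the early and
  medium-severe levels.

The total maps to grades 0 (0 points), I (1-2), II (3-4), III (5-7) and
IV (8-9).  The Outerbridge cartilage morphology field is carried as an
annotation only and never scored (it is a dissection finding, not a
radiological one).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Optional

import pandas as pd

from .errors import ValidationError

__all__ = [
    "Osteophytes",
    "JointSpace",
    "Sclerosis",
    "Erosion",
    "Destruction",
    "RadiologicFeatures",
    "OAScore",
    "kl_points",
    "samilson_points",
    "larsen_points",
    "composite_score",
    "score_to_grade",
    "GRADES",
    "score_table",
]

GRADES = ("0", "I", "II", "III", "IV")


class Osteophytes(IntEnum):
    NONE = 0
    DEFINITE = 1
    MODERATE_MULTIPLE = 2
    LARGE = 3


class JointSpace(IntEnum):
    NORMAL = 0
    POSSIBLE_NARROWING = 1
    DEFINITE_NARROWING = 2
    MARKED_NARROWING = 3


class Sclerosis(IntEnum):
    NONE = 0
    SOME = 1
    SEVERE = 2


class Erosion(IntEnum):
    NONE = 0
    PRESENT = 1
    MEDIUM_SEVERE = 2


class Destruction(IntEnum):
    NONE = 0
    EARLY = 1
    MEDIUM_SEVERE = 2
    MUTILATING = 3


@dataclass(frozen=True)
class RadiologicFeatures:
    """Radiological findings of one shoulder, as scored on 3D-CT."""

    osteophytes: Osteophytes = Osteophytes.NONE
    joint_space: JointSpace = JointSpace.NORMAL
    sclerosis: Sclerosis = Sclerosis.NONE
    exostosis_height_mm: float = 0.0
    glenohumeral_irregularity: bool = False
    erosion: Erosion = Erosion.NONE
    destruction: Destruction = Destruction.NONE
    outerbridge_morphology: Optional[str] = None  # annotation only: I..IV

    def __post_init__(self):
        if self.exostosis_height_mm < 0:
            raise ValidationError("exostosis_height_mm must be >= 0")
        if self.outerbridge_morphology is not None and (
            self.outerbridge_morphology not in ("I", "II", "III", "IV")
        ):
            raise ValidationError("outerbridge_morphology must be one of I..IV")


@dataclass(frozen=True)
class OAScore:
    kl_points: int
    samilson_points: int
    larsen_points: int
    total: int
    grade: str

    def __post_init__(self):
        if self.total != self.kl_points + self.samilson_points + self.larsen_points:
            raise ValidationError("total must equal the sum of the three sub-scores")
        if not 0 <= self.total <= 9:
            raise ValidationError("total must lie in [0, 9]")


def kl_points(features: RadiologicFeatures) -> int:
    """Kellgren-Lawrence sub-score (0-3), any-of row matching."""
    row3 = (
        features.osteophytes >= Osteophytes.LARGE
        or features.joint_space >= JointSpace.MARKED_NARROWING
        or features.sclerosis >= Sclerosis.SEVERE
    )
    row2 = (
        features.osteophytes >= Osteophytes.MODERATE_MULTIPLE
        or features.joint_space >= JointSpace.DEFINITE_NARROWING
        or features.sclerosis >= Sclerosis.SOME
    )
    row1 = (
        features.osteophytes >= Osteophytes.DEFINITE
        or features.joint_space >= JointSpace.POSSIBLE_NARROWING
    )
    if row3:
        return 3
    if row2:
        return 2
    if row1:
        return 1
    return 0


def samilson_points(features: RadiologicFeatures) -> int:
    """Samilson-Prieto sub-score (0-3) from the exostosis height in mm."""
    h = features.exostosis_height_mm
    if h < 0:
        raise ValidationError("exostosis_height_mm must be >= 0")
    if h == 0:
        return 0
    if h < 3:
        return 1
    if h <= 7:
        return 2
    return 3


def larsen_points(features: RadiologicFeatures) -> int:
    """Larsen sub-score (0-3) from destruction severity and erosion."""
    if features.destruction >= Destruction.MUTILATING:
        return 3
    if (
        features.destruction >= Destruction.MEDIUM_SEVERE
        or features.erosion >= Erosion.MEDIUM_SEVERE
    ):
        return 2
    if features.destruction >= Destruction.EARLY or features.erosion >= Erosion.PRESENT:
        return 1
    return 0


def score_to_grade(total: int) -> str:
    """Map a 0-9 composite total to radiological grade 0/I/II/III/IV."""
    if not 0 <= total <= 9:
        raise ValidationError(f"composite total {total} outside [0, 9]")
    if total == 0:
        return "0"
    if total <= 2:
        return "I"
    if total <= 4:
        return "II"
    if total <= 7:
        return "III"
    return "IV"


def composite_score(features: RadiologicFeatures) -> OAScore:
    kl = kl_points(features)
    sam = samilson_points(features)
    lar = larsen_points(features)
    total = kl + sam + lar
    return OAScore(
        kl_points=kl,
        samilson_points=sam,
        larsen_points=lar,
        total=total,
        grade=score_to_grade(total),
    )


def score_table(feature_rows) -> pd.DataFrame:
    """Score an iterable of ``(id, side, RadiologicFeatures)`` into a table."""
    rows = []
    for spec_id, side, feats in feature_rows:
        s = composite_score(feats)
        rows.append(
            {
                "id": spec_id,
                "side": side,
                "kl": s.kl_points,
                "samilson": s.samilson_points,
                "larsen": s.larsen_points,
                "total": s.total,
                "grade": s.grade,
            }
        )
    return pd.DataFrame(rows)
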