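"""Histology and electron-microscopy scoring.

Light-microscopy morphometry uses stereological point counting: a 100-point
grid is overlaid on each of 10 random non-coincident fields per lung and
every point is classified as falling on collapsed parenchyma, normal
parenchyma, or other (non-parenchymal) structures. The per-animal collapse
fraction is the median across fields, reported with the interquartile
range, matching the nonparametric presentation customary for such data.

Ultrastructural (electron-microscopy) damage is graded per image on a
five-point severity scale driven by the fraction of examined tissue showing
changes: 0 = normal parenchyma; 1 = changes in 1-25%; 2 = 26-50%;
3 = 51-75%; 4 = 76-100%. Agreement between two blinded observers is
quantified with unweighted Cohen's kappa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .errors import InsufficientDataError, InvalidArgumentError, UndefinedKappaError

__all__ = [
    "FieldCount",
    "EMGrade",
    "CollapseSummary",
    "collapse_fraction",
    "em_grade_from_fraction",
    "cohens_kappa",
]


@dataclass(frozen=True)
class FieldCount:
    """Point-count tally for one microscopic field."""

    field_id: str
    n_collapsed: int
    n_normal: int
    n_other: int = 0
    n_points: int = 100

    def __post_init__(self) -> None:
        if min(self.n_collapsed, self.n_normal, self.n_other) < 0:
            raise InvalidArgumentError("counts must be non-negative")
        if self.n_collapsed + self.n_normal + self.n_other != self.n_points:
            raise InvalidArgumentError("counts must sum to n_points")

    @property
    def n_parenchyma(self) -> int:
        return self.n_collapsed + self.n_normal


@dataclass(frozen=True)
class EMGrade:
    """One observer's severity grade (0-4) for one electron micrograph."""

    image_id: str
    observer_id: str
    grade: int

    def __post_init__(self) -> None:
        if self.grade not in (0, 1, 2, 3, 4):
            raise InvalidArgumentError("grade must be an integer in 0..4")


@dataclass(frozen=True)
class CollapseSummary:
    """Animal-level collapse statistics across fields (percent)."""

    per_field: np.ndarray
    median: float
    q1: float
    q3: float
    mean: float
    n_fields: int
    n_excluded: int
    denominator: str


def collapse_fraction(
    fields: list[FieldCount], denominator: str = "all_points"
) -> CollapseSummary:
    """Per-animal alveolar collapse percentage from point counts.

    ``denominator`` selects the per-field divisor: ``all_points`` (the
    total grid count) or ``parenchyma_only`` (collapsed + normal points,
    excluding vessels and airways). Fields with a zero denominator are
    excluded with a warning count. The animal value is the median across
    fields, with the IQR; the mean is also carried.
    """
    if denominator not in ("all_points", "parenchyma_only"):
        raise InvalidArgumentError(f"unknown denominator {denominator!r}")
    if not fields:
        raise InsufficientDataError("need at least one field")
    fracs = []
    excluded = 0
    for f in fields:
        d = f.n_points if denominator == "all_points" else f.n_parenchyma
        if d <= 0:
            excluded += 1
            continue
        fracs.append(100.0 * f.n_collapsed / d)
    if not fracs:
        raise InsufficientDataError("all fields excluded (zero denominators)")
    per_field = np.asarray(fracs)
    q1, med, q3 = np.percentile(per_field, [25, 50, 75])
    return CollapseSummary(
        per_field=per_field,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        mean=float(per_field.mean()),
        n_fields=len(fracs),
        n_excluded=excluded,
        denominator=denominator,
    )


def em_grade_from_fraction(fraction_changed: float) -> int:
    """Map percent of tissue showing changes to the 0-4 severity grade.

    Grade 0 requires a fraction that rounds to 0% (normal parenchyma);
    otherwise the bins are (0, 25] -> 1, (25, 50] -> 2, (50, 75] -> 3 and
    (75, 100] -> 4, inclusive on the upper edge.
    """
    if not (0 <= fraction_changed <= 100):
        raise InvalidArgumentError("fraction must lie in [0, 100]")
    pct = round(fraction_changed)
    if pct == 0:
        return 0
    if pct <= 25:
        return 1
    if pct <= 50:
        return 2
    if pct <= 75:
        return 3
    return 4


def cohens_kappa(grades_a, grades_b) -> float:
    """Unweighted Cohen's kappa between two observers' grade lists."""
    a = np.asarray(grades_a)
    b = np.asarray(grades_b)
    if len(a) != len(b):
        raise InvalidArgumentError("grade lists must have equal length")
    if len(a) < 2:
        raise InvalidArgumentError("need at least 2 paired grades")
    n = len(a)
    cats = np.union1d(a, b)
    pa = np.array([(a == c).mean() for c in cats])
    pb = np.array([(b == c).mean() for c in cats])
    p_e = float(pa @ pb)
    if p_e >= 1.0 - 1e-15:
        raise UndefinedKappaError("degenerate marginals: expected agreement is 1")
    return float(cohen_kappa_score(a, b))


def field_counts_to_frame(records: list[tuple[str, str, FieldCount]]) -> pd.DataFrame:
    """Tidy table from (animal_id, lung_side, FieldCount) records."""
    return pd.DataFrame(
        [
            {
                "animal_id": aid,
                "lung_side": side,
                "field_id": f.field_id,
                "n_points": f.n_points,
                "n_collapsed": f.n_collapsed,
                "n_normal": f.n_normal,
                "n_other": f.n_other,
            }
            for aid, side, f in records
        ]
    )
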