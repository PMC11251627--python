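"""Domain types for longitudinal EDSS cohorts.

The Expanded Disability Status Scale (EDSS) is the standard ordinal
disability score for multiple sclerosis.  It runs from 0 (no disability)
to 10 (death from MS) in half-point categories, with the quirk that 0.5
does not exist: the ladder is 0, 1.0, 1.5, 2.0, ..., 9.5, 10.0 — twenty
categories in all.  Trajectory descriptors weight *category steps* on
this ladder, so the ladder index (a bijection onto 0..19) is the unit of
account everywhere downstream, never the raw score difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

#: The twenty EDSS categories, in order.  No 0.5 between 0 and 1.
EDSS_LADDER: tuple[float, ...] = (0.0,) + tuple(
    1.0 + 0.5 * k for k in range(19)
)

_LADDER_INDEX: dict[float, int] = {v: i for i, v in enumerate(EDSS_LADDER)}


class ValidationError(ValueError):
    """Input violates a structural contract (off-ladder score, bad file)."""


class DomainError(ValueError):
    """A computation's preconditions are not met (e.g. too few visits)."""


def ladder_index(score: float) -> int:
    """Ordinal index of an EDSS score on the category ladder.

    ``ladder_index(0) == 0``, ``ladder_index(1.0) == 1``, ...,
    ``ladder_index(10.0) == 19``.  Off-ladder values (such as 0.5, which
    does not exist on the scale) are rejected rather than rounded:
    silent coercion would corrupt the category-step weighting.
    """
    try:
        return _LADDER_INDEX[float(score)]
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(
            f"EDSS value {score!r} is not on the ladder {EDSS_LADDER}"
        ) from exc


def ladder_value(index: int) -> float:
    """Inverse of :func:`ladder_index`."""
    if not 0 <= index < len(EDSS_LADDER):
        raise ValidationError(f"ladder index {index} out of range 0..19")
    return EDSS_LADDER[index]


@dataclass(frozen=True)
class EDSSSeries:
    """A patient's ordered EDSS assessments.

    ``days`` are offsets from the first assessment (so ``days[0] == 0``)
    and strictly increasing; ``scores`` are on-ladder EDSS values.
    """

    days: tuple[float, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.days) != len(self.scores):
            raise ValidationError("days and scores differ in length")
        if len(self.days) == 0:
            raise ValidationError("series must contain at least one assessment")
        if self.days[0] != 0:
            raise ValidationError("first assessment must be at day 0")
        for a, b in zip(self.days, self.days[1:]):
            if b <= a:
                raise ValidationError(f"assessment days not strictly increasing: {a} then {b}")
        for s in self.scores:
            ladder_index(s)

    def __len__(self) -> int:
        return len(self.days)

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(ladder_index(s) for s in self.scores)


def series_from_pairs(pairs) -> EDSSSeries:
    """Build a series from ``[(day, score), ...]`` pairs."""
    days, scores = zip(*pairs)
    return EDSSSeries(tuple(float(d) for d in days), tuple(float(s) for s in scores))


def canonicalize_visits(pairs) -> list[tuple[float, float]]:
    """Sort visits by day and collapse same-day repeats, keeping the
    last-entered value (a warning is logged per collapse)."""
    seen: dict[float, float] = {}
    for day, score in pairs:
        day = float(day)
        if day in seen and seen[day] != float(score):
            logger.warning(
                "duplicate assessment at day %s: keeping last-entered value %s", day, score
            )
        seen[day] = float(score)
    return sorted(seen.items())


def follow_up_days(series: EDSSSeries) -> float:
    """Days between the first and last assessment (0 for a single visit)."""
    if len(series) == 0:  # unreachable through the constructor; belt and braces
        raise DomainError("empty series has no follow-up")
    return series.days[-1] - series.days[0]


@dataclass(frozen=True)
class PatientRecord:
    id: str
    sex: str  # "female" | "male"
    age_at_onset: float  # years
    features: dict[str, object]  # baseline-MRI-derived; None marks missing
    series: EDSSSeries
    has_baseline_mri: bool = True

    def __post_init__(self) -> None:
        if self.age_at_onset <= 0:
            raise ValidationError(f"age_at_onset must be positive, got {self.age_at_onset}")
        if self.sex not in ("female", "male"):
            raise ValidationError(f"sex must be 'female' or 'male', got {self.sex!r}")


@dataclass(frozen=True)
class Cohort:
    """A set of patients plus the declared baseline-feature schema.

    ``feature_schema`` maps feature name -> type ("numeric" or
    "categorical"); every patient's feature map is aligned to it on
    construction, with absent entries filled by ``None`` (the explicit
    missing marker)."""

    patients: tuple[PatientRecord, ...]
    feature_schema: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in self.feature_schema.values():
            if t not in ("numeric", "categorical"):
                raise ValidationError(f"unknown feature type {t!r}")
        aligned = []
        for p in self.patients:
            feats = {name: p.features.get(name) for name in self.feature_schema}
            aligned.append(replace(p, features=feats))
        object.__setattr__(self, "patients", tuple(aligned))

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)


#: Exclusion reasons, in reporting priority order (first matching wins).
REASON_TOO_FEW = "fewer than two EDSS evaluations"
REASON_SHORT_FOLLOW_UP = "follow-up < 1 year"
REASON_NO_MRI = "no baseline MRI"


@dataclass
class ExclusionReport:
    n_input: int
    n_retained: int
    counts: dict[str, int]

    @property
    def n_excluded(self) -> int:
        return sum(self.counts.values())


def apply_inclusion_criteria(
    cohort: Cohort,
    min_follow_up_days: float = 365.0,
    min_assessments: int = 2,
) -> tuple[Cohort, ExclusionReport]:
    """Apply the study inclusion filters.

    A patient is retained when they have at least ``min_assessments``
    EDSS evaluations, at least ``min_follow_up_days`` between first and
    last assessment, and an associated baseline MRI.  Exclusions are
    counted by the first matching reason.
    """
    retained: list[PatientRecord] = []
    counts = {REASON_TOO_FEW: 0, REASON_SHORT_FOLLOW_UP: 0, REASON_NO_MRI: 0}
    for p in cohort.patients:
        if len(p.series) < min_assessments:
            counts[REASON_TOO_FEW] += 1
        elif follow_up_days(p.series) < min_follow_up_days:
            counts[REASON_SHORT_FOLLOW_UP] += 1
        elif not p.has_baseline_mri:
            counts[REASON_NO_MRI] += 1
        else:
            retained.append(p)
    report = ExclusionReport(len(cohort), len(retained), counts)
    return Cohort(tuple(retained), dict(cohort.feature_schema)), report
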