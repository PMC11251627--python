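"""Trajectory descriptors for ordinal EDSS series.

Three descriptors summarize a patient's disability trajectory:

* ``beta1`` — the end-to-end "slope": the weighted category change
  between the first and last assessment divided by the days between
  them.  Intermediate visits are ignored by construction.
* ``beta2`` — a cumulative descriptor: for each consecutive pair of
  assessments, the weighted per-segment rate of change multiplied by the
  time remaining until the final assessment, summed over segments.  It
  reflects how early in the follow-up changes occur (an early change is
  amplified by the long remaining horizon).
* ``EDSS(t)`` — the categorical value at fixed horizons 0, 1, 2, 5 and
  10 years, with a three-month tolerance window and a stability
  imputation rule for horizons falling between two equal assessments.

Score changes are weighted by 0.5 per *category step* on the EDSS
ladder, increasing or decreasing alike, so moving 2.0 -> 3.0 (two
half-point categories) counts +1.0 and 1.5 -> 0 (two categories, since
0.5 does not exist) counts -1.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    Cohort,
    DomainError,
    EDSSSeries,
    ladder_index,
)

#: Prediction horizons, in years.
DEFAULT_HORIZONS: tuple[int, ...] = (0, 1, 2, 5, 10)
#: Three-month matching window around each horizon, in days.
DEFAULT_WINDOW_DAYS: float = 90.0
DAYS_PER_YEAR: float = 365.0


def weighted_delta(a: float, b: float, convention: str = "category_steps") -> float:
    """Signed weighted change from score ``a`` to score ``b``.

    With the default ``category_steps`` convention the change is 0.5 per
    ladder category crossed (sign preserved); the ``raw_score``
    alternative returns the plain score difference ``b - a``.
    """
    if convention == "category_steps":
        return 0.5 * (ladder_index(b) - ladder_index(a))
    if convention == "raw_score":
        ladder_index(a), ladder_index(b)  # still validate
        return float(b) - float(a)
    raise ValueError(f"unknown delta convention {convention!r}")


def _require_two_points(series: EDSSSeries) -> None:
    if len(series) < 2:
        raise DomainError("descriptor needs at least two assessments")
    if series.days[-1] <= series.days[0]:
        raise DomainError("zero time span between first and last assessment")


def beta1(series: EDSSSeries, convention: str = "category_steps") -> float:
    """End-to-end weighted slope, in category-step units per day."""
    _require_two_points(series)
    delta = weighted_delta(series.scores[0], series.scores[-1], convention)
    return delta / (series.days[-1] - series.days[0])


def beta2(series: EDSSSeries, convention: str = "category_steps") -> float:
    """Cumulative early-weighted change, in category-step units.

    Each consecutive-pair rate ``w(s_{i-1}, s_i) / (T_i - T_{i-1})`` is
    multiplied by the time remaining to the last assessment,
    ``T_n - T_{i-1}``, and the products are summed.  For a two-point
    series the time factors cancel and beta2 equals the weighted total
    change exactly.
    """
    _require_two_points(series)
    t = series.days
    s = series.scores
    t_n = t[-1]
    total = 0.0
    for i in range(1, len(t)):
        # delta * (remaining / segment): associativity chosen so the
        # single-segment case reduces to the weighted delta *exactly*
        # (the time ratio is then bitwise 1.0)
        delta = weighted_delta(s[i - 1], s[i], convention)
        total += delta * ((t_n - t[i - 1]) / (t[i] - t[i - 1]))
    return total


def edss_at_timepoints(
    series: EDSSSeries,
    horizons: tuple[int, ...] = DEFAULT_HORIZONS,
    window: float = DEFAULT_WINDOW_DAYS,
) -> dict[int, float | None]:
    """EDSS value at each horizon (years), or ``None`` when undecidable.

    Horizon 0 always returns the first assessment.  Otherwise, in order:

    a. if any assessment lies within ``window`` days of the horizon, the
       nearest one is returned (ties resolve to the earlier visit);
    b. else, if the horizon is bracketed by a previous and a subsequent
       assessment carrying the *same* score, that shared score is
       returned — the stability assumption that a value matching its
       neighbours remained unchanged in between;
    c. else the horizon is missing.
    """
    out: dict[int, float | None] = {}
    days = np.asarray(series.days)
    scores = series.scores
    for h in horizons:
        if h == 0:
            out[h] = scores[0]
            continue
        target = round(h * DAYS_PER_YEAR)
        dist = np.abs(days - target)
        j = int(np.argmin(dist))  # argmin returns the first (earlier) tie
        if dist[j] <= window:
            out[h] = scores[j]
            continue
        before = np.nonzero(days < target)[0]
        after = np.nonzero(days > target)[0]
        if before.size and after.size and scores[before[-1]] == scores[after[0]]:
            out[h] = scores[before[-1]]
        else:
            out[h] = None
    return out


@dataclass(frozen=True)
class TrajectoryDescriptors:
    beta1: float
    beta2: float
    edss_t: dict[int, float | None]


def describe(series: EDSSSeries, convention: str = "category_steps",
             horizons: tuple[int, ...] = DEFAULT_HORIZONS,
             window: float = DEFAULT_WINDOW_DAYS) -> TrajectoryDescriptors:
    return TrajectoryDescriptors(
        beta1=beta1(series, convention),
        beta2=beta2(series, convention),
        edss_t=edss_at_timepoints(series, horizons, window),
    )


def compute_all(
    cohort: Cohort,
    convention: str = "category_steps",
    horizons: tuple[int, ...] = DEFAULT_HORIZONS,
    window: float = DEFAULT_WINDOW_DAYS,
) -> pd.DataFrame:
    """Descriptor table for a cohort, one row per patient.

    Columns: ``patient_id, beta1, beta2, edss_0, edss_1, ..., error``.
    Missing horizon values are NaN.  Per-patient domain errors (e.g. a
    single-assessment series that slipped past filtering) are recorded
    in the ``error`` column rather than aborting the run.
    """
    rows = []
    for p in cohort:
        row: dict[str, object] = {"patient_id": p.id, "error": ""}
        try:
            d = describe(p.series, convention, horizons, window)
            row["beta1"] = d.beta1
            row["beta2"] = d.beta2
            for h in horizons:
                row[f"edss_{h}"] = np.nan if d.edss_t[h] is None else d.edss_t[h]
        except DomainError as exc:
            row["beta1"] = np.nan
            row["beta2"] = np.nan
            for h in horizons:
                row[f"edss_{h}"] = np.nan
            row["error"] = str(exc)
        rows.append(row)
    cols = ["patient_id", "beta1", "beta2"] + [f"edss_{h}" for h in horizons] + ["error"]
    return pd.DataFrame(rows, columns=cols)


#: Categories at or above this score are pooled in count/classification views.
POOL_AT_OR_ABOVE: float = 6.0


def pool_category(score: float) -> str:
    """Display/class label for a score, pooling >=6 into one category."""
    if score >= POOL_AT_OR_ABOVE:
        return ">=6"
    return f"{score:g}"


def edss_count_matrix(desc: pd.DataFrame,
                      horizons: tuple[int, ...] = DEFAULT_HORIZONS) -> pd.DataFrame:
    """Patients-per-category count matrix across horizons.

    Rows are ``EDSS(h)`` horizons, columns the EDSS categories with
    everything >=6 pooled into a single ``>=6`` column; entries count
    patients with a non-missing value at that horizon.
    """
    below = [v for v in (0.0, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5)
             ]
    columns = [f"{v:g}" for v in below] + [">=6"]
    mat = pd.DataFrame(0, index=[f"EDSS({h})" for h in horizons], columns=columns)
    for h in horizons:
        vals = desc[f"edss_{h}"].dropna()
        for v in vals:
            mat.loc[f"EDSS({h})", pool_category(float(v))] += 1
    return mat
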