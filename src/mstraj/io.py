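"""CSV/JSON ingestion and serialization of cohorts.

On-disk layout (UTF-8, comma-separated, header row required):

* ``visits.csv`` — long format: ``patient_id`` plus either ``day``
  (integer offset) or ``date`` (ISO-8601), and ``edss``.
* ``baseline.csv`` — wide format: ``patient_id, sex, age_at_onset``,
  optional ``has_baseline_mri`` (0/1), then one column per baseline
  feature.  Empty cells are explicit missing values.
* ``schema.json`` — sidecar mapping feature name -> "numeric" |
  "categorical".  Without it every extra baseline column is treated as
  numeric.

Calendar dates are converted to day offsets anchored at each patient's
first assessment; same-day repeats keep the last-entered value (with a
warning).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .cohort import (
    Cohort,
    EDSSSeries,
    PatientRecord,
    ValidationError,
    canonicalize_visits,
)

RESERVED_BASELINE = {"patient_id", "sex", "age_at_onset", "has_baseline_mri"}


def _require_columns(df: pd.DataFrame, cols: set[str], path) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {sorted(missing)}")


def read_cohort(visits_path, baseline_path, schema_path=None) -> Cohort:
    """Parse and validate a cohort from its CSV pair (+ optional schema)."""
    visits = pd.read_csv(visits_path)
    baseline = pd.read_csv(baseline_path)
    _require_columns(visits, {"patient_id", "edss"}, visits_path)
    if "day" not in visits.columns and "date" not in visits.columns:
        raise ValidationError(f"{visits_path}: need a 'day' or 'date' column")
    _require_columns(baseline, {"patient_id", "sex", "age_at_onset"}, baseline_path)

    if schema_path is not None:
        schema = {str(k): str(v) for k, v in json.loads(Path(schema_path).read_text()).items()}
    else:
        schema = {c: "numeric" for c in baseline.columns if c not in RESERVED_BASELINE}

    known = set(baseline["patient_id"].astype(str))
    orphans = sorted(set(visits["patient_id"].astype(str)) - known)
    if orphans:
        raise ValidationError(
            f"patients present in visits but not in baseline: {orphans}")

    baseline = baseline.set_index(baseline["patient_id"].astype(str))
    patients = []
    for pid, grp in visits.groupby(visits["patient_id"].astype(str), sort=True):
        if "day" in grp.columns and grp["day"].notna().all():
            pairs = list(zip(grp["day"].astype(float), grp["edss"].astype(float)))
        else:
            dates = pd.to_datetime(grp["date"])
            t0 = dates.min()
            pairs = list(zip((dates - t0).dt.days.astype(float), grp["edss"].astype(float)))
        pairs = canonicalize_visits(pairs)
        t0 = pairs[0][0]
        pairs = [(d - t0, s) for d, s in pairs]
        series = EDSSSeries(tuple(d for d, _ in pairs), tuple(s for _, s in pairs))
        row = baseline.loc[pid]
        features = {}
        for name in schema:
            if name not in baseline.columns:
                features[name] = None
                continue
            v = row[name]
            features[name] = None if pd.isna(v) else (
                float(v) if schema[name] == "numeric" else v)
        has_mri = True
        if "has_baseline_mri" in baseline.columns:
            has_mri = bool(int(row["has_baseline_mri"]))
        patients.append(PatientRecord(
            id=pid, sex=str(row["sex"]), age_at_onset=float(row["age_at_onset"]),
            features=features, series=series, has_baseline_mri=has_mri))
    return Cohort(tuple(patients), schema)


def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    """Write ``visits.csv``, ``baseline.csv`` and ``schema.json``;
    returns the paths.  Round-trips through :func:`read_cohort`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    visit_rows = []
    base_rows = []
    for p in cohort:
        for d, s in zip(p.series.days, p.series.scores):
            visit_rows.append({"patient_id": p.id, "day": d, "edss": s})
        row = {"patient_id": p.id, "sex": p.sex, "age_at_onset": p.age_at_onset,
               "has_baseline_mri": int(p.has_baseline_mri)}
        row.update(p.features)
        base_rows.append(row)
    paths = {
        "visits": str(outdir / "visits.csv"),
        "baseline": str(outdir / "baseline.csv"),
        "schema": str(outdir / "schema.json"),
    }
    pd.DataFrame(visit_rows).to_csv(paths["visits"], index=False)
    pd.DataFrame(base_rows).to_csv(paths["baseline"], index=False)
    Path(paths["schema"]).write_text(json.dumps(cohort.feature_schema, indent=1))
    return paths
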