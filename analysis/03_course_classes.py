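#!/usr/bin/env python
"""Label disease-course severity and fit beta1 thresholds.

Applies the consensus criteria (mild: EDSS <= 3.0 after >= 10 years;
aggressive: EDSS >= 6.0 within 10 years) to every included patient,
then derives the two beta1 cut points that best separate the groups,
turning the continuous slope descriptor into a course classifier.
"""

import argparse
import json
import sys
from pathlib import Path

import pandas as pd

from mstraj.classes import INELIGIBLE, criteria_label, fit_beta1_thresholds
from mstraj.cohort import apply_inclusion_criteria
from mstraj.descriptors import describe
from mstraj.io import read_cohort


def main(argv=None):
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/classes"))
    args = ap.parse_args(argv)

    cohort = read_cohort(args.cohort / "visits.csv", args.cohort / "baseline.csv",
                         args.cohort / "schema.json")
    cohort, _ = apply_inclusion_criteria(cohort)

    rows = []
    for p in cohort:
        d = describe(p.series)
        lab = criteria_label(p.series, d)
        rows.append({"patient_id": p.id, "label": lab.label,
                     "basis": lab.basis, "beta1": d.beta1})
    df = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out / "labels.csv", index=False)
    print("label counts:", dict(df["label"].value_counts()))

    decided = df[df["label"] != INELIGIBLE]
    thr = fit_beta1_thresholds(decided["beta1"], decided["label"])
    (args.out / "beta1_thresholds.json").write_text(
        json.dumps({"lower": thr.lower, "upper": thr.upper}, indent=1))
    agreement = (decided["beta1"].map(thr.classify) == decided["label"]).mean()
    print(f"beta1 thresholds: lower {thr.lower:.3e}, upper {thr.upper:.3e}; "
          f"threshold-classifier agreement with criteria labels: {agreement:.3f}")
    print(f"outputs -> {args.out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
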