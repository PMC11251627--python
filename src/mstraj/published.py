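"""Reference values from the clinical registry study this pipeline was
designed around (446-patient Galician MS cohort; data not public).

These numbers are inputs for context and sanity arithmetic — e.g.
expressing a model's MAE as a percentage of the descriptor's spread —
not quantities this package can recompute, since the underlying cohort
is unavailable.
"""

from __future__ import annotations

#: Cohort-wide descriptor moments reported by the reference study.
BETA1_MEAN = 0.02
BETA1_SD = 1.23
BETA2_MEAN = -1.47
BETA2_SD = 12.76

#: Test-set MAE of the three regressors in the reference study.
REPORTED_MAE = {
    "linear_regression": {"beta1": 0.25, "beta2": 7.22},
    "xgboost_default": {"beta1": 0.19, "beta2": 6.87},
    "xgboost_tuned": {"beta1": 0.11, "beta2": 5.18},
}


def mae_percent_of_sd(mae: float, sd: float) -> float:
    """A regression error expressed as a percentage of the target's
    standard deviation — the scale-free way the reference study
    summarizes its regressors (e.g. the tuned beta2 model: 40.60%)."""
    if sd <= 0:
        raise ValueError("standard deviation must be positive")
    return 100.0 * mae / sd
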