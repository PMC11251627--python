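"""Synthetic MS cohort generator.

The clinical registry the analysis was designed around (446 patients,
irregular EDSS assessments over 1-30+ years) is not publicly available,
so this module generates cohorts with the same statistical skeleton:

* a latent severity group (mild / average / aggressive) whose odds are
  tilted by one designated *causal* baseline-MRI feature, giving an
  exact known odds-ratio link for generator self-checks;
* a monotone latent disability drift (category steps/year) whose rate
  increases with age at onset, plus transient relapse excursions and
  per-visit observation noise on top;
* baseline EDSS concentrated below 4.0, driven by non-additive
  lesion-pattern burden; visits from a Poisson process over a uniformly
  drawn follow-up, 2-40 assessments per patient;
* a panel of nuisance MRI features drawn independently of the severity
  group, so explanation tests have an unambiguous planted signal to
  recover (one designated causal feature).

Monotone drift plus additive transients is a deliberate simplification
of MS natural history: it is sufficient to make the trajectory
descriptors informative and recoverable, not a disease model.

Two independent random streams are used — one for cohort *structure*
(groups, drifts, baselines, visit schedules), one for *noise* (nuisance
features, relapses, observation jitter) — so that changing the noise
seed never changes the ground-truth labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    Cohort,
    EDSSSeries,
    PatientRecord,
    ladder_value,
)
from .descriptors import DAYS_PER_YEAR

CAUSAL_FEATURE = "Nb lesions/Brain (> = 9)"

#: Nuisance baseline-MRI features: name -> (kind, parameter).
#: All are drawn independently of the severity group; a few contribute
#: to the *baseline* disability level (see generate_cohort), the rest
#: are pure distractors for the explanation tests.
NUISANCE_FEATURES: dict[str, tuple[str, float]] = {
    "Nb lesions/Spinal cord (> = 3)": ("binary", 0.30),
    "Gd-enhancing lesions": ("binary", 0.25),
    "Infratentorial lesions": ("binary", 0.40),
    "Juxtacortical lesions": ("binary", 0.45),
    "Periventricular lesions": ("binary", 0.60),
    "Lesion volume (ml)": ("lognormal", 1.0),
    "Brainstem lesions": ("binary", 0.30),
    "Cerebellar lesions": ("binary", 0.25),
    "Corpus callosum lesions": ("binary", 0.40),
    "Black holes (T1)": ("binary", 0.35),
    "Diffuse atrophy": ("binary", 0.15),
    "Optic nerve lesion": ("binary", 0.20),
    "Cervical cord lesion": ("binary", 0.25),
    "Dorsal cord lesion": ("binary", 0.20),
    "Symptomatic lesion enhancement": ("binary", 0.15),
    "Temporal horn enlargement": ("binary", 0.10),
    "Nb Barkhof criteria": ("count4", 2.0),
}

GROUPS = ("mild", "average", "aggressive")

#: Latent drift means per group, in category steps / year.
GROUP_DRIFT_MEANS = {"mild": 0.05, "average": 0.35, "aggressive": 1.3}


@dataclass(frozen=True)
class SynthConfig:
    """Generator knobs; defaults emulate the study cohort's structure."""

    n_patients: int = 446
    seed: int = 0
    group_weights: dict[str, float] = field(
        default_factory=lambda: {"mild": 0.45, "average": 0.42, "aggressive": 0.13}
    )
    #: log odds-ratio linking the causal feature to the aggressive group
    feature_effect: float = 2.0
    #: prevalence of the causal binary feature
    causal_prevalence: float = 0.30
    #: multiplicative effect of age at onset on drift and on the
    #: average-vs-mild group odds (per SD of age at onset)
    age_effect: float = 0.8
    visit_rate: float = 1.5  # mean assessments / year
    follow_up_range: tuple[float, float] = (1.0, 30.0)  # years
    relapse_rate: float = 0.2  # transient events / year
    relapse_magnitude: int = 2  # category steps at onset of the excursion
    noise_prob: float = 0.1  # per-visit +-1 category jitter probability
    max_assessments: int = 40
    #: separate stream for nuisance features / relapses / jitter;
    #: derived from ``seed`` when None
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        total = sum(self.group_weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"group_weights must sum to 1, got {total}")
        for name, rate in [("visit_rate", self.visit_rate),
                           ("relapse_rate", self.relapse_rate)]:
            if rate < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.noise_prob <= 1:
            raise ValueError("noise_prob must be a probability")


@dataclass(frozen=True)
class GroundTruth:
    """Per-patient latent state the generator committed to."""

    table: pd.DataFrame  # patient_id, group, drift (steps/year)
    causal_feature: str = CAUSAL_FEATURE


def _draw_group(rng: np.random.Generator, cfg: SynthConfig, causal: int,
                z_age: float = 0.0) -> str:
    """Group draw: the causal feature multiplies the aggressive odds by
    exp(feature_effect); age tilts the average-vs-mild odds (older onset
    progresses faster) without touching the aggressive share, so the
    feature->aggressive odds ratio stays exactly exp(feature_effect)."""
    w = np.array([cfg.group_weights[g] for g in GROUPS], dtype=float)
    if causal:
        w[GROUPS.index("aggressive")] *= math.exp(cfg.feature_effect)
    mild_avg = w[GROUPS.index("mild")] + w[GROUPS.index("average")]
    tilt = math.exp(cfg.age_effect * z_age)
    m = w[GROUPS.index("mild")]
    a = w[GROUPS.index("average")] * tilt
    scale = mild_avg / (m + a)
    w[GROUPS.index("mild")] = m * scale
    w[GROUPS.index("average")] = a * scale
    w /= w.sum()
    return GROUPS[rng.choice(len(GROUPS), p=w)]


def _visit_days(rng: np.random.Generator, cfg: SynthConfig, follow_up_years: float) -> list[float]:
    t_end = follow_up_years * DAYS_PER_YEAR
    days = [0.0]
    if cfg.visit_rate > 0:
        t = 0.0
        mean_gap = DAYS_PER_YEAR / cfg.visit_rate
        while True:
            t += rng.exponential(mean_gap)
            if t >= t_end - 1:
                break
            days.append(round(t))
    days.append(round(t_end))
    # de-duplicate after rounding, keep 2..max_assessments visits
    days = sorted(set(days))
    if len(days) > cfg.max_assessments:
        days = days[: cfg.max_assessments - 1] + [days[-1]]
    return days


def generate_cohort(config: SynthConfig) -> tuple[Cohort, GroundTruth]:
    """Draw a cohort and its ground truth, deterministically per seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)  # structure stream
    noise_seed = cfg.noise_seed if cfg.noise_seed is not None else cfg.seed + 1_000_003
    nrng = np.random.default_rng(noise_seed)  # noise stream

    def _baseline_burden(causal: int, f: dict[str, object]) -> float:
        """Baseline disability driven by lesion *patterns*: isolated
        findings contribute little, co-occurring findings compound.
        The non-additive structure is deliberate — it is the planted
        signal that separates interaction-capable learners from purely
        additive ones."""
        b = lambda name: float(bool(f[name]))  # noqa: E731
        return (
            2.0 * causal
            + 1.5 * causal * b("Periventricular lesions")
            + 1.2 * (float(f["Lesion volume (ml)"]) > 4.5)
            + 1.0 * b("Infratentorial lesions") * b("Brainstem lesions")
            + 1.0 * b("Periventricular lesions") * b("Black holes (T1)")
            + 0.8 * b("Juxtacortical lesions") * b("Corpus callosum lesions")
            + 0.5 * b("Gd-enhancing lesions")
            + 0.4 * b("Nb lesions/Spinal cord (> = 3)")
        )

    patients: list[PatientRecord] = []
    truth_rows = []
    for k in range(cfg.n_patients):
        pid = f"P{k:05d}"
        causal = int(rng.random() < cfg.causal_prevalence)
        age = float(np.round(np.clip(rng.normal(30.0, 8.0), 15.0, 60.0), 1))
        z_age = (age - 30.0) / 8.0
        group = _draw_group(rng, cfg, causal, z_age)

        # nuisance baseline-MRI findings: independent of the *group*
        # (noise stream), but not of baseline disability or of drift
        # within group — lesion burden correlates with how disabled a
        # patient presents and spinal involvement compounds focal load
        nuisance: dict[str, object] = {}
        for name, (kind, param) in NUISANCE_FEATURES.items():
            if kind == "binary":
                nuisance[name] = float(nrng.random() < param)
            elif kind == "count4":
                nuisance[name] = float(min(4, nrng.poisson(param)))
            else:
                nuisance[name] = float(np.round(nrng.lognormal(param, 0.6), 2))
        spinal = int(bool(nuisance["Nb lesions/Spinal cord (> = 3)"]))

        drift = (
            GROUP_DRIFT_MEANS[group]
            * math.exp(cfg.age_effect * z_age)
            * math.exp(0.5 * causal * spinal)  # non-additive worsening
            * (0.6 if age < 20.0 else 1.0)  # pediatric onset progresses slower
            * math.exp(rng.normal(0.0, 0.2))
        )

        # baseline EDSS index: right-skewed, concentrated well below
        # EDSS 4, driven by the observed lesion-pattern burden plus a
        # small unexplained remainder
        burden = _baseline_burden(causal, nuisance)
        baseline_idx = min(19, int(burden + rng.gamma(1.0, 0.6)))
        follow_up = rng.uniform(*cfg.follow_up_range)
        days = _visit_days(rng, cfg, follow_up)

        # latent monotone path
        idx_path = [
            min(19, baseline_idx + round(drift * d / DAYS_PER_YEAR)) for d in days
        ]

        # transient relapse excursions (noise stream)
        if cfg.relapse_rate > 0:
            n_events = nrng.poisson(cfg.relapse_rate * follow_up)
            events = np.sort(nrng.uniform(0.0, days[-1], size=n_events))
        else:
            events = np.array([])
        observed = []
        for d, base in zip(days, idx_path):
            lift = 0
            for ev in events:
                gap = d - ev
                if 0 <= gap < 90:
                    lift = max(lift, round(cfg.relapse_magnitude * (1 - gap / 90)))
            val = min(19, base + lift)
            if cfg.noise_prob > 0 and nrng.random() < cfg.noise_prob:
                val = int(np.clip(val + nrng.choice((-1, 1)), 0, 19))
            observed.append(val)

        features: dict[str, object] = {CAUSAL_FEATURE: float(causal)}
        features.update(nuisance)
        sex = "female" if nrng.random() < 0.7 else "male"

        series = EDSSSeries(
            tuple(float(d) for d in days),
            tuple(ladder_value(i) for i in observed),
        )
        patients.append(
            PatientRecord(
                id=pid, sex=sex, age_at_onset=age, features=features,
                series=series, has_baseline_mri=True,
            )
        )
        truth_rows.append({"patient_id": pid, "group": group, "drift": drift})

    schema = {CAUSAL_FEATURE: "numeric"}
    schema.update({name: "numeric" for name in NUISANCE_FEATURES})
    cohort = Cohort(tuple(patients), schema)
    truth = GroundTruth(pd.DataFrame(truth_rows))
    return cohort, truth


def cohort_summary(cohort: Cohort) -> dict[str, pd.Series]:
    """Descriptive views: visit counts per EDSS category, follow-up-year
    histogram, and assessments-per-patient histogram."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    score_counts: dict[float, int] = {}
    fu_years = []
    n_visits = []
    for p in cohort:
        for s in p.series.scores:
            score_counts[s] = score_counts.get(s, 0) + 1
        fu_years.append((p.series.days[-1] - p.series.days[0]) / DAYS_PER_YEAR)
        n_visits.append(len(p.series))
    edss = pd.Series(score_counts).sort_index()
    edss.index.name = "edss"
    fu = pd.cut(pd.Series(fu_years), bins=range(0, 36, 5)).value_counts().sort_index()
    visits = pd.cut(pd.Series(n_visits), bins=[0, 2, 5, 10, 20, 40]).value_counts().sort_index()
    return {
        "edss_category_counts": edss,
        "follow_up_years": fu,
        "assessments_per_patient": visits,
    }


def fraction_below(cohort: Cohort, threshold: float = 4.0) -> float:
    """Fraction of all visit scores strictly below ``threshold``."""
    counts = cohort_summary(cohort)["edss_category_counts"]
    total = counts.sum()
    return float(counts[counts.index < threshold].sum() / total)


def empirical_odds_ratio(cohort: Cohort, truth: GroundTruth,
                         feature: str = CAUSAL_FEATURE) -> float:
    """Empirical odds ratio of the causal feature vs the aggressive
    ground-truth label (generator self-check against exp(feature_effect))."""
    x = np.array([int(bool(p.features[feature])) for p in cohort])
    y = (truth.table["group"] == "aggressive").to_numpy()
    a = np.sum(x & y) + 0.5  # Haldane correction for rare zero cells
    b = np.sum(x & ~y) + 0.5
    c = np.sum(~x.astype(bool) & y) + 0.5
    d = np.sum(~x.astype(bool) & ~y) + 0.5
    return float((a * d) / (b * c))
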