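"""Trajectory descriptors: examples, algebraic identities, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mstraj.cohort import DomainError, ladder_value, series_from_pairs
from mstraj.descriptors import (
    beta1,
    beta2,
    compute_all,
    edss_at_timepoints,
    edss_count_matrix,
    weighted_delta,
)
from mstraj.synth import SynthConfig, generate_cohort

from conftest import random_ladder_walk


# ---------------------------------------------------------------- oracles

def oracle_beta1(days, scores):
    """Two-endpoint definition, written out independently."""
    d = 0.5 * (ladder_idx(scores[-1]) - ladder_idx(scores[0]))
    return d / (days[-1] - days[0])


def oracle_beta2(days, scores):
    """Literal transliteration of the expanded summation: for each
    consecutive pair, (weighted change / segment days) * (days remaining
    to the final assessment)."""
    n = len(days)
    total = 0.0
    for i in range(1, n):
        delta_i = 0.5 * (ladder_idx(scores[i]) - ladder_idx(scores[i - 1]))
        dt_i = days[i] - days[i - 1]
        total += (delta_i / dt_i) * (days[-1] - days[i - 1])
    return total


_LADDER = [0.0] + [1.0 + 0.5 * k for k in range(19)]


def ladder_idx(score):
    return _LADDER.index(score)


# ---------------------------------------------------------- weighted delta

class TestWeightedDelta:
    @pytest.mark.parametrize("a,b,expected", [
        (2.0, 2.0, 0.0),
        (2.0, 3.0, +1.0),   # two category steps up, 0.5 each
        (1.5, 0.0, -1.0),   # 1.5 -> 1.0 -> 0: two steps down
        (0.0, 1.0, +0.5),   # a single category despite the 1.0 score jump
        (0.0, 10.0, +9.5),  # full ladder: 19 steps
    ])
    def test_category_steps_convention(self, a, b, expected):
        assert weighted_delta(a, b) == expected

    def test_raw_score_convention_switch(self):
        assert weighted_delta(2.0, 3.0, convention="raw_score") == 1.0
        assert weighted_delta(0.0, 1.0, convention="raw_score") == 1.0

    def test_antisymmetry(self, rng):
        for _ in range(50):
            a, b = ladder_value(rng.integers(0, 20)), ladder_value(rng.integers(0, 20))
            assert weighted_delta(a, b) == -weighted_delta(b, a)

    def test_off_ladder_rejected(self):
        with pytest.raises(ValueError):
            weighted_delta(0.5, 2.0)


# ------------------------------------------------------------------ beta1

class TestBeta1:
    def test_constant_series_is_zero(self):
        assert beta1(series_from_pairs([(0, 2.0), (400, 2.0)])) == 0.0

    def test_single_step_slope(self):
        assert beta1(series_from_pairs([(0, 2.0), (400, 3.0)])) == pytest.approx(0.0025)

    def test_intermediate_points_ignored(self):
        s = series_from_pairs([(0, 3.0), (200, 2.5), (500, 2.0)])
        assert beta1(s) == pytest.approx(-1.0 / 500)

    def test_too_few_assessments(self):
        with pytest.raises(DomainError):
            beta1(series_from_pairs([(0, 2.0)]))

    def test_time_scaling_inverse(self, rng):
        for _ in range(20):
            s = random_ladder_walk(rng)
            scaled = series_from_pairs(
                [(d * 3.0, v) for d, v in zip(s.days, s.scores)])
            assert beta1(scaled) == pytest.approx(beta1(s) / 3.0)

    def test_score_reversal_negates(self, rng):
        for _ in range(20):
            s = random_ladder_walk(rng)
            rev = series_from_pairs(list(zip(s.days, s.scores[::-1])))
            assert beta1(rev) == pytest.approx(-beta1(s))


# ------------------------------------------------------------------ beta2

class TestBeta2:
    def test_constant_series_is_zero(self, constant_series):
        assert beta2(constant_series) == 0.0

    def test_two_point_reduces_to_weighted_delta(self, rng):
        # with one segment the remaining-time factor cancels the denominator
        for _ in range(200):
            s = random_ladder_walk(rng, length=2)
            assert beta2(s) == pytest.approx(
                weighted_delta(s.scores[0], s.scores[1]), abs=1e-12)

    def test_hand_computed_example(self):
        s = series_from_pairs([(0, 2.0), (100, 3.0), (400, 3.0)])
        # segment 1: (+1.0/100) * 400 = 4.0 ; segment 2: 0
        assert beta2(s) == pytest.approx(4.0)

    def test_oracle_equivalence_1000_walks(self, rng):
        worst = 0.0
        for _ in range(1000):
            s = random_ladder_walk(rng)
            worst = max(worst, abs(beta2(s) - oracle_beta2(s.days, s.scores)))
            worst = max(worst, abs(beta1(s) - oracle_beta1(s.days, s.scores)))
        assert worst < 1e-12

    def test_two_point_invariant_under_time_scaling(self, rng):
        for _ in range(20):
            s = random_ladder_walk(rng, length=2)
            scaled = series_from_pairs(
                [(d * 5.0, v) for d, v in zip(s.days, s.scores)])
            assert beta2(scaled) == pytest.approx(beta2(s))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.data())
def test_beta_oracles_property(data):
    n = data.draw(st.integers(2, 12))
    gaps = data.draw(st.lists(st.integers(1, 500), min_size=n - 1, max_size=n - 1))
    idx = data.draw(st.lists(st.integers(0, 19), min_size=n, max_size=n))
    days = [0.0]
    for g in gaps:
        days.append(days[-1] + g)
    s = series_from_pairs([(d, ladder_value(i)) for d, i in zip(days, idx)])
    assert beta1(s) == pytest.approx(oracle_beta1(s.days, s.scores), abs=1e-12)
    assert beta2(s) == pytest.approx(oracle_beta2(s.days, s.scores), abs=1e-12)


# ---------------------------------------------------------------- EDSS(t)

class TestEdssAtTimepoints:
    def test_exact_hit(self):
        s = series_from_pairs([(0, 2.0), (365, 3.0), (900, 3.5)])
        assert edss_at_timepoints(s)[1] == 3.0

    def test_nearest_within_window(self):
        s = series_from_pairs([(0, 2.0), (310, 2.5), (800, 3.0)])
        assert edss_at_timepoints(s)[1] == 2.5

    def test_tie_resolves_to_earlier(self):
        s = series_from_pairs([(0, 2.0), (355, 2.5), (375, 3.0)])
        assert edss_at_timepoints(s)[1] == 2.5

    def test_stability_imputation_equal_brackets(self):
        # no visit within 90 d of day 365, but equal scores on both sides
        s = series_from_pairs([(0, 2.0), (250, 2.0), (500, 2.0)])
        assert edss_at_timepoints(s)[1] == 2.0

    def test_unequal_brackets_missing(self):
        s = series_from_pairs([(0, 2.0), (200, 2.0), (600, 3.0)])
        assert edss_at_timepoints(s)[1] is None

    def test_horizon_zero_always_first_assessment(self, rng):
        for _ in range(20):
            s = random_ladder_walk(rng)
            assert edss_at_timepoints(s)[0] == s.scores[0]

    def test_beyond_follow_up_missing(self):
        s = series_from_pairs([(0, 2.0), (400, 2.5)])
        out = edss_at_timepoints(s)
        assert out[5] is None and out[10] is None


# ------------------------------------------------------------- cohort-wide

class TestComputeAll:
    def test_degenerate_constant_cohort_all_zero(self):
        from dataclasses import replace

        from mstraj.cohort import Cohort

        cfg = SynthConfig(n_patients=20, seed=5, relapse_rate=0.0, noise_prob=0.0,
                          group_weights={"mild": 1.0, "average": 0.0, "aggressive": 0.0},
                          age_effect=0.0)
        cohort, _ = generate_cohort(cfg)
        # flatten every series: constant trajectories must give zero betas
        flat = tuple(
            replace(p, series=series_from_pairs(
                [(d, p.series.scores[0]) for d in p.series.days]))
            for p in cohort
        )
        desc = compute_all(Cohort(flat, cohort.feature_schema))
        assert (desc["beta1"] == 0).all() and (desc["beta2"] == 0).all()

    def test_count_matrix_column_sums(self, rng):
        cohort, _ = generate_cohort(SynthConfig(n_patients=200, seed=11))
        desc = compute_all(cohort)
        mat = edss_count_matrix(desc)
        for h in (0, 1, 2, 5, 10):
            assert mat.loc[f"EDSS({h})"].sum() == desc[f"edss_{h}"].notna().sum()

    def test_oracle_equivalence_rowwise(self):
        cohort, _ = generate_cohort(SynthConfig(n_patients=200, seed=7))
        desc = compute_all(cohort)
        for p, (_, row) in zip(cohort, desc.iterrows()):
            assert row["beta1"] == pytest.approx(
                oracle_beta1(p.series.days, p.series.scores), abs=1e-12)
            assert row["beta2"] == pytest.approx(
                oracle_beta2(p.series.days, p.series.scores), abs=1e-12)

    def test_edss0_never_missing(self):
        cohort, _ = generate_cohort(SynthConfig(n_patients=100, seed=3))
        desc = compute_all(cohort)
        assert desc["edss_0"].notna().all()

    def test_single_visit_flagged_not_fatal(self):
        from mstraj.cohort import Cohort, PatientRecord
        p = PatientRecord("solo", "female", 30.0, {}, series_from_pairs([(0, 2.0)]))
        desc = compute_all(Cohort((p,)))
        assert desc.loc[0, "error"] != ""
        assert np.isnan(desc.loc[0, "beta1"])
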