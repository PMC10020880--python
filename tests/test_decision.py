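"""Interval-assignment decision analysis."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lunginterval import (
    Cohort,
    LungRadsCategory,
    assign_by_fraction,
    assign_by_lungrads,
    fraction_assigned_at_delay,
    one_screen_per_person,
    restrict_lungrads2,
    stratify,
    tradeoff_curve,
)
from lunginterval.data_model import ScreenRecord, SizeClass
from lunginterval.errors import DataError


def brute_force_assignment(risks, outcomes, fraction):
    """Sort (stable), take N=round(f*n) lowest, count delayed cancers."""
    n = len(risks)
    n_assign = int(np.floor(fraction * n + 0.5))
    order = sorted(range(n), key=lambda i: (risks[i], i))
    taken = order[:n_assign]
    return n_assign, sum(outcomes[i] for i in taken)


class TestAssignByFraction:
    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 30), st.integers(0, 1)), min_size=1, max_size=500
        ),
        fraction=st.floats(0.0, 1.0),
    )
    def test_matches_brute_force_oracle(self, data, fraction):
        risks = np.array([r / 30.0 for r, _ in data])
        outcomes = np.array([y for _, y in data])
        res = assign_by_fraction(risks, outcomes, fraction)
        n_assign, n_delayed = brute_force_assignment(risks, outcomes, fraction)
        assert (res.n_assigned, res.n_delayed) == (n_assign, n_delayed)

    def test_two_lowest_of_five(self):
        res = assign_by_fraction([0.01, 0.02, 0.03, 0.04, 0.05], [0, 0, 1, 0, 1], 0.4)
        assert res.n_assigned == 2 and res.n_delayed == 0
        assert res.risk_threshold == pytest.approx(0.02)

    def test_rounding_of_target_counts(self):
        """Nearest-integer rounding of fraction x cohort size."""
        risks = np.linspace(0.001, 0.999, 10_831)
        outcomes = np.zeros(10_831, dtype=int)
        outcomes[-1] = 1
        assert assign_by_fraction(risks, outcomes, 0.66).n_assigned == 7_148
        assert assign_by_fraction(risks, outcomes, 0.80).n_assigned == 8_665
        assert assign_by_fraction(risks, outcomes, 0.90).n_assigned == 9_748

    def test_fraction_one_recovers_prevalence(self):
        rng = np.random.default_rng(4)
        risks = rng.random(500)
        outcomes = (rng.random(500) < 0.1).astype(int)
        res = assign_by_fraction(risks, outcomes, 1.0)
        assert res.absolute_risk == pytest.approx(100.0 * outcomes.mean())
        assert res.pct_cancers_delayed == 100.0

    def test_fraction_zero_is_flagged(self):
        res = assign_by_fraction([0.1, 0.2], [0, 1], 0.0)
        assert res.n_assigned == 0 and res.flagged and np.isnan(res.absolute_risk)


class TestAssignByLungrads:
    def test_threshold_2_on_fixture(self, fixture_cohort):
        res = assign_by_lungrads(fixture_cohort, LungRadsCategory.CAT_2)
        assert res.n_delayed == 69
        assert res.n_assigned - res.n_delayed == 7_026
        assert res.absolute_risk == pytest.approx(0.97, abs=0.005)

    def test_threshold_4b_assigns_everyone(self, fixture_cohort):
        res = assign_by_lungrads(fixture_cohort, LungRadsCategory.CAT_4B)
        assert res.n_assigned == 10_831 and res.n_delayed == 195
        assert res.absolute_risk == pytest.approx(1.80, abs=0.005)


class TestTradeoffCurve:
    def test_perfect_score_hugs_corner(self):
        risks = np.concatenate([np.full(50, 0.1), np.full(5, 0.9)])
        outcomes = np.concatenate([np.zeros(50, int), np.ones(5, int)])
        curve = tradeoff_curve(risks, outcomes)
        # all noncases assigned before any cancer is delayed
        i = np.flatnonzero(curve.pct_noncases_assigned == 100.0)[0]
        assert curve.pct_cancers_delayed[i] == 0.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        risks = rng.random(300)
        outcomes = (rng.random(300) < 0.15).astype(int)
        a = tradeoff_curve(risks, outcomes)
        b = tradeoff_curve(np.log(risks / (1 - risks)), outcomes)
        assert np.array_equal(a.pct_cancers_delayed, b.pct_cancers_delayed)
        assert np.array_equal(a.pct_noncases_assigned, b.pct_noncases_assigned)

    def test_reversed_risks_reflect_through_antidiagonal(self):
        """Brute-force symmetry check on 20-record toys with distinct risks."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            risks = rng.permutation(20) / 20.0 + 0.01
            outcomes = (rng.random(20) < 0.3).astype(int)
            if not 0 < outcomes.sum() < 20:
                continue
            fwd = tradeoff_curve(risks, outcomes)
            rev = tradeoff_curve(-risks, outcomes)
            assert np.allclose(rev.pct_cancers_delayed, 100.0 - fwd.pct_cancers_delayed[::-1])
            assert np.allclose(
                rev.pct_noncases_assigned, 100.0 - fwd.pct_noncases_assigned[::-1]
            )

    def test_uninformative_risks_average_to_diagonal(self):
        """With all-equal risks and random tie order, the assigned-noncase
        percentage at 5% cancers delayed matches the order-statistic
        expectation (k+1)/(m+1)."""
        rng = np.random.default_rng(10)
        n, m = 2_000, 100
        outcomes_base = np.array([1] * m + [0] * (n - m))
        risks = np.full(n, 0.5)
        k = int(0.05 * m)
        vals = []
        for _ in range(200):
            outcomes = outcomes_base[rng.permutation(n)]
            vals.append(fraction_assigned_at_delay(risks, outcomes, 0.05).pct_noncases_assigned)
        expected = 100.0 * (k + 1) / (m + 1)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 4 * se + 0.1


class TestFractionAssignedAtDelay:
    def test_delay_one_assigns_everyone(self):
        res = fraction_assigned_at_delay([0.1, 0.2, 0.3], [0, 1, 0], 1.0)
        assert res.n_assigned == 3

    def test_delay_zero_stops_below_first_cancer(self):
        risks = [0.01, 0.02, 0.03, 0.04, 0.05]
        outcomes = [0, 0, 1, 0, 1]
        res = fraction_assigned_at_delay(risks, outcomes, 0.0)
        assert res.n_assigned == 2 and res.n_delayed == 0

    def test_ten_record_toy(self):
        """Cancers at risk-ranks 3 and 7, tolerating half the cancers delayed:
        ranks 1..6 are assigned."""
        risks = [(i + 1) / 100 for i in range(10)]
        outcomes = [0, 0, 1, 0, 0, 0, 1, 0, 0, 0]
        res = fraction_assigned_at_delay(risks, outcomes, 0.5)
        assert res.n_assigned == 6 and res.n_delayed == 1


class TestStratify:
    def _sized_cohort(self):
        rng = np.random.default_rng(12)
        sizes = [SizeClass.MM_4_5, SizeClass.MM_6_7, SizeClass.MM_8_10]
        records = []
        risks = []
        for i in range(300):
            s = sizes[i % 3]
            risk = {SizeClass.MM_4_5: 0.01, SizeClass.MM_6_7: 0.05, SizeClass.MM_8_10: 0.2}[s]
            risk += rng.random() * 0.005
            records.append(
                ScreenRecord(
                    person_id=f"s{i}",
                    round="T0",
                    image_score=risk,
                    prescreen_risk=0.01,
                    lung_rads=LungRadsCategory.CAT_2,
                    size_class=s,
                    outcome=int(rng.random() < risk),
                )
            )
            risks.append(risk)
        return Cohort(records), np.array(risks)

    def test_stratum_counts_sum_to_overall(self):
        cohort, risks = self._sized_cohort()
        overall = assign_by_fraction(risks, cohort.outcomes, 0.66)
        rows = stratify(cohort, risks, 0.66, by="size_class")
        assert sum(r.n_assigned for _, r in rows) == overall.n_assigned
        assert sum(r.n_delayed for _, r in rows) == overall.n_delayed

    def test_single_stratum_equals_overall(self, fixture_cohort):
        risks = np.linspace(0.001, 0.999, len(fixture_cohort))
        overall = assign_by_fraction(risks, fixture_cohort.outcomes, 0.5)
        rows = dict(stratify(fixture_cohort, risks, 0.5, by="size_class"))
        res = rows["NA"]  # the fixture is single-stratum in size
        assert (res.n_assigned, res.n_delayed) == (overall.n_assigned, overall.n_delayed)

    def test_assigned_fraction_decreases_with_size(self):
        """Risk increases with size class, so the overall threshold assigns a
        shrinking share of larger-nodule screens."""
        cohort, risks = self._sized_cohort()
        rows = dict(stratify(cohort, risks, 0.66, by="size_class"))
        frac = {
            s: rows[s].n_assigned / 100 for s in ("4-5", "6-7", "8-10")
        }
        assert frac["4-5"] >= frac["6-7"] >= frac["8-10"]
        assert frac["4-5"] > frac["8-10"]

    def test_empty_stratum_gives_zero_row(self, fixture_cohort):
        risks = np.full(len(fixture_cohort), 0.5)
        rows = dict(stratify(fixture_cohort, risks, 0.5, by="size_class"))
        assert rows["4-5"].n_assigned == 0 and rows["4-5"].flagged


class TestSensitivityRestrictions:
    def _two_screen_cohort(self):
        r0 = ScreenRecord(
            person_id="p",
            round="T0",
            image_score=0.3,
            prescreen_risk=0.01,
            lung_rads=LungRadsCategory.CAT_2,
            size_class=SizeClass.NA,
            outcome=0,
        )
        return Cohort([r0, dataclasses.replace(r0, round="T1")])

    def test_singletons_are_identity(self, fixture_cohort):
        sub = Cohort(fixture_cohort.records[:50])
        out = one_screen_per_person(sub, seed=0)
        assert list(out.records) == list(sub.records)

    def test_two_screen_person_keeps_exactly_one(self):
        cohort = self._two_screen_cohort()
        out = one_screen_per_person(cohort, seed=1)
        assert len(out) == 1

    def test_round_choice_is_unbiased(self):
        """Over seeded replicates, T0 is kept about half the time."""
        cohort = self._two_screen_cohort()
        kept_t0 = sum(
            one_screen_per_person(cohort, seed=s).records[0].round == "T0"
            for s in range(10_000)
        )
        assert abs(kept_t0 / 10_000 - 0.5) < 0.02

    def test_restrict_lungrads2_on_fixture(self, fixture_cohort):
        sub = restrict_lungrads2(fixture_cohort)
        assert len(sub) == 7_095 and sub.n_cases == 69

    def test_restrict_is_idempotent(self, fixture_cohort):
        once = restrict_lungrads2(fixture_cohort)
        twice = restrict_lungrads2(once)
        assert list(once.records) == list(twice.records)

    def test_no_category2_warns_and_returns_empty(self, fixture_cohort):
        others = fixture_cohort.subset(
            fixture_cohort.lungrads_ranks > 1, provenance="no-cat2"
        )
        with pytest.warns(UserWarning, match="Lung-RADS 2"):
            out = restrict_lungrads2(others)
        assert len(out) == 0


def test_fraction_out_of_range_rejected():
    with pytest.raises(DataError):
        assign_by_fraction([0.1], [0], 1.5)
    with pytest.raises(DataError):
        fraction_assigned_at_delay([0.1, 0.2], [0, 1], -0.1)
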