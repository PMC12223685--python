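"""Split construction: held-out test sets, nested stratified budgets and
minimal oversampling arithmetic."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from narrsim.splits import (
    OversamplePlan,
    SplitPlan,
    composition_after_addition,
    make_nested_train_splits,
    make_oversampled_splits,
    make_test_split,
    plan_oversample_addition,
    restrict_cohort,
)
from narrsim.synthetic import NarrativeRecord


def make_pool(n_pos, n_neg, outcome="drive_by"):
    records = []
    for i in range(n_pos + n_neg):
        records.append(
            NarrativeRecord(
                record_id=f"p{i:05d}",
                le_narrative="text",
                cme_narrative="text",
                sex="male",
                race_ethnicity="black_nh",
                weapon_type="firearm",
                manner="homicide",
                circumstances_known=True,
                outcomes={outcome: 1 if i < n_pos else 0},
            )
        )
    return records


def brute_force_min_addition(n_pos, n_neg, f):
    target = Fraction(f).limit_denominator(1_000_000)
    a = 0
    while Fraction(n_pos + a, n_pos + n_neg + a) < target:
        a += 1
    return a


class TestRestrictCohort:
    def test_identity_on_firearm_homicides(self, small_cohort):
        assert restrict_cohort(small_cohort) == list(small_cohort)

    def test_drops_nonqualifying(self):
        records = make_pool(2, 8)
        other = NarrativeRecord(
            record_id="x",
            le_narrative="",
            cme_narrative="",
            sex="male",
            race_ethnicity="white_nh",
            weapon_type="sharp instrument",
            manner="homicide",
            circumstances_known=True,
            outcomes={"drive_by": 0},
        )
        assert len(restrict_cohort(records + [other])) == 10


class TestMakeTestSplit:
    def test_rounded_size(self):
        records = make_pool(3, 7)
        assert len(make_test_split(records, "drive_by", 0.30, 1)) == 3

    def test_deterministic_and_seed_sensitive(self):
        records = make_pool(100, 900)
        a = make_test_split(records, "drive_by", 0.30, 1)
        b = make_test_split(records, "drive_by", 0.30, 1)
        c = make_test_split(records, "drive_by", 0.30, 2)
        assert a == b
        assert len(a) == len(c) == 300
        assert a != c

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError, match="empty"):
            make_test_split([], "drive_by", 0.3, 1)
        with pytest.raises(ValueError, match="test_fraction"):
            make_test_split(make_pool(1, 9), "drive_by", 1.5, 1)
        with pytest.raises(ValueError, match="too small"):
            make_test_split(make_pool(1, 0), "drive_by", 0.3, 1)


class TestNestedTrainSplits:
    def test_stratified_counts(self):
        pool = make_pool(100, 900)
        out = make_nested_train_splits(pool, "drive_by", [100], 1)
        labels = {r.record_id: r.outcomes["drive_by"] for r in pool}
        assert sum(labels[i] for i in out[100]) == 10
        assert len(out[100]) == 100

    def test_rare_outcome_rounding(self):
        # pool fraction 0.059: budget 2000 carries round(2000*0.059) = 118
        pool = make_pool(59, 941)
        out = make_nested_train_splits(pool, "drive_by", [1000], 5)
        labels = {r.record_id: r.outcomes["drive_by"] for r in pool}
        assert sum(labels[i] for i in out[1000]) == 59
        pool = make_pool(59 * 4, 941 * 4)
        out = make_nested_train_splits(pool, "drive_by", [2000], 5)
        labels = {r.record_id: r.outcomes["drive_by"] for r in pool}
        assert sum(labels[i] for i in out[2000]) == 118

    def test_nested_across_budgets(self):
        pool = make_pool(100, 900)
        out = make_nested_train_splits(pool, "drive_by", [200, 500, 1000], 2)
        assert out[200] < out[500] < out[1000]

    def test_budget_exceeding_pool_rejected(self):
        with pytest.raises(ValueError, match="exceeds pool"):
            make_nested_train_splits(make_pool(5, 45), "drive_by", [100], 1)

    def test_non_increasing_budgets_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            make_nested_train_splits(make_pool(50, 450), "drive_by", [200, 200], 1)


class TestOversampleArithmetic:
    @pytest.mark.parametrize(
        "n_pos, n_neg, f, expected",
        [
            (10, 90, 0.50, 80),
            (54, 940, 0.10, 51),
            (100, 100, 0.10, 0),
            (50, 950, 0.50, 900),
        ],
    )
    def test_examples(self, n_pos, n_neg, f, expected):
        assert plan_oversample_addition(n_pos, n_neg, f) == expected

    def test_exact_boundary_needs_no_addition(self):
        assert plan_oversample_addition(20, 80, 0.20) == 0

    @settings(derandomize=True, max_examples=300)
    @given(
        st.integers(1, 200),
        st.integers(1, 200),
        st.sampled_from([round(0.05 * k, 2) for k in range(1, 20)]),
    )
    def test_matches_exhaustive_search(self, n_pos, n_neg, f):
        assert plan_oversample_addition(n_pos, n_neg, f) == brute_force_min_addition(
            n_pos, n_neg, f
        )

    def test_monotone_in_target(self):
        adds = [plan_oversample_addition(54, 940, f) for f in (0.1, 0.2, 0.3, 0.4, 0.5)]
        assert adds == sorted(adds)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError, match="target_fraction"):
            plan_oversample_addition(10, 90, 1.0)

    def test_composition_after_addition(self):
        total_pos, total, frac = composition_after_addition(54, 940, 59)
        assert total_pos == 113
        assert total == 1053
        assert frac == pytest.approx(113 / 1053)


class TestMakeOversampledSplits:
    def setup_method(self):
        self.records = make_pool(300, 1700)
        self.test_ids = make_test_split(self.records, "drive_by", 0.30, 3)
        pool = [r for r in self.records if r.record_id not in self.test_ids]
        self.base = make_nested_train_splits(pool, "drive_by", [400], 4)[400]

    def test_added_ids_positive_and_disjoint(self):
        plan = make_oversampled_splits(
            self.records, "drive_by", self.base, self.test_ids, [0.2, 0.3], 5
        )
        labels = {r.record_id: r.outcomes["drive_by"] for r in self.records}
        for ids in plan.added_pos_ids_by_fraction.values():
            assert all(labels[i] == 1 for i in ids)
            assert not ids & self.base
            assert not ids & self.test_ids

    def test_additions_nested_and_minimal(self):
        plan = make_oversampled_splits(
            self.records, "drive_by", self.base, self.test_ids, [0.2, 0.3, 0.35], 5
        )
        added = plan.added_pos_ids_by_fraction
        assert added[0.2] <= added[0.3] <= added[0.35]
        labels = {r.record_id: r.outcomes["drive_by"] for r in self.records}
        n_pos = sum(labels[i] for i in self.base)
        for f, ids in added.items():
            assert len(ids) == plan_oversample_addition(n_pos, 400 - n_pos, f)

    def test_already_met_fraction_adds_nothing(self):
        plan = make_oversampled_splits(
            self.records, "drive_by", self.base, self.test_ids, [0.10], 5
        )
        assert plan.added_pos_ids_by_fraction[0.10] == frozenset()

    def test_pool_exhaustion_rejected(self):
        with pytest.raises(ValueError, match="pool has"):
            make_oversampled_splits(
                self.records, "drive_by", self.base, self.test_ids, [0.9], 5
            )


class TestPlanSerialization:
    def test_split_plan_round_trip(self, tmp_path):
        pool = make_pool(100, 900)
        test_ids = make_test_split(pool, "drive_by", 0.3, 1)
        rest = [r for r in pool if r.record_id not in test_ids]
        train = make_nested_train_splits(rest, "drive_by", [100, 200], 2)
        plan = SplitPlan(
            outcome="drive_by",
            test_ids=test_ids,
            train_budgets=(100, 200),
            train_ids_by_budget=train,
            seed=2,
        )
        plan.validate()
        path = tmp_path / "plan.json"
        plan.to_json(path)
        back = SplitPlan.from_json(path)
        assert back == plan

    def test_oversample_plan_round_trip(self, tmp_path):
        records = make_pool(300, 1700)
        test_ids = make_test_split(records, "drive_by", 0.3, 3)
        pool = [r for r in records if r.record_id not in test_ids]
        base = make_nested_train_splits(pool, "drive_by", [400], 4)[400]
        plan = make_oversampled_splits(
            records, "drive_by", base, test_ids, [0.2, 0.3], 5
        )
        path = tmp_path / "oversample.json"
        plan.to_json(path)
        assert OversamplePlan.from_json(path) == plan
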