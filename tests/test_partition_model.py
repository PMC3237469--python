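"""Entropy machinery, optimal cuts and the ordered partition chain."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ohca_partition import SyntheticConfig, generate_cohort
from ohca_partition.partition_model import (
    FAVORABLE_CPC,
    SURVIVAL_1MO,
    NoSplit,
    OrderedPartitionModel,
    assign_final_node,
    best_cut,
    binary_entropy,
    fit_ordered_partition,
    split_gain,
)
from ohca_partition.registry_io import Cohort


def brute_force_best_cut(values, outcomes):
    """Independent oracle: try every midpoint between consecutive distinct
    values, recomputing the gain from the 2x2 contingency table directly."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    distinct = np.unique(v)
    best = None
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        cut = (lo + hi) / 2.0
        left = v <= cut
        n_l, n_r = left.sum(), (~left).sum()
        k_l, k_r = y[left].sum(), y[~left].sum()

        def h(k, n):
            if n == 0 or k == 0 or k == n:
                return 0.0
            p = k / n
            return -p * math.log2(p) - (1 - p) * math.log2(1 - p)

        gain = h(y.sum(), y.size) - (n_l * h(k_l, n_l) + n_r * h(k_r, n_r)) / y.size
        if best is None or gain > best[0] + 1e-12:
            best = (gain, cut)
    return best


class TestBinaryEntropy:
    @pytest.mark.parametrize("p, expected", [(0.5, 1.0), (0.0, 0.0), (1.0, 0.0)])
    def test_known_values(self, p, expected):
        assert binary_entropy(p) == pytest.approx(expected)

    @pytest.mark.parametrize("p", [0.25, 0.1, 0.37])
    def test_symmetry(self, p):
        assert binary_entropy(p) == pytest.approx(binary_entropy(1 - p))

    @pytest.mark.parametrize("p", [-0.01, 1.01])
    def test_domain_error(self, p):
        with pytest.raises(ValueError):
            binary_entropy(p)

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_bounded_by_one_bit(self, p):
        assert 0.0 <= binary_entropy(p) <= 1.0


class TestSplitGain:
    def test_perfect_separation_yields_one_bit(self):
        assert split_gain([1, 1, 9, 9], [True, True, False, False], 5) == pytest.approx(1.0)

    def test_equal_branch_proportions_yield_zero(self):
        assert split_gain([1, 2, 3, 4], [True, False, True, False], 2.5) == pytest.approx(0.0, abs=1e-12)

    def test_empty_branch_rejected(self):
        with pytest.raises(ValueError):
            split_gain([1, 2, 3], [True, False, True], 10)

    def test_matches_direct_contingency_recomputation(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = rng.integers(4, 60)
            v = rng.integers(0, 20, n).astype(float)
            y = rng.random(n) < 0.4
            cuts = np.unique(v)
            if cuts.size < 2:
                continue
            cut = (cuts[0] + cuts[1]) / 2
            left = v <= cut
            p, pl, pr = y.mean(), y[left].mean(), y[~left].mean()
            expected = binary_entropy(p) - (
                left.sum() * binary_entropy(pl) + (~left).sum() * binary_entropy(pr)
            ) / n
            assert split_gain(v, y, cut) == pytest.approx(max(0.0, expected), abs=1e-12)


class TestBestCut:
    def test_worked_example_five_points(self):
        node = best_cut([3, 4, 5, 6, 7], [True, True, True, False, False])
        assert node.cut == pytest.approx(5.5)
        assert node.acceptable_threshold == 5
        # children are pure, so the gain is the parent entropy H(3/5)
        assert node.gain == pytest.approx(binary_entropy(0.6))
        assert node.continued_branch == "left"

    def test_constant_outcome_is_no_split(self):
        result = best_cut([1, 2, 3, 4], [True, True, True, True])
        assert isinstance(result, NoSplit) and result.reason == "zero_gain"

    def test_constant_values_is_no_split(self):
        result = best_cut([2, 2, 2], [True, False, True])
        assert isinstance(result, NoSplit) and result.reason == "constant_values"

    def test_min_child_restricts_candidates(self):
        values = [1, 2, 2, 2, 2, 2]
        outcomes = [True, True, True, False, False, False]
        unrestricted = best_cut(values, outcomes)
        assert unrestricted.n_left == 1
        restricted = best_cut(values, outcomes, min_child=2)
        assert isinstance(restricted, NoSplit) and restricted.reason == "node_too_small"

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(300):
            n = int(rng.integers(4, 200))
            v = rng.integers(0, 30, n).astype(float)
            y = rng.random(n) < rng.uniform(0.1, 0.9)
            oracle = brute_force_best_cut(v, y)
            node = best_cut(v, y)
            if oracle is None or oracle[0] <= 1e-12:
                assert isinstance(node, NoSplit)
                continue
            assert node.gain == pytest.approx(oracle[0], abs=1e-10)
            assert node.cut == pytest.approx(oracle[1])

    def test_matches_sklearn_depth_one_tree(self):
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(3)
        for _ in range(10):
            v = rng.integers(0, 15, 400).astype(float)
            y = (v <= 6) & (rng.random(400) < 0.6) | (rng.random(400) < 0.1)
            node = best_cut(v, y)
            tree = DecisionTreeClassifier(criterion="entropy", max_depth=1).fit(
                v.reshape(-1, 1), y
            )
            assert node.cut == pytest.approx(tree.tree_.threshold[0])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        v = rng.integers(0, 25, 300).astype(float)
        y = (v <= 10) ^ (rng.random(300) < 0.2)
        base = best_cut(v, y)
        transformed = best_cut(np.exp(v / 5.0), y)
        # the cut value moves, the induced record partition does not
        assert (v <= base.cut).sum() == transformed.n_left
        assert transformed.gain == pytest.approx(base.gain, abs=1e-10)

    def test_gain_bounded_by_parent_entropy(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            v = rng.integers(0, 12, 80).astype(float)
            y = rng.random(80) < 0.3
            node = best_cut(v, y)
            if isinstance(node, NoSplit):
                continue
            k = y.sum()
            assert 0.0 <= node.gain <= binary_entropy(k / y.size) + 1e-12

    def test_tie_breaks_toward_smallest_cut(self):
        # two symmetric candidate cuts with identical gain
        node = best_cut([1, 2, 3, 4], [False, True, True, False])
        assert node.cut == pytest.approx(1.5)


class TestFitOrderedPartition:
    def test_chain_counts_are_consistent(self, clean_cohort):
        model = fit_ordered_partition(
            clean_cohort, FAVORABLE_CPC, ["t_cpr", "t_amb", "t_hosp"], min_node=20
        )
        for parent, child in zip(model.nodes[:-1], model.nodes[1:]):
            continued = (
                parent.n_left if parent.continued_branch == "left" else parent.n_right
            )
            assert child.n_parent == continued
        for node in model.nodes:
            assert node.n_left + node.n_right == node.n_parent
            assert node.gain >= 0

    def test_recovers_planted_thresholds_single_seed(self):
        cohort, truth = generate_cohort(SyntheticConfig(n=30_000, seed=8))
        model = fit_ordered_partition(cohort, FAVORABLE_CPC, ["t_cpr", "t_amb", "t_hosp"])
        assert model.thresholds["t_cpr"] == truth.thresholds["t_cpr"]
        assert model.thresholds["t_amb"] == truth.thresholds["t_amb"]

    def test_outcome_independent_of_time_stops_with_zero_gain(self, make_record):
        rng = np.random.default_rng(0)
        records = [
            make_record(
                t_cpr=int(rng.integers(0, 15)),
                cpc=1 if rng.random() < 0.3 else 5,
                survival_1mo=bool(rng.random() < 0.5),
            )
            for _ in range(400)
        ]
        # make cpc/survival consistent
        records = [
            r if r.cpc == 5 or r.survival_1mo else r.__class__(**{**r.__dict__, "survival_1mo": True})
            for r in records
        ]
        cohort = Cohort.from_records(records, "independent")
        model = fit_ordered_partition(cohort, FAVORABLE_CPC, ["t_cpr"], min_node=5)
        if model.nodes:  # a spurious split can squeak through at tiny n
            assert model.nodes[0].gain < 0.01
        else:
            assert model.stopping["t_cpr"] in ("zero_gain", "node_too_small")

    def test_fit_is_deterministic(self, clean_cohort):
        a = fit_ordered_partition(clean_cohort, SURVIVAL_1MO, ["t_cpr", "t_amb"], 20)
        b = fit_ordered_partition(clean_cohort, SURVIVAL_1MO, ["t_cpr", "t_amb"], 20)
        assert a.to_json() == b.to_json()

    def test_missing_outcome_rejected(self, toy_cohort):
        with pytest.raises(ValueError, match="undefined"):
            fit_ordered_partition(toy_cohort, FAVORABLE_CPC, ["t_cpr"], min_node=2)

    def test_json_round_trip(self, clean_cohort, tmp_path):
        model = fit_ordered_partition(clean_cohort, FAVORABLE_CPC.name, ["t_cpr", "t_amb"], 20)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = OrderedPartitionModel.from_json(path)
        assert back.to_json() == model.to_json()

    def test_render_text_mentions_every_split(self, clean_cohort):
        model = fit_ordered_partition(clean_cohort, FAVORABLE_CPC, ["t_cpr", "t_amb"], 20)
        text = model.render_text()
        for node in model.nodes:
            assert f"{node.variable} <= {node.acceptable_threshold}" in text


class TestAssignFinalNode:
    @pytest.fixture
    def model(self, clean_cohort):
        return fit_ordered_partition(
            clean_cohort, FAVORABLE_CPC, ["t_cpr", "t_amb", "t_hosp"], min_node=20
        )

    def test_within_all_thresholds_true(self, model, make_record):
        thr = model.thresholds
        record = make_record(
            t_cpr=thr["t_cpr"] - 1, t_amb=thr["t_amb"] - 1, t_hosp=thr["t_hosp"] - 1
        )
        assert assign_final_node(model, record) is True

    def test_exactly_at_threshold_is_inside(self, model, make_record):
        thr = model.thresholds
        record = make_record(**thr)
        assert assign_final_node(model, record) is True

    def test_one_minute_beyond_is_outside(self, model, make_record):
        thr = model.thresholds
        record = make_record(
            t_cpr=thr["t_cpr"], t_amb=thr["t_amb"], t_hosp=thr["t_hosp"] + 1
        )
        assert assign_final_node(model, record) is False

    def test_missing_split_variable_not_evaluable(self, model, make_record):
        import pandas as pd

        record = make_record(t_hosp=None)
        assert assign_final_node(model, record) is pd.NA

    def test_vectorized_agrees_with_per_record(self, model, clean_cohort):
        series = assign_final_node(model, clean_cohort.df.head(100))
        singles = [
            assign_final_node(model, rec)
            for rec in list(clean_cohort.records())[:100]
        ]
        assert list(series) == singles
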