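"""Apriori mining, rule generation, and agreement with brute-force oracles."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from behaviorminer import (
    ConfigurationError,
    Item,
    MiningConfig,
    ValidationError,
    brute_force_frequent_itemsets,
    brute_force_rules,
    canonical_itemset,
    generate_rules,
    mine_frequent_itemsets,
    support_of,
)
from behaviorminer.apriori import support_count

from conftest import make_dataset, random_dataset


def records_as_set(records):
    return {(r.itemset, r.count) for r in records}


def rules_as_set(rules):
    return {
        (r.antecedent, r.consequent, r.count, r.antecedent_count, r.consequent_count)
        for r in rules
    }


class TestSupport:
    def test_toy_database_support_is_exactly_0_7(self, mask70_dataset):
        assert support_of([Item("mask", "yes")], mask70_dataset) == 0.7

    def test_empty_itemset_has_support_one(self, abc_dataset):
        assert support_of([], abc_dataset) == 1.0

    def test_matches_direct_containment_scan(self):
        ds = random_dataset(11, n_transactions=20)
        items = sorted({it for t in ds.transactions for it in t.items})[:2]
        expected = sum(1 for t in ds.transactions if set(items) <= t.items)
        assert support_of(items, ds) == expected / ds.n


class TestFrequentItemsets:
    def test_hand_enumerated_five_transaction_example(self, abc_dataset):
        # transactions {abc, ab, ac, bc, abc}: every 1- and 2-itemset is
        # frequent at 0.6 (supports 0.8 / 0.6), {a,b,c} at 0.4 is not
        records = mine_frequent_itemsets(abc_dataset, MiningConfig(min_support=0.6))
        got = {
            "".join(it.question_id for it in r.itemset): r.support for r in records
        }
        assert got == {
            "a": 0.8, "b": 0.8, "c": 0.8, "ab": 0.6, "ac": 0.6, "bc": 0.6,
        }

    def test_unanimous_support_threshold_keeps_only_universal_item(self, abc_codebook):
        rows = [[Item("a", "1"), Item("b", "1")], [Item("a", "1")]]
        ds = make_dataset(abc_codebook, rows)
        records = mine_frequent_itemsets(ds, MiningConfig(min_support=1.0))
        assert [r.itemset for r in records] == [(Item("a", "1"),)]

    def test_min_support_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            MiningConfig(min_support=1.01)
        with pytest.raises(ConfigurationError):
            MiningConfig(min_support=0.0)

    def test_boundary_support_is_inclusive(self, abc_codebook):
        # exactly 1 of 20 transactions carries the item; 5% must qualify
        rows = [[Item("a", "1")]] + [[] for _ in range(19)]
        ds = make_dataset(abc_codebook, rows)
        records = mine_frequent_itemsets(ds, MiningConfig(min_support=0.05))
        assert (Item("a", "1"),) in [r.itemset for r in records]

    def test_max_itemset_size_caps_pattern_length(self, abc_dataset):
        records = mine_frequent_itemsets(
            abc_dataset, MiningConfig(min_support=0.2, max_itemset_size=2)
        )
        assert max(len(r.itemset) for r in records) == 2

    @pytest.mark.parametrize("seed", range(12))
    def test_equivalence_with_brute_force_enumeration(self, seed):
        ds = random_dataset(seed, n_questions=6, n_transactions=12)
        config = MiningConfig(min_support=0.25, min_confidence=0.5)
        assert records_as_set(
            mine_frequent_itemsets(ds, config)
        ) == records_as_set(brute_force_frequent_itemsets(ds, config))

    def test_anti_monotonicity_on_output(self):
        ds = random_dataset(99, n_questions=5, n_transactions=30)
        records = mine_frequent_itemsets(ds, MiningConfig(min_support=0.1))
        counts = {r.itemset: r.count for r in records}
        for itemset, count in counts.items():
            for i in range(len(itemset)):
                sub = itemset[:i] + itemset[i + 1:]
                if sub:
                    assert count <= counts[sub]

    def test_ordering_is_size_then_support_then_canonical(self):
        ds = random_dataset(5, n_questions=5, n_transactions=30)
        records = mine_frequent_itemsets(ds, MiningConfig(min_support=0.1))
        keys = [(len(r.itemset), -r.count, r.itemset) for r in records]
        assert keys == sorted(keys)

    def test_determinism_identical_runs(self):
        ds = random_dataset(42, n_questions=6, n_transactions=25)
        config = MiningConfig(min_support=0.15)
        assert mine_frequent_itemsets(ds, config) == mine_frequent_itemsets(ds, config)


class TestRules:
    def test_hand_computed_metrics_for_a_implies_b(self, abc_dataset):
        config = MiningConfig(min_support=0.6, min_confidence=0.1)
        rules = generate_rules(
            mine_frequent_itemsets(abc_dataset, config), abc_dataset, config
        )
        rule = next(
            r
            for r in rules
            if r.antecedent == (Item("a", "1"),) and r.consequent == (Item("b", "1"),)
        )
        assert rule.support == 0.6
        assert rule.confidence == pytest.approx(0.75)
        assert rule.lift == pytest.approx(0.9375)

    def test_identical_supports_give_confidence_one_and_lift_reciprocal(
        self, abc_codebook
    ):
        # X and Y always co-occur with support s: confidence 1, lift 1/s
        rows = [[Item("a", "1"), Item("b", "1")]] * 2 + [[]] * 2
        ds = make_dataset(abc_codebook, rows)
        config = MiningConfig(min_support=0.5, min_confidence=0.5)
        rules = generate_rules(mine_frequent_itemsets(ds, config), ds, config)
        assert rules, "co-occurring items must yield rules"
        for rule in rules:
            assert rule.confidence == 1.0
            assert rule.lift == pytest.approx(1 / rule.support)

    def test_metric_identities_on_random_output(self):
        for seed in (3, 17, 31):
            ds = random_dataset(seed, n_questions=5, n_transactions=30)
            config = MiningConfig(min_support=0.1, min_confidence=0.2, enforce_roles=False)
            frequent = mine_frequent_itemsets(ds, config)
            counts = {r.itemset: r.count for r in frequent}
            for rule in generate_rules(frequent, ds, config):
                assert rule.count <= min(rule.antecedent_count, rule.consequent_count)
                assert rule.confidence >= rule.support
                assert rule.lift == pytest.approx(
                    rule.confidence / (rule.consequent_count / rule.n)
                )
                # lift is symmetric in the two sides
                assert rule.lift_fraction == Fraction(
                    rule.count * rule.n,
                    counts[rule.consequent] * counts[rule.antecedent],
                )

    @pytest.mark.parametrize("seed", range(10))
    def test_equivalence_with_brute_force_rules(self, seed):
        ds = random_dataset(seed + 100, n_questions=5, n_transactions=25)
        config = MiningConfig(min_support=0.2, min_confidence=0.6)
        mined = generate_rules(mine_frequent_itemsets(ds, config), ds, config)
        assert rules_as_set(mined) == rules_as_set(brute_force_rules(ds, config))

    def test_role_constraints_respected(self):
        ds = random_dataset(8, n_questions=6, n_transactions=30)
        config = MiningConfig(min_support=0.1, min_confidence=0.2)
        rules = generate_rules(mine_frequent_itemsets(ds, config), ds, config)
        for rule in rules:
            for it in rule.antecedent:
                assert ds.codebook.role_of(it.question_id) in ("antecedent", "both")
            for it in rule.consequent:
                assert ds.codebook.role_of(it.question_id) in ("consequent", "both")

    def test_disabling_roles_yields_superset(self):
        ds = random_dataset(8, n_questions=6, n_transactions=30)
        constrained = MiningConfig(min_support=0.1, min_confidence=0.2)
        free = MiningConfig(min_support=0.1, min_confidence=0.2, enforce_roles=False)
        frequent = mine_frequent_itemsets(ds, constrained)
        with_roles = rules_as_set(generate_rules(frequent, ds, constrained))
        without = rules_as_set(generate_rules(frequent, ds, free))
        assert with_roles <= without

    def test_rule_ordering_deterministic(self):
        ds = random_dataset(21, n_questions=5, n_transactions=30)
        config = MiningConfig(min_support=0.1, min_confidence=0.3, enforce_roles=False)
        frequent = mine_frequent_itemsets(ds, config)
        a = generate_rules(frequent, ds, config)
        b = generate_rules(frequent, ds, config)
        assert a == b
        keys = [
            (-r.count, -r.confidence_fraction, -r.lift_fraction, r.antecedent, r.consequent)
            for r in a
        ]
        assert keys == sorted(keys)


class TestBruteForceGuard:
    def test_refuses_large_item_universe(self):
        ds = random_dataset(2, n_questions=12, n_answers=3, n_transactions=30)
        universe = {it for t in ds.transactions for it in t.items}
        if len(universe) <= 10:  # pragma: no cover - seed chosen to avoid this
            pytest.skip("universe unexpectedly small")
        with pytest.raises(ValidationError, match="guard"):
            brute_force_frequent_itemsets(ds, MiningConfig(), max_items=10)

    def test_empty_result_above_max_singleton_support(self, abc_dataset):
        assert brute_force_frequent_itemsets(abc_dataset, MiningConfig(min_support=0.9)) == []


class TestCanonicalItemset:
    def test_sorted_and_deduplicated(self):
        items = [Item("b", "2"), Item("a", "1"), Item("b", "2")]
        assert canonical_itemset(items) == (Item("a", "1"), Item("b", "2"))

    def test_rejects_two_answers_to_one_question(self):
        with pytest.raises(ValidationError):
            canonical_itemset([Item("a", "1"), Item("a", "2")])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), min_support=st.sampled_from([0.1, 0.25, 0.4]))
def test_property_apriori_equals_brute_force(seed, min_support):
    ds = random_dataset(seed, n_questions=4, n_transactions=15)
    config = MiningConfig(min_support=min_support)
    assert records_as_set(mine_frequent_itemsets(ds, config)) == records_as_set(
        brute_force_frequent_itemsets(ds, config)
    )


def test_support_count_is_containment_count():
    ds = random_dataset(55, n_questions=4, n_transactions=20)
    item = sorted({it for t in ds.transactions for it in t.items})[0]
    assert support_count([item], ds) == sum(
        1 for t in ds.transactions if item in t.items
    )
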