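"""Rule-mining unit and property tests.

The independent oracle throughout is exhaustive subset enumeration over a
boolean membership matrix — no level-wise search, no pruning.
"""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chmnet.claims import Transaction
from chmnet.mining import (
    MiningConfig,
    compute_lift,
    derive_rules,
    mine_frequent_itemsets,
    round_half_up,
    single_item_supports,
    top_combinations,
)
from .conftest import tx


def brute_force_supports(
    transactions: list[Transaction], max_size: int
) -> dict[frozenset, int]:
    """Count every itemset up to max_size by direct enumeration."""
    items = sorted({c for t in transactions for c in t.items})
    out: dict[frozenset, int] = {}
    for size in range(1, max_size + 1):
        for combo in combinations(items, size):
            s = frozenset(combo)
            count = sum(1 for t in transactions if s <= t.items)
            if count:
                out[s] = count
    return out


class TestFrequentItemsets:
    def test_worked_example(self):
        transactions = tx("AB", "AB", "A", "C")
        result = mine_frequent_itemsets(
            transactions, MiningConfig(min_support=0.5, max_itemset_size=3)
        )
        supports = {tuple(sorted(e.items)): e.support for e in result}
        assert supports == {("A",): 0.75, ("B",): 0.5, ("A", "B"): 0.5}

    def test_unanimity_threshold(self):
        result = mine_frequent_itemsets(tx("AB", "A", "A"), MiningConfig(min_support=1.0))
        assert [set(e.items) for e in result] == [{"A"}]

    def test_empty_transaction_list_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            mine_frequent_itemsets([], MiningConfig())

    def test_sorted_by_size_then_support_then_items(self):
        result = mine_frequent_itemsets(
            tx("AB", "AB", "AC", "BC", "A"), MiningConfig(min_support=0.2)
        )
        keys = [(len(e.items), -e.support, tuple(sorted(e.items))) for e in result]
        assert keys == sorted(keys)

    def test_anti_monotone_over_full_output(self):
        rng = np.random.default_rng(5)
        transactions = [
            Transaction(str(i), frozenset(np.array(list("ABCDEFG"))[rng.random(7) < 0.4]) or frozenset("A"))
            for i in range(200)
        ]
        result = mine_frequent_itemsets(transactions, MiningConfig(min_support=0.02, max_itemset_size=4))
        smap = {e.items: e.support for e in result}
        for s, sup in smap.items():
            for t, sup_t in smap.items():
                if s < t:
                    assert sup >= sup_t

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_enumeration(self, data):
        alphabet = "ABCDEFGH"
        n = data.draw(st.integers(5, 60))
        transactions = [
            Transaction(
                str(i),
                frozenset(
                    data.draw(
                        st.sets(st.sampled_from(alphabet), min_size=1, max_size=6)
                    )
                ),
            )
            for i in range(n)
        ]
        config = MiningConfig(min_support=data.draw(st.sampled_from([0.05, 0.2, 0.5])), max_itemset_size=3)
        mined = {e.items: e.count for e in mine_frequent_itemsets(transactions, config)}
        brute = {
            s: c
            for s, c in brute_force_supports(transactions, 3).items()
            if c >= config.min_support * n
        }
        assert mined == brute


class TestRules:
    def test_worked_example_metrics(self):
        transactions = tx("AB", "AB", "A", "C")
        config = MiningConfig(min_support=0.25, min_confidence=0.30, min_lift=1.0)
        itemsets = mine_frequent_itemsets(transactions, config)
        rules = derive_rules(itemsets, transactions, config)
        ab = {tuple(sorted(r.antecedent)): r for r in rules}
        r = ab[("A",)]
        assert r.confidence == pytest.approx(2 / 3, abs=1e-12)
        assert r.lift == pytest.approx(4 / 3, abs=1e-12)
        assert r.support == pytest.approx(0.5)

    def test_exact_independence_is_not_emitted(self):
        # support(AB) = support(A) * support(B) exactly -> lift = 1, strict screen
        transactions = tx("AB", "A", "B", "C")
        config = MiningConfig(min_support=0.25, min_confidence=0.0)
        itemsets = mine_frequent_itemsets(transactions, config)
        rules = derive_rules(itemsets, transactions, config)
        assert all({"A", "B"} != set(r.itemset) for r in rules)

    def test_confidence_just_below_threshold_not_emitted(self):
        # conf = 0.29 in both directions, lift = 4.08: blocked only by confidence
        transactions = tx(*(["AB"] * 29 + ["A"] * 71 + ["B"] * 71 + ["C"] * 829))
        config = MiningConfig(min_support=0.01, min_confidence=0.30)
        itemsets = mine_frequent_itemsets(transactions, config)
        rules = derive_rules(itemsets, transactions, config)
        assert all(set(r.itemset) != {"A", "B"} for r in rules)

    def test_screens_do_not_alter_metrics(self):
        rng = np.random.default_rng(11)
        transactions = [
            Transaction(str(i), frozenset(np.array(list("ABCDE"))[rng.random(5) < 0.5]) or frozenset("A"))
            for i in range(300)
        ]
        loose = MiningConfig(min_support=0.01, min_confidence=0.0, min_lift=0.0)
        strict = MiningConfig(min_support=0.01, min_confidence=0.30, min_lift=1.0)
        itemsets = mine_frequent_itemsets(transactions, loose)
        all_rules = {
            (r.antecedent, r.consequent): r for r in derive_rules(itemsets, transactions, loose)
        }
        for r in derive_rules(itemsets, transactions, strict):
            full = all_rules[(r.antecedent, r.consequent)]
            assert (r.support, r.confidence, r.lift) == (
                full.support,
                full.confidence,
                full.lift,
            )

    def test_lift_symmetric_across_direction(self):
        transactions = tx(*(["AB"] * 40 + ["A"] * 20 + ["B"] * 10 + ["C"] * 30))
        config = MiningConfig(min_support=0.05, min_confidence=0.0, min_lift=0.0)
        itemsets = mine_frequent_itemsets(transactions, config)
        rules = derive_rules(itemsets, transactions, config)
        by_dir = {tuple(sorted(r.antecedent)): r.lift for r in rules if len(r.itemset) == 2}
        assert by_dir[("A",)] == pytest.approx(by_dir[("B",)], abs=1e-12)


class TestComputeLift:
    def test_independence_gives_one(self):
        assert compute_lift(0.25, 0.25) == pytest.approx(1.0)

    def test_zero_consequent_support_is_an_error(self):
        with pytest.raises(ValueError, match="consequent"):
            compute_lift(0.5, 0.0)


class TestTopCombinations:
    def _rules(self, transactions, **kw):
        config = MiningConfig(**kw)
        itemsets = mine_frequent_itemsets(transactions, config)
        return derive_rules(itemsets, transactions, config)

    def test_direction_collapse_keeps_higher_confidence(self):
        transactions = tx(*(["AB"] * 36 + ["A"] * 4 + ["B"] * 50 + ["C"] * 10))
        rules = self._rules(transactions, min_support=0.05, min_confidence=0.0, min_lift=0.0)
        (row,) = [r for r in top_combinations(rules, 2, 10) if r.items == ("A", "B")]
        assert row.antecedent == ("A",)  # conf A->B = 0.9 beats B->A ~ 0.42
        assert row.confidence == pytest.approx(0.9)

    def test_ranked_by_support_and_truncated(self):
        txs = tx(*(
            ["AB"] * 50 + ["CD"] * 40 + ["EF"] * 30 + ["GH"] * 20 + ["IJ"] * 10
        ))
        rules = self._rules(txs, min_support=0.01, min_confidence=0.0, min_lift=0.0)
        rows = top_combinations(rules, 2, 3)
        assert [r.items for r in rows] == [("A", "B"), ("C", "D"), ("E", "F")]
        assert [r.rank for r in rows] == [1, 2, 3]

    def test_k_larger_than_available_returns_all(self):
        rules = self._rules(tx(*["AB"] * 10), min_support=0.5, min_confidence=0.0, min_lift=0.0)
        assert len(top_combinations(rules, 2, 99)) == 1

    def test_k_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            top_combinations([], 2, 0)


class TestRounding:
    @pytest.mark.parametrize(
        "value,decimals,expected",
        [(1.4448, 1, 1.4), (1.15, 1, 1.2), (1.25, 1, 1.3), (40.55, 1, 40.6)],
    )
    def test_half_up(self, value, decimals, expected):
        assert round_half_up(value, decimals) == expected


def test_single_item_supports_matches_size_one_itemsets():
    transactions = tx("AB", "AB", "A", "C")
    sup = single_item_supports(transactions)
    mined = mine_frequent_itemsets(transactions, MiningConfig(min_support=1e-9))
    for e in mined:
        if len(e.items) == 1:
            (code,) = e.items
            assert sup[code] == e.support
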