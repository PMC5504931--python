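"""Association rule mining over CHM prescriptions.

Frequent-itemset mining (level-wise Apriori, written out in full — the
level-wise search with subset pruning is the primitive this package is
built around), rule derivation under the three-threshold screen used in
the source analysis (support >= 1%, confidence >= 30%, lift strictly > 1),
and ranked unordered combination tables ("prevalence" of a combination is
the itemset support).

Definitions, with N the number of transactions (prescriptions):

    support(S)      = |{t : S subset of t}| / N
    confidence(A→B) = support(A ∪ B) / support(A)
    lift(A→B)       = confidence(A→B) / support(B)

Lift is 1 under independence and symmetric in rule direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .claims import Transaction

__all__ = [
    "Transaction",
    "ItemsetSupport",
    "AssociationRule",
    "MiningConfig",
    "CombinationRow",
    "mine_frequent_itemsets",
    "derive_rules",
    "compute_lift",
    "top_combinations",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed report tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ItemsetSupport:
    """A frequent itemset with its absolute count and relative support."""

    items: frozenset[str]
    support: float
    count: int


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: float  # support of antecedent ∪ consequent
    confidence: float
    lift: float

    @property
    def itemset(self) -> frozenset[str]:
        return self.antecedent | self.consequent


@dataclass(frozen=True)
class MiningConfig:
    """Mining thresholds; defaults follow the published screen."""

    min_support: float = 0.01
    min_confidence: float = 0.30
    min_lift: float = 1.0  # strict: a rule must have lift > min_lift
    max_itemset_size: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.min_support <= 1):
            raise ValueError("min_support must be in (0, 1]")
        if not (0 <= self.min_confidence <= 1):
            raise ValueError("min_confidence must be in [0, 1]")
        if self.max_itemset_size < 1:
            raise ValueError("max_itemset_size must be >= 1")


@dataclass(frozen=True)
class CombinationRow:
    """One unordered CHM combination of a ranked table."""

    rank: int
    items: tuple[str, ...]  # sorted codes
    support: float
    confidence: float  # of the retained (higher-confidence) direction
    lift: float
    antecedent: tuple[str, ...]
    consequent: tuple[str, ...]


def _sort_key(entry: ItemsetSupport) -> tuple:
    return (len(entry.items), -entry.support, tuple(sorted(entry.items)))


def mine_frequent_itemsets(
    transactions: Sequence[Transaction], config: MiningConfig | None = None
) -> list[ItemsetSupport]:
    """All itemsets of size 1..max_itemset_size with support >= min_support.

    Level-wise search: frequent k-itemsets are joined on a shared
    (k-1)-prefix to form (k+1)-candidates, and any candidate with an
    infrequent subset is pruned before counting (support is anti-monotone).
    Output is sorted by (size asc, support desc, lexicographic itemset).
    """
    config = config or MiningConfig()
    n = len(transactions)
    if n == 0:
        raise ValueError("support is undefined on an empty transaction list")
    min_count = config.min_support * n

    txn_sets = [t.items for t in transactions]
    counts_1: dict[str, int] = {}
    for t in txn_sets:
        for code in t:
            counts_1[code] = counts_1.get(code, 0) + 1
    frequent: dict[frozenset[str], int] = {
        frozenset([c]): k for c, k in counts_1.items() if k >= min_count
    }
    current = sorted(
        (tuple(sorted(s)) for s in frequent), key=lambda t: t
    )  # size-1 tuples
    size = 1
    while current and size < config.max_itemset_size:
        size += 1
        prev_frequent = {frozenset(t) for t in current}
        # join step: tuples sharing the first size-2 codes
        candidates: list[tuple[str, ...]] = []
        for i, a in enumerate(current):
            for b in current[i + 1 :]:
                if a[:-1] != b[:-1]:
                    break
                cand = a + (b[-1],)
                # prune: every (size-1)-subset must be frequent
                if all(
                    frozenset(cand[:j] + cand[j + 1 :]) in prev_frequent
                    for j in range(size)
                ):
                    candidates.append(cand)
        if not candidates:
            break
        cand_counts = {c: 0 for c in candidates}
        cand_index = set(candidates)
        for t in txn_sets:
            if len(t) < size:
                continue
            inter = sorted(c for c in t if frozenset([c]) in frequent or size == 1)
            if len(inter) < size:
                continue
            for combo in combinations(inter, size):
                if combo in cand_index:
                    cand_counts[combo] += 1
        current = sorted(c for c, k in cand_counts.items() if k >= min_count)
        for c in current:
            frequent[frozenset(c)] = cand_counts[c]

    out = [
        ItemsetSupport(items=s, support=k / n, count=k) for s, k in frequent.items()
    ]
    out.sort(key=_sort_key)
    return out


def compute_lift(confidence: float, consequent_support: float) -> float:
    """lift = confidence / support(consequent); 1 means independence."""
    if consequent_support <= 0:
        raise ValueError("lift undefined: consequent support must be positive")
    return confidence / consequent_support


def derive_rules(
    itemsets: Sequence[ItemsetSupport],
    transactions: Sequence[Transaction],
    config: MiningConfig | None = None,
) -> list[AssociationRule]:
    """Directional rules from frequent itemsets passing all three screens.

    For every frequent itemset of size >= 2 and every non-empty proper
    subset as antecedent, the rule is emitted iff confidence >=
    min_confidence AND lift > min_lift AND support >= min_support.  The
    screens are filters only: emitted metrics equal the unfiltered ones.
    """
    config = config or MiningConfig()
    support_map = {e.items: e.support for e in itemsets}
    rules: list[AssociationRule] = []
    for entry in itemsets:
        if len(entry.items) < 2 or entry.support < config.min_support:
            continue
        items = sorted(entry.items)
        for r in range(1, len(items)):
            for ante in combinations(items, r):
                a = frozenset(ante)
                b = entry.items - a
                sa = support_map.get(a)
                sb = support_map.get(b)
                if sa is None or sb is None:
                    # subsets of a frequent itemset are frequent; guard anyway
                    continue
                conf = entry.support / sa
                lift = compute_lift(conf, sb)
                if conf >= config.min_confidence and lift > config.min_lift:
                    rules.append(
                        AssociationRule(
                            antecedent=a,
                            consequent=b,
                            support=entry.support,
                            confidence=conf,
                            lift=lift,
                        )
                    )
    rules.sort(
        key=lambda r: (
            len(r.itemset),
            -r.support,
            tuple(sorted(r.itemset)),
            tuple(sorted(r.antecedent)),
        )
    )
    return rules


def top_combinations(
    rules: Sequence[AssociationRule], size: int, k: int
) -> list[CombinationRow]:
    """Collapse rule directions to unordered itemsets; rank and truncate.

    Each qualifying itemset of the requested size is reported once with
    its (union) support as the combination's prevalence and the metrics of
    the higher-confidence direction (tie: lexicographically smaller
    antecedent).  Ranked by support desc, then lift desc, then
    lexicographic itemset.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if size < 2:
        raise ValueError("combinations have size >= 2")
    best: dict[frozenset[str], AssociationRule] = {}
    for r in rules:
        if len(r.itemset) != size:
            continue
        cur = best.get(r.itemset)
        if (
            cur is None
            or r.confidence > cur.confidence
            or (
                r.confidence == cur.confidence
                and tuple(sorted(r.antecedent)) < tuple(sorted(cur.antecedent))
            )
        ):
            best[r.itemset] = r
    ranked = sorted(
        best.values(),
        key=lambda r: (-r.support, -r.lift, tuple(sorted(r.itemset))),
    )
    return [
        CombinationRow(
            rank=i + 1,
            items=tuple(sorted(r.itemset)),
            support=r.support,
            confidence=r.confidence,
            lift=r.lift,
            antecedent=tuple(sorted(r.antecedent)),
            consequent=tuple(sorted(r.consequent)),
        )
        for i, r in enumerate(ranked[:k])
    ]


def combinations_to_records(rows: Iterable[CombinationRow]) -> list[dict]:
    """Plain-dict view (items joined by '+', percentages at table precision)."""
    out = []
    for r in rows:
        out.append(
            {
                "rank": r.rank,
                "combination": "+".join(r.items),
                "prevalence_pct": round_half_up(100 * r.support, 1),
                "confidence_pct": round_half_up(100 * r.confidence, 1),
                "lift": round_half_up(r.lift, 1),
            }
        )
    return out


def single_item_supports(
    transactions: Sequence[Transaction],
) -> Mapping[str, float]:
    """Support of every individual item (no threshold)."""
    n = len(transactions)
    if n == 0:
        raise ValueError("support is undefined on an empty transaction list")
    counts: dict[str, int] = {}
    for t in transactions:
        for c in t.items:
            counts[c] = counts.get(c, 0) + 1
    return {c: k / n for c, k in counts.items()}
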