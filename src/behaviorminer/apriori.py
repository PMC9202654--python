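"""Apriori frequent-itemset mining and association-rule generation.

Implements level-wise Apriori over survey transaction databases: frequent
k-itemsets are built by joining frequent (k-1)-itemsets that share a
(k-2)-prefix under the canonical item order, candidates with any infrequent
(k-1)-subset are pruned (the anti-monotone / downward-closure property), and
supports are counted by a full scan per level with transaction pruning.

Interestingness metrics follow the classical definitions. For a rule
X -> Y over a database of n transactions:

    support(X -> Y)    = |{t : X ∪ Y ⊆ t}| / n
    confidence(X -> Y) = support(X ∪ Y) / support(X)
    lift(X -> Y)       = support(X ∪ Y) / (support(X) · support(Y))

Lift 1 indicates independence of X and Y; >1 positive association.

All threshold comparisons (min_support, min_confidence) are made on exact
count ratios via :class:`fractions.Fraction`, never on floats, so boundary
cases (a support of exactly 5%) are decided deterministically.

A brute-force enumerator over the full itemset lattice is provided as an
independent test oracle for small item universes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from .errors import ConfigurationError, ValidationError
from .survey_model import Item, SurveyDataset

#: An itemset is a canonically ordered, duplicate-free tuple of items in
#: which no two items share a question id.
Itemset = tuple[Item, ...]


def _threshold_fraction(x) -> Fraction:
    """Exact rational value of a threshold.

    Floats are read through their shortest decimal repr so that 0.05 means
    exactly 1/20 — otherwise a support of exactly 5% would fall on the wrong
    side of the binary-float value of 0.05.
    """
    if isinstance(x, Fraction):
        return x
    return Fraction(str(x))


def canonical_itemset(items: Iterable[Item]) -> Itemset:
    """Sort items canonically and validate the one-answer-per-question rule."""
    out = tuple(sorted(set(items)))
    qids = [it.question_id for it in out]
    if len(set(qids)) != len(qids):
        raise ValidationError(f"itemset has two answers to one question: {out}")
    return out


@dataclass(frozen=True)
class ItemsetRecord:
    itemset: Itemset
    count: int
    support: float

    def support_fraction(self, n: int) -> Fraction:
        return Fraction(self.count, n)


@dataclass(frozen=True)
class AssociationRule:
    """A mined rule X -> Y with its interestingness metrics.

    ``count`` is the number of transactions containing X ∪ Y; the integer
    counts of the antecedent and consequent are kept alongside the float
    metrics so that downstream comparisons can stay exact.
    """

    antecedent: Itemset
    consequent: Itemset
    count: int
    antecedent_count: int
    consequent_count: int
    n: int
    support: float
    confidence: float
    lift: float

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise ValidationError("rule sides must be non-empty")
        if set(self.antecedent) & set(self.consequent):
            raise ValidationError("antecedent and consequent overlap")

    @property
    def confidence_fraction(self) -> Fraction:
        return Fraction(self.count, self.antecedent_count)

    @property
    def lift_fraction(self) -> Fraction:
        return Fraction(self.count * self.n, self.antecedent_count * self.consequent_count)


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds and constraints for mining and rule generation.

    Defaults follow the study design: minimum support 5% and minimum
    confidence 68%, both inclusive. ``max_itemset_size`` optionally caps the
    pattern length. Role constraints restrict which questions may appear on
    each rule side; they apply at rule generation only (itemset mining is
    role-agnostic) and can be disabled with ``enforce_roles=False`` to count
    the unrestricted rule total over all possible consequents.
    """

    min_support: float = 0.05
    min_confidence: float = 0.68
    max_itemset_size: int | None = None
    antecedent_roles: tuple[str, ...] = ("antecedent", "both")
    consequent_roles: tuple[str, ...] = ("consequent", "both")
    enforce_roles: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_support <= 1:
            raise ConfigurationError(f"min_support {self.min_support} outside (0, 1]")
        if not 0 < self.min_confidence <= 1:
            raise ConfigurationError(
                f"min_confidence {self.min_confidence} outside (0, 1]"
            )
        if self.max_itemset_size is not None and self.max_itemset_size < 1:
            raise ConfigurationError("max_itemset_size must be >= 1")


# ---------------------------------------------------------------------------
# Support counting


def support_of(itemset: Sequence[Item], dataset: SurveyDataset) -> float:
    """Fraction of transactions containing the itemset; 1.0 for the empty set."""
    return support_count(itemset, dataset) / dataset.n


def support_count(itemset: Sequence[Item], dataset: SurveyDataset) -> int:
    target = frozenset(itemset)
    return sum(1 for t in dataset.transactions if target <= t.items)


# ---------------------------------------------------------------------------
# Level-wise Apriori


def _record_sort_key(rec: ItemsetRecord):
    # size ascending, support (count) descending, canonical itemset order
    return (len(rec.itemset), -rec.count, rec.itemset)


def _apriori_join(frequent_k: list[Itemset]) -> list[Itemset]:
    """Join frequent k-itemsets sharing a (k-1)-prefix into (k+1)-candidates."""
    candidates = []
    frequent_set = set(frequent_k)
    for i, a in enumerate(frequent_k):
        for b in frequent_k[i + 1:]:
            if a[:-1] != b[:-1]:
                # sorted list: once prefixes diverge, later b's diverge too
                break
            last_a, last_b = a[-1], b[-1]
            if last_a.question_id == last_b.question_id:
                continue  # would put two answers of one question together
            cand = a + (last_b,)
            # prune: every k-subset must be frequent
            if all(
                cand[:j] + cand[j + 1:] in frequent_set
                for j in range(len(cand) - 2)  # dropping last two is a/b themselves
            ):
                candidates.append(cand)
    return candidates


def mine_frequent_itemsets(
    dataset: SurveyDataset, config: MiningConfig
) -> list[ItemsetRecord]:
    """All itemsets with support >= min_support (and size <= the cap, if set).

    Output is sorted by (size ascending, support descending, canonical
    itemset order) and is deterministic for identical input.
    """
    n = dataset.n
    min_sup = _threshold_fraction(config.min_support)

    def min_count_ok(c: int) -> bool:
        return Fraction(c, n) >= min_sup

    # level 1: tally every observed item
    singleton_counts: dict[Item, int] = {}
    for t in dataset.transactions:
        for it in t.items:
            singleton_counts[it] = singleton_counts.get(it, 0) + 1
    counts: dict[Itemset, int] = {
        (it,): c for it, c in singleton_counts.items() if min_count_ok(c)
    }
    frequent_items = {it for (it,) in counts}

    # transaction pruning: restrict each transaction to frequent singletons
    db = [
        pruned
        for t in dataset.transactions
        if (pruned := frozenset(it for it in t.items if it in frequent_items))
    ]

    level = sorted(counts)
    k = 1
    while level:
        k += 1
        if config.max_itemset_size is not None and k > config.max_itemset_size:
            break
        candidates = _apriori_join(level)
        if not candidates:
            break
        cand_counts = dict.fromkeys(candidates, 0)
        cand_set = set(candidates)
        surviving_db = []
        for items in db:
            if len(items) < k:
                continue
            hit = False
            for cand in itertools.combinations(sorted(items), k):
                if cand in cand_set:
                    cand_counts[cand] += 1
                    hit = True
            if hit:
                surviving_db.append(items)
        db = surviving_db
        level = sorted(c for c in candidates if min_count_ok(cand_counts[c]))
        counts.update({c: cand_counts[c] for c in level})

    records = [
        ItemsetRecord(itemset=s, count=c, support=c / n) for s, c in counts.items()
    ]
    records.sort(key=_record_sort_key)
    return records


# ---------------------------------------------------------------------------
# Rule generation


def _rule_sort_key(rule: AssociationRule):
    return (
        -rule.count,  # support descending (same n throughout)
        -rule.confidence_fraction,
        -rule.lift_fraction,
        rule.antecedent,
        rule.consequent,
    )


def generate_rules(
    frequent: Sequence[ItemsetRecord],
    dataset: SurveyDataset,
    config: MiningConfig,
) -> list[AssociationRule]:
    """Association rules from frequent itemsets.

    For every frequent itemset Z with |Z| >= 2 and every non-empty proper
    subset A of Z, the rule A -> Z∖A is emitted when its confidence meets
    min_confidence and, if roles are enforced, every antecedent item comes
    from an antecedent-eligible question and every consequent item from a
    consequent-eligible one. Metrics are computed from the itemset supports
    already counted during mining.
    """
    n = dataset.n
    counts = {rec.itemset: rec.count for rec in frequent}
    min_conf = _threshold_fraction(config.min_confidence)
    codebook = dataset.codebook

    def roles_ok(itemset: Itemset, allowed: tuple[str, ...]) -> bool:
        return all(codebook.role_of(it.question_id) in allowed for it in itemset)

    rules = []
    for itemset, count in counts.items():
        if len(itemset) < 2:
            continue
        for r in range(1, len(itemset)):
            for ante in itertools.combinations(itemset, r):
                cons = tuple(it for it in itemset if it not in ante)
                c_ante = counts.get(ante)
                c_cons = counts.get(cons)
                if c_ante is None or c_cons is None:  # pragma: no cover
                    raise ConfigurationError(
                        "frequent collection is not downward closed; "
                        "was it produced by mine_frequent_itemsets on this dataset?"
                    )
                if Fraction(count, c_ante) < min_conf:
                    continue
                if config.enforce_roles and not (
                    roles_ok(ante, config.antecedent_roles)
                    and roles_ok(cons, config.consequent_roles)
                ):
                    continue
                rules.append(
                    AssociationRule(
                        antecedent=ante,
                        consequent=cons,
                        count=count,
                        antecedent_count=c_ante,
                        consequent_count=c_cons,
                        n=n,
                        support=count / n,
                        confidence=count / c_ante,
                        lift=count * n / (c_ante * c_cons),
                    )
                )
    rules.sort(key=_rule_sort_key)
    return rules


def mine_rules(dataset: SurveyDataset, config: MiningConfig) -> list[AssociationRule]:
    """Convenience: mine frequent itemsets then generate rules."""
    return generate_rules(mine_frequent_itemsets(dataset, config), dataset, config)


# ---------------------------------------------------------------------------
# Brute-force oracle


def brute_force_frequent_itemsets(
    dataset: SurveyDataset, config: MiningConfig, *, max_items: int = 20
) -> list[ItemsetRecord]:
    """Exhaustive frequent-itemset enumeration; the independent test oracle.

    Enumerates every non-empty itemset over the observed item universe and
    filters by min_support. Refuses universes above ``max_items`` distinct
    items to guard against exponential blowup. Same ordering contract as
    :func:`mine_frequent_itemsets`.
    """
    universe = sorted({it for t in dataset.transactions for it in t.items})
    if len(universe) > max_items:
        raise ValidationError(
            f"brute force refused: {len(universe)} distinct items > guard {max_items}"
        )
    n = dataset.n
    min_sup = _threshold_fraction(config.min_support)
    cap = config.max_itemset_size or len(universe)
    records = []
    for k in range(1, min(cap, len(universe)) + 1):
        for combo in itertools.combinations(universe, k):
            qids = {it.question_id for it in combo}
            if len(qids) < k:
                continue  # two answers to one question can never co-occur
            count = support_count(combo, dataset)
            if count and Fraction(count, n) >= min_sup:
                records.append(
                    ItemsetRecord(itemset=combo, count=count, support=count / n)
                )
    records.sort(key=_record_sort_key)
    return records


def brute_force_rules(
    dataset: SurveyDataset, config: MiningConfig, *, max_items: int = 20
) -> list[AssociationRule]:
    """Rule generation with every support recounted by direct scan.

    Independent of the Apriori path: itemsets come from the exhaustive
    enumerator and each rule's antecedent/consequent supports are recounted
    against the raw transactions.
    """
    frequent = brute_force_frequent_itemsets(dataset, config, max_items=max_items)
    n = dataset.n
    min_conf = _threshold_fraction(config.min_confidence)
    codebook = dataset.codebook
    rules = []
    for rec in frequent:
        if len(rec.itemset) < 2:
            continue
        for r in range(1, len(rec.itemset)):
            for ante in itertools.combinations(rec.itemset, r):
                cons = tuple(it for it in rec.itemset if it not in ante)
                c_ante = support_count(ante, dataset)
                c_cons = support_count(cons, dataset)
                if Fraction(rec.count, c_ante) < min_conf:
                    continue
                if config.enforce_roles and not all(
                    codebook.role_of(it.question_id) in config.antecedent_roles
                    for it in ante
                ):
                    continue
                if config.enforce_roles and not all(
                    codebook.role_of(it.question_id) in config.consequent_roles
                    for it in cons
                ):
                    continue
                rules.append(
                    AssociationRule(
                        antecedent=ante,
                        consequent=cons,
                        count=rec.count,
                        antecedent_count=c_ante,
                        consequent_count=c_cons,
                        n=n,
                        support=rec.count / n,
                        confidence=rec.count / c_ante,
                        lift=rec.count * n / (c_ante * c_cons),
                    )
                )
    rules.sort(key=_rule_sort_key)
    return rules
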