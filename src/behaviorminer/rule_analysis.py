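"""Post-mining analysis of protective-behavior rules.

Four questionnaire behaviors drive the analysis: keeping at least 1 m of
distance when out of the house, sanitizing/washing hands when out, only
leaving home when strictly necessary and masked, and continuing to go out
normally for work as usual. Mined rules are filtered by whether their
consequent mentions these behaviors and split into two groups — respondents
who kept going out normally versus respondents adopting at least one of the
three protective measures — and the cohort itself is partitioned into the
2^4 Venn cells defined by presence/absence of the four behavior items.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .apriori import AssociationRule
from .errors import ValidationError
from .survey_model import Item, SurveyDataset


@dataclass(frozen=True)
class BehaviorSpec:
    """The "yes" item of each of the four behavior questions."""

    distance_item: Item
    sanitize_item: Item
    mask_item: Item
    go_out_normally_item: Item

    def __post_init__(self) -> None:
        qids = {
            self.distance_item.question_id,
            self.sanitize_item.question_id,
            self.mask_item.question_id,
            self.go_out_normally_item.question_id,
        }
        if len(qids) != 4:
            raise ValidationError("behavior items must reference four distinct questions")

    @property
    def protective_items(self) -> tuple[Item, Item, Item]:
        return (self.distance_item, self.sanitize_item, self.mask_item)

    @property
    def all_items(self) -> tuple[Item, Item, Item, Item]:
        return (*self.protective_items, self.go_out_normally_item)

    def validate_against(self, dataset: SurveyDataset) -> None:
        for it in self.all_items:
            if it.question_id not in dataset.codebook:
                raise ValidationError(f"behavior question {it.question_id!r} not in codebook")
            dataset.codebook.validate_item(it)

    @classmethod
    def from_dict(cls, d: Mapping) -> "BehaviorSpec":
        def item(key: str) -> Item:
            v = d[key]
            return Item.parse(v) if isinstance(v, str) else Item(v["question"], v["answer"])

        return cls(
            distance_item=item("distance"),
            sanitize_item=item("sanitize"),
            mask_item=item("mask"),
            go_out_normally_item=item("go_out_normally"),
        )


@dataclass(frozen=True)
class RuleGroups:
    """Rules split by which behavior items their consequent mentions.

    ``group_continued``: consequent contains the go-out-normally item.
    ``group_protective``: consequent contains at least one of the three
    protective items. ``group_all_protective`` is the subset of the latter
    whose consequent contains all three. Rules mentioning no behavior item
    are discarded.
    """

    group_continued: tuple[AssociationRule, ...]
    group_protective: tuple[AssociationRule, ...]
    group_all_protective: tuple[AssociationRule, ...]

    @property
    def n_retained(self) -> int:
        # a rule may belong to both groups if its consequent mixes behaviors
        return len(set(self.group_continued) | set(self.group_protective))


def filter_rules_by_consequent(
    rules: Sequence[AssociationRule], spec: BehaviorSpec,
    dataset: Optional[SurveyDataset] = None,
) -> RuleGroups:
    """Partition rules into the two behavior groups by consequent content."""
    if dataset is not None:
        spec.validate_against(dataset)
    protective = set(spec.protective_items)
    continued, prot, all_prot = [], [], []
    for rule in rules:
        cons = set(rule.consequent)
        if spec.go_out_normally_item in cons:
            continued.append(rule)
        hits = cons & protective
        if hits:
            prot.append(rule)
            if len(hits) == 3:
                all_prot.append(rule)
    return RuleGroups(
        group_continued=tuple(continued),
        group_protective=tuple(prot),
        group_all_protective=tuple(all_prot),
    )


def rule_coverage(rule: AssociationRule, dataset: SurveyDataset) -> int:
    """Respondents covered by a rule: those containing antecedent ∪ consequent."""
    union = frozenset(rule.antecedent) | frozenset(rule.consequent)
    return sum(1 for t in dataset.transactions if union <= t.items)


# ---------------------------------------------------------------------------
# Venn partition

#: Cell profiles are 4-tuples of 0/1 flags in the fixed order
#: (distance, sanitize, mask, go_out_normally).
Profile = tuple[int, int, int, int]

PROFILE_ORDER = tuple(
    (d, s, m, g)
    for d in (0, 1) for s in (0, 1) for m in (0, 1) for g in (0, 1)
)


@dataclass(frozen=True)
class VennTable:
    """Counts over the 16 presence/absence profiles of the four behaviors."""

    cells: Mapping[Profile, int]
    n: int

    def __post_init__(self) -> None:
        if set(self.cells) != set(PROFILE_ORDER):
            raise ValidationError("Venn table must have exactly the 16 profiles")
        if any(c < 0 for c in self.cells.values()):
            raise ValidationError("negative Venn cell count")
        if sum(self.cells.values()) != self.n:
            raise ValidationError("Venn cells do not sum to n")

    def count(self, distance: bool, sanitize: bool, mask: bool, go_out: bool) -> int:
        return self.cells[(int(distance), int(sanitize), int(mask), int(go_out))]

    def to_frame(self, *, decimals: int = 1) -> pd.DataFrame:
        rows = [
            {
                "distance": p[0],
                "sanitize": p[1],
                "mask": p[2],
                "go_out_normally": p[3],
                "count": self.cells[p],
                "percent": float(format_percentage(self.cells[p], self.n, decimals)),
            }
            for p in PROFILE_ORDER
        ]
        return pd.DataFrame(rows)


def venn_partition(
    dataset: SurveyDataset,
    spec: BehaviorSpec,
    *,
    rules: Optional[Sequence[AssociationRule]] = None,
) -> VennTable:
    """Assign each respondent to one of the 16 behavior-profile cells.

    The partition is computed from respondent data directly. If ``rules``
    is given, only respondents covered by at least one of the rules are
    counted (the rule-covered reporting mode); otherwise all respondents.
    """
    spec.validate_against(dataset)
    transactions = dataset.transactions
    if rules is not None:
        unions = [frozenset(r.antecedent) | frozenset(r.consequent) for r in rules]
        transactions = tuple(
            t for t in transactions if any(u <= t.items for u in unions)
        )
    cells = {p: 0 for p in PROFILE_ORDER}
    d_it, s_it, m_it = spec.protective_items
    g_it = spec.go_out_normally_item
    for t in transactions:
        profile = (
            int(d_it in t.items),
            int(s_it in t.items),
            int(m_it in t.items),
            int(g_it in t.items),
        )
        cells[profile] += 1
    return VennTable(cells=cells, n=len(transactions))


# ---------------------------------------------------------------------------
# Reporting


def format_percentage(count: int, n: int, decimals: int = 1) -> str:
    """100·count/n as a string rounded half-up to ``decimals`` places.

    Half-up (not banker's) rounding matches conventional percentage
    reporting in survey tables. Computed in exact decimal arithmetic.
    """
    if n <= 0:
        raise ValidationError(f"n must be positive, got {n}")
    if not 0 <= count <= n:
        raise ValidationError(f"count {count} outside [0, {n}]")
    with decimal.localcontext() as ctx:
        ctx.prec = 50
        value = decimal.Decimal(100 * count) / decimal.Decimal(n)
        quantum = decimal.Decimal(1).scaleb(-decimals)
        return str(value.quantize(quantum, rounding=decimal.ROUND_HALF_UP))
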