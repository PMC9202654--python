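"""Readers and writers for the CSV/YAML/JSON interchange formats.

CSV is the interchange format between pipeline stages so any intermediate
can be inspected or swapped. Itemsets and rule sides are serialized as
semicolon-joined ``question=answer`` tokens.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .apriori import AssociationRule, ItemsetRecord, Itemset
from .errors import ValidationError
from .rule_analysis import BehaviorSpec, VennTable
from .survey_model import Codebook, Item

ITEM_SEP = ";"


def itemset_to_token(itemset: Itemset) -> str:
    return ITEM_SEP.join(str(it) for it in itemset)


def itemset_from_token(token: str) -> Itemset:
    from .apriori import canonical_itemset

    return canonical_itemset(Item.parse(t) for t in token.split(ITEM_SEP))


def read_responses(path) -> pd.DataFrame:
    """Read a respondent-by-question CSV (first column = respondent id)."""
    frame = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    return frame


def read_codebook(path) -> Codebook:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"codebook file {path} is not a mapping")
    return Codebook.from_dict(data)


def read_behavior_spec(path) -> BehaviorSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return BehaviorSpec.from_dict(data)


def write_itemsets_csv(records: Sequence[ItemsetRecord], path) -> None:
    pd.DataFrame(
        {
            "itemset": [itemset_to_token(r.itemset) for r in records],
            "size": [len(r.itemset) for r in records],
            "count": [r.count for r in records],
            "support": [r.support for r in records],
        }
    ).to_csv(path, index=False)


def rules_to_frame(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "antecedent": [itemset_to_token(r.antecedent) for r in rules],
            "consequent": [itemset_to_token(r.consequent) for r in rules],
            "count": [r.count for r in rules],
            "antecedent_count": [r.antecedent_count for r in rules],
            "consequent_count": [r.consequent_count for r in rules],
            "n": [r.n for r in rules],
            "support": [r.support for r in rules],
            "confidence": [r.confidence for r in rules],
            "lift": [r.lift for r in rules],
        }
    )


def write_rules_csv(rules: Sequence[AssociationRule], path) -> None:
    rules_to_frame(rules).to_csv(path, index=False)


def read_rules_csv(path) -> list[AssociationRule]:
    frame = pd.read_csv(path)
    rules = []
    for row in frame.to_dict("records"):
        count, c_ante, c_cons, n = (
            int(row["count"]), int(row["antecedent_count"]),
            int(row["consequent_count"]), int(row["n"]),
        )
        rules.append(
            AssociationRule(
                antecedent=itemset_from_token(row["antecedent"]),
                consequent=itemset_from_token(row["consequent"]),
                count=count,
                antecedent_count=c_ante,
                consequent_count=c_cons,
                n=n,
                support=count / n,
                confidence=count / c_ante,
                lift=count * n / (c_ante * c_cons),
            )
        )
    return rules


def write_rule_groups_csv(groups, path) -> None:
    """Rule CSV plus a ``group`` column; one row per (rule, group) membership."""
    frames = []
    for name, rules in (
        ("continued", groups.group_continued),
        ("protective", groups.group_protective),
        ("all_protective", groups.group_all_protective),
    ):
        if rules:
            f = rules_to_frame(rules)
            f.insert(0, "group", name)
            frames.append(f)
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = rules_to_frame([])
        out.insert(0, "group", pd.Series(dtype=str))
    out.to_csv(path, index=False)


def write_venn_csv(table: VennTable, path, *, decimals: int = 1) -> None:
    table.to_frame(decimals=decimals).to_csv(path, index=False)


def write_summary_csv(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
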