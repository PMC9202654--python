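"""Survey data model: codebooks, items, transactions and encoding.

A survey response table is turned into a *transaction database*: each
respondent becomes a set of (question, answer) pairs ("items"), the atomic
units over which frequent patterns and association rules are defined.
Questions carry a *role* deciding on which side of a rule their items may
appear: sociodemographic and work/economic questions are antecedent-eligible,
protective-behavior questions are consequent-eligible.

Also hosts the CCEB economic classification (Brazilian Economic
Classification Criteria): an integer score in [0, 46] mapped through
user-supplied cutoffs to one of six raw classes A, B1, B2, C1, C2, DE, then
through a merge map (default B1,B2 -> B and C1,C2 -> C) to the reported
class. The score-to-class cutoffs are revised periodically by ABEP and are
not hard-coded; they are mandatory configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from .errors import CodebookError, ConfigurationError, ValidationError

ROLES = ("antecedent", "consequent", "both", "excluded")
MISSING_POLICIES = ("omit_item", "explicit_missing_item")

#: Answer token emitted for missing cells under the ``explicit_missing_item``
#: policy, and the token the synthetic generator uses internally.
MISSING_TOKEN = "missing"


class Item(NamedTuple):
    """One (question, answer) pair; the atomic unit of patterns.

    Canonical total order is the tuple order: question_id first, then
    answer, both lexicographic. All downstream determinism rests on it.
    """

    question_id: str
    answer: str

    def __str__(self) -> str:  # "question=answer" token used in CSV output
        return f"{self.question_id}={self.answer}"

    @classmethod
    def parse(cls, token: str) -> "Item":
        q, sep, a = token.partition("=")
        if not sep or not q or not a:
            raise ValidationError(f"cannot parse item token {token!r}")
        return cls(q, a)


@dataclass(frozen=True)
class QuestionDef:
    question_id: str
    label: str
    allowed_answers: tuple[str, ...]
    role: str = "antecedent"

    def __post_init__(self) -> None:
        if not self.allowed_answers:
            raise CodebookError(
                f"question {self.question_id!r}: allowed_answers is empty"
            )
        if len(set(self.allowed_answers)) != len(self.allowed_answers):
            raise CodebookError(
                f"question {self.question_id!r}: duplicate allowed answers"
            )
        if self.role not in ROLES:
            raise CodebookError(
                f"question {self.question_id!r}: unknown role {self.role!r}"
            )


@dataclass(frozen=True)
class Codebook:
    """Ordered collection of question definitions plus the missing policy."""

    questions: tuple[QuestionDef, ...]
    missing_policy: str = "omit_item"

    def __post_init__(self) -> None:
        ids = [q.question_id for q in self.questions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CodebookError(f"duplicate question ids: {dupes}")
        if self.missing_policy not in MISSING_POLICIES:
            raise CodebookError(f"unknown missing_policy {self.missing_policy!r}")
        roles = {q.role for q in self.questions}
        if not roles & {"antecedent", "both"}:
            raise CodebookError("codebook has no antecedent-eligible question")
        if not roles & {"consequent", "both"}:
            raise CodebookError("codebook has no consequent-eligible question")

    def __getitem__(self, question_id: str) -> QuestionDef:
        try:
            return self._by_id[question_id]
        except KeyError:
            raise CodebookError(f"unknown question id {question_id!r}") from None

    def __contains__(self, question_id: str) -> bool:
        return question_id in self._by_id

    @property
    def _by_id(self) -> dict[str, QuestionDef]:
        # cached on first use; frozen dataclass, so stash via object.__setattr__
        cache = self.__dict__.get("_by_id_cache")
        if cache is None:
            cache = {q.question_id: q for q in self.questions}
            object.__setattr__(self, "_by_id_cache", cache)
        return cache

    def role_of(self, question_id: str) -> str:
        return self[question_id].role

    def validate_item(self, item: Item) -> None:
        q = self[item.question_id]
        if item.answer == MISSING_TOKEN and self.missing_policy == "explicit_missing_item":
            return
        if item.answer not in q.allowed_answers:
            raise ValidationError(
                f"answer {item.answer!r} not allowed for question {item.question_id!r}"
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "Codebook":
        try:
            questions = tuple(
                QuestionDef(
                    question_id=str(q["id"]),
                    label=str(q.get("label", q["id"])),
                    allowed_answers=tuple(str(a) for a in q["answers"]),
                    role=str(q.get("role", "antecedent")),
                )
                for q in d["questions"]
            )
        except KeyError as exc:
            raise CodebookError(f"codebook mapping missing key: {exc}") from None
        return cls(questions=questions, missing_policy=str(d.get("missing_policy", "omit_item")))

    def to_dict(self) -> dict:
        return {
            "missing_policy": self.missing_policy,
            "questions": [
                {
                    "id": q.question_id,
                    "label": q.label,
                    "answers": list(q.allowed_answers),
                    "role": q.role,
                }
                for q in self.questions
            ],
        }


@dataclass(frozen=True)
class Transaction:
    """One respondent's item set at one timepoint.

    At most one item per question: a respondent answers each question once.
    """

    respondent_id: str
    timepoint: str
    items: frozenset[Item]

    def __post_init__(self) -> None:
        qids = [it.question_id for it in self.items]
        if len(set(qids)) != len(qids):
            raise ValidationError(
                f"respondent {self.respondent_id!r}: multiple answers to one question"
            )

    def sorted_items(self) -> tuple[Item, ...]:
        return tuple(sorted(self.items))


@dataclass(frozen=True)
class SurveyDataset:
    """The transaction database over which supports are computed."""

    codebook: Codebook
    transactions: tuple[Transaction, ...]

    def __post_init__(self) -> None:
        if not self.transactions:
            raise ValidationError("dataset has no transactions")
        for t in self.transactions:
            for it in t.items:
                self.codebook.validate_item(it)

    @property
    def n(self) -> int:
        return len(self.transactions)


# ---------------------------------------------------------------------------
# CCEB economic classification


@dataclass(frozen=True)
class CCEBConfig:
    """Score-to-class cutoffs for the 0-46 CCEB score.

    ``cutoffs`` maps inclusive integer intervals ``(lo, hi)`` to a raw class
    token; the intervals must partition [0, 46]. ``merge_map`` folds raw
    classes into reported ones (default: B1,B2 -> B; C1,C2 -> C).
    """

    cutoffs: tuple[tuple[int, int, str], ...]
    merge_map: Mapping[str, str] = field(
        default_factory=lambda: {
            "A": "A", "B1": "B", "B2": "B", "C1": "C", "C2": "C", "DE": "DE",
        }
    )

    def __post_init__(self) -> None:
        covered = sorted(self.cutoffs)
        expect = 0
        for lo, hi, cls in covered:
            if lo != expect or hi < lo:
                raise ConfigurationError(
                    f"CCEB cutoffs do not partition [0, 46]: gap/overlap at {lo}"
                )
            if cls not in self.merge_map:
                raise ConfigurationError(f"raw class {cls!r} missing from merge_map")
            expect = hi + 1
        if expect != 47:
            raise ConfigurationError("CCEB cutoffs do not cover up to 46")


def cceb_class(score: int, config: CCEBConfig) -> str:
    """Map a CCEB score to its reported (merged) economic class."""
    if not isinstance(score, int) or isinstance(score, bool):
        raise ValidationError(f"CCEB score must be an integer, got {score!r}")
    if not 0 <= score <= 46:
        raise ValidationError(f"CCEB score {score} outside [0, 46]")
    for lo, hi, raw in config.cutoffs:
        if lo <= score <= hi:
            return config.merge_map[raw]
    raise ConfigurationError(f"no cutoff interval covers score {score}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Encoding and summary


def _is_missing(value) -> bool:
    return pd.isna(value) or (isinstance(value, str) and value.strip() == "")


def encode_transactions(
    raw_table: pd.DataFrame,
    codebook: Codebook,
    *,
    timepoint: str = "T1",
    ignore_columns: Iterable[str] = (),
) -> SurveyDataset:
    """Encode a respondent-by-question categorical table into transactions.

    One transaction per row. Missing cells (NaN or empty string) are handled
    per the codebook's missing policy: ``omit_item`` emits no item,
    ``explicit_missing_item`` emits an item with the answer token "missing".

    Raises :class:`CodebookError` for a column with no codebook question and
    :class:`ValidationError` for an illegal answer (naming row and column) or
    an empty table.
    """
    if raw_table.shape[0] == 0:
        raise ValidationError("input table has no rows; a dataset must be non-empty")
    ignore = set(ignore_columns)
    columns = [c for c in raw_table.columns if c not in ignore]
    for col in columns:
        if col not in codebook:
            raise CodebookError(f"column {col!r} has no codebook question")

    explicit = codebook.missing_policy == "explicit_missing_item"
    transactions = []
    for pos, (row_label, row) in enumerate(raw_table.iterrows()):
        items = []
        for col in columns:
            value = row[col]
            if _is_missing(value):
                if explicit:
                    items.append(Item(col, MISSING_TOKEN))
                continue
            answer = str(value)
            if answer not in codebook[col].allowed_answers:
                raise ValidationError(
                    f"row {row_label!r}, column {col!r}: answer {answer!r} "
                    f"not in allowed answers"
                )
            items.append(Item(col, answer))
        transactions.append(
            Transaction(
                respondent_id=str(row_label) if row_label is not None else str(pos),
                timepoint=timepoint,
                items=frozenset(items),
            )
        )
    return SurveyDataset(codebook=codebook, transactions=tuple(transactions))


def dataset_summary(dataset: SurveyDataset, *, decimals: int = 1) -> pd.DataFrame:
    """Per-question answer counts and percentages, including a missing row.

    For every question, the answer counts plus the missing count sum to the
    number of transactions n; percentages are 100 * count / n rounded
    half-up to ``decimals`` places.
    """
    from .rule_analysis import format_percentage  # local import: avoid cycle

    n = dataset.n
    counts: dict[tuple[str, str], int] = {}
    for t in dataset.transactions:
        for it in t.items:
            counts[it] = counts.get(it, 0) + 1

    rows = []
    for q in dataset.codebook.questions:
        answered = 0
        for answer in q.allowed_answers:
            c = counts.get((q.question_id, answer), 0)
            answered += c
            rows.append((q.question_id, answer, c))
        explicit_missing = counts.get((q.question_id, MISSING_TOKEN), 0)
        rows.append((q.question_id, MISSING_TOKEN, n - answered))
        # under explicit_missing_item the emitted missing items must agree
        if dataset.codebook.missing_policy == "explicit_missing_item":
            assert explicit_missing == n - answered
    frame = pd.DataFrame(rows, columns=["question_id", "answer", "count"])
    frame["percent"] = [
        float(format_percentage(int(c), n, decimals)) for c in frame["count"]
    ]
    return frame
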