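"""Shared fixtures: tiny hand-checkable datasets and seeded random cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from behaviorminer import (
    Codebook,
    Item,
    QuestionDef,
    SurveyDataset,
    Transaction,
)


def make_dataset(codebook: Codebook, itemsets, timepoint: str = "T1") -> SurveyDataset:
    """Build a dataset from an iterable of item collections, one per respondent."""
    transactions = tuple(
        Transaction(
            respondent_id=f"r{i}",
            timepoint=timepoint,
            items=frozenset(items),
        )
        for i, items in enumerate(itemsets)
    )
    return SurveyDataset(codebook=codebook, transactions=transactions)


@pytest.fixture
def abc_codebook() -> Codebook:
    """Three single-answer questions a, b, c usable on either rule side."""
    return Codebook(
        questions=tuple(
            QuestionDef(q, q, allowed_answers=("1",), role="both") for q in "abc"
        )
    )


@pytest.fixture
def abc_dataset(abc_codebook) -> SurveyDataset:
    """Five transactions {abc, ab, ac, bc, abc}: the hand-enumerated example."""
    rows = ["abc", "ab", "ac", "bc", "abc"]
    return make_dataset(
        abc_codebook, [[Item(q, "1") for q in row] for row in rows]
    )


@pytest.fixture
def mask_codebook() -> Codebook:
    return Codebook(
        questions=(
            QuestionDef("gender", "gender", ("female", "male"), role="antecedent"),
            QuestionDef("mask", "wears mask out of home", ("yes", "no"), role="consequent"),
        )
    )


@pytest.fixture
def mask70_dataset(mask_codebook) -> SurveyDataset:
    """100 respondents, 70 of whom carry mask=yes: the toy support database."""
    rows = [[Item("mask", "yes" if i < 70 else "no")] for i in range(100)]
    return make_dataset(mask_codebook, rows)


def random_dataset(
    seed: int,
    *,
    n_questions: int = 5,
    n_answers: int = 3,
    n_transactions: int = 40,
    answer_drop: float = 0.2,
) -> SurveyDataset:
    """Seeded random survey dataset for oracle-equivalence sweeps.

    Each question gets up to ``n_answers`` answer tokens; each respondent
    answers each question with probability 1 - answer_drop, choosing an
    answer non-uniformly so supports spread across the threshold.
    """
    rng = np.random.default_rng(seed)
    qids = [f"q{j}" for j in range(n_questions)]
    roles = ["antecedent", "consequent", "both"]
    codebook = Codebook(
        questions=tuple(
            QuestionDef(
                qid,
                qid,
                tuple(f"a{k}" for k in range(int(rng.integers(2, n_answers + 1)))),
                role=roles[j % 3] if n_questions >= 3 else "both",
            )
            for j, qid in enumerate(qids)
        )
    )
    rows = []
    for _ in range(int(rng.integers(5, n_transactions + 1))):
        items = []
        for q in codebook.questions:
            if rng.random() < answer_drop:
                continue
            m = len(q.allowed_answers)
            weights = np.arange(m, 0, -1, dtype=float)
            weights /= weights.sum()
            answer = q.allowed_answers[rng.choice(m, p=weights)]
            items.append(Item(q.question_id, answer))
        rows.append(items)
    return make_dataset(codebook, rows)
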