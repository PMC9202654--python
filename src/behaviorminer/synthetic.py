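"""Seeded synthetic survey cohorts with plantable rule structure.

Real respondent-level data for this kind of web survey are rarely
deposited, so the pipeline is exercised on synthetic cohorts drawn from a
latent-class model: each respondent samples a class from the mixture
weights, then answers every question independently from that class's
answer distribution (which may include a "missing" mass). On top of the
mixture, *planted rules* inject exact antecedent→consequent dependencies:
for each respondent the antecedent answers are overwritten with the
configured prevalence, and among antecedent carriers the consequent answers
are overwritten with the configured confidence — giving ground truth whose
recovery by the mining pipeline can be asserted.

``default_t1_profile`` is a single-class specification whose per-question
marginals equal the first-round (May–June 2020, N=7802) answer frequencies
of the Brazilian COVID-19 behavior survey this package models: 11
sociodemographic questions, 11 work-situation/economic-perception
questions, and the 4 precautionary-behavior questions. Marginals are built
from the published integer counts, so they are exact rather than
rounded-percentage approximations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .apriori import Itemset, canonical_itemset
from .errors import SpecificationError
from .survey_model import (
    MISSING_TOKEN,
    Codebook,
    Item,
    QuestionDef,
    SurveyDataset,
    encode_transactions,
)

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class LatentClassSpec:
    """Finite mixture over respondent classes with per-class answer profiles.

    ``profiles[k][question_id]`` maps each answer token (plus optionally
    ``"missing"``) to its probability in class k; every such distribution
    must sum to 1 within 1e-9.
    """

    class_weights: tuple[float, ...]
    profiles: tuple[Mapping[str, Mapping[str, float]], ...]

    def __post_init__(self) -> None:
        if len(self.class_weights) != len(self.profiles):
            raise SpecificationError("one profile per class weight required")
        if any(w < 0 for w in self.class_weights):
            raise SpecificationError("class weights must be non-negative")
        if abs(sum(self.class_weights) - 1.0) > _SUM_TOL:
            raise SpecificationError("class weights must sum to 1")
        qids = set(self.profiles[0])
        for prof in self.profiles:
            if set(prof) != qids:
                raise SpecificationError("all classes must cover the same questions")
            for qid, dist in prof.items():
                if any(p < 0 for p in dist.values()):
                    raise SpecificationError(f"negative probability for {qid!r}")
                if abs(sum(dist.values()) - 1.0) > _SUM_TOL:
                    raise SpecificationError(
                        f"answer distribution for {qid!r} does not sum to 1"
                    )

    @property
    def question_ids(self) -> tuple[str, ...]:
        return tuple(self.profiles[0])

    def marginal(self, question_id: str, answer: str) -> float:
        """Analytic (pre-sampling) marginal probability of one answer."""
        return sum(
            w * prof[question_id].get(answer, 0.0)
            for w, prof in zip(self.class_weights, self.profiles)
        )


@dataclass(frozen=True)
class PlantedRuleSpec:
    """Ground-truth dependency injected into a synthetic cohort."""

    antecedent: Itemset
    consequent: Itemset
    target_confidence: float
    antecedent_prevalence: float

    def __post_init__(self) -> None:
        if not 0 < self.target_confidence <= 1:
            raise SpecificationError("target_confidence must be in (0, 1]")
        if not 0 < self.antecedent_prevalence < 1:
            raise SpecificationError("antecedent_prevalence must be in (0, 1)")
        canonical_itemset(self.antecedent + self.consequent)  # no shared question


@dataclass(frozen=True)
class SyntheticConfig:
    codebook: Codebook
    spec: LatentClassSpec
    n: int
    seed: int
    planted: tuple[PlantedRuleSpec, ...] = ()
    timepoint: str = "T1"

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise SpecificationError("cohort size n must be positive")
        cb_qids = {q.question_id for q in self.codebook.questions}
        if set(self.spec.question_ids) - cb_qids:
            raise SpecificationError("latent-class spec references unknown questions")
        touched: dict[str, str] = {}
        for rule in self.planted:
            for it in rule.antecedent + rule.consequent:
                if it.question_id not in cb_qids:
                    raise SpecificationError(
                        f"planted item references unknown question {it.question_id!r}"
                    )
                prev = touched.get(it.question_id)
                if prev is not None and prev != it.answer:
                    raise SpecificationError(
                        f"planted rules conflict on question {it.question_id!r}"
                    )
                touched[it.question_id] = it.answer


def _alternative_answer(codebook: Codebook, item: Item) -> str:
    """First allowed answer different from the item's — used to force absence."""
    for a in codebook[item.question_id].allowed_answers:
        if a != item.answer:
            return a
    raise SpecificationError(
        f"question {item.question_id!r} has no alternative to {item.answer!r}; "
        "cannot plant a probabilistic dependency on it"
    )


def simulate_responses(config: SyntheticConfig) -> tuple[pd.DataFrame, dict]:
    """Draw a raw response table plus a ground-truth metadata sidecar.

    One pseudo-random stream is consumed in a fixed order — class labels,
    then each question in spec order, then per planted rule the prevalence
    and confidence draws — so a fixed seed reproduces the cohort bit for
    bit on any platform.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    weights = np.asarray(config.spec.class_weights, dtype=float)
    classes = np.searchsorted(np.cumsum(weights), rng.random(n), side="right")
    classes = np.minimum(classes, len(weights) - 1)

    columns: dict[str, np.ndarray] = {}
    for qid in config.spec.question_ids:
        allowed = config.codebook[qid].allowed_answers
        tokens = list(allowed) + [MISSING_TOKEN]
        # per-class cumulative distribution in fixed token order
        cum = np.empty((len(weights), len(tokens)))
        for k, prof in enumerate(config.spec.profiles):
            probs = np.array([prof[qid].get(tok, 0.0) for tok in tokens])
            cum[k] = np.cumsum(probs)
        u = rng.random(n)
        idx = np.empty(n, dtype=int)
        for k in range(len(weights)):
            mask = classes == k
            idx[mask] = np.searchsorted(cum[k], u[mask], side="right")
        idx = np.minimum(idx, len(tokens) - 1)
        columns[qid] = np.array(tokens, dtype=object)[idx]

    for rule in config.planted:
        carrier = rng.random(n) < rule.antecedent_prevalence
        for it in rule.antecedent:
            alt = _alternative_answer(config.codebook, it)
            col = columns[it.question_id]
            col[carrier] = it.answer
            col[~carrier & (col == it.answer)] = alt
        follow = rng.random(n) < rule.target_confidence
        for it in rule.consequent:
            alt = _alternative_answer(config.codebook, it)
            col = columns[it.question_id]
            col[carrier & follow] = it.answer
            col[carrier & ~follow] = alt

    frame = pd.DataFrame(columns)
    frame = frame.mask(frame == MISSING_TOKEN, "")
    width = len(str(n - 1))
    frame.index = pd.Index(
        [f"r{i:0{width}d}" for i in range(n)], name="respondent_id"
    )
    metadata = {
        "seed": config.seed,
        "n": n,
        "timepoint": config.timepoint,
        "class_weights": list(config.spec.class_weights),
        "planted": [
            {
                "antecedent": [str(it) for it in r.antecedent],
                "consequent": [str(it) for it in r.consequent],
                "target_confidence": r.target_confidence,
                "antecedent_prevalence": r.antecedent_prevalence,
            }
            for r in config.planted
        ],
        # planting overwrites answers, so the marginals of the touched
        # questions deviate from the latent-class configuration
        "marginals_distorted_by_planting": sorted(
            {
                it.question_id
                for r in config.planted
                for it in r.antecedent + r.consequent
            }
        ),
    }
    return frame, metadata


def simulate_survey(config: SyntheticConfig) -> SurveyDataset:
    """Sample a cohort and encode it into a transaction database."""
    frame, _ = simulate_responses(config)
    return encode_transactions(frame, config.codebook, timepoint=config.timepoint)


def write_cohort(config: SyntheticConfig, csv_path, sidecar_path=None) -> None:
    frame, metadata = simulate_responses(config)
    frame.to_csv(csv_path)
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(metadata, fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Default first-round (T1) cohort profile
#
# Published answer counts at the first collection round (N=7802). Counts,
# not rounded percentages, so each question's distribution is exact.
# The four behavior questions have no missing row; for the others the
# "missing" mass is the published Missing count.

T1_N = 7802

_T1_COUNTS: dict[str, dict[str, int]] = {
    # --- sociodemographic (antecedent-eligible) ---
    "gender": {"female": 5366, "male": 1148, MISSING_TOKEN: 1288},
    "age_group": {
        "18-19": 98, "20-29": 1188, "30-39": 1601, "40-49": 1464,
        "50-59": 1133, "60-69": 599, "70-90": 118, MISSING_TOKEN: 1601,
    },
    "education": {
        "no_schooling": 21, "doctorate": 429, "elementary_diploma": 232,
        "incomplete_elementary": 91, "high_school_diploma": 1871,
        "masters": 638, "higher_education": 3079, MISSING_TOKEN: 1441,
    },
    "ethnicity": {
        "asian": 108, "white": 3128, "indigenous": 20, "brown": 1173,
        "black": 244, MISSING_TOKEN: 3129,
    },
    "marital_status": {
        "married_cohabitation": 3206, "divorced": 801, "single": 2204,
        "widowed": 33, MISSING_TOKEN: 1558,
    },
    "work_type": {
        "full_time_employee": 1279, "self_employed": 947, "unemployed": 1431,
        "liberal_professional": 735, "public_servant": 1871, MISSING_TOKEN: 1539,
    },
    "economic_class": {
        "A": 889, "B": 2435, "C": 1242, "DE": 125, MISSING_TOKEN: 3111,
    },
    "household_income": {
        "<=500": 105, "501-1000": 235, "1001-1500": 349, "1501-2000": 368,
        "2001-2500": 267, "2501-3000": 382, "3001-4000": 417,
        "4001-5000": 429, "5001-10000": 970, "10001-25000": 765,
        ">=25001": 269, MISSING_TOKEN: 3246,
    },
    "household_size": {
        "1": 470, "2": 1286, "3-5": 2557, "6+": 172, MISSING_TOKEN: 3317,
    },
    "maternal_education": {
        "no_schooling_incomplete_elementary": 769, "elementary_diploma": 1085,
        "junior_high_diploma": 541, "high_school_diploma": 1149,
        "higher_education": 1099, MISSING_TOKEN: 3159,
    },
    "region": {
        "north": 273, "northeast": 961, "central_west": 362,
        "southeast": 3624, "south": 1076, MISSING_TOKEN: 1506,
    },
    # --- work situation & economic perception (antecedent-eligible) ---
    "feels_more_productive": {"no": 7126, "yes": 676},
    "feels_less_productive": {"no": 5616, "yes": 2186},
    "worked_from_home_before": {"no": 7423, "yes": 379},
    "home_office": {"no": 5110, "yes": 2692},
    "video_calls": {"no": 5144, "yes": 2658},
    "reduced_hours": {"no": 6999, "yes": 803},
    "waiting_rules_suspension": {"no": 7213, "yes": 589},
    "must_leave_home_afraid": {"no": 6981, "yes": 821},
    "afraid_financial_difficulties": {"no": 5663, "yes": 2139},
    "economy_recover_soon": {"no": 5791, "yes": 2011},
    "economy_recover_late": {"no": 4347, "yes": 3455},
    # --- precautionary behaviors (consequent-eligible) ---
    "distance": {"no": 3277, "yes": 4525},
    "sanitize": {"no": 2939, "yes": 4863},
    "mask": {"no": 2818, "yes": 4984},
    "go_out_normally": {"no": 7679, "yes": 123},
}

_CONSEQUENT_QUESTIONS = ("distance", "sanitize", "mask", "go_out_normally")

_T1_LABELS = {
    "distance": "Stays at least 1 m apart from people when out of the house",
    "sanitize": "Sanitizes hands with alcohol gel or washes hands when out of the house",
    "mask": "Only leaves home when extremely necessary and wearing a face covering",
    "go_out_normally": "Keeps moving outdoors (leaving home) for work as usual",
}


def default_t1_codebook(missing_policy: str = "omit_item") -> Codebook:
    """Codebook of the 26 modelled questions with their rule roles."""
    questions = tuple(
        QuestionDef(
            question_id=qid,
            label=_T1_LABELS.get(qid, qid.replace("_", " ")),
            allowed_answers=tuple(a for a in dist if a != MISSING_TOKEN),
            role="consequent" if qid in _CONSEQUENT_QUESTIONS else "antecedent",
        )
        for qid, dist in _T1_COUNTS.items()
    )
    return Codebook(questions=questions, missing_policy=missing_policy)


def default_t1_profile() -> LatentClassSpec:
    """Single-class spec with the first-round answer frequencies as marginals."""
    profile = {}
    for qid, dist in _T1_COUNTS.items():
        total = sum(dist.values())
        if total != T1_N:
            raise SpecificationError(  # pragma: no cover - frozen table
                f"calibration counts for {qid!r} sum to {total}, expected {T1_N}"
            )
        profile[qid] = {a: c / T1_N for a, c in dist.items()}
    return LatentClassSpec(class_weights=(1.0,), profiles=(profile,))


def default_t1_behavior_items() -> dict[str, Item]:
    """The four behavior "yes" items of the default codebook."""
    return {qid: Item(qid, "yes") for qid in _CONSEQUENT_QUESTIONS}


def default_t1_config(
    n: int = T1_N, seed: int = 0, planted: Sequence[PlantedRuleSpec] = ()
) -> SyntheticConfig:
    return SyntheticConfig(
        codebook=default_t1_codebook(),
        spec=default_t1_profile(),
        n=n,
        seed=seed,
        planted=tuple(planted),
        timepoint="T1",
    )
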