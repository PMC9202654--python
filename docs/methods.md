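# Methods

## Data model

A survey response table (one row per respondent, one categorical column per
question) is encoded against a codebook into a transaction database. The
atomic unit is the **item**, a `(question_id, answer)` pair; a respondent's
**transaction** is their set of items at one timepoint, with at most one
item per question. Items carry a canonical total order — `question_id`
first, then `answer`, both lexicographic — and every itemset, rule side and
output ordering in the package is defined in terms of it, which makes all
stages byte-deterministic for identical inputs.

Missing answers default to the `omit_item` policy: no item is emitted, so a
pattern's support is defined over *present* answers only. The alternative
`explicit_missing_item` policy emits an item with the answer token
`missing`, which lets per-question summary tables reproduce a published
"Missing" row. Whether the original analyses dropped incomplete respondents
or treated missingness as absence is generally unstated in survey reports;
`omit_item` keeps the support semantics clean and is the default.

Timepoints are separate datasets. Cross-sectional rounds of a repeated
survey are mined independently; the package never pools transactions across
timepoints.

The CCEB (Brazilian Economic Classification Criteria) score is an integer
in [0, 46] mapped to raw classes A, B1, B2, C1, C2, DE and then merged
(B1,B2 → B; C1,C2 → C by default). The score-to-class cutoffs are revised
periodically by ABEP and are **not** hard-coded: `CCEBConfig` requires the
user to supply intervals that partition [0, 46], and validates the
partition. Class A here is the top class; household income per class is
documentation, not computation.

## Mining

`mine_frequent_itemsets` is classical level-wise Apriori. Frequent
1-itemsets are tallied directly; frequent (k+1)-candidates are produced by
joining frequent k-itemsets that share a (k−1)-prefix under the canonical
order, skipping joins that would put two answers of one question in the
same pattern, and pruning any candidate with an infrequent k-subset
(downward closure). Supports are counted by a scan per level; transactions
that contain no surviving candidate are dropped from subsequent levels
(they cannot contain a longer candidate, since every frequent k-subset of
a (k+1)-candidate was itself a candidate). This is adequate at survey scale
(~10⁴ respondents, ~60 items); no FP-Growth/Eclat variant is provided.

`generate_rules` emits, for every frequent itemset Z with |Z| ≥ 2 and every
non-empty proper subset A ⊂ Z, the rule A → Z∖A when its confidence meets
the threshold. All metrics come from the itemset counts already gathered
during mining, so a rule's support/confidence/lift are exact integer-count
ratios rendered to float only at the boundary.

Numerical choices:

* **Thresholds are inclusive** (≥ 5% support, ≥ 68% confidence): the
  parameters are *minimums*.
* **Minimum support applies to the union A∪C** of a rule — the standard
  Apriori reading, since rules are enumerated from frequent itemsets.
* **Threshold comparisons use rational arithmetic.** A float threshold is
  read through its shortest decimal representation (`0.05` means exactly
  1/20) and compared with `Fraction(count, n)`, so a support of exactly 5%
  is frequent on every platform. Float equality never decides inclusion.
* **Role constraints are applied at rule generation, not mining.** The
  itemset lattice is role-agnostic; `enforce_roles=False` reproduces the
  unrestricted "all possible consequents" rule total. Restricting the
  lattice itself would change supports of mixed patterns and is never done.
* **Ordering.** Itemsets: size ascending, support descending, canonical
  order. Rules: support, then confidence, then lift (all descending, all
  compared as exact fractions), then canonical antecedent/consequent order.

`brute_force_frequent_itemsets` and `brute_force_rules` enumerate the full
itemset lattice (guarded to ≤ 20 distinct items) and recount every support
by direct containment scans. They share no code path with the level-wise
miner beyond the dataset container and serve as the independent oracle in
the test suite.

## Behavior groups and the Venn partition

Four behavior items (the "yes" answers of the distance, sanitize, mask and
go-out-normally questions) drive the post-mining analysis. Rules are
grouped by **consequent containment only** — the antecedent is ignored when
deciding group membership: `group_continued` holds rules whose consequent
contains the go-out item, `group_protective` those containing at least one
of the three protective items, and `group_all_protective` the subset
containing all three. Rules mentioning no behavior item are discarded. A
rule whose consequent mixes the go-out item with protective items would
belong to both groups; group counts are therefore reported per group, not
assumed disjoint.

A respondent is **covered** by a rule when their transaction contains the
rule's antecedent ∪ consequent — the same containment that defines the
rule's support, so coverage/n equals support exactly.

The Venn table assigns each respondent to one of the 2⁴ = 16 cells defined
by presence/absence of the four behavior items, computed from respondent
data directly and independent of any mined rules. A second mode restricts
the partition to respondents covered by at least one of a supplied rule
set, for reporting tied to the mined rules; which mode a published figure
used is often ambiguous, so both are provided. Cells always sum to the
number of partitioned respondents.

Percentages everywhere are formatted by exact decimal arithmetic with
**half-up** rounding (not banker's), matching conventional survey-table
reporting; `100·45/7802` prints as `0.6`, `100·11/32877` at two decimals as
`0.03`.

## Synthetic cohorts

The generator samples from a finite mixture ("latent classes"): each
respondent draws a class from the mixture weights, then answers every
question independently from that class's answer distribution, which may
include a `missing` mass. A single `numpy` PRNG stream (PCG64, seeded) is
consumed in a fixed order — class labels, then each question in spec order,
then the planted-rule draws — so a configuration reproduces its cohort bit
for bit across platforms.

`default_t1_profile` is a single-class specification calibrated to the
published first-round answer frequencies of the Brazilian COVID-19 behavior
survey this package models (N=7802): 11 sociodemographic questions, 11
work-situation/economic-perception questions and the 4 behavior questions.
It is built from the published integer counts rather than the rounded
percentages, so every configured marginal is exact (counts per question sum
to 7802, enforced at construction). Two further work-area variables of the
original instrument are not representable here: average daily hours worked
is continuous, and the retiree/businessperson work types were only surveyed
at the second round. The published tables report only marginals, so the
single-class default has no dependence between questions; multi-class
specifications are the supported way to induce realistic correlation, and
the class count/profiles of any such spec are a modelling convenience, not
an estimate.

**Planted rules** inject ground-truth dependencies by post-hoc overwrite:
for each respondent a Bernoulli(prevalence) draw decides whether the
antecedent answers are written in (or, if present by chance, replaced by an
alternative answer); among antecedent carriers a Bernoulli(confidence) draw
decides whether the consequent answers are written in or forced out. Both
the antecedent prevalence and the conditional frequency of the consequent
therefore hit their targets exactly in expectation, at the cost of
distorting the touched questions' marginals away from the latent-class
configuration; the affected question ids are recorded in the cohort's JSON
sidecar. Joint-distribution construction would avoid the distortion but
gives only indirect control of the planted confidence. Planted rules that
assign conflicting answers to one question are rejected at configuration
time.

What passing tests on these cohorts do and do not show: marginal
calibration and planted-rule recovery demonstrate that the pipeline
measures what was put in; they do not demonstrate that real cohorts contain
rules of any particular strength, since real answer dependence (which the
single-class default lacks entirely) is exactly what mining is meant to
discover.

## Pipeline and scale

The `run` pipeline executes encode → mine → rules → filter → venn, writes
each stage as CSV, and records a manifest with the configuration hash and
per-stage counts (n, frequent itemsets, rules, rules per group) so a run is
auditable. Any stage failure removes partial outputs and aborts with a
stage-labelled error.

Problem sizes used in the shipped tests: oracle-equivalence sweeps use 50
seeded random datasets of ≤ 40 transactions over ≤ 15 items, where
exhaustive enumeration is exact and fast; recovery experiments use
7-question cohorts of n=5000 over 20 seeds; calibration uses one full-size
n=7802 cohort; the independence check uses n=50,000 over two questions.
Full-profile mining examples cap the itemset size at 3 — with 26 mostly
high-prevalence questions the uncapped frequent-pattern lattice at 5%
support grows combinatorially, and rule sets built from patterns of more
than a few items are not interpretable in this application anyway.

## Known limitations

* No statistical significance testing or multiple-comparison control of
  rules; support/confidence/lift are descriptive, as is standard in
  frequent-pattern analysis.
* No closed/maximal itemset condensation; the rule list is redundant by
  construction (every frequent split is emitted).
* The synthetic generator does not model longitudinal linkage of
  respondents across rounds, nor copulas over all questions.
* The graphical rule-tree rendering of published figures is out of scope;
  rules are emitted as tables.
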