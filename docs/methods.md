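# Methods

This note documents the models implemented in `hfdx`, the parameters that
matter, the numerical conventions, and what the synthetic benchmark can —
and cannot — establish.

## Diagnostic model

A patient record carries 14 attributes: age (years), sex (`male`), four
binary clinical findings (HF symptoms/signs, clinical history, physical
exam, abnormal ECG), NT-proBNP (pg/L), and seven echocardiographic indices
— LVEF (%), LAVI (mL/m²), LVMI (mg/m²), E/e′, septal e′ (cm/s), TRV (m/s),
GLS (%, stored as the strain magnitude). Any value may be Missing; Missing
is a first-class state and is never imputed by the data layer — only
knowledge models decide how to route it.

Four outcomes: `HFrEF`, `HFmrEF`, `HFpEF`, `NoHF`. The ejection-fraction
phenotype uses half-open intervals exactly as defined clinically:
[0, 40) reduced, [40, 50) mid-range, [50, 100] preserved; `classify_lvef`
is a total step function on [0, 100] and raises on Missing input.

### Expert model (CKM)

The built-in expert tree implements the guideline logic: no HF
symptoms/signs ⇒ `NoHF`, whatever the echo shows (asymptomatic dysfunction
is not HF under this definition). With symptoms, LVEF < 40 % alone
establishes `HFrEF`; the mid-range and preserved phenotypes additionally
require at least one piece of supporting evidence, checked in a fixed
order: NT-proBNP ≥ 125 pg/L, LAVI > 34 mL/m², LVMI ≥ 115 (men) / 95
(women) mg/m², E/e′ ≥ 13, abnormal ECG; all negative ⇒ `NoHF`. The
guideline sources name the evidence *categories* without fixing all
cut-offs; these defaults follow the 2016 European convention and are fully
configurable (`ThresholdConfig`). "Lung congestion" is not among the
captured attributes, so the evidence set consists of the biomarker, the
structural echo indices and the ECG.

The expert tree deliberately ships with **no Not-Available routing**: a
record with a Missing value on its path is Uncovered, with the failure
node reported. Supplying NA paths is the hybridizer's job, which keeps the
division of labor honest and testable.

### Learned model (CART)

`induce_cart` is a from-scratch CART-style learner: greedy binary
recursive partitioning minimizing weighted Gini impurity
(1 − Σₖ pₖ²). Candidate thresholds are midpoints between consecutive
distinct observed values; binary attributes split on false/true. Records
Missing the split attribute join the side holding the majority of the
observed records (tie → the low/false side); that side is recorded on the
node (`na_route`), so induced trees are total. No surrogate splits, no
pruning. Ties in impurity decrease are broken toward the earlier schema
attribute, then the smaller threshold, making induction fully
deterministic.

Defaults (`InductionParams`): `max_depth = 6`, `min_samples_leaf = 5`,
`min_impurity_decrease = 0.0` (a split must still strictly decrease
impurity). These are unstated in the underlying workflow and were chosen
as conventional values for cohorts of a few hundred records; a depth-6
tree stays reviewable by a physician, which is the point of a white-box
system.

Feature importance (`rank_features`) is the node-weighted total Gini
decrease per attribute in a fully grown tree (depth 64,
`min_samples_leaf = 1`), normalized to sum to 1.

Candidate learners are compared (`rank_algorithms`) on cross-validated
accuracy, rule count and attribute count:

    rank = 0.6·Ã + 0.2·(1 − R̃) + 0.2·(1 − T̃)

with min-max normalization across candidates (a constant axis normalizes
to 1 for accuracy, 0 for the complexity counts, so a lone candidate scores
1.0). The exact published rank formula is not recoverable; this weighted
form preserves its stated monotonicities (higher accuracy better, fewer
rules/attributes better) with configurable weights. Accuracy comes from
seeded stratified 5-fold cross-validation — the original validation
protocol is likewise unstated. Only the CART learner is implemented
natively; other algorithms participate as externally supplied
`RankScore` inputs.

### Hybridization

`hybridize(ckm, pm, records)` measures coverage of the expert model on a
cohort, groups the uncovered records by failure point and reason
(`missing` vs `gap`), and grafts a learned subtree at each point:

* a **Not-Available branch** (`na_child`) where traversal died on a
  Missing value;
* **gap branches** covering the uncovered sub-intervals (or the missing
  boolean branch) where a value matched no branch.

Each grafted subtree is re-fit with the same CART procedure on exactly
the uncovered sub-population reaching that point, so the graft reflects
the conditional distribution there rather than copying the global
prediction model verbatim (the global PM supplies labels for any record
without a gold diagnosis). Sub-populations smaller than
2·`min_samples_leaf` get a majority-class leaf (no micro-grafts); an
empty or unlabelable sub-population gets a `NoHF` leaf. Grafting repeats
until the cohort is fully covered (new failure points can surface deeper
in the tree once earlier ones are fixed).

Invariants, enforced and property-tested: existing expert nodes are never
modified, so every CKM-covered record keeps its diagnosis (*expert
precedence*); coverage is non-decreasing and reaches 1.0 on the
hybridization cohort; the rule count never shrinks; all grafted nodes
carry `provenance = "grafted"`.

### Rules

`extract_rules` maps each root-to-leaf path to one conjunctive IF-THEN
rule; the rule set of a valid tree is mutually exclusive, and on every
covered record the unique firing rule reproduces tree traversal (tested
exhaustively on random trees). Branches that absorb Missing values via
`na_route` mark their term `or_missing`; dedicated NA subtrees emit
`attribute is missing` terms. The JSON rule-base document (see
`docs/knowledge-model-format.md`) is a deliberately simplified analogue
of a Medical Logic Module: identifier, machine- and human-readable
conditions, conclusion, provenance, and optional terminology codes via
`code_map`. Arden slot grammar and terminology-server bindings are out of
scope.

## Synthetic cohort generator

No patient-level data are public, so experiments run on seeded synthetic
cohorts (`table1_default_spec`). Class priors follow the reference
test-set composition (108 NoHF / 199 HFrEF / 63 HFmrEF / 228 HFpEF of
598). Within a class, each continuous attribute is a truncated normal
with the published class mean/SD — except NT-proBNP, whose printed SDs
approach its means, so it is modeled lognormal matched to the printed
mean/SD (physiological right skew). Binary attributes are Bernoulli with
the published prevalences. LVEF is truncated to the phenotype interval of
its class ([5, 40) / [40, 50) / [50, 85]; NoHF also [50, 85] — a modeling
choice keeping the generative classes separable in principle, not a data
claim). Other truncation bounds are physiologic plausibility limits (age
[18, 100], LAVI [5, 200], …). Values are rounded to one decimal and
nudged back inside open bounds so phenotype consistency survives
rounding. GLS is generated for every record; a missingness rate
reproduces partial-availability designs when wanted.

Attributes are sampled **independently within class**: only marginal
summaries are published, and no correlation structure is invented
(`CohortSpec` is the hook if one is ever wanted). Missingness is MCAR per
attribute, injected after sampling, seeded, idempotent on already-Missing
values. Identical specs (including seed) reproduce cohorts byte-for-byte
through CSV serialization. Sample moments are tested against analytic
truncated-distribution expectations at n = 2000.

### What the benchmark shows — and what it cannot

Passing tests establish: boundary-exact phenotyping; split search
equal to brute-force enumeration; recovery of the generative LVEF
boundaries (within 2 points, LVEF at the root) from n = 600 cohorts;
coverage monotonicity, expert precedence and rule growth of
hybridization over random model/cohort triples; full post-hybridization
coverage under 10 % MCAR missingness; and the evaluation arithmetic.

They do **not** establish real-world diagnostic accuracy, and one
qualitative finding of the original clinical workflow is *not*
reproduced here: that the hybrid system outscores the pure learned model.
Under this generator the gold label is the generative class, and
independent marginals make roughly four fifths of symptomatic NoHF
records satisfy the clinical HF definition (some structural criterion is
positive by chance), so the expert logic — and with it the hybrid model
on every expert-covered record — systematically "misclassifies" records
that a learned model keying on NT-proBNP and LVEF labels correctly. In
the clinical study the gold standard was specialists applying that same
definition, coupling labels to the expert logic; emulating that coupling
would require a correlation structure the published marginals do not
determine. The hybrid-vs-expert comparison, by contrast, is
generator-independent: under the common-denominator scoring convention
the refined model can never score below the expert model it extends.

## Evaluation conventions

* Concordance = percent agreement with the gold diagnosis; per-class
  concordance is within-gold-class agreement (recall), matching how
  per-subtype rates are usually presented.
* Sensitivity/specificity collapse the three HF subtypes to HF vs NoHF;
  the association statistic is the product-moment correlation (φ) of the
  binary codes, reported as None when either side is constant.
* Uncovered predictions: `evaluate` excludes them from all metrics by
  default and reports `n_uncovered` separately (the conservative choice
  when a model simply abstains). `compare_engines` defaults to scoring
  them as discordant instead, because engines with different coverage are
  only comparable over a common denominator — and under that convention
  "hybrid ≥ expert" holds by construction. Both policies are explicit
  arguments.
* Group summaries use Student's t (continuous) and the χ² test without
  continuity correction (binary), falling back to Fisher's exact test
  exactly when some expected 2×2 cell count is < 5; degenerate
  comparisons (no variance) report P = 1.0 with a flag.
* Echo subset analysis: set A uses records as given; set B masks every
  echo attribute except LVEF, LAVI and LVMI to Missing before diagnosis.
  Age strata are half-open intervals over configurable bounds.

## Problem sizes and determinism

The standard experiment mirrors the reference study design at its actual
scale: 600 training / 598 test records, 10 % MCAR missingness, fixed
seeds. Property suites use 100 random hybridization triples, 200 random
split-oracle instances and n = 2000 generator-fidelity cohorts. Every
stochastic step (generation, missingness, fold assignment) takes an
explicit seed; `scripts/acceptance.py` derives all of its seeds from its
single `--seed` argument, and the whole pipeline is deterministic given
that seed.

## Known limitations

* The attribute set is inferred from the published cohort table; the
  original system's full factor list (and its expert tree) are not
  public, so the built-in CKM is a faithful *reconstruction of the
  guideline logic*, not a transcription.
* Independent within-class marginals (see above) — the main reason
  absolute accuracies here should not be read as clinical performance.
* Single-expert, single-pass knowledge modeling: no consensus workflow,
  no versioning, no authoring UI.
* The rule-base format is a JSON analogue of a Medical Logic Module, not
  HL7/Arden/SNOMED-conformant; `code_map` is a hook, not a terminology
  binding.
* No probabilistic leaves: every decision is a hard label with a path,
  which is the intended white-box trade-off.
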