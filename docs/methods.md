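# Methods

This note records the statistical model behind `causaltext`, the defaults
that matter, what the synthetic generator does and does not emulate, and
the numerical choices a maintainer should know about.

## The causal estimand and its assumptions

For a corpus D = {(x_i, y_i)} the classifier estimates
p(x_i) = P(endpoint | x_i). For an entity `ner`, the do-calculus component
compares the conditional-probability expectations

    E[p(x) | ner ∈ x]   vs   E[p(x) | ner ∉ x]

via the unequal-variance two-sample z statistic with unbiased (n−1)
variances and an upper-tail normal p-value. "DO" is operationalized as
*observed presence partitioning*: no counterfactual text edit is performed,
and the intervention reading is only as good as the assumption that entity
presence is not confounded with other endpoint-raising text features. The
method cannot distinguish genuine causes from confounders or colliders;
it reports association between entity presence and the classifier's
endpoint probability, screened for direction (one-tailed: presence raises
probability) and multiplicity.

Decisions are made on Benjamini–Hochberg-adjusted p-values at α = 0.05
(`adjust_pvalues` delegates to `statsmodels.stats.multitest`; Bonferroni,
Holm and BY are selectable). A raw z-threshold mode (`z_threshold`,
conventionally 1.645 for one-tailed α = 0.05) is provided for fidelity to
the pseudocode formulation of the algorithm; the adjusted-p route is the
default because it is the stated decision rule of the published analysis.

## Classifier: why a sparse full-batch fit

The default classifier is a bag-of-words logistic model trained by
**full-batch proximal gradient descent** (ISTA) on the mean cross-entropy
loss with an L1 penalty (λ₁ = 7.5e-3) and a small ridge term (λ₂ = 1e-4),
2,500 steps with 500-step linear learning-rate warmup (base rate 2.0), a
held-out-loss checkpoint every 200 steps, and minimum-held-out-loss
checkpoint selection.

Two of these choices are load-bearing and were made deliberately:

* **L1 with exact zeros.** The pipeline scores the *same* corpus the model
  was fitted on (as the published workflow does). Any nonzero fitted weight
  on an entity token — even pure noise — systematically separates that
  entity's DO and NOT-DO prediction means, and the z-test then flags fitted
  noise as signal (a double-dipping artifact). Soft-thresholding drives
  noise-feature weights to exactly zero, which restores the null
  calibration of the downstream test. λ₁ was chosen by the package's own
  null-generator calibration runs: at 7.5e-3 the unadjusted one-tailed
  rejection rate over 200 null entities stays near 0.05 (range 0.030–0.085
  across 20 seeds) and BH yields zero discoveries in 19 of 20 seeds, while
  planted β = 2 effects are recovered with precision ≈ 0.95 and recall 1.0.
* **Full batch rather than mini-batch.** With mini-batch SGD the per-step
  gradient noise keeps re-introducing weight between proximal steps, so
  entity weights never settle at zero and the same double-dipping inflation
  reappears (measured null rejection 0.14–0.36 across penalty settings).
  The mini-batch-128 schedule is therefore reserved for the LM adapter
  (`LM_ADAPTER_CONFIG`), whose regularization story is different; the
  desk-scale default is deterministic given its seed (used only for weight
  initialization, immaterial at the convex optimum).

Probabilities inside the loss are clipped to [1e-12, 1−1e-12] so a
confident mistake cannot yield an infinite loss.

On the default synthetic corpus the held-out accuracy of this model is
≈ 0.78–0.81. That is essentially the ceiling: the generator's
Bayes-optimal accuracy under its own structural model (computable in
closed form, `GroundTruth.bayes_accuracy()`) is ≈ 0.81 at the default
conditions, because most sentences contain no effect-carrying entity and
the base rate is 0.249. Good recovery of causal terms does not require
high classification accuracy — only informative, well-calibrated
probability differences.

## Corpus conventions

* Tokenization: lowercase, split on non-alphanumeric runs, numerals kept.
  Deterministic and identical for corpus text and lexicon surface forms,
  so gazetteer matches are exact token-subsequence matches.
* Sentence splitting: rule-based on `.!?` followed by whitespace and an
  upper-case letter or digit, with an abbreviation guard; decimal numbers
  never split because the terminator must be followed by whitespace.
* tf-idf follows `tf = count/len(d)`, `idf = log(N/(df+1))` with natural
  log by default (the formula's `log` is unqualified; base 10 is a
  parameter). The `df+1` smoothing makes idf negative for a term in every
  document; scores are reported as-is rather than clamped.
* Stratified split: per class, the train count is `floor(class_n × f)` and
  the remainder goes to the test set, with membership drawn by a seeded
  permutation. At the LiverTox class balance (3,578 / 10,783, f = 0.9)
  this reproduces the published 12,924 / 1,437 partition exactly. The
  published per-class *test* composition (360 positives) is not derivable
  from any single rounding rule and is treated as an input where needed,
  not a target of the splitter.

## NER conventions

Matching is longest-match-first on token subsequences, duplicates collapse
to per-instance sets, and entity frequency counts *instances containing
the entity*, not raw mentions — the do-calculus partition is by presence,
so instance support is the relevant quantity. The frequency filter keeps
entities with support strictly greater than 50. Probability-based mention
decisions, span offsets and ontology normalization are out of scope; the
lexicon contract is what the causal engine needs.

## Synthetic generator

The generator emulates a LiverTox-style sentence corpus:

* **Lengths**: truncated normal (minimum 3 tokens) whose location is
  calibrated so the realized mean is `length_mean` (default 26.84; the
  configured sd 15.58 applies to the pre-truncation distribution, so the
  realized sd is somewhat smaller, ≈ 12.5–13.5).
* **Fillers**: a Zipf-weighted vocabulary (default 2,000 types), giving a
  realistic skew of document frequencies.
* **Entities**: 60 by default (11 drugs, 8 genes, 41 diseases), each
  independently included with probability 0.05 (expected support ≈ 250
  instances, comfortably above the >50 filter; a config whose expected
  support falls below the filter warns rather than errors). Every third
  entity has a two-token surface form so longest-match NER is exercised.
  The filler-token count of a sentence is drawn *independently* of entity
  inclusion and entity spans are inserted on top: coupling them (fixing
  total length) would correlate filler composition with entity presence
  and silently break the causal null.
* **Labels**: `y_i ~ Bernoulli(sigmoid(base_logit + Σ_e β_e Z_ie))` with 10
  disease entities carrying β = 2.0 by default. `base_logit` is calibrated
  by exact enumeration of the planted-effect distribution so the marginal
  positive rate equals 0.249. The logistic structural model makes every
  entity's DO/NOT-DO difference available in closed form
  (`analytic_do_difference`), which is the oracle the causal engine is
  tested against.

What the generator does **not** emulate: discourse structure, section
headings, synonym variation, nested or overlapping entity mentions beyond
the planted forms, label noise from imperfect expert categories, and
entity–entity correlation. Passing tests therefore demonstrate the
statistical machinery is correct under clean conditions; they do not
certify performance on real clinical prose.

The patient-cohort generator draws R uniformly within each of the three
pattern regimes (so all patterns appear), AST uniform on [40, 300] U/L with
ALT = R·AST, and embeds causal-tree terms consistent with a sampled
severity level; expert labels are produced by the same rules the
stratifier applies, so exact recovery (pattern agreement 1.0, R
concordance 1.0) is the correctness check, not an empirical claim.

## Stratification rules

R = ALT/AST as the upstream case study defines it; note the
clinical-standard R uses (ALT/ULN)/(ALP/ULN) — an ULN-normalized variant
(`r_score_uln`) exists but is off by default. The strict inequalities
(hepatocellular R > 5, cholestatic R < 2) leave the boundaries undefined;
both are folded into "mixed" so the rule is total, and the thresholds are
configurable (`RScoreRules`). Severity bucketing maps matched
clinical-outcome terms to ordinal levels (acute liver failure → 5+,
hepatic/liver failure → 4+, cirrhosis and sinusoidal obstruction
syndrome → 3+, jaundice/hypersensitivity → 2+, rash → 1+), takes the
maximum over matches, and defaults to the lowest level with no match; the
mapping is fully configurable because no authoritative assignment rule is
published.

## Robustness metrics

POT(L) is the size of the intersection of all runs' top-L z-ranked
enriched lists divided by L, for L = 1..30; a run shorter than L
contributes its full list. Note this makes POT(L) ≤ |enriched|/L for
L beyond the list length, so identical runs with m < 30 enriched terms
average below 1.0 by construction — with the default generator's 10
planted terms, three identical runs give an average POT of ≈ 0.69.
Commonality is |intersection| / |union| of the enriched sets
(intersection over mean set size is selectable). z ties rank
lexicographically by entity id so repeated runs rank deterministically.

## Numerical notes

* z-test: pooled standard errors at or below 1e-9 raise a zero-variance
  error. Floating-point cancellation on (near-)constant prediction vectors
  produces variance "dust" around 1e-33, which would otherwise yield
  astronomically large dust/dust z statistics; any genuine standard error
  on probability-scale data is many orders of magnitude above the floor.
* Groups smaller than `min_group` (default 5) are skipped with a recorded
  reason — the normal approximation is not trusted below that; the >50
  frequency filter makes this moot at realistic scale.
* Sentence-length sampling, entity inclusion, label draws and split
  membership all flow from a single `numpy` Generator per seed; pipelines
  rerun bit-identically apart from manifest timestamps.

## Problem sizes used in the checks

The shipped checks run at desk scale, chosen to keep the full suite fast
while leaving Monte-Carlo error well inside the asserted bands: corpus
n = 5,000 sentences (20,000 for the marginal-rate convergence check); 60
candidate entities with 10 planted for recovery (10 seeds); 200 null
entities over 20 seeds for false-discovery calibration; 175 patients for
stratification; 10,000 random lab pairs for the pattern-rule equivalence.
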