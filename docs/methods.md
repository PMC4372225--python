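# Methods

This note documents the models and procedures `fpqsar` implements, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Activity thresholding and conflict removal

Compounds are labelled at a stated IC50 cutoff (nanomolar): *inhibitor* iff
every measurement is strictly below the cutoff, *non-inhibitor* iff every
measurement is at or above it. A measurement exactly at the cutoff therefore
counts as inactive — the active rule is a strict `<`, so equality falls to
the inactive side, and a compound measured twice at exactly the cutoff is a
non-conflicting non-inhibitor. Compounds with measurements on both sides are
*conflicting*: they are removed and counted, never relabelled. Conflict
removal is idempotent, and the removal count always equals (distinct
compounds in) − (compounds out).

Compounds sharing a SMILES under different identifiers are **not** merged:
deduplication is by conflicting activity, not by structure. Rows with
unparseable SMILES or non-positive IC50 are rejected at load time with a
logged count; a file yielding zero valid records is a hard error.

## Train/validation split

Stratified by label: per class, `round(fraction × class size)` compounds
(default fraction 0.1) are drawn into the validation set with a seeded
generator, so both classes are represented at their marginal rates and the
split is exactly reproducible. The split is hand-rolled rather than
delegated, because the contract pins the per-class validation count to the
rounded product; library splitters distribute the total differently.

## Scaffold classes

Class membership is decided by SMARTS substructure matching against a
priority-ordered registry. The default registry puts quinazoline
(`c1ccc2ncncc2c1`, priority 1) above pyrimidine (`c1ccncn1`, priority 2):
every quinazoline contains a 1,3-diazine ring, so without the priority every
quinazoline would be classified as a pyrimidine. `class_subset` and
`leave_class_out` partition any dataset exactly, and the leave-class-out
result is guaranteed to contain no compound matching the left-out pattern —
the property that makes it a genuine cross-scaffold generalisation test.

## Fingerprint scoring and selection

Percent class frequencies `F^A`, `F^I` and the score `FS = F^A − F^I` are
computed at full precision; displayed tables round to 2 decimals, so a
rounded score can disagree with the difference of the rounded frequencies by
one unit in the last digit (the bundled published reference panel contains
two such rows, kept as printed). `FrequencyScoreResults` also reports a
delta-method standard error for each score, treating the two class counts as
independent binomials: `SE = 100·sqrt(p_A(1−p_A)/N_A + p_I(1−p_I)/N_I)`.

**Redundancy filter.** The correlation between two binary columns is the phi
coefficient (Pearson r on 0/1 values, computed from the 2×2 table).
Zero-variance columns, for which phi is undefined, are dropped first and
logged; they carry score 0 and could never be selected. The remaining
columns are scanned greedily in index order and a column is kept iff its
|φ| against every previously kept column is ≤ the threshold (default 0.6).
Keep-first was chosen because it is deterministic and independent of the
scores — filtering happens before scoring — and the removal log names the
kept column that blocked each drop. The filter is idempotent by
construction.

**Selection.** Among survivors, the `k_pos` highest strictly positive
scores (descending) and `k_neg` most negative scores (ascending) form the
panel, defaults 10 + 10. Ties break toward the earlier column index; fewer
are returned when fewer qualify. Selection must only ever see training
data: the cross-validation harness re-runs the filter and the selection
inside every training fold when evaluating the sum-score rule, so reported
performance is not contaminated by test-fold frequencies.

## Sum-score classifier

Unit weights only: score = #positive-panel bits set − #negative-panel bits
set, predict inhibitor iff score ≥ t with t = 1 by default, so a balanced
compound (score 0) is a non-inhibitor. Weighted variants are deliberately
not implemented; the threshold is exposed as the one tuning knob, since
raising it trades sensitivity for specificity. The threshold sweep covers
every integer t from the minimum observed score to the maximum + 1, which
guarantees both degenerate rows (all-inhibitor, none-inhibitor) appear and
makes the monotonicity of sensitivity and specificity checkable.

## Metrics and cross-validation

Sensitivity, specificity and accuracy are percentages from the confusion
counts with inhibitor as the positive class. MCC uses the standard closed
form; when any factor under the square root is zero it is defined as 0, a
common convention that keeps reports total. AUROC is the Mann–Whitney
statistic on the learner's real-valued decision score (vote fraction for
the forest, class probability for naive Bayes, margin for the SVM, the
integer score for the sum rule), with ties counted ½ via midranks.

Cross-validation is stratified k-fold (default 5) repeated (default 5
times) with per-repeat fold seeds derived from the run seed; metrics are
macro-averaged over the k × repeats test folds (the pooled confusion counts
are carried alongside). Macro averaging was chosen over pooling because the
per-fold metric is what repetition is averaging; for the near-balanced fold
sizes produced by stratification the two differ negligibly. Random-forest
hyperparameters beyond the 100 trees are library defaults with a fixed,
logged seed.

The experiment grid runs, for a dataset and a list of class names: CV on
the train split, the train model on the validation split, and per class —
CV within the class, the class model on the other classes, CV on the
leave-class-out complement, and the complement model on the held-out class
(six reports for one class, ten for two).

## Synthetic benchmarks

The generator draws each descriptor independently per compound from a
class-conditional Bernoulli: background bits share one probability (default
0.3) in both classes; planted bits have distinct class probabilities, so
their expected score is known exactly (100·(p_A − p_I)). Redundant columns
are near-copies of planted columns with per-bit flip probability; IC50
values are log-uniform within two decades below the cutoff for actives and
two decades above for inactives, with a configurable fraction of extra
compounds measured once on each side to exercise conflict removal. Class
structure is added by tagging a random fraction of compounds, giving them a
diazine-bearing SMILES (so SMARTS assignment recovers the tag) and setting
a marker descriptor. Everything is bit-reproducible from the spec seed.

Two presets matter. `planted_preset`: balanced 500/500 with 5 positive bits
at 0.7/0.4 and 5 negative at 0.4/0.7 over 881 descriptors — the scale at
which selection recovers the full planted panel and a 100-tree forest
clears CV MCC 0.4. `egfr10_like_preset`: 508/2997 with the 20 published
best fingerprints planted at their published frequencies plus redundant
copies and conflicting compounds, reproducing the benchmark's imbalance.

**What the synthetic results do not show.** Real substructure fingerprints
are heavily correlated and carry signal across hundreds of bits; the
generator's independence (outside the explicit copies) is a deliberate
simplification. One consequence is worth stating plainly: with independent,
symmetric planted bits the unit-weight signed sum over the true bits *is*
the Bayes-optimal statistic, so on these benchmarks the interpretable sum
rule matches or slightly beats the random forest (e.g. CV MCC ≈ 0.51 vs
0.50 on the balanced preset), whereas on the real benchmark the forest was
reported well ahead of the sum rule. Passing the synthetic suite therefore
demonstrates correctness of the pipeline mechanics — selection hygiene,
fold bookkeeping, metric arithmetic, recovery of known signal — not the
real-data ranking of learners. On the imbalanced preset the forest tends to
collapse to the majority class (MCC ≈ 0) while the sum rule, being
threshold-based, does not; that again reflects the thin planted signal, not
the learners' real-data behaviour.

## Numerical and degenerate-input conventions

- Frequencies and scores are exact ratios in float64; no intermediate
  rounding.
- Single-class inputs are errors for frequency computation, AUROC and the
  threshold sweep rather than silently degenerate outputs.
- Sensitivity/specificity are defined as 0 when their denominator is empty
  (only reachable through degenerate fold contents).
- Matrix values are validated to {0,1} on construction and stored as int8.
- All randomness (splits, folds, forests, generators) flows from explicit
  integer seeds; CLI reruns with the same config are bit-identical.

## Problem sizes

The bundled checks run at 500/500 × 881 (balanced preset), half scale of
508/2997 × 886 (imbalanced preset) and 300 × 100 (leave-class-out), sizes
chosen so the full pipeline — including 50 forest fits in repeated CV —
completes in well under a minute on one CPU while keeping binomial noise on
percent frequencies near one point.

## Known limitations

- Fingerprint bits are inputs; the package does not compute the 881-bit
  PubChem scheme from SMILES.
- No structure standardisation (tautomers, salts) beyond SMILES parsing.
- The published benchmark's absolute performance (MCC ≈ 0.49 on the 10 nM
  set, ≈ 0.71 on the 1000 nM validation set) requires the original activity
  database and is not reproduced here; the synthetic benchmarks target the
  pipeline's correctness properties instead.
- `bayes_net`-style structured Bayes learners are not provided; the learner
  roster is random forest, Bernoulli naive Bayes, k-NN, SVM and the sum
  rule.
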