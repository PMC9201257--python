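# Methods

This note documents the models and algorithms `scrules` implements, the
defaults and conventions it chooses where the procedure leaves them open,
what the synthetic benchmarks do and do not demonstrate, and known
limitations.

## Data model

The universal input is an `ExpressionDataset`: a dense cells × genes matrix
of non-negative, finite expression values on a continuous RPKM-like scale,
with unique gene identifiers, cell identifiers, and a binary class label
per cell. The positive class defaults to `"T2D"` and is configurable; it is
recorded in every report. Expression values are used **raw** — rule
thresholds are meaningful on the RPKM scale — with an optional `log1p`
flag (default off). No gene-type filtering exists anywhere in the
pipeline: pseudogenes and non-coding entries are first-class features.

Readers accept the common genes-in-rows TSV dialect (first column gene id,
header row of cell ids, optional gzip) and its transpose; labels arrive as
an external two-column table aligned by cell id, never by file order.
Ragged rows, non-numeric or negative values and duplicate gene ids are
hard errors. Human-oriented CSV/text output rounds floats to 4 decimals;
JSON output keeps full precision so every object round-trips exactly.

## Monte Carlo feature selection

`run_mcfs` draws `s` random gene subsets ("projections") of size `m`
without replacement; for each projection it grows `t` CART trees (Gini
criterion, minimum leaf size 2, no depth limit; the trees are delegated to
scikit-learn, whose tree structure exposes per-node split features, gains
and sample weights) on bootstrap samples of `bootstrap_fraction` of the
cells drawn with replacement. Defaults:

| parameter | default | rationale |
| --- | --- | --- |
| `m` (projection size) | max(⌈0.05·n_genes⌉, 1) | a small random fraction keeps trees weak and decorrelated |
| `t` (trees/projection) | 5 | standard small multiplier |
| `bootstrap_fraction` | 0.66 | classical bootstrap training fraction |
| `s` (projections) | ⌈15·n_genes/m⌉ | each gene expected in ≥ 15 projections |
| `u`, `v` | 1, 1 | neutral exponents of the weighted score |

Two relative-importance variants are kept because the verbal description
("overall number of splits") and the weighted formulation of the Monte
Carlo feature-selection literature differ:

* `weighted` (default): each split of gene *g* contributes
  `wAcc(tree)^u · gain(node) · (n_node/n_tree)^v`, with `wAcc` the tree's
  class-balanced out-of-bag accuracy and `gain` the Gini improvement.
* `split_count`: one point per split; the sum of all scores then equals
  the total number of internal nodes grown, a conservation property the
  tests exploit.

The ranking sorts by descending RI with lexicographic gene-id tie-break, so
output is deterministic given the seed and cell order. Genes with RI = 0
(never a useful split — e.g. constant genes) are retained but flagged
discardable, and every downstream stage excludes them.

**Informative features.** The full Monte Carlo procedure is rerun
`n_permutations` times (default 20) on label-permuted copies of the data.
For each gene, a one-sided one-sample t-test asks whether the observed RI
exceeds its permutation-null sample mean; the informative set is the
maximal *prefix* of the ranking all of whose members pass at `alpha`
(default 0.05). The prefix rule enforces the defining property that
informative features are always top-ranking. The per-gene comparison (as
opposed to a max-RI null) is an interpretation choice; with 20 permutations
the t-test is lenient for borderline genes, and measured type-I control on
a pure null is comfortably within 2× nominal (the acceptance benchmark
measures ~0.03 informative fraction at α = 0.05).

**Seed stability.** Between-seed agreement of RI scores is governed by the
number of trees each gene participates in, not by total tree count: with
2,000 genes and 2,500 trees of 50 genes each (~60 trees/gene) the
between-seed Spearman correlation is ~0.26 even though planted-gene
recovery is already perfect, because the exchangeable background genes'
ranks are pure sampling noise at that coverage. The stability test
therefore uses a dense-coverage benchmark (100 genes, m = 10, s = 2,500,
i.e. ~1,250 trees per gene·projection) where the convergence property is
measurable (Spearman ≥ 0.8). Users ranking tens of thousands of genes
should read small RI differences among background genes as noise;
top-of-ranking content is far more stable than whole-list rank order.

## Performance measures and cross-validation

Six measures are computed from a binary confusion summary: SN (recall),
SP, ACC, MCC, precision, F1; F1 is the selection criterion throughout.
Zero-denominator conventions (bounded and testable): SN, SP, precision → 0
when undefined; MCC → 0 when any marginal is zero; F1 → 0 when
SN + precision = 0.

`cross_validate` uses stratified, shuffled k-fold splits (k = 10 by
default), reproducible from the seed, with one derived seed per repeat.
The default aggregation pools out-of-fold confusion counts across all
folds and repeats before computing measures; per-repeat metric sets are
retained as an alternative aggregation (mean-of-repeats), since either
convention is defensible. Anything fit on training data — including the
standardizer for SVM/KNN and the entire reducer + rule learner — is fit
inside the training fold only.

A statistical subtlety the tests account for: under a label-permutation
null the *pooled MCC* has a small negative bias (within a fold the label
counts are fixed, so TP and TN are negatively coupled and
E[TP·TN − FP·FN] < 0 — about −0.05 at 200 cells with 5 folds). This is a
property of the statistic under permutation coupling, not of the
implementation; null-behavior checks therefore compare MCC against its
Monte-Carlo spread across permutation seeds rather than against a
standard error of the mean.

## Incremental feature selection

Nested prefixes of the usable (positive-RI) ranking are built with step 5
up to a cap of 5,000 features (a terminal prefix at the cap is appended
when the cap is not a step multiple). The classifier grid is SVM with
linear/polynomial/RBF/sigmoid kernels, KNN with k ∈ {1, 5, 10}, and random
forests with 20/40/60/80/100 trees; remaining hyperparameters stay at
scikit-learn defaults and are recorded in run metadata. SVM and KNN see
per-fold standardized inputs (z-scores fit on training folds) because
margin and distance computations on raw RPKM scales would be dominated by
a handful of high-expression genes; random forests use raw values. The
same fold assignment is reused across all subset sizes and classifiers so
the IFS curves differ only through their feature sets. The optimum
maximizes F1, with ties broken toward the smaller subset (parsimony), then
toward earlier grid order. `compare_informative` reports, per classifier,
F1 on the informative set and the decrement relative to that classifier's
IFS optimum.

## Johnson reducer

Each feature is discretized by entropy-based binary-recursive
partitioning with the MDL stopping criterion (a feature may end up with no
cuts, i.e. one bin). A pair of differently-labeled cells is *discernible*
by a feature when their bins differ. The reducer greedily selects the
feature discerning the most still-uncovered pairs until every coverable
pair is covered, with ties resolved toward the higher-RI feature (input
order). If no feature discerns any pair the classes are indiscernible:
standalone use raises an error, while the cross-validated rule evaluator
treats the fold as rule-free and predicts the majority class — the
behavior that makes the learner exactly chance-level on permuted labels.
The discretization choice is a design decision: a rough-set reducer needs
categorical attributes and the entropy-MDL cut is the canonical supervised
discretizer.

## RIPPER

Binary rule induction learns the minority class; the majority class is the
terminal default (with single-class input the rule list is empty). Per
rule, the remaining data are split stratified 2:1 into growing and pruning
sets (re-drawn per rule from the run seed). Growing adds, greedily, the
single threshold condition maximizing FOIL gain
`p1·(log2(p1/(p1+n1)) − log2(p0/(p0+n0)))` (gain 0 when p1 = 0), with
candidate thresholds at midpoints of consecutive distinct sorted values of
the currently covered samples, until the rule covers no negatives or no
condition improves; ties break deterministically (feature order, `≤`
before `≥`, smaller threshold). Pruning deletes trailing conditions to
maximize (p − n)/(p + n) on the pruning set, preferring the shorter rule
on ties. Rule-set construction stops when no positives remain, when a
candidate rule's pruning-set error exceeds 50%, or when the rule set's
description length exceeds the best found so far by more than 64 bits.

Description length uses the canonical MDL accounting: theory bits per rule
= 0.5·(log2 k + subset-coding of its k conditions out of the 2·n_genes
possible ones) — the 0.5 is the usual redundancy discount — plus exception
bits coding false positives among covered samples and false negatives
among uncovered ones with a count header and a log-binomial each. The
external tooling around this algorithm family does not document its exact
bookkeeping; the formulation here is self-consistent and is used both for
the stop criterion and for the global optimization pass, in which each
rule is revisited (replacement grown from scratch, revision grown from the
rule) and a variant is accepted only if it lowers the total DL — hence DL
never increases across the default 2 optimization rounds. Accepted rules
finally get coverage stats (p, n) on the full training data in list order,
and rules left covering no positives are dropped.

`apply_rules` is an ordered decision list: first matching rule wins,
unmatched samples get the default class, so prediction is total and
order-sensitive. `evaluate_rules` refits reducer + RIPPER inside every
training fold (default 10-fold × 3 repeats, pooled counts), and the
reported rule list comes from one final fit on all samples — evaluation
and reporting are deliberately separate fits.

## Synthetic data

The generator emulates the target study's data shape: two unbalanced cell
classes (defaults 949 positive / 651 negative), a continuous non-negative
expression scale, and heavy sparsity. Components:

* **Background genes** — i.i.d. zero-inflated log-normal, identical across
  classes. Dropout is applied independently per entry after the expression
  draw, default rate 0.7 (an assumption; the source data's sparsity is not
  published). The log-normal σ is fixed at 1.0 (natural log): this spans
  about two decades of expression and, at study-scale cell counts, keeps
  the background exactly class-exchangeable *as seen by a t-test* — the
  generator's stated null contract (per-gene Welch p-values ~Uniform;
  with σ = 1.5 the t-test is visibly miscalibrated on such skewed raw
  values and the contract fails for distributional reasons).
* **Planted DE genes** — log2-normal with unit σ in log2 space and the
  positive-class mean shifted by the stated number of log2 units, drawn
  without dropout, so the planted shift *is* the standardized mean
  difference between classes (the property tests verify calibration to
  within 20% at 500+ cells/class).
* **Planted rule genes** — the implied class lies on the stated side of
  the threshold and everyone else on the other side, separated by an
  empty band of relative half-width `rule_gap` (default 0.05) around the
  cut; `rule_noise` flips a stated fraction of cells. With zero noise a
  decision stump in the gap is exact by construction.
* **`plant_conjunction`** — rewrites chosen columns so that target-class
  cells satisfy every condition of a conjunction and each other cell
  violates a random non-empty subset, for testing multi-condition rule
  recovery.

Ground truth is emitted as a separate structured record so tests never
infer it from the matrix. `permute_labels` shuffles labels uniformly
(multiset preserved, matrix untouched) and is the shared null primitive.

What passing these benchmarks shows: the ranking finds genes whose
marginal distribution separates the classes; IFS selects a separating
prefix; RIPPER recovers planted threshold structure. What they do not
show: robustness to donor-level correlation, batch effects, cell-subtype
mixtures or count noise — none of which the generator models (the
motivating design deliberately pools subtypes), nor performance claims on
any real dataset.

## Benchmark and test sizes

Simulation sizes were chosen as the smallest at which each property is
statistically meaningful: metric formulas are checked exhaustively over
all 46,375 confusion matrices with ≤ 30 samples; threshold recovery on 20
replicates of 200 cells; conjunction recovery on 20 replicates of 500
cells; ranking recovery on 2,000 genes × 200 cells with 2,500 trees;
informative-set type-I control on 1,000 genes × 100 cells with 20
permutations × 5 seeds; permutation-null behavior over 8 seeds. The
acceptance script runs the same benchmarks once each from a user seed.

## Known limitations

* The permutation t-test for informative features uses few permutations
  (default 20); its p-values are coarse and the informative boundary on
  weak-signal data is noisy. More permutations sharpen it linearly in
  cost.
* The MDL bookkeeping, while canonical in structure, is not guaranteed to
  match any particular external implementation split for split; rule
  lists on noisy data can differ in late, low-coverage rules.
* Grow/prune splitting means thresholds are midpoints of the growing
  subset; on finite noiseless data a threshold can fall outside the
  full-data gap, occasionally yielding an extra low-coverage refinement
  rule rather than the single minimal rule.
* The IFS wrapper refits every grid classifier at every subset size; at
  the full 5,000-feature cap with 10-fold CV this is compute-heavy by
  design — the step size, cap and grid are all configurable.
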