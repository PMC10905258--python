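# Methods

## Scope and model

`batcheval` treats batch-effect assessment as three complementary
measurements on a merged observations × genes count matrix with a batch
label per observation: (1) distributional tests on per-observation totals,
(2) the separability of batches to a supervised classifier, and (3)
neighborhood-composition and cluster-geometry metrics in a low-dimensional
embedding. The composite score is the unweighted mean of the classifier
accept rate and the two F1-combined metric pairs; every component lies in
[0, 1] and the composite is their mean to machine precision.

## Preprocessing and embeddings

Counts are scaled by global min–max over the entire merged matrix and
mapped through log1p, so every entry lands in [0, log 2]. The min and max
are deliberately global rather than per-gene: per-gene scaling would
equalize distributions across batches and erase the cross-batch depth
differences the downstream tests are meant to see.

PCA (default 50 components, deterministic sign convention: the
largest-magnitude loading of each component is made positive) runs on the
normalized layer; UMAP (default 15 neighbors, seeded) runs on the PCA
scores and is used for display only. All neighborhood metrics operate on
the PCA embedding: UMAP's layout distorts local neighborhood composition,
which is exactly what k-BET and LISI measure.

kNN graphs are exact: chunked pairwise Euclidean distances with a stable
argsort, self excluded, distance ties broken toward the lower index. This
makes every metric bit-reproducible and lets a brute-force distance scan
serve as an oracle in the tests.

## Statistical battery

The tested quantity is the per-observation total count — the library-size
proxy that differs most visibly between platforms and runs. One-way ANOVA
is reported together with the critical value F(1−α; k−1, N−k) so a reader
can compare the statistic to its reference directly; Kruskal–Wallis
(average ranks for ties, divisor 1 − Σ(t³−t)/(N³−N), χ² p-value on k−1 df)
covers the heteroscedastic cross-platform case where the ANOVA variance
assumption fails; all unordered batch pairs get a two-sample K–S statistic
with the asymptotic two-sided p-value, no multiple-testing correction
(raw p-values are reported as such). The contingency analysis
cross-tabulates an experimental condition against the batch and reports
Pearson χ² (no continuity correction), Cramér's V with k = the smaller
table dimension, and the contingency coefficient √(χ²/(χ²+N)). When no
condition column exists, cell-type labels are used if present, else
total-count quartiles serve as a proxy condition and the report says so.

An edge case worth documenting: all-identical values make the
Kruskal–Wallis tie correction zero; H is then defined as 0 with p = 1
rather than raising.

## Domain classifier

The classifier is a single relu hidden layer (default 128 units) with a
softmax output over the k batches, written directly in numpy with
hand-derived gradients — a relu unit alone cannot emit class
probabilities, so the softmax head is the minimal completion that lets the
focal loss apply. Training is plain mini-batch SGD (default lr 0.01,
100 epochs, batch 64) on the focal loss −α(1−P_t)^γ log P_t (defaults
α = 1, γ = 2; γ = 0 recovers cross-entropy exactly, which the tests
check by finite differences and closed form). Class imbalance across
batches is handled by the focal loss alone. P_t is clamped at 1e-12; a
non-finite loss aborts with diagnostics rather than silently diverging.

The split is stratified by batch with the global train size fixed at
⌊train_fraction · N⌋ (default 0.70): per-batch floors plus a
largest-fractional-part remainder rule, with a small epsilon guard because
0.7 · N is not always exactly representable in floating point. Features
default to the normalized gene matrix; the benchmark loop instead passes
each variant's own embedding so corrected methods are judged in their
output space. Input features are standardized internally so the default
learning rate behaves across feature spaces of different scale.

## Metrics

**k-BET** (default k = 25 neighbors, α = 0.05, 10% of observations tested
with a floor of 100, seeded): κⱼ = Σᵢ (nⱼᵢ − fᵢk)²/(fᵢk) over the k
neighbors of each tested observation, compared to χ² with l−1 degrees of
freedom, where batches with zero global frequency are dropped from l. The
summary "95% p value" column is the mean p-value over tested
neighborhoods. k below 10 triggers a warning (χ² adequacy).

**LISI** (default k = 90): neighborhoods are the observation itself plus
its k nearest neighbors with uniform weights — a fixed-k neighborhood
rather than a perplexity-weighted kernel, which keeps the statistic simple
and exactly testable. Raw inverse Simpson values lie in [1, #labels]; the
per-observation vector for each label set is min-max normalized to [0, 1]
and then averaged (a constant vector normalizes to zeros). A single-level
label set yields 0 with a warning.

**Silhouette**: the standard mean silhouette coefficient (Euclidean, full
pairwise distances), subsampled with a seeded draw above 10,000
observations to keep the O(N²) distance matrix desk-scale.

**F1 combiners.** The LISI pair combines as
2(1−cLISI)·iLISI/((1−cLISI)+iLISI). For the silhouette pair two modes are
exposed. The default, `table_consistent`, combines the raw coefficients
(clipped to [0, 1]) as 2(1−iSS)·cSS/((1−iSS)+cSS). The alternative,
`equation_9`, first rescales both to (1+s)/2 ∈ [0, 1] and then combines.
The two disagree — on the pair (0.6675, 0.6155) they give 0.4318 and
0.2757 respectively — and the primed variant is inconsistent with the
reference summary values this package reproduces, so the unprimed form is
the default and the primed one remains available and documented rather
than hidden. Zero denominators yield 0 in both combiners.

When no cell/domain-type annotation exists, type labels fall back to
Leiden clustering of the kNN graph (resolution 1.0, seeded) and the report
marks the scores as cluster-based.

## Benchmark and recommendation

Correction methods are callables returning either a corrected embedding or
a corrected expression layer (re-embedded by PCA before scoring). Each
variant — raw plus each method — is evaluated with identical seeds; a
method that raises is marked failed without sinking the run. External
tools (Harmony etc.) are optional plug-ins that register only if their
package imports; a dependency-free per-batch center/scale of the PCA
scores is built in so the loop always has at least one correction to
exercise. The recommendation is the argmax of the composite score among
corrected variants, ties broken alphabetically; the "requires further
processing" conclusion fires when the raw score is below 0.5. The 0.5
cutoff is a design choice on a score bounded in [0, 1]: the observed
regime on data with a real batch effect is far below it, and a score above
it requires all three components to be reasonably healthy on average.

## Synthetic data generator

The generator emulates the features of multi-section integration that the
metrics respond to: counts are negative binomial (gamma–Poisson, default
gamma shape 10) with mean

    μ = base_g · typefactor_gt · batchfactor_gb · libsize_cb

where base_g is log-normal, a `de_fraction` (default 0.1) of genes are
markers multiplied by exp(type_effect) in their owner type (3 types by
default), log batchfactor ~ Normal(0, batch_effect²) per gene and batch,
and per-batch depth multipliers are drawn uniformly from `libsize_factor`
(default 0.7–1.3) with mild per-cell log-normal variation. Defaults (3
batches × 300 cells × 500 genes) generate in well under a second;
batch_effect = 0 with equal depth gives exchangeable batches, and the
composite score decreases monotonically in batch_effect, which the test
suite asserts via Spearman correlation over five strength levels.

What the generator does **not** emulate: spatial expression patterns
(coordinates, when requested, are uniform noise), gene–gene correlation
beyond the shared type/batch factors, ambient RNA, doublets, or zero
inflation beyond what the negative binomial provides. Passing tests
therefore demonstrate the metrics' behavior under controlled multiplicative
batch effects and depth differences, not performance on every real-data
pathology.

## Problem sizes and numerical choices

The test suite and examples run on datasets of 100–500 observations and
80–200 genes with 20–30 PCA components — sizes at which every quantity is
recomputable from scratch and cross-checkable against brute-force oracles
(exact kNN scans, per-neighborhood χ² tables, reference implementations of
the rank test). The stochastic property tests (null ANOVA exceedance,
classifier chance accuracy, k-BET acceptance under random labels) use
fixed seeds and tolerances wide enough for their sampling variance at
those sizes, e.g. a ±4 sd binomial band for the 5% exceedance rate over
500 replicates.

All randomness flows through numpy Generators seeded from explicit
arguments; the pipeline derives stage seeds from the single run seed by
fixed offsets. Determinism contracts (same seed → bit-identical
embeddings, splits, metric bundles) are asserted in the tests.

## Known limitations

- The classifier is deliberately small and CPU-bound; on tens of
  thousands of observations with full gene-space features, PCA features
  (`features="pca"`) are the practical choice.
- LISI min-max normalization is relative to the dataset's own spread of
  inverse Simpson values, so scores are comparable between variants of the
  same dataset, not across datasets.
- k-BET assumes the χ² approximation holds in each neighborhood; very
  small k or very rare batches weaken it (warned at k < 10, rare batches
  drop from the degrees of freedom).
- The HTML report is static; figures are rendered once per variant and
  subsampled beyond 50,000 points.
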