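# Methods

## Overview

`statepert` implements a counterfactual ("restore to normal") analysis of
gene expression: given labeled expression profiles — here four tumor
stages plus normal tissue from two repositories — it learns, per sample,
the additive per-gene change `P` that moves the profile `X` into the
feature space of a chosen *target* class, so that a frozen classifier
assigns `X + P` to that class. The perturbations are then mined for
per-sample outlier genes, cross-sample consistency signatures, and
functional enrichment.

All modelling happens on log2-scale, quantile-normalized expression, so
`P` is directly in log2-expression units.

## Preprocessing (`gem_io`)

* **Merging.** Matrices from different sources are merged by
  concatenating sample columns over the *intersection* of their gene
  sets (first input's order). Intersection rather than union avoids
  imputing whole rows for samples from a source that lacks a gene.
* **log2.** `x → log2(x)` for positive entries. Zeros become missing
  (the log is undefined there and a zero FPKM carries no magnitude
  information); negative input is an error.
* **Quantile normalization.** Every sample column is mapped onto one
  shared empirical distribution: the per-rank mean of the columns'
  sorted values. Tied values receive the mean of the reference values
  their ranks span ("average ties"). Columns with missing entries are
  ranked over their non-missing values against a reference interpolated
  to a common grid, so unequal missing counts are handled. The operation
  is idempotent and equalizes column means to numerical precision.
* **Imputation.** Missing entries are filled with the *global* minimum
  of the training matrix — a "below everything observed" pseudo-value.
  Held-out and perturbed matrices are imputed with the *training*
  minimum so no held-out information leaks into preprocessing.

## Synthetic cohorts (`synthetic`)

The generator emulates the statistical structure of a merged
tumor/normal cohort at desk scale. Defaults (all log2 units):

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | genes (stand-in for a ~19k-gene matrix) |
| `classes` | 4 tumor stages + `normal-tcga`, `normal-gtex` | six classes |
| `n_train_per_class` / `n_heldout_per_class` | 40 / 10 | per-class sample counts |
| `baseline_log_mean_range` | [2, 10] | per-gene baseline, uniform |
| `effect_size` | 2.0 | planted |log2 fold change| vs normal |
| `n_shared_effect_genes` | 20 | perturbed in *all* tumor stages |
| `n_stage_specific_genes` | 20 | per tumor stage |
| `batch_offset` | 0.5 | added to `n_batch_genes` (100) in `normal-tcga` only |
| `noise_sd` | 0.7 | Gaussian sample noise |
| `missing_rate` | 0.001 | i.i.d. missing mask |

Each planted set is half up- and half down-regulated (±`effect_size`).
A "tumor-up" truth gene sits *above* normal, so restoring normal
expression requires a *negative* perturbation — the sign convention used
throughout. The batch offset on `normal-tcga` emulates residual
repository batch structure between the two normal sources.

What the simulation does **not** model: count-based noise
(negative-binomial mean–variance coupling), library-size effects,
correlated gene modules, isoform or copy-number structure, and outlier
samples. Passing tests therefore demonstrate that the pipeline recovers
*additive log-scale class signals under Gaussian noise*, not that it is
robust to every property of real RNA-seq.

`generate_term_mapping` builds a matching gene→term annotation with one
term planted on the stage-shared tumor-up set, so enrichment can be
tested end-to-end: every tumor class's up-query should hit the planted
term, the normal→normal control should not.

## Perturbation engine (`engine`)

Two fully-connected networks, trained full-batch with Adam on CPU
(hand-written backprop in `nn.py`; no GPU framework needed at this
scale).

**Classifier** (2000→512→128→6, ReLU, softmax): cross-entropy on the
training samples, 200 epochs, lr 1e-3, decoupled weight decay 10.
Features are z-scored per gene *inside the model* with training-set
statistics (the scaler is stored in the checkpoint); callers always pass
raw log2 expression and `P` stays in log2 units. Without the weight
decay the net memorises per-sample noise directions and its held-out
accuracy drops well below the ~0.95+ a linear model achieves on this
data; with it the net matches the linear reference and, crucially, its
decision boundaries rely on the class-level signal that the generator
must then manipulate.

**Generator** (2000→512→128→512→2000, ReLU encoder–decoder emitting `P`
directly) minimises, with the classifier frozen:

```
L = CE(classifier(X+P), target)
    + λ_magnitude · mean(P²)            λ_magnitude = 0.01
    + λ_target   · mean((X+P − μ_T)²)   λ_target   = 3.0
```

where `μ_T` is the per-gene mean of the target class's training
samples. Training: 800 epochs, Adam lr 2e-3 with cosine decay,
decoupled weight decay 3, and Gaussian jitter (SD 1.0 in standardized
units) added to the net *input* each epoch.

Why each term and regularizer is there — these choices were the genuinely
open part of the design, and each one is load-bearing:

* **CE alone is not enough.** With only the adversarial term (plus the
  magnitude penalty) the generator drives the classifier to the target
  along whatever directions are cheapest, most of which are
  non-biological; planted-gene recovery was ~20% and even target-class
  control samples acquired a consistent artificial pattern. The
  `λ_target` anchor ties `X+P` to the target-class mean, which is also
  what the per-sample heatmaps of such analyses show (`X+P ≈ μ_T`).
* **Weight decay + input jitter make the generator denoise.** The
  per-sample 2-SD significance rule only recovers a planted gene in
  *all* 10 samples of a class if the generator outputs the class-level
  correction consistently, without re-emitting each sample's own noise
  (which inflates the per-sample threshold and randomises the calls).
  An unregularized generator memorises training residuals; decay and
  jitter force it toward the smooth class-conditional correction while
  leaving enough input dependence that perturbations of *target-class*
  samples remain individual — which is exactly why the normal→normal
  control produces no commonly perturbed genes.
* **Cosine decay** settles the weights at a converged point; with a
  constant learning rate the final weights sit at a random phase of the
  late-training oscillation and per-seed results fluctuate.

Degenerate inputs: zero-variance genes pass through the scaler with unit
scale (centred only) and are retained. `X+P` is not clamped to the
observed expression range.

## Perturbation statistics (`stats`)

Per sample, genes with perturbation strictly greater than
`mean + k·SD` (tumor-downregulated, positive `P`) or strictly less than
`mean − k·SD` (tumor-upregulated, negative `P`) are significant, with
`k = 2` and the *population* SD (ddof 0) of the sample's full
perturbation vector; at ~2k–19k genes the n vs n−1 distinction is
irrelevant but is fixed for reproducibility. A constant vector (SD 0)
yields empty sets with a warning.

Per class: commonly perturbed genes (set intersection per direction over
all samples), mean per-sample counts ± SE, mean pairwise shared counts
and Jaccard proportions over unordered sample pairs (self-pairs
excluded; SE over pairs; an empty-union pair contributes 0), and the
pooled mean/SD of significant perturbation values per direction (pooled
over flagged (sample, gene) pairs; population SD; per-sample means are
recoverable from the per-sample calls).

## Enrichment (`enrichment`)

Per module (class × direction), the query is the *union* of per-sample
significant genes. Each term annotated in the background (all genes of
the matrix) is tested for over-representation with the one-sided
hypergeometric tail `P(X ≥ k)` (Fisher exact). Filtering keeps terms
with raw `p < 0.01` **and** Bonferroni-corrected `p < 1e-5`, the
multiplier being the number of terms actually tested within the module
(configurable; not the vocabulary's full size). No GO-graph propagation
and no FDR alternatives are provided.

## Pipeline and reporting (`pipeline`, `plots`, `cli`)

`run_pipeline` chains simulate/load → (optional log2+QN) → split →
impute → train classifier → train generator → perturb → significance →
class signatures → enrichment → figures, and writes a manifest with the
seed, full configuration, stage wall-times and SHA-256 of every tabular
output; a rerun with the same seed reproduces the hashes. The t-SNE
embedding is a report-only convenience; the one property asserted about
it operationally is that perturbed samples land nearer the target-class
centroid than their sources.

## Problem sizes and tolerances

The standard study conditions are the synthetic defaults above
(6 × 50 = 300 samples, 2000 genes, 60 perturbed). A full run —
generation through enrichment — takes on the order of two minutes on one
CPU core; the test suite re-runs it for five seeds. Numerical
tolerances: quantile-normalization invariants at 1e-9, perturbation
matrix identity `(X+P) − X = P` at 1e-6 (float32-free, pure float64
path), hypergeometric p-values vs the exact integer tail sum at 1e-12.

## Known limitations

* Recovered perturbation *amplitudes* are conservative: the regularized
  generator under-shoots the planted ±2.0 effects (roughly −1 on planted
  genes in held-out samples); the relative 2-SD calling is unaffected,
  but `P` should not be read as an unbiased effect-size estimate.
* The classifier's residual confusion is between the two normal sources
  (batch offset 0.5 vs noise 0.7) — mirroring the real difficulty of
  separating repositories after batch correction.
* Enrichment treats terms independently; overlapping term memberships
  are tested as-is.
* Determinism is guaranteed for a fixed seed, platform and BLAS; exact
  bitwise equality across different BLAS builds is not.
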