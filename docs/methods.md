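# Methods

## Problem setting

`histomil` implements a weakly supervised pipeline for predicting binary
molecular biomarkers (the motivating case is MSI/dMMR status in
colorectal cancer, with *BRAF* and *KRAS* as further targets) from
hematoxylin-and-eosin-stained whole-slide images. Only a patient-level
label is available; no tile-level annotation is used. Each patient is
represented as a *bag* of tile embeddings, and an aggregation network
maps the bag to a probability.

The pipeline has three stages:

1. **Preprocessing** (`wsiprep`): tissue segmentation, tessellation into
   512 x 512 px tiles at 0.5 microns per pixel (20x), and tile
   embedding. The production embedder is a pretrained histology
   transformer treated as a black box behind the `EmbeddingProvider`
   interface (output dimension 768); this package ships a deterministic
   toy featurizer so the pipeline runs end to end without pretrained
   weights.
2. **Aggregation** (`aggregator`): a small transformer encoder over the
   bag, with AttentionMIL and mean-pooling baselines.
3. **Training/evaluation** (`training`, `evaluation`, `explain`):
   patient-level stratified 5-fold cross-validation with in-domain
   validation and test folds, AUROC/AUPRC reporting, operating-point
   analysis, and attention-based explainability.

## Tissue segmentation and tessellation

A pixel is background when all three RGB channels exceed
`rgb_threshold` (default 224, near white). Blurry or texture-free
regions are rejected by a local Canny edge-density criterion: edges are
detected (hysteresis thresholds 40/100 on 8-bit intensity), the edge
fraction is averaged over a square window (default 64 px), and pixels
below `min_edge_density` (default 2%) are dropped. Morphological
closing (radius 8) restores contiguity. These thresholds are exposed in
the API because no canonical values exist; the defaults follow common
practice in WSI pipelines. The density filter uses zero padding outside
the image so that adding white margin never changes the mask — a tested
invariant.

Tessellation first rescales the slide by `mpp / target_mpp` so each
tile covers a fixed physical area, then cuts a non-overlapping grid.
Tiles with tissue fraction below `min_tissue_fraction` (default 0.5)
and partial edge tiles are dropped; padding edge tiles would create
bags with mixed geometry. All surviving tiles enter the bag regardless
of tumor content. Coordinates are 0-based `(col, row)` in tile units
with origin top-left, so heatmaps can be reconstructed without the
source image.

## The transformer aggregator

Tile embeddings `x in R^{n x 768}` are projected to `d_model = 512`
with a linear layer and ReLU. A learned class token is prepended and
the sequence passes through `L = 2` transformer layers, each pre-norm:
layer norm -> multi-head self-attention -> residual, then layer norm ->
MLP -> residual. Self-attention is the scaled dot product

    SA(Q, K, V) = softmax(Q K^T / sqrt(d_k)) V

with `h = 8` heads of dimension `d_k = d_v = d_model / h = 64`,
concatenated and mixed by `W_O in R^{h d_v x d_model}`. The transformed
class token feeds an MLP head (one hidden layer of width `d_model`,
ReLU) producing the logit; the probability is its logistic transform.
No positional encoding is used, so the bag output is permutation
invariant (a tested property). A mean-token variant replaces the class
token by averaging all sequence elements before the head; it is
provided because it performs comparably, but the class token is the
default since its attention rows are directly interpretable.
Multi-target prediction attaches one class token and one head per
target.

Choices the architecture description leaves open, fixed here:

- transformer MLP hidden width: `4 * d_model` (2048), the standard
  ratio;
- MLP head: one hidden layer of width `d_model`;
- query/key/value projections carry biases (switchable off, which the
  attention-oracle tests use);
- class tokens are initialized N(0, 0.02^2); weights Glorot-uniform;
- dropout defaults to 0 at full scale.

### Baselines

*AttentionMIL* (gated attention pooling): per-tile weights
`a_i = softmax_i(w^T (tanh(V e_i) * sigmoid(U e_i)))` over projected
embeddings `e_i`, bag embedding `sum_i a_i e_i`, linear classifier.
*Mean pooling*: a linear classifier on the tile-mean embedding, the
aggregation rule of the CNN-era pipelines.

## Training protocol

Folds are stratified by label at the patient level (a patient's slides
always share a fold). For fold `f` of `k = 5`: test = fold `f`,
validation = fold `(f+1) mod k`, training = the rest; cycling the test
fold yields pooled in-domain test scores over the whole cohort. The
loss is binary cross-entropy on logits (summed over targets when
multi-target); batch size is 1 because bags have unequal length.
Full-scale defaults: AdamW with learning rate and weight decay 2e-5,
8 epochs, validation every 500 iterations (1000 for multi-cohort runs).
AttentionMIL: Adam, weight decay 1e-2, fit-one-cycle schedule with max
learning rate 1e-4 and 25% warm-up, 32 epochs. The checkpoint with the
highest validation AUROC is kept; equal AUROCs are broken by lower
validation loss (AUROC saturates quickly on small validation sets, and
always keeping the earliest saturated checkpoint systematically selects
undertrained models), exact ties by the earlier iteration. Test
patients are never touched during training. External cohorts are scored
by every fold's best checkpoint and reported as mean +/- std over
folds.

### Scaled-down profile for synthetic experiments

All synthetic-data experiments in the test suite and acceptance script
use `TrainConfig.synthetic_profile`: a d_model = 64, 8-head, 2-layer
model (mlp_hidden 128) on 64-dimensional bags, trained with AdamW,
one-cycle schedule (max lr 2e-3, 25% warm-up), weight decay 1e-4,
gradient clipping at global norm 1, 16 epochs. Training a transformer
from scratch on ~120 bags with ~15 positives is an unstable regime —
a single run occasionally converges to a poor basin, and a 40-patient
validation set (~5 positives) is too coarse to detect this — so three
safeguards apply:

- checkpoints inside the first 30% of the schedule are excluded from
  model selection (during warm-up the model is still near its random
  initialization, and a near-constant score vector can by chance rank a
  handful of validation positives highly);
- equal validation AUROCs are broken by validation loss (above);
- each fold trains a small deep ensemble (`n_runs = 2` independent
  initializations) and averages their probabilities; the
  ensemble is robust to one failed member, which validation alone
  cannot reliably identify. The best-validation member is stored as
  the fold's representative checkpoint for explainability.

Regularization alternatives (dropout 0.2, weight decay 1e-2) were
less effective than ensembling in this regime. The null (no-signal)
run uses a single member, since averaging has nothing to recover when
no member can learn signal. These sizes keep a full 5-fold
cross-validation on 200 patients within minutes on one CPU while
exercising exactly the same code paths as the full-scale
configuration.

## Evaluation

AUROC (the Mann-Whitney statistic, ties counted half) is the primary
metric; AUPRC is computed as average precision (step-wise integration,
not trapezoidal, which would be optimistic in PR space) because
positives are rare (prevalence ~12.9%). Cross-validated results report
per-fold mean +/- std as the headline plus pooled per-patient curves.
Operating points use the rule: the *largest* threshold whose
sensitivity on the threshold-fixing set reaches the target (default
0.95); the threshold is then applied unchanged to external sets, where
sensitivity/specificity/PPV/NPV are reported. Subgroup evaluation
computes per-group AUROC and skips single-class groups with a warning.
The data-efficiency harness draws stratified patient subsamples of
increasing size (five repetitions each), trains for a fixed, reduced
number of epochs (8), and scores a fixed held-out cohort.

## Explainability

*Attention rollout*: per layer, attention matrices are averaged over
heads, mixed with the identity for the residual path
(`0.5 A + 0.5 I`, switchable off), and row-renormalized; the layer
factors are multiplied recursively and the class-token row at tile
positions is the per-tile contribution map. Every intermediate matrix
stays row-stochastic. *Per-head maps* show the class token's
post-softmax attention over tiles for each of the 2 x 8 = 16
layer/head pairs (raw pre-softmax logits are also exportable, since
either reading of "query-key product" is defensible). *Patch scores*
feed each tile through the model as a singleton bag; the resulting
probabilities are displayed unclamped. For display, rollout and head
maps are clamped to their 5%/95% quantiles and min-max rescaled to
[0, 1]; a constant map renders as 0.5 by convention.

## Synthetic data

`synthdata` generates the planted-witness benchmark every training and
explainability claim is tested on. A bag is positive iff it contains
witness tiles (the standard MIL assumption): positive bags carry
`round(w n)` witnesses (at least 1, default witness fraction w = 0.05)
drawn `N(delta u, sigma^2 I)` along a fixed unit direction `u`;
background tiles are `N(0, sigma^2 I)`. Labels are Bernoulli with
prevalence 0.129; bag sizes are log-normal (full scale: median 2000,
capped at 12000; test scale: median 120, clipped to [50, 300]); d = 768
full scale, 64 at test scale. Per-cohort mean offsets and
`generate_external_cohort` (a global shift of chosen magnitude) model
site/scanner domain shifts. Ground-truth witness masks are stored per
bag, which is what the rollout-recovery checks use.

**Noise calibration.** With delta = 1.5, the background scale is
sigma = 0.3, i.e. the witness shift is five background standard
deviations. This places the benchmark in the regime the MIL assumption
describes — witness tiles are individually recognizable, as
label-defining morphology is to a pathologist, and the difficulty is
aggregation under weak supervision, not per-tile detection. The choice
matters: if sigma is of the same order as the shift (sigma = 1), the
exact likelihood-ratio oracle with full knowledge of the generator
reaches only ~0.82 AUROC on these bag sizes, so no aggregator could
meet the pipeline's stated recovery behavior; per-tile detectability is
what makes the planted-signal task well posed.

What the generator deliberately does not emulate: the geometry of real
histology embeddings (cluster structure, anisotropy), spatial
correlation between neighboring tiles, label noise from imperfect
MSI/dMMR assays, and witness morphology heterogeneity. Passing the
synthetic checks therefore demonstrates that the machinery — attention
aggregation, cross-validation protocol, rollout attribution — works as
specified, not that clinical-grade accuracy would be reached on real
cohorts.

## Numerical choices

Computation is float64 numpy throughout; gradients come from a small
reverse-mode tape (`histomil.nn`) whose primitives are verified against
central finite differences. Softmax subtracts the row maximum;
binary cross-entropy is computed in log-sum-exp form; layer norm uses
eps = 1e-5. Attention row sums are asserted to 1e-5; permutation
invariance to 1e-4 relative (float reordering noise); oracle
comparisons to 1e-6. Every random draw — generator, fold assignment,
initialization, shuffling, dropout — flows from explicit integer seeds,
so reruns are bit-identical; there is no nondeterministic kernel
anywhere in the stack.

## Known limitations

- **Very-low-data regime.** In the data-efficiency sweep the
  from-scratch transformer does not overtake the mean-pooling linear
  probe until training sets exceed ~50 patients: the synthetic bag
  signal is a mean shift along one direction, which is exactly the
  probe's hypothesis class, so the probe is maximally sample-efficient
  on it, while the transformer must discover witness attention from a
  handful of positive bags (~3 at 25 patients). The production-scale
  data-efficiency advantage of transformer aggregation is relative to
  AttentionMIL at hundreds of patients on pretrained embeddings; the
  desk-scale sweep reproduces the monotone size-performance curve but
  not a transformer win at 25 patients.

- Bags are pooled per patient (all slides concatenated into one bag);
  per-slide prediction with score averaging is not implemented, only
  per-slide scoring of single-slide bags.
- The toy featurizer captures color/texture statistics only; it is a
  plumbing stand-in, not a learned representation.
- Batch size is fixed at 1; there is no gradient accumulation.
- No confidence intervals or significance tests between models
  (mean +/- std over folds only, matching the reporting convention).
- The full-scale (d = 768, bags up to 12000 tiles) configuration is
  functional but slow on CPU; the scaled-down profile is the supported
  desk-scale regime.
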