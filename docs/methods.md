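# Methods

## Problem and model

The quantity regressed is the percent of tumor cells staining positive for
a marker (c-MYC or BCL2) in an IHC image. Labels exist only at the level of
a whole TMA core or slide — typically in deciles — never per nucleus, which
makes this a multiple-instance regression problem: a *bag* (core or
mini-bag) holds many patch *instances* and carries one percent label.

Each 224×224 patch is embedded to a vector h_k. A prepended fully-connected
layer (ReLU, width M) re-embeds the input features; the gated attention
network then computes a raw score per instance,

    s_k = wᵀ( tanh(V h_k) ⊙ sigmoid(U h_k) ),

normalizes the scores with a softmax into weights a_k ≥ 0, Σ a_k = 1, pools
the bag as z = Σ_k a_k h_k, and a linear head maps z to the predicted
fraction. The tanh branch captures signed evidence, the sigmoid branch
gates its magnitude; their product gives the attention mechanism more
expressive scoring than a single linear layer. Average pooling (a_k = 1/K)
with the same embedder and head is the baseline.

Training minimizes mean squared error between the head output and the
label rescaled to [0, 1]. Predictions are clamped to [0, 100] only at
report time; the raw head output is used in the loss. The forward pass,
analytic gradients and the Adam optimizer are implemented directly in
numpy: the model is small enough that this is fast on one CPU, fully
deterministic, and free of framework dependencies. Gradients are verified
against central differences in the test suite.

### Determinism and permutation invariance

Instances are sorted by a canonical lexicographic key before pooling, so a
bag's prediction is bit-identical under any instance reordering (floating
point summation order is fixed). Training shuffles bag order with the
config seed; identical seeds give bit-identical parameters.

### Defaults

| parameter | default | notes |
|---|---|---|
| embedder width M | 128 | capacity is not limiting at these feature dims |
| attention width L | 64 | |
| optimizer | Adam, lr 1e-3 | one step per bag; 150 epochs |
| loss | MSE on labels/100 | |
| cross-validation | 10 folds, 90/10 | folds disjoint, sizes differ ≤ 1 |

The learning rate and epoch budget were chosen for convergence of *both*
heads of the network: at lr 1e-4 with a 100-epoch budget the regression
head fits but the attention branch remains near its initialization
(near-uniform weights), which degrades held-out MAE about threefold and
leaves the attention maps uninformative. All of these are exposed in
`TrainConfig`.

## Featurizers

The default **toy featurizer** is deterministic and weight-free: the patch
is unmixed into hematoxylin and DAB optical densities with the standard
published H-DAB stain matrix (in conventional log10 OD units), and
summarized by 13 statistics — per-channel OD means, 75th/90th percentiles
and maxima, the DAB-positive pixel fraction (OD > 0.15), the stained-tissue
pixel fraction, and HSV-saturation statistics. The summary deliberately
stays at raw appearance statistics; positivity *relative to tissue content*
is left for the MIL model to infer, as it would be with a learned
embedding.

The **backbone featurizer** is the interface for a pretrained ResNet50:
blocks 1–4 give 256/512/1024/2048-dim spatially averaged embeddings. It
requires torch/torchvision with weights and raises a catchable
`FeaturizerUnavailableError` otherwise — never a silent fallback. 20x
working magnification is realized from a 40x raster by 2× block averaging;
no color normalization is applied.

**Foreground detection** (unspecified upstream conventions vary): Otsu's
threshold on HSV saturation, floored at 0.05, computed once per image; a
patch is foreground when at least 10% of its pixels exceed the cut. Images
whose saturation never exceeds the floor (blank slides) yield no
foreground; Otsu is undefined on constant images and this guard covers
that case.

## Whole-slide translation

A slide cannot be scored as one giant bag by a model trained on ~45-patch
cores, so foreground patch centers are clustered with k-means
(k = max(1, round(n/45)), k-means++ init, 10 restarts, fixed seed) into
convex *mini-bags* that tile the tissue without the overlap circular
windows would create. Each mini-bag is scored like a core; the slide
prediction is the median of mini-bag scores (mean of the two central
values for even counts). Scoring accepts either one model or the list of
cross-validation fold models, averaging predictions per mini-bag (the
default when fold models are available; a single-model option remains).
Empty k-means clusters, if any, are dropped so the partition is always
disjoint, exhaustive and non-empty. Attention heatmaps paint each patch's
raw softmax weight (summing to 1 within each mini-bag) at its footprint;
cluster score maps fill each mini-bag's footprint with its score on a
black(0)–white(100) scale.

## Statistics

* Pearson r with a percentile bootstrap CI (1000 resamples over cases;
  degenerate resamples skipped).
* ICC(2,1): two-way random effects, absolute agreement, single
  measurement; p from the subjects F test. Computed via pingouin and
  cross-checked against an explicit ANOVA mean-squares oracle in tests.
* Clinical calls: positive iff score strictly exceeds 40 (c-MYC) or
  50 (BCL2); double expressor iff both are positive. Thresholds are
  parameters so the survival grid can sweep them.
* Sensitivity TP/(TP+FN), specificity TN/(TN+FP), percentile bootstrap
  CIs; undefined cases (no positives / no negatives) raise rather than
  return silent NaNs.
* Bland–Altman: mean difference ± 1.96 × sample sd (n−1 denominator).
* Log-rank: standard two-group statistic with aggregated risk sets at
  ties, chi-square with 1 df, two-sided; Kaplan–Meier curves via
  lifelines, cross-checked against the product-limit hand formula.
* Threshold grid: −log10 of the log-rank p at every (c-MYC, BCL2)
  threshold pair over deciles 0–90; cells where either group is empty are
  masked, not zero. Significance convention: a cell > 1.3 means p < 0.05.
  **No multiple-testing correction is applied across grid cells**; the
  grid is a descriptive sweep of one highly correlated family.

## Synthetic data: what it emulates, and what it does not

`generate_core` renders a disc of non-overlapping antialiased nuclei
(jittered grid placement) on a near-white background: negatives in a
hematoxylin-like blue-purple, positives in a DAB-like brown, with exactly
round(fraction × n_cells) positives. Positive cells cluster around one or
two random foci by default, mimicking the focal, spatially correlated
positivity of real tissue (scattered placement is available). The core
cohort generator varies disc diameter (70–100% of the canvas) and
cellularity (40–90% of packing capacity) between cores, as partial punches
and variable density do in a real TMA — this matters for the attention
branch: with background-diluted patches occurring in bag-varying
proportion, fitting the labels *requires* down-weighting background, which
is what makes the learned attention track tissue. `generate_slide` tiles
such regions with per-region fractions (and optionally per-region
cellularity) into a pseudo-WSI whose slide truth is the cell-weighted mean.
`generate_embedding_bags` is the image-free fixture: instances drawn from
two latent prototypes (unit offset, Gaussian noise) in proportion to a
decile label. `generate_survival` draws exponential event times with the
hazard multiplied by the hazard ratio for double-expressors and independent
U(0, c) censoring with c solved to hit the target censor rate.

Not emulated: nuclear morphology and texture, stain intensity variation,
scanner artifacts, tissue folds, non-tumor cell populations, pyramid
containers. Passing tests therefore show that the *pipeline machinery* —
tiling, featurization, attention pooling, tessellation, aggregation and
statistics — behaves correctly when the signal is present; they do not
certify accuracy on clinical material, which depends on a real feature
extractor and real staining variability.

### Attention localization: what is (and is not) identifiable

With fraction-valued labels the bag *mean* encodes the label whenever the
featurization is informative per patch, so average pooling is a strong
baseline and attention directed specifically at *positive* (DAB+) patches
is not forced by the objective — its direction is an accident of
optimization. What the objective does force, once bags contain variable
amounts of background, is attention toward tissue-bearing patches:
background dilution varies per bag and cannot be corrected by the head
alone. Accordingly, the localization claim made and tested here is that
attention mass concentrates on dense, tumor-bearing regions rather than
background-dominated ones, regardless of their positivity — verified on
slides with one dense positive-rich region among sparse regions by a sign
test over 20 slides within shared mini-bags.

## Problem sizes

The test and acceptance runs use: 200 embedding bags (30–60 instances,
dim 64, noise sd 0.5, 80/20 split) for parameter recovery; 66 rendered
cores (six per decile, 672 px) for image-stage training; 20 slides
(2×2 regions of 448 px) for slide translation; 1000 replicates for null
calibration of the log-rank test and 200 for power at hazard ratio 3,
n = 200. These sizes give stable estimates while keeping a full run in the
low minutes on a single CPU.

## Known limitations

* The toy featurizer is tuned to the two-chromogen synthetic color model;
  on real slides the backbone path (with weights) is the intended route.
* Mini-bag size control is indirect (k = round(n/45)); very irregular
  tissue can produce clusters well off the target size, as it does in
  practice.
* The median is the only slide aggregator implemented; the score
  distribution is exported so alternative summaries can be studied.
* Bootstrap resampling treats cases as exchangeable units (patient-level
  resampling); duplicated cores per patient are averaged into one
  patient-level prediction before scoring.
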