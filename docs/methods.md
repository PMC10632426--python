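# Methods

## The problem

Hormone-receptor status (estrogen receptor alpha, ER; progesterone receptor,
PR) guides treatment decisions in breast cancer and is normally determined by
immunohistochemistry. A weakly supervised deep-learning pipeline can instead
predict a patient's binary receptor status directly from routine H&E-stained
whole-slide images: the slide is tessellated into tiles, each tile is encoded
as a feature vector, and a small attention-based multiple-instance-learning
(attMIL) head pools the tile features into one slide-level prediction using
only patient-level labels — no region annotations. A central scientific
question for such models is whether they transfer across patient populations;
this package makes that question testable end-to-end on synthetic cohorts
with known ground truth, including a "shifted" deployment cohort whose
tile-morphology-to-label coupling differs from the training cohort's
(emulating, for example, deployment of a model trained on female breast
cancer to a male breast cancer population).

## Model

For a patient ("bag") with tiles k = 1..K and feature vectors x_k ∈ R^d:

- embedding: h_k = W₂ · relu(W₁ x_k + b₁) + b₂ ∈ R^256
- attention: a_k = exp(wᵀ tanh(V h_k)) / Σ_j exp(wᵀ tanh(V h_j)),
  with V ∈ R^{128×256}, w ∈ R^128 (the ungated tanh attention form)
- pooling: h_sum = Σ_k a_k h_k
- classifier: BatchNorm1d(256) over the patient batch → dropout p = 0.5 →
  fully connected 256→2 → softmax.

The positive-class probability is the patient's prediction score; the
attention vector is retained for heatmaps and top-tile export. All layers
carry biases. The softmax is stabilised by max-subtraction (equation-
equivalent, overflow-safe). The loss is the 2-class cross-entropy (optional
inverse-frequency class weighting is available but off by default).

The head, its gradients, the AdamW-style optimiser and the schedule are
implemented directly in NumPy (float64). The network is small enough that
dense BLAS covers it comfortably; this keeps every stage bit-reproducible
from a seed and lets the forward pass and gradients be verified against
scalar-loop oracles and central finite differences (both are part of the
test suite, at 1e-6 and 1e-4 relative tolerance respectively).

## Training recipe

- Per epoch, each patient's bag is resampled to K tiles (default K = 512):
  without replacement when the bag has at least K tiles, with replacement
  otherwise. A fresh draw is taken every epoch.
- Adam with decoupled ("AdamW") 1% weight decay on the weight matrices
  (biases and batch-norm parameters are not decayed), β₂ = 0.99, eps = 1e-8.
- One-cycle schedule over 32 epochs, stepped per optimizer update with
  progress = updates_done / total_updates: the learning rate follows a
  half-cosine from max_lr/25 up to max_lr (default 1e-4) over the first
  8 epochs, then a half-cosine down to max_lr·1e-6. The momentum (Adam β₁)
  is modulated the same way from 0.85 up to 0.95 and back to 0.85. Note this
  momentum direction is the opposite of the common one-cycle convention
  (high→low→high); the `momentum_inverted` switch restores the convention.
- Batches of 64 patients; an incomplete final batch is used, not dropped.
- A stratified quarter of each training fold is reserved as an inner tune
  set; its loss and AUROC are recorded every epoch to monitor overfitting.
  No early stopping: the final-epoch parameters are returned.

Evaluation-mode forward passes use batch-norm running statistics and
identity dropout, are deterministic, and are permutation-invariant over
tiles. The full bag (not a resample) is used at evaluation time.

## Preprocessing

Images are tessellated into non-overlapping tiles of 256 µm physical edge,
resampled to 224×224 px (effective ~1.14 µm/px); the source window side is
round(256/mpp) pixels and partial edge tiles are dropped, so the tile count
is exactly floor(W/side)·floor(H/side). Tiles are screened by a Canny edge
criterion: keep iff edge fraction ≥ 0.02 and mean grayscale brightness
≤ 240, with hysteresis thresholds (10, 30) at σ = 1 on the 0–255 grayscale.
These thresholds are this package's own defaults — chosen to reject blank
and blurred tiles while keeping the smooth synthetic tissue renders, and
deliberately config-overridable because renders are smoother than real
histology (real tissue has sharper nuclear boundaries and tolerates higher
thresholds).

Macenko stain normalisation: optical density is OD = −log10((I+1)/255) per
channel; pixels with any channel below β = 0.15 OD are discarded; the top-2
eigenvectors of the OD covariance span the stain plane; the 1st and 99th
percentile angles within the plane give the two stain vectors (α = 1);
columns are sign-fixed non-negative and unit-normalised; the column with the
larger red-channel OD component is hematoxylin (hematoxylin absorbs red
strongly; eosin barely). Concentrations are least-squares solutions; the
99th percentile per stain is the concentration scale. Tiles are re-rendered
under a fixed built-in reference basis (the standard H&E OD vectors) after
per-stain concentration rescaling; normalisation is a first-class switch so
every experiment can be run with and without it. Stain vectors are estimated
once per slide (slides are the staining unit). Estimation failure (too few
tissue pixels, or a rank-deficient OD cloud, threshold: second eigenvalue
below 1e-3 of the first — quantisation noise alone produces ~1e-4) is an
explicit signal; affected slides pass through un-normalised and flagged.

## Synthetic cohorts

The generator produces the study conditions the pipeline is validated under:

- **Feature bags.** Noise tiles are standard multivariate normal in R^d;
  signal tiles add `effect_size` along a fixed unit direction per target
  (two orthonormal directions for the two targets, deterministic functions of
  d). In a positive bag each tile is signal with probability `witness_rate`
  (at least one is guaranteed); negative bags contain none. Default
  prevalences are 0.75 (ER) and 0.65 (PR) with independent targets; a
  Gaussian-copula mode generates correlated targets (the achievable binary
  correlation is capped by the Fréchet bound, ≈0.79 at these margins).
  An Allred-style mode draws integer 0–8 scores calibrated so that
  P(score ≥ 3) equals the prevalence and dichotomises at ≥ 3.
- **Bag sizes** default to 100–300 tiles per patient. Real slides tessellate
  into hundreds to thousands of 256 µm tiles, and the K = 512 resampling in
  the training recipe presumes bags of that order. This is also the regime
  where the default MIL task is statistically solvable: the Bayes-optimal
  (log-likelihood-ratio) AUROC for witness 0.1 / effect 2.0 is ≈0.89 at
  20–60 tiles per bag but ≈0.997 at 100–300, so unrealistically small bags
  would change the task, not merely slow it.
- **H&E-like tiles** are rendered by Beer–Lambert mixing, I = 255·10^(−S c),
  through the same OD convention the estimator uses: Gaussian nuclear blobs
  weight the hematoxylin column, a smooth stroma texture (suppressed under
  nuclei) weights the eosin column, with concentrations reaching deep-stain
  levels so that near-pure pixels of both stains survive the Macenko β
  filter, as they do in real tissue. Signal tiles carry 4× denser, larger
  nuclei. Artifact tiles are near-uniform bright background or heavily
  blurred renders.
- **Shifted cohorts.** With decoupling fraction f, a tile is signal with
  probability witness·((1−f)·label + f·prevalence): at f = 0 the design
  matches the source cohort, at f = 1 signal occurs at the same base rate in
  both classes (labels independent of tiles, forcing AUROC to 0.5), and the
  marginal signal-tile rate is preserved in expectation so the cohorts share
  marginal feature statistics. A feature-shift mode adds a fixed offset
  vector to every tile instead (or in addition).

What the generator does **not** emulate: spatial correlation between
neighbouring tiles, site/scanner batch effects within a cohort, label noise,
class-dependent bag sizes, or realistic nuclear morphology. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that its
qualitative behaviours (learnability, chance-level nulls, domain-shift
degradation, attention concentration) emerge under controlled conditions —
not that any particular clinical AUROC would be reached on real cohorts.

## Evaluation

The primary endpoint is the patient-level AUROC in its Mann–Whitney form
(concordant pairs + half the ties, over n_pos·n_neg pairs), computed from
average ranks. Cross-validation is biomarker-stratified 5-fold at patient
level (per-fold label ratios within one patient of the global ratio); each
fold's model is trained on its training patients minus the stratified tune
quarter and scored on its test fold, so every patient is scored exactly
once. Reported dispersion ("±") is the standard deviation across the five
fold models. External deployment scores the full cohort with each fold model
independently and summarises the five AUROCs the same way; the per-patient
ensemble-mean scores are retained for density diagnostics. Patients lacking
a label for the evaluated target are excluded for that target only.

Significance against chance uses a two-sided label-permutation test of
|AUROC − 0.5| with p = (1 + #{permuted ≥ observed}) / (1 + n_perm),
n_perm = 1000 by default — distribution-free, with the minimum attainable p
of 1/(n_perm+1). A DeLong-style Mann–Whitney normal approximation is
available as an alternative. Domain shift in score space is summarised by
per-cohort kernel-density estimates, quantiles, moment skewness (scores
piling toward 1 give left/negative skew) and the two-sample
Kolmogorov–Smirnov gap.

Cross-target sensitivity deploys the models trained for one biomarker
against the other biomarker's labels; with independently generated targets
this sits at chance by construction, and rises with the generated label
correlation.

## Explainability

Two spatial layers per slide: the attention layer stores each window's
pre-softmax attention logit wᵀ tanh(V h_k) — softmax weights depend on bag
size, so the raw logit is the cross-slide-comparable quantity — and the
prediction layer stores each window's positive-class probability from
applying the classifier to that window's embedding alone (a bag of one),
since the bag head yields only one slide-level score. Layers are min–max
normalised within a cohort (idempotent; a degenerate cohort maps to 0.5
with a warning) and rendered purple→gold (attention) or blue→red
(prediction, blue = negative) over the slide thumbnail. The dense scoring
grid defaults to stride 32 px with the full tile-sized window as receptive
field; bare 32-px windows are equally supported via the window/stride
parameters. Top-n attention tiles are exported with deterministic
lexicographic tie-breaking by (slide_id, x, y).

## Experiment scales and numerical choices

The shipped experiments run on one CPU core:

- Slide-level learning: 200-patient cohorts, d = 64 features, witness 0.1,
  effect 2.0, the full 32-epoch recipe with K = 512. Five-fold CV means
  land around 0.87–0.94 across cohort seeds; the spread is optimization
  variance — 200 patients yield only ~64 optimizer updates versus ~350 in a
  1085-patient cohort, while the Bayes-oracle AUROC of the task is ≈1.0.
- Domain-shift and attention experiments use K = 64: the resampling size
  changes training cost, not the qualitative properties these experiments
  measure (AUROC drop under decoupling; attention enrichment).
- The attention-recovery experiment uses a strong-contrast cohort (witness
  0.2, effect 8.0). Under the mild witness-0.1/effect-2.0 design the model
  separates bags well, but ~100 small optimizer updates move the attention
  head only ~1e-2 in weight space — too little to build O(1) logit
  separation from random initialisation, so attention stays near uniform.
  With tile classes separated as strongly as distinct tissue types are in a
  pretrained encoder's feature space, the same recipe concentrates
  attention on signal tiles (enrichment well above 2×). This mirrors how
  attention maps behave in practice: they sharpen where tile feature
  contrast is large.
- Degenerate inputs are errors, not silent defaults: single-class training
  sets, empty bags, insufficient tissue for stain estimation, missing
  labels. Ties in attention ranking and stain-plane sign ambiguities are
  broken deterministically.

## Known limitations

- The built-in extractor is a seeded random projection, not a learned
  encoder; it fulfils the extractor contract and preserves coarse
  colour/texture, nothing more. Any callable tile→vector can be plugged in.
- NumPy training is single-core; cohorts beyond a few thousand patients or
  K well above 512 would warrant a GPU implementation behind the same
  interfaces.
- Pyramidal scanner formats are out of scope (pre-converted PNG/TIFF only),
  as are stain-normalisation methods other than Macenko.
- The momentum direction follows the recipe's published description; if the
  original experiments used the conventional inverted modulation, results
  differ marginally (the switch exists to check this).
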