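# Methods

This note documents the models, the synthetic data, the parameter choices
and the numerical conventions of `glaucovit`, in the package's own words.
It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

Glaucoma grading from colour fundus photographs is a five-class problem
(`glaucoma`, `normal`, `POAG/NTG`, `referable`, `suspect`) with severe
class imbalance: the reference collection the package's ledgers describe
holds 11,665 images of which only 40 are POAG/NTG and a few dozen are
suspect.  Two structural cues dominate clinical reading: the optic disc (a
bright, roughly circular region) and the optic cup inside it (brighter
still); the cup-to-disc ratio (CDR) grows as glaucoma progresses.  The
package attacks the imbalance with budgeted classical augmentation plus
conditional-GAN sampling, and attacks the subtlety of the cue with a
contour-guided training signal.

## Synthetic fundus phantoms

Real fundus data cannot ship with a library; the phantom generator
(`glaucovit.phantom`) produces the minimal structure the rest of the
toolchain is designed to detect:

* background plateau at intensity 40, a filled elliptical disc at 150, a
  concentric cup at 220 — the cup brighter than its surrounding disc, as on
  a real photograph;
* per-class default CDRs {normal 0.30, suspect 0.45, referable 0.55,
  POAG/NTG 0.60, glaucoma 0.70}: a clinically plausible, strictly
  increasing encoding of severity.  These are fixture constants,
  overridable in configuration;
* darker random-walk vessel polylines, a linear illumination gradient
  (default 0.15 intensity/px) and Gaussian sensor noise (default σ = 4 on
  the 8-bit scale);
* per-image seeds derived from `SeedSequence(master, spawn_key=(class,
  index))`, so a dataset is bit-reproducible from one integer yet images
  are mutually distinct.

What the phantoms do **not** model: photographic texture, vessel branching
topology, peripapillary atrophy, media opacity, camera vignetting, or any
pathology other than cupping.  A test passing on phantoms therefore shows
that an operator implements its contract (geometry recovery, loss algebra,
learnability of a separable signal) — not that the pipeline reaches
clinical accuracy on real fundus images.

Default sizes: 64 px phantoms for classifier work, 512 px being the
full-scale setting for real photographs; the GAN works at 16–32 px at desk
scale.

## Contour chain

Grayscale (luma 0.299/0.587/0.114) → Gaussian blur (default 5×5 kernel,
σ = 0.3·((k−1)/2 − 1) + 0.8) → 3×3 Sobel → non-maximum suppression →
double threshold (low 0.10, high 0.30 of the maximum magnitude) →
eight-connected hysteresis.  The published description names the kernel
family but no thresholds; the defaults here are the common Canny choices
and every parameter is a flag.

Numerical conventions, fixed once and mirrored bit-for-bit by the
brute-force reference (`glaucovit.reference`):

* reflect (mirror-without-edge) borders; convolution taps accumulate in
  row-major order so vectorized and per-pixel loops produce identical
  IEEE-754 sums;
* gradient direction quantized to 4 bins by sign/slope comparisons against
  tan 22.5° and tan 67.5° — no trigonometry, hence no rounding ambiguity at
  bin boundaries; the `direction` field in degrees is diagnostic only;
* suppression keeps ties (`>=` both neighbours); out-of-frame neighbours
  count as magnitude 0;
* a pixel exactly at `high·max` is strong (inclusive); a maximum magnitude
  below 1e−9 (the numerical residue of blurring a flat image) means an
  empty contour;
* coordinates are 0-based (row, col) throughout.

The full-chain bit-identity against the independent nested-loop reference
on 100 random 32×32 images is asserted by the test suite and recomputed by
the acceptance script.

**Disc localization** runs a circular Hough transform over the edge map and
returns the accumulator maximum with deterministic (row, col, radius)
tie-breaking.  Votes are deliberately *unnormalized*: a complete circle
scores about its circumference, so the outer disc ring dominates the
equally complete but smaller cup ring.  The accumulator itself comes from
scikit-image; candidate selection and tie-breaking are the package's.

**Cup segmentation** thresholds the disc ROI at `percentile` percent
(default 70) of the robust ROI intensity *range* (5th–99.5th intensity
percentiles) and reports CDR = sqrt(cup area / disc area).  A rank
percentile was rejected by design: on continuous-valued images the mask
fraction above a rank cut is identically (100−p)/100, making the estimate
independent of actual cup size; an intensity-level cut recovers the
constructed CDR exactly on two-level phantoms and stays monotone in the
bright-core size of GAN outputs.  A uniform ROI degenerates to an empty cup
(CDR 0, finite by convention).  Disc/cup localization is a diagnostic/QC
output; it does not feed the classifier.

## Classical augmentation

Ops: transpose, horizontal/vertical flip, rotation ({90°, 180°, 270°} plus
a ±15° range), brightness (±30), Gaussian blur (σ 0.5–1.5), elastic
distortion (α = 6, σ = 4), contrast scaling (0.7–1.3 about the mean), and
CLAHE (8×8 tile grid, clip limit 0.02 in scikit-image's fractional
convention, the analogue of the common clip limit 2).  The published op
list carries no parameters; these ranges keep a centred disc in frame and
the phantom's dynamic range intact.  Budgets are explicit per-class counts
of new images because the published generation ledger implies non-uniform
multipliers (glaucoma ×3, referable ×2, normal ≈ ×1.27).

## Conditional GAN

Encoder → (class logits, latent), generator (latent + one-hot class →
tanh image), critic (realness scalar + class logits).  The loss system:

* gradient penalty `λ₁·E[(‖∇x̂ Ds(x̂)‖₂ − 1)²]` with λ₁ = 10 at convex
  interpolates with ε ~ U[0,1] drawn fresh per sample;
* auxiliary classifier loss: categorical cross-entropy against the true
  class.  The printed auxiliary form without a label dependence (an entropy
  of a softmax) is kept as the diagnostic `entropy_monitor`;
* critic objective `E[Ds(fake)] − E[Ds(real)] + GP ± λ₂·L_CE`.  The
  package's training default *adds* the auxiliary term to the minimized
  objective (the AC-GAN convention: the class head is trained toward the
  labels).  The alternative subtracted composition is available as
  `aux_sign_convention="as_printed"`; measured on phantoms it anti-trains
  the class head and the reconstruction error diverges instead of falling,
  which is why it is not the default.  The pure `discriminator_loss`
  function itself is the exact subtracted-form transcription;
* encoder+generator objective `E[Ds(fake)] + λ₄·log p(Dd(fake)=class) −
  λ₅·L1(x, x̄) − L_CE`, maximized (implemented as minimizing its negation).
  The class-consistency term uses the log-probability for gradient health;
  a raw-probability mode exists in configuration.  λ₂ = λ₄ = λ₅ = 1.
  λ₃ is stored but enters no composition (it is declared but unused in the
  source formulation; kept for fidelity);
* expectations are batch means; the GAN batch size is a configuration
  choice (default 16 full scale, 8 desk scale).

Architecture: 1×1/3×3 convolution blocks with batch-norm + ReLU and
stride-2 resampling stages, linear heads; nearest-neighbour upsampling +
convolution in the generator; the critic is normalization-free with leaky
ReLU, as a per-sample gradient penalty requires.  Latent dimension 128 full
scale, 16 at desk scale.  Optimizer: Adam(lr 1e−4, β = (0.5, 0.9)),
`n_critic` = 5 critic updates per generator update at full scale; the desk
configuration uses `n_critic` = 1 to fit CPU budgets.

The encoder is deterministic: the formulation is conditional with a
reconstruction path, and no sampling or KL term appears in its published
description, so none is invented.  Class-conditional *sampling* draws
`z ~ N(0, I)` — the natural prior matching the latent scale.

## Dual-branch transformer

Backbone: conv patch embedding (patch 32 at 512 px; patch 8 at 64 px desk
scale) + learned positional embeddings → pre-norm transformer encoder
stack → decoder whose learned query embeddings self-attend and
cross-attend to the encoder memory → layer-norm, mean over query outputs →
linear 5-way presence head.  Full-scale depth 6+6, desk scale 2+2 with
hidden 64, 2 heads, 8 queries, dropout 0.1.  Positional/query embeddings
initialize at σ = 0.005 so an untrained network attends near-uniformly on
featureless inputs.

Training computes `ŷ = backbone(image) + backbone(contour)` with a single
shared parameter set — the equation uses one backbone symbol for both
branches, and sharing is what makes the image-only inference path
well-defined — then softmax and the weighted cross-entropy (batch-mean
form; probabilities clamped at 1e−12 with a warning).  Class weights are
inverse-frequency, `w_j = N/(C·n_j)` with C = 5; balanced data gives unit
weights, and `Σ_j w_j·n_j = N` always.  Optimizer Adam with lr 1e−5 and
weight decay 1e−6 at full scale; the desk configuration raises lr to 3e−4
because a 2-layer model on 64 px phantoms sees far fewer steps.

Inference applies softmax to the image branch alone and breaks argmax ties
toward the smaller class code.  Decoder cross-attention maps (mean over
queries per head; each sums to 1 over spatial positions) are exported for
inspection, and pooled decoder features are exported as CSV for external
embedding such as t-SNE.

## Pipeline and bookkeeping

Phase 1 (generation): split originals 70/15/15 stratified by class
(the published protocol reserves 30% for validation+testing without fixing
the ratio; 15/15 is the package's choice, configurable), then add
augmentation and GAN budgets and extract one contour per training record.
Phase 2 (training) consumes (image, contour) pairs; phase 3 (inference)
consumes images only.  Manifests are append-only across phases, ids stay
unique, augmented/generated records are train-only, and per-class ledger
totals are logged after every phase.

The package ships the published ledgers as constants: the source table
(totals 11,665 across 10 named datasets) and the generation ledger
(augmented 20,092 + generated 4,035 = 24,127 combined training records;
e.g. glaucoma 4,794 + 1,000 = 5,794).  Two published inconsistencies are
kept as published and logged rather than resolved: the suspect class sums
to 25 in the source table but 27 in the generation ledger, and the prose
generation counts for suspect/POAG-NTG (123/140) disagree with the tabled
budgets (15/20) — only the table is consistent with the 4,035 total, so
the table is normative.

## Desk-scale study conditions

Chosen once for CPU execution and used by both the test suite and the
acceptance script:

* classifier end-to-end: 3 classes (normal/suspect/glaucoma), 200 phantoms
  per class at 64×64, noise σ = 4, 10 epochs, batch 50, three seeds;
  the check asks for above-chance test accuracy in at least 2 of 3 seeds;
* GAN progress: 2 classes, 24+24 phantoms at 16×16, 500 steps, three
  seeds; the check compares the median reconstruction L1 of the last ten
  steps against the first ten;
* contour oracle: 100 random 32×32 images, bit-identity required;
* contour-branch benefit: 5 seeds on noisy 32×32 phantoms (60/class,
  6 epochs), mean validation accuracy with the dual-branch alignment versus
  image-only training; the two numbers are reported by the acceptance
  script, not asserted, since the effect at this scale is small relative to
  seed noise;
* ledger checks run in dry-run manifest mode (records without pixels), so
  the published totals are verified in seconds.

## Known limitations

* The phantom's separability makes classification easier than on real
  fundus images; desk-scale accuracies say nothing about clinical
  performance.
* The autodiff core favours clarity over speed; full-scale (512 px, depth
  6+6) training is out of reach on CPU and untested.
* The GAN's conditional separation at 16×16 after a few hundred steps is
  weak — the CDR probe separates the conditions in most but not all seeds;
  longer training sharpens it.
* Cup segmentation assumes the cup is the brightest structure inside the
  disc; pathologies that brighten the rim would bias the CDR estimate.
* The t-SNE embedding itself is out of scope; only feature export is
  provided.
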