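# Methods

## The model

A multilevel taxonomic classifier predicts one category per rank of a
biological hierarchy (Kingdom → … → Species) from a single colour
image. One convolutional backbone produces a feature vector that is
forwarded to L isolated fully connected layers, one per rank; layer
*i* has as many output neurons as rank *i* has categories and applies
its own softmax, σ(z)ᵢ = exp(zᵢ)/Σⱼ exp(zⱼ) (computed with
max-subtraction). The training objective is the unweighted sum of
per-rank categorical cross-entropies; weighting across ranks is
exposed as `TrainConfig.level_weights` but defaults to equal, the
minimal assumption. A flat classifier — a single head over the finest
rank — is the same machinery with one softmax group.

The heads are independent, so argmax decisions need not trace a valid
root-to-leaf path; `is_consistent_prediction` quantifies cross-rank
agreement as a diagnostic.

### Backbone

Any object with `forward: (N, H, W, 3) → (N, feature_dim)` can serve
as the backbone (`BackboneContract`). The default, `TinyConvBackbone`,
is three 3×3 convolution blocks (ReLU, 2×2 average pooling) with
He-scaled Gaussian filters drawn once from a seeded generator, global
average pooling, 64 features. The filters stay frozen and only the
heads train — a linear probe over random convolutional features, the
desk-scale analogue of fine-tuning a pretrained backbone. This keeps
the whole pipeline NumPy-only and lets full training runs (including
the cascade, which trains 1 + R models) finish in CPU seconds.
Features are standardized per dimension (zero mean, unit variance,
statistics frozen from the training split and stored with the
checkpoint); this conditions the head optimisation independently of
the backbone's activation scale and is what makes small-margin
distinctions (sibling species differing only in a small marking)
train reliably.

### Optimisation and early stopping

Adam with the reference hyperparameters: learning rate 1e-4 (the
tests and examples use larger rates because a linear probe tolerates
them; the default stays faithful), β₁ 0.9, β₂ 0.999, ε 1e-7. An
AMSGrad toggle exists because the update rule could be read either
way; plain Adam is the default. Batches are reshuffled every epoch
from the config seed.

Training nominally runs forever: an evaluation every
`test_interval_epochs` (10) epochs monitors finest-rank top-1, and the
loop halts once `patience_tests` (10) consecutive evaluations fail to
beat the best by more than `min_delta` (0 — "significant" is left to
the user). The returned model is the best checkpoint, not the last.
The monitored split defaults to the test split, reproducing the
reference protocol; the trainer logs a warning, and any split can be
monitored instead (`eval_split`), with `holdout_split` providing a
stratified train carve-out.

## Data handling

Pixel convention everywhere: RGB, channel-last, float in [0, 1].
Resizing is corner-aligned bilinear (`map_coordinates` on a
`linspace(0, n−1, out)` grid) — chosen over the half-pixel-center
convention so that resampling is exactly interpolatory at the corners
and the arithmetic is auditable by hand. Non-square images are resized
anisotropically to the square input; no letterboxing. Grayscale images
are replicated to three channels.

Two manifest dialects are read: the iNaturalist-competition COCO-style
JSON (images / annotations / categories with the seven rank fields)
and a flat CSV (path, split, one display name per rank, plus
augmentation-provenance columns). Category ids are dense 0-based
integers per rank assigned by lexicographic display-name order, so
identical records always produce identical trees with no external id
files. Splits are adopted verbatim; nothing is deduplicated or
filtered.

## Augmentation and balancing

`standard` applies a random non-empty subset of six operators in a
fixed canonical order (geometric → photometric → noise → blur):
horizontal flip, vertical flip, channel shift, brightness/contrast,
Gaussian noise, Gaussian blur. The source protocol leaves the
parameter ranges unstated; the defaults (flip probability 0.5 each,
channel shift ±0.1, brightness ±0.2, contrast 0.8–1.2, noise σ up to
0.05, blur σ up to 1.5 px) are mild enough to preserve class identity
and are serialized into every run config so they are auditable.

`central_crop` takes the centered window of side `round(0.8·side)`
(offsets computed in integer arithmetic, `(side − new)/2` floored, to
dodge float rounding); the crop fraction is read as a per-dimension
linear fraction, consistent with the 50–80% phrasing of the
multiscale variant. Crops happen before resizing, on the
original-resolution image. `multiscale_crop` adds three central crops
with independent fractions uniform in [0.5, 0.8]. Both crop regimes
also apply `standard`.

Balancing equalizes every finest-rank class to the pre-balance
maximum count. Crop regimes first add their crop records (one per
source for central, three for multiscale), then under-represented
classes gain augmented copies of their own records, round-robin over
sources, until counts are exactly equal. Augmented records are lazy:
they store (source path, transform seed, crop fraction) and are
materialised at load time, so the record-count contract holds without
writing the hundreds of thousands of files a materialised balanced
set would need; the seeded lazy scheme also makes the balanced set
identical across experiments. The test split is never touched.

## Ensembles

*Boosting*: per rank, combined score = Σᵢ wᵢ·yᵢ over members,
renormalised; wᵢ is member *i*'s measured top-1 accuracy. The
weights are per rank by default (each rank's combination uses that
rank's accuracy); a single global weight per member is available via
`measure_member_weights(per_level=False)`, since the source phrasing
("its theoretical accuracy", singular) is ambiguous. Weights are
measured on a stratified 10% train carve-out by default; measuring on
the test split (the looser historical protocol) is possible by
passing that stream explicitly.

*Stacking*: meta-features are the concatenated log-probabilities of
all members at all ranks (log rather than raw probabilities so that
an identity-initialised meta-layer reproduces a single member exactly
— softmax inverts the log). The meta-model is one fully connected
layer with one softmax group per rank, trained with the same Adam
machinery on frozen member outputs from the carve-out, never from
the members' own training stream.

*Cascade*: a router classifies one coarse rank (Phylum in the
reference setting, 4 categories); one specialist per routing category
is trained only on that category's records, over label spaces
restricted and reindexed to its subtree. At prediction time the
router's argmax selects the specialist; its subtree-local
probabilities are scattered back to global ids (exactly zero mass
outside the routed subtree), ranks coarser than the routing rank are
filled one-hot from the routed category's ancestors (exact in a
tree), and the routing rank keeps the router's own probability
vector. Specialists do not re-predict the routing rank. A routing
category with zero training records is an error naming the category.

Argmax ties break toward the lowest category id everywhere
(stable argsort), so all decisions are deterministic.

## Evaluation

Per rank: top-1 and top-5 accuracy (top-k falls back to k = rank size
for ranks with fewer than five categories). At the finest rank:
per-class one-vs-rest precision/recall/F1 from argmax decisions,
support-weighted mean F1 over classes with non-zero support, and
macro one-vs-rest ROC AUC over classes with at least one positive and
one negative. The per-class F1 distribution is summarised by a normal
fit: μ is the sample mean and σ the population standard deviation
(divide by n; the sample convention is behind `sample_sd=True`),
matching the descriptive use of such fits; the empirical coverage
within μ±σ and μ±2σ is reported rather than assumed from normality.
F1/AUC are computed via scikit-learn; the test suite checks every
metric against independently coded brute-force enumerations.

## The synthetic benchmark generator

The generator emulates the statistical structure of crowd-sourced
wildlife imagery without any photorealism:

* **Rank-nested appearance.** The coarsest ancestor sets the
  background hue band; intermediate ancestors set the subject
  silhouette (fixed shape alphabet), fill texture, and stroke
  pattern; the leaf sets only a small checkered marking at the
  subject's centre (~30% of the subject side). Coarse attributes
  therefore occupy many more pixels than fine ones, which yields the
  coarse-to-fine accuracy decay seen in real taxonomic data and makes
  "clades share features" true by construction.
* **Pathologies.** Strong class imbalance (per-leaf counts, with a
  geometric long-tail helper), subject scale from full-frame down to
  a small patch at a random position, background clutter blobs,
  additive Gaussian noise, probabilistic Gaussian blur. Defaults:
  scale 0.3–1.0, noise σ 0.05, blur probability 0.25 — mild but
  non-trivial conditions.
* **Determinism.** Each sample's randomness comes from
  `SeedSequence(seed, spawn_key=(leaf, index))`, and all stochastic
  draws are independent of the leaf identity, so generation order
  never changes content, identical generator states give identical
  images, and two leaves sharing all ancestors render identically
  outside the marking box — properties the tests assert literally.

What passing tests on this generator do **not** show: robustness to
real photographic nuisance (pose, lighting, occlusion by vegetation,
mislabeled subjects), inter-class similarity gradients finer than the
marking construction, or anything about full-scale backbone training.
The generator validates the machinery — losses, balancing, ensembles,
evaluation, reproducibility — not field accuracy.

## Study conditions used by the tests and the acceptance script

* Structural checks build the published rank shape 3/4/9/34/57/72/1010
  via `make_shaped_taxonomy` (category *c* at rank *i* parented to
  *c* mod sizeᵢ₋₁) and verify 7 heads, widths 1010/57, and 4 cascade
  specialists.
* Balancing arithmetic uses 1010 classes with a 350 maximum → 353 500.
* The end-to-end run uses branching (2,2), 10 images per leaf
  (32 train / 8 test), 32 px, zero noise/blur, subject scale fixed at
  1.0. Under these conditions every render of a leaf is identical, a
  nearest-centroid oracle on raw pixels is exact, and the trained
  probe must reach 1.0 top-1 at both ranks.
* The augmentation-direction experiment imposes a (20, 10, 4, 2)
  long-tail train profile on a branching-(2,2) set (noise σ 0.3, blur
  0.25, scale 0.8–1.0) and evaluates finest-rank top-1 on a balanced
  160-image test split — the balanced-evaluation protocol standard in
  imbalance studies, since gains concentrate in minority classes.
  The per-seed effect of balancing-with-augmentation is small
  (~+0.03) against per-run noise of similar size, so the claim is
  directional and averaged over paired seeds (5 in the test suite, 10
  in the acceptance script); a single unlucky seed pair can still be
  negative, which is the honest behaviour of a small effect at this
  scale with a frozen backbone.

Problem sizes throughout (32 px images, tens-to-hundreds of samples,
64 features) were chosen so the full suite and the acceptance script
run in well under a minute each on one CPU; they are desk-scale
stand-ins, not reproductions of the full 268k-image experiments.

## Known limitations

* The backbone does not train; effects that depend on representation
  learning (e.g. augmentation reshaping features, resolution scaling
  laws) appear only in attenuated, linear-probe form.
* No validation-split discipline by default (kept for protocol
  fidelity); unbiased model selection requires `eval_split` plus
  `holdout_split`.
* DAG taxonomies, partial rank paths and video input are out of
  scope; the cascade routes at exactly one rank.
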