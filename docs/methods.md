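# Methods

## Problem and pipeline

A seed mix is described by a composition vector **y**: nonnegative weight
fractions over an ordered catalog of categories, summing to 1. The canonical
catalog has 12 categories — 11 cereal/legume varieties plus a residual
"other" class — because physically weighed ground truth includes debris
(stems, husks, unidentified seeds) and cannot sum to 1 without it. An
11-category catalog (no residual) is supported through the same types for
settings where the residual is absent; the `includes_other` flag on the
catalog selects the regime. The residual label is always last, and serialized
vectors always use the fixed canonical variety order, so files from different
runs are comparable.

The pipeline is: render (or load) images with per-image ground truth → split
by mix → train a regression head on image features → predict per-image
compositions → aggregate per mix → convert to nutritional value.

## Losses and heads

Scores **z** ∈ ℝᵈ from the model are converted to simplex outputs by the
head paired with the training loss:

* **KL divergence on softmax.** KL(**q** ‖ softmax(**z**)) with the target
  **q**, using the 0·log 0 convention on the target side and a fused
  log-softmax (no ε-clamping of probabilities). The direction is
  target-relative — the standard distribution-fitting form. Gradient:
  softmax(**z**) − **q**.
* **Sparsemax.** The Euclidean projection of **z** onto the simplex,
  computed by the sort-based threshold algorithm: with z₍₁₎ ≥ … ≥ z₍d₎,
  the support size k is the largest j with z₍ⱼ₎·j > Σᵢ≤ⱼ z₍ᵢ₎ − 1, the
  threshold is τ = (Σᵢ≤ₖ z₍ᵢ₎ − 1)/k, and the output is max(z − τ, 0).
  Its companion loss is
  L(**z**; **q**) = −**q**·**z** + ½ Σ_{j∈S} (zⱼ² − τ²) + ½‖**q**‖², with
  S the support; it is nonnegative, zero iff sparsemax(**z**) = **q**, and
  its gradient is sparsemax(**z**) − **q** — the property the training loop
  uses. The projection is unique, so sort tie-breaking cannot change the
  result; the implementation is nevertheless deterministic (stable sort).

Batch reduction is mean over images, sum over categories, for both losses.
In tests, sparsemax is validated against an independent oracle that bisects
the water-filling threshold (a different algorithm from the sorting route)
and the loss gradient against central differences.

## Synthetic renderer

The renderer emulates the acquisition protocol: a round box centered on a
uniform background, photographed from above; each mix is scooped into 5
samples and each sample photographed 5 times, with the box shaken between
photos. Emulated features: occlusion and partial visibility (random z-order
painting of rotated ellipses), per-seed size and color variation, global
lighting gain per photo, additive sensor noise, and debris ("other") as
irregular polygons. Not emulated: photorealistic texture, camera optics,
shadows, perspective, seed-on-seed physics; synthetic "other" makes no claim
of visual realism. Consequently, passing recovery tests shows the pipeline's
machinery (targets, splitting, optimization, aggregation, conversion) is
correct and that composition is recoverable from color/shape statistics at
the rendered contrast — it does not show that the desk backbone would reach
the same accuracy on real photographs of visually similar grains.

Ground truth is *exact by construction*: requested fractions are converted
to integer seed counts by largest-remainder rounding of
mass·wᵥ/per-seed-massᵥ (total count fixed to the rounded ideal total), and
the stored target is recomputed from the integer counts — mirroring physical
weighing, and keeping targets exactly consistent with the rendered pixels.
If the residual class has weight but no rendering profile, its mass is kept
continuous (weighed, not discretized); with the preset profiles it is
rendered as debris particles. Requested varieties whose ideal count rounds
to zero produce a warning, and the realized composition reflects the zero.

Per-seed masses and colors are configuration defaults chosen at the order of
real thousand-kernel weights (e.g. wheat 45 mg, faba bean 550 mg); none is a
measurement. The 6-variety high-contrast profile set exists so desk
experiments do not hinge on fragile visual similarity. Coordinates are pixel
coordinates, origin top-left, y down; ellipse angles in degrees CCW. All
randomness flows from one dataset seed; each image's sub-seed is the SHA-256
hash of (dataset seed, mix id, sample index, shake index), recorded in the
metadata, so any image can be re-rendered bit-identically in isolation.

Default study conditions for the recovery experiment: 40 mixes over the 6
high-contrast varieties, 1–4 varieties per mix with Dirichlet(1) fractions
(each present variety ≥ 5% so discretization cannot erase it), 12 g samples,
5 samples × 5 photos, 128 px renders. The sizes keep a full render + 5
training runs within a couple of minutes on one CPU while leaving ≈ 200
validation images across 8 held-out mixes.

## Splitting and augmentation

The split unit is the mix: photos of one mix are near-duplicates, and an
image-level split would leak validation content into training. Validation
mix count is round(val_fraction · n_mixes), minimum 1; mix ids are sorted
before seeded shuffling so the split is invariant to manifest row order.
Reference campaign bookkeeping (images per year/type, split totals) ships in
`seedmix.reference` for consistency checks. The historical 163/42 partition
of 205 mixes recorded there does not equal round(0.2·205) = 41 under any
standard rounding; the package documents its own rule rather than guessing
the original's.

Augmentation policies are named, ordered and serializable
(`center_crop`, `random_rotation`, `color_jitter`, `auto_contrast`,
`randaugment`, `autoaugment`); they apply to training images only —
validation gets the deterministic resize + center crop. The automated
policies are applied as compact random sequences over a shared pool of PIL
operations and echo their standard configuration strings (e.g.
"rand-m9-mstd0.5", policy V0); re-deriving the published sub-policy
schedules is out of scope. With augmentation enabled, each training image is
augmented once per fit (features are extracted a single time), a deliberate
trade of augmentation diversity for CPU time.

## Model and training

`tiny_cnn`, the desk backbone: the image is resized (shorter side) to 128 px
and center-cropped; a 64×64 downsample is cut into 8×8 patches projected
through a fixed Gaussian filter bank (48 filters, seeded once as an
architecture constant) with ReLU, mean- and max-pooled over patches; a 4³
RGB histogram and global color mean/std are appended (166 features).
Features are standardized with training-set statistics stored in the
checkpoint. Only the linear score head is trained. The large pretrained
classification backbones are declared with their native resolutions
(380/384/512 px) behind the same `BackboneSpec` contract but raise on build:
they need a GPU deep-learning runtime and pretrained weights that this
package does not ship.

Training is plain minibatch SGD (batch 10) with reduce-on-plateau: when the
validation MAE has not improved (by > 1e-6 absolute) for 5 consecutive
epochs, the learning rate is multiplied by 0.1. The learning rate default is
per-backbone — 5e-5 for the large pretrained architectures at batch 10,
scaled to 0.05 for the tiny backbone whose trainable part is a linear head
on standardized features — following the usual practice of maintaining a
comparable step-to-parameter-scale ratio across model sizes. Model selection
is lowest validation image-level MAE. A NaN/inf epoch loss aborts with a
diagnostic. Fits are deterministic given the config seed; checkpoints are
single-file JSON (weights, scaler, config, catalog, history).

For the desk-scale recovery experiment the sparsemax head is the default
objective: with a linear head its gradient (sparsemax(**z**) − **q**) makes
training a projected least-squares fit, which matches the MAE evaluation
metric, whereas KL weights *relative* error — it drives scores for
absent-variety categories without bound, which at this feature scale costs
generalization. Both heads remain available and tested; the sparsemax head
also exhibits the expected behavioral difference (exact zeros in
predictions) against the softmax head's strictly positive outputs.

## Metrics and aggregation

MAE and MSE pool over all (row, category) pairs. R² is pooled across
categories and rows (one scalar per model), with the baseline being the
per-category mean of the *evaluated* truth — so the constant-mean predictor
scores exactly 0; a constant truth makes R² undefined and is reported as
such rather than as a number. Max MAE/seed names the worst-predicted
category, ties broken by catalog order. Mix-level predictions are arithmetic
means of image-level simplex vectors (closed under averaging, no
renormalization); mix-level truth is the mean of the per-sample realized
compositions, which differ only by count rounding.

## Nutrition

MFU/kgDM of a composition is Σᵥ w̃ᵥ·mfuᵥ over the 11 tabulated varieties,
where w̃ is the composition renormalized after removing the residual class
(debris has no tabulated feed value; a residual fraction above 0.15 logs a
warning because the extrapolation grows aggressive). The tabulated values
are stored as exact decimals; no dry-matter correction is applied (they are
already per kgDM). The conversion is linear at fixed residual fraction, so
converting-then-averaging equals averaging-then-converting whenever a mix's
images share their residual fraction; otherwise the two differ by at most
(max−min table value) × spread of the residual fraction. Outputs always lie
within the table's [0.93, 1.34] range. 1 MFU = 1,700 kcal.

## Numerical choices and degenerate inputs

* Composition validation tolerance: 1e-6 by default for user data (1e-4 for
  CSV round-trips at the 6-decimal serialization precision); accepted
  vectors are renormalized to sum exactly to 1.
* Renormalization divides by the known-mass total rather than 1 − other, so
  the output is exactly on the simplex after float rounding; an entirely
  residual composition raises.
* sparsemax_loss clips a ≤ 1e-16 negative rounding residue at the optimum
  to 0.
* Overfull boxes (requested seed footprint > 5× box area) raise with a
  suggestion to lower the sample mass.
* Unreadable images at prediction time are skipped with a collected warning;
  the batch keeps row order for the remaining images.

## Known limitations

The renderer's visual simplicity means desk-scale accuracy numbers do not
transfer to real photographs; the tiny backbone has no capacity for the
fine shape/texture cues that distinguish visually similar grains (vetch vs
forage peas, triticale vs wheat); the automated augmentation policies are
approximations by name; and stratified or composition-balanced splitting is
not implemented.
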