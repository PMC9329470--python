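# Methods

`silfat` re-implements, at desk scale, a pipeline that estimates body-fat
distribution from the binary outline of a person: two orthogonal silhouette
projections of a segmented whole-body volume are fed to a multi-task
convolutional regressor that predicts visceral (VAT), abdominal subcutaneous
(ASAT) and gluteofemoral (GFAT) adipose-tissue volumes and the VAT/ASAT
ratio. Because the population imaging data behind the original analysis is
access-controlled, the package ships a synthetic body-phantom cohort whose
statistical structure emulates that population; every downstream claim the
test suite makes is therefore a claim about recovery of a *known* generative
model, not about human anatomy.

## The phantom population model

Each body is a stack of elliptical axial cross-sections: a head/neck/torso
column, two arms, two legs. Voxels carry labels in
`{background, lean, VAT, ASAT, GFAT, other_fat}`. The design goal is that
depot volumes are **analytically controllable**: per-slice target areas are
derived from closed-form depot "intents", so the rasterized volumes track the
latent model to well under 1%.

Latent variables per participant:

- `size_factor` (SF) — global girth scale, `ln SF ~ N(0, 0.12)`. Cross-section
  areas scale with SF, so weight, BMI, waist and all depots co-vary with it.
- `vat_asat_shape` (s) — the fat-distribution axis, `s ~ N(0, 1)`, independent
  of SF. It multiplies VAT by `exp(+k_v s)` and ASAT by `exp(-k_a s)`.
- `gfat_factor` — an independent log-normal GFAT multiplier.
- height, age, sex — Gaussian/sex-specific marginals from the reference
  population (male 176.3 ± 6.6 cm, 65.2 ± 7.7 y; female 162.8 ± 6.35 cm,
  63.8 ± 7.5 y; 51% female).

The dispersion constants `k_v`, `k_a`, `sigma_g` are solved in closed form so
each depot's log-variance matches the reference coefficient of variation
(male VAT 5.0 ± 2.3 L, ASAT 5.9 ± 2.5 L, GFAT 9.3 ± 2.6 L; female 2.6 ± 1.5,
7.9 ± 3.3, 11.3 ± 3.2 L), with base volumes mean-corrected analytically
(`E[SF² e^{ks}] = e^{2σ_SF² + k²/2}`). Nothing is tuned empirically; realized
sex-stratified means land within a few percent of the targets.

**The waist-invariant shape axis.** The shape axis must be invisible to a
tape measure but visible to a silhouette — this is the scientific point of the
whole exercise. The abdominal outer wall is sized from the *shape-neutral*
depot intents, giving a perimeter independent of `s`; `s` then (a) moves the
interior VAT/ASAT boundary and (b) re-aspects the outer ellipse (depth/width
`q ∝ e^{0.15 s}`) at **fixed perimeter**, solved exactly via the Ramanujan
perimeter approximation, which is linear in the semi-major axis at fixed
aspect. Consequence: VAT/ASAT ratio rises strictly with `s`, waist
circumference changes < 1% over ±1.5 SD, but coronal width and sagittal depth
trade against each other — exactly the information a two-view silhouette
carries and a single circumference cannot.

Fat is distributed along the body axis by flat-topped (Tukey) windows — VAT
over height fractions 0.32–0.54, ASAT 0.28–0.56, GFAT split 35% to a pelvic
ring (0.50–0.58) and 65% to thigh shells (0.58–0.78) — normalized on the
realized slice grid so depot volumes are exact up to voxelization. Lean
cross-section anchors were set once from anatomical plausibility (they
reproduce waist ≈ 93/90 cm and weight ≈ 78/66 kg for the reference male /
female, a few percent from the reference means; only the *depot* marginals
carry an accuracy requirement).

Anthropometrics are *measured from the voxel grid*, not copied from the
latents: height from occupied slice extent, weight from per-label volumes at
1.06 kg/L (lean) and 0.92 kg/L (fat), waist/hip as marching-squares contour
perimeters at the widest slice of a z-window (the landmark is a package
choice; the source analysis used field tape measurements), and five
bioimpedance channels as noisy affine functions of lean volume / height².
Contours are measured on a lightly Gaussian-smoothed mask so the sub-pixel
level set tracks the shape rather than the voxel staircase (a 150 mm disc
measures 94.9 cm against the analytic 94.2 cm at 2.232 mm pixels).

An `analytic_cohort_table` pathway draws the same population without
rasterizing voxels (waist/hip from the same closed-form slice-content
formulas plus 0.8 cm of tape noise). It exists for large-n epidemiological
simulations where building 20,000 volumes would be wasteful; the rasterized
and analytic pathways share the latent model and constants.

## Disease simulation

Prevalent disease is Bernoulli with logit `β₀ + β_r z(ratio) + β_b z(BMI) +
β_a z(age) + center`, z-scores sex-stratified; incident disease among the
disease-free has exponential event times with proportional hazards in the
same covariates, censored administratively at `U(0, 2·2.8)` years so the
realized median follow-up is 2.8 years. Generating effect sizes use the
published association scale where available (e.g. type-2-diabetes OR/SD 1.78
male / 1.97 female; incident coronary-disease HR/SD 1.19 / 1.09; baseline
prevalences 6.5%/3.1% T2D, 7.9%/2.0% CAD, 37.0%/24.6% hypertension,
27.7%/15.4% hypercholesterolemia) and documented defaults elsewhere.
Imaging centers get small random intercepts (±0.05 logits).

## Silhouette construction

Axial slices are segmented by global Otsu thresholding (a fixed threshold is
available), keeping 4-connected components at least 25% of the slice's
largest — pure largest-component would amputate a leg below the crotch — and
filling in-plane holes. Projections are filled shadows: a coronal pixel
`(z, x)` is 1 iff any segmented voxel exists along y (an `--outline` variant
keeps the 1-pixel boundary). Panels are aspect-corrected for anisotropic
voxels (nearest neighbor), centered and rescaled each into a 237 × 128 frame
and concatenated — coronal left, sagittal right — into the fixed 237 × 256
binary image. All resampling is nearest-neighbor with a 0.5 re-threshold so
binarity is exact by construction. The per-panel 128/128 split, centering,
and binarize-before-resize order are package choices; the upstream
publication does not pin them down.

Multi-series acquisitions are supported by `merge_series`: trilinear
resampling to the target grid (default 3.0 × 2.232 × 2.232 mm z/y/x),
placement by z-offset, overlap resolution by `keep_first` or `mean`, and a
hard error on gaps of more than one slice.

## The multi-task regressor

A small convolutional trunk — 4× average-pooled input, three strided ReLU
convolutions (8, 16, 32 channels), a 64-unit dense layer — feeds one linear
layer with four outputs, i.e. per-task heads on a shared embedding
(~1.4 × 10⁵ parameters). Targets are standardized per task with training-split
statistics; the loss is equally weighted MSE; optimization is Adam (lr 1e-3,
batch 32) with early stopping (patience 10, restore-best) on the inner
held-out fold. The implementation is plain numpy (im2col convolutions,
hand-written gradients, verified against finite differences): no deep-learning
framework is assumed by the runtime environment, and at this scale numpy on
one CPU is entirely adequate. A DenseNet-scale trunk is out of scope.

**Nested cross-validation.** The cohort is shuffled into five near-equal
partitions. Outer model `m` trains on partitions `{m, m+1, m+2}`, uses
`m+3` for model selection and collects predictions on `m+4`; rotating `m`
tiles the validation partitions over the cohort so each participant gets
exactly one out-of-fold prediction, produced by a model that never saw them
(audited from stored fold provenance). Within each outer training split,
`inner_k = 3` nets are trained, each early-stopped on its held-out inner
fold; the fold's predictor is their mean-ensemble, de-standardized to liters.
The ratio head is trained directly; a config flag derives it as VAT̂/ASAT̂
instead.

## Benchmarks and associations

Linear comparators (BMI: age+BMI; Waist: age+waist; WHR: age+WHR; Anthro:
age+weight+height+BMI+waist+hip+WHR+5 impedances; Silhouette: age + the CNN
prediction) are OLS, sex-stratified, fit and evaluated under the *same* fold
rotation as the CNN. R² is `1 − SSres/SStot`; confidence intervals are
percentile bootstrap with 1000 paired resamples; model differences use the
same resample indices for both models (paired ΔR²). Associations are
sex-stratified logistic (OR/SD, Wald CI) and Cox (HR/SD, Efron ties,
prevalent cases excluded) models with adjustment sets {age+center, +BMI,
+BMI+waist}. Standardized prevalence is marginal standardization
(g-computation): an adjusted logistic model with cell indicators is fit per
sex; every participant's probability is predicted under counterfactual cell
membership and averaged; CIs by bootstrap over participants. BMI bins use
WHO edges (18.5/25/30/40), elevated waist defaults to 102 cm (male) / 88 cm
(female) with optional per-BMI-subgroup overrides — the exact bin definitions
of the source analysis are not public.

## What a green suite establishes — and what it does not

The phantoms are stacked ellipses with exactly known labels: no imaging
physics, no pose variation, no segmentation ambiguity, no label noise. On
such data the silhouette CNN reaches out-of-fold R² ≈ 0.95 for VAT and
beats the full anthropometric model by ΔR² ≈ 0.3 — far cleaner than any
real-data result, because here depot volumes are (noisy) deterministic
functions of visible shape. Green tests establish that the *machinery* is
correct (projections match oracles, folds never leak, ensembling dominates,
estimators recover generating coefficients at their nominal coverage), not
that silhouettes achieve any particular accuracy on human MRI.

## Numerical choices and edge cases

- All randomness flows through explicit integer seeds (`numpy` Generator);
  cohort tables hash-reproducibly.
- Ellipse perimeters use Ramanujan's approximation (relative error < 1e-4 at
  the aspect ratios in play).
- Ring radii are clipped so a lean core of at least 3% of the cross-section
  survives; infeasibly large fat targets are clipped rather than erroring.
- Zero-variance targets, rank-deficient designs (collinear columns are named
  via greedy QR), zero-event Cox strata, empty silhouette panels, and
  non-contiguous series are hard errors; background-only slices segment to
  empty masks silently.
- 4-connected hole filling can absorb isolated background voxels reachable
  only diagonally (≈1 voxel per 10⁷); "no body voxel lost" is the guaranteed
  invariant.
- Coverage-style tests pool replicate streams before comparing against their
  nominal rate, since a single 100-replicate stream carries ±2.2% binomial
  noise.
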