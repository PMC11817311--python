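# Methods

This note documents the models, conventions and deliberate design
choices behind `scribepd`, in the order data flows through the package.

## Signal model and file conventions

A recording is six channels on a uniform 180 Hz grid: pen position
(x, y; tablet units, y up, origin lower-left), pen height z (0 on
contact, positive while lifted), azimuth ∈ [0, 360), altitude ∈
[0, 90] (degrees), and tip pressure ≥ 0.  Stored timestamps are
informational; every rate uses Δt = 1/fs.  Files use the SVC text
dialect (`count` header; `x y timestamp pen_status azimuth altitude
pressure [z]`).  We always write the optional z column so read∘write
is the identity; when reading 7-column files from elsewhere, z is
reconstructed as 0 on-surface with a raised-cosine arc per in-air run
— the same lift model the generator uses — because in-air z features
need *some* consistent convention and this one is the package's own.

## Synthetic cohorts

The generator emulates the structure of a digit-writing cohort, not
any particular patient population.  Digits 0–9 are single-stroke
skeleton polylines normalized to unit height, traversed at constant
nominal pen speed (4500 units/s, digit box 700×1000 units), with
straight-line pen-up transitions (0.25 s nominal, raised-cosine z
bump, zero pressure).  Pen-down and pen-up samples therefore partition
each recording exactly, and a default recording has 10 on-surface runs.

PD-like effects, one parameter each:

| parameter | meaning | HC range | PD range (default) |
|---|---|---|---|
| `micrographia_severity` | 0 → none; 1 → digit 9 at half size (linear shrink) | 0 | 0.4–0.8 |
| `tremor_amplitude` / `tremor_freq` | on-surface sinusoid, tablet units / 4–6 Hz | 0 | 6–14 units |
| `pressure_scale` | multiplicative attenuation | 0.85–1.0 | 0.55–0.80 |
| `pressure_noise` | CV of multiplicative log-normal noise | 0.05–0.10 | 0.25–0.45 |
| `speed_factor` | slow-down (≥ 1) | 1.0–1.15 | 1.2–1.6 |
| `jitter_sigma` | Gaussian positional jitter | 1–2 units | 1–2 units |
| `style_jitter` | writer-style size spread (per-digit and overall, ±fraction) | 0.12 | 0.12 |

`style_jitter` is nuisance variation, not a disease effect: it models
the large between-writer (and digit-to-digit) size variability of real
handwriting identically in both groups.  Without it every subject
writes near-identical glyphs and even mild micrographia becomes
trivially visible in the rendered images, which real cohorts do not
support.

Profiles are drawn uniformly from these ranges with per-subject seeds
derived from one master seed (`SeedSequence([master, index])`), so
cohorts are bit-reproducible.  Random draws happen in a fixed order,
so toggling one effect leaves all other draws unchanged — e.g. adding
tremor moves pen-down samples only.

Two named scenarios fix the study conditions used by the tests and the
reproduction script: the **exchangeability null** (both groups drawn
from the HC ranges — any classifier should sit at chance) and the
**pressure-dominant** cohort (pressure_scale 0.50–0.70 and
pressure_noise 0.35–0.55 against mild shape effects, micrographia
0.10–0.25 and near-zero tremor).  The ranges were chosen once as
plausible strong/mild regimes; at n = 60 the pressure pipeline sits
near 100% while the image branch lands well below it, so the
dynamic-vs-image comparison is read as an ordering, not as a
reproduction of any particular accuracy.

What the generator does **not** model: biomechanics of the arm,
writing-style variability beyond the listed effects, letters or words,
action-vs-rest tremor distinctions (tremor is on-surface only by
default), or non-uniform sampling.  Passing tests therefore show the
pipeline recovers *planted* effects of these kinds; they say nothing
about effect sizes in real patients.

## Dynamic features

On-surface is `pressure > 0` (the observable proxy for z = 0).
Differences are taken within contiguous runs only — never across a pen
lift, which would create spurious jumps — and per-run results are
concatenated.  Azimuth differences are wrapped into (−180, 180].  A
local extremum is a strict sign change of consecutive differences;
plateaus do not count, and counts are summed per run.  NCP uses Δp, p′
and p″; NCV/NCA use each base signal's velocity/acceleration tier; the
R-variants divide by the segment-class duration (samples/fs).  The
pressure set needs one on-surface run of ≥ 4 samples (third
difference); kinematic sets need ≥ 5 samples in the segment class.

Cardinalities after the functional step: pressure 5×4 + 6 = 26;
on-surface kinematic 24×4 + 24 = 120; in-air 28×4 + 28 = 140 (Δz
exists in-air only); the kinematic functional block alone is
4×52 = 208 and the pressure block 4×5 = 20.

## Static representations

Functionals: mean, sd (n−1 denominator), skewness and excess kurtosis
as bias-uncorrected moment ratios; both shape moments are defined as 0
when the signal is constant (sd = 0), which keeps constant features
usable instead of erroring or producing NaN.

GMM supervector: per subject, vector features are stacked column-wise,
right-truncated to the shortest tier (differencing shortens each tier
by one per order; truncation loss is ≤ 3 frames).  A diagonal-
covariance mixture with M components (M even, 2–30; M = 1 allowed as a
degenerate closed-form case) is fit with scikit-learn (k-means
initialization from the spec seed, `reg_covar` = 10⁻⁶ of the mean
per-column variance as a numerical floor).  Components are sorted by
descending weight with ties broken by the first mean coordinate, so
the serialized supervector is invariant to the fitter's internal
component permutation.  Each subject's GMM is fit independently; no
universal background model or MAP adaptation is used.  Note the p ≫ n
regime this creates for large M (M = 28 over 52 features gives 2912
dimensions from ~100 subjects); the SVM tolerates it but users should
read such accuracies cautiously.

## Image branch

Rendering centers the pen-down trace, scales it isotropically into a
144×216 raster with a 10 px margin, and draws 2 px anti-aliased white
strokes on black (3× supersampling + Lanczos), so the image is
invariant to global translation and uniform scaling of the trace.

The micrographia law leaves the onset digit at scale 1.0 and
interpolates linearly to exactly 0.5 at digit 9 — "progressive
reduction" developing after the onset.  The pre-training corpus is
half modified / half non-modified sequences built from the glyph bank
with mild per-digit size (±12%) and baseline (±6%) jitter for
writer-like variability, all rotated by an angle from
{−15°, −5°, 0°, 5°, 15°}; the default split is 6/7 train, 1/7 test.

The network (in-package numpy implementation) uses same-padded 5×5
convolutions so that only the max-pools halve the maps:
144×216 → 72×108×16 → 36×54×8 → 18×27×4, flattened to the 1944-dim
embedding that feeds the SVM.  Training is Adam (lr 10⁻³, batch 8,
early stopping on held-out loss, patience 3), deterministic for a
fixed seed single-threaded.  Freezing schemes control which conv
layers may move during fine-tuning (fully_frozen: none;
partially_frozen: conv1; semi_frozen: conv1+conv2; unfrozen: all); the
dense head is always trainable, and trainable-parameter counts are
strictly ordered along that chain.  Because the embedding is the conv
stack's output, fully_frozen embeddings equal the pre-trained ones
regardless of head fine-tuning; cross-validated fine-tuned schemes use
a per-fold embedder that retrains on the training portion only.

## Evaluation protocol

One stratified 5-fold plan (seeded, hashed) is reused by every
representation.  Per outer fold: standardization fit on the training
portion, grid search C, γ ∈ {10⁻³ … 10³}, kernel ∈ {linear, rbf}
(γ dropped for linear) by nested stratified 3-fold CV on the training
portion, refit, score the held-out fold.  Nested selection is the
default because tuning on the evaluation folds leaks; the simpler
tune-on-the-same-folds protocol is available behind `nested=False`.
PD is the positive class for sensitivity/F1.  ROC and AUC are computed
from pooled out-of-fold decision scores (one curve per pipeline).  GMM
model order is chosen by mean training-portion grid-search accuracy
over the outer folds, ties to the smaller M, and only then evaluated
on the held-out folds.

## Problem sizes used by tests and the reproduction script

Cohorts of n = 60 (30/30), 30–40 repetitions for the null calibration,
a 120-sequence pre-training corpus and 3 training epochs: sizes chosen
so the whole suite re-runs comfortably on a single CPU while leaving
the statistical checks well-powered (the null's mean accuracy has a
standard error of ~1.5 percentage points at 30 repetitions).

## Known limitations

* The synthetic effect sizes are conventions, not estimates of any
  clinical cohort; absolute accuracies on synthetic cohorts are not
  comparable to accuracies on patients.
* The glyph bank has one stroke per digit; multi-stroke digit styles
  (and hence within-digit pen lifts) are not exercised by default.
* The numpy network is deliberately small and CPU-bound; it is not a
  general deep-learning component.
* `nested=False` model selection is provided for protocol comparison
  only and is knowingly optimistic.
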