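# Methods

This note documents the models, parameter choices, and numerical
conventions behind `gazesal`, and what the synthetic studies do and do
not establish about real eye-tracking data.

## Attention-map preprocessing

A participant's raw heat map is rendered from fixation events: each
fixation deposits a truncated Gaussian kernel (support radius 25 px,
σ = radius/2) centred on its pixel and scaled linearly by its duration in
milliseconds; deposits sum.  Commercial eye-tracking renderers use
proprietary kernels; a radially decaying kernel with the study's stated
25-px radius reproduces their qualitative shape, and linearity in duration
is assumed (total map mass is proportional to total gaze time away from
the image border).  Coordinates are row-major, origin top-left, 0-based,
with pixel-centre semantics, everywhere in the package.

Group preprocessing follows the chain *subtract common attention per
participant → average → smooth → threshold*:

* **Common attention** is the mean of every participant×image map of a
  group, capturing the universal eyes/nose/mouth bias; it is subtracted
  from each participant map with negatives clipped at zero.  Clipping at
  subtraction (rather than deferred) keeps nonnegativity a global
  invariant.  Subtracting per participant before averaging is equivalent
  to subtracting from the average whenever no pixel clips (an exact
  commutation, verified by test); with clipping the per-participant order
  is used.
* **Smoothing** is a uniform box filter (default 15 px, configurable) with
  shrink-to-valid edge handling, rescaled so the post-smoothing maximum
  equals the pre-smoothing maximum.  This implements the "intensity
  boost" of heat-map display pipelines deterministically and keeps the
  map quantitative; whether that step is display-only in the original
  workflow is ambiguous, so it is retained but made max-preserving.
* **Noise thresholds** zero pixels strictly below a cutoff.  The study's
  numeric cutoffs are not published; by default the cutoffs are resolved
  in *coverage* terms — the low threshold keeps ≈7% of the face region
  nonzero and the high threshold ≈3.5%, matching the coverages observed
  for human maps at the two levels (6–8% and 3–4%).  Absolute and
  fraction-of-max modes remain available.

## Occlusion saliency

For a classifier exposing labels and a `predict(image) → probabilities`
contract, saliency for a target label places a 20×20 box at stride-10
offsets, fully inside the image only (partial edge boxes would make
evaluations incomparable; the ≤10-px unreachable border lies outside the
face at study scale).  Each placement records
drop = p(target | original) − p(target | occluded), clipped at zero so
only positive contributions count.  With overlapping boxes a pixel's
value is the **mean** drop over all boxes covering it, which keeps the
scale independent of overlap multiplicity.  The occlusion fill is raw 0.
Saliency is refused when the target probability is ≤ 1e-4 (the map would
be meaningless) and a warning is issued below 1e-2.  Ensembles average
member maps pixel-wise.

Images are analysed at the classifier's native resolution and the
saliency map is mapped back to the attention-map resolution by
nearest-neighbour resampling.

**Coverage matching.**  Occlusion maps are much denser than human maps,
which makes IoU/KL unreliable; before a human–saliency comparison the
saliency map is thresholded so its nonzero in-face pixel count matches
the human reference's.  The cutoff is found by rank selection on the
sorted in-mask values (equivalent to a grid search over cutoffs).  With
ties at the boundary value, all tied pixels are kept if that lands closer
to the target count, otherwise all are dropped; at an exact tie the
sparser map wins, and a cutoff that would empty the map is never chosen.
Human–human comparisons are never coverage-matched: two participant
groups may legitimately differ in how dispersed their attention is.

## Comparison metrics

IoU binarizes at "nonzero" and returns |A∩B|/|A∪B|; when both maps are
empty the value is undefined and reported as missing (never 0 or 1), and
the image is dropped from pooling with a logged reason.  Symmetric KL
restricts both maps to the union of their nonzero supports (intersected
with the face mask when one is supplied), adds an epsilon, rescales to
probability distributions, and averages the two directed divergences in
nats.  The epsilon defaults to 1e-9 × each map's own mean nonzero
intensity, which keeps the metric exactly scale-invariant and finite on
disjoint supports.

Bootstrap standard deviations resample **participants** (the independent
unit, not pixels) with replacement, rebuild the group map through the
same preprocessing, and recompute the metric against the fixed other
map; B = 1000 by default at the API level, seeded.  Replicates with an
undefined metric are dropped with a warning.  Inside the pipeline the
replicate preprocessing omits the smoothing step: it barely moves
coverage-ranked cutoffs but triples the per-replicate cost.

AOI summaries use ray-casting point-in-polygon with boundary counting as
inside; "time to first whole fixation" is approximated as the onset of
the first fixation event falling inside the polygon.

## Response statistics and pooling

Accuracy tables count correct/incorrect affected-vs-unaffected calls per
image and group.  The two groups are compared with a Pearson chi-square
on the summed 2×2 table, df = 1, **without** continuity correction — the
uncorrected statistic on the published counts reproduces the printed
p = 0.0032, the Yates-corrected one (0.0043) does not; both were checked.

Per-image metric estimates are pooled with DerSimonian–Laird
random effects (the standard forest-plot default; the study names only
"random effects meta-analysis"), using squared bootstrap SDs as
within-image variances, on the raw metric scale (no logit/log
transform, matching how such results are plotted).  Zero variances are
floored at 1e-8 to avoid infinite weights.

## Synthetic studies

The generator emulates the study design: 22 clinicians + 22
non-clinicians, 16 images (10 conditions, 6 unaffected controls),
7-second trials, 720×720 frames (the study's minimum image resolution),
25-px rendering radius.  A face layout places canonical landmarks with
seeded jitter inside an elliptical face mask (~52% of the frame) and
assigns each condition image an elliptical feature region (semi-axes
0.16 W × 0.125 H) at one of ten plausible dysmorphology sites.

Gaze profiles are mixtures over landmark regions plus the image's
feature region.  Defaults: clinicians put 36% of fixations on the
condition feature and the rest on landmarks; non-clinicians attend
landmarks only — both groups share the landmark bias, mirroring the
qualitative finding that common attention dominates raw maps.  Fixation
spread is σ = 20 px around the chosen centre; ~18 fixations per trial
with gamma-distributed durations filling 80% of the 7-s window.  Each
participant receives a fixed idiosyncratic gaze translation (σ = 15 px)
and log-normal jitter of their mixture weights, emulating observed
per-participant signatures.  Response accuracy defaults to the observed
group rates (85.6% / 76.9%).  A single integer seed fans out to
per-participant and per-trial substreams through `SeedSequence` spawn
keys, so enlarging a cohort never perturbs existing streams.

The toy classifier ensemble consists of five prototype classifiers
(softmax over negative mean-squared distance to one prototype per label,
temperature 0.01, prototypes jittered per member).  All stimuli share an
identical schematic base face; an affected image adds a Gaussian bump
(σ = region radius/2.4, keeping ~94% of its energy inside the advertised
region) in its feature region, so label-discriminative content — hence
the truly salient region — is exactly the feature region.  The toy
ensemble runs at 224×224 by default: with the study's 20×20/10 occlusion
geometry this keeps the box a comparable fraction of the face to the
448×448 study resolution while remaining desk-scale, and ≥80% of the
resulting saliency mass falls inside the known feature region.

**What the synthetic studies do not show.**  The generator produces
schematic faces and mixture-model gaze, not photographs or oculomotor
dynamics (no saccade kinematics, pupilometry, calibration error, or
fixation-detection noise).  Passing tests demonstrate that the pipeline
recovers known ground truth and the qualitative threshold trend under
controlled conditions; they do not reproduce the magnitudes of any
real-data result, which depend on the undeposited recordings and a
GPU-trained classifier.

## Orchestration

`run_study` partitions participants per image into successful /
underperforming × clinician / non-clinician (membership varies by image),
builds common maps per group over **all** images, and emits four
comparison families: successful clinicians vs coverage-matched ensemble
saliency (affected images, both levels), successful clinicians vs
successful non-clinicians (all images, both levels), successful vs
underperforming within group (low level, as such comparisons are
reported), and per-participant affected-vs-unaffected self-consistency
(low level; reported per participant and not pooled, since the pooling
unit elsewhere is the image).  A subgroup needs ≥ 2 participants (the
bootstrap minimum); smaller cells are skipped and logged, as are images
whose classifier target probability is near zero.  Rows emitted plus
logged exclusions always equal the full pair×level×image grid, and
reruns with the same seed write byte-identical tables.

Default problem sizes for the orchestrated synthetic study: bootstrap
B = 100 per cell (the API minimum that still stabilises the
inverse-variance weights; the standalone `bootstrap_sd` default remains
1000) and the 224×224 toy-classifier resolution above.  A full default
study runs in about two minutes on one CPU.

## Known limitations

* The noise-threshold *levels* are coverage-calibrated, not the study's
  (unpublished) absolute cutoffs; absolute comparisons of KL magnitudes
  against published figures are therefore not meaningful.
* KL is reported in nats; published values may use another base.
* The bootstrap resamples one side of each comparison (the first-named
  group) against a fixed other map.
* Self-consistency rows carry no uncertainty estimate.
* The prototype classifier is a deliberately transparent stand-in; no
  neural classifier, training, or cross-validation is included.
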