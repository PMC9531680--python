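# Methods

This note records the models, the synthetic data-generating processes, the
numerical choices and the known limitations of the package. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from elsewhere.

## Coordinate and data conventions

Pixels are 0-based with the origin at the top-left; rectangles are half-open
`[x0, x1) × [y0, y1)`, so area arithmetic needs no ±1 corrections.
Segmentation masks index a fixed palette `UL=0, BG=1, COR=2, EP=3, DE=4,
DMN=5, EPN=6` (unlabeled, background, stratum corneum, epidermis, dermis,
dermal nest, epidermal nest) and are stored as indexed PNG; on read, labels
are resolved through the registered palette *colors*, so files with permuted
palettes round-trip correctly and unregistered colors are rejected.
Timestamps are float seconds from session start.

## The numpy neural-network core (`melanopath.nn`)

All learned models run on a small reverse-mode autodiff engine over float64
numpy arrays: elementwise ops, matmul, reductions, shape ops, stable
softplus/log-softmax/BCE, convolution by shift-and-accumulate (one einsum
per kernel offset), nearest-neighbor upsampling and average pooling, layer
norm, multi-head self-attention and pre-norm transformer blocks, with SGD
and Adam optimizers. Every analytic gradient is verified against central
finite differences in `tests/test_nn.py`. Computation is deterministic:
identical parameters, inputs and seeds reproduce results bit for bit. The
engine is intentionally minimal — no GPU, no dropout/batch-norm — because
every model here trains at tile scale on one CPU; its determinism is what
makes the recovery tests exact study conditions rather than averages.

## Synthetic data (`melanopath.synthio`)

**Tissue tiles.** Horizontal bands top-to-bottom (BG, COR, EP, DE; default
height fractions 0.15/0.10/0.30/0.45, remainder background) with fixed
H&E-like colors; elliptical nests rejection-sampled inside their parent
band with a minimum separation so connected-component counts equal the
requested nest counts; melanocyte nuclei as small ellipses (radius 2–3 px)
in a distinct blue-purple, kept off nests and apart from each other so each
instance box covers exactly one nucleus; optional speckled mitotic nuclei;
Gaussian pixel noise (default sd 4 intensity units) added in float and
clipped to [0, 255]. The virtual-stain reference is deterministic:
desaturate every pixel to its channel mean, then paint melanocyte boxes
with the fixed SOX10 red-brown (150, 60, 30). Because desaturated pixels
have equal channels, no background pixel can collide with that color, which
makes pixel-count oracles exact.

**Patches.** 101×101 tiles on stroma background; the mitotic class draws a
dark, speckle-textured nucleus, the normal class a lighter smoothly-shaded
one. The class-conditional mean intensity difference makes the set
separable — deliberately, since the patch-classifier tests are recovery
bounds, not difficulty benchmarks.

**Multi-magnification renderings.** Tags 7.5×/10×/12.5× are realized as
anti-aliased resamplings of one tile at relative factors 0.6/0.8/1.0. The
nest-density cohort assigns class labels by dermal nest count (0/3/7, narrow
radius band 4–5 px so total nest area tracks count). The cross-scale-cue
cohort plants a global stain cast only in the 7.5× rendering and fine dark
speckle only in the 12.5× rendering, with class = (coarse cue, fine cue) ∈
{(0,0), (0,1), (1,1)}; with balanced classes the best single-scale accuracy
is 2/3 by construction while the scales jointly determine the label. This
emulates diagnoses requiring integration of low-power architecture with
high-power cytology; it intentionally gives the scale-specific cues a
sharper separation than real magnification differences would.

**Viewport logs.** The zoom trajectory is a random walk on an ordered
ladder of zoom multipliers (default 1/2/4/8 — abstract units, since real
viewer units vary) with drawn transition probabilities (zoom-in, zoom-out,
pan) and *reflecting boundaries*: a zoom-in drawn at the top level is
realized as a zoom-out, and vice versa at the bottom. On a bounded ladder
every ascent is matched by a descent, so with symmetric zoom probabilities
the realized zoom-in share converges to the drawn probability; with
asymmetric probabilities boundary reflections bias it — the convergence
tests therefore use the symmetric condition. The viewport rectangle is the
slide extent divided by the zoom (so at the lowest zoom the whole slide is
visible and panning cannot move the rectangle — such transitions count as
static, not scanning). Panning re-centers near a random ROI centroid with
probability `roi_dwell_target`, else uniformly. Step times are exponential
with configurable mean; timestamps are strictly increasing.

**Interpretation cohorts.** One row per pathologist×case. Per-interpretation
behavior parameters are jittered (Dirichlet around the transition
probabilities, clipped-normal ROI dwell, lognormal step-time factor,
Poisson viewport count) so the seven summaries vary realistically across
rows. The binary accuracy outcome is drawn from
`logit P = intercept + beta · z(effect variable) + u_pathologist`, with
`u ~ N(0, sd²)` per pathologist and the z-score computed over the realized
cohort. Experience years and board certification are per-pathologist
covariates. Because `beta` is planted, the cohort is a ground-truth fixture
for the association estimator.

## Viewport analytics and the mixed model (`melanopath.viewbehave`)

Durations are forward differences of timestamps; the final viewport gets
duration 0 (it has no successor). Zoom statistics are unweighted per
viewport (not duration-weighted) — a deliberate convention, flagged here
because it is a genuine ambiguity; a duration-weighted variant would change
`avg_zoom` whenever long dwells happen at extreme zooms. Magnification and
scanning percentages use transitions (viewports with a predecessor) as the
denominator; each transition is exactly one of zoom-in, same-zoom move,
zoom-out, or static, so magnification% + scanning% + other% = 100 — a
partition identity the tests assert on random logs. ROI time uses any
positive-area intersection (edge contact does not count). One consequence
of these conventions: appending a viewport to a log changes the transition
denominators and the unweighted zoom moments, so no nontrivial append
operation leaves all seven summaries invariant.

`fit_association` standardizes the behavior variable (odds ratios are per
SD, which is what makes them comparable across variables with different
units), adds experience covariates, and fits a Bayesian binomial mixed GLM
with a pathologist random intercept by variational inference (statsmodels).
CI and p-value come from the Gaussian posterior approximation of the fixed
effect. Degenerate predictors (zero variance) and non-finite fits raise
instead of returning numbers. At the study size used by the recovery tests
(20 pathologists × 250 cases, random-intercept sd 0.5, 30 viewports per
log), 20 replicate null fits give odds ratios within [0.9, 1.1] and p>0.05
in ≥90% of seeds, and a planted per-SD log-odds of 0.3 is recovered with
the correct sign and p<0.05; the mean fitted log-OR across seeds lands
within a few percent of 0.3.

## Mitosis patch classification (`melanopath.patchclass`)

Patch extraction centers the 101×101 window on the candidate (center pixel
→ index (50,50)) with edge-replication padding at borders; "approximately
centered" is realized as exactly centered, and edge padding was chosen over
reflection (the two are indistinguishable for this task; edge is simpler to
oracle). Augmentation returns exactly six variants: rotations by
45/90/135/225° (90° exact; oblique angles bilinear with edge padding,
recropped to 101×101) plus horizontal and vertical mirrors. The split is
stratified per class at 80/20 and seeded. Two built-in encoders stand in
for published efficient/dense designs at desk scale: a strided 3-conv CNN
and a variant with concatenative feature reuse; both end in global average
pooling and a linear head, trained with Adam (lr 1e-2 default) on BCE.
Mitosis is the positive class throughout; the decision threshold defaults
to 0.5 and is configurable. On the separable synthetic set both encoders
reach ≥0.95 validation accuracy within 10 epochs.

## Virtual staining with joint detection (`melanopath.vsgd`)

The generator is a depth-2 encoder–decoder (strided convs down,
nearest-upsample + conv up) with optional attention-gated skips (a learned
sigmoid gate on each skip connection); output passes through a sigmoid so
the stain lives in [0, 1]. Input dimensions must be divisible by 2^depth.
Two architecturally identical CNN discriminators operate at full and
half (average-pooled ×2) resolution. The detection branch is anchor-free:
a conv trunk on the finest decoder level (configurably, concatenated
coarser levels upsampled) yields a dense objectness logit map and a 2-channel
box-size regression; decoding takes 3×3 local maxima of the sigmoid map at
or above the score threshold and emits boxes of the regressed size, clipped
to image bounds. This is the proposal+box-regression reduction appropriate
at tile scale; a full FPN/RPN/mask stack is out of scope.

Losses: non-saturating adversarial for G (binary cross-entropy of the
discriminators' outputs against "real") averaged over the two scales;
standard real/fake BCE for D; objectness BCE with positive-pixel weight 60
(one positive per nucleus center against ~4000 background pixels) plus an
L1 size term at positives (weight 0.1); and a paired L1 reconstruction term
toward the deterministic stain reference (weight 10 by default). The
reconstruction term is the standard paired image-translation ingredient and
is what makes pixel-accurate staining reachable in a few hundred steps at
this scale; adversarial-only training would need far more capacity and
steps. Detection gradients flow into the decoder because the Det input is
part of the generator graph; the generator and detection head share one
Adam, the discriminators another. Non-finite losses abort with a state
dump. After 300 joint steps on twelve 64×64 tiles, held-out stain MAE is
≈0.02 (bound tested: <0.15) and detection F1 at IoU 0.5 is ≈0.98 (bound
tested: ≥0.7).

## Two-stage segmentation (`melanopath.segtwostage`)

Both stages use a two-level U-Net (strided-conv encoder, nearest-upsample
decoder with skip concatenation, 1×1 head). Stage 1 predicts
{BG, COR, EP, DE}; pixels labeled UL are excluded from numerator and
denominator of the loss, so an all-UL mask contributes exactly zero.
Region masking replaces pixels outside the kept region with white
(255,255,255), matching slide background; stage 2 trains on full masked
frames rather than region crops (simpler geometry, and the fill teaches
the net to ignore non-region area). Stage-2 models are binary
(region vs nest); composition starts from the stage-1 mask and accepts a
nest prediction only where the stage-1 label is the parent region, which
enforces DMN ⊆ DE and EPN ⊆ EP by construction and makes composition with
empty stage-2 masks the identity. DMN/EPN cannot collide because their
parent regions are disjoint. At 200 Adam steps on twelve 64×64 tiles the
held-out coarse mean Dice is ≈1.0 (bound: ≥0.85) and nest Dice ≈0.99
(bound: ≥0.5; nests are the hard class and the bound is set accordingly).

## Scale-aware diagnosis (`melanopath.scatnet`)

Tiling pads with white to multiples of the patch size and yields row-major
positions; patch embeddings come from a small CNN applied independently per
patch (so identical patches embed identically and permutation of patches
permutes embeddings). Sinusoidal positional embeddings use the standard
sin/cos frequency ladder over row-major linearized indices (1-D
linearization chosen over a 2-D split; at m≤dozens of patches the
distinction is immaterial). The per-scale transformer runs over patch
tokens and the token mean gives one e-vector per scale; per-scale weights
are *not* shared across scales, since scale statistics differ. Scale fusion
adds learnable per-scale embeddings, runs a second transformer over the S
scale tokens and returns S×e; classification flattens to S·e and applies a
linear softmax layer over C classes (default C=4 for the melanocytic
spectrum from mildly atypical nevi through invasive melanoma; the synthetic
cohorts use C=3). Training is end-to-end (encoder included) with Adam and
cosine learning-rate decay, which stabilizes the late epochs at these tiny
cohort sizes. Without positional embeddings the per-scale stage is
permutation-invariant (attention + mean); with them it is not — both
directions are asserted. Study sizes: 48 training / 12 held-out cases at
80 epochs for the nest-density cohort (held-out accuracy ≥0.9); 45/15 at 40
epochs for the cross-scale cohort, where the three-scale model strictly
beats the best single scale (2/3 ceiling by construction). Metrics are
macro-averaged (one-vs-rest) with rank-based AUC.

## Evaluation metrics (`melanopath.evalmetrics`)

Undefined ratios (zero denominators) are reported as NaN, never 0.
Detection matching is greedy in descending score order with one-to-one
claims at IoU ≥ threshold (default 0.5); the tests verify agreement with
exhaustive optimal assignment on scenes where predictions overlap at most
one truth box, and the greedy TP count never exceeds the optimal one.
Detection Jaccard is box-level TP/(TP+FP+FN), which algebraically equals
F1/(2−F1) — the identity is property-tested and is also how the published
detection table's F1↔Jaccard relationship is reproduced from its printed
precision/recall. Dice ≥ IoU always, with equality exactly at 0 and 1.
Report tables round to 3 decimals, round-half-even. Macro AUC uses the
Mann–Whitney rank formulation with midranks for ties.

## Numerical and reproducibility notes

- All randomness flows through `numpy.random.Generator` seeded from
  explicit parameters; derived seeds use `SeedSequence` and stay below 2³¹.
- Recomputing a mean by a different float summation order can differ by an
  ulp; the oracle-equivalence tests compare order-dependent accumulations
  (means, variances, duration ratios) at 1e-12 relative tolerance and
  everything discrete exactly.
- Printed-table identities: metrics recomputed from printed confusion
  counts match the printed 3-decimal values exactly; F1 recomputed from a
  printed precision/recall pair can differ in the last printed digit
  because the inputs are themselves rounded, so that check carries ±0.001.

## Limitations

The synthetic tissue is a layered cartoon: real histology has curved,
interdigitating boundaries, stain variation, overlapping nuclei and
artifacts none of which are modeled; passing recovery tests demonstrates
that the pipelines are implemented correctly and can learn their intended
signals, not that they would reach these scores on clinical slides. The
accuracy-generating model for cohorts is exactly the logistic
random-intercept model the estimator assumes, so the GLMM study verifies
estimator correctness, not robustness to misspecification. Zoom units are
abstract multipliers; mapping to physical magnification is left to
configuration. Networks are intentionally small; no claim is made about
behavior at published-architecture scale.
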