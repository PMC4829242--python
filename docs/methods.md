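# Methods

## Measurement model

The quantity of interest is the erythema index (EI) of the palpebral
conjunctiva. For a pixel with red and green brightness `R`, `G` in
[0, 255],

    EI = slog(R) − slog(G),   slog(v) = c · ln v,  c = 255 / ln 255,

so `EI = c · ln(R/G)` wherever both channels are positive. The scale
constant keeps the logarithm on the 8-bit image scale (`slog(255) = 255`,
`slog(1) = 0`), which is the scale on which published screening cut-offs
(18.14 for a compact camera, 30.49 for a phone camera) are quoted; on a
natural-log scale those numbers would be meaningless. EI is a pure
function of the red/green ratio, hence exactly invariant to any scalar
applied to both channels — this is what makes white-balance
standardisation effective against multiplicative lighting casts.

Pixels with `R = 0` or `G = 0` cannot be logged. They take the
conventional value 0 in the EI map, are flagged, and are excluded from
ROI means: such pixels are specular burnout or deep shadow, and
including a convention value would bias the mean unpredictably. An ROI
consisting only of flagged pixels is a geometry error.

### Numeric modes

Two modes run through standardisation and the EI computation:

* `real` (default): floating-point throughout; negative EI permitted.
* `imagej8`: after each stage the planes are rounded half-up and clamped
  to [0, 255], and the EI subtraction clamps negatives at 0. This
  emulates legacy 8-bit image-calculator workflows, under which the
  published cut-offs were derived; the clamp silently censors EI < 0,
  which is why it is opt-in and labelled rather than the default.

Rounding is half-up everywhere (`floor(x + 0.5)`), chosen once for
reproducibility.

## Standardisation

Each channel is multiplied by `200 / M_B`, with `M_B` the mean
brightness of the calibration card's white square in that channel,
then clamped to [0, 255]. `M_B` is computed per channel by default: a
single global scalar cannot remove a colour cast, and the whole point
of the card is cast removal. A `global` mode (one `M_B` averaged over
channels) exists for comparison. The white square must cover at least
25 pixels; a zero channel mean is a degenerate-card error. Values
scaled above 255 are clamped and reported as a `clipped_fraction` so
pipelines can reject over-exposed frames: the white-mean-equals-200
contract is exact only when nothing clips. With a white reflectance of
200, any channel gain above 255/200 = 1.275 necessarily clips the
white square, which bounds the lighting casts under which exact
invariance can be demonstrated.

## Polygon ROIs

Coordinates are 0-based, `x` = column, `y` = row. A pixel belongs to an
ROI when its centre lies inside the polygon under the even-odd
(crossing-number) rule; polygons must be simple. The convention is
fixed because GUI tools rasterise selections differently at boundaries,
and ROI means must be reproducible bit-for-bit. The test suite checks
the rasteriser against an independent computational-geometry oracle on
random polygons whose vertices keep pixel centres off the edges (edge
pixels are the one place two correct rasterisers may differ).

## Quality control

The visual image-selection criteria (card and conjunctiva in focus,
adequate conjunctiva exposed, no bright reflections, no lighting
difference between card and conjunctiva) are operationalised as:

| check | metric | default threshold |
|---|---|---|
| focus | variance of Laplacian of the green channel | ≥ 10.0 |
| conjunctiva exposed | both ROIs present, each area in px | ≥ 200 |
| no specular | fraction of conjunctival pixels with all channels ≥ 250 | ≤ 0.01 |
| lighting uniform | brightness ratio, card ring / conjunctiva ring | in [0.8, 1.25] |

The rings are 4-step dilations around the white square and around the
union of conjunctival ROIs. The focus threshold was fixed once at 10
after measuring sharp synthetic scenes (variance ~10²) against
σ = 2 Gaussian-blurred ones (< 1); all four thresholds are config
values, since the original criteria were subjective. Degenerate inputs
produce failing flags, never exceptions, so batch runs exclude rather
than abort. Image selection is first-pass-wins over each participant's
candidate images; a participant with no passing image is excluded with
the failing flags recorded.

## Statistics

* **Diagnostic summaries**: positive class = anaemic = haemoglobin
  < 110 g/L (strict); a score predicts anaemia when strictly below the
  cut-off. Proportion CIs are exact Clopper–Pearson from beta
  quantiles — consistent with a printed training interval of
  "68 to 100%" for 14/15, which no Wald interval can produce.
  LR+ = sens/(1 − spec), +∞ at spec = 1.
* **Fisher's exact test**: two-sided by summing hypergeometric
  probabilities ≤ that of the observed table; validated against full
  enumeration for totals ≤ 60.
* **ROC**: candidate thresholds are midpoints between consecutive
  distinct scores plus ±∞ sentinels; AUC by trapezoid, which equals the
  Mann–Whitney probability (ties ½) — asserted against a brute-force
  pairwise count. The Youden cut-off maximises sensitivity +
  specificity with ties broken toward the lower threshold (higher
  specificity). AUC CIs use the Hanley–McNeil standard error and are
  reporting-grade only.
* **Two-way ANOVA** (repeatability: lighting × subject): main effects
  only by default, type II sums of squares, since replicate-level data
  with no interaction term is what the repeatability design produces.
  A zero-residual guard reports F = ∞ (p = 0) for a non-zero effect in
  a perfectly explained design and F = 0 otherwise.
* **One-way ANOVA with Bonferroni**: pairwise t statistics use the
  pooled residual variance; adjusted p = min(1, m·p).
* **Cohen's kappa**: `(p_o − p_e)/(1 − p_e)`; the p value is the
  large-sample z test of κ = 0 using the null standard error.
* **Paired t, D'Agostino–Pearson**: standard two-sided forms; the
  normality test requires n ≥ 20. All p values are two-sided.

## Synthetic scenes and cohorts

A scene is an 80 × 120 canvas: skin background (reflectance
185/150/135), card border (155/155/155 — matched to mean skin
brightness so the QC lighting ratio is ≈ 1 under uniform lighting),
white square (200, 324 px), and palpebral (635 px) and forniceal
(480 px) polygons. Conjunctival colour is specified directly in EI
space, `red = green_base · exp(EI*/c)` with `green_base = 110`, so
ground truth is exact by construction; no spectral modelling is
attempted because the analysis only ever sees the red/green ratio.
The palpebral EI target is `EI* = 8.02 + 0.092 · Hb`, anchoring the
observed regression slope and placing EI*(110 g/L) at the 18.14
cut-off; the forniceal offset −6 EI encodes the (real, but
unquantified) pallor of the fornix. `green_base = 110` keeps the red
channel unclipped over Hb ∈ [50, 180] g/L under all lighting presets.
The canvas is a desk-scale stand-in for multi-megapixel photographs;
every reported quantity is a per-pixel or ROI-mean statistic
independent of frame size.

Rendering applies, in order: per-channel lighting gains (presets:
fluorescent 0.95/1.05/1.10, incandescent 1.25/1.00/0.75, daylight
1/1/1 — plausible casts; no acceptance value depends on them), additive
Gaussian sensor noise (default sd 2 brightness units), clamping, and
8-bit quantisation. Rendering is a pure function of (params, model).
Artefact injectors (specular glints, a half-frame shadow, Gaussian
blur) exist solely to exercise the QC path.

Cohorts draw haemoglobin from a truncated normal (113 ± 21 g/L on
[50, 180]), matching the study population's moments; that distribution
puts ≈ 44% below 110 g/L. An optional rejection-free stratified draw
(`match_prevalence=0.40`) pins the anaemic fraction at the study's 40%
exactly. Photo-to-blood delays are drawn from a three-part mixture
sized to the study's delay subgroups (~44% within 4 h, ~43% beyond
12 h). Each participant also receives an EI offset drawn with sd 3.2
EI units, representing everything the linear Hb model does not capture
(vascularity, pigmentation, device tone-mapping). The value is derived
in closed form, not tuned: `r² = β²·Var(Hb) / (β²·Var(Hb) + σ²)` with
β = 0.092 and sd(Hb) ≈ 20.9 gives σ ≈ 3.2 for the r² ≈ 0.27 observed
on real photographs. Setting `ei_scatter_sd = 0` yields the "low
noise" regime (r² > 0.99) used for parameter-recovery checks.

The repeatability generator (3 subjects × 3 lighting conditions ×
5 images) adds a per-image EI jitter (default sd 0.5 EI) for pose and
exposure variation between repeat photographs; pixel noise alone
averages away over a 600-pixel ROI and cannot produce a realistic
between-image CV. 0.5 EI against a mean near 20 gives CVs around 2%,
the right order of magnitude for repeat clinical photographs.

### What passing tests do and do not show

The generator reproduces the *structure* the analysis assumes —
monotone Hb→colour link, multiplicative casts, sensor noise,
quantisation — so passing tests demonstrate that the pipeline recovers
known ground truth under that structure and that standardisation
removes exactly multiplicative casts. Real photographs additionally
contain device tone-mapping (non-multiplicative, device-specific — the
known reason the two cameras need different cut-offs), specular
microstructure, pose/anatomy variation and demosaicing artefacts, none
of which are modelled; test results therefore do not certify clinical
performance.

## Pipeline conventions

* Training/validation split: alternation in cohort-file order, first
  participant to training — recruitment order is the only ordering key
  available.
* Delay subgroups: ≤ 4 h and > 12 h, with the (4, 12] band reported but
  assigned to neither (the real subgroups do not partition the cohort).
* Only palpebral EI feeds classification; forniceal EI enters the
  comparison regression and the paired t test only.
* Eligibility window |photo − blood| ≤ 36 h, inclusive.
* Candidate images are `<participant>_<k>.png`; reports are a pure
  function of (config, inputs) — reruns are byte-identical.
* Haemoglobin bands for the group-wise ANOVA: < 90, 90–110, 110–130,
  ≥ 130 g/L; bands with fewer than two participants are dropped.

## Problem sizes

Simulated experiments use n = 200 cohorts (≈ 100 training) for
recovery checks and the 3 × 3 × 5 layout for repeatability, sizes at
which every experiment in the test suite and acceptance script runs in
seconds. Because Youden threshold estimates at n ≈ 100 training with
realistic scatter have a spread of roughly ±1 EI, the threshold-recovery
check averages the fitted cut-off over three independent cohorts.

## Known limitations

* Tone-mapping and other non-multiplicative camera processing are not
  modelled, and no cross-device harmonisation is attempted.
* The colour card's coloured patches are unused; only the white square
  drives standardisation.
* Automatic card/conjunctiva localisation is out of scope: polygon ROIs
  are inputs.
* Boundary pixel membership of polygon ROIs follows this package's
  even-odd convention and may differ from GUI tools at edges.
* The Hanley–McNeil AUC interval and the kappa z test are large-sample
  approximations.
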