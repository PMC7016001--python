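# Methods

This note documents the models implemented in `meniscus_qmri`, the
assumptions behind them, the synthetic cohort's calibration, and the
numerical and design choices that were genuinely open.

## Experimental setting being modelled

A lateral meniscus body sample (standard 15 mm length, natural width,
mean ≈ 8.4 mm) sits in an MRI-compatible pneumatic loading device and is
imaged in the mediolateral plane at three positions: δ₀ (unloaded, 0 bar),
δ₁ (2 bar set pressure ≈ 37.1 N compressive force) and δ₂ (4 bar ≈ 69.1 N).
Over a 15 × 8.4 mm contact face these forces correspond to mean contact
pressures of ≈ 0.30 and 0.55 MPa — the static-loading regime of prolonged
standing.  At each position the sample is re-segmented on morphological
images; masks are 2-D, one slice.  Under load the wedge-shaped
cross-section flattens and loses pixels.

## Relaxometry

### Signal models

All three contrasts use mono-exponential models — the standard
single-compartment description at clinical field strength:

* multi-spin-echo T2: `S(TE) = A·exp(−TE/T2)`, TE = n·8.4 ms, n = 1…6;
* spin-lock T1ρ: `S(TSL) = A·exp(−TSL/T1ρ)`, TSL = 0, 10, 20, 30, 40 ms;
* inversion-recovery T1 on magnitude images:
  `S(TI) = |a + b·exp(−TI/T1)|`, TI = 150, 300, 500, 800, 1000, 1500 ms.

The three-parameter magnitude-IR form absorbs imperfect inversion (ideal
inversion gives a = A, b = −2A).  Polarity lost by the magnitude operation
is restored by enumerating every "first k points negative" restoration
(k = 0…n) and keeping the lowest-residual fit.  No repetition-time
saturation correction is applied: the TRs are treated as long, a documented
approximation.  Multi-component relaxation, B₀/B₁ inhomogeneity and
dictionary methods are out of scope.

### Fitting engine

Each pixel poses a small bounded nonlinear least-squares problem.  The
amplitude parameters are linear given the relaxation time, so they are
profiled out in closed form (variable projection), leaving a smooth 1-D
problem in T that is solved by a dense logarithmic grid (T2/T1ρ: 200
points on [1, 500] ms; T1: 160 points on [50, 5000] ms) followed by 70
golden-section iterations on the bracketing interval.  This reaches the
least-squares minimiser to ~1e−10 relative tolerance and vectorises over
all pixels of a map, which is what keeps whole-cohort simulations fast on
one CPU.  For T1, every polarity restoration is refined before choosing
the winner: selecting the restoration from grid residuals alone can pick
the wrong branch when the signal null falls near an acquired TI.

Flagging: pixels whose optimum lands on a relaxation-time bound, whose
amplitude is non-positive, whose IR fit is not an inversion (b ≥ 0), or
whose signal is non-positive at every point are marked non-converged and
excluded from all ROI summaries.  Degenerate (e.g. constant) decays drift
to the upper bound; the map reports that bound with the flag cleared.

Noiseless recovery is exact to ≤ 0.1 % for all three contrasts; under
Rician noise the median estimate carries the expected small magnitude-bias
(bounded in tests: ≤ 2 % for T2 at SNR 100, ≤ 5 % for T1ρ at SNR 40,
verified against dense grid-search oracles).

## Zonal geometry

Boundary pixels are removed by a single 8-connectivity morphological
erosion (partial-volume suppression).  The erosion depth is an assumption;
one pixel is the minimal, conservative choice.

The eroded mask is partitioned into mediolateral thirds between its
extreme columns x_min and x_max: the interval [x_min, x_max + 1) is cut at
thirds and every pixel is classified by the third containing its column
centre (x + 0.5).  Centres have half-integer coordinates while cuts are
multiples of w/3, so a centre can never coincide with a cut: the rule is
tie-free, conserves pixels exactly, is translation invariant, and
mirror-symmetric (flipping the image and the apex-side label mirrors the
partition bit-exactly).  Zone I is the apex side, III the base side; which
image side is the apex is explicit configuration, never inferred from
image content.

## Response to loading

Per loading position and ROI (entire sample, zones I/II/III) the map is
summarised as median (IQR) over unflagged pixels; quartiles use linear
interpolation (numpy's default), frozen for reproducibility.  Positions
are summarised independently — no inter-load registration — matching
per-position re-segmentation.  The response statistic is the per-sample
relative change Δᵢ = (value(δᵢ)/value(δ₀) − 1)·100 %, negative for
decreases; cohort Δ statistics are means ± SD over per-sample Δ values,
never ratios of cohort medians.  Cohort medians of absolute values are
medians of per-sample ROI medians (per-sample-first; whether pixels should
instead be pooled across samples is unknowable from summary tables, and
per-sample-first keeps samples exchangeable units).

## Biomechanics

Unconfined compression of 4 mm biopsy cores (3 mm height, 0.0083 mm/s to
100 % strain) yields stress–strain curves fitted with the two-parameter
exponential model

    σ(ε) = c·(exp(bε) − 1),     EM(ε) = dσ/dε = c·b·exp(bε)

where b (dimensionless) sets the degree of nonlinearity and c (MPa) scales
the stress.  EM is evaluated at ε = 0.2 and 0.8 (engineering strain
fractions).  The associated strain-energy form Ψ(ε) = c/(2b)·(exp(bε)−1)²
is provided as an alternative energy evaluator; its second strain
derivative is *not* c·b·exp(bε), so the package defines EM from the stress
model — the form whose tangent modulus is exactly the expression above —
rather than from Ψ.  A tare offset (the stress at the smallest strain) is
removed before fitting so σ(0) = 0.

Fitting is bounded least squares (scipy `trf`) multi-started over
b ∈ {1, 3, 5, 8, 12} with the amplitude c initialised by linear projection;
the best residual wins.  Standard errors come from the Gauss–Newton
covariance.  Fewer than 5 points is an error; a strain span below 50 % only
warns (the small-strain limit c·b·ε is itself a useful fit).  EM₈₀ > EM₂₀
holds identically, with EM₈₀/EM₂₀ = exp(0.6·b).

## Histology scoring

The Pauli classification sums surface integrity (femoral + tibial + inner,
0–3 each), cellularity (0–3), collagen organization (0–3) and matrix
staining (0–3) into a 0–18 score binned as Grade I (0–4), II (5–9),
III (10–14), IV (15–18); Grades III and IV are collapsed into "≥III" for
group analyses.  One consensus score tuple per sample; inter-rater
variability is out of scope.

## Statistical plan

* Absolute values, across grades: Kruskal–Wallis (tie-corrected), with
  Dunn's pairwise z-tests.
* Absolute values, across loading positions: Friedman test on complete
  per-sample triplets, Dunn's post-hoc on within-block rank sums,
  pairwise flags reported in the order δ₀–δ₁, δ₀–δ₂, δ₁–δ₂.
* Δ values: one-way ANOVA across grades and unpaired Student's t-test
  Δ₁ vs Δ₂, gated by D'Agostino–Pearson normality screening at 0.05
  (fewer than 8 observations are treated as non-normal).
* Pixel counts: repeated-measures ANOVA (statsmodels `AnovaRM`).
* qMRI vs Elastic Modulus: tie-aware Spearman ρ.

The omnibus significance level defaults to α = 0.005.  Post-hoc pairwise
flags use Bonferroni-adjusted p ≤ 0.05: with n ≤ 16 samples per group, the
Friedman–Dunn z for adjacent loading positions is bounded by
1/√(k(k+1)/(6n)) ≈ 2.74 even under a perfect per-sample ordering, so a
0.005 post-hoc threshold could never flag an adjacent pair at these sample
sizes; the conventional 0.05 on adjusted p is the only reading under which
the canonical result pattern (all three pairwise contrasts flagged at
n = 15) is attainable.  Both thresholds are configurable and frozen in
tests.  Dunn's tests are tie-corrected; no multiplicity control beyond the
Bonferroni over the three pairs is applied.  Exact/permutation p-values
(full enumeration of within-block orderings for Friedman when feasible,
Monte-Carlo label permutation for Kruskal–Wallis) are available for small
samples and are validated against independent enumeration oracles in the
test suite.

## Synthetic cohort: what it emulates, and what not

The generator produces the study conditions end to end:

* **Cohort structure** — 45 samples split 14/16/15 across Pauli grade
  groups I / II / ≥III (largest-remainder allocation of the grade
  fractions).
* **Geometry** — one 64 × 64 image at 0.25 mm/pixel per loading position;
  a triangular wedge of mean width 8.4 ± 1.0 mm and mean base height
  11.45 ± 2.0 mm (chosen so the unloaded mask holds ≈ 800 pixels, the
  published cohort mean).  Loading compresses the wedge geometrically:
  per-column heights are re-allocated by largest remainder so the loaded
  pixel count equals round(f·n₀) exactly, with area-retention factors
  f = 1.0 / 0.896 / 0.754 (the published 801 → 718 → 604 pixel-count
  ratios); width is preserved, emulating flattening.  No biomechanical
  deformation simulation and no inter-load registration — each position is
  generated and analysed independently.
* **Relaxation ground truth** — zone/grade/load central values are the
  published cohort medians for this experiment type (e.g. unloaded
  entire-sample T1 ≈ 696 ms, T1ρ ≈ 46.7 ms, T2 ≈ 24.7 ms, with T1
  decreasing everywhere under load, apex T1ρ rising in Grade-I/II and
  falling in ≥III samples, apex T2 falling in degenerative samples).  Per
  sample, one offset per contrast (SD 70 / 8 / 3 ms for T1/T1ρ/T2,
  IQR-derived between-sample spreads) is shared across zones and loads,
  plus small per-zone-and-load jitter (7 / 1.5 / 0.8 ms) representing
  repositioning and measurement repeatability.  Within a zone the truth is
  homogeneous, so an ideal pipeline's ROI medians equal the stored truth
  exactly — this is what makes the ≤ 0.5 ms noiseless recovery check
  sharp.  Real tissue is heterogeneous within zones; passing these tests
  therefore demonstrates correctness of the pipeline, not robustness to
  intra-zonal texture.
* **Acquisition noise** — Rician: the modulus of the noiseless signal plus
  complex Gaussian noise (σ = 2 at amplitude 100, SNR 50, a typical
  small-coil regime).  Averaging many draws at high SNR recovers the
  noiseless signal within 1 %.
* **Biomechanics** — per grade group, (b, c) are derived from log-normal
  draws of EM₂₀ and EM₈₀ around the published group means (15.5–17.8 and
  343–354 MPa) via b = ln(EM₈₀/EM₂₀)/0.6, c = EM₂₀/(b·e^{0.2b}).  The
  published SD structure (EM₂₀ CV ≈ 0.6 but EM₈₀ CV ≈ 0.2) implies a
  strong negative correlation between log EM₂₀ and b, which this
  parametrisation encodes directly.  Curves carry Gaussian stress noise of
  2 % of the maximum stress on a 0–100 % strain grid in 1 % steps.
* **Degeneration coupling** — one latent standard-normal factor per sample
  loads the qMRI offsets with weight +0.75 and the log-EM draws with
  −0.75, giving a latent Pearson correlation of ≈ −0.56 — inside the
  published Spearman band [−0.67, −0.43] for unloaded qMRI vs Elastic
  Modulus.
* **Histology** — Pauli sum scores are drawn per group (3.4 ± 0.9 clipped
  to 0–4; 8.0 ± 0.9 to 5–9; 12.3 ± 1.5 to 10–16, the published group
  means) and decomposed uniformly into valid component tuples; grading and
  trichotomisation then run through the same scoring code as real data.

All randomness flows through a single seeded generator; identical seeds
give bit-identical cohorts.

Not emulated: 3-D volumes, B₀/B₁ field effects, intra-zonal tissue
heterogeneity and focal lesions, perimeniscal soft tissue, loading-device
mechanics (torque lever, confinement inlays), and the acquisition physics
beyond the mono-exponential signal forms.

## Problem sizes used in the test suite

The default test configuration analyses 45-sample cohorts at 64 × 64
resolution; the end-to-end detection property (the encoded T1 and zonal
T1ρ response patterns recovered at α = 0.005) is evaluated over ten seeded
replicates and must succeed in at least nine.  Structure, determinism and
recovery tests use 3–9-sample cohorts.  These sizes were chosen to make
the full suite a few minutes on one CPU while keeping every statistical
check at the cohort's real group sizes.

## Known limitations

* The vendor map-fitting algorithm used by any particular scanner is
  proprietary; only model-level recovery, not numerical equality with
  vendor maps, can be asserted.
* The magnitude-IR polarity search assumes a single null (prefix sign
  restorations), which is exact for mono-exponential inversion recovery.
* No TR-saturation correction; T1 values from short-TR protocols would be
  biased.
* The statistics module implements the fixed test plan above; mixed-effects
  models and FDR-style multiplicity control are out of scope.
* Δ statistics require a positive unloaded reference median; flagged or
  missing references propagate as missing values, not errors.
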