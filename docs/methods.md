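# Methods

This note documents the models, conventions and numerical choices behind
`ppcv`: what each stage assumes, which knobs matter, what the synthetic
generators do and do not emulate, and where the design was genuinely open.

## 1. Scan geometry and coordinates

A dense B-scan OCTA volume ("DART" scan) is modeled as `n_slices` (default
25) co-registered B-scans of `n_ascans` (default 512) A-scans covering a
`lateral_extent_mm × slab_depth` strip, default 3.0 mm laterally and
(25 − 1) × 6 μm = 144 μm along the slice-advance axis. The nominal strip
dimensions are quoted in degrees by the device (10° × 0.5°); the package
works directly in the millimetre equivalents and ignores eye-model optics,
since all quantification downstream is metric. Axial extent and pixel
pitch are instrument details not fixed by the protocol; defaults of
0.35 mm and 3.9 μm/px cover a full retinal thickness at Spectralis-like
axial sampling and are configurable.

Axes: `x` = slice advance (slice *i* at xᵢ = i·Δh), `u` = lateral within a
B-scan, `z` = axial depth. Images are indexed `[slice, row, col]` with
row ↔ z, col ↔ u; pixel centers sit at integer pixel coordinates.

One deliberate ambiguity is resolved as follows: "25 slices at ~6 μm
spacing over ~0.15 mm" could mean 25 × 6 μm = 150 μm of tissue or
24 intervals × 6.25 μm. The package takes Δh = 6.0 μm exactly over 24
intervals (slab depth 144 μm), since Δh is the quantity that enters the
quadrature.

## 2. Vascular phantom

`generate_network` draws straight cylindrical vessel segments in three
capillary plexuses (superficial/intermediate/deep, at configurable depth
fractions) plus a few large vessels:

* **Radii.** Capillaries uniform in [2, 6] μm, large vessels in
  [15, 60] μm.
* **Orientation.** Retinal capillary plexuses run predominantly parallel
  to the retinal surface, so a fraction `parallel_fraction` (default 0.9)
  of capillaries gets an elevation within 10° of the en-face plane.
  Azimuths concentrate around the slice-advance axis (SD 25°): the scan
  strip sits tangentially beside the disc, and peripapillary capillaries
  follow the radial nerve-fiber bundles, crossing the B-scan planes
  steeply. This matters numerically as well — a vessel lying *within* a
  B-scan plane produces an arbitrarily long flow streak whose equivalent
  diameter can exceed the vessel-exclusion cutoff.
* **Disjoint lumina.** Capillary candidates that would interpenetrate an
  already placed vessel are redrawn (up to 60 attempts), so the
  cylinder-sum ground-truth volume has no double counting.
* **No grazing.** Along each axis the whole tube is kept inside the
  scanned box whenever the segment's span allows it; otherwise the segment
  crosses that face steeply. This keeps the analytic volume (π r² times
  the centerline length clipped to the box, flat end caps) exact: oblique
  face cuts through the centerline are volume-antisymmetric, and grazing
  cuts — the one configuration that breaks that argument — cannot occur.
* **Density.** Default 40 capillaries per plexus (120 in the strip) gives
  per-slice capillary areas around 10⁴ μm² and volumes around 10⁶ μm³,
  the order of magnitude consistent with the regression coefficients the
  cohort module targets.

Ground truth (`analytic_capillary_volume`) reports the exact cylinder-sum
capillary and large-vessel volumes inside the box and the true capillary
cross-section area at every slice plane, the latter sampled on a 0.5 μm
grid restricted to each cylinder's plane-crossing support (error
≪ 1 μm² per vessel). An independent 0.5 μm voxelization oracle in the
test suite confirms the volumes to within 1%.

Not modeled, deliberately: vessel tortuosity and branching topology,
optical ray tracing, OCT interferometric signal formation, projection
artifacts, and pathological morphology (microaneurysms, neovascular
fronds). Passing phantom tests therefore demonstrates the correctness of
the measurement chain, not robustness to every artifact of in-vivo OCTA.

## 3. Rendering model

Each slice image is the flat-capped cylinder cross-section of all
segments at that plane, rasterized with 3× subpixel supersampling into a
fractional coverage map, mapped to intensity
`background + (foreground − background) · coverage` (defaults 20/200 on a
0–255 scale), blurred by an isotropic Gaussian PSF (default σ = 1.5 μm),
multiplied by unit-mean gamma speckle (default shape 16, ≈ 25% contrast)
and clipped. Speckle-as-multiplicative-gamma and Gaussian PSF are the
standard first-order OCT approximations. The renderer also attaches clean
pixel-center rasterizations of the capillary-only and vessel-only cross
sections as per-slice ground-truth masks.

## 4. Flow segmentation

The manual ImageJ workflow is reproduced as five deterministic steps with
**one settings object per batch** ("same brightness and threshold in each
picture"): affine brightness mapping clipped to the intensity range;
strict `intensity > t` thresholding; polygon ROI (pixel-center, even-odd
containment; self-intersecting polygons rejected; `None` = full frame);
large-vessel exclusion; area = pixel count × lateral pitch × axial pitch
(anisotropic pixels).

* **Vessel exclusion.** The study's expert-confirmed manual vessel
  exclusion is replaced by a stated criterion: connected components
  (default 8-connectivity) whose equivalent diameter √(4A/π) exceeds
  20 μm are removed. Capillaries are anatomically below ~10 μm, and
  their slightly oblique cross-sections stay below the cutoff, while
  large vessels (≥ 30 μm wide) always exceed it.
* **Threshold default (88).** The intensity threshold used in the study
  is unreported; only the convention that one value is used throughout is
  stated. Absolute areas are therefore not reproducible — only the
  procedure is. The package default is set by a flat-field calibration:
  at this pixel pitch capillary cross-sections are *sub-pixel*, so the
  textbook half-amplitude (FWHM) threshold systematically loses small
  discs whose peak coverage never reaches 0.5 (≈ 19% of capillary area on
  default phantoms). Thresholded area as a function of threshold shows a
  wide plateau at background + 35–42% of amplitude where it equals the
  rasterized cross-section area of noise-free default phantoms; the
  default 88 = 20 + 0.378 × 180 sits mid-plateau. The residual bias of
  the full noisy chain is about +3–5%, well inside the ±10% recovery
  envelope verified over 20 phantom seeds.

## 5. Volume reconstruction

`trapezoid_volume` applies the composite trapezoidal rule
V = Δh Σ (Aᵢ + Aᵢ₊₁)/2 — exact for affine profiles, O(Δh²) for smooth
ones (both properties are tested). Volumes are reported in μm³ with an
nL convenience field (1 nL = 10⁶ μm³); the μm³ scale is an inference from
the magnitude of the published regression coefficients (10⁴–10⁶ per unit
predictor), since the source workflow never states PPCV units.

A variant expansion that has appeared in print —
½[A(x₁)+A(x_{n+1})]Δh + Σᵢ₌₂ⁿ⁻¹[A(xᵢ)+A(xᵢ₊₁)]Δh — is *not* algebraically
the trapezoidal rule (the summation lacks its ½ and skips one interval,
roughly doubling interior weight). It is available verbatim behind
`formula="as_printed"` for comparison and is never used by the pipeline.

Quadrant volumes are reported per quadrant and never summed: the
downstream statistics treat quadrant measurements as separate
observations.

## 6. Synthetic cohorts

`generate_cohort` emulates the statistical structure of a peripapillary
DR study:

    PPCV = β₀ + β_age·age + β_nasal·1{nasal} + β_DR·1{DR}
           + offset(group, visit) + b_subject + b_eye + ε

* Healthy arm: 101 subjects, one randomly chosen eye, four quadrant
  records at baseline. Ages are truncated-normal on [18, 90] with the
  *realized* mean/SD equal to 46.79/19.30 (the latent parameters are
  solved for, so the generated moments match the design).
* Treatment arms: 62 anti-VEGF, 74 PRP and 51 surgery eyes (≈ 34% of
  eyes are fellow eyes of bilateral patients), six visits
  (baseline, w1, w2, m1, m2, m3), four quadrants each.
* Effects: β_age = −20790.03 μm³/year and β_nasal = −1.129 × 10⁶ μm³ are
  the published effect sizes the generator is calibrated to; β₀ =
  5.5 × 10⁶ and σ_ε = 5 × 10⁵ are free design constants chosen so all
  simulated volumes stay positive and the printed effects are detectable
  at the study's sample sizes. β_DR = −1.5 × 10⁶ encodes the reported
  DR deficit. All are configurable, none hard-coded.
* Visit offsets follow the qualitative published time courses —
  anti-VEGF: dip at weeks 1–2, recovery by month 1; PRP: flat through
  month 1, rise at months 2–3; surgery: dip at week 1, recovery, rise at
  month 3 — with magnitudes as free design parameters (the source figures
  print no numbers).
* Change-score coupling: at month 3, ΔPPCV = offset + slope·ΔlogMAR + η
  per eye, with slopes −9.67 × 10⁵ (PRP), −6.83 × 10⁵ (surgery) and 0
  (anti-VEGF). ΔPPCV is taken as the *response* and ΔlogMAR as the
  predictor; the β magnitudes (~10⁵–10⁶) only make sense in that
  orientation.
* Inter-eye correlation: eye-level random effects split into a subject
  share ρ (default 0.6 — the source only states that GEE was used to
  handle the correlation) and an eye-specific remainder.

`generate_rater_pairs` adds two independent measurement columns
truth + N(0, σ²ₑ) with σ²ₑ = σ²_b(1 − ICC)/ICC, the variance-component
identity that fixes the population ICC(2,1).

## 7. Statistics

* **t test**: pooled-variance by default (that is what "Student's t"
  names), Welch by flag. Two constant equal groups return P = 1 by
  convention.
* **SNK**: stepwise studentized-range over sorted means; a stretch of r
  means is significant when its range exceeds
  q(α, r, df_err)·√(MS_within/2·(1/nᵢ + 1/nⱼ)) (Tukey–Kramer-style
  harmonic allowance for unequal n); non-significant stretches form
  homogeneous subsets and are not subdivided. Quantiles come from
  `scipy.stats.studentized_range` and are validated against published
  tables at α = 0.05, r = 2–5, df = 10/20/60. Under the complete null the
  familywise error equals the first-step level, verified by simulation.
* **LSD**: pairwise t against baseline using the pooled within-group mean
  square and error df of the full one-way ANOVA, unadjusted. The
  multiplicity stance mirrors common clinical practice: SNK controls
  stepwise, LSD and t are unadjusted, and no extra FDR layer is added.
* **OLS + VIF**: statsmodels OLS with intercept; sex and hemisphere coded
  binary (temporal quadrants pooled vs nasal pooled, following the
  reported absence of superior/inferior differences); VIFⱼ = 1/(1 − R²ⱼ)
  from auxiliary regressions, clamped at ≥ 1 against floating-point
  round-off; rank-deficient designs raise an error naming the collinear
  predictors.
* **GEE comparison**: marginal mean model y = β₀ + β₁·1{group A} with
  exchangeable working correlation (moment estimate of ρ, capped at
  0.99), identity link, sandwich covariance with the small-sample factor
  m/(m−1)·(N−1)/(N−p) and a t reference on m − p df (m = clusters).
  The small-sample correction is why this is implemented directly rather
  than delegated: uncorrected sandwich CIs under-cover at
  double-digit cluster counts, and the corrected version reaches nominal
  95% coverage in simulation (the statsmodels GEE fitter serves as an
  independent cross-check in the tests). With one record per cluster the
  procedure reduces to the ordinary two-sample comparison, and
  duplicating every record leaves the standard error unchanged rather
  than shrinking it by √2.
* **ICC**: ICC(2,1) — two-way random effects, absolute agreement, single
  measurement — computed from the two-way ANOVA mean squares; the
  model/type choice is documented here because reliability reports often
  omit it. Cross-checked against an independent implementation to 1e-9.
* **κ**: Cohen's κ with marginal-product chance agreement, defined only
  for categorical inputs with ≥ 2 observed categories. Repeatability of a
  *continuous* measurement has no canonical κ; `quartile_bins` is the
  documented helper for discretizing repeated continuous readings first.

## 8. Pipeline and formats

Stacks travel as multi-page float32 TIFF plus a JSON sidecar (geometry,
seeds, ground truth); profiles and cohorts as CSV; configs, manifests and
fits as JSON. The native device format is proprietary and undocumented,
hence the open interchange choice. All randomness flows from named seeds
in the config; `run_full` writes every artifact, hashes it into a
manifest, and reproduces identical hashes on identical configs. CLI exit
codes: 0 success, 2 validation error, 1 runtime error.

## 9. Problem sizes in the checks

The verification suite uses desk-scale problem sizes chosen to make
Monte-Carlo error small relative to the tested tolerances: 20 phantom
seeds for end-to-end recovery, 20 small random networks against the
voxelization oracle, 200 replicate cohorts for effect-size recovery and
rater reliability, 10 000 replicates for SNK familywise error and 2 000
for GEE coverage.

## 10. Known limitations

* Straight, non-branching vessel segments; no flow-speed weighting of the
  OCTA signal (flow is binary in/out of a lumen).
* The absolute flow areas depend on the threshold convention, as they do
  in the manual workflow; only the calibrated-default pipeline is
  validated against ground truth.
* The GEE implementation covers the two-group mean comparison used here,
  not a general marginal-model framework.
* κ on continuous repeats requires explicit binning; results depend on
  the chosen bins.
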