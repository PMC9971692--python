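# Methods

This note documents the models behind each pipeline stage, the defaults
that matter, what the synthetic generators do and do not emulate, and the
design choices made where the underlying methodology is genuinely open.

## Stain quantification (HSB gating)

Pixels are partitioned in hue/saturation/brightness space. The gating
logic differs per stain:

- **PSR** — background iff saturation < `background_max_saturation`
  (default 0.15; brightness is ignored). Tissue pixels are split into
  Sirius-red collagen (hue in [330°, 30°), wrapping through 0) versus
  picric-acid muscle (hue in [30°, 90°)). Tissue hues in neither window
  are force-assigned to the nearer window by circular hue distance, so
  that red + yellow exhaust the tissue: the fibrosis-fraction denominator
  is red + yellow only, and silently dropping ambiguous pixels would bias
  it. Per-image fraction = red/(red+yellow); per-sample value =
  arithmetic mean over images.
- **AP** — background iff brightness > `background_min_brightness`
  (default 0.92). Stain-positive requires saturation ≥ 0.20 *and* hue in
  [330°, 25°); all other non-background pixels are counterstained tissue.
  Per-image fraction = red/total tissue; per-sample value = geometric
  mean, because AP staining is focal and a log-scale average is the
  stabler summary. Zero per-image fractions are replaced before the log
  by ε = 1/(tissue pixel count) of that image — the smallest expressible
  nonzero fraction.

Both metrics are area-based by design; no intensity weighting. The
numeric windows are package defaults chosen to contain the synthetic
generator's colour models with ≥ 10° hue margin; real staining batches
vary, so the gate spec is an explicit, serialisable object
(`HsbGateSpec.to_json`/`from_json`) meant to be recalibrated per batch and
stored with the results. Batch identity is recorded and reported, never
corrected for. Images with fewer than 1% tissue pixels raise an
empty-field error rather than returning a meaningless fraction.

## Fibre morphometry

**Segmentation.** Boundary images (bright basement-membrane rings, dark
fibre interiors) are thresholded (Otsu default), and a marker-based
watershed on the interior distance transform splits fibres whose shared
boundary is incomplete. Elongated fibres carry several distance-transform
peaks, so every watershed split is audited against the original image:
two adjacent regions are merged back when the pixels along their dividing
line show no boundary signal (mean intensity below threshold). The
limitation is symmetric: two genuinely fused fibres with *no* boundary
evidence between them will be merged too — that case is what the manual
`correction_mask` (painted boundary strokes) is for.

**Minimum Feret diameter.** Polygons are traced at label boundaries with
sub-pixel marching-squares contours (stabler under rotation than pixel
point sets), and the MFD is computed exactly on the convex hull: the
minimum caliper width of a convex set is attained with one jaw flush to a
hull edge, so minimising the farthest-vertex distance over hull edges is
exact. Border-touching fibres are excluded by default (clipped profiles
bias the MFD low); labels under 10 px are dropped.

**Summaries.** CoV uses the sample SD (n−1). Histogram bins are
left-closed 5 µm bins from 0 with an open top bin. Normalised medians
(median/bodyweight, median/femur length) are computed only when the
covariate is present — absent, not zero. Femur length is treated as an
arbitrary consistent unit.

**ROUT outliers.** The regression-based ROUT procedure is adapted to a
univariate sample: robust location = median; robust scale = RSDR, the
68.27th percentile of absolute residuals with small-sample correction
n/(n−1); residual t probabilities (df = n−1) tested from the most extreme
inward against the stepwise threshold Q·(n−i+1)/n, Q = 1% by default.
A zero RSDR with nonzero residuals (constant core plus spikes) flags the
spikes directly. Flags are reported but **not** removed from medians/CoV
unless removal is requested — outlier flagging exists for display, not
for silently changing the statistics.

## qPCR relative quantification

Cq model: technical replicates are averaged on the Cq scale (SD > 0.5
cycles flagged); RQ = (1+E)^(anchor−Cq) with per-target efficiency E
(default 1.0, i.e. perfect doubling — assay efficiencies in the
motivating design all fell within 95–105%, and per-target values are a
config field). The anchor is the per-target mean Cq of the calibration
samples; any anchor cancels in the between-group ratios the analyses
report. Non-detects are missing, never zero.

**Inter-plate calibration.** A set of ≥ 4 calibration samples measured on
every plate yields per-plate factors: the geometric mean over calibration
samples of (cross-plate consensus RQ / plate RQ), consensus defined in
log space for symmetry. A whole-plate Cq offset cancels exactly; the
procedure is idempotent to machine precision. A calibration sample
missing from any plate is an error naming the plate and sample.

**Normalisation.** GOI RQ / geometric mean of the three reference-gene
RQs per sample (SDHA, RPL13a, HPRT1 by default). Samples missing a
reference are excluded and listed, never imputed. A geNorm-style M
stability value is reported as a diagnostic but never swaps references.

**Dystrophin metrics.** With primers along the transcription unit, the
maturity fraction (exon 62–64 RQ / exon 1–2 RQ) tracks survival of the
mature transcript pool: nonsense-mediated decay degrades only transcripts
past the nuclear-export checkpoint, so initiation (exon 1–2) is preserved
while the 3' signal collapses in dystrophic muscle. The mid-transcript
fraction (exon 44–45) is transcribed hours earlier and is the larger
subset in well-behaved data. dp71, from an internal promoter, is carried
as its own normalised RQ with log10 reporting.

## Cohort statistics

Model: `value ~ group + level + group:level` with a random intercept per
animal, fitted by REML (statsmodels MixedLM). The random-effects
covariance beyond a random intercept is not identifiable from the designs
targeted here; richer residual structures were deliberately left out.
Term tests are Wald F statistics with containment-style denominator
degrees of freedom — the group main effect against between-animal df
(animals − groups), within-animal terms against residual df. This is an
approximation (no Kenward-Roger or Satterthwaite correction); its
practical calibration is verified by simulation: the full pipeline holds
a 4.1% empirical type-I rate at nominal 5% over 1000 null cohorts of 10
animals/group. Designs where the intercept is inestimable (one animal
per group, boundary variance) fall back to OLS and say so.

The log10-vs-identity decision is made once per biomarker across the
whole dataset (not per age): Shapiro-Wilk per design cell on both scales,
log10 chosen when a majority of cells fail raw normality and more cells
pass after logging. Shapiro has low power below ~15 values per cell, so
small pilot datasets default to the identity scale — by construction, not
by accident. Non-positive values force identity with a warning.

Post-hoc: per repeated level, the marginal group difference is a linear
contrast of the fixed effects, tested with a t statistic on
between-animal df; the correction family is the set of levels of one
biomarker, adjusted by Holm-Šídák
(adjusted₍ₖ₎ = max over j ≤ k of 1−(1−p₍ⱼ₎)^(m−j+1), clipped to 1) and
mapped to the star convention (*, **, ***, **** at 0.05/0.01/0.001/
0.0001). A second contrast family (e.g. young vs old dystrophic groups)
is obtained by calling the post-hoc with a different group pair.

Mann-Whitney uses the exact null distribution up to n = 25 per sample and
the tie-corrected normal approximation beyond; Pearson reports (r, r²,
two-sided p).

## Power analysis

Effect construction: treated = untreated + f·(reference − untreated) per
repeated level, f ∈ [0, 1] the restoration fraction. Power is for the
treated-vs-untreated two-group comparison; f = 1 reduces to the
reference-vs-untreated contrast.

Default test: Hotelling-Lawley trace. With a single between-group
contrast the trace is Hotelling's T², whose F form is exact:
T² = [pν/(ν−p+1)]·F(p, ν−p+1; λ), ν = 2n−2,
λ = (n/2)·δ'Σ⁻¹δ. At zero effect the power equals α exactly, and with
one repeated level the computation reproduces classical two-sample t
power to < 10⁻⁴. When ν < p the covariance is inestimable and power 0 is
returned so integer searches skip infeasible n; for a 10-level panel this
means n ≥ 6 per group is required for the multivariate test. The
univariate path applies the Geisser-Greenhouse correction
ε = tr(Σ)²/(p·tr(Σ²)) to both degrees of freedom and the noncentrality.
α defaults to 0.05 two-sided. `minimal_n` searches upward from n = 2,
caps at 10 000 with an explicit infeasibility flag, and zero effects
return an unsatisfiable result rather than a number.

The Monte-Carlo oracle draws multivariate-normal cohorts from the
design's means and covariance and performs the designated test with
sample estimates; it validates the noncentral-F arithmetic independently
(agreement within 3 binomial SEs at 2000 reps across an f × n grid). An
LMM-based simulated power is available by composing `simulate_cohort`
with `fit_lmm`.

Pilot covariance estimation uses the unstructured sample covariance of
complete per-animal profiles, falling back to compound symmetry when
complete profiles number fewer than levels + 2. Design files round-trip
through a native JSON schema; GLIMMPSE-style study-design JSON is
imported best-effort (beta and error-covariance matrices, alpha, test),
with unmapped sections reported in `design.notes["unsupported"]`.

## Synthetic data: what a green test establishes

The generators reproduce the *statistical structure* the analyses assume,
not realistic histology or assay artefacts:

- **Stain images** place stain-positive pixels as correlated blobs
  (Gaussian-smoothed noise thresholded at the exact within-tissue
  quantile), so `true_fraction` is exact by construction and spatial
  aggregation is exercised. Colours are sampled inside generator windows
  that sit strictly within the default gates (2° interior margin absorbs
  8-bit quantisation drift), so exact gate recovery is *by design* — a
  green recovery test validates the gating arithmetic, not robustness to
  stain variability, uneven illumination or out-of-gate hues.
- **Fibre mosaics** are jittered-grid Voronoi cells, eroded to leave
  ~3 px bright boundaries and shrunk to match lognormal MFD targets
  (median m, σ = √log(1+CoV²)), rank-matched to cell sizes and clamped to
  fit; the realised median/CoV therefore carry declared tolerances
  (±10% relative, ±0.05 absolute) while `true_mfd` itself is recomputed
  exactly from the final polygons. Boundaries are complete — the
  round-trip validates segmentation/measurement accuracy, not
  gap-sealing on degraded real staining.
- **Cq tables** follow Cq = base − log2(FC)·[group 2] + per-sample
  loading + plate offset + N(0, σ) noise, with 2 replicates and 4
  calibration samples on every plate; the normalised group ratio equals
  the requested fold change exactly before noise.
- **Cohorts** are cell mean + N(0, sd_between) animal intercept +
  within-animal MVN residual (compound-symmetry or full correlation
  matrix), with optional per-cell dropout. Default simulated scenarios
  use 6 repeated levels, sd_between = sd_within = 0.5 and ρ = 0.3 —
  moderate between-animal heterogeneity with modest within-animal
  correlation, the regime longitudinal biopsy biomarkers typically show.

Everything is reproducible bit-for-bit from the seed. Field pixel
dimensions and µm/px are configurable, not inferred (defaults: 512²
fields, 0.5 µm/px).

## Known limitations

- Gate defaults are declared, not reverse-engineered from any particular
  staining protocol; recalibrate per batch.
- No stain-vector colour deconvolution and no intensity-weighted AP
  scoring — the metrics are area-based on purpose.
- The mixed model does not attempt to replicate any specific commercial
  implementation's covariance structure or denominator-df method.
- Revertant-fibre counts are supplied (manual counts), not detected.
- GLIMMPSE import is best-effort over the matrix/alpha/test sections; it
  does not implement the full feature set (Kenward-Roger Wald options,
  confidence-limited power curves).
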