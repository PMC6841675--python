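# Methods

This note documents the models and procedures implemented in `samquant`,
the parameter choices that matter, what the synthetic-data generators do
and do not emulate, and the numerical decisions a maintainer should know
about.

## Meristem-centre estimation

**Sphere fit.** The dome of L1 nuclei is modelled as a spherical cap.
The fit is the algebraic (Coope-style) linear least-squares solution of
`|p|² = 2c·p + k` with `r = sqrt(k + |c|²)`, computed on mean-centred
coordinates for conditioning.  By default one Gauss–Newton pass on the
geometric residuals `‖p−c‖ − r` follows; the reported RMS residual is
always geometric.  The algebraic solution is closed-form and
deterministic; the single refinement pass is enough to make algebraic and
geometric optima agree to well under 0.1 µm at realistic noise (0.5 µm
positional error on 20 points).  Rank deficiency of the design matrix
(coplanar nuclei) raises a degenerate-configuration error rather than
returning an unstable fit.

**P_center.** The three primordium seed points are projected radially
onto the fitted sphere.  All three projected seeds lie on a plane; the
two intersections of the sphere with the line through its centre along
that plane's normal are the only points equidistant (great-circle sense)
to all three.  The summit-side candidate is selected using a summit hint
— by default the projected centroid of the nuclei used in the fit — and
the antipodal candidate is retained for audit.  Great-circle distance is
used for all on-sphere distances; chord distance is monotonically related
and would select the same point.

**Validation against the reporter centre.** The stem-cell reporter
(CLV3) provides an independent centre estimate: the intensity-weighted
centroid of L1 nuclei, projected to the sphere.  On synthetic meristems
at default noise the geometric and reporter-derived centres agree within
one cell diameter in ≥ 95% of runs (the acceptance script measures this
on 100 meristems, and separately on nine reference seeds, where 9/9 is
the expected outcome).

## Radial quantification

**Cross-section profiles.** The top-view surface projection is sampled
by bilinear interpolation along the full line through the centre at each
of `n_sections = 100` angles (step 3.6°), at one sample per pixel out to
the grid edge.  Signed positions are folded to radial distance (the two
half-rays of a section are averaged), sections are averaged per distance
bin (bin width = pixel size), and samples outside the grid are missing
and excluded.  On rotationally symmetric inputs the per-section spread is
limited only by bilinear interpolation error, which scales as
`(pixel/σ)²` for a feature of scale σ; the verification uses a wide
Gaussian on 0.1 µm pixels where this is below 10⁻⁶ of the signal.

**Central window and time courses.** Group comparisons use one number
per meristem (the mean profile value within ±12.5 µm of the centre) so
the experimental unit is the meristem, not the pixel.  "Student's
t-test" is the equal-variance two-sample test (two-sided); Welch's
variant is available by flag.  Multi-group time courses use one-way
ANOVA with Tukey's HSD post hoc (delegated to scipy).  The central-window
test holds its nominal 5% level on null synthetic groups (measured:
within 5% ± 1.5% over 2000 simulations).

**Central-minimum size (120% threshold).** The centre background is, by
definition, the distance-0 bin of the averaged profile; the readout is
the first distance at which the profile reaches
`background_threshold_factor` (default 1.2) × background, linearly
interpolated between bins — interpolation is required because the
quantity is reported at sub-pixel resolution.  Profiles that never reach
the threshold are *censored* at the maximal measured distance rather than
given a fake value.
Because the distance-0 bin of a cell-mosaic image rests on a single cell
patch, its multiplicative noise propagates 1:1 into the threshold; the
config therefore offers `background_halfwidth` (µm) to average the
background over a small central disc.  The recovery studies use 2.5 µm.
Reported distances are radii, not diameters.

**Stem-cell gate and normalisation.** A cell is a stem cell iff its
perpendicular distance to the central axis is ≤ ¼·rad_sphere, boundary
inclusive.  Distances and per-cell mean intensities are min–max
normalised *within each meristem*, making meristems imaged under
different gain settings comparable; cross-day gain correction is
otherwise the user's responsibility.

**Kernel regression.** Nadaraya–Watson with a Gaussian kernel;
`bandwidth="auto"` is Silverman's rule of thumb on the distances.  The
95% band is the pointwise 2.5/97.5 percentile over `B = 10 000`
case-resampled refits.  The default resampling unit is the cell (pooled
across meristems, matching the pooled per-cell analyses); meristem-level
resampling is available by flag.  The bootstrap is computed by drawing
multinomial case weights and reusing the precomputed kernel matrix, so
all `B` refits reduce to two matrix products.  Measured pointwise
coverage of a known curve is 94–96% at the pooled four-meristem scale
(~200 records); small samples (a few dozen records) undercover slightly,
as percentile bootstraps do.

## Group statistics

Fisher's exact test enumerates the hypergeometric probabilities of all
tables with the observed margins and sums those not exceeding the
probability of the observed table (two-sided probability-mass rule;
mid-p is not used).  Odds ratio conventions for zero cells: both
off-diagonal cells empty → ∞ (complete association); a zero margin →
NaN.  The chi-square statistic is Pearson's `Σ(O−E)²/E` with optional
Yates correction (off by default), p from χ²₁.  Zero-variance t-test
inputs degrade explicitly: equal means → (t=0, p=1); unequal means → a
signed infinite t with p=0.

## Interval post-processing

All coordinates are 0-based half-open; GFF3 (1-based closed) is
converted on read and write.  Design decisions:

- *Reduction* merges overlapping **and abutting** intervals (a 1 bp gap
  does not merge).  Reduction is idempotent and conserves covered bases;
  the verification checks this against a per-base boolean-array oracle.
- *Conflict removal*: the gap between an acetylation-increase and a
  -decrease interval is 0 when they overlap, otherwise the distance
  between nearest ends.  Every pair with gap **strictly less than** 73 bp
  (≈ half a nucleosome) has **both** members removed; exactly 73 bp is
  kept.  The threshold and the symmetric-removal policy are configurable.
- *Annotation* classifies each interval by its **midpoint** with priority
  upstream > 5′UTR > exon > intron > 3′UTR > downstream > intergenic,
  windows 2500 bp upstream / 1000 bp downstream, strand-aware (upstream
  of a − strand gene extends rightward).  Ties between genes resolve to
  the nearest TSS.  Genes without annotated sub-features count their body
  as exonic.  Signed TSS distances are negative upstream.
- *Venn overlaps* count elements (≥ 1 bp overlap), per set, keyed by
  membership pattern, so each set's cells sum to its size; element counts
  of a shared cell may differ between the participating sets (three
  intervals of A can overlap one of B).
- *Enrichment* builds the 2×2 table (in-class / not × target / not)
  restricted to the background universe and applies Fisher's exact test;
  targets and class must be subsets of the background.
- The upstream domain caller's window sizes (100 bp for transcription
  factors, 500 bp for histone marks) are properties of that caller and
  appear here only as defaults of the synthetic interval widths.

## Synthetic data: what is and is not emulated

**Meristem generator.**  L1 nuclei sit on a Fibonacci lattice covering a
75° spherical cap of a 40 µm dome at ≈ 5 µm spacing (≈ 344 cells; the
count is fully determined by cap area and spacing).  Deeper layers (L2,
inner) repeat the construction at smaller radii.  Defaults are
order-of-magnitude choices for an inflorescence meristem and stay
configurable; nothing downstream depends on their exact values.
Reporter fields:

- CLV3: `A·exp(−g²/2σ²)` in geodesic distance `g` from the apex
  (A = 1000 a.u., σ = 8 µm — a central zone of roughly ¼ of the dome
  radius).
- DR5: base level 500 a.u. with a deep central minimum (floor 10% of
  base) around the axis and Gaussian wedge maxima at the primordium
  azimuths (0°, 137.5°, 275°; colatitude 65°).  The logistic transition
  (width 2 µm) is placed so that **the noise-free field crosses 120% of
  its central value exactly at `dr5_central_min_radius`** (default
  15 µm): the planted parameter is defined as the quantity the
  120%-threshold readout estimates.

Intensity noise is `I·LogNormal(0, 0.2) + Normal(0, 5)`, clipped at zero
— multiplicative gain variation plus additive background, applied
per cell and channel.  The surface grid assigns each 1 µm pixel the
intensity of its nearest L1 nucleus (a Voronoi mosaic, emulating a
projected segmentation); pixels beyond one cell diameter from any
nucleus are background.

Not emulated: voxel-level nucleus shapes and PSF blur, cell division and
growth, anisotropic resolution, bleaching, or segmentation errors.
Passing tests therefore validate the estimators against geometric and
statistical ground truth, not robustness to segmentation artefacts.

Known limitation: the cell-mosaic discretisation biases the recovered
central-minimum radius low by about half a cell spacing projected onto
the transition foot (−0.5 µm noise-free at defaults).  At default noise
the per-meristem readout is strongly bimodal: because a cell's
multiplicative noise is perfectly correlated across its whole patch,
roughly 40% of meristems have one central-disc cell drawn high enough
that an inner bin crosses the 120% threshold early, collapsing the
readout toward zero.  The noise-free readout recovers the planted radius
within one pixel, and so does the median across ~50 noisy meristems in
most seed batches, but in a minority of batches the collapse fraction
exceeds one half and the median itself collapses.  Real surface
projections are smoother (ER-localised reporters, optical blur), so this
is a worst case introduced by the mosaic rasterisation, not a property
expected of real data.

**Interval-world generator.**  A 2 Mb single chromosome with 300
non-overlapping genes (lognormal lengths, mean 2 kb, 1–4 exons), 300
binding sites whose midpoints are Normal(TSS, 500 bp) offsets in the
gene's orientation, linked acetylation-decrease intervals spawned with
probability 0.6 at Normal(0, 300 bp) offsets from their parent site,
plus independent background intervals in both directions.  Posterior
scores are Beta(9, 1) so the 0.9 filter removes a meaningful fraction.
Open-chromatin promoter windows (70% of genes) provide the enrichment
background.  Not emulated: multiple chromosomes, read-level coverage,
replicate structure, or the domain caller itself.

## Determinism and problem sizes

Every stochastic operation takes an explicit seed; the pipeline manifest
records config hash, seeds and SHA-256 of every output, and re-running a
config reproduces identical hashes.  The verification studies use
problem sizes chosen to make Monte-Carlo error small relative to the
tolerances: 100 meristems for centre accuracy, 2000 simulations for test
calibration, 200 replicates × B = 2000 for bootstrap coverage, 1000
random instances for interval oracles, exhaustive enumeration up to
margin totals of 30 for Fisher.
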