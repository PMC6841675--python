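# samquant

Quantification toolkit for confocal imaging studies of the *Arabidopsis*
shoot apical meristem (SAM), plus the genomic-interval post-processing
used alongside them in transcription-factor / chromatin profiling.

The SAM is a dome of stem cells whose behaviour is read out through
fluorescent reporters — a stem-cell marker (CLV3) peaking at the dome
summit and an auxin-output reporter (DR5) with a characteristic *minimum*
at the centre.  Turning such images into numbers requires a reproducible
definition of "the centre" and of "signal as a function of distance from
it".  `samquant` implements that machinery as a tested library + CLI, and
ships seeded synthetic-data generators with planted ground truth so every
estimator can be validated end to end.

## What it computes

**Geometry** (`samquant.geometry`).  A sphere is fitted to the centroids
of L1 (epidermal) nuclei by least squared distances: solving the
linearised system `|p|² = 2c·p + (r² − |c|²)` gives centre `c` and radius
`r` (*rad_sphere*) in closed form, optionally polished by one Gauss–Newton
pass on the geometric residuals `‖p−c‖ − r`.  Three primordium seed
points are projected onto the sphere; the meristem centre **P_center** is
the spherical-Voronoi vertex equidistant (in great-circle distance) to
all three — the intersection of the sphere with the normal of the seed
plane, taking the solution on the summit side.  The central axis runs
from the sphere centre through P_center.

**Radial quantification** (`samquant.radial`).
- Radial profiles: intensity histograms along 100 central cross-sections
  of a top-view surface projection, rotated by 3.6° steps, folded and
  averaged into one profile per meristem.
- Central-window comparison: mean signal within ±12.5 µm of the centre,
  per meristem, compared between groups by Student's *t*-test (Welch by
  flag); time courses by one-way ANOVA + Tukey HSD.
- Central-minimum size: the distance at which the profile first reaches
  120% of the centre background signal, linearly interpolated between
  bins (censored at the profile end if never reached).
- Stem-cell gating: cells with axis distance ≤ ¼·rad_sphere (boundary
  inclusive); per-meristem min–max normalisation of distances and
  intensities.
- Kernel regression: Nadaraya–Watson with a Gaussian kernel
  (`ŷ(d) = Σᵢ K((d−dᵢ)/h) yᵢ / Σᵢ K((d−dᵢ)/h)`), Silverman's rule for
  `h="auto"`, and 95% confidence bands from 10 000 case-resampled
  bootstrap refits.

**Group statistics** (`samquant.groupstats`).  Fisher's exact test (exact
hypergeometric enumeration, two-sided by the probability-mass rule),
Pearson's chi-square (optional Yates correction), pooled and Welch
*t*-tests — written from their formulas and cross-checked against scipy
and brute-force enumeration in the test suite.

**Interval post-processing** (`samquant.intervals`).  BED-style 0-based
half-open intervals throughout: posterior filter (keep score > 0.9),
reduction (merge overlapping *or abutting* regions), removal of
opposite-direction histone-mark changes closer than 73 bp (both members
of a violating pair are dropped; a gap of exactly 73 bp is kept),
promoter-window annotation (2500 bp upstream / 1000 bp downstream of the
TSS, strand-aware, priority upstream > 5′UTR > exon > intron > 3′UTR >
downstream > intergenic), three-set Venn overlaps, strand-aware TSS
metaprofiles with bootstrap bands, and Fisher-exact enrichment of a gene
class against a background universe (e.g. open-chromatin genes).

**Synthetic data** (`samquant.synthetic`).  Seeded generators for (a) a
hemispherical dome of cells with planted reporter fields and
multiplicative-lognormal + additive-Gaussian intensity noise, and (b) a
toy genome with genes, promoter-concentrated binding sites and correlated
acetylation-change intervals.  Ground truth is recorded next to every
dataset.

## Worked example

```bash
samq simulate sam --seed 1 --out demo/           # synthetic meristem
# primordium seed coordinates (one x y z row each) come from the ground
# truth here; on real data they are picked on the image
python -c "import json; gt=json.load(open('demo/sam_ground_truth.json')); \
  open('demo/seeds.tsv','w').write('\n'.join('\t'.join(map(str,s)) for s in gt['primordium_seeds']))"
samq fit-center --cells demo/cells.tsv --seeds demo/seeds.tsv
```

```json
{
  "center": [-5.5e-16, -1.9e-17, -9.5e-16],
  "rad_sphere": 40.0,
  "rms_residual": 3.4e-15,
  "n_points_used": 344,
  "p_center": [-5.5e-16, -1.9e-17, 40.0],
  "axis_direction": [0.0, 0.0, 1.0]
}
```

The 344 L1 nuclei of this synthetic meristem lie exactly on a 40 µm
sphere, so the fit recovers centre and radius to machine precision and
places P_center at the dome summit `(0, 0, 40)` — the planted centre.

```bash
samq radial min-size --grid demo/grid.tsv --center 0 0 --background-halfwidth 2.5
```

```json
{"censored": false, "threshold_distance_um": 9.654370242136732}
```

This is the auxin-minimum size of *one* noisy meristem: the distance at
which the DR5 profile first exceeds 120% of the central background.  At
the default noise level this per-meristem readout fluctuates strongly
(the generator plants a 15 µm minimum; this seed reads 9.7 µm, the next
reads 13.0 µm); the batch median across ~50 meristems recovers the
planted radius to within one pixel, which is exactly what the
reproduction script below measures.

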