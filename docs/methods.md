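# Methods

## Model and assumptions

The package operationalizes the climate-envelope hypothesis: a species'
tolerance of an abiotic stressor is bounded by the climatic conditions
its wild occurrences actually experience. Tolerance is therefore read
from the *realized* niche — presence records only, no absences, no
mechanistic physiology. Two consequences shape everything downstream:

* the indicator is deliberately robust (the **median** of extracted
  values per species), since occurrence data carry gross location and
  identification errors;
* the output is a *screening* list, not a verdict: distributions also
  reflect dispersal history, competition and land use, so candidates are
  hypotheses for physiological validation, and the statistics here only
  establish that the interspecific signal is real, not causal.

Two variables summarize exposure: PDQ (precipitation of the driest
quarter, mm; bio17) and MTCM (minimum temperature of the coldest month,
°C; bio6). Both rasters and coordinates are assumed to share WGS84; no
reprojection is performed.

## Pipeline stages and fixed conventions

Order: read → clean → thin → extract/link → minimum-specimen filter →
Moran QC → pooled tests → profiles → clustering → thresholds →
classification → sensitivity → separation test. The ≥ 10-specimen filter
is applied *after* climate linking so that records lost to nodata cells
cannot leave a species under-sampled unnoticed; every stage logs
input = output + dropped.

Conventions the literature leaves open are fixed and documented here:

* **Grid cells are half-open**: cell index (⌊lon/c⌋, ⌊lat/c⌋), a point on
  a shared edge belongs to the higher-index cell, for both the 0.1°
  thinning grid and raster extraction. Extraction is containing-cell
  value, never interpolation (matching the default point-sampling
  behavior of desktop GIS extraction tools).
* **Thinning** retains one uniformly drawn record per species per
  occupied cell. Within a cell candidates are ordered by coordinates
  before the draw, and each species consumes an independent child stream
  of the run seed, so the retained set is reproducible and invariant to
  input row order. Thinning an already-thinned set is the identity.
* **Ranks and ties**: mid-ranks everywhere; Kruskal–Wallis H carries the
  standard tie correction and a χ²(k−1) upper-tail p; Mann–Whitney p is
  exact by enumeration when both n ≤ 50 with no pooled ties, otherwise
  the tie-adjusted normal approximation with continuity correction. All
  p-values are two-sided. The fully degenerate Mann–Whitney comparison
  (every pooled value identical) is defined as U = n_x n_y / 2, p = 1
  rather than a division-by-zero.
* **Quantiles** use linear interpolation at h = (n−1)q. A
  sub-cell-resolution threshold such as 0.925 °C can only arise from an
  interpolating rule, which is why it is the default; other rules would
  shift thresholds by up to one order statistic.
* **Moran's I** uses binary distance-band weights (w_ij = 1 iff
  0 < d_ij ≤ lag; great-circle km, Earth radius 6371.0088 km), no row
  standardization, variance under the normality assumption — the
  simplest reading of "lag distance" diagnostics and the default of the
  common analysis packages. Inverse-distance-within-band weights are
  available as an option. The statistic is computed on the extracted PDQ
  and MTCM values at each species' points (a flagged interpretation:
  coordinates alone are not a variable). Species whose points yield no
  pair within a lag are reported as such in the QC table, not errors.
* **Clustering** is agglomerative on (median PDQ, median MTCM) with
  squared Euclidean distances and between-groups average linkage (Ward
  optional). Because mm and °C are incommensurable the two axes are
  z-scored by default; raw-scale clustering is available but can group
  differently, which is why the flag is prominent. Cluster labels are
  renumbered by first appearance along the alphabetically sorted species
  list, making assignments order-invariant.
* **Screening** uses strict `<` at every threshold (boundary species are
  nontolerant), thresholds computed from species *medians*, not pooled
  specimens, and candidates ranked by ascending median (ties broken by
  label). Clustering output is reported alongside thresholds as
  descriptive context but never alters them. The sensitivity ladder
  (5–35th percentiles) inherits nesting from quantile monotonicity, so
  the consistency score is simply how far down the ladder a species
  remains tolerant; ≥ 5 of 7 flags a core candidate. No multiplicity
  correction is applied across the seven scenarios — they are nested
  re-descriptions of one ordering, not independent tests.

## Synthetic data: what it emulates, what it does not

`synthetic_data` builds the virtual study every test runs against:

* **Surfaces**: deterministic gradient (base + gradient·lat +
  lon_gradient·lon) plus white noise convolved with a Gaussian kernel
  (3-cell correlation length, rescaled to the stated amplitude) — the
  simplest controllable random field. Defaults span lat 18–34°,
  lon 98–122° at 0.25°: MTCM falls latitudinally (≈ 10 → −6 °C,
  noise sd 1.5 °C), PDQ rises longitudinally (≈ 40 → 170 mm, noise
  sd 15 mm), ranges chosen to match a subtropical monsoon domain. The
  gradients are deliberately orthogonal: if both variables rode
  latitude, landscape climate space would collapse onto a line and a
  niche center off that line (dry-but-mild) would be unrealizable, so
  planted structure could not be recovered by any method. Real
  bioclimatic surfaces are between these extremes (correlated but not
  collinear).
* **Species**: bivariate Gaussian suitability over cell climate values,
  exp(−(v_P−μ_P)²/2σ_P² − (v_T−μ_T)²/2σ_T²). Default breadths
  σ_P = 12 mm, σ_T = 1.2 °C — wide enough that realized niches of
  neighboring species overlap, narrow enough that medians are estimable
  from ~10–30 records. Planted species draw the matching niche center
  uniformly below the landscape's 25th percentile (strict `<`, mirroring
  the strict classification rule); all other centers come from the
  landscape interquartile range. The drought- and cold-planted subsets
  are disjoint so the per-variable planted counts are exact by
  construction. Occurrences are drawn per cell proportional to
  suitability, then placed uniformly inside the cell; per-species
  sampling intensity is log-normal (median ≈ 25, clipped to 10–120)
  unless fixed.
* **Not emulated**: coordinate error, taxonomic mislabeling, spatial
  sampling bias (records cluster only through suitability — the
  reference procedure reports no spatial bias, so none is injected),
  elevation, dispersal limits, biotic interactions. Passing tests
  therefore show the *procedure* is correct and well-calibrated, not
  that real occurrence data meet its assumptions. Notably, extracted
  values along a gradient *are* spatially autocorrelated here, so the
  Moran QC table on synthetic runs is expected to flag species — the QC
  is a report, not a gate.

## Numerical choices and degenerate inputs

Seeds: one run seed drives all stochastic stages through independent
spawned child streams (thinning never perturbs generation draws).
Empty inputs, constant samples, single-species pools, k outside [1, n],
zero-variance Moran inputs and bandless lag choices all raise typed
errors with stage context rather than propagating NaN. ASCII-grid
round-trips are exact (values serialized at full float precision);
nodata is NaN in memory and a sentinel on disk. Shapiro–Wilk is applied
to each variable pooled across species and is limited to n ≤ 5000 (the
approximation's validity range; larger pools are reproducibly
subsampled). Agglomeration tie-breaks follow the deterministic order of
the linkage implementation over the sorted species list, so repeated
runs agree bit-for-bit.

## Problem sizes

Tests and the acceptance script run the virtual study at 35 species
(9 planted per variable) with 30 records per species for the recovery
experiment and uneven sampling for the end-to-end run; null calibrations
use 2,000 replicates; exhaustive oracles (permutation enumeration for
rank statistics, best-partition search for clustering) are run at pooled
N ≤ 8 and 10 species respectively, sizes where enumeration is exact and
fast. These sizes were chosen so each check has enough replication to
be decisive while the whole suite stays interactive.

## Known limitations

GeoTIFF input is not supported; rasters are consumed as ESRI ASCII
grids (single-band, plain text). No automatic choice of k; no
upper-tail (heat/wet) screening, though the comparison direction is the
only thing that would change; thresholds are purely quantile-based —
any externally imposed threshold (e.g. from published freezing-damage
experiments) must be supplied as an explicit override and is then a
config input, not a derived quantity.
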