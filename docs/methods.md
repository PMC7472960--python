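# Methods

## Template grid and conventions

All masks and maps live on one immutable `TemplateGrid` (default 45×54×45
voxels at 4 mm — an MNI-like bounding box at reduced resolution, chosen so
desk-scale simulations cover the whole head in ~110k voxels). The affine is
RAS+ and centres the grid at the world origin; with an odd voxel count
along x the mid-sagittal plane lies exactly on world x = 0, which the
laterality analysis and the mirrored atlas rely on. Negative world x is the
left hemisphere.

Voxel volume defaults to |det| of the affine's linear part (64 mm³ at 4 mm
spacing) and can be overridden, because published volume figures are
sometimes calibrated to a constant (0.08 mm³ per voxel in the series this
package models) that matches no standard template spacing; the override
changes volume *reporting* only, never geometry. Masks are binarised at
0.5 after any resampling — robust to interpolation blur of a binary
segmentation — and an image is accepted onto the grid only when its shape
matches exactly and its affine agrees within 10⁻³ mm per element (float
round-trip slack through NIfTI headers). Missing covariates stay explicit
(`None`) and are excluded per analysis, never imputed; e.g. records without
a recorded extent of resection remain in every non-EOR analysis.

## Fisher engine

The per-voxel 2×2 table (a, b = patients of phenotype A / B with tumour at
the voxel; c, d = the tumour-free remainders) follows the hypergeometric
law under the null. Point probabilities are evaluated in log space via
log-gamma, so tables at cohort scale (n in the thousands) lose no
precision. The two-sided p is the method of small p-values: the sum over
all tables with the observed margins whose point probability is ≤ the
observed one within relative tolerance 10⁻⁷ (absorbing float ties without
changing which genuinely different tables qualify). Tables are
canonicalised over the group-swap / row-swap symmetry group before
evaluation, which makes the p value *exactly* invariant under swapping the
two phenotypes and shrinks the memoisation cache.

Voxels with fewer than `min_count` (default 1) lesion-bearing patients
overall are untested and reported as p = 1 — their table is degenerate and
p = 1 analytically. Because the group sizes are constant across voxels, the
map computation deduplicates voxels by their (a, b) pair; a whole-brain map
typically costs a few hundred distinct Fisher evaluations. No
multiple-testing correction is applied by default (the method is used as a
descriptive mapping tool and corrections change the display threshold, not
the table values); Benjamini–Hochberg q maps are available opt-in.

Significant-voxel clusters are connected components (26-connectivity by
default; 6 and 18 available) of {tested ∧ p < α}. A cluster is labelled by
the atlas category its voxels overlap most, falling back to the label at
its centroid voxel. The design was open here: labelling by a point lookup
at the centroid fails in practice because real clusters are much larger
than the atlas seed regions, so almost every cluster would read
"background"; majority overlap is deterministic (ties break toward the
lower category id) and matches how a reader interprets a cluster lying on a
region.

## Synthetic cohorts

The generator's defaults are the study conditions of a published
single-centre surgical series of 1,107 meningiomas: the 15-category
location distribution at its published counts, grade shares 89.7/9.1/1.2%,
female share 70.9%, age ~N(56, 13²) clipped to the published 13–85 range,
log-normal volumes with median 22.828 cm³ (log-sd 0.8, an artifact choice —
the source publishes only the median and its CI), grade-dependent
recurrence 2.8/7.9/53.8%, EOR missing at 57/1107 with 90% GTR among the
observed. Marker positivity rates (p53 0.35, Ki67>5% 0.25, EMA 0.85, PR
0.65, CD34 0.55) are plausible clinical values chosen once; the source
publishes no marker marginals.

Each patient consumes independent random streams derived from
(seed, stream, patient-index), so cohorts are bit-reproducible and
insensitive to generation order. A lesion is rendered as the k grid voxels
nearest a jittered centre (k = drawn volume / voxel volume; jitter
isotropic Gaussian of one voxel), clipped at the grid boundary —
eccentricity and texture are deliberately not modelled since downstream
analyses consume occupancy only. The region atlas places one 6 mm seed
sphere per category at fixed template-like coordinates (mirrored pairs for
bilateral categories, spheres straddling x = 0 for midline ones); bilateral
categories toss a fair coin for the hemisphere.

An `EffectSpec` plants regional enrichment: patients carrying the chosen
phenotype have their odds for one category multiplied (and, optionally,
their hemisphere odds tilted toward one side by the same factor). Without
an effect, location is drawn independently of every phenotype, giving an
exact null for calibration.

What passing tests on these cohorts do *not* show: behaviour under real
registration error, non-spherical or multifocal lesions, spatially
correlated covariates, or informative censoring — the synthetic follow-up
is uniform-on-(0, horizon] for events and horizon-censored otherwise, with
a 60-month default horizon (the source does not publish its follow-up
distribution).

## Statistics around the core

- Volumes: exact voxel-count × voxel-volume products; group comparisons via
  tie-corrected Kruskal–Wallis (chi-square tail, k−1 df). Dunn's post hoc
  uses mean-rank differences over the tie-corrected pooled standard error
  with Bonferroni adjustment over all pairs — conservative and
  reproducible; the adjustment scheme is configurable.
- Categorical association (e.g. sex by grade) uses Pearson chi-square
  without continuity correction, which reproduces the published p = 0.005
  on the published counts.
- Laterality assigns each lesion by the world-x of its occupancy-weighted
  centroid with a ±2 mm midline buffer (registration slop); midline lesions
  are excluded from the exact two-sided binomial balance test and reported
  separately. Centroid assignment (rather than majority voxel) is robust
  for blobs straddling the midline.
- Survival: Kaplan–Meier product-limit estimation and the one-degree
  log-rank test (delegated to lifelines; events precede censorings at tied
  times). Published survival p values depend on unpublished per-patient
  follow-up and are out of scope; the machinery is verified against
  hand-computed examples and a grade-split power check on synthetic
  outcomes.

## Demographic fixture

`reference.demographic_fixture_cohort()` materialises the published
demographic table exactly: grade, sex-within-grade, per-grade recurrence
and EOR counts all match the printed values. The published table does not
split its 68 grade-II+III females across II and III; the fixture uses 60/8
(proportional), which preserves every margin the summaries consume.
Percentages are rounded half away from zero to one decimal. Two printed
percentages are internally inconsistent with their own counts
(179/1107 = 16.17% prints as 16.1; 86/1107 = 7.77% prints as 7.7); the
package reports the arithmetic truth of the counts.

## Problem sizes and numerical choices

Calibration tests use 20 replicates of 500-patient null cohorts on the full
default grid (~560k tested voxels pooled) and bound the empirical p < 0.05
rate by 0.06; Fisher's exact test is conservative, so the observed rate
sits near 1.5–2%. Planted-effect recovery uses odds 8 at n = 1,000. The
laterality fair-coin calibration uses 1,000 replicates of 40-patient
cohorts so the Monte Carlo error (~0.6 pp) is small against its 6% bound.
The exhaustive Fisher check covers every 2×2 table with n ≤ 40 against an
exact integer-arithmetic enumerator at 10⁻⁹ relative error.

Known limitations: no permutation-based cluster inference, no
covariate-adjusted voxel models, no smoothing of frequency surfaces, no
Cox regression, and no handling of multifocal lesions — each either out of
scope for the mapping design or intentionally left to downstream tools.
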