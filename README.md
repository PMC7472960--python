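# lesionmap

Voxel-wise lesion mapping for cohorts of template-space binary masks:
stereospecific frequency heatmaps, per-voxel two-tailed Fisher's exact
p-value heatmaps comparing two phenotypes, normalised tumour-volume
statistics, hemispheric laterality, and recurrence-free survival — plus a
synthetic meningioma cohort generator so the whole pipeline is testable
without imaging data.

## The problem

When every patient's lesion has been segmented and registered to a common
brain template (e.g. MNI152), the cohort becomes a stack of co-registered
binary masks and voxel-wise questions become answerable. Superimposing the
masks gives a lesion frequency atlas: at voxel *v*, the percentage of
patients whose lesion occupies *v*. To ask whether a *phenotype* (older vs
younger at the median age, male vs female, WHO grade I vs II+III, GTR vs
STR resection, marker positive vs negative…) prefers particular locations,
each voxel yields a 2×2 contingency table

|                 | phenotype A | phenotype B |
|-----------------|-------------|-------------|
| tumour at *v*   | a           | b           |
| tumour-free     | c           | d           |

with *n = a+b+c+d* patients, tested with the two-tailed Fisher's exact
test. The point probability of a table under fixed margins is

    p = (a+b)! (c+d)! (a+c)! (b+d)! / (a! b! c! d! n!)

and the two-sided p value sums the probabilities of all tables with the
same margins that are no more probable than the observed one. The result is
a p-value heatmap whose sub-α clusters are the locations preferring one
phenotype. Identical tables repeat across voxels, so p values are memoised
per distinct (a, b) pair: millions of voxel tests collapse to a few hundred
distinct computations.

Around that core the package provides normalised volumes (voxel count ×
single-voxel volume, with an optional calibration override), Kruskal–Wallis
+ Dunn post hoc volume comparisons across location groups, Pearson
chi-square association for categorical demographics, centroid-based
left/right/midline laterality with an exact binomial balance test, and
Kaplan–Meier / log-rank recurrence-free survival under the standard
dichotomisation rules (age ≥ 56, grade I vs II+III, Ki67 > 5%, volume ≥
22.828 cm³, GTR vs STR).

The synthetic generator emulates a large published surgical meningioma
series: 15 dural location categories at their published frequencies,
log-normal volumes around the published 22.828 cm³ median, 3:7
male:female, ~90/9/1% grade shares, grade-dependent recurrence
(2.8/7.9/53.8%), and an optional planted regional enrichment of one
phenotype for power/recovery studies. Without a planted effect, phenotype
labels are independent of location by construction — the basis for type-I
calibration tests.

## Worked example

```python
from lesionmap import make_grid, build_region_atlas, compute_pvalue_map
from lesionmap.synthetic import SimulationConfig, EffectSpec, generate_cohort
from lesionmap.voxelwise import split_by_levels, extract_significant_clusters
from lesionmap.frequency import build_frequency_map

grid = make_grid((45, 54, 45), (4, 4, 4))        # 4 mm MNI-like grid
atlas = build_region_atlas(grid)

# synthetic cohort with high-grade lesions enriched 8x in the left convexity
effect = EffectSpec(covariate="who_grade", levels=frozenset({"II", "III"}),
                    region="convexity", odds_multiplier=8.0, side="left")
cohort, masks = generate_cohort(
    SimulationConfig(n_patients=600, seed=1, effect=effect), atlas)

fmap = build_frequency_map(list(masks.values()), cohort.n)
print(f"peak lesion frequency: {fmap.percentage.max():.1f}% of {cohort.n} patients")

split = split_by_levels("who_grade", {"II", "III"}, {"I"}, name="grade_II_III_vs_I")
pmap = compute_pvalue_map(cohort, masks, split)
print(f"groups: {pmap.n_a} grade II/III vs {pmap.n_b} grade I; "
      f"{pmap.tested.sum()} voxels tested, {pmap.n_distinct_tables} distinct tables")
top = extract_significant_clusters(pmap, atlas).iloc[0]
print(f"largest significant cluster: {top.voxel_count} voxels at "
      f"({top.centroid_x:.0f}, {top.centroid_y:.0f}, {top.centroid_z:.0f}) mm "
      f"-> {top.atlas_category}, peak -log10 p = {top.peak_neg_log10_p:.1f}")
```

prints

```
peak lesion frequency: 17.0% of 600 patients
groups: 60 grade II/III vs 540 grade I; 29825 voxels tested, 829 distinct tables
largest significant cluster: 2655 voxels at (-40, 9, 58) mm -> convexity, peak -log10 p = 19.5
```

The peak frequency says the busiest voxel carries 17% of all lesions; the
29,825 tested voxels needed only 829 distinct Fisher evaluations; and the
comparison recovers the planted left-convexity enrichment as its dominant
cluster (negative x = left hemisphere), at p values far below any display
threshold.

The same analyses run from the shell over a config file:

```bash
lesionmap simulate -o data/ --seed 1 --n 200      # cohort.csv + masks/*.nii.gz
lesionmap run -o results/ --seed 1                # maps/, tables/, log.txt
lesionmap report -o results/
```

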