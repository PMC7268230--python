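# swmlabel

Automatic labeling of **short association (superficial white matter) fiber
bundles** from diffusion-MRI tractography.

Short U-shaped fibers connecting adjacent gyri are numerous, variable across
individuals, and — unlike the major deep tracts — have no accepted naming
scheme. `swmlabel` names them automatically from the cortical regions they
connect, per subject, and then establishes a common labeling across a cohort
so that the same bundle carries the same name in every subject.

## Who this is for

Researchers with whole-brain tractograms (TRK/TCK), cortical surface meshes
(PLY/OFF) and a per-vertex parcellation (Desikan–Killiany-style: integer
region index + short name such as `22=PoC`, `24=PrC`), all in one spatial
frame, who want reproducible bundle labels such as `lh_PoC-PrC_1`.

## The method

**Intra-subject labeling**, four stages per hemisphere:

1. **Fiber clustering.** Every fiber is resampled to K = 21 equidistant
   points. Mini-batch k-means on the 3D point clouds at a subset of the
   positions ({0, 5, 10, 15, 20}) gives each fiber a label tuple; fibers
   sharing a tuple (directly or reversed — storage direction is arbitrary)
   form preliminary clusters; small clusters are reassigned to the nearest
   large one, and close clusters sharing the central-point label are merged.
2. **Filtering.** Keep a cluster iff it has ≥ 10 fibers and its centroid
   length is within [30, 80] mm — the short-association band.
3. **Mesh intersection.** Each fiber extremity is tested against the
   cortical mesh along a segment from one resampled point inside the fiber
   to two point-spacings beyond the endpoint, using Möller–Trumbore
   ray–triangle solves over candidates from a uniform 1.5 mm grid:

       O + t·D = (1 − u − v)·V₀ + u·V₁ + v·V₂

4. **Naming.** A triangle's region is the majority of its three vertex
   labels; fibers are flip-aligned to the cluster centroid; the most common
   start and end regions name the bundle (ordered by atlas index, so both
   PoC→PrC and PrC→PoC bundles become `PoC-PrC`); bundles sharing a region
   pair get a positional index by sorting their centroids' cortical
   intersection points along the y axis (bottom-up).

**Inter-subject labeling** regroups bundles by region pair and unifies
indices cohort-wide, by either

* **matching** — iterative reference subjects, rectangular minimum-cost
  (Hungarian) assignment on the pairwise MDF matrix, gated by a distance
  threshold; or
* **clustering** — a single QuickBundles-style online pass over the pooled
  bundle centroids, merging same-subject near-duplicates.

All fiber comparison uses the **minimum average direct-flip (MDF)
distance**:

    MDF(a, b) = min( (1/K) Σᵢ ‖aᵢ − bᵢ‖ , (1/K) Σᵢ ‖aᵢ − b_{K+1−i}‖ )

A built-in synthetic-cohort generator (parcellated icosphere "cortex" with
planted, jittered U-bundles and a ground-truth table) makes the whole
pipeline testable without any imaging data.

## Worked example

```python
from swmlabel import CohortSpec, make_cohort, PipelineConfig, run_cohort, summary_table
from swmlabel.metrics import reproducibility_counts

cohort = make_cohort(CohortSpec(n_subjects=3, n_families=6, n_noise_fibers=50,
                                random_seed=11))
config = PipelineConfig(method="qb", threshold_mm=10.0, seed=11)
subject_sets, result = run_cohort(cohort.tractograms, cohort.mesh, config)

print(result.table.head(6).to_string(index=False))
print(reproducibility_counts(result.table))
print(summary_table(result.table, cohort_size=3))
```

prints

```
subject hemisphere region_pair    old_label    new_label  new_index  n_fibers  mdf_to_reference
 sub000         lh     BSTS-PH lh_BSTS-PH_0 lh_BSTS-PH_0          0        44               NaN
 sub000         lh      CAC-IC  lh_CAC-IC_0  lh_CAC-IC_0          0        36               NaN
 sub000         lh      CAC-IP  lh_CAC-IP_0  lh_CAC-IP_0          0        33               NaN
 sub000         lh       Cu-Fu   lh_Cu-Fu_0   lh_Cu-Fu_0          0        36               NaN
 sub000         lh       Cu-MT   lh_Cu-MT_0   lh_Cu-MT_0          0        48               NaN
 sub000         lh       En-IP   lh_En-IP_0   lh_En-IP_0          0        58               NaN

new_label
lh_BSTS-PH_0    3
...
{'max_subjects_top': 3, 'n_ge_50pct': 6, 'n_ge_75pct': 6, 'n_labels': 6}
```

Each row is one labeled bundle of one subject: the intra-subject name, the
group-wise name after relabeling, and its fiber count. The reproducibility
count (3 of 3 subjects for every planted family here) says in how many
subjects each group-wise bundle was found; the summary counts labels reaching
50% / 75% of the cohort.

The same pipeline is available from the shell:

```bash
swmlabel simulate --seed 11 --subjects 3 --families 6 --out cohort/
swmlabel run-all --cohort cohort/ --method qb --threshold 10 --seed 11 --out out/
```

## Layout

| module | role |
|---|---|
| `swmlabel.geometry` | resampling, lengths, flips, MDF |
| `swmlabel.io` | TRK/TCK/text tractograms, PLY/OFF meshes, label tables, bundle outputs |
| `swmlabel.intra` | stage 1 whole-brain fiber clustering |
| `swmlabel.filtering` | stage 2 size/length filter |
| `swmlabel.intersection` | stage 3 grid + Möller–Trumbore intersection |
| `swmlabel.labeling` | stage 4 connectivity naming and positional indices |
| `swmlabel.matching` | group-wise labeling by gated Hungarian matching |
| `swmlabel.qb` | group-wise labeling by online centroid clustering |
| `swmlabel.metrics` | reproducibility histograms, heatmaps, summaries |
| `swmlabel.synthetic` | synthetic meshes, bundles, cohorts, ground truth |
| `swmlabel.pipeline` / `swmlabel.cli` | orchestration and the `swmlabel` command |

See `docs/methods.md` for the model details, parameter choices and known
limitations.
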