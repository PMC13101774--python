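# modemorph

Mode-based morphometry (MBM) of cortical surface maps: geometric eigenmode
decomposition of cortical thickness, permutation inference on modal
coefficients, and multiscale hemispheric asymmetry indices — with a synthetic
cohort generator so the entire pipeline is testable without imaging data.

## Who this is for

Neuroimaging researchers analyzing surface-based cortical measures (thickness,
area, curvature) who want a *spectral* view of group differences. Conventional
surface-based morphometry (SBM) tests each vertex independently; MBM instead
decomposes a map into the resonant modes of the cortical geometry and tests
each mode, separating coarse, global effects from fine, focal ones. The
motivating application is asymmetric neurodegeneration (e.g. progranulin-
related frontotemporal dementia, where atrophy is strongly left-lateralized),
but nothing in the package is disease-specific.

## The model

The geometric eigenmodes are solutions of the Helmholtz equation on the
cortical surface S:

    Δψ_k = −λ_k ψ_k,      0 = λ_1 < λ_2 ≤ λ_3 ≤ …

Δ is the Laplace–Beltrami operator, discretized here with cotangent stiffness
and lumped (barycentric) vertex-area mass on a triangle mesh. The modes form a
mass-orthonormal basis ordered from coarse to fine spatial scale; on a sphere
they reduce to spherical harmonics, with eigengroups of size 2g+1 mirroring
the degree-g degeneracy (the constant mode is group 0, and groups 0–4 comprise
exactly 25 modes).

A masked per-vertex map f (e.g. cortical thickness in mm) is represented by
modal loading coefficients β from the least-squares fit

    f ≈ Σ_{k=1}^{N} β_k ψ_k .

**Group inference.** For two cohorts, a pooled-variance two-sample t-map is
computed vertex-wise, projected onto the basis, and each |β_k| is referred to
its permutation null (subject relabelings):
p_k = (1 + #{|β_k^null| ≥ |β_k^obs|}) / (n_perm + 1). Modes with p ≤ α form
the significant pattern, ranked by |β|.

**Asymmetry.** Two per-subject indices on a shared left/right template
(homotopic correspondence = vertex-index identity):

* SBM-AI = (CT_RH − CT_LH) / (0.5 (CT_RH + CT_LH)) within a symmetric
  bilateral region of interest (0 = symmetric), with the similarity transform
  1 − |AI| for group comparisons;
* MBM-AI = |Pearson correlation of the hemispheres' β vectors| over the first
  25 modes (1 = identical multiscale profiles; lower = more asymmetric).

Group comparisons use Kruskal–Wallis with Dunn/Benjamini–Hochberg post-hocs
and Cohen's d; brain–behavior links use Spearman correlations and a mode-wise
OLS of clinical scores on significant-mode weights.

## Worked example

```python
import numpy as np
import modemorph as mm

# 1. synthetic three-group cohort (19 HC / 15 presymptomatic / 27 symptomatic)
cohort, truth = mm.generate_cohort(mm.SimulationConfig(seed=7))

# 2. permutation test on the modal coefficients of the HC-vs-symptomatic t-map
result = mm.mbm_group_test(
    cohort.group_maps("HC", "lh"),
    cohort.group_maps("symptomatic", "lh"),
    cohort.basis,
    n_perm=1000, alpha=0.05, seed=1, n_modes=25,
)
print("significant LH modes (by |beta|):", list(result.ranking))

# 3. per-subject asymmetry indices over the full cortex
roi = mm.SurfaceMap.full(cohort.lh_mesh, np.ones(cohort.lh_mesh.n_vertices))
table = mm.asymmetry_table(cohort.maps, cohort.basis, roi, n_modes=25)
table = table.merge(cohort.clinical, on="subject")
print(table.groupby("group")[["mbm_ai", "sbm_ai_similarity"]].mean().round(4))
```

prints

```
significant LH modes (by |beta|): [1, 2, 13, 9, 10, 16, 7]
                mbm_ai  sbm_ai_similarity
group
HC              0.9996             0.9964
presymptomatic  0.9996             0.9943
symptomatic     0.9963             0.8658
```

The generator plants symptomatic-only left-hemisphere atrophy on modes
{1, 2, 13, 9, 10} (plus a weaker right echo on 9 and 13): the test recovers
exactly those five as the top-ranked significant modes — mode 1 is global
thinning, mode 2 an anterior–posterior gradient, the rest intermediate-scale
patterns — with two extra modes at the uncorrected 0.05 level. Both asymmetry
indices separate the symptomatic group (lower = more asymmetric) while HC and
presymptomatic subjects, who carry no planted effect, stay near 1.

A command-line interface mirrors the library (`modemorph simulate`,
`eigenmodes`, `decompose`, `group-test`, `asymmetry`, `stats`, `pipeline`);
`modemorph pipeline --cohort <dir> --out <dir>` runs everything end to end and
writes CSV/JSON outputs plus a hashed manifest.

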