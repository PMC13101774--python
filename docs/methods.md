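# Methods

## Discrete Laplace–Beltrami operator

The eigenmodes solve Δψ = −λψ on the surface. We use the cotangent
finite-element stiffness matrix A with a lumped barycentric mass matrix M
(one third of the incident triangle area per vertex), giving the generalized
symmetric problem A ψ = λ M ψ. Because M is diagonal, the problem is reduced
to a standard symmetric one, B = M^{-1/2} A M^{-1/2}, and solved with
shift-invert Lanczos near zero using a deterministic start vector, so the
spectrum is reproducible bit-for-bit. λ₁ is clamped to exactly 0 when
|λ₁| < 1e-8 · λ₂ (the kernel of the Laplacian is the constant function; the
residual value is pure solver noise). The lumped mass (rather than the full
linear-FEM mass) was chosen because it keeps the reduction exact and the
discretization error is absorbed by the validation against the sphere's
closed-form spectrum: on a subdivision-4 icosphere the eigengroup means match
l(l+1) to well under 2 % with the 2g+1 degeneracies intact.

Eigenvector signs are arbitrary. Every basis follows a canonical rule (the
vertex of largest |ψ| is positive, ties to the lowest index); when two bases
must be comparable (e.g. across hemispheres) `align_mode_signs` flips modes to
make the mass-weighted inner product with a reference basis non-negative.
Degenerate eigenspaces are never compared mode-by-mode: tests compare
eigen-subspace projectors per eigengroup.

**Eigengroups.** The constant mode forms group 0; group g ≥ 1 holds the next
2g+1 modes, mirroring spherical-harmonic multiplicities. Groups 0–4 therefore
span 1+3+5+7+9 = 25 modes, which is the default truncation for the asymmetry
index.

## Modal projection

β coefficients are the unweighted least-squares fit of the masked map onto
the first N mode columns. Two deliberate choices:

* *Unweighted* (not mass-weighted) residuals over masked-in vertices; the
  mass-weighted alternative would change β slightly on irregular meshes but
  the convention here matches common practice for modal decomposition of
  masked cortical maps.
* *Truncation refits jointly*: the 25-mode fit solves a fresh least-squares
  problem on 25 columns rather than slicing a longer fit. Under a mask the
  columns are not orthogonal, so the two differ; the joint fit is the one
  that actually minimizes the 25-mode reconstruction error.

Rank deficiency (mask too small or degenerate) raises an error reporting the
condition number rather than returning a silently unstable fit.

## Permutation mode test

The group statistic is the pooled-variance two-sample t-map (contrast
controls − carriers, so thinner carriers give positive t), projected onto the
basis. The null is built by uniformly re-permuting subject labels n_perm
times and recomputing the t-map and its β; p_k uses the add-one estimator
(1 + exceedances)/(n_perm + 1), with ties counting as exceedances
(conservative), so p ≥ 1/(n_perm+1) and the test is exact-level under
exchangeability. Per-mode p-values are *not* additionally corrected across
modes by default; an optional family-wise variant referring each |β_k| to the
permutation distribution of max_k |β_k| is available (`family_wise=True`).
Because the cortex mask is fixed across permutations, one pseudo-inverse of
the masked design serves every permutation, which keeps 10 000 permutations
on a desk-scale mesh to a few seconds.

The vertex-threshold map (two-tailed Student p < threshold with an optional
minimum-cluster-area rule, default 100 mm²) is a deterministic surrogate for
simulation-based cluster correction; it is used for building the bilateral
asymmetry mask, not for primary inference.

## Asymmetry indices

SBM-AI follows the standard normalized difference
(CT_RH − CT_LH)/(0.5(CT_RH + CT_LH)) of mean thickness within a symmetric
bilateral ROI; the ROI is the dominant-hemisphere significance map binarized
at p < 0.05 and copied to the contralateral hemisphere by vertex-index
identity (the package assumes both hemispheres share one template topology —
the right surface is the mirrored left — so homotopic correspondence needs no
registration). Because the raw index is 0 for a symmetric brain while group
comparisons are conventionally reported on a "1 = symmetric" scale, the
similarity transform 1 − |AI| is computed alongside and used for group
statistics.

MBM-AI is the absolute Pearson correlation of the two hemispheres' β vectors
over the first 25 modes of the shared, sign-aligned basis. The constant mode
is included by default (a literal first-25-modes reading; excluding it is one
flag). Identical hemispheric maps return exactly 1. Note the index is
intentionally scale-free: multiplying both hemispheres by a constant leaves
it unchanged, and a purely global offset moves only β₁.

## Cohort statistics

Group comparisons are non-parametric throughout: tie-corrected
Kruskal–Wallis, Dunn's pairwise z on pooled ranks with Benjamini–Hochberg
adjustment, plus Cohen's d (pooled-sd) as the effect size. Shapiro–Wilk and
Levene checks are exposed as advisory diagnostics only. Brain–behavior
analyses use Spearman's ρ (listwise deletion, logged) and an OLS of each
clinical outcome on the significant modes' per-subject β weights (intercept
included, two-sided t on n − p − 1 df); collinear designs are rejected with
the most variance-inflated columns named. Disease staging treats controls as
a separate reference group and bins carriers by their global CDR score.

## Synthetic study conditions

The generator defines the conditions every simulation-based check runs under;
they were fixed once, as follows, with no per-test adjustment.

* **Template**: icosphere, subdivision 3 (642 vertices), radius 50 mm — a
  desk-scale stand-in for a cortical hemisphere (area ≈ 3.1 × 10⁴ mm²); the
  right hemisphere is its mirror across x = 0, an exact isometry, so one
  basis serves both. An optional smooth radial perturbation breaks exact
  sphericity; flipped triangles are rejected.
* **Cohort**: 19 controls, 15 presymptomatic carriers (no planted effect),
  27 symptomatic carriers.
* **Baseline anatomy**: 2.5 mm mean thickness plus a fixed low-order modal
  pattern (peak amplitudes 0.08–0.15 mm on modes 2, 3, 4, 5, 7), shared by
  all subjects so that hemispheric β profiles are non-degenerate.
* **Atrophy**: symptomatic left-hemisphere thinning on modes
  {1, 2, 13, 9, 10} at peak amplitudes {0.30, 0.25, 0.22, 0.18, 0.15} mm —
  the coarse-scale pattern of asymmetric frontotemporal degeneration — with
  a right-hemisphere echo on modes {9, 13} at ratio 0.4. Amplitudes are
  *peak mm* (mode divided by its max |ψ|), making them template-independent.
  Each subject scales each mode by an independent severity multiplier
  N(1, 0.35²) truncated at 0.1; independence across modes is what makes the
  mode-wise GLM identifiable.
* **Noise**: i.i.d. Gaussian vertex noise, sd 0.25 mm, emulating residual
  measurement noise on maps that are generated smooth (real pipelines smooth
  at ~10 mm FWHM before analysis; the modal baseline plays that role here).
  Spatially correlated noise is deliberately not the default.
* **Clinical linkage**: TMT-A = 12 + 40·m₁ + 35·m₉ + 45·m₁₃ + N(0, 8²) s
  (mean ≈ 132 s, matching a symptomatic cohort's scale); TMT-B =
  414 + N(0, 155²) s with no modal linkage, mirroring a null executive
  association; TMT scores exist only for symptomatic subjects. CDR global
  stages are sampled at frequencies 9/15, 6/15 (presymptomatic 0 / 0.5) and
  6, 7, 11, 3 out of 27 (symptomatic 0.5 / 1 / 2 / 3); controls are 0.
* **Reproducibility**: each subject's stream is spawned from the master seed
  keyed by (group, within-group index), so resizing one group never changes
  another group's data.

What the generator does **not** emulate: cortical folding geometry, spatially
correlated noise, scanner/site effects, age/sex structure, longitudinal
change, or any coupling between CDR stage and atrophy severity. Passing tests
therefore demonstrate the *statistical machinery* — calibration, power,
recovery, monotone sensitivity — under idealized conditions, not performance
on real MRI data.

## Problem sizes used in validation

Monte-Carlo checks run on the 642-vertex template with a 25-mode test basis:
type-I calibration uses 200 replicate null cohorts (n = 20 + 20) at 100
permutations; planted-mode power and GLM recovery use 100 replicates each;
the asymmetry sweep uses 5 amplitude points × 50 subjects. The full-pipeline
demonstration uses 10 000 permutations and a 50-mode basis. These sizes give
binomial standard errors of ~1.5 % on the rates while keeping the whole
validation suite in the tens of seconds.

## Known limitations

* The permutation test assumes exchangeability of subjects under the null; no
  nuisance covariates (age, sex, site) are supported in the design matrix.
* Homotopic correspondence by vertex-index identity presumes data were
  resampled to a shared mirrored template; the package does not perform
  cross-hemispheric registration.
* The cluster-area rule is a deterministic filter, not a corrected cluster
  inference.
* Uncorrected per-mode p-values at α = 0.05 imply ≈ 0.05 × K false positives
  across K modes; use the family-wise option when mode identities matter.
* The VTK reader supports exactly one dialect (legacy ASCII polydata,
  triangles only) by design.
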