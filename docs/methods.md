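# Methods

## Overview

`gradientkit` implements a connectome-manifold analysis of inter-individual
phenotype variation. The pipeline, in execution order:

1. **Connectome construction.** Per subject, Pearson correlations between
   all pairs of parcel time series, Fisher r-to-z transformed (r clipped at
   |r| = 1 − 1e−7 so degenerate synthetic inputs stay finite), zero
   diagonal. The group connectome is the entrywise mean over subjects.
2. **Density thresholding.** Row-wise: each parcel keeps its
   `ceil(density · (n−1))` strongest connections (signed ranking, so
   strong negative correlations are dropped); ties at the cut are all
   retained so the rule needs no ordering assumption. Default density 0.10,
   with 0.05–0.20 available in the sensitivity sweep. Thresholding operates
   on the z-valued matrix; since atanh is monotone the retained set is
   identical to thresholding r.
3. **Affinity.** Normalized-angle kernel between thresholded connectivity
   profiles: `A_ij = 1 − arccos(cos_sim(row_i, row_j))/π`, clipped into
   [−1, 1] before arccos; parallel profiles → 1, orthogonal → 0.5,
   anti-parallel → 0.
4. **Diffusion-map embedding.** The affinity is α-normalized
   (`W = D^−α A D^−α`, α = 0.5, removing sampling-density influence), turned
   into a Markov operator, and eigendecomposed through its symmetric
   conjugate `D_W^−1/2 W D_W^−1/2` for numerical stability. The stationary
   eigenvector (eigenvalue 1) is discarded. With t = 0 the eigenvectors are
   scaled by λ/(1−λ) (multiscale rule, the documented behaviour of the
   diffusion-mapping tools this mirrors); a flag switches to plain λ^t.
   Variance explained is λ_i over the sum of all nontrivial nonnegative
   eigenvalues of the computed spectrum. Eigenvector signs are pinned by
   making each column's largest-magnitude entry positive. A repeated unit
   eigenvalue (disconnected affinity graph) is an error.
5. **Template alignment.** The template manifold comes from the group
   connectome. Each subject is embedded with identical parameters and
   rotated onto the template by orthogonal Procrustes (SVD solution,
   reflections allowed, no centering or scaling). The rotation is fitted on
   the full internally computed eigenspace (10 components by default) and
   the leading 3 aligned columns (E1–E3) are reported. Aligning in the full
   space matters: when neighbouring eigenvalues are close, subject-level
   perturbations rotate components into each other, and a rotation fitted
   on the reported columns alone cannot undo mixing with discarded ones.
6. **Manifold eccentricity.** Per parcel, the Euclidean distance between
   its aligned E1–E3 coordinates and the template center (the explicit
   column mean of the template eigenvectors).
7. **Parcel-wise association.** For each parcel, the k = 3 aligned
   coordinates are regressed on an intercept, age, sex and BMI
   (untransformed kg/m²; covariates unstandardized — the statistics are
   scale-invariant), and the BMI row is tested with Hotelling's T²
   converted to an exact F on (k, n − p − k + 1) degrees of freedom. For a
   rank-1 hypothesis all classical MANOVA statistics coincide, so the
   Hotelling–Lawley form is used. An exactly fitted parcel (zero residual)
   returns statistic 0, p 1, rather than a ratio of round-off terms.
   Benjamini–Hochberg FDR across parcels (q = 0.05) defines the
   significant-parcel mask used downstream.
8. **Nulls.** Subject-level permutation tests use the Freedman–Lane
   scheme: both variables residualized on covariates, the null built by
   permuting the response residuals, add-one two-tailed p-values
   (`(1 + #{|r_null| ≥ |r_obs|})/(n_perm + 1)`, default n_perm 5000).
   Spatial (spin) nulls rotate the spherical atlas by uniformly random 3-D
   rotations and reassign each parcel its nearest rotated neighbour's
   value (default 100 rotations), preserving the spatial autocorrelation
   family while breaking alignment.
9. **Graph context.** Within-module degree z (population SD within each
   module; zero-SD modules give z = 0), participation coefficient
   `1 − Σ_m (κ_pm/κ_p)²`, seeded Louvain community detection (resolution 1,
   100 restarts, best modularity kept), and betweenness / eigenvector /
   strength centralities. All graph measures run on the symmetrized
   (max(W, Wᵀ)) thresholded matrix with negative weights zeroed.
10. **Transcriptomic decoding.** Per donor, Pearson correlation of each
    gene's parcel profile with the statistic map; the gene statistic is
    the back-transformed mean Fisher z across donors, with a two-sided
    one-sample t-test on donor z-values. Genes passing parametric FDR are
    re-tested against the spin null (add-one p per gene, BH across the
    tested list) — the sequential order matters: with 100 rotations the
    smallest attainable spin p is 1/101, so correcting spin p-values
    across an entire multi-hundred-gene panel could never reject; the
    spin stage validates an already-selected list, which is also the
    natural reading of the workflow it reproduces. Survivors are filtered
    for donor consistency (all pairwise donor–donor profile correlations,
    Fisher z, one-sided one-sample t, BH across genes), then tested for
    enrichment against user-supplied gene sets (one-sided hypergeometric
    with odds ratio and a normal-approximation z reported alongside) and
    against nested cell-type specificity sets at four stringency
    thresholds (0.05/0.01/0.001/0.0001), with one BH correction across
    all (cell type, threshold) cells. The per-donor-correlation
    aggregation is a deliberate random-intercept-free approximation of a
    donor-level mixed model; it is the package's own definition of the
    statistic, swappable behind the same interface.

## Synthetic study conditions

The generator produces everything the pipeline consumes, with ground truth
recorded, and its defaults define the study conditions used by the tests
and the acceptance script.

**Atlas.** Parcels on a deterministic Fibonacci lattice of the unit
sphere; modules are consecutive latitude bands (balanced sizes, spatially
contiguous); four hierarchy classes cycle across modules. The study scale
is 100 parcels and 12 modules. Twelve, not the seven canonical
intrinsic networks, because visibility of inter-module structure under
row-wise thresholding requires the retained degree (k = ceil(0.10·99) = 10)
to exceed the module size: with balanced 7-module blocks every retained
link is intra-module and the connectome's between-network structure is
erased before the kernel ever sees it. At larger parcel counts the
canonical seven would be compatible with the same constraint.

**Cohort.** Subject covariates: age ~ U(22, 36) years, sex ~ Bernoulli(½)
coded 0/1, BMI log-normal with parameters solved exactly for mean
26.30 kg/m² and SD 5.16 (positive support, right skew), height
~ N(1.70, 0.08) m and weight = BMI·height² so weight-based sensitivity
models have inputs. Parcel signals are mixtures of per-module latent
Gaussian series plus white noise (SD 1.0). Background modules couple to
each other at 0.35. The two *affected* modules form an internally
coherent system (own-latent loading 1.4 vs 1.0) that is decoupled from
the background (cross-coupling 0) and mutually coupled at
0.45 − effect_size·z(BMI), clipped at zero: higher-BMI subjects show
progressive segregation of two strongly interacting networks — the effect
lives in connectivity, which is what the pipeline measures, not in signal
amplitude.

Three structural properties of this design are load-bearing:

- the affected coupling (0.45) sits above the thresholding cut, so the
  effect survives density thresholding;
- the affected system's internal coherence gives its embedding components
  an eigenvalue gap over the exchangeable (hence near-degenerate)
  background contrasts, pinning them into the reported E1–E3 regardless
  of seed;
- zero cross-coupling keeps the zero-sum affected-contrast eigenvectors
  exactly localized on affected parcels, so the planted effect is
  confined and "unaffected parcel" is a well-defined ground truth. With
  any appreciable cross-coupling the modulation leaks into every parcel's
  correlations (through shared variance and global eigen-scaling), which
  a parcel-level truth cannot represent.

**Effect calibration.** The default planted effect size (0.08) was
calibrated once, on independent draws, so that the *parcel-level
standardized effect* — the partial multivariate correlation between
z(BMI) and the aligned E1–E3 coordinates at affected parcels with
n = 150 subjects and 200 timepoints — is ≈ 0.5. Under these conditions
the pipeline flags on long-run average 92% of affected parcels at
FDR < 0.05 with a 5–7% false-flag rate among unaffected parcels.

**What the generator does not emulate.** No fMRI autocorrelation, scanner
drift, head motion, hemispheric structure, or spatially graded
within-module heterogeneity. Passing recovery tests therefore shows the
pipeline's statistical machinery is correct and calibrated on modular
correlated signals; it does not certify performance on real rs-fMRI.

**Structural maps / expression panels / cell-type tables.** Structural
proxies (thickness, folding, myelin) are a smooth latitude-dependent mean
plus subject noise, with an optional linear BMI effect in designated
parcels. Expression panels give signal genes the profile
`ρ·z(target) + sqrt(1−ρ²)·noise` per donor (expected spatial correlation
ρ with the target map; expected donor–donor correlation ρ²); noise genes
are independent per donor. Cell-type specificity draws a uniform p per
(gene, cell type), shrinks it by 10⁻⁶ for signal genes in the planted
type, and thresholds at the four stringency levels — nesting holds by
construction.

## Numerical choices and degenerate inputs

- Fisher z clip at |r| = 1 − 1e−7; cosine clipped into [−1, 1] before
  arccos (precision near ±1 is ~√ε, so closed-form kernel values are
  exact only to ~1e−7).
- Eigendecomposition via `scipy.linalg.eigh` on the symmetric conjugate;
  eigenvector equivalence with a general dense solver on the raw Markov
  operator holds to 1e−8 (tested to n = 20).
- Hotelling with a singular residual covariance falls back to a
  pseudoinverse; an exactly-zero residual short-circuits to (0, 1).
- Zero-variance parcels, all-zero connectivity rows, rank-deficient
  designs, empty universes and single-donor consistency are errors that
  name the offending unit; singleton modules, isolated nodes and
  constant-gene donors degrade gracefully with a warning.
- All randomness flows through `numpy.random.default_rng(seed)` or
  seeded SciPy/NetworkX calls; repeated seeded runs of the full pipeline
  are digest-identical.

## Known limitations

- Parcel-level specificity of the multivariate map is limited by the
  global nature of spectral coordinates: a confined connectivity effect
  still perturbs every subject's eigenvalues, and the multiscale λ/(1−λ)
  scaling carries a diffuse trace of it into unaffected parcels
  (measured ~5–7% false-flag rate at the study conditions, against ~5%
  expected from the FDR level alone). Plain λ^t scaling removes the leak
  but also most of the sensitivity.
- At the 100-parcel scale, 5% density retains fewer links per row than
  the affected-module size, cutting the affected system's inter-module
  links; template maps are near-identical across 10–20% density
  (spatial r > 0.99) but not against 5%.
- The sequential decoding chain inherits the resolution limit of 100
  rotations (minimum spin p = 1/101).
- Group comparison requires both BMI groups to have at least k + 2
  members after excluding underweight subjects; smaller cohorts skip the
  stage with a warning.
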