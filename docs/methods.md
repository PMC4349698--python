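# Methods

This note documents the statistical models, numerical choices and defaults
behind `occlusal`, and what the synthetic-data tests do and do not
establish about real specimens.

## Phylogenetic model

Trees are rooted Newick with branch lengths (arbitrary time units,
ultrametricity not required, multifurcations allowed). Under Brownian
motion with rate σ², a trait's tip covariance is σ²·C with
`C[i,j]` the root-to-MRCA shared path length and `C[i,i]` the root-to-tip
depth. C is assembled from leaf depths and patristic distances
(`C_ij = (d_i + d_j − d_ij)/2`) and validated as symmetric PSD.

**Pagel's λ** rescales the off-diagonal of C by λ ∈ [0, 1]. The ML fit
profiles the mean and rate analytically (`μ̂ = (1ᵀC⁻¹y)/(1ᵀC⁻¹1)`,
`σ̂² = rᵀC⁻¹r/n`), evaluates the profile likelihood on a 21-point grid,
refines with bounded 1-D minimization (xatol 1e-8), and breaks likelihood
ties (within 1e-9) toward the larger λ. λ is deliberately bounded at 1;
implementations that allow λ slightly above 1 (where C stays PD) can
report marginally higher likelihoods on the same data — the package's
tests cross-check both the bounded optimum and the PGLS coefficients
against R's comparative stack. The reported p-value is a χ²(1)
likelihood-ratio test against λ = 0 (phylogenetic independence), matching
the convention of reporting whether a trait's signal "differs from 0".

**PGLS** fits `y = a + bx` on species means with error covariance
proportional to the λ-transformed C (GLS solve via statsmodels). λ is
fixed at 1 by default — the shearing analysis treats SQ residuals as fully
Brownian, and λ = 1 is the common default of the comparative tools this
workflow descends from — with any fixed value or `"ml"` available. λ = 0
reduces exactly to OLS (regression-tested to 1e-10). R² is `1 − RSS/TSS`
in the whitened (Cholesky) metric with TSS about the GLS grand mean, i.e.
the same metric the fit minimizes; other GLS-R² definitions exist and give
different numbers. Singular or near-singular covariances (condition above
1e12, estimated from the Cholesky pivots) raise a numeric error that
reports the condition number.

**Brownian simulation** draws one N(0, σ²·branch) increment per edge in
preorder; a Cholesky-based vectorized variant (distributionally identical,
verified by replicate covariance) serves the phylogenetic-ANOVA null.

## Shearing quotient

Total shear is the plain sum of the six crest lengths; crest identities
are opaque labels (no geometric re-derivation), columns fixed at six, and
log base 10 throughout, matching the printed calibration equations. The
calibration regresses species-mean log10 S on species-mean log10 L over
frugivores only, so SQ reads as percent deviation from a typical
frugivore. Expected values for individual specimens use the specimen's own
length by default (`level="individual"`); species-level SQ from mean
log-quantities is also provided, since the source protocol is ambiguous
between the two — outputs record which was used. SQ is not invariant to a
units change unless b = 1; lengths are millimetres by convention.

## Topographic indices

TSA is the triangle-area sum (degenerate faces contribute zero; duplicate
faces count — mesh repair is out of scope). PSA is the area of the exact
2-D union of projected triangles (shapely), so overlapping projections
count once; a bounded-error rasterization estimator exists as a fallback
and as an independent second route in tests. RFI = ½·ln(TSA/PSA); a
TSA < PSA result (impossible for a height-field crown) warns rather than
errors, as it signals an orientation or cropping fault.

The OR crop passes a horizontal plane through the basin point and keeps
the mesh at or above it, splitting straddling triangles exactly (trimesh
plane slicing; verified against a Sutherland–Hodgman clipping oracle).
Auto-detection of the basin point — lowest vertex whose projection lies
strictly inside the convex hull of the cusp tips (local height maxima
above the 75th height percentile; the hull is buffered by 5% of the
footprint when fewer than three tips leave it degenerate; ties break to
the lowest vertex index) — operationalizes a step done by eye in manual
workflows; explicit specification remains the primary path. OR applies to
lower molars by default; a flag permits any mesh. CEJ cropping and
occlusal-plane orientation are the user's responsibility (up axis
configurable, default z). No smoothing or decimation is applied before
area measurement.

## Group statistics

Diet categories follow the feeding-record rule: >50% leaves → folivore,
else substantial hard-object feeding → hard object, else fruit primary →
frugivore. Group summaries report means with two-sided t-intervals over
individuals (the CI method of the published group table is unstated; this
is the conventional choice), or sample-size-weighted means `Σwx/Σw` for
rolling species means up to group means — the arithmetic used to
reconstruct the published group table, where 11 of the 15 group-mean cells
reproduce exactly and the other four (folivore and frugivore lower-molar
SQ, frugivore upper-molar SQ, hard-object lower-molar RFI) are internally
inconsistent in the source tables and excluded. The two Callicebus species
are named differently in the two source tables; the bundled alias map uses
the pairing under which the most cells reconstruct.

Kruskal–Wallis is tie-corrected with a χ²(k−1) p-value (constant data
returns H = 0, p = 1 by convention). Pairwise Wilcoxon rank-sum uses exact
enumeration when both groups have ≤ 10 observations and no ties, otherwise
the normal approximation with tie and continuity corrections; the report
records which ran. The Bonferroni criterion is α divided by the number of
pairs actually tested, rounded only for display (0.05/3 = 0.0167).

The phylogenetic ANOVA computes the ordinary one-way F on species means
and simulates its null by Brownian motion on the tree with σ² estimated by
ML from the pooled species-mean vector (single-mean model), keeping group
labels fixed: `p = (1 + #{F_sim ≥ F_obs})/(1 + n_sim)`. Default
n_sim = 1000; a seed is mandatory, making the p-value exactly
reproducible. Single-species groups are permitted but flagged.

## Classification

Pooled-covariance LDA with equal priors (scikit-learn eigen solver behind
the module surface; the brute-force Gaussian-discriminant rule and manual
leave-one-out refits act as independent oracles in the tests). Equal
priors remove the bias from unequal group sampling; posterior ties break
toward the earlier group in sorted label order (folivore < frugivore <
hard_object), deterministically. Variables enter together — no stepwise
selection. No regularization by default; a ridge flag (mapped to shrinkage
toward the average eigenvalue) rescues near-singular feature sets.
Leave-one-out is the only cross-validation scheme; fitting requires every
group to keep ≥ 2 members after removal, so LOO needs ≥ 3 per group.
Canonical scores are projections onto the eigenvectors of
within⁻¹ × between scatter, with percent-of-variance from the eigenvalue
shares.

## Synthetic generator

Defaults encode the study conditions: 13 species (3 folivores, 7
frugivores, 3 hard-object feeders) on a unit-depth pure-birth tree, 8
individuals per species. Species means evolve by Brownian motion plus
additive diet offsets patterned on the published group separations (OR
≈ 1.8/1.7/1.5; lower RFI 0.54/0.53/0.51; shear offsets multiplicative,
≈ +34.5%/0/−12.25% upper and +20%/0/−13.25% lower). Within-species SDs
follow the medians of the published per-species SD columns (OR 0.09, RFI
0.02, shear ≈ 0.024–0.027 dex; one published lower-SQ SD carries a stray
minus sign and is used as its magnitude). Molar lengths are log-normal
about 5 mm with Brownian between-species spread (0.15 dex), so log shear
vs log length has a known true frugivore line (upper a=0.45, b=0.74; lower
a=0.30, b=0.91). Crest lengths split total shear in fixed proportions.
The pure-birth simulator stops at the n-th speciation; tips are extended
by one exponential waiting time so terminal branches are strictly positive
(otherwise the Brownian covariance is singular).

Tooth meshes are height fields — an elliptical dome plus Gaussian cusps on
a polar grid — with an analytic height function for numeric-integration
area oracles. Being single-valued in z, they provably satisfy TSA ≥ PSA;
real scans with undercuts, cingulum shelves, wear facets or crenulation
are *not* modelled, so passing mesh tests demonstrates correctness of the
geometry code, not robustness to scan pathology. Likewise the trait
generator draws RFI/OR values directly as noisy traits; it does not couple
them to the generated meshes.

## Problem sizes and determinism

Simulation-based tests use sizes chosen for tight oracles at modest cost:
λ-recovery on 30-leaf trees over 50 replicates, phylogenetic-ANOVA
null/power over 50 replicates at n_sim = 150–200 (p-resolution ≤ 1/151,
ample for the >0.05 / ≤0.01 assertions), group-ordering recovery over 100
simulated studies at 4 individuals per species, and Monte-Carlo Brownian
checks at 2,000–10,000 draws. Every stochastic routine takes an explicit
seed; the full pipeline is byte-identical across reruns with the same
seed, and the run log records the λ mode, calibration coefficients,
Wilcoxon method and basin-point source actually used.

## Known limitations

* Measured-specimen inputs are accepted but the package ships no real
  measurement data; the published specimen table and dated phylogeny must
  be supplied by the user to reproduce specimen-level published rates.
* λ is estimated on 13 species in the reference design; power to detect
  signal at n < 20 is known to be poor, so λ near 0 there is weak evidence
  of absence.
* The basin-point auto-detector assumes cusps surround the basin; it will
  refuse (with an error suggesting manual specification) on crowns where
  the lowest interior vertex is not enclosed by cusp tips.
* OR on upper molars is possible behind a flag but unsupported as a
  protocol: cingulum variation defeats a consistent crop.
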