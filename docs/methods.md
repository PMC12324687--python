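# Methods

This note documents the models and procedures `perfmap` implements, the
parameter defaults and why they were chosen, what the synthetic cohort
generator does and does not emulate, and the numerical choices that matter
for reproducing results.

## The synthetic cohort generator

The generator is the validation substrate for every analysis in the
package: it plants, at parcel scale on a unit sphere, each piece of
statistical structure the methods are supposed to detect, and ships the
ground truth alongside the data.

**Geometry.** Parcels are points of a Fibonacci lattice (near-equal-area,
the property spin tests rely on); distances are great-circle arcs in
radians. Spatially autocorrelated maps are white noise smoothed with the
kernel `exp(-d²/2ℓ²)` and standardized (sample sd). Perfusion fields use
lengthscale ℓ = 0.4 rad — on a unit sphere this gives a map with roughly a
dozen independent patches, enough smoothness to make naive correlation
tests visibly anticonservative while leaving ~400 parcels informative.
Annotation ("gene-like") maps use ℓ = 0.25 rad, reflecting that expression
maps are typically patchier than hemodynamic maps.

**Mean model.** Log perfusion for subject *i*, parcel *v* is

    log μ_iv = log 50 + 0.25·m_v + 0.1·[female_i] + b_v·(age_i − ā) + t_{i,τ(v)}

with `m` a standardized smooth field (the *shared map*), a +0.1 log-unit
female offset (≈ +10%, the direction and rough size of reported sex
differences in CBF), slopes `b_v = −0.005/yr` doubled on a "transmodal"
spherical cap (z above the median; age-related decline of a fraction of a
percent per year, stronger in association cortex), and per-subject
territory factors `t` (two x-hemifields by default, sd 0.15 — individual
differences in territory-level perfusion of ±15%). Observations are drawn
from the generalized gamma `GG(μ, σ=0.1, ν=1.5)` — positive and
right-skewed by construction. Ages are uniform over the union of
5–22 and 36–100 years, mimicking a two-release lifespan cohort with a gap;
55% of subjects are female.

The mean model is multiplicative (log link) so no configuration can
produce negative perfusion; the group-analysis GLMs are additive, so
slope-recovery analyses fit the linear model on *log* perfusion, where the
planted slopes live. The shared-map scale 0.25 keeps `exp(0.25·m)` nearly
linear in `m` (corr ≈ 0.98 analytically), so the PCA score map of
row-standardized data can recover the planted field; much larger scales
would degrade the recovery not because PCA fails but because the planted
log-field and the data-scale pattern decouple.

**Biomarkers.** A standardized subject latent combines (negative) age and
the mean territory factor; 8 of 28 biomarkers load on it with coupling 0.8
plus Gaussian noise (sd 0.6), the rest are independent standard normals.
This is the planted target for PLS.

**Annotations.** Planted category members are
`α·target + √(1−α²)·independent field` (α = 0.8, 40 members by default)
among independent decoy maps; decoy categories draw 31–60 members from the
decoy pool. Optional per-donor replicates (map + donor noise) support
differential-stability filtering.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: voxel/vertex-level structure and resampling
between mesh densities, ASL acquisition noise (label efficiency, transit
times), site and scanner effects, non-uniform parcel sizes, correlated
biomarker panels, longitudinal structure, and any realistic vascular
anatomy beyond block covariance. Recovery results certify the estimators
under their assumed generative structure, not robustness to these
violations.

## Score maps and effect maps

Subject maps are z-scored within subject (sample sd, divisor n−1 —
everywhere in the package). The score map is the first right singular
vector of the stacked matrix; by default columns are *not* centered before
the SVD, so PC1 can absorb the shared mean pattern and closely tracks the
group mean map — the behaviour group perfusion studies report; column
centering is available by flag (`center_columns=True`) for the textbook
variant. The sign is fixed so the score map correlates non-negatively with
the column mean map. Variance explained is sₖ²/Σs².

Effect maps are per-parcel OLS with a shared design (intercept, age, sex
[male = 1, female = 0], optional interactions and polynomial age terms),
solved by QR — normal equations square the condition number, which is
fatal for cubic-age designs. p-values are two-sided t; the Bonferroni mask
thresholds at 0.05 / n_parcels. `residualize_covariates` returns raw
residuals (orthogonal to every design column) by default; with
`keep_intercept=True` it returns covariate-adjusted maps (residual +
per-parcel intercept), the variant to use when re-deriving a score map
after covariate adjustment — raw residuals have zero column means and
therefore cannot retain the shared pattern.

## Spatial null models

All map–map inference uses spatial-autocorrelation-preserving nulls:

- **spin**: Haar-uniform rotations (QR of a Gaussian matrix with sign
  fix); each original parcel takes the value of the nearest rotated
  parcel, duplicates allowed. Parcels whose nearest rotated position is an
  excluded ("medial-wall") parcel take the next closest non-excluded one —
  implemented as nearest-non-excluded, which is what "walk to the next
  closest" converges to. An optional two-hemisphere mode applies R to the
  left hemisphere and the x-mirrored M·R·M to the right, preserving the
  mirrored-rotation convention when two hemispheres are supplied.
- **vasa**: bijective variant; original/rotated pairs are matched greedily
  by ascending distance with uniqueness enforced, ties broken by lowest
  (original, rotated) index. A Hungarian (optimal assignment) mode exists
  behind a flag. Every null row is a true permutation, so value multisets
  are preserved exactly — required by the enrichment ensemble null.
- **variogram surrogates**: permute the map, smooth with Gaussian kernels
  over a geometric grid of 10 scales spanning [min positive distance,
  π/2], rank-remap onto the original value multiset, and keep the scale
  whose 25-equal-count-bin variogram best matches the source in squared
  error. The candidate is rank-remapped *before* scoring: smoothing
  shrinks amplitude, and the delivered surrogate is the remapped map, so
  scoring the raw smoothed map would conflate amplitude with
  autocorrelation and degenerate toward minimal smoothing.

Permutation p-values are inclusive: `p = (1 + #extreme)/(1 + N)`, never 0,
minimum 1/(N+1) — with the default N = 1000, the floor is 9.99×10⁻⁴.
Default sidedness is two-sided for map–map correlations and one-sided
positive for enrichment scores. Heavy loops derive one RNG stream per
iteration from a master seed (`SeedSequence([seed, k])`), so ensembles are
reproducible and order-independent.

Tie-breaking inside spin/vasa nearest-neighbour searches rounds dot
products to 12 decimals first, so floating-point noise cannot reorder
genuinely tied candidates.

## Enrichment

Category score = mean over members of `atanh(r)` with r clipped to
|r| ≤ 1−10⁻⁷ (keeps a perfect member finite). The null replaces the
*target* with each ensemble map — the annotation maps are never permuted —
and the positive-sided inclusive p is FDR-corrected across categories.
Both the raw score and the null-standardized score (observed minus null
mean over null sd) are reported. Annotations with differential stability
(mean pairwise inter-donor correlation) below 0.1 are dropped when donor
replicates exist; categories need more than 30 members after filtering.

A sizing constraint worth knowing: with m categories and one true
positive, the smallest attainable FDR-adjusted p is m/(N+1), so the
ensemble must satisfy N > m/q − 1 for detection at level q to be possible
at all. The enrichment acceptance check uses N = 2500 with m = 51.

## Behavioral PLS

With column-z-scored X (subjects × parcels) and Y (subjects × biomarkers),
`R = X′Y = USV′`; U spans parcels, V spans biomarkers; subject scores are
XU and YV; loadings are correlations of each original column with its
score; covariance explained is sₖ²/Σs² (invariant to scaling R by
1/(n−1)). Missing biomarkers can be imputed with the within-sex-group mode
before z-scoring.

- *Significance*: X rows are permuted (Y optionally, equivalent in
  distribution), R rebuilt, and singular values compared per ordered
  component (LV k against the k-th null singular value) with the inclusive
  one-sided p.
- *Stability*: subjects resampled with replacement, blocks re-z-scored,
  resampled singular vectors sign-aligned to the original by inner
  product (adequate in the single-dominant-LV regime; a limitation for
  multi-LV patterns, where Procrustes alignment would be needed);
  bootstrap ratio = original weight / bootstrap sd. Zero bootstrap sd
  yields a signed-infinity sentinel with a warning.
- *Generalizability*: repeated 80/20 splits; train-only column statistics;
  test scores `X_test U_train`, `Y_test V_train`; the statistic is the
  mean out-of-sample correlation of the two LV1 scores. The permutation
  null shuffles X rows before splitting; because re-running the full split
  loop per permutation is quadratic in splits, each permutation evaluates
  its mean over `n_splits_null` (default 20) splits — the null mean is
  what matters, and 20 splits estimate it to within a few hundredths.

Dominance analysis enumerates all 2^p predictor subsets (p ≤ 20), averages
each predictor's incremental R² within subset sizes and then across sizes;
contributions sum to the full-model R² to machine precision and equal the
Shapley value of the R² game.

## Generalized-gamma trajectories

The Stacy/location-scale-shape parameterisation is used: with
θ = 1/(σ²ν²) and z = (y/μ)^ν,

    log f = log|ν| + θ log θ + θν(log y − log μ) − θz − log Γ(θ) − log y,

so ν = 1 is a gamma law with shape θ and mean μ and the quantile function
inverts the gamma CDF of θz (reflected for ν < 0). μ(x) and σ(x) are
log-linked fractional polynomials of age; ν is constant, and the fit
restricts ν > 0 (the density and quantiles support ν < 0; positive shapes
cover the right-skewed perfusion regime, and the sign is not identifiable
from moderate samples anyway). Ages are rescaled to decades (and shifted
positive if needed) before the power basis — recorded in the fit.

The candidate space is all FP1 (8) and FP2-with-repetition (36) power
multisets, 44 per stage; power 0 maps to log x and a repeated power p to
(x^p, x^p·log x). The search is two-stage — μ powers with intercept-only
σ, then σ powers (including intercept-only) given the best μ — bounding
the work at 89 candidate fits; a `joint=True` flag searches the full cross
product for small data. Selection is by GAIC = −2ℓ + k·n_params with
k = 2 (AIC) by default, k exposed. Each candidate is fitted by L-BFGS-B on
(β_μ, β_σ, log ν) with OLS-on-log-y initialisation and 3 random restarts;
internal link-scale clips (η_μ ∈ ±30, η_σ ∈ [−8, 4], ν ∈ [0.05, 8]) keep
the objective finite far from the optimum. Model-selection caveat: with
AIC, spuriously selected small terms shrink as 1/√n, so "flat data give a
flat fitted curve" is a large-n property (≈1% fitted-μ variation at
n = 3000), not a guarantee at small n.

## Territories

Double z-scoring (within subject, then per region across subjects) removes
the global mean pattern and subject offsets; the region × region Pearson
matrix across subjects is the covariance graph. The embedding recipe is:
optional top-(1−sparsity) row sparsification, clip negatives to zero,
symmetrize by averaging, α-normalize with α = 0.5, row-normalize to a
transition operator, eigendecompose (via the symmetric conjugate), drop
the constant eigenvector, scale eigenvectors by eigenvalues (λ^t for
diffusion time t > 0), and fix each gradient's sign so its largest-|value|
location is positive.

Sparsification default and a deliberate exception: `diffusion_gradients`
defaults to sparsity 0.9, appropriate for dense, predominantly positive
affinity matrices. Signed covariance graphs are different: with two crisp
territories the between-territory correlations are *negative* (row
centering makes the two territory factors anti-correlated), so after
clipping, the blocks are connected only through near-zero noise-positive
pairs — which top-k sparsification removes entirely, provably
disconnecting the graph (the function raises rather than embedding
components independently). The territory pipeline therefore embeds the
full clipped graph (`sparsity=0.0`); thresholding gradient 1 at zero then
classifies parcels into territories essentially perfectly on the default
cohort.

## Problem sizes and determinism

Validation problem sizes were chosen so the full suite certifies behaviour
at the study's own scale while remaining a desk-scale run: cohorts of
200–300 subjects × 400 parcels, 1000-null ensembles (2500 for the
enrichment FDR check, see above), 1000 permutations/bootstraps, 200-repeat
calibration loops, trajectory fits at n = 800–3000. Everything is seeded;
identical configurations reproduce bit-identical cohorts, ensembles and
pipeline manifests (content-hashed in `manifest.json`).

## Known limitations

- Spin/vasa tie-breaking and the greedy matching order are this package's
  documented rules; other implementations may differ parcel-by-parcel.
  Calibration, not bit-parity, is the tested contract.
- Bootstrap sign alignment is per-component inner product, not Procrustes.
- The GG fit does not search negative ν and has no lognormal (ν → 0)
  limit.
- Volumetric (subcortical) geometry, mesh resampling, and voxelwise nulls
  are out of scope; everything operates at parcel scale on a sphere.
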