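# Methods

`morphherit` estimates how much of the variation in a 2-D landmark shape
is additive-genetic, maternal, paternal and residual, for a pedigreed
sample such as a captive-breeding colony. This note describes the models
and algorithms, the choices made where several defensible options exist,
and what the synthetic-data generator does and does not emulate.

## Shape variables

**Superimposition.** Configurations of k landmarks are centered, scaled to
unit centroid size (CS, the square root of the summed squared landmark
distances from the centroid) and iteratively rotated to the running
consensus; the consensus is the normalized mean shape and the loop stops
when its root-mean-square change falls below 1e-10 (at most 100
iterations; failure raises, reporting the last change). This is *partial*
Procrustes fitting: scale is fixed at unit CS rather than re-optimized
per iteration. The final shapes are put in a canonical orientation (major
principal axis of the consensus on the y axis, half-turn resolved by the
farthest landmark) so that the output is invariant to arbitrary
per-specimen rotations, translations and scalings of the input.

**Semilandmark sliding.** Semilandmarks declared by the scheme slide
along the chord between their two curve neighbors (measured on the
specimen) to minimize thin-plate-spline bending energy relative to the
current consensus. Sliding alternates with re-superimposition for up to 5
cycles or until the consensus change falls below 1e-8. The bending-energy
matrix is the inverted TPS system of the consensus; the per-specimen
slide is the exact minimizer of the resulting quadratic form (a small
ridge, 1e-12 of the mean energy scale, guards rank deficiency).

**Tangent projection.** The aligned coordinates are orthogonally
projected onto the tangent plane at the consensus (`project=True`, the
default). Unit-CS shapes live on a sphere; without projection the
curvature of that sphere contributes a spurious extra principal component
whose relative eigenvalue is of the order of the shape variance (~1e-3
here), i.e. far above numerical noise. With projection the symmetric
shape space of the 40-landmark scheme has *exactly* 38 positive
eigenvalues (2 per bilateral pair + 1 per midline landmark, minus axial
translation and scale), which is the structural result the pipeline
reproduces. The cost is that projected shapes have CS = 1 only to
O(shape variance); `project=False` gives exactly unit-CS shapes.

**Object symmetry.** Each configuration is averaged with its reflected,
pair-relabeled copy: originals and reflections are superimposed together,
the joint consensus midline is rotated onto the y axis (least squares,
i.e. the rotation minimizing the distance of the consensus from the
exactly symmetric subspace; grid search plus bounded refinement), each
specimen is averaged with its reflection, and the average is projected
exactly onto the symmetric subspace — so mirrored landmark pairs coincide
to machine precision about the y axis. The symmetrized shapes are then
re-superimposed. Only the symmetric component is analyzed further;
directional and fluctuating asymmetry are discarded, not quantified.

**PCA.** Principal components of the sample covariance (n-1 denominator)
of the aligned coordinates; eigenvector signs are fixed so the
largest-magnitude loading is positive. The retained scores (default 15,
configurable; requesting more than the positive-eigenvalue rank is an
error) are the traits passed to the quantitative-genetic stage, together
with log CS of the original configurations.

**Dimorphism test.** A permutation (M)ANOVA: F is the ratio of model to
residual mean squared distances, and significance comes from permuting
the residuals of the intercept-only model (1000 permutations by default,
seeded), p = (1 + #{F* >= F}) / (1 + n_perm). It is calibrated (type-I
error at the nominal level under the null) and is reported for adults and
offspring separately when sex labels are present; its outcome does not
gate the pipeline — sexes are pooled for the heritability analysis.

## The animal model

For t traits on n individuals,

    y = X beta + a + m + p + e,

with per-trait intercept and centered log-CS covariate (allometry),
`a ~ N(0, G ⊗ A)` where A is the numerator relationship matrix from the
pedigree (tabular method; founders unrelated and non-inbred),
`m ~ N(0, Mat ⊗ I_dams)` and `p ~ N(0, Pat ⊗ I_sires)` indexed by
maternal/paternal identity (i.i.d. across parents — these are
environmental-style parental effects, not genetic maternal effects, and
no direct-maternal covariance is modeled), and `e ~ N(0, R ⊗ I)`.
Individuals with unknown dam (the founders) contribute no maternal level.
P = G + Mat + Pat + R is the phenotypic covariance; reported summaries
are trace proportions of P.

**REML.** The restricted log-likelihood
`-(log|V| + log|X'V^-1X| + y'Py)/2` is maximized over the four t x t
blocks. Evaluations exploit the structure
`V = G ⊗ A_obs + R ⊗ I + low rank`: a one-time eigendecomposition of
A_obs rotates the observations so that the genetic-plus-residual core is
block diagonal (one t x t block per eigenvalue of A_obs), and the
maternal/paternal terms — whose kernels have rank equal to the number of
dams and sires — enter through the Woodbury identity. One evaluation
costs O(n t^3 + n L^2) with L = dams + sires, against O((nt)^3) for the
dense form (which is retained as a cross-checked reference).

**Optimization.** EM-REML updates
`S <- S + S (B_c - T_c) S / q_c` (the conditional-expectation covariance
of the augmented effects) keep every block positive semidefinite and
increase the likelihood monotonically; `method='em'` runs them pure. The
default `method='hybrid'` runs a short over-relaxed EM burn-in (doubling
line search along the EM direction) and then L-BFGS on Cholesky factors
of the blocks with the analytic gradient. The quasi-Newton stage exists
because these designs produce long, flat likelihood ridges — with
two-generation sib data, full-sib / half-sib covariances alone satisfy
c_full = c_mat + c_pat, so G is separated from Mat + Pat only through
parent-offspring covariance, and both plain EM and damped
average-information steps crawl along the resulting ridge, while L-BFGS's
accumulated curvature model traverses it. Starting values are the sample
phenotypic covariance divided equally among the active components.

**Convergence** requires |dlogL| < 1e-8 together with a max relative
parameter change of the *EM map* below 1e-6. The EM map's fixed points
are exactly the REML stationary points, so a negligible EM move is a
genuine stationarity certificate, whereas the smallness of a damped
accelerated step is not. Boundary estimates (a component heading to zero
variance, e.g. a true-zero paternal effect) are reached smoothly through
the Cholesky parameterization; estimates are PSD by construction. A fit
that exhausts `max_iter` (default 2000 likelihood evaluations) returns
`converged=False` rather than raising; the pipeline reflects this in its
exit code.

Components can be excluded (fixed at zero) via `components=`; a
sire-plus-residual model on a balanced paternal half-sib design
reproduces the classical expectation-of-mean-squares ANOVA estimator.
Standard errors of the variance components are not computed (point
estimates only).

## Heritability summaries

`GP-` is G times the Moore-Penrose pseudoinverse of P (SVD, singular
values below 1e-10 of the largest treated as zero, configurable); the
asymmetric product is used as such, with eigenvalues sorted by real part
and any imaginary magnitude >= 1e-8 treated as an error. The dominant
eigenvalue is h2_max, the maximum heritability over directions of trait
space; `MatP-` is treated identically for the maternal analogue. For
REML-fitted (PSD) components all GP- eigenvalues lie in [0, 1] up to
numerical tolerance. Eigenvalue concentrations are reported both as
fractions of the positive spectrum and of the full trace (the two
conventions differ when negative eigenvalues occur). Angles between
leading eigenvectors of P, G and Mat use the absolute dot product
(range [0, 90] degrees), computed via atan2 for accuracy near 0. The
multivariate breeders' equation `delta_z = GP- S` predicts selection
response, and any trait-space vector can be mapped back to a landmark
displacement field through the orthonormal PC loadings (visualization of
deformation grids is left to external tools).

## Synthetic data

The generator emulates the study design so every stage is testable by
parameter recovery. A bilaterally symmetric 40-landmark head template
(18 pairs, 4 midline points, 12 semilandmarks; centered, CS = 1) is
perturbed inside an orthonormal basis of its symmetric tangent space
(pair/midline-symmetrized coordinate perturbations with the axial
translation and scale directions projected out — 38 dimensions). True
covariance components are expressed in the first t basis directions, so
the pipeline's estimates are comparable to the truth after its own
GPA/PCA: trace proportions and the GP- spectrum are invariant to the
orthonormal basis change between the generator's frame and the PC frame.

Per phenotyped individual: log CS ~ N(cs_mean, cs_sd); trait deviation
`beta (logCS - cs_mean) + a_i + m_dam + p_sire + e_i` with breeding
values propagated through the pedigree by Mendelian sampling
(variance (1/2 - (F_dam + F_sire)/4) G); the deviation is mapped to
landmarks, i.i.d. Gaussian digitization noise (asymmetric, per
coordinate) is added, and a random rotation, translation and scale
exp(logCS) is applied.

Presets (defaults chosen once as study-realistic values):

- `viper_*`: 12 families from 8 dams x 6 sires, 221 offspring, parents
  phenotyped (235 configurations); trace proportions G 49.13%,
  Mat 50.69%, Pat 8.85e-4%, residual the remainder; leading eigenvalue
  concentrating ~91% of G and ~77% of Mat; total shape variance 1e-3
  squared Procrustes units (typical for head-shape data); log CS mean
  log 25 (image units), sd 0.15; digitization noise sd 0.002 template
  units (~0.2% of head size); allometric slope ~0.07 on the first trait,
  alternating and decaying on the rest.
- `recovery_*`: 40 dams x 30 sires, 120 cross-classified families
  (each dam ~3 sires, each sire ~4 dams), 800 offspring, parents
  phenotyped; proportions G:Mat:Pat:R = 0.45:0.45:0:0.10. The
  cross-classified mating and the phenotyped parents are what make all
  four components identifiable (see the REML section); recovery tests
  use 20 replicate seeds of this design with t = 3.

What the generator does **not** emulate: ontogenetic allometry beyond a
single log-CS slope, clutch/common-environment effects beyond dam
identity, multiple paternity, correlated or non-Gaussian digitization
error, missing landmarks, and real photographic distortion. Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to violations of it.

## Numerical notes and limitations

- GPA convergence 1e-10 (RMS consensus change), sliding 5 cycles / 1e-8;
  eigenvector signs fixed by the largest-magnitude element; canonical
  orientation by consensus principal axes.
- The positive-eigenvalue count uses a relative threshold of 1e-10.
- V is kept invertible by a tiny diagonal inflation of R (1e-12 of the
  trait scale) only when a factorization fails.
- Degenerate input (constant traits) short-circuits to zero components.
- Identifiability is a property of the design, not the code: with
  offspring-only phenotypes in a two-generation pedigree, G cannot be
  separated from Mat + Pat; estimates then sit on a likelihood ridge and
  only their identified combinations are meaningful. The study-like
  presets avoid this by phenotyping parents.
- Whether reported eigenvalue percentages should be fractions of the
  positive spectrum or of the trace is convention; both are reported.
- Sliding uses the consensus as the bending-energy reference and the
  specimen's own neighbor chord as the tangent; tangent projection and
  partial (unit-CS) fitting are defaults, both configurable.
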