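# Methods

## Model and assumptions

The package analyses genotype × environment means from multi-environment
trials in two weighted stages. Stage 1 fits, per trial (location–year cell),
the fixed-effects model `y_ir = μ + b_r + g_i + e_ir` by ordinary least
squares and carries forward the genotype LS-means with weights equal to the
inverse of their estimated sampling variance. Missing plots are handled by
OLS on the available cells (the LS-mean is the genotype prediction averaged
over all blocks); near-zero residual variance is capped so weights never
exceed 1e8 (configurable), with a logged warning.

Stage 2 is a Gaussian linear mixed model for the adjusted means with the
residual variance fixed at 1 and scaled by the stage-1 weights. All models
share: a fixed intercept, optionally fixed slopes on the standardized
covariates (the "main EC effect", requiring more environments than
covariates), and six independent scaled-identity deviation terms — location,
year, location×year, and their genotype interactions. Covariates are centred
and scaled to unit sample variance on the training environments; the stored
centres/scales map held-out environments onto the same scale.

The genotype covariate-response block `(a_i, c_i)` is exchangeable across
genotypes with covariance Σ chosen per model family: a main effect only
(baseline); `diag(σ²_α, I_p σ²_γ)`, marginally identical to a random
environmental-kernel effect with kernel `X Xᵀ` and therefore a ridge-type
regression on the covariates (kernel); a rank-q factor-analytic `Λ Λᵀ`
without specific variances (RRR); unstructured (RFR); or unstructured on q
synthetic covariates `Z = X Λ_γ` (FW-US). The kernel model is implemented
through its iid-slope parameterization because that form extrapolates
naturally to unseen environments; a fixed-kernel covariance structure exists
in the engine and a test asserts the exact marginal equivalence of the two
forms. Unstructured and reduced-rank structures are translation-invariant
(an affine change of covariate basis does not change the maximized
likelihood); the kernel structure is not, which is why covariates are always
standardized. Genotypes are treated as unrelated; kinship matrices are out of
scope.

Synthetic covariates are extracted by fitting a model with fixed genotype
intercepts, fixed environment main effects (so the loadings explain
interaction rather than environmental main effects), random genotype slopes
with covariance `Λ_γ Λ_γᵀ` of rank q, and random genotype × location / year /
environment deviations. The identification constraint is `λ_kh = 0` for
`h > k` (lower-trapezoidal), leaving `pq − q(q−1)/2` free loadings — 8 for
one and 15 for two synthetic covariates with p = 8 — and the sign of each
factor is fixed by its first free loading. The lower-trapezoidal form is the
canonical representative (Λ Λᵀ is invariant to right-rotations), so no
separate column-ordering rule is imposed. The second stage refits the
regression on the standardized synthetic covariates rather than holding the
extraction-stage coefficients fixed.

## REML engine

All models reduce to grouped random-coefficient terms: a grouping factor, a
per-row covariate vector, and a shared d × d covariance with one of four
parameterizations — log variance (scaled identity, fixed kernel), Cholesky
factor with log diagonal (unstructured), or raw loadings with the
identification zeros (reduced rank). The REML criterion uses an
orthonormalized fixed-effects basis and the constant −(n−f)/2·log 2π, so its
value is invariant to the fixed-design parameterization; `full_loglik` is the
ML log-likelihood at the GLS fixed-effect solution and the REML variance
parameters, and AIC is `−2·full_loglik + 2(VarP + FixedP + SP)` with
design-fixed parameters (the unit residual variance, identification-zero
loadings) excluded and optimizer-pinned components included.

Two likelihood paths give identical values (asserted to 1e-8 in tests). The
dense path assembles the n × n marginal covariance. The fast path applies
when the data form a complete genotype × environment grid with
environment-constant weights: genotype exchangeability makes the covariance
`I_I ⊗ A + 1_I 1_Iᵀ ⊗ B`, which an orthogonal genotype contrast
block-diagonalizes into one J × J block `A + I·B` (carrying the genotype
mean and all environment-level fixed effects) and I−1 identical blocks `A`
whose data enter only through the pooled within-genotype cross-product
matrix. Each evaluation then costs two J × J Cholesky factorizations,
independent of I; fixed genotype intercepts (the synthetic-covariate
extraction model) are supported by a rank-one fixed effect in the contrast
blocks. This decomposition is what makes the simulation studies below cheap.

Optimization is L-BFGS-B on the transformed parameters with
finite-difference gradients (cheap at these problem sizes), bounds keeping
log-variances in `[vy·1e−10, vy·1e7]` and loadings within ±30 response SDs,
relative-likelihood tolerance 1e-11, gradient tolerance 1e-5, at most 500
iterations, and a perturbed restart when the first pass fails. Because a
variance component drifting to zero stalls on the log scale, each scalar
variance near its floor is snapped to the boundary after convergence if that
does not worsen the criterion, and reported as a boundary estimate (still
counted in VarP). The richer structures are fitted in a cascade: the baseline
model's variance components seed the deviation terms, the genotype variance
seeds the leading loading or the Σ diagonal, and cross-validation folds are
warm-started from the full-data fit — without this the factor-analytic
models occasionally stop in a scaled-up local basin. Starting values can
also be supplied directly.

BLUEs, BLUPs and the joint coefficient covariance are computed lazily at the
converged parameters from the GLS identities `var(β̂) = (WᵀV⁻¹W)⁻`,
`var(û − u) = G − G Zᵀ P Z G`, `cov(β̂, û − u) = −(WᵀV⁻¹W)⁻ WᵀV⁻¹ Z G`,
which remain valid for singular G; for nonsingular G this is exactly the
inverse of Henderson's mixed-model-equations coefficient matrix, and for
reduced-rank structures it equals the inverse of the nonsingular
factor-score system mapped back to the coefficient scale (both asserted in
tests). The full matrix — including fixed–random and cross-genotype blocks —
is used by the prediction-variance machinery.

## Prediction into unseen environments

The EC history is decomposed by a multivariate two-way model
`x_lm = μ + L_l + Y_m + (LY)_lm` using method-of-moments mean cross-product
matrices (MANOVA-style EMS) rather than multivariate REML: EC layouts are
balanced or nearly so, only the quadratic-form targets are needed, and the
moment estimator is unbiased on balanced grids (verified by simulation).
With one observation per cell the interaction component absorbs EC
measurement error. Indefinite moment differences are projected to the
nearest PSD matrix by eigenvalue clipping. All matrices carry a leading zero
intercept row/column, so quadratic forms ignore the intercept coefficient.
For cases 3 and 4 the location effect is fixed (the target location's
history identifies it) and `Σ_L` plays no role. The sampling variance of the
plug-in vector `ξ̂′` is the grand-mean variance
`Σ_L/L + Σ_Y/M + Σ_LY/(LM)` for cases 1–2 and the location-mean variance
`(Σ_Y + Σ_LY)/M_l` for cases 3–4; the case-2 mean is the unweighted two-way
grand mean.

The total prediction variance adds three parts: the exact variance of a
product of independent random vectors and its bias-corrected estimator
(subtracting, rather than adding, the trace term), the bias-reduced
quadratic-form estimator `γ̂′ᵀΣ̂γ̂′ − trace[var(γ̂′)Σ̂]`, and the deviation
components appropriate to the case (none for case 1; year components for
case 2; location components for case 3; all six for case 4 — for pairwise
differences the purely environmental components drop and genotype
interactions count twice). Bias-corrected estimators can go negative in
finite samples; reported per-genotype and per-pair values are floored at
zero with a log message, while the closed trace form of the pair-averaged
variance is evaluated without flooring so that it equals the arithmetic mean
of the unfloored pairwise values exactly. EC and yield data are assumed
independent. For synthetic-covariate models the EC-scale target is mapped
through the estimated loadings (and the SC standardization), treating the
loadings as fixed; like the variance components themselves, their estimation
uncertainty is not propagated — a known limitation of model-based prediction
variances in this framework.

## Cross-validation

LOEO holds out one environment, keeps the single global covariate
standardization, plugs the held-out environment's observed covariates into
the fitted model and adds every BLUP available for it (genotype, location,
year, genotype×location, genotype×year); only the location–year and
three-way effects are unavailable. LYLO mimics case 4: covariates are
replaced by the location's mean over training years (numerically identical
to the case-4 plug-in on balanced layouts), no year- or location-linked
BLUPs are used, standardization is repeated per fold, and the model-based
variance is computed with the case-4 machinery from the fold's own fit. By
default only the held-out (location, year) pair leaves the training set —
the prediction mechanics require no more — with a strict variant removing
the whole year and location as a sensitivity analysis. Model-based MVP/VPD
are reported for LYLO only; under LOEO the prediction mixes BLUPs whose
error covariance is not part of the four-case framework, so those columns
are left empty. Folds whose model fails to converge are recorded and
excluded from aggregates. Metrics follow the standard definitions
(per-environment Pearson correlation, MSPE, MSEPD with the factor
2/(I−1), MVP, pair-averaged VPD), aggregated as both means and medians since
their distributions are skewed.

## Synthetic data

The generator draws the covariate process from the two-way model with
separable location/year/interaction covariances, genotype coefficient
vectors from the chosen structure (on the standardized covariate scale),
the six deviation components, and either plot-level RCBD records (block
effects N(0, 0.05²), iid plot error) or genotype×environment means with the
matching stage-1 noise `σ²_e/R` and weights `R/σ²_e` (exact for balanced
designs, and keeping weights environment-constant so the fast likelihood
path applies). Default scale — 20 genotypes, 6 locations × 10 years, 4
covariates, 3 blocks — mirrors a long-term rainfed rice trial network
scaled down to desk size, with deviation components (t/ha)²
L 0.0568, Y 0.0262, LY 0.4434, αL 0.0307, αY 0.0142, αLY 0.2695, genotype
variance 0.2422, overall level 4.5 t/ha, and plot error 0.5. The generator
reproduces the statistical structure the models assume — it does not emulate
weather processes, spatial field trends, genotype relatedness, unbalanced
variety turnover, or covariate measurement error, so passing tests show
correctness of the machinery under the stated model, not robustness to
those real-data features.

## Simulation studies in the test suite

Problem sizes were chosen to give each check adequate power at desk scale.
Reduced-rank recovery uses 40 genotypes on an 8×12 grid with 4 covariates
and rank-1 loadings (0.45, 0.30, −0.25, 0.20, 0.15), 20 networks; kernel
slope-variance recovery uses the default network scale over 200 replicates.
The C-inverse is validated against the sampling covariance of
(β̂, û − u) over 20 000 replicates at the true parameters (judged by
Monte-Carlo standard errors: 99% of entries within 3 SE, all within 5 SE,
since an elementwise 3-SE rule over thousands of entries fails by chance).
The variance-calibration study predicts a sixth location, with EC history
but no trials, from a 12-genotype 5×6 network (kernel truth, slope variance
0.05) over 40 training sets × 10 future years, comparing the mean
model-based variance with the realized mean squared error. The
cross-validation ordering study defines an "EC-driven" world as rank-1
covariate-driven interaction (loadings 0.45, 0.35, 0.30, −0.25 over 3
covariates) with the three-way component reduced to 0.12 on a 12-genotype
5×5 network; with interaction dominated by terms no covariate can explain,
no model ordering is detectable at this scale.

## Known limitations

Variance-component and loading uncertainty is not propagated into the
prediction variances; the moment-based EC decomposition is only approximate
on heavily unbalanced histories; model-based variances assume the fitted
model is correct and therefore omit misspecification bias; and the engine
targets desk-scale problems (hundreds of environments), not sparse
large-scale solvers.
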