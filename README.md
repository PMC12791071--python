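# envgxe

Mixed-model analysis of genotype–environment interaction in multi-environment
trials (METs) using environmental covariates (ECs), with model-based
prediction — and honest prediction variances — for environments that were
never tested.

Plant breeders and variety-testing agencies must recommend varieties for
farms and future seasons, i.e. for locations and years outside the trial
network. `envgxe` implements a family of weighted linear mixed models that
regress genotype performance on environmental covariates (seasonal weather
aggregates and the like), links the seemingly distinct approaches in this
space (factorial regression, environmental-kernel/ridge models,
reduced-rank/factor-analytic regression, extended Finlay–Wilkinson regression
on synthetic covariates), and quantifies the uncertainty of a prediction into
an unseen environment — including the part that comes from not knowing the
future covariate values.

## The models

Stage 1 adjusts plot-level data per trial, `y_ir = μ + b_r + g_i + e_ir`,
yielding genotype means with inverse-variance weights. Stage 2 models the
adjusted mean of genotype *i* in environment *j* (a location×year cell):

```
y_ij = (μ_α + a_i) + Σ_k (μ_γk + c_ik) x_jk + L_l + Y_m + (LY)_lm
       + (αL)_il + (αY)_im + (αLY)_ilm + e_ij
```

with standardized covariates `x_jk`, fixed mean regression `μ_α, μ_γ`, and a
residual variance fixed at 1 scaled by the stage-1 weights. The model
families differ only in `Σ = var(a_i, c_i)`:

| model    | Σ for (intercept, slopes)                  | variance parameters |
|----------|--------------------------------------------|---------------------|
| Baseline | `σ²_α` (no slopes)                         | 1                   |
| Kernel   | `diag(σ²_α, I_p σ²_γ)` ⇔ `w_i ~ N(0, XXᵀσ²_γ)` | 2               |
| RRRq     | `Λ Λᵀ`, rank-q loadings                    | `(p+1)q − q(q−1)/2` |
| RFR      | unstructured                               | `(p+1)(p+2)/2`      |
| FWq-US   | unstructured on q synthetic covariates `Z = X Λ_γ` | `(q+1)(q+2)/2` (+ SP) |

Predictions target four scenarios: the long-term mean of the target
population of environments (case 1), a new year at that mean (case 2), the
long-term mean of a new location with EC history (case 3), and a new year at
a new location (case 4). The EC history is decomposed by a two-way
location×year model; the total prediction variance for genotype *i* is

```
υ_i = est.var(γ̂′ᵢᵀ ξ̂′) + φ̃_x′(i) + υ_R
```

where the first term is a bias-corrected Goodman-type variance of the product
of two estimated vectors, `φ̃ = γ̂′ᵀ Σ̂_x′ γ̂′ − trace[var(γ̂′) Σ̂_x′]` covers the
deviation of the realized covariates from their plug-in expectation, and
`υ_R` sums the deviation variance components that are unknowable for the
target. Pairwise differences and their pair-averaged variance (via the
pairing matrix `P = 2(I−1)⁻¹[I_I − K_I]`) are also provided, as are
leave-one-environment-out (LOEO) and leave-year-and-location-out (LYLO)
cross-validation with PCC / MSPE / MSEPD / MVP / VPD metrics.

REML estimation is performed by an internal engine supporting
scaled-identity, unstructured, reduced-rank and fixed-kernel covariance
structures, with the full mixed-model-equations coefficient-matrix inverse
("C-inverse", valid for singular reduced-rank structures) needed by the
variance estimators. On complete genotype×environment grids the likelihood
is evaluated by an exact block decomposition that makes the cost independent
of the number of genotypes.

## Worked example

```
$ envgxe simulate --config toy.yaml --seed 1 --out sim
wrote sim/plots.csv (864 plots), ec.csv, truth.json
$ envgxe prep --plots sim/plots.csv --out-means means.csv
wrote means.csv (288 means)
$ envgxe fit --model kernel --means means.csv --ec sim/ec.csv --out fit
model Kernel: reml_loglik=-358.214 (path=grid); wrote fit/fit.json
$ envgxe predict --model kernel --case 4 --location L01 \
    --means means.csv --ec-history sim/ec.csv --out pred
case 4: MVP=0.8935 VPD=0.8371; wrote pred/predictions.csv
$ head -4 pred/predictions.csv
genotype,eta_hat,var_product,phi,upsilon_R,upsilon_total
G001,3.074668562622044,0.06186818769237693,0.0,0.7762598923931047,0.8381280800854816
G002,4.5824505380556255,0.10093124410165188,0.20202860344652346,0.7762598923931047,1.07921973994128
G003,3.8592248432411935,0.0656080910047204,0.0,0.7762598923931047,0.8418679833978251
```

Here `toy.yaml` describes a 12-genotype, 4-location × 6-year network with 3
covariates and an environmental-kernel generating model. The `predict` call
asks for genotype means at location L01 in a future year (case 4): `eta_hat`
is the predicted yield (t/ha), `var_product` the contribution from estimating
both the genotype coefficients and the location's covariate means, `phi` the
contribution from year-to-year covariate variability at L01 (floored at zero
when the bias correction overshoots), and `upsilon_R` the deviation
components (location, year and interaction effects unknowable for a new
location-year). MVP averages `upsilon_total` over genotypes; VPD is the
pair-averaged variance of a predicted difference, in which purely
environmental components cancel.

```
$ envgxe cv --scheme lylo --model kernel --means means.csv --ec sim/ec.csv --out cv
           pcc    mspe   msepd     mvp     vpd
mean    0.5425  1.0836  1.2699  0.8982  0.8373
median  0.5642  0.9271  1.2239  0.9069  0.8322
```

LYLO cross-validation mimics case 4: each environment is predicted using only
the location's covariate history from other years; the model-based MVP
(0.898) sits close to the realized mean squared prediction error, which is
what the bias-corrected variance estimators are for.

The same operations are available as a library
(`envgxe.build_model`, `envgxe.predict`, `envgxe.run_cv`, ...), which the CLI
wraps thinly.

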