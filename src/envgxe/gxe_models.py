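"""Builders for the second-stage genotype x environment models.

Seven model families share the same backbone — fixed overall intercept (plus
optional fixed covariate slopes, the "main EC effect"), random location, year
and location x year main effects, and random genotype x location, genotype x
year and genotype x location x year deviations — and differ only in how the
genotype-specific response to environmental covariates is modeled:

* ``baseline``: random genotype main effect only, no covariate response;
* ``kernel``: genotype main effect plus iid random slopes on every EC with a
  common variance — marginally identical to a random environment-kernel
  effect w_i ~ N(0, X X' sigma2_gamma);
* ``rrr``: joint genotype (intercept, slopes) vector with a rank-q
  factor-analytic covariance Lambda Lambda' (no specific variances);
* ``rfr``: the same joint vector with an unstructured covariance;
* ``fw_us``: unstructured regression on q synthetic covariates Z = X Lambda_g
  estimated in a separate extraction stage (extended Finlay-Wilkinson).

Residual variance is fixed at 1 and scaled by the stage-1 inverse-variance
weights in all models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm_engine import (
    FitResult,
    GridInfo,
    ModelSpec,
    RandomTerm,
    ReducedRank,
    ScaledIdentity,
    Unstructured,
    reml_fit,
)
from .met_data import ECMatrix, MetMeans, env_key, standardize_ec

MODEL_NAMES = ("baseline", "kernel", "rrr", "rfr", "fw_us")

#: variance terms common to every model (deviations from the regression)
DEVIATION_TERMS = ("L", "Y", "LY", "alphaL", "alphaY", "alphaLY")


@dataclass(frozen=True)
class GxeModelKind:
    """Which genotype-covariate structure to use, and its rank where needed."""

    name: str
    q: int | None = None
    main_ec_effect: bool = True

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model name {self.name!r}")
        if self.name in ("rrr", "fw_us"):
            if self.q is None or self.q < 1:
                raise ValueError(f"model {self.name} requires rank q >= 1")

    @classmethod
    def parse(cls, text: str, main_ec_effect: bool = True) -> "GxeModelKind":
        """Parse CLI-style names: baseline, kernel, rrr1, rrr2, rfr, fw1us, fw2us."""
        t = text.strip().lower().replace("-", "")
        if t in ("baseline", "kernel", "rfr"):
            return cls(t, main_ec_effect=main_ec_effect)
        if t.startswith("rrr") and t[3:].isdigit():
            return cls("rrr", q=int(t[3:]), main_ec_effect=main_ec_effect)
        if t.startswith("fw") and t.endswith("us") and t[2:-2].isdigit():
            return cls("fw_us", q=int(t[2:-2]), main_ec_effect=main_ec_effect)
        raise ValueError(f"cannot parse model name {text!r}")

    def label(self) -> str:
        if self.name == "rrr":
            return f"RRR{self.q}"
        if self.name == "fw_us":
            return f"FW{self.q}-US"
        return {"baseline": "Baseline", "kernel": "Kernel", "rfr": "RFR"}[self.name]


@dataclass
class SyntheticCovariates:
    """Synthetic covariates Z = X Lambda_gamma from the extraction stage.

    ``loadings`` is the p x q matrix Lambda_gamma with lower-trapezoidal
    identification zeros; Z always satisfies Z = X @ loadings exactly on the
    extraction environments.
    """

    Z: np.ndarray
    loadings: np.ndarray
    environments: list[tuple[str, str]]
    column_names: list[str]
    extraction_fit: FitResult | None = None

    @property
    def q(self) -> int:
        return self.loadings.shape[1]

    @property
    def n_free_loadings(self) -> int:
        p, q = self.loadings.shape
        return p * q - q * (q - 1) // 2


@dataclass
class GxeModel:
    """An assembled second-stage model bound to its data and covariates."""

    kind: GxeModelKind
    spec: ModelSpec
    genotypes: list[str]
    environments: list[tuple[str, str]]
    locations: list[str]
    years: list[str]
    X: np.ndarray                 # J x p standardized EC values (model scale)
    ec: ECMatrix
    sc: SyntheticCovariates | None = None
    sc_centers: np.ndarray | None = None
    sc_scales: np.ndarray | None = None

    met: MetMeans | None = None

    @property
    def geno_term(self) -> str:
        """Label of the random term holding the genotype regression block."""
        return {
            "baseline": "genotype",
            "kernel": "genotype",
            "rrr": "geno_regression",
            "rfr": "geno_regression",
            "fw_us": "geno_regression",
        }[self.kind.name]

    def fit(self, start=None, cascade=True, **kwargs) -> FitResult:
        """REML-fit the model.

        For the richer genotype structures (kernel, rrr, rfr, fw_us) the
        default is a cascade: the baseline model is fitted first and its
        deviation variances and genotype variance seed the starting values,
        which stabilizes convergence of the factor-analytic and unstructured
        blocks.
        """
        if start is None and cascade and self.kind.name != "baseline":
            start = self._cascade_start(**kwargs)
        return reml_fit(self.spec, start=start, **kwargs)

    def _cascade_start(self, **kwargs) -> np.ndarray:
        base_kind = GxeModelKind(
            "baseline",
            main_ec_effect=self.kind.main_ec_effect and self.kind.name != "fw_us",
        )
        base = build_model(base_kind, self.met, self.ec)
        bfit = reml_fit(base.spec, **kwargs)
        dev = {lab: bfit.variance_estimates[lab]["variance"]
               for lab in DEVIATION_TERMS}
        s2a = bfit.variance_estimates["genotype"]["variance"]
        vy = float(np.var(self.spec.y)) or 1.0
        eps = 0.02 * np.sqrt(max(s2a, 0.01 * vy))
        per = []
        for t in self.spec.terms:
            st = t.structure
            if t.label in dev:
                per.append(st.theta_from_variance(max(dev[t.label], 1e-6 * vy)))
            elif t.label == "genotype":
                per.append(st.theta_from_variance(max(s2a, 1e-4 * vy)))
            elif t.label == "geno_slopes":
                per.append(st.theta_from_variance(max(0.05 * s2a / st.dim, 1e-6 * vy)))
            else:  # geno_regression block
                d = st.dim
                if st.kind == "reduced_rank":
                    lam = np.zeros((d, st.q))
                    lam[0, 0] = np.sqrt(max(s2a, 1e-4 * vy))
                    lam[1:, 0] = eps
                    for h in range(1, st.q):
                        lam[h:, h] = eps * 0.5 ** h
                    per.append(st.theta_from_loadings(lam))
                else:
                    sig = np.eye(d) * max(0.05 * s2a, 1e-4 * vy)
                    sig[0, 0] = max(s2a, 1e-4 * vy)
                    per.append(st.theta_from_cov(sig))
        return self.spec.pack_theta(per, resvar=None)


def _align(met: MetMeans, ec: ECMatrix):
    """Common codes for genotypes, environments, locations and years."""
    df = met.data
    genotypes = sorted(df["genotype"].unique())
    environments = sorted(set(zip(df["location"], df["year"])))
    missing = [e for e in environments if e not in ec.environments]
    if missing:
        raise ValueError(f"environments missing from EC matrix: {missing[:5]}")
    locations = sorted({l for l, _ in environments})
    years = sorted({m for _, m in environments})
    env_idx = {e: j for j, e in enumerate(environments)}
    gi = pd.Categorical(df["genotype"], categories=genotypes).codes.astype(int)
    ei = np.array([env_idx[(l, m)] for l, m in zip(df["location"], df["year"])])
    env_loc = np.array([locations.index(l) for l, _ in environments])
    env_year = np.array([years.index(m) for _, m in environments])
    return genotypes, environments, locations, years, gi, ei, env_loc, env_year


def _deviation_terms(gi, ei, env_loc, env_year, genotypes, environments,
                     locations, years) -> list[RandomTerm]:
    """The six scaled-identity deviation terms shared by every model."""
    n = len(gi)
    ones = np.ones((n, 1))
    I = len(genotypes)
    loc_of_row = env_loc[ei]
    year_of_row = env_year[ei]
    env_labels = [env_key(l, m) for l, m in environments]

    def geno_cross(codes, n_levels, labels):
        groups = gi * n_levels + codes
        glabels = [f"{g}:{lab}" for g in genotypes for lab in labels]
        return groups, glabels

    gl_groups, gl_labels = geno_cross(loc_of_row, len(locations), locations)
    gy_groups, gy_labels = geno_cross(year_of_row, len(years), years)
    ge_groups, ge_labels = geno_cross(ei, len(environments), env_labels)
    return [
        RandomTerm("L", ScaledIdentity(1), loc_of_row, ones,
                   group_labels=locations, grid_kind="env",
                   env_factor_codes=env_loc),
        RandomTerm("Y", ScaledIdentity(1), year_of_row, ones,
                   group_labels=years, grid_kind="env",
                   env_factor_codes=env_year),
        RandomTerm("LY", ScaledIdentity(1), ei, ones,
                   group_labels=env_labels, grid_kind="env",
                   env_factor_codes=np.arange(len(environments))),
        RandomTerm("alphaL", ScaledIdentity(1), gl_groups, ones,
                   group_labels=gl_labels, grid_kind="geno_env",
                   env_factor_codes=env_loc),
        RandomTerm("alphaY", ScaledIdentity(1), gy_groups, ones,
                   group_labels=gy_labels, grid_kind="geno_env",
                   env_factor_codes=env_year),
        RandomTerm("alphaLY", ScaledIdentity(1), ge_groups, ones,
                   group_labels=ge_labels, grid_kind="geno_env",
                   env_factor_codes=np.arange(len(environments))),
    ]


def build_model(
    kind: GxeModelKind,
    met: MetMeans,
    ec: ECMatrix,
    sc: SyntheticCovariates | None = None,
) -> GxeModel:
    """Assemble the mixed-model specification for one model family.

    ``ec`` must be standardized on the training environments. For ``fw_us``,
    synthetic covariates are extracted first (or passed in via ``sc``) and
    then standardized like observed covariates before entering the model.
    """
    if not ec.standardized:
        raise ValueError("EC matrix must be standardized before model building")
    genotypes, environments, locations, years, gi, ei, env_loc, env_year = _align(met, ec)
    J = len(environments)
    p = ec.n_covariates
    X_env = ec.subset(environments).values
    df = met.data
    y = df["mean"].to_numpy(float)
    w = df["weight"].to_numpy(float)
    n = len(df)

    sc_centers = sc_scales = None
    if kind.name == "fw_us":
        if sc is None:
            sc = extract_synthetic_covariates(met, ec, kind.q)
        if sc.q != kind.q:
            raise ValueError("synthetic covariates have the wrong rank")
        sc_ec = ECMatrix(environments, np.asarray(sc.Z, float),
                         [f"SC{h + 1}" for h in range(sc.q)])
        sc_ec = standardize_ec(sc_ec)
        sc_centers, sc_scales = sc_ec.centers, sc_ec.scales
        reg_X = sc_ec.values
        reg_names = sc_ec.column_names
    else:
        reg_X = X_env
        reg_names = list(ec.column_names)

    # fixed part
    n_slopes = reg_X.shape[1]
    if kind.main_ec_effect:
        if n_slopes >= J:
            raise ValueError(
                "the fixed mean regression requires more environments than "
                f"covariates (p={n_slopes}, J={J})"
            )
        W_env = np.hstack([np.ones((J, 1)), reg_X])
        fixed_names = ["intercept"] + [f"slope_{c}" for c in reg_names]
    else:
        W_env = np.ones((J, 1))
        fixed_names = ["intercept"]
    W = W_env[ei]

    terms = _deviation_terms(gi, ei, env_loc, env_year, genotypes,
                             environments, locations, years)
    ones = np.ones((n, 1))
    if kind.name == "baseline":
        terms.append(RandomTerm("genotype", ScaledIdentity(1), gi, ones,
                                group_labels=genotypes, grid_kind="geno_block",
                                u_env=np.ones((J, 1))))
    elif kind.name == "kernel":
        terms.append(RandomTerm("genotype", ScaledIdentity(1), gi, ones,
                                group_labels=genotypes, grid_kind="geno_block",
                                u_env=np.ones((J, 1))))
        terms.append(RandomTerm("geno_slopes", ScaledIdentity(p), gi, X_env[ei],
                                group_labels=genotypes,
                                comp_names=list(ec.column_names),
                                grid_kind="geno_block", u_env=X_env))
    else:
        U_env = np.hstack([np.ones((J, 1)), reg_X])
        comp_names = ["intercept"] + list(reg_names)
        if kind.name == "rrr":
            structure = ReducedRank(n_slopes + 1, kind.q)
        else:  # rfr, fw_us
            structure = Unstructured(n_slopes + 1)
        terms.append(RandomTerm("geno_regression", structure, gi, U_env[ei],
                                group_labels=genotypes, comp_names=comp_names,
                                grid_kind="geno_block", u_env=U_env))

    grid = GridInfo(
        geno_codes=gi, env_codes=ei, n_geno=len(genotypes), n_env=J,
        W_env=W_env, geno_fixed_intercepts=False,
    )
    spec = ModelSpec(y=y, weights=w, W=W, fixed_names=fixed_names, terms=terms,
                     residual="fixed", grid=grid)
    return GxeModel(kind=kind, spec=spec, genotypes=genotypes,
                    environments=environments, locations=locations, years=years,
                    X=X_env, ec=ec, sc=sc, sc_centers=sc_centers,
                    sc_scales=sc_scales, met=met)


def extract_synthetic_covariates(
    met: MetMeans, ec: ECMatrix, q: int, start=None
) -> SyntheticCovariates:
    """Estimate loadings Lambda_gamma and synthetic covariates Z = X Lambda_gamma.

    Fits the extraction model: fixed genotype intercepts, fixed environment
    main effects (so the loadings are optimized to explain interaction, not
    environmental main effects), random genotype slopes c_i with
    var(c_i) = Lambda_gamma Lambda_gamma' of rank q, and random genotype x
    location, genotype x year and genotype x environment deviations.
    """
    if not ec.standardized:
        raise ValueError("EC matrix must be standardized before SC extraction")
    genotypes, environments, locations, years, gi, ei, env_loc, env_year = _align(met, ec)
    p = ec.n_covariates
    if q > p:
        raise ValueError(f"rank q={q} exceeds the number of covariates p={p}")
    J = len(environments)
    X_env = ec.subset(environments).values
    df = met.data
    y = df["mean"].to_numpy(float)
    w = df["weight"].to_numpy(float)
    n = len(df)
    I = len(genotypes)

    # fixed: genotype indicators + environment dummies (reference coding)
    W_env = np.zeros((J, J - 1))
    for j in range(1, J):
        W_env[j, j - 1] = 1.0
    G_ind = np.zeros((n, I))
    G_ind[np.arange(n), gi] = 1.0
    W = np.hstack([G_ind, W_env[ei]])
    fixed_names = [f"geno_{g}" for g in genotypes] + \
                  [f"env_{env_key(*environments[j])}" for j in range(1, J)]

    ones = np.ones((n, 1))
    dev = _deviation_terms(gi, ei, env_loc, env_year, genotypes, environments,
                           locations, years)
    terms = [t for t in dev if t.label in ("alphaL", "alphaY", "alphaLY")]
    terms.append(RandomTerm("geno_slopes", ReducedRank(p, q), gi, X_env[ei],
                            group_labels=genotypes,
                            comp_names=list(ec.column_names),
                            grid_kind="geno_block", u_env=X_env))

    grid = GridInfo(geno_codes=gi, env_codes=ei, n_geno=I, n_env=J,
                    W_env=W_env, geno_fixed_intercepts=True)
    spec = ModelSpec(y=y, weights=w, W=W, fixed_names=fixed_names, terms=terms,
                     residual="fixed", grid=grid)
    if start is None:
        # cascade: deviation variances from the slope-free model seed the fit
        spec0 = ModelSpec(y=y, weights=w, W=W, fixed_names=fixed_names,
                          terms=terms[:-1], residual="fixed", grid=grid)
        fit0 = reml_fit(spec0)
        vy = float(np.var(y)) or 1.0
        per = [
            t.structure.theta_from_variance(
                max(fit0.variance_estimates[t.label]["variance"], 1e-6 * vy))
            for t in terms[:-1]
        ]
        st = terms[-1].structure
        lam0 = np.zeros((p, q))
        for h in range(q):
            lam0[h:, h] = 0.1 * np.sqrt(vy) * 0.5 ** h
        per.append(st.theta_from_loadings(lam0))
        start = spec.pack_theta(per)
    fit = reml_fit(spec, start=start)
    st = spec.terms[-1].structure
    idx = [t.label for t in spec.terms].index("geno_slopes")
    lam = st.canonical_loadings(fit.theta_terms[idx])
    Z = X_env @ lam
    return SyntheticCovariates(Z=Z, loadings=lam, environments=environments,
                               column_names=[f"SC{h + 1}" for h in range(q)],
                               extraction_fit=fit)


def omega_identity_check(lam: np.ndarray, X: np.ndarray) -> float:
    """Max absolute deviation between the direct and two-stage Omega matrices.

    Omega_direct = (1 : X) Lambda Lambda' (1 : X)' with the full
    (p+1) x q loadings; Omega_twostage uses the synthetic covariates
    Z = X Lambda_gamma and the reduced loadings (lambda_alpha : I_q)'.
    """
    lam = np.atleast_2d(np.asarray(lam, float))
    X = np.atleast_2d(np.asarray(X, float))
    p, q = X.shape[1], lam.shape[1]
    if lam.shape[0] != p + 1:
        raise ValueError("loadings must have p+1 rows (intercept + slopes)")
    J = X.shape[0]
    one = np.ones((J, 1))
    direct = np.hstack([one, X]) @ lam @ lam.T @ np.hstack([one, X]).T
    lam_alpha = lam[0, :]
    lam_gamma = lam[1:, :]
    Z = X @ lam_gamma
    lam_tilde = np.vstack([lam_alpha, np.eye(q)])   # (q+1) x q
    twostage = np.hstack([one, Z]) @ lam_tilde @ lam_tilde.T @ np.hstack([one, Z]).T
    return float(np.max(np.abs(direct - twostage)))


def count_parameters(kind: GxeModelKind, p: int) -> tuple[int, int, int]:
    """(FixedP, VarP, SP) for a model family with p observed covariates.

    Counts follow the AIC convention: the residual variance fixed at 1 and
    identification-fixed loadings are excluded; the six deviation variances
    are always included; for fw_us the fixed slopes are on the q synthetic
    covariates and SP counts the free extraction loadings.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    q = kind.q or 0
    if kind.name in ("rrr", "fw_us") and q > p:
        raise ValueError("q must not exceed p")
    if kind.name == "fw_us":
        fixed = 1 + (q if kind.main_ec_effect else 0)
    else:
        fixed = 1 + (p if kind.main_ec_effect else 0)
    geno = {
        "baseline": 1,
        "kernel": 2,
        "rrr": (p + 1) * q - q * (q - 1) // 2,
        "rfr": (p + 1) * (p + 2) // 2,
        "fw_us": (q + 1) * (q + 2) // 2,
    }[kind.name]
    varp = 6 + geno
    sp = p * q - q * (q - 1) // 2 if kind.name == "fw_us" else 0
    return fixed, varp, sp
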