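"""Model-based prediction into unseen environments with variance estimates.

The predicted mean for genotype i is eta_i = gamma_i'^T xi', the inner product
of the genotype's regression coefficient vector (intercept plus covariate
slopes, combining the fixed mean regression and the genotype BLUP deviation)
with the plug-in EC expectation for the chosen prediction case. Its total
prediction variance has three parts:

1. the variance of a product of two independent random vectors
   (coefficients estimated from yield data, EC expectation estimated from EC
   history) — Goodman-type exact formula and its bias-corrected estimator;
2. phi, the contribution of the deviation of the realized EC vector from its
   plug-in expectation (a quadratic form in the case's Sigma_x'), again with
   a bias-corrected estimator; and
3. upsilon_R, the deviations from the regression (location/year/interaction
   variance components that are unknowable for the target environment).

Pairwise differences replace gamma_i' by delta = gamma_i' - gamma_i''; purely
environmental components drop out of upsilon_R. The average variance of a
predicted difference over all genotype pairs has a closed trace form using
the pairing matrix P = 2 (I-1)^{-1} [I_I - K_I].

Bias-corrected estimators can go negative in finite samples; reported
variances are floored at zero (with a log message), while the internal
pairwise-average identity is evaluated without flooring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ec_model import PredictionTarget
from .gxe_models import DEVIATION_TERMS, GxeModel
from .lmm_engine import FitResult

logger = logging.getLogger(__name__)

__all__ = [
    "product_variance_scalar", "est_product_variance_scalar", "phi_scalar",
    "product_variance_vector", "est_product_variance_vector", "phi_vector",
    "upsilon_R", "GenotypeCoefficients", "PredictionResult", "predict",
    "pairwise_vpd", "average_vpd",
]


# ---------------------------------------------------------------------------
# Product-variance building blocks
# ---------------------------------------------------------------------------

def product_variance_scalar(gamma: float, xi: float,
                            v_gamma: float, v_xi: float) -> float:
    """Exact variance of a product of two independent random scalars."""
    if v_gamma < 0 or v_xi < 0:
        raise ValueError("variances must be nonnegative")
    return gamma ** 2 * v_xi + xi ** 2 * v_gamma + v_gamma * v_xi


def est_product_variance_scalar(gamma_hat: float, xi_hat: float,
                                v_gamma: float, v_xi: float,
                                floor: bool = True) -> float:
    """Bias-corrected estimator of the product variance from estimates."""
    if v_gamma < 0 or v_xi < 0:
        raise ValueError("variances must be nonnegative")
    val = gamma_hat ** 2 * v_xi + xi_hat ** 2 * v_gamma - v_gamma * v_xi
    if floor and val < 0:
        logger.info("product-variance estimate %.3g floored at 0", val)
        return 0.0
    return val


def phi_scalar(gamma_hat: float, v_gamma: float, sigma2_x: float,
               floor: bool = True) -> float:
    """Bias-reduced estimator of gamma^2 sigma2_x."""
    if sigma2_x < 0:
        raise ValueError("sigma2_x must be nonnegative")
    val = (gamma_hat ** 2 - v_gamma) * sigma2_x
    if floor and val < 0:
        logger.info("phi estimate %.3g floored at 0 (gamma_hat^2 < v_gamma)", val)
        return 0.0
    return val


def product_variance_vector(gamma: np.ndarray, xi: np.ndarray,
                            V_gamma: np.ndarray, V_xi: np.ndarray) -> float:
    """Exact variance of the inner product of two independent random vectors.

    var(gamma' xi) = gamma' V_xi gamma + xi' V_gamma xi + trace(V_gamma V_xi).
    """
    gamma = np.asarray(gamma, float).ravel()
    xi = np.asarray(xi, float).ravel()
    V_gamma = np.atleast_2d(np.asarray(V_gamma, float))
    V_xi = np.atleast_2d(np.asarray(V_xi, float))
    d = gamma.shape[0]
    if xi.shape[0] != d or V_gamma.shape != (d, d) or V_xi.shape != (d, d):
        raise ValueError("dimension mismatch between vectors and covariances")
    return float(gamma @ V_xi @ gamma + xi @ V_gamma @ xi
                 + np.trace(V_gamma @ V_xi))


def est_product_variance_vector(gamma_hat: np.ndarray, xi_hat: np.ndarray,
                                V_gamma: np.ndarray, V_xi: np.ndarray,
                                floor: bool = True) -> float:
    """Bias-corrected estimator of the vector product variance."""
    gamma_hat = np.asarray(gamma_hat, float).ravel()
    xi_hat = np.asarray(xi_hat, float).ravel()
    V_gamma = np.atleast_2d(np.asarray(V_gamma, float))
    V_xi = np.atleast_2d(np.asarray(V_xi, float))
    d = gamma_hat.shape[0]
    if xi_hat.shape[0] != d or V_gamma.shape != (d, d) or V_xi.shape != (d, d):
        raise ValueError("dimension mismatch between vectors and covariances")
    val = float(gamma_hat @ V_xi @ gamma_hat + xi_hat @ V_gamma @ xi_hat
                - np.trace(V_gamma @ V_xi))
    if floor and val < 0:
        logger.info("product-variance estimate %.3g floored at 0", val)
        return 0.0
    return val


def phi_vector(gamma_hat: np.ndarray, V_gamma: np.ndarray,
               Sigma_x: np.ndarray, floor: bool = True) -> float:
    """Bias-reduced estimator of the quadratic form gamma' Sigma_x gamma."""
    gamma_hat = np.asarray(gamma_hat, float).ravel()
    V_gamma = np.atleast_2d(np.asarray(V_gamma, float))
    Sigma_x = np.atleast_2d(np.asarray(Sigma_x, float))
    val = float(gamma_hat @ Sigma_x @ gamma_hat - np.trace(V_gamma @ Sigma_x))
    if floor and val < 0:
        logger.info("phi estimate %.3g floored at 0", val)
        return 0.0
    return val


def upsilon_R(case: int, varcomps: dict[str, float],
              differences: bool = False) -> float:
    """Deviation-from-regression contribution to the prediction variance.

    ``varcomps`` maps the six deviation labels (L, Y, LY, alphaL, alphaY,
    alphaLY) to variance components. For genotype means: case 1 -> 0, case 2
    -> sigma2_Y + sigma2_alphaY, case 3 -> sigma2_L + sigma2_alphaL, case 4
    -> the sum of all six. For pairwise differences the purely environmental
    components drop out and each genotype-interaction component counts twice.
    """
    v = {k: float(varcomps[k]) for k in DEVIATION_TERMS}
    if case == 1:
        return 0.0
    if case == 2:
        return 2.0 * v["alphaY"] if differences else v["Y"] + v["alphaY"]
    if case == 3:
        return 2.0 * v["alphaL"] if differences else v["L"] + v["alphaL"]
    if case == 4:
        if differences:
            return 2.0 * (v["alphaL"] + v["alphaY"] + v["alphaLY"])
        return sum(v.values())
    raise ValueError("case must be 1, 2, 3 or 4")


# ---------------------------------------------------------------------------
# Genotype coefficient vectors and their joint covariance
# ---------------------------------------------------------------------------

@dataclass
class GenotypeCoefficients:
    """Stacked genotype regression vectors gamma_i' and their covariance.

    ``gamma`` is I x (d+1) (intercept + d slopes, fixed mean regression plus
    genotype BLUP deviations); ``var_gamma`` is the I(d+1) x I(d+1) joint
    covariance extracted from the full C-inverse, including fixed-random and
    cross-genotype blocks. ``scale`` is "ec" for observed covariates or "sc"
    for synthetic covariates (with the transform stored on the model).
    """

    genotypes: list[str]
    gamma: np.ndarray
    var_gamma: np.ndarray
    scale: str = "ec"

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def dim(self) -> int:
        return self.gamma.shape[1]

    def block(self, i: int, j: int) -> np.ndarray:
        d = self.dim
        return self.var_gamma[i * d:(i + 1) * d, j * d:(j + 1) * d]

    @classmethod
    def from_fit(cls, fit: FitResult, model: GxeModel) -> "GenotypeCoefficients":
        """Assemble gamma_i' and var(gamma_hat') from a converged fit.

        The coefficient map is linear, gamma = T (beta, u), so the covariance
        is the congruent transform of the joint C-inverse.
        """
        spec = fit.spec
        genotypes = model.genotypes
        I = len(genotypes)
        if model.kind.name == "fw_us":
            d = model.kind.q + 1
            scale = "sc"
        else:
            d = model.X.shape[1] + 1
            scale = "ec"
        f = spec.W.shape[1]
        index = fit.coefficient_index()
        n_coef = len(index)
        T = np.zeros((I * d, n_coef))
        # fixed part: intercept and (optionally) slopes, shared by genotypes
        slope_names = [nm for nm in spec.fixed_names if nm.startswith("slope_")]
        for i in range(I):
            T[i * d, spec.fixed_names.index("intercept")] = 1.0
            for comp, nm in enumerate(slope_names, start=1):
                T[i * d + comp, spec.fixed_names.index(nm)] = 1.0
        # random part: genotype main / regression blocks
        for k, (term, group, comp) in enumerate(index):
            if term == "genotype":
                i = genotypes.index(group)
                T[i * d, k] = 1.0
            elif term == "geno_slopes":
                i = genotypes.index(group)
                cnames = [t for t in spec.terms if t.label == "geno_slopes"][0].comp_names
                T[i * d + 1 + cnames.index(comp), k] = 1.0
            elif term == "geno_regression":
                i = genotypes.index(group)
                t = [t for t in spec.terms if t.label == "geno_regression"][0]
                T[i * d + t.comp_names.index(comp), k] = 1.0
        coefs = np.concatenate([fit.fixed_estimates] +
                               [fit.blups[t.label].ravel() for t in spec.terms])
        gamma = (T @ coefs).reshape(I, d)
        var_gamma = T @ fit.c_inverse @ T.T
        return cls(genotypes=genotypes, gamma=gamma,
                   var_gamma=0.5 * (var_gamma + var_gamma.T), scale=scale)


def _map_target_to_sc(target: PredictionTarget, model: GxeModel
                      ) -> PredictionTarget:
    """Transform an EC-scale target onto the model's synthetic-covariate scale.

    zeta' = (1, (Lambda_g' xi - center) / scale); covariance matrices are
    transformed congruently. Uncertainty in the estimated loadings is ignored
    (they are treated as fixed).
    """
    lam = model.sc.loadings                     # p x q
    s = model.sc_scales
    A = lam / s[None, :]                        # maps xi slopes -> scaled SC
    q = lam.shape[1]
    d = len(target.xi)

    def tx_vec(xi):
        z = (lam.T @ xi[1:] - model.sc_centers) / s
        return np.concatenate([[1.0], z])

    def tx_mat(M):
        out = np.zeros((q + 1, q + 1))
        out[1:, 1:] = A.T @ M[1:, 1:] @ A
        return out

    return PredictionTarget(
        case=target.case, xi=tx_vec(target.xi), Sigma_x=tx_mat(target.Sigma_x),
        xi_variance=tx_mat(target.xi_variance), location=target.location,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    """Per-genotype predictions and variance components for one target."""

    case: int
    table: pd.DataFrame          # genotype, eta_hat, var_product, phi, upsilon_R, upsilon_total
    mvp: float                   # mean of upsilon_total across genotypes
    average_vpd: float           # Eq-49-style average variance of a difference
    location: str | None = None

    @property
    def eta_hat(self) -> np.ndarray:
        return self.table["eta_hat"].to_numpy()

    @property
    def upsilon_total(self) -> np.ndarray:
        return self.table["upsilon_total"].to_numpy()


def _deviation_varcomps(fit: FitResult) -> dict[str, float]:
    return {k: fit.variance_estimates[k]["variance"] for k in DEVIATION_TERMS}


def predict(fit: FitResult, coeffs: GenotypeCoefficients,
            target: PredictionTarget, model: GxeModel | None = None,
            varcomps: dict[str, float] | None = None) -> PredictionResult:
    """Predicted genotype means and bias-corrected prediction variances.

    For synthetic-covariate models pass ``model`` so the EC-scale target can
    be mapped through the estimated loadings.
    """
    if coeffs.scale == "sc":
        if model is None or model.sc is None:
            raise ValueError("synthetic-covariate predictions need the model")
        if len(target.xi) != coeffs.dim:
            target = _map_target_to_sc(target, model)
    if len(target.xi) != coeffs.dim:
        raise ValueError("target dimension does not match coefficient vectors")
    varcomps = varcomps or _deviation_varcomps(fit)
    u_r = upsilon_R(target.case, varcomps, differences=False)
    rows = []
    for i, g in enumerate(coeffs.genotypes):
        gam = coeffs.gamma[i]
        Vg = coeffs.block(i, i)
        eta = float(gam @ target.xi)
        vp = est_product_variance_vector(gam, target.xi, Vg, target.xi_variance)
        ph = phi_vector(gam, Vg, target.Sigma_x)
        rows.append((g, eta, vp, ph, u_r, vp + ph + u_r))
    table = pd.DataFrame(rows, columns=["genotype", "eta_hat", "var_product",
                                        "phi", "upsilon_R", "upsilon_total"])
    avg = average_vpd(coeffs, target, varcomps)
    return PredictionResult(case=target.case, table=table,
                            mvp=float(table["upsilon_total"].mean()),
                            average_vpd=avg, location=target.location)


def pairwise_vpd(coeffs: GenotypeCoefficients, target: PredictionTarget,
                 varcomps: dict[str, float], floor: bool = False
                 ) -> pd.DataFrame:
    """Total prediction variance of each pairwise genotype difference.

    Computed directly per pair with delta = gamma_i - gamma_i' and
    var(delta_hat) from the joint coefficient covariance (cross-genotype
    blocks included). With ``floor=False`` the bias-corrected components are
    left unfloored so the pairwise mean matches the closed trace form exactly.
    """
    I = coeffs.n_genotypes
    if I < 2:
        raise ValueError("pairwise differences need at least 2 genotypes")
    u_r = upsilon_R(target.case, varcomps, differences=True)
    rows = []
    for i in range(I):
        for j in range(i + 1, I):
            delta = coeffs.gamma[i] - coeffs.gamma[j]
            Vd = (coeffs.block(i, i) + coeffs.block(j, j)
                  - coeffs.block(i, j) - coeffs.block(j, i))
            vp = est_product_variance_vector(delta, target.xi, Vd,
                                             target.xi_variance, floor=floor)
            ph = phi_vector(delta, Vd, target.Sigma_x, floor=floor)
            rows.append((coeffs.genotypes[i], coeffs.genotypes[j],
                         vp, ph, u_r, vp + ph + u_r))
    return pd.DataFrame(rows, columns=["genotype_1", "genotype_2",
                                       "var_product", "phi", "upsilon_R",
                                       "upsilon_delta"])


def average_vpd(coeffs: GenotypeCoefficients, target: PredictionTarget,
                varcomps: dict[str, float]) -> float:
    """Average total prediction variance of a difference over genotype pairs.

    Closed trace form with the pairing matrix P = 2 (I-1)^{-1} [I_I - K_I];
    identical to the arithmetic mean of the unfloored pairwise variances.
    """
    I = coeffs.n_genotypes
    if I < 2:
        raise ValueError("need at least 2 genotypes")
    d = coeffs.dim
    P = 2.0 / (I - 1) * (np.eye(I) - np.full((I, I), 1.0 / I))
    M = target.xi_variance + target.Sigma_x
    G = coeffs.gamma
    # trace{[P x M] gamma gamma'} = sum_{ii'} P_ii' gamma_i' M gamma_i'
    term1 = float(np.einsum("ij,ik,kl,jl->", P, G, M, G))
    # trace[var(gamma_hat) (P x xi xi')]
    V = coeffs.var_gamma
    xi = target.xi
    Vb = V.reshape(I, d, I, d)
    term2 = float(np.einsum("ij,iajb,a,b->", P, Vb, xi, xi))
    term3 = float(np.einsum("ij,iajb,ab->", P, Vb, M))
    u_r = upsilon_R(target.case, varcomps, differences=True)
    return term1 + term2 - term3 + u_r
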