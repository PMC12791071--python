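"""Weighted Gaussian linear mixed model fitting by REML.

The engine fits models of the form

    y ~ N(W beta, sum_t Z_t (I x Sigma_t) Z_t' + sigma2_e D^{-1})

where D is a diagonal matrix of known weights (inverse variances carried
forward from a first-stage analysis) and sigma2_e is either fixed at 1 (the
weighted two-stage setting) or a free multiplier. Every random term is a
grouped random-coefficient term: a grouping factor with G levels, a per-row
covariate vector u of dimension d, and a d x d covariance Sigma shared by all
groups. Supported covariance structures: scaled identity, unstructured
(Cholesky-parameterized), reduced rank (factor loadings with lower-trapezoidal
identification zeros, no specific variances), and a fixed positive
semidefinite kernel scaled by a single variance.

Two likelihood evaluation paths are available and give identical REML
log-likelihoods:

* a dense general path that assembles the n x n marginal covariance; and
* a fast path for complete genotype x environment grids with
  environment-constant weights, where exchangeability of genotypes decomposes
  the likelihood into one "between-genotype" block of size J and a pooled
  "within-genotype" part, so each evaluation costs two J x J Cholesky
  factorizations regardless of the number of genotypes.

Fixed-effect estimates (BLUEs), random-effect predictions (BLUPs) and the
joint coefficient covariance ("C-inverse": var(beta_hat), prediction-error
covariance var(u_hat - u) and all cross blocks) are computed lazily at the
converged parameters from the generalized-least-squares identities, which are
valid for singular covariance matrices G (reduced-rank structures) as well.

The REML log-likelihood uses the constant -(n - f)/2 log(2 pi) with an
orthonormalized fixed-effects basis, so values are invariant to the fixed
design parameterization; ``full_loglik`` is the (ML) log-likelihood at the
GLS fixed-effect solution and the REML variance parameters, used for AIC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi
#: a variance component pinned below this fraction of the response variance
#: is reported as a boundary estimate
BOUNDARY_FRACTION = 1e-8
_LOG_VAR_FLOOR = np.log(1e-10)
_LOG_VAR_CEIL = np.log(1e7)


class ConvergenceError(RuntimeError):
    """REML iteration failed; carries the optimizer trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace or []


# ---------------------------------------------------------------------------
# Variance structures
# ---------------------------------------------------------------------------

class VarianceStructure:
    """Base class: a parameterized d x d PSD covariance matrix."""

    kind: str = "base"
    dim: int
    n_free: int

    def cov(self, theta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def factor(self, theta: np.ndarray) -> np.ndarray:
        """A matrix F with F F' = cov(theta)."""
        raise NotImplementedError

    def default_theta(self, var_share: float) -> np.ndarray:
        raise NotImplementedError

    def bounds(self, var_scale: float) -> list[tuple[float, float]]:
        raise NotImplementedError

    def natural(self, theta: np.ndarray):
        """Report parameters on the natural scale (variance / Sigma / Lambda)."""
        raise NotImplementedError

    def boundary(self, theta: np.ndarray, var_scale: float) -> bool:
        """True if any implied variance is pinned at (near) zero."""
        c = np.diag(self.cov(theta))
        return bool(np.any(c < BOUNDARY_FRACTION * var_scale))

    @property
    def n_varp(self) -> int:
        """Number of variance parameters counted for AIC."""
        return self.n_free


class ScaledIdentity(VarianceStructure):
    """Sigma = sigma2 * I_d, parameterized by log sigma2."""

    kind = "scaled_identity"

    def __init__(self, dim: int = 1):
        self.dim = int(dim)
        self.n_free = 1

    def cov(self, theta):
        return np.exp(theta[0]) * np.eye(self.dim)

    def factor(self, theta):
        return np.sqrt(np.exp(theta[0])) * np.eye(self.dim)

    def default_theta(self, var_share):
        return np.array([np.log(max(var_share / self.dim, 1e-12))])

    def bounds(self, var_scale):
        lv = np.log(var_scale)
        return [(lv + _LOG_VAR_FLOOR, lv + _LOG_VAR_CEIL)]

    def natural(self, theta):
        return {"variance": float(np.exp(theta[0]))}

    def theta_from_variance(self, s2: float) -> np.ndarray:
        return np.array([np.log(s2)])


class FixedKernel(VarianceStructure):
    """Sigma = sigma2 * K for a fixed symmetric PSD kernel K."""

    kind = "fixed_kernel"

    def __init__(self, K: np.ndarray):
        K = np.asarray(K, float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kernel must be square")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("kernel must be symmetric")
        w, U = np.linalg.eigh(K)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise ValueError("kernel must be positive semidefinite")
        w = np.clip(w, 0.0, None)
        self.K = K
        self._factor = U * np.sqrt(w)
        self.dim = K.shape[0]
        self.n_free = 1

    def cov(self, theta):
        return np.exp(theta[0]) * self.K

    def factor(self, theta):
        return np.sqrt(np.exp(theta[0])) * self._factor

    def default_theta(self, var_share):
        scale = max(np.trace(self.K) / self.dim, 1e-12)
        return np.array([np.log(max(var_share / self.dim / scale, 1e-12))])

    def bounds(self, var_scale):
        scale = max(np.trace(self.K) / self.dim, 1e-12)
        lv = np.log(var_scale / scale)
        return [(lv + _LOG_VAR_FLOOR, lv + _LOG_VAR_CEIL)]

    def natural(self, theta):
        return {"variance": float(np.exp(theta[0]))}

    def theta_from_variance(self, s2: float) -> np.ndarray:
        return np.array([np.log(s2)])


class Unstructured(VarianceStructure):
    """Unstructured Sigma via its Cholesky factor (log-diagonal transform).

    Parameters are packed row-wise over the lower triangle; diagonal entries
    are stored on the log scale so Sigma is positive definite at any theta.
    """

    kind = "unstructured"

    def __init__(self, dim: int):
        self.dim = int(dim)
        self.n_free = self.dim * (self.dim + 1) // 2
        rows, cols = np.tril_indices(self.dim)
        self._rows, self._cols = rows, cols
        self._isdiag = rows == cols

    def _chol(self, theta):
        L = np.zeros((self.dim, self.dim))
        vals = np.asarray(theta, float).copy()
        vals[self._isdiag] = np.exp(vals[self._isdiag])
        L[self._rows, self._cols] = vals
        return L

    def cov(self, theta):
        L = self._chol(theta)
        return L @ L.T

    def factor(self, theta):
        return self._chol(theta)

    def default_theta(self, var_share):
        theta = np.zeros(self.n_free)
        theta[self._isdiag] = 0.5 * np.log(max(var_share / self.dim, 1e-12))
        return theta

    def bounds(self, var_scale):
        ld = 0.5 * np.log(var_scale)
        sd = np.sqrt(var_scale)
        out = []
        for isd in self._isdiag:
            if isd:
                out.append((ld + 0.5 * _LOG_VAR_FLOOR, ld + 0.5 * _LOG_VAR_CEIL))
            else:
                out.append((-30.0 * sd, 30.0 * sd))
        return out

    def natural(self, theta):
        return {"sigma": self.cov(theta)}

    def theta_from_cov(self, sigma: np.ndarray) -> np.ndarray:
        L = np.linalg.cholesky(np.asarray(sigma, float))
        vals = L[self._rows, self._cols].copy()
        vals[self._isdiag] = np.log(vals[self._isdiag])
        return vals


class ReducedRank(VarianceStructure):
    """Sigma = Lambda Lambda' for a dim x q loading matrix Lambda.

    Identification: lambda_{kh} = 0 for h > k (entries above the diagonal of
    the leading q x q block), leaving dim*q - q(q-1)/2 free loadings; the sign
    of each factor is fixed by forcing its first free loading nonnegative.
    This is a factor-analytic structure with no specific variances, so Sigma
    is singular whenever q < dim.
    """

    kind = "reduced_rank"

    def __init__(self, dim: int, q: int):
        if not 1 <= q <= dim:
            raise ValueError("rank q must be in 1..dim")
        self.dim = int(dim)
        self.q = int(q)
        # free entries, column-major: column h has rows h..dim (0-based h-1..)
        rows, cols = [], []
        for h in range(self.q):
            for k in range(h, self.dim):
                rows.append(k)
                cols.append(h)
        self._rows = np.array(rows)
        self._cols = np.array(cols)
        self.n_free = len(rows)

    def loadings(self, theta):
        L = np.zeros((self.dim, self.q))
        L[self._rows, self._cols] = theta
        return L

    def cov(self, theta):
        L = self.loadings(theta)
        return L @ L.T

    def factor(self, theta):
        return self.loadings(theta)

    def default_theta(self, var_share):
        base = np.sqrt(max(var_share / self.dim, 1e-12))
        theta = np.zeros(self.n_free)
        for h in range(self.q):
            sel = self._cols == h
            theta[sel] = base * 0.5 ** h
        return theta

    def bounds(self, var_scale):
        sd = np.sqrt(var_scale)
        return [(-30.0 * sd, 30.0 * sd)] * self.n_free

    def natural(self, theta):
        return {"loadings": self.canonical_loadings(theta)}

    def canonical_loadings(self, theta):
        """Loadings with the sign of each factor's first nonzero entry fixed."""
        L = self.loadings(theta).copy()
        for h in range(self.q):
            col = L[:, h]
            nz = np.flatnonzero(np.abs(col) > 1e-12)
            if len(nz) and col[nz[0]] < 0:
                L[:, h] = -col
        return L

    def theta_from_loadings(self, lam: np.ndarray) -> np.ndarray:
        lam = np.asarray(lam, float)
        zeros = lam[self._zero_mask()]
        if zeros.size and np.max(np.abs(zeros)) > 1e-10:
            raise ValueError("loadings violate the identification zero pattern")
        return lam[self._rows, self._cols]

    def _zero_mask(self):
        mask = np.zeros((self.dim, self.q), dtype=bool)
        for h in range(self.q):
            mask[:h, h] = True
        return mask


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass
class RandomTerm:
    """A grouped random-coefficient term u_g ~ N(0, Sigma) per group g.

    ``groups`` holds integer group codes per data row and ``u`` the per-row
    covariate vector (n x d). For terms that live on a complete genotype x
    environment grid, ``grid_kind`` and the environment-level summaries allow
    the fast likelihood path: "env" (grouping is a function of the
    environment), "geno_env" (genotype crossed with an environment factor) or
    "geno_block" (grouped by genotype with environment-level covariate rows).
    """

    label: str
    structure: VarianceStructure
    groups: np.ndarray
    u: np.ndarray
    group_labels: list[str] | None = None
    comp_names: list[str] | None = None
    grid_kind: str | None = None          # "env" | "geno_env" | "geno_block"
    env_factor_codes: np.ndarray | None = None   # (J,) for env / geno_env
    u_env: np.ndarray | None = None       # (J, d) for geno_block

    def __post_init__(self):
        self.groups = np.asarray(self.groups, dtype=int)
        self.u = np.atleast_2d(np.asarray(self.u, float))
        if self.u.shape[0] != self.groups.shape[0]:
            self.u = self.u.T
        if self.u.shape[1] != self.structure.dim:
            raise ValueError(
                f"term {self.label}: u has {self.u.shape[1]} columns, "
                f"structure dim is {self.structure.dim}"
            )

    @property
    def n_groups(self) -> int:
        return int(self.groups.max()) + 1

    @property
    def n_coef(self) -> int:
        return self.n_groups * self.structure.dim


@dataclass
class GridInfo:
    """Complete-grid metadata enabling the fast likelihood path."""

    geno_codes: np.ndarray
    env_codes: np.ndarray
    n_geno: int
    n_env: int
    W_env: np.ndarray                      # (J, f_env) environment-level fixed design
    geno_fixed_intercepts: bool = False


@dataclass
class ModelSpec:
    """A mixed model: response, weights, fixed design and random terms."""

    y: np.ndarray
    weights: np.ndarray
    W: np.ndarray
    fixed_names: list[str]
    terms: list[RandomTerm]
    residual: str = "fixed"               # "fixed" (sigma2_e = 1) or "free"
    grid: GridInfo | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, float).ravel()
        self.weights = np.asarray(self.weights, float).ravel()
        self.W = np.atleast_2d(np.asarray(self.W, float))
        n = self.y.shape[0]
        if self.weights.shape[0] != n or self.W.shape[0] != n:
            raise ValueError("response, weights and fixed design must align")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")
        if self.residual not in ("fixed", "free"):
            raise ValueError("residual must be 'fixed' or 'free'")
        for t in self.terms:
            if t.groups.shape[0] != n:
                raise ValueError(f"term {t.label} does not align with data rows")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def n_theta(self) -> int:
        k = sum(t.structure.n_free for t in self.terms)
        return k + (1 if self.residual == "free" else 0)

    def split_theta(self, theta):
        theta = np.asarray(theta, float)
        out, pos = [], 0
        for t in self.terms:
            out.append(theta[pos:pos + t.structure.n_free])
            pos += t.structure.n_free
        resvar = np.exp(theta[pos]) if self.residual == "free" else 1.0
        return out, resvar

    def pack_theta(self, per_term: list[np.ndarray], resvar: float | None = None):
        parts = [np.asarray(p, float).ravel() for p in per_term]
        if self.residual == "free":
            parts.append(np.array([np.log(resvar)]))
        return np.concatenate(parts) if parts else np.zeros(0)


def _orth(M: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of M (rank-revealing SVD)."""
    if M.size == 0:
        return np.zeros((M.shape[0], 0))
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    tol = max(M.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    return U[:, s > tol]


# ---------------------------------------------------------------------------
# Likelihood evaluators
# ---------------------------------------------------------------------------

class _DenseEvaluator:
    """General REML evaluation from the dense n x n marginal covariance."""

    path = "dense"

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        n = spec.n
        self.Q = _orth(spec.W)
        self.f_rank = self.Q.shape[1]
        self._masks = [
            np.equal.outer(t.groups, t.groups) for t in spec.terms
        ]
        self._const = (n - self.f_rank) * np.log(TWO_PI)

    def marginal_cov(self, theta) -> np.ndarray:
        spec = self.spec
        per_term, resvar = spec.split_theta(theta)
        V = np.diag(resvar / spec.weights)
        for t, th, mask in zip(spec.terms, per_term, self._masks):
            sig = t.structure.cov(th)
            V += (t.u @ sig @ t.u.T) * mask
        return V

    def neg2_reml(self, theta) -> float:
        spec = self.spec
        V = self.marginal_cov(theta)
        try:
            cf = cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return np.inf
        logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Viy = cho_solve(cf, spec.y, check_finite=False)
        quad = float(spec.y @ Viy)
        logdet_m = 0.0
        if self.f_rank:
            ViQ = cho_solve(cf, self.Q, check_finite=False)
            M = self.Q.T @ ViQ
            cm = cho_factor(M, lower=True, check_finite=False)
            logdet_m = 2.0 * np.sum(np.log(np.diag(cm[0])))
            b = self.Q.T @ Viy
            quad -= float(b @ cho_solve(cm, b, check_finite=False))
        return self._const + logdet_v + logdet_m + quad


class _GridEvaluator:
    """Fast REML evaluation on a complete genotype x environment grid.

    With exchangeable genotypes the marginal covariance is
    I_I x A + 1_I 1_I' x B for J x J matrices A (within-genotype) and B
    (shared environmental). An orthogonal contrast of genotypes block-
    diagonalizes it into one block A + I*B carrying the genotype mean and
    I - 1 identical blocks A carrying within-genotype contrasts, whose data
    enter only through the pooled cross-product matrix S_w.
    """

    path = "grid"

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        g = spec.grid
        I, J = g.n_geno, g.n_env
        self.I, self.J = I, J
        # response grid and pooled within-genotype cross products
        Y = np.zeros((I, J))
        Y[g.geno_codes, g.env_codes] = spec.y
        ybar = Y.mean(axis=0)
        Yc = Y - ybar
        self.S_w = Yc.T @ Yc
        self.y1 = np.sqrt(I) * ybar
        # environment-level weights
        w_env = np.zeros(J)
        w_env[g.env_codes] = spec.weights
        self.w_env = w_env
        # fixed design blocks
        X1 = g.W_env
        if g.geno_fixed_intercepts:
            X1 = np.hstack([X1, np.ones((J, 1))])
        self.Q1 = _orth(X1)
        self.geno_fixed = g.geno_fixed_intercepts
        self.f_rank = self.Q1.shape[1] + (I - 1) * int(self.geno_fixed)
        self._const = (spec.n - self.f_rank) * np.log(TWO_PI)
        # per-term environment-level pieces
        self._env_masks = []
        for t in spec.terms:
            if t.grid_kind in ("env", "geno_env"):
                codes = t.env_factor_codes
                self._env_masks.append(np.equal.outer(codes, codes).astype(float))
            else:
                self._env_masks.append(None)

    @staticmethod
    def supports(spec: ModelSpec) -> bool:
        g = spec.grid
        if g is None:
            return False
        if g.n_geno < 2:
            return False
        n = spec.n
        if n != g.n_geno * g.n_env:
            return False
        pair = g.geno_codes.astype(np.int64) * g.n_env + g.env_codes
        if len(np.unique(pair)) != n:
            return False
        w_env = np.zeros(g.n_env)
        w_env[g.env_codes] = spec.weights
        if not np.allclose(spec.weights, w_env[g.env_codes], rtol=1e-10, atol=0):
            return False
        return all(t.grid_kind is not None for t in spec.terms)

    def _ab(self, theta):
        spec = self.spec
        per_term, resvar = spec.split_theta(theta)
        J = self.J
        A = np.diag(resvar / self.w_env)
        B = np.zeros((J, J))
        for t, th, mask in zip(spec.terms, per_term, self._env_masks):
            if t.grid_kind == "env":
                B += t.structure.cov(th)[0, 0] * mask
            elif t.grid_kind == "geno_env":
                A += t.structure.cov(th)[0, 0] * mask
            else:  # geno_block
                sig = t.structure.cov(th)
                A += t.u_env @ sig @ t.u_env.T
        return A, B

    def neg2_reml(self, theta) -> float:
        I = self.I
        A, B = self._ab(theta)
        C1 = A + I * B
        try:
            cf1 = cho_factor(C1, lower=True, check_finite=False)
            cfa = cho_factor(A, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return np.inf
        logdet_c1 = 2.0 * np.sum(np.log(np.diag(cf1[0])))
        logdet_a = 2.0 * np.sum(np.log(np.diag(cfa[0])))
        # block 1: genotype mean
        Ciy = cho_solve(cf1, self.y1, check_finite=False)
        quad1 = float(self.y1 @ Ciy)
        logdet_m1 = 0.0
        if self.Q1.shape[1]:
            CiQ = cho_solve(cf1, self.Q1, check_finite=False)
            M1 = self.Q1.T @ CiQ
            cm1 = cho_factor(M1, lower=True, check_finite=False)
            logdet_m1 = 2.0 * np.sum(np.log(np.diag(cm1[0])))
            b = self.Q1.T @ Ciy
            quad1 -= float(b @ cho_solve(cm1, b, check_finite=False))
        # blocks 2..I: within-genotype contrasts, pooled
        AiS = cho_solve(cfa, self.S_w, check_finite=False)
        quad2 = float(np.trace(AiS))
        logdet_m2 = 0.0
        if self.geno_fixed:
            a = cho_solve(cfa, np.ones(self.J), check_finite=False)
            d = float(a.sum())  # 1' A^-1 1
            quad2 -= float(a @ self.S_w @ a) / d
            logdet_m2 = (self.I - 1) * np.log(d / self.J)
        return (
            self._const
            + logdet_c1 + logdet_m1 + quad1
            + (I - 1) * logdet_a + logdet_m2 + quad2
        )


def _make_evaluator(spec: ModelSpec, use_grid="auto"):
    if use_grid in ("auto", True) and _GridEvaluator.supports(spec):
        return _GridEvaluator(spec)
    if use_grid is True:
        raise ValueError("model is not eligible for the grid likelihood path")
    return _DenseEvaluator(spec)


def profile_loglik(spec: ModelSpec, theta, use_grid="auto") -> float:
    """REML log-likelihood at the given packed variance parameter vector."""
    val = _make_evaluator(spec, use_grid).neg2_reml(np.asarray(theta, float))
    if not np.isfinite(val):
        raise np.linalg.LinAlgError("singular marginal covariance at these parameters")
    return -0.5 * val


# ---------------------------------------------------------------------------
# Fit result and solution of the mixed-model equations
# ---------------------------------------------------------------------------

@dataclass
class Convergence:
    converged: bool
    iterations: int
    n_evals: int
    grad_norm: float
    boundary_terms: list[str]
    message: str
    trace: list[float] = field(default_factory=list)


class FitResult:
    """Converged REML fit: parameters, likelihoods, lazy BLUEs/BLUPs/C-inverse."""

    def __init__(self, spec: ModelSpec, theta: np.ndarray, reml_loglik: float,
                 convergence: Convergence, path: str):
        self.spec = spec
        self.theta = np.asarray(theta, float)
        self.reml_loglik = float(reml_loglik)
        self.convergence = convergence
        self.path = path
        per_term, resvar = spec.split_theta(self.theta)
        self.theta_terms = per_term
        self.residual_variance = float(resvar)
        self.variance_estimates = {
            t.label: t.structure.natural(th) for t, th in zip(spec.terms, per_term)
        }
        self._solution = None
        self._c_inverse = None

    # -- parameter counts ---------------------------------------------------

    @property
    def n_var_params(self) -> int:
        k = sum(t.structure.n_varp for t in self.spec.terms)
        return k + (1 if self.spec.residual == "free" else 0)

    @property
    def n_fixed_params(self) -> int:
        return int(np.linalg.matrix_rank(self.spec.W)) if self.spec.W.size else 0

    # -- heavy linear algebra (lazy) ----------------------------------------

    def _solve(self):
        if self._solution is not None:
            return self._solution
        spec = self.spec
        V = _DenseEvaluator(spec).marginal_cov(self.theta)
        cf = cho_factor(V, lower=True, check_finite=False)
        W = spec.W
        ViW = cho_solve(cf, W, check_finite=False)
        Viy = cho_solve(cf, spec.y, check_finite=False)
        WViW = W.T @ ViW
        # generalized inverse with aliased-column detection
        eigval, eigvec = np.linalg.eigh(WViW)
        tol = max(WViW.shape[0], 1) * np.finfo(float).eps * max(eigval.max(), 1.0)
        keep = eigval > tol
        Aff = (eigvec[:, keep] / eigval[keep]) @ eigvec[:, keep].T
        aliased = [
            spec.fixed_names[j]
            for j in range(W.shape[1])
            if not keep.all() and np.allclose(Aff[j], 0)
        ]
        beta = Aff @ (W.T @ Viy)
        resid = spec.y - W @ beta
        Vir = cho_solve(cf, resid, check_finite=False)
        blups = {}
        for t, th in zip(spec.terms, self.theta_terms):
            sig = t.structure.cov(th)
            # u_hat_g = Sigma * sum_{rows in g} u_row * Vir_row
            s = np.zeros((t.n_groups, t.structure.dim))
            np.add.at(s, t.groups, t.u * Vir[:, None])
            blups[t.label] = s @ sig.T
        n = spec.n
        logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
        full = -0.5 * (n * np.log(TWO_PI) + logdet_v + float(resid @ Vir))
        self._solution = {
            "cho": cf, "Aff": Aff, "beta": beta, "blups": blups,
            "aliased": aliased, "full_loglik": full, "ViW": ViW, "Vir": Vir,
        }
        return self._solution

    @property
    def fixed_estimates(self) -> np.ndarray:
        return self._solve()["beta"]

    @property
    def blups(self) -> dict[str, np.ndarray]:
        """Per-term BLUP matrices of shape (n_groups, dim)."""
        return self._solve()["blups"]

    @property
    def aliased_fixed(self) -> list[str]:
        return self._solve()["aliased"]

    @property
    def full_loglik(self) -> float:
        return self._solve()["full_loglik"]

    def coefficient_index(self) -> list[tuple[str, str, str]]:
        """(term, group, component) labels for rows of the C-inverse.

        Fixed effects come first as ("fixed", name, "").
        """
        out = [("fixed", nm, "") for nm in self.spec.fixed_names]
        for t in self.spec.terms:
            glabels = t.group_labels or [str(g) for g in range(t.n_groups)]
            cnames = t.comp_names or [f"c{k}" for k in range(t.structure.dim)]
            for g in range(t.n_groups):
                for c in cnames:
                    out.append((t.label, str(glabels[g]), c))
        return out

    @property
    def c_inverse(self) -> np.ndarray:
        """Joint covariance of (beta_hat, u_hat - u) over all coefficients.

        Computed from the GLS identities var(beta_hat) = (W'V^-1 W)^-,
        var(u_hat - u) = G - G Z' P Z G and cov(beta_hat, u_hat - u)
        = -(W'V^-1 W)^- W'V^-1 Z G, which remain valid when G is singular
        (reduced-rank structures). For nonsingular G this equals the inverse
        of the mixed-model-equations coefficient matrix.
        """
        if self._c_inverse is not None:
            return self._c_inverse
        sol = self._solve()
        spec = self.spec
        cf, Aff, ViW = sol["cho"], sol["Aff"], sol["ViW"]
        n = spec.n
        # Z G stacked over terms (n x r)
        zg_blocks, g_blocks = [], []
        for t, th in zip(spec.terms, self.theta_terms):
            sig = t.structure.cov(th)
            d, G = t.structure.dim, t.n_groups
            ZG = np.zeros((n, G * d))
            rows = np.arange(n)
            vals = t.u @ sig.T  # (n, d)
            for k in range(d):
                ZG[rows, t.groups * d + k] = vals[:, k]
            zg_blocks.append(ZG)
            g_blocks.append((sig, G))
        ZG = np.hstack(zg_blocks) if zg_blocks else np.zeros((n, 0))
        r = ZG.shape[1]
        f = spec.W.shape[1]
        ViZG = cho_solve(cf, ZG, check_finite=False)
        WViZG = spec.W.T @ ViZG
        # P Z G = V^-1 ZG - V^-1 W Aff W' V^-1 ZG
        PZG = ViZG - ViW @ (Aff @ WViZG)
        Crr = -(ZG.T @ PZG)
        pos = 0
        for sig, G in g_blocks:
            d = sig.shape[0]
            for g in range(G):
                s = pos + g * d
                Crr[s:s + d, s:s + d] += sig
            pos += G * d
        Cfr = -Aff @ WViZG
        C = np.zeros((f + r, f + r))
        C[:f, :f] = Aff
        C[:f, f:] = Cfr
        C[f:, :f] = Cfr.T
        C[f:, f:] = Crr
        self._c_inverse = 0.5 * (C + C.T)
        return self._c_inverse

    def to_dict(self) -> dict:
        """JSON-serializable summary of the fit."""
        out = {
            "reml_loglik": self.reml_loglik,
            "full_loglik": self.full_loglik,
            "residual_variance": self.residual_variance,
            "path": self.path,
            "converged": self.convergence.converged,
            "iterations": self.convergence.iterations,
            "boundary_terms": self.convergence.boundary_terms,
            "fixed": {
                nm: float(b)
                for nm, b in zip(self.spec.fixed_names, self.fixed_estimates)
            },
            "variance_estimates": {},
        }
        for label, nat in self.variance_estimates.items():
            out["variance_estimates"][label] = {
                k: (v.tolist() if isinstance(v, np.ndarray) else float(v))
                for k, v in nat.items()
            }
        return out


def compute_c_inverse(fit: FitResult) -> np.ndarray:
    """Joint coefficient covariance matrix of the converged fit."""
    return fit.c_inverse


# ---------------------------------------------------------------------------
# REML fitting
# ---------------------------------------------------------------------------

def _response_variance(spec: ModelSpec) -> float:
    """Rough response variance after removing the fixed part (for scaling)."""
    y, W = spec.y, spec.W
    if W.size:
        beta, *_ = np.linalg.lstsq(W, y, rcond=None)
        r = y - W @ beta
    else:
        r = y - y.mean()
    v = float(r @ r) / max(len(y) - np.linalg.matrix_rank(W), 1)
    return max(v, 1e-8)


def default_start(spec: ModelSpec) -> np.ndarray:
    """Starting values: equal partition of the response variance."""
    vy = _response_variance(spec)
    k = len(spec.terms) + 1
    per_term = [t.structure.default_theta(vy / k) for t in spec.terms]
    return spec.pack_theta(per_term, resvar=vy / k)


def reml_fit(
    spec: ModelSpec,
    start: np.ndarray | None = None,
    max_iter: int = 500,
    gtol: float = 1e-5,
    ftol: float = 1e-11,
    use_grid="auto",
) -> FitResult:
    """Maximize the REML log-likelihood and return the fitted model.

    Uses L-BFGS-B on transformed parameters (log variances, Cholesky factors
    for unstructured, raw loadings for reduced rank). On an unsuccessful
    first pass the optimizer is restarted from a perturbed point and the best
    solution is kept.
    """
    ev = _make_evaluator(spec, use_grid)
    vy = _response_variance(spec)
    bounds = []
    for t in spec.terms:
        bounds.extend(t.structure.bounds(vy))
    if spec.residual == "free":
        bounds.append((np.log(vy) + _LOG_VAR_FLOOR, np.log(vy) + _LOG_VAR_CEIL))
    if spec.n_theta() == 0:
        val = ev.neg2_reml(np.zeros(0))
        conv = Convergence(True, 0, 1, 0.0, [], "no variance parameters", [])
        return FitResult(spec, np.zeros(0), -0.5 * val, conv, ev.path)
    theta0 = np.asarray(start, float) if start is not None else default_start(spec)
    theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])

    trace: list[float] = []

    def obj(th):
        return ev.neg2_reml(th)

    def cb(th):
        trace.append(-0.5 * obj(th))

    opts = {"maxiter": max_iter, "gtol": gtol, "ftol": ftol}
    res = optimize.minimize(obj, theta0, method="L-BFGS-B", bounds=bounds,
                            options=opts, callback=cb)
    best = res
    if not res.success or not np.isfinite(res.fun):
        rng = np.random.default_rng(0)
        for _ in range(2):
            jitter = rng.normal(scale=0.3, size=len(theta0))
            t1 = np.clip(res.x + jitter, [b[0] for b in bounds], [b[1] for b in bounds])
            res2 = optimize.minimize(obj, t1, method="L-BFGS-B", bounds=bounds,
                                     options=opts, callback=cb)
            if np.isfinite(res2.fun) and res2.fun <= best.fun:
                best = res2
            if best.success:
                break
    if not np.isfinite(best.fun):
        raise ConvergenceError("REML optimization failed to find a finite optimum",
                               trace)
    theta = best.x.copy()
    best_fun = best.fun
    # boundary snap: a scalar variance drifting to zero stalls on the log
    # scale; pin it at the floor if that does not worsen the objective
    pos = 0
    for t in spec.terms:
        k = t.structure.n_free
        if t.structure.kind in ("scaled_identity", "fixed_kernel"):
            lo = bounds[pos][0]
            if lo < theta[pos] < lo + 12.0:
                cand = theta.copy()
                cand[pos] = lo
                val = obj(cand)
                if val <= best_fun + 1e-6:
                    theta, best_fun = cand, min(val, best_fun)
        pos += k
    grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.nan
    boundary = []
    per_term, _ = spec.split_theta(theta)
    for t, th in zip(spec.terms, per_term):
        if t.structure.boundary(th, vy):
            boundary.append(t.label)
    conv = Convergence(
        converged=bool(best.success),
        iterations=int(best.nit),
        n_evals=int(best.nfev),
        grad_norm=grad_norm,
        boundary_terms=boundary,
        message=str(best.message),
        trace=trace,
    )
    if not best.success and best.nit >= max_iter:
        raise ConvergenceError(
            f"REML did not converge in {max_iter} iterations: {best.message}", trace
        )
    return FitResult(spec, theta, -0.5 * best_fun, conv, ev.path)


def aic(fit: FitResult, sp: int = 0) -> float:
    """Akaike information criterion from the full log-likelihood.

    AIC = -2 LogLik + 2 (VarP + FixedP + SP), where SP counts parameters
    involved in constructing synthetic covariates (zero for models fitted on
    observed covariates).
    """
    k = fit.n_var_params + fit.n_fixed_params + int(sp)
    return -2.0 * fit.full_loglik + 2.0 * k
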