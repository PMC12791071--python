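"""Synthetic multi-environment trial generator.

Generates data with exactly the statistical structure the modeling stack
assumes: a crossed location x year environmental-covariate process with
separable location/year/interaction covariances, genotype-specific intercepts
and covariate slopes drawn from a chosen covariance structure, three-way
deviations from the regression (L, Y, LY, and their genotype interactions),
and either plot-level records under a randomized complete block design or
genotype x environment means with the matching inverse-variance weights.

Default sizes and variance components mirror a long-term rainfed rice variety
trial network scaled down to desk size: 20 genotypes, 6 locations x 10 years,
4 covariates, 3 blocks; the six deviation components default to the values
estimated for such a network's baseline model (in (t/ha)^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gxe_models import GxeModelKind
from .met_data import ECMatrix, MetMeans, PlotRecords

__all__ = ["SimConfig", "simulate_ec", "simulate_met", "simulate_means"]


def _default_kind() -> GxeModelKind:
    return GxeModelKind("rfr")


@dataclass
class SimConfig:
    """Generating model for one synthetic MET.

    Genotype coefficients (intercept a_i, slopes c_i) are drawn according to
    ``kind``: from ``sigma2_alpha`` alone (baseline), iid slopes with
    ``sigma2_gamma`` (kernel), loadings ``lam`` (rrr) or the full matrix
    ``sigma_geno`` (rfr). Slopes act on the standardized covariate scale.
    """

    n_genotypes: int = 20
    n_locations: int = 6
    n_years: int = 10
    n_covariates: int = 4
    n_blocks: int = 3
    seed: int = 0

    kind: GxeModelKind = field(default_factory=_default_kind)
    mu_alpha: float = 4.5                      # overall yield level, t/ha
    mu_gamma: np.ndarray | float = 0.1         # mean regression slopes
    sigma2_alpha: float = 0.2422               # genotype main-effect variance
    sigma2_gamma: float = 0.02                 # kernel: common slope variance
    sigma_geno: np.ndarray | None = None       # rfr: (p+1) x (p+1) covariance
    lam: np.ndarray | None = None              # rrr: (p+1) x q loadings

    # EC process (raw covariate scale)
    ec_mu: np.ndarray | float = 0.0
    ec_sigma_L: np.ndarray | float = 0.5
    ec_sigma_Y: np.ndarray | float = 0.3
    ec_sigma_LY: np.ndarray | float = 0.4

    # deviations from the regression, (t/ha)^2
    sigma2_L: float = 0.0568
    sigma2_Y: float = 0.0262
    sigma2_LY: float = 0.4434
    sigma2_alphaL: float = 0.0307
    sigma2_alphaY: float = 0.0142
    sigma2_alphaLY: float = 0.2695

    sigma2_plot: float = 0.5                   # plot-level error variance

    def _vec(self, v, p=None) -> np.ndarray:
        p = p or self.n_covariates
        v = np.asarray(v, float)
        return np.full(p, float(v)) if v.ndim == 0 else v

    def _mat(self, v, p=None) -> np.ndarray:
        p = p or self.n_covariates
        v = np.asarray(v, float)
        if v.ndim == 0:
            return float(v) * np.eye(p)
        if v.ndim == 1:
            return np.diag(v)
        return v

    @property
    def locations(self) -> list[str]:
        return [f"L{l + 1:02d}" for l in range(self.n_locations)]

    @property
    def years(self) -> list[str]:
        return [f"{2001 + m}" for m in range(self.n_years)]

    @property
    def genotypes(self) -> list[str]:
        return [f"G{i + 1:03d}" for i in range(self.n_genotypes)]

    @property
    def covariates(self) -> list[str]:
        return [f"ec{k + 1}" for k in range(self.n_covariates)]

    def genotype_covariance(self) -> np.ndarray:
        """The (p+1) x (p+1) covariance of (a_i, c_i) implied by the config."""
        p = self.n_covariates
        if self.kind.name == "baseline":
            S = np.zeros((p + 1, p + 1))
            S[0, 0] = self.sigma2_alpha
            return S
        if self.kind.name == "kernel":
            S = np.eye(p + 1) * self.sigma2_gamma
            S[0, 0] = self.sigma2_alpha
            return S
        if self.kind.name == "rrr":
            lam = np.atleast_2d(np.asarray(self.lam, float))
            if lam.shape[0] != p + 1:
                raise ValueError("lam must have p+1 rows")
            return lam @ lam.T
        if self.kind.name == "rfr":
            if self.sigma_geno is not None:
                S = np.asarray(self.sigma_geno, float)
            else:
                S = np.diag([self.sigma2_alpha] + [self.sigma2_gamma] * p)
            if S.shape != (p + 1, p + 1):
                raise ValueError("sigma_geno must be (p+1) x (p+1)")
            w = np.linalg.eigvalsh(S)
            if w.min() < -1e-10:
                raise ValueError("sigma_geno must be positive semidefinite")
            return S
        raise ValueError(f"cannot simulate under kind {self.kind.name!r}")


def _mvn(rng, cov, size):
    """Draws from N(0, cov) via eigen factor (PSD-safe, deterministic)."""
    w, U = np.linalg.eigh(np.asarray(cov, float))
    w = np.clip(w, 0.0, None)
    F = U * np.sqrt(w)
    z = rng.standard_normal(size=(size, cov.shape[0]))
    return z @ F.T


def simulate_ec(config: SimConfig, rng: np.random.Generator | None = None):
    """Draw the crossed location x year EC process.

    Returns ``(ECMatrix, truth)`` where truth holds the drawn location, year
    and interaction effect vectors. One covariate row per (location, year).
    """
    rng = rng or np.random.default_rng(config.seed)
    p, L, M = config.n_covariates, config.n_locations, config.n_years
    mu = config._vec(config.ec_mu)
    SL = config._mat(config.ec_sigma_L)
    SY = config._mat(config.ec_sigma_Y)
    SLY = config._mat(config.ec_sigma_LY)
    Lx = _mvn(rng, SL, L)
    Yx = _mvn(rng, SY, M)
    LYx = _mvn(rng, SLY, L * M).reshape(L, M, p)
    envs, rows = [], []
    for l in range(L):
        for m in range(M):
            envs.append((config.locations[l], config.years[m]))
            rows.append(mu + Lx[l] + Yx[m] + LYx[l, m])
    ec = ECMatrix(envs, np.array(rows), config.covariates)
    truth = {"mu": mu, "L": Lx, "Y": Yx, "LY": LYx}
    return ec, truth


def _draw_effects(config: SimConfig, rng):
    """All yield-side random effects plus genotype coefficient vectors."""
    I, L, M, p = (config.n_genotypes, config.n_locations, config.n_years,
                  config.n_covariates)
    S = config.genotype_covariance()
    ac = _mvn(rng, S, I)                               # (I, p+1)
    mu_g = config._vec(config.mu_gamma)
    gamma = ac.copy()
    gamma[:, 0] += config.mu_alpha
    gamma[:, 1:] += mu_g
    eff = {
        "gamma": gamma,
        "geno_deviation": ac,
        "L": rng.normal(0, np.sqrt(config.sigma2_L), L),
        "Y": rng.normal(0, np.sqrt(config.sigma2_Y), M),
        "LY": rng.normal(0, np.sqrt(config.sigma2_LY), (L, M)),
        "alphaL": rng.normal(0, np.sqrt(config.sigma2_alphaL), (I, L)),
        "alphaY": rng.normal(0, np.sqrt(config.sigma2_alphaY), (I, M)),
        "alphaLY": rng.normal(0, np.sqrt(config.sigma2_alphaLY), (I, L, M)),
    }
    return eff


def _true_surface(config: SimConfig, ec_std: ECMatrix, eff) -> np.ndarray:
    """Noiseless genotype x environment means (I x J), env order as in ec_std."""
    I = config.n_genotypes
    J = ec_std.n_env
    X1 = np.hstack([np.ones((J, 1)), ec_std.values])
    eta = eff["gamma"] @ X1.T                           # (I, J)
    loc_idx = [config.locations.index(l) for l, _ in ec_std.environments]
    yr_idx = [config.years.index(m) for _, m in ec_std.environments]
    out = eta.copy()
    for j in range(J):
        l, m = loc_idx[j], yr_idx[j]
        out[:, j] += (eff["L"][l] + eff["Y"][m] + eff["LY"][l, m]
                      + eff["alphaL"][:, l] + eff["alphaY"][:, m]
                      + eff["alphaLY"][:, l, m])
    return out


def simulate_met(config: SimConfig, ec_std: ECMatrix,
                 rng: np.random.Generator | None = None):
    """Plot-level records under an RCBD per trial, plus the generating truth.

    ``ec_std`` must be standardized; genotype slopes act on that scale. Block
    effects are drawn once per trial from N(0, 0.05^2); plot errors are iid
    N(0, sigma2_plot).
    """
    if not ec_std.standardized:
        raise ValueError("simulate_met expects a standardized EC matrix")
    rng = rng or np.random.default_rng(config.seed + 1)
    eff = _draw_effects(config, rng)
    surface = _true_surface(config, ec_std, eff)
    I, R = config.n_genotypes, config.n_blocks
    rows = []
    for j, (loc, yr) in enumerate(ec_std.environments):
        b = rng.normal(0, 0.05, R)
        err = rng.normal(0, np.sqrt(config.sigma2_plot), (I, R))
        for i, g in enumerate(config.genotypes):
            for r in range(R):
                rows.append((g, loc, yr, f"B{r + 1}", surface[i, j] + b[r] + err[i, r]))
    plots = PlotRecords(pd.DataFrame(
        rows, columns=["genotype", "location", "year", "block", "yield"]))
    truth = dict(eff)
    truth["surface"] = surface
    truth["varcomps"] = _varcomp_dict(config)
    return plots, truth


def simulate_means(config: SimConfig, ec_std: ECMatrix,
                   rng: np.random.Generator | None = None):
    """Genotype x environment means with the stage-1 sampling noise built in.

    Equivalent to running the plot layer and a balanced stage-1 adjustment:
    means get iid noise with variance sigma2_plot / n_blocks and every record
    carries the matching weight n_blocks / sigma2_plot. Faster than the plot
    route and exact for balanced designs.
    """
    if not ec_std.standardized:
        raise ValueError("simulate_means expects a standardized EC matrix")
    rng = rng or np.random.default_rng(config.seed + 1)
    eff = _draw_effects(config, rng)
    surface = _true_surface(config, ec_std, eff)
    I = config.n_genotypes
    var_mean = config.sigma2_plot / config.n_blocks
    noise = rng.normal(0, np.sqrt(var_mean), surface.shape)
    w = 1.0 / var_mean
    rows = []
    for j, (loc, yr) in enumerate(ec_std.environments):
        for i, g in enumerate(config.genotypes):
            rows.append((g, loc, yr, surface[i, j] + noise[i, j], w))
    means = MetMeans(pd.DataFrame(
        rows, columns=["genotype", "location", "year", "mean", "weight"]))
    truth = dict(eff)
    truth["surface"] = surface
    truth["varcomps"] = _varcomp_dict(config)
    return means, truth


def _varcomp_dict(config: SimConfig) -> dict[str, float]:
    return {
        "L": config.sigma2_L, "Y": config.sigma2_Y, "LY": config.sigma2_LY,
        "alphaL": config.sigma2_alphaL, "alphaY": config.sigma2_alphaY,
        "alphaLY": config.sigma2_alphaLY,
    }
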