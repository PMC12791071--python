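"""Two-way location x year models for environmental covariates.

Decomposes the historical EC process x_lm = mu + L_l + Y_m + (LY)_lm into a
mean vector and location, year and location-year covariance matrices by
multivariate method of moments (MANOVA-style mean cross-product matrices on
the crossed layout). The location-year component absorbs any EC measurement
residual, since there is one observation per location-year cell.

All matrices are returned in the augmented (p+1) form with a leading
intercept row/column of zeros, matching the coefficient vectors
gamma_i' = (alpha_i, gamma_i1, ..., gamma_ip) used for prediction, and are
projected to the nearest positive semidefinite matrix (eigenvalue clipping)
because method-of-moments differences can be indefinite.

Four prediction targets are supported: the long-term mean of the target
population of environments (case 1), a new year at that mean (case 2), the
long-term mean of a new location with EC history (case 3), and a new year at
such a location (case 4). Cases 3 and 4 treat location as a fixed effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .met_data import ECMatrix

__all__ = ["ECDecomposition", "PredictionTarget", "fit_ec_decomposition",
           "make_target", "impute_lylo_xi"]


def _psd_project(M: np.ndarray) -> np.ndarray:
    M = 0.5 * (M + M.T)
    w, U = np.linalg.eigh(M)
    if w.min() >= 0:
        return M
    w = np.clip(w, 0.0, None)
    return (U * w) @ U.T


def _augment(M: np.ndarray) -> np.ndarray:
    """Embed a p x p matrix as (p+1) x (p+1) with zero intercept row/column."""
    p = M.shape[0]
    out = np.zeros((p + 1, p + 1))
    out[1:, 1:] = M
    return out


@dataclass
class ECDecomposition:
    """Estimated two-way decomposition of the EC process.

    ``mu`` is the (p+1)-vector with leading 1; the three Sigma matrices are
    (p+1) x (p+1), symmetric PSD, with zero first row and column. In
    ``fixed_locations`` mode the per-location effect vectors (location mean
    minus grand mean, augmented with a leading 0) are used for prediction and
    Sigma_L plays no role in the target variances.
    """

    mu: np.ndarray
    location_effects: dict[str, np.ndarray]
    Sigma_L: np.ndarray
    Sigma_Y: np.ndarray
    Sigma_LY: np.ndarray
    mode: str
    n_locations: int
    n_years: int
    years_per_location: dict[str, int]

    @property
    def p(self) -> int:
        return len(self.mu) - 1

    def grand_mean_variance(self) -> np.ndarray:
        """Sampling variance of the estimated grand mean mu_x'."""
        L, M = self.n_locations, self.n_years
        V = self.Sigma_L / L + self.Sigma_Y / M + self.Sigma_LY / (L * M)
        return _psd_project(V)

    def location_mean_variance(self, location: str) -> np.ndarray:
        """Sampling variance of the location-mean estimator mu + L(l0)."""
        m = self.years_per_location[str(location)]
        return _psd_project((self.Sigma_Y + self.Sigma_LY) / m)


@dataclass
class PredictionTarget:
    """Plug-in EC vector and its variances for one prediction case."""

    case: int
    xi: np.ndarray                 # (p+1), leading 1
    Sigma_x: np.ndarray            # conditional variance of x' given xi
    xi_variance: np.ndarray        # sampling variance of xi-hat
    location: str | None = None


def fit_ec_decomposition(ec_history: ECMatrix, mode: str = "random_locations"
                         ) -> ECDecomposition:
    """Method-of-moments two-way decomposition of an EC history table.

    Requires at least 2 locations and 2 years. Layouts with a few missing
    location-year cells are handled by computing means over available cells
    (exactly the balanced ANOVA estimator when the layout is complete).
    """
    if mode not in ("random_locations", "fixed_locations"):
        raise ValueError("mode must be 'random_locations' or 'fixed_locations'")
    locs = sorted({l for l, _ in ec_history.environments})
    years = sorted({m for _, m in ec_history.environments})
    L, M = len(locs), len(years)
    if L < 2 or M < 2:
        raise ValueError("EC decomposition needs >= 2 locations and >= 2 years")
    p = ec_history.n_covariates
    X = np.full((L, M, p), np.nan)
    for (l, m), row in zip(ec_history.environments, ec_history.values):
        X[locs.index(l), years.index(m)] = row
    present = ~np.isnan(X[:, :, 0])
    n_cells = int(present.sum())
    if n_cells < L + M:
        raise ValueError("too few location-year cells to separate components")

    loc_means = np.nanmean(X, axis=1)          # (L, p)
    year_means = np.nanmean(X, axis=0)         # (M, p)
    grand = np.nanmean(X.reshape(-1, p), axis=0)

    dl = loc_means - grand
    dy = year_means - grand
    r = X - loc_means[:, None, :] - year_means[None, :, :] + grand
    r = np.where(present[:, :, None], r, 0.0)

    M_L = (dl.T @ dl) * (n_cells / L) / (L - 1)
    M_Y = (dy.T @ dy) * (n_cells / M) / (M - 1)
    df_ly = max(n_cells - L - M + 1, 1)
    M_LY = np.einsum("lmp,lmq->pq", r, r) / df_ly

    # balanced EMS: E[M_L] = M Sigma_L + Sigma_LY, E[M_Y] = L Sigma_Y + Sigma_LY
    m_per_loc = present.sum(axis=1).mean()
    l_per_year = present.sum(axis=0).mean()
    S_LY = _psd_project(M_LY)
    S_L = _psd_project((M_L - S_LY) / m_per_loc)
    S_Y = _psd_project((M_Y - S_LY) / l_per_year)

    mu = np.concatenate([[1.0], grand])
    loc_eff = {
        loc: np.concatenate([[0.0], loc_means[i] - grand])
        for i, loc in enumerate(locs)
    }
    ypl = {loc: int(present[i].sum()) for i, loc in enumerate(locs)}
    return ECDecomposition(
        mu=mu, location_effects=loc_eff,
        Sigma_L=_augment(S_L), Sigma_Y=_augment(S_Y), Sigma_LY=_augment(S_LY),
        mode=mode, n_locations=L, n_years=M, years_per_location=ypl,
    )


def make_target(case: int, dec: ECDecomposition,
                l0: str | None = None) -> PredictionTarget:
    """Plug-in EC expectation and variances for prediction case 1-4.

    Case 1: long-term mean of the TPE (xi = mu, no EC uncertainty beyond
    estimation of mu). Case 2: a new year at the TPE mean (Sigma_x =
    Sigma_Y). Case 3: long-term mean at a new location l0 with EC history
    (xi = mu + L(l0)). Case 4: a new year at such a location (Sigma_x =
    Sigma_Y + Sigma_LY).
    """
    if case not in (1, 2, 3, 4):
        raise ValueError("case must be 1, 2, 3 or 4")
    d = len(dec.mu)
    zero = np.zeros((d, d))
    if case in (1, 2):
        xi = dec.mu.copy()
        xi_var = dec.grand_mean_variance()
        sigma_x = zero if case == 1 else dec.Sigma_Y.copy()
        return PredictionTarget(case, xi, sigma_x, xi_var)
    if dec.mode != "fixed_locations":
        raise ValueError("cases 3 and 4 require a fixed-locations decomposition")
    if l0 is None or str(l0) not in dec.location_effects:
        raise KeyError(f"location {l0!r} has no EC history in the decomposition")
    l0 = str(l0)
    xi = dec.mu + dec.location_effects[l0]
    xi_var = dec.location_mean_variance(l0)
    sigma_x = zero if case == 3 else _psd_project(dec.Sigma_Y + dec.Sigma_LY)
    return PredictionTarget(case, xi, sigma_x, xi_var, location=l0)


def impute_lylo_xi(ec_train: ECMatrix, l0: str) -> np.ndarray:
    """Per-covariate mean over the training years at location ``l0``.

    Returns the (p+1)-vector (1, mean covariates) on the scale of
    ``ec_train``. In a balanced fixed-locations layout this is numerically
    identical to the case-4 plug-in value mu + L(l0).
    """
    l0 = str(l0)
    rows = [x for (l, _), x in zip(ec_train.environments, ec_train.values)
            if l == l0]
    if not rows:
        raise KeyError(f"location {l0!r} absent from the training EC table")
    return np.concatenate([[1.0], np.mean(rows, axis=0)])
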