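"""Trial data model and I/O.

Handles plot-level multi-environment trial (MET) records, the first-stage
adjustment of plot data to weighted genotype means per trial, and the
environment x covariate (EC) table with its standardization metadata.

Environments are identified by (location, year) pairs throughout; a derived
string key ``"location:year"`` is used in outputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Cap applied to inverse-variance weights when the stage-1 residual variance
#: is (near) zero, to avoid infinite weights destabilizing the second stage.
DEFAULT_MAX_WEIGHT = 1e8

PLOT_COLUMNS = ("genotype", "location", "year", "block", "yield")
MEANS_COLUMNS = ("genotype", "location", "year", "mean", "weight")


class FormatError(ValueError):
    """Raised when an input table does not have the expected layout."""


def env_key(location: str, year: str) -> str:
    return f"{location}:{year}"


# ---------------------------------------------------------------------------
# Plot-level records
# ---------------------------------------------------------------------------

@dataclass
class PlotRecords:
    """Plot-level yield records: one row per (genotype, location, year, block)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PLOT_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"plot table is missing columns: {missing}")
        df = self.data.loc[:, list(PLOT_COLUMNS)].copy()
        for c in ("genotype", "location", "year", "block"):
            df[c] = df[c].astype(str)
        df["yield"] = pd.to_numeric(df["yield"], errors="coerce")
        bad = df.index[~np.isfinite(df["yield"].to_numpy(float))]
        if len(bad):
            raise FormatError(f"non-finite or non-numeric yield at rows {list(bad[:5])}")
        dup = df.duplicated(subset=["genotype", "location", "year", "block"])
        if dup.any():
            key = df.loc[dup.idxmax(), ["genotype", "location", "year", "block"]]
            raise FormatError(f"duplicate plot record for {tuple(key)}")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def trials(self) -> list[tuple[str, str]]:
        """Distinct (location, year) trials present."""
        return sorted(set(zip(self.data["location"], self.data["year"])))


def read_plot_csv(path, column_map: dict[str, str] | None = None) -> PlotRecords:
    """Read plot records from a headered CSV.

    ``column_map`` maps the canonical names (genotype, location, year, block,
    yield) to the column names used in the file.
    """
    df = pd.read_csv(path, dtype=str)
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    return PlotRecords(df)


def write_plot_csv(plots: PlotRecords, path) -> None:
    plots.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Genotype x environment means (stage-2 response)
# ---------------------------------------------------------------------------

@dataclass
class MetMeans:
    """Adjusted genotype means per environment with inverse-variance weights."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MEANS_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"means table is missing columns: {missing}")
        df = self.data.loc[:, list(MEANS_COLUMNS)].copy()
        for c in ("genotype", "location", "year"):
            df[c] = df[c].astype(str)
        df["mean"] = pd.to_numeric(df["mean"])
        df["weight"] = pd.to_numeric(df["weight"])
        if (df["weight"] <= 0).any():
            raise FormatError("weights must be strictly positive")
        dup = df.duplicated(subset=["genotype", "location", "year"])
        if dup.any():
            key = df.loc[dup.idxmax(), ["genotype", "location", "year"]]
            raise FormatError(f"duplicate mean record for {tuple(key)}")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def environments(self) -> list[tuple[str, str]]:
        return sorted(set(zip(self.data["location"], self.data["year"])))

    def genotypes(self) -> list[str]:
        return sorted(set(self.data["genotype"]))

    def filter_min_years(self, min_years: int) -> "MetMeans":
        """Drop genotypes tested in fewer than ``min_years`` distinct years."""
        nyears = self.data.groupby("genotype")["year"].nunique()
        keep = set(nyears.index[nyears >= min_years])
        return MetMeans(self.data[self.data["genotype"].isin(keep)].copy())


def read_means_csv(path) -> MetMeans:
    return MetMeans(pd.read_csv(path, dtype={"genotype": str, "location": str, "year": str}))


def write_means_csv(means: MetMeans, path) -> None:
    means.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Stage-1 adjustment
# ---------------------------------------------------------------------------

def stage1_adjust_trial(
    plots: PlotRecords,
    location: str,
    year: str,
    max_weight: float = DEFAULT_MAX_WEIGHT,
) -> pd.DataFrame:
    """Least-squares genotype means for one trial under ``mu + block + genotype``.

    Returns a means-table fragment (genotype, location, year, mean, weight),
    where the mean is the adjusted genotype mean (genotype LS-mean, i.e. the
    estimate of ``mu + g_i`` averaged over blocks) and the weight is the
    inverse of its estimated variance.
    """
    sub = plots.data[(plots.data["location"] == location) & (plots.data["year"] == year)]
    if sub.empty:
        raise ValueError(f"no plots for trial ({location}, {year})")
    genos = sorted(sub["genotype"].unique())
    blocks = sorted(sub["block"].unique())
    if len(blocks) < 2:
        raise ValueError(f"trial ({location}, {year}) has fewer than 2 blocks")
    if len(genos) < 2:
        raise ValueError(f"trial ({location}, {year}) has fewer than 2 genotypes")

    n = len(sub)
    gi = pd.Categorical(sub["genotype"], categories=genos).codes
    bi = pd.Categorical(sub["block"], categories=blocks).codes
    I, R = len(genos), len(blocks)
    # full-rank design: intercept, blocks 2..R (reference coding), genotypes 2..I
    X = np.zeros((n, 1 + (R - 1) + (I - 1)))
    X[:, 0] = 1.0
    for r in range(1, R):
        X[bi == r, r] = 1.0
    for g in range(1, I):
        X[gi == g, R - 1 + g] = 1.0
    y = sub["yield"].to_numpy(float)

    rank = np.linalg.matrix_rank(X)
    df_resid = n - rank
    if df_resid <= 0:
        raise ValueError(
            f"trial ({location}, {year}) has zero residual degrees of freedom"
        )
    XtX = X.T @ X
    XtXi = np.linalg.pinv(XtX)
    beta = XtXi @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / df_resid

    rows = []
    for g in range(I):
        # LS-mean contrast: intercept + mean of block effects + genotype effect
        k = np.zeros(X.shape[1])
        k[0] = 1.0
        k[1:R] = 1.0 / R  # each non-reference block dummy enters the block average with 1/R
        if g > 0:
            k[R - 1 + g] = 1.0
        mean = float(k @ beta)
        var = sigma2 * float(k @ XtXi @ k)
        if var <= 1.0 / max_weight:
            logger.warning(
                "trial (%s, %s): near-zero variance for genotype %s; capping weight",
                location, year, genos[g],
            )
            weight = max_weight
        else:
            weight = 1.0 / var
        rows.append((genos[g], location, year, mean, weight))
    return pd.DataFrame(rows, columns=list(MEANS_COLUMNS))


def stage1_adjust(plots: PlotRecords, max_weight: float = DEFAULT_MAX_WEIGHT) -> MetMeans:
    """Apply the stage-1 adjustment to every trial in ``plots``."""
    frames = [
        stage1_adjust_trial(plots, loc, yr, max_weight=max_weight)
        for loc, yr in plots.trials()
    ]
    return MetMeans(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# EC matrix
# ---------------------------------------------------------------------------

@dataclass
class ECMatrix:
    """Environment x covariate matrix with standardization metadata.

    ``values`` has one row per environment in ``environments`` (a list of
    (location, year) pairs). After :func:`standardize_ec`, ``centers`` and
    ``scales`` record the training-set column means and sample SDs so the same
    affine map can be applied to held-out environments.
    """

    environments: list[tuple[str, str]]
    values: np.ndarray
    column_names: list[str]
    centers: np.ndarray | None = None
    scales: np.ndarray | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.environments = [(str(l), str(m)) for l, m in self.environments]
        if self.values.ndim != 2 or self.values.shape[0] != len(self.environments):
            raise FormatError("EC matrix must have one row per environment")
        if self.values.shape[1] != len(self.column_names):
            raise FormatError("EC matrix column count does not match names")
        if len(set(self.environments)) != len(self.environments):
            raise FormatError("duplicate environment rows in EC matrix")

    @property
    def n_env(self) -> int:
        return self.values.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]

    def row(self, location: str, year: str) -> np.ndarray:
        try:
            j = self.environments.index((str(location), str(year)))
        except ValueError:
            raise KeyError(f"environment ({location}, {year}) not in EC matrix") from None
        return self.values[j]

    def subset(self, environments: list[tuple[str, str]]) -> "ECMatrix":
        idx = [self.environments.index((str(l), str(m))) for l, m in environments]
        return ECMatrix(
            [self.environments[j] for j in idx],
            self.values[idx],
            list(self.column_names),
            None if self.centers is None else self.centers.copy(),
            None if self.scales is None else self.scales.copy(),
            self.standardized,
        )

    def apply_standardization(self, x: np.ndarray) -> np.ndarray:
        """Map raw covariate rows onto the stored standardized scale."""
        if self.centers is None or self.scales is None:
            raise ValueError("EC matrix has no stored standardization metadata")
        return (np.asarray(x, float) - self.centers) / self.scales

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df.insert(0, "location", [l for l, _ in self.environments])
        df.insert(1, "year", [m for _, m in self.environments])
        return df


def standardize_ec(ec: ECMatrix) -> ECMatrix:
    """Center and scale every covariate column to mean 0, sample SD 1.

    Idempotent: standardizing an already standardized matrix recomputes
    (numerically trivial) centers/scales against the same rows. The original
    centers and scales are stored so held-out environments can be mapped onto
    the training scale with :meth:`ECMatrix.apply_standardization`.
    """
    if ec.n_env < 2:
        raise ValueError("standardization needs at least 2 environments")
    centers = ec.values.mean(axis=0)
    scales = ec.values.std(axis=0, ddof=1)
    const = np.flatnonzero(scales == 0)
    if len(const):
        names = [ec.column_names[k] for k in const]
        raise ValueError(f"constant covariate column(s): {names}")
    values = (ec.values - centers) / scales
    if ec.standardized:
        # compose with the previous affine map so raw rows still standardize
        centers = ec.centers + centers * ec.scales
        scales = ec.scales * scales
    return ECMatrix(
        list(ec.environments), values, list(ec.column_names), centers, scales, True
    )


def read_ec_csv(path) -> ECMatrix:
    """Read a wide EC table: location, year, then one column per covariate."""
    df = pd.read_csv(path)
    if "location" not in df.columns or "year" not in df.columns:
        raise FormatError("EC table must have 'location' and 'year' columns")
    covs = [c for c in df.columns if c not in ("location", "year")]
    if not covs:
        raise FormatError("EC table has no covariate columns")
    envs = list(zip(df["location"].astype(str), df["year"].astype(str)))
    return ECMatrix(envs, df[covs].to_numpy(float), covs)


def write_ec_csv(ec: ECMatrix, path) -> None:
    ec.to_frame().to_csv(path, index=False)
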