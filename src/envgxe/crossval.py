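"""Leave-one-environment-out (LOEO) and leave-year-and-location-out (LYLO)
cross-validation of the second-stage models.

LOEO plugs the held-out environment's observed covariates into the fitted
model and adds every BLUP that is available for that environment (genotype
main effect and slopes, location and year main effects, genotype x location
and genotype x year interactions) — only the location-year and three-way
effects are unknown. Covariates are standardized once on the full table.

LYLO mimics prediction into an unseen environment: the held-out environment's
covariates are replaced by the location's mean over training years, no
year- or location-linked BLUPs are used, and the model-based prediction
variance is computed with the case-4 machinery (Sigma_Y + Sigma_LY and all
six deviation components). Standardization is repeated inside every fold.
By default only the held-out (location, year) pair is removed from training;
``strict=True`` removes every environment sharing the held-out year or
location (a sensitivity analysis, since the location's remaining EC history
is still used for imputation).

Metrics per environment: Pearson correlation (PCC), mean squared prediction
error (MSPE), mean squared error of predicted differences (MSEPD), mean
model-based variance of predictions (MVP) and the average variance of a
predicted difference (VPD); aggregated as means and medians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ec_model import PredictionTarget, fit_ec_decomposition, impute_lylo_xi, make_target
from .gxe_models import DEVIATION_TERMS, GxeModelKind, build_model
from .lmm_engine import ConvergenceError
from .met_data import ECMatrix, MetMeans, env_key, standardize_ec
from .prediction import GenotypeCoefficients, average_vpd, predict

logger = logging.getLogger(__name__)

__all__ = ["CvFold", "CvReport", "split", "predict_fold", "metrics", "run_cv"]


@dataclass
class CvFold:
    held_out: tuple[str, str]
    train_means: MetMeans
    train_ec: ECMatrix             # standardized per scheme
    test_means: MetMeans
    scheme: str
    full_ec: ECMatrix | None = None  # raw table (for LYLO location history)


@dataclass
class CvReport:
    per_environment: pd.DataFrame
    aggregates: pd.DataFrame
    failed_folds: list[str]

    def to_dict(self) -> dict:
        return {
            "aggregates": {
                f"{stat}_{col}": (None if pd.isna(v) else float(v))
                for stat, row in self.aggregates.iterrows()
                for col, v in row.items()
            },
            "n_folds": int(len(self.per_environment)),
            "failed_folds": self.failed_folds,
        }


def split(met: MetMeans, ec: ECMatrix, scheme: str,
          strict: bool = False) -> list[CvFold]:
    """One fold per environment; held-out records never appear in training."""
    if scheme not in ("loeo", "lylo"):
        raise ValueError("scheme must be 'loeo' or 'lylo'")
    envs = met.environments()
    if len(envs) < 3:
        raise ValueError("cross-validation needs at least 3 environments")
    ec_global = standardize_ec(ec) if scheme == "loeo" else None
    folds = []
    df = met.data
    for l0, m0 in envs:
        mask = (df["location"] == l0) & (df["year"] == m0)
        test = df[mask]
        if test["genotype"].nunique() < 2:
            logger.warning("skipping fold %s: fewer than 2 genotypes", env_key(l0, m0))
            continue
        if scheme == "lylo" and strict:
            train = df[(df["location"] != l0) & (df["year"] != m0)]
        else:
            train = df[~mask]
        train_means = MetMeans(train.copy())
        train_envs = train_means.environments()
        if scheme == "loeo":
            train_ec = ec_global.subset(train_envs)
        else:
            train_ec = standardize_ec(ec.subset(train_envs))
        folds.append(CvFold((l0, m0), train_means, train_ec,
                            MetMeans(test.copy()), scheme, full_ec=ec))
    return folds


def _loeo_predict(fold: CvFold, model, fit, ec_global: ECMatrix) -> pd.DataFrame:
    l0, m0 = fold.held_out
    x0 = ec_global.values[ec_global.environments.index((l0, m0))]
    coeffs = GenotypeCoefficients.from_fit(fit, model)
    if coeffs.scale == "sc":
        z = (model.sc.loadings.T @ x0 - model.sc_centers) / model.sc_scales
        xi = np.concatenate([[1.0], z])
    else:
        xi = np.concatenate([[1.0], x0])
    base = coeffs.gamma @ xi
    # environment-linked BLUPs available under LOEO
    blups = fit.blups
    terms = {t.label: t for t in fit.spec.terms}
    adj = 0.0
    if l0 in model.locations:
        adj += float(blups["L"][model.locations.index(l0), 0])
    if m0 in model.years:
        adj += float(blups["Y"][model.years.index(m0), 0])
    pred = base + adj
    for i, g in enumerate(model.genotypes):
        if l0 in model.locations:
            gl = terms["alphaL"].group_labels.index(f"{g}:{l0}")
            pred[i] += float(blups["alphaL"][gl, 0])
        if m0 in model.years:
            gy = terms["alphaY"].group_labels.index(f"{g}:{m0}")
            pred[i] += float(blups["alphaY"][gy, 0])
    return pd.DataFrame({"genotype": model.genotypes, "predicted": pred,
                         "variance": np.nan, "vpd": np.nan})


def _lylo_predict(fold: CvFold, model, fit) -> pd.DataFrame:
    l0, _ = fold.held_out
    # location EC history on the fold's standardized scale
    hist_envs = [e for e in fold.full_ec.environments
                 if e in fold.train_ec.environments or
                 (e[0] == l0 and e != fold.held_out)]
    raw = fold.full_ec.subset(hist_envs)
    std_values = fold.train_ec.apply_standardization(raw.values)
    ec_hist = ECMatrix(hist_envs, std_values, list(raw.column_names),
                       fold.train_ec.centers, fold.train_ec.scales, True)
    dec = fit_ec_decomposition(ec_hist, mode="fixed_locations")
    target = make_target(4, dec, l0)
    coeffs = GenotypeCoefficients.from_fit(fit, model)
    res = predict(fit, coeffs, target, model=model)
    out = res.table[["genotype", "eta_hat", "upsilon_total"]].rename(
        columns={"eta_hat": "predicted", "upsilon_total": "variance"})
    out["vpd"] = res.average_vpd
    return out


def predict_fold(fold: CvFold, kind: GxeModelKind,
                 start: np.ndarray | None = None) -> pd.DataFrame:
    """Fit the model on the fold's training data and predict the held-out env.

    Returns one row per genotype present in the held-out environment with
    observed and predicted values (and, for LYLO, the model-based prediction
    variance and average VPD). ``start`` warm-starts the fold fit, typically
    from the full-data fit of the same model.
    """
    model = build_model(kind, fold.train_means, fold.train_ec)
    fit = model.fit(start=start)
    if fold.scheme == "loeo":
        # train_ec is a subset of the single global standardization; map the
        # held-out row onto the same scale
        raw_x0 = fold.full_ec.row(*fold.held_out)
        x0_std = fold.train_ec.apply_standardization(raw_x0)
        ec0 = ECMatrix([fold.held_out], x0_std[None, :],
                       list(fold.train_ec.column_names),
                       fold.train_ec.centers, fold.train_ec.scales, True)
        preds = _loeo_predict(fold, model, fit, ec0)
    else:
        preds = _lylo_predict(fold, model, fit)
    obs = fold.test_means.data[["genotype", "mean"]].rename(columns={"mean": "observed"})
    out = obs.merge(preds, on="genotype", how="inner")
    out.insert(0, "environment", env_key(*fold.held_out))
    return out


def metrics(results: pd.DataFrame) -> CvReport:
    """Per-environment PCC/MSPE/MSEPD/MVP/VPD and mean/median aggregates.

    ``results`` must have columns environment, genotype, observed, predicted
    and (optionally) variance and vpd.
    """
    rows = []
    for env, sub in results.groupby("environment", sort=True):
        y = sub["observed"].to_numpy(float)
        yhat = sub["predicted"].to_numpy(float)
        I = len(y)
        f = y - yhat
        mspe = float(np.sum(f ** 2) / I)
        msepd = float(2.0 * np.sum((f - f.mean()) ** 2) / (I - 1)) if I > 1 else np.nan
        if I > 1 and np.std(y) > 0 and np.std(yhat) > 0:
            pcc = float(np.corrcoef(y, yhat)[0, 1])
        else:
            pcc = np.nan
        mvp = float(sub["variance"].mean()) if "variance" in sub else np.nan
        vpd = float(sub["vpd"].mean()) if "vpd" in sub else np.nan
        rows.append((env, I, pcc, mspe, msepd, mvp, vpd))
    per_env = pd.DataFrame(rows, columns=["environment", "n_genotypes", "pcc",
                                          "mspe", "msepd", "mvp", "vpd"])
    cols = ["pcc", "mspe", "msepd", "mvp", "vpd"]
    agg = pd.DataFrame(
        [per_env[cols].mean(), per_env[cols].median()],
        index=["mean", "median"],
    )
    return CvReport(per_environment=per_env, aggregates=agg, failed_folds=[])


def run_cv(met: MetMeans, ec: ECMatrix, kind: GxeModelKind, scheme: str,
           strict: bool = False) -> CvReport:
    """Full cross-validation of one model under one scheme.

    The model is first fitted once to the complete data; its variance
    parameters serve as starting values for every fold, which stabilizes and
    speeds up the per-fold fits.
    """
    folds = split(met, ec, scheme, strict=strict)
    try:
        ec_full = standardize_ec(ec)
        start = build_model(kind, met, ec_full).fit().theta
    except ConvergenceError:
        start = None
    frames, failed = [], []
    for fold in folds:
        try:
            frames.append(predict_fold(fold, kind, start=start))
        except ConvergenceError as exc:
            logger.warning("fold %s failed to converge: %s",
                           env_key(*fold.held_out), exc)
            failed.append(env_key(*fold.held_out))
    if not frames:
        raise RuntimeError("every cross-validation fold failed")
    report = metrics(pd.concat(frames, ignore_index=True))
    report.failed_folds = failed
    return report
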