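import numpy as np
import pytest

from envgxe import (
    GxeModelKind, SimConfig, build_model, simulate_ec, simulate_means,
    standardize_ec,
)


@pytest.fixture(scope="session")
def small_world():
    """A small kernel-generated MET: means, standardized ECs, config, truth."""
    cfg = SimConfig(n_genotypes=8, n_locations=3, n_years=4, n_covariates=2,
                    seed=101, kind=GxeModelKind("kernel"), sigma2_gamma=0.05)
    ec, _ = simulate_ec(cfg)
    ecs = standardize_ec(ec)
    means, truth = simulate_means(cfg, ecs)
    return {"cfg": cfg, "ec_raw": ec, "ec": ecs, "means": means, "truth": truth}


@pytest.fixture(scope="session")
def rfr_fit(small_world):
    """A converged RFR fit (with coefficient machinery) reused across tests."""
    model = build_model(GxeModelKind("rfr"), small_world["means"],
                        small_world["ec"])
    fit = model.fit()
    return model, fit


def true_theta(cfg: SimConfig, spec):
    """Pack the generating variance parameters for a spec built on cfg data."""
    vals = {
        "L": cfg.sigma2_L, "Y": cfg.sigma2_Y, "LY": cfg.sigma2_LY,
        "alphaL": cfg.sigma2_alphaL, "alphaY": cfg.sigma2_alphaY,
        "alphaLY": cfg.sigma2_alphaLY, "genotype": cfg.sigma2_alpha,
    }
    per = []
    for t in spec.terms:
        st = t.structure
        if t.label in vals:
            per.append(st.theta_from_variance(vals[t.label]))
        elif t.label == "geno_slopes":
            per.append(st.theta_from_variance(cfg.sigma2_gamma))
        elif t.label == "geno_regression":
            if st.kind == "reduced_rank":
                per.append(st.theta_from_loadings(np.asarray(cfg.lam, float)))
            else:
                per.append(st.theta_from_cov(cfg.genotype_covariance()))
        else:
            raise KeyError(t.label)
    return spec.pack_theta(per)
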