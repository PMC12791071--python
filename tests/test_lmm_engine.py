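import numpy as np
import pytest

from envgxe.lmm_engine import (
    Convergence, FitResult, FixedKernel, ModelSpec, RandomTerm, ReducedRank,
    ScaledIdentity, Unstructured, _DenseEvaluator, _GridEvaluator, aic,
    profile_loglik, reml_fit,
)
from envgxe.gxe_models import GxeModelKind, build_model

from conftest import true_theta


def _oneway_spec(y, g, npg):
    groups = np.repeat(np.arange(g), npg)
    return ModelSpec(y=y, weights=np.ones(g * npg), W=np.ones((g * npg, 1)),
                     fixed_names=["intercept"],
                     terms=[RandomTerm("group", ScaledIdentity(1), groups,
                                       np.ones((g * npg, 1)))],
                     residual="free")


def _fixed_theta_fit(spec, theta):
    """FitResult at user-supplied parameters (no optimization)."""
    conv = Convergence(True, 0, 0, 0.0, [], "fixed parameters")
    return FitResult(spec, np.asarray(theta, float), 0.0, conv, "dense")


class TestRemlBasics:
    def test_oneway_matches_ems_closed_form(self):
        rng = np.random.default_rng(1)
        g, npg = 5, 4
        u = rng.normal(0, 1.0, g)
        y = 2.0 + np.repeat(u, npg) + rng.normal(0, 0.7, g * npg)
        fit = reml_fit(_oneway_spec(y, g, npg))
        Y = y.reshape(g, npg)
        mse = ((Y - Y.mean(1, keepdims=True)) ** 2).sum() / (g * (npg - 1))
        msb = npg * ((Y.mean(1) - y.mean()) ** 2).sum() / (g - 1)
        assert np.isclose(fit.residual_variance, mse, rtol=1e-4)
        assert np.isclose(fit.variance_estimates["group"]["variance"],
                          (msb - mse) / npg, rtol=1e-4)
        assert np.isclose(fit.fixed_estimates[0], y.mean(), atol=1e-8)

    def test_identical_group_means_boundary(self):
        g, npg = 4, 3
        y = np.tile(np.array([1.0, 2.0, 3.0]), g)  # same within-group pattern
        fit = reml_fit(_oneway_spec(y, g, npg))
        assert "group" in fit.convergence.boundary_terms
        assert fit.variance_estimates["group"]["variance"] < 1e-6

    def test_optimum_beats_generating_parameters(self, small_world):
        model = build_model(GxeModelKind("kernel"), small_world["means"],
                            small_world["ec"])
        fit = model.fit()
        th_true = true_theta(small_world["cfg"], model.spec)
        assert fit.reml_loglik >= profile_loglik(model.spec, th_true) - 1e-6

    def test_monotone_loglik_trace(self, small_world):
        model = build_model(GxeModelKind("kernel"), small_world["means"],
                            small_world["ec"])
        fit = model.fit(cascade=False)
        trace = np.array(fit.convergence.trace)
        assert np.all(np.diff(trace) >= -1e-8)


class TestProfileLoglik:
    def test_single_observation_conventions(self):
        spec = ModelSpec(y=np.array([1.3]), weights=np.array([1.0]),
                         W=np.ones((1, 1)), fixed_names=["intercept"],
                         terms=[], residual="fixed")
        fit = reml_fit(spec)
        # REML with (n - f) log 2pi convention: zero for a saturated model
        assert np.isclose(fit.reml_loglik, 0.0, atol=1e-12)
        # the ML likelihood at the GLS solution is the N(y; mu_hat, 1) profile
        assert np.isclose(fit.full_loglik, -0.5 * np.log(2 * np.pi), atol=1e-12)

    def test_vanishing_random_variance_is_weighted_ols(self):
        rng = np.random.default_rng(7)
        n = 12
        w = rng.uniform(0.5, 2.0, n)
        y = rng.normal(3, 1, n)
        W = np.column_stack([np.ones(n), rng.normal(size=n)])
        groups = np.arange(n) % 3
        spec = ModelSpec(y=y, weights=w, W=W, fixed_names=["b0", "b1"],
                         terms=[RandomTerm("g", ScaledIdentity(1), groups,
                                           np.ones((n, 1)))],
                         residual="fixed")
        ll = profile_loglik(spec, np.array([np.log(1e-14)]))
        # closed-form weighted-OLS REML loglik (residual fixed at 1/w)
        V = np.diag(1 / w)
        Vi = np.diag(w)
        Q, _ = np.linalg.qr(W)
        M = Q.T @ Vi @ Q
        beta = np.linalg.solve(W.T @ Vi @ W, W.T @ Vi @ y)
        r = y - W @ beta
        expected = -0.5 * ((n - 2) * np.log(2 * np.pi)
                           + np.log(np.linalg.det(V))
                           + np.log(np.linalg.det(M)) + r @ Vi @ r)
        assert np.isclose(ll, expected, atol=1e-6)

    def test_singular_covariance_raises(self):
        spec = ModelSpec(y=np.array([1.0, 2.0]), weights=np.array([1.0, 1.0]),
                         W=np.ones((2, 1)), fixed_names=["intercept"],
                         terms=[], residual="free")
        with pytest.raises(np.linalg.LinAlgError):
            profile_loglik(spec, np.array([-2000.0]))

    def test_invariance_to_row_and_term_order(self, small_world):
        model = build_model(GxeModelKind("kernel"), small_world["means"],
                            small_world["ec"])
        spec = model.spec
        th = true_theta(small_world["cfg"], spec)
        base = profile_loglik(spec, th, use_grid=False)
        rng = np.random.default_rng(0)
        perm = rng.permutation(spec.n)
        spec_p = ModelSpec(
            y=spec.y[perm], weights=spec.weights[perm], W=spec.W[perm],
            fixed_names=spec.fixed_names,
            terms=[RandomTerm(t.label, t.structure, t.groups[perm], t.u[perm])
                   for t in spec.terms],
            residual="fixed")
        assert np.isclose(profile_loglik(spec_p, th), base, atol=1e-8)
        order = rng.permutation(len(spec.terms))
        per, _ = spec.split_theta(th)
        spec_t = ModelSpec(y=spec.y, weights=spec.weights, W=spec.W,
                           fixed_names=spec.fixed_names,
                           terms=[spec.terms[k] for k in order],
                           residual="fixed")
        th_t = spec_t.pack_theta([per[k] for k in order])
        assert np.isclose(profile_loglik(spec_t, th_t, use_grid=False), base,
                          atol=1e-8)


class TestGridPath:
    def test_grid_matches_dense_at_random_parameters(self, small_world):
        for name, q in [("kernel", None), ("rrr", 1), ("rfr", None),
                        ("baseline", None)]:
            model = build_model(GxeModelKind(name, q=q), small_world["means"],
                                small_world["ec"])
            spec = model.spec
            assert _GridEvaluator.supports(spec)
            rng = np.random.default_rng(3)
            ge, de = _GridEvaluator(spec), _DenseEvaluator(spec)
            for _ in range(3):
                th = rng.normal(-1.5, 0.5, spec.n_theta())
                assert np.isclose(ge.neg2_reml(th), de.neg2_reml(th),
                                  rtol=1e-10, atol=1e-8)

    def test_grid_refused_for_unbalanced_data(self, small_world):
        from envgxe.met_data import MetMeans
        df = small_world["means"].data.iloc[:-1]  # drop one record
        model = build_model(GxeModelKind("kernel"), MetMeans(df.copy()),
                            small_world["ec"])
        assert not _GridEvaluator.supports(model.spec)
        fit = model.fit(cascade=False)
        assert fit.path == "dense"


class TestSolutionsAndCInverse:
    def test_blue_blup_match_explicit_mme(self, small_world):
        """GLS-based BLUEs/BLUPs equal the mixed-model-equations solution."""
        model = build_model(GxeModelKind("kernel"), small_world["means"],
                            small_world["ec"])
        spec = model.spec
        th = true_theta(small_world["cfg"], spec)
        fit = _fixed_theta_fit(spec, th)
        n = spec.n
        Rinv = np.diag(spec.weights)
        Zs, Gs = [], []
        per, _ = spec.split_theta(th)
        for t, p in zip(spec.terms, per):
            d = t.structure.dim
            Z = np.zeros((n, t.n_groups * d))
            for k in range(d):
                Z[np.arange(n), t.groups * d + k] = t.u[:, k]
            Zs.append(Z)
            Gs.append(np.kron(np.eye(t.n_groups), t.structure.cov(p)))
        Z = np.hstack(Zs)
        from scipy.linalg import block_diag
        G = block_diag(*Gs)
        W = spec.W
        C = np.block([[W.T @ Rinv @ W, W.T @ Rinv @ Z],
                      [Z.T @ Rinv @ W, Z.T @ Rinv @ Z + np.linalg.inv(G)]])
        rhs = np.concatenate([W.T @ Rinv @ spec.y, Z.T @ Rinv @ spec.y])
        sol = np.linalg.solve(C, rhs)
        f = W.shape[1]
        assert np.allclose(fit.fixed_estimates, sol[:f], atol=1e-8)
        u_hat = np.concatenate([fit.blups[t.label].ravel() for t in spec.terms])
        assert np.allclose(u_hat, sol[f:], atol=1e-8)
        # C-inverse equals the inverse MME coefficient matrix (nonsingular G)
        assert np.allclose(fit.c_inverse, np.linalg.inv(C), atol=1e-8)

    def test_c_inverse_fixed_effects_only(self):
        rng = np.random.default_rng(5)
        n = 10
        w = rng.uniform(0.5, 3, n)
        W = np.column_stack([np.ones(n), rng.normal(size=n)])
        spec = ModelSpec(y=rng.normal(size=n), weights=w, W=W,
                         fixed_names=["b0", "b1"], terms=[], residual="fixed")
        fit = _fixed_theta_fit(spec, np.zeros(0))
        assert np.allclose(fit.c_inverse,
                           np.linalg.inv(W.T @ np.diag(w) @ W), atol=1e-10)

    def test_singular_g_matches_factor_parameterized_mme(self):
        """Reduced-rank G: joint covariance equals the nonsingular MME in the
        factor scores v (u = Lambda v), mapped back to the u scale."""
        rng = np.random.default_rng(3)
        n, g, d = 30, 5, 3
        groups = np.repeat(np.arange(g), n // g)
        u = rng.normal(size=(n, d))
        lam = np.array([0.5, 0.3, -0.2])
        spec = ModelSpec(y=rng.normal(size=n), weights=np.ones(n),
                         W=np.ones((n, 1)), fixed_names=["intercept"],
                         terms=[RandomTerm("rr", ReducedRank(d, 1), groups, u)],
                         residual="free")
        th = spec.pack_theta([lam], resvar=0.8)
        fit = _fixed_theta_fit(spec, th)
        Z = np.zeros((n, g * d))
        for k in range(d):
            Z[np.arange(n), groups * d + k] = u[:, k]
        Zv = Z @ np.kron(np.eye(g), lam[:, None])
        Rinv = np.eye(n) / 0.8
        W = spec.W
        Cv = np.block([[W.T @ Rinv @ W, W.T @ Rinv @ Zv],
                       [Zv.T @ Rinv @ W, Zv.T @ Rinv @ Zv + np.eye(g)]])
        T = np.block([[np.eye(1), np.zeros((1, g))],
                      [np.zeros((g * d, 1)), np.kron(np.eye(g), lam[:, None])]])
        expected = T @ np.linalg.inv(Cv) @ T.T
        assert np.allclose(fit.c_inverse, expected, atol=1e-10)
        # and the factor system satisfies the g-inverse defining relation
        Mv = np.linalg.inv(Cv)
        assert np.allclose(Cv @ Mv @ Cv, Cv, atol=1e-8)


class TestStructures:
    @pytest.mark.parametrize("structure,nfree", [
        (ScaledIdentity(3), 1),
        (Unstructured(4), 10),
        (ReducedRank(5, 2), 9),
        (FixedKernel(np.eye(3) + 0.5), 1),
    ])
    def test_psd_at_random_parameters(self, structure, nfree):
        rng = np.random.default_rng(11)
        assert structure.n_free == nfree
        for _ in range(10):
            th = rng.normal(0, 1.5, structure.n_free)
            cov = structure.cov(th)
            F = structure.factor(th)
            assert np.allclose(cov, cov.T, atol=1e-12)
            assert np.allclose(F @ F.T, cov, atol=1e-10)
            assert np.linalg.eigvalsh(cov).min() > -1e-10

    def test_reduced_rank_zero_pattern_and_sign(self):
        st = ReducedRank(4, 2)
        th = np.arange(1.0, 1.0 + st.n_free)
        lam = st.loadings(th)
        assert lam[0, 1] == 0.0  # identification zero (h > k)
        th2 = -th
        canon = st.canonical_loadings(th2)
        assert canon[0, 0] > 0  # sign fixed on the first free loading

    def test_unstructured_roundtrip(self):
        st = Unstructured(3)
        sigma = np.array([[2.0, 0.3, -0.1], [0.3, 1.0, 0.2], [-0.1, 0.2, 0.5]])
        assert np.allclose(st.cov(st.theta_from_cov(sigma)), sigma, atol=1e-12)


class TestAic:
    def test_aic_definition_and_sp_adjustment(self, small_world):
        model = build_model(GxeModelKind("baseline"), small_world["means"],
                            small_world["ec"])
        fit = model.fit()
        k = fit.n_var_params + fit.n_fixed_params
        assert np.isclose(aic(fit, sp=0), -2 * fit.full_loglik + 2 * k)
        assert np.isclose(aic(fit, sp=8) - aic(fit, sp=0), 16.0)
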