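import numpy as np
import pandas as pd
import pytest

from phenogp.mm import (FAKronecker, GRM, IIDGroup, KnownMatrix,
                        KroneckerRegression, MixedModel, bend_psd,
                        vanraden_grm)


class Markers:
    def __init__(self, D):
        self.dosage = np.asarray(D, float)
        self.genotypes = [f"G{i}" for i in range(self.dosage.shape[0])]


# ---------------------------------------------------------------------------
# VanRaden GRM
# ---------------------------------------------------------------------------

def test_vanraden_hand_example():
    D = np.array([[0.0, 2.0], [2.0, 0.0], [1.0, 1.0]])
    g = vanraden_grm(Markers(D))
    p = np.array([0.5, 0.5])
    Z = D - 1.0
    K = Z @ Z.T / (2 * np.sum(p * (1 - p)))
    np.testing.assert_allclose(g.K, K, atol=1e-12)


def test_vanraden_identical_genotypes_equal_rows():
    D = np.array([[0, 2, 1, 0], [0, 2, 1, 0], [2, 0, 1, 2]], float)
    g = vanraden_grm(Markers(D))
    np.testing.assert_allclose(g.K[0], g.K[1])
    assert g.K[0, 0] == pytest.approx(g.K[0, 1])


def test_vanraden_hwe_diagonal_near_one(rng):
    p = rng.uniform(0.1, 0.9, 5000)
    D = rng.binomial(2, p, size=(40, 5000)).astype(float)
    g = vanraden_grm(Markers(D))
    assert abs(g.mean_diag - 1.0) < 0.05


def test_vanraden_monomorphic_error():
    with pytest.raises(ValueError, match="polymorphic"):
        vanraden_grm(Markers(np.full((5, 12), 2.0)))


def test_bend_psd_floors_eigenvalues():
    A = np.array([[1.0, 1.2], [1.2, 1.0]])
    B = bend_psd(A)
    assert np.linalg.eigvalsh(B).min() >= 0


# ---------------------------------------------------------------------------
# REML oracle equivalences
# ---------------------------------------------------------------------------

def test_reml_matches_anova_closed_form(rng):
    g = np.repeat(np.arange(6), 4)
    y = 10 + rng.normal(0, 2.0, 6)[g] + rng.normal(0, 1.0, 24)
    res = MixedModel(y, np.ones((24, 1)), [("grp", IIDGroup(g))]).fit()
    means = np.array([y[g == i].mean() for i in range(6)])
    mse = sum(((y[g == i] - means[i]) ** 2).sum() for i in range(6)) / (24 - 6)
    msb = 4 * ((means - means.mean()) ** 2).sum() / 5
    vc = res.variance_components()
    assert vc["grp"] == pytest.approx((msb - mse) / 4, abs=1e-6)
    assert vc["residual"] == pytest.approx(mse, abs=1e-6)
    assert res.beta[0] == pytest.approx(means.mean(), abs=1e-8)


def test_reml_matches_restricted_likelihood_grid(rng):
    """6 genotypes x 2 obs, 2 variance parameters: the REML solution must
    sit at the argmax of a dense grid of the directly computed restricted
    likelihood (written independently here)."""
    g = np.repeat(np.arange(6), 2)
    y = 5 + rng.normal(0, 1.5, 6)[g] + rng.normal(0, 1.0, 12)
    Z = np.zeros((12, 6))
    Z[np.arange(12), g] = 1.0
    X = np.ones((12, 1))

    def logl(sg2, se2):
        V = sg2 * Z @ Z.T + se2 * np.eye(12)
        Vi = np.linalg.inv(V)
        C = X.T @ Vi @ X
        P = Vi - Vi @ X @ np.linalg.inv(C) @ X.T @ Vi
        _, ldV = np.linalg.slogdet(V)
        _, ldC = np.linalg.slogdet(C)
        return -0.5 * (ldV + ldC + y @ P @ y)

    grid = np.linspace(0.05, 8.0, 200)
    vals = np.array([[logl(a, b) for b in grid] for a in grid])
    i, j = np.unravel_index(np.argmax(vals), vals.shape)
    res = MixedModel(y, X, [("g", IIDGroup(g))]).fit()
    vc = res.variance_components()
    h = grid[1] - grid[0]
    assert abs(vc["g"] - grid[i]) <= h
    assert abs(vc["residual"] - grid[j]) <= h
    assert res.logl >= vals[i, j] - 1e-6


def test_reml_ridge_blup_closed_form(rng):
    n = 25
    y = 3 + rng.normal(0, 1.2, n) + rng.normal(0, 0.8, n)
    res = MixedModel(y, np.ones((n, 1)),
                     [("g", KnownMatrix(np.arange(n), np.eye(n)))]).fit()
    lam = res.residual_variance / res.term_params("g")[0]
    blup_cf = (y - y.mean()) / (1 + lam)
    np.testing.assert_allclose(res.blup("g").to_numpy(), blup_cf, atol=1e-8)


def test_weight_reparameterization_invariance(rng):
    n = 30
    g = np.repeat(np.arange(6), 5)
    y = rng.normal(0, 1, n) + rng.normal(0, 1, 6)[g]
    w = rng.uniform(0.5, 2.0, n)
    X = np.ones((n, 1))
    r1 = MixedModel(y, X, [("g", IIDGroup(g))], weights=w).fit()
    r2 = MixedModel(y, X, [("g", IIDGroup(g))], weights=2 * w).fit()
    # R = sigma_e^2 diag(1/w): doubling w doubles the fitted scale and the
    # fit is otherwise identical
    assert r2.residual_variance == pytest.approx(2 * r1.residual_variance,
                                                 rel=1e-4)
    assert r1.beta[0] == pytest.approx(r2.beta[0], abs=1e-8)
    # V is unchanged under (w, sigma_e^2) -> (2w, sigma_e^2/2): same logl
    assert r1.logl == pytest.approx(r2.logl, abs=1e-5)


def test_logl_invariant_to_fixed_basis(rng):
    n = 24
    g = np.repeat(np.arange(4), 6)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = X @ [2.0, 1.0] + rng.normal(0, 1, 4)[g] + rng.normal(0, 1, n)
    T = np.array([[2.0, 1.0], [0.5, 1.0]])
    r1 = MixedModel(y, X, [("g", IIDGroup(g))]).fit()
    r2 = MixedModel(y, X @ T, [("g", IIDGroup(g))]).fit()
    # same variance estimates; logl shifts by the constant log|det T|
    for k, v in r1.variance_components().items():
        assert v == pytest.approx(r2.variance_components()[k], rel=1e-4,
                                  abs=1e-8)
    offset = np.log(abs(np.linalg.det(T)))
    assert r1.logl - r2.logl == pytest.approx(offset, abs=1e-5)


def test_aliased_fixed_columns_dropped(rng):
    n = 12
    X = np.column_stack([np.ones(n), np.ones(n)])
    y = rng.normal(size=n)
    with pytest.warns(UserWarning, match="aliased"):
        m = MixedModel(y, X, [("g", IIDGroup(np.repeat([0, 1], 6)))])
    assert m.X.shape[1] == 1 and m.kept_columns == [0]


def test_accepted_likelihood_sequence_nondecreasing(small_blues, small_grm):
    from phenogp.models import GBLUP
    res = GBLUP(small_blues, small_grm).fit(max_iter=50, tol_logl=1e-6,
                                            on_fail="return")
    lls = [t[1] for t in res.reml.trace]
    assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


# ---------------------------------------------------------------------------
# BLUP prediction
# ---------------------------------------------------------------------------

def test_blup_unrecorded_genotype_identity_K(rng):
    K = np.eye(5)
    idx = np.array([0, 1, 2, 3])  # genotype 4 unrecorded
    y = rng.normal(0, 1, 4)
    res = MixedModel(y, np.ones((4, 1)), [("g", KnownMatrix(idx, K))]).fit(
        on_fail="return")
    u = res.blup("g")
    assert u.iloc[4] == 0.0
    pev = res.pev("g")
    assert pev[4, 4] == pytest.approx(res.term_params("g")[0])


def test_blup_borrows_through_relatives(rng):
    K = np.eye(5)
    K[3, 4] = K[4, 3] = 0.6  # genotype 4 related to recorded genotype 3
    idx = np.array([0, 1, 2, 3])
    u_true = np.linalg.cholesky(K + 1e-9 * np.eye(5)) @ rng.normal(0, 2, 5)
    y = u_true[idx] + rng.normal(0, 0.3, 4)
    res = MixedModel(y, np.ones((4, 1)), [("g", KnownMatrix(idx, K))]).fit(
        on_fail="return")
    u = res.blup("g")
    assert u.iloc[4] != 0.0
    assert np.sign(u.iloc[4]) == np.sign(u.iloc[3])


def test_masked_cell_prediction_matches_refit(rng):
    """Predicting a masked record from the training fit equals refitting with
    the cell absent at the same variance parameters (conditional-mean
    consistency)."""
    n, m = 40, 10
    g = np.tile(np.arange(m), 4)
    K = np.eye(m)
    u = rng.normal(0, 1.5, m)
    y = 2 + u[g] + rng.normal(0, 0.8, n)
    res = MixedModel(y[:-1], np.ones((n - 1, 1)),
                     [("g", KnownMatrix(g[:-1], K))]).fit(on_fail="return")
    pred_masked = res.blup("g").iloc[g[-1]]
    res2 = MixedModel(y[:-1], np.ones((n - 1, 1)),
                      [("g", KnownMatrix(g[:-1], K))]).fit(
        start=res.theta, max_iter=1, on_fail="return")
    assert pred_masked == pytest.approx(res2.blup("g").iloc[g[-1]], abs=1e-8)


# ---------------------------------------------------------------------------
# structured covariances
# ---------------------------------------------------------------------------

def test_fa2_recovers_rank2_environment_covariance(rng):
    J, ng = 10, 150
    Lam = rng.normal(0, 1.0, (J, 2))
    Lam[0, 1] = 0
    SE = Lam @ Lam.T
    env = np.repeat(np.arange(J), ng)
    gi = np.tile(np.arange(ng), J)
    ge = np.linalg.cholesky(SE + 1e-10 * np.eye(J)) @ rng.normal(0, 1, (J, ng))
    y = 3 + rng.normal(0, 1, ng)[gi] + ge[env, gi] + rng.normal(0, 0.7, J * ng)
    res = MixedModel(y, np.eye(J)[env],
                     [("g", KnownMatrix(gi, np.eye(ng))),
                      ("ge", FAKronecker(env, gi, np.eye(ng), q=2))]).fit(
        max_iter=80, tol_logl=1e-6, on_fail="return")
    Sh = res.term("ge").sigma_e(res.term_params("ge"))
    rel = np.linalg.norm(Sh - SE) / np.linalg.norm(SE)
    assert rel < 0.5
    assert np.linalg.eigvalsh(Sh).min() >= -1e-8


def test_fa_requires_enough_environments():
    with pytest.raises(ValueError, match="needs >="):
        FAKronecker(np.arange(4), np.arange(4), np.eye(4), q=2)


def test_kronecker_regression_derivative_consistency(rng):
    """dcov must match finite differences of cov."""
    n, ng, d = 15, 5, 3
    X = np.column_stack([np.ones(n), rng.normal(size=(n, d - 1))])
    idx = rng.integers(0, ng, n)
    K = np.eye(ng)
    t = KroneckerRegression(X, idx, K)
    params = rng.uniform(0.5, 2.0, t.n_params)
    eps = 1e-6
    for k in range(t.n_params):
        up = params.copy(); up[k] += eps
        dn = params.copy(); dn[k] -= eps
        fd = (t.cov(up) - t.cov(dn)) / (2 * eps)
        np.testing.assert_allclose(t.dcov(params, k), fd, atol=1e-5)


def test_fa_derivative_consistency(rng):
    n_env, ng = 5, 4
    env = np.tile(np.arange(n_env), ng)
    idx = np.repeat(np.arange(ng), n_env)
    t = FAKronecker(env, idx, np.eye(ng), q=2)
    params = rng.normal(0, 1, t.n_params)
    eps = 1e-6
    for k in range(t.n_params):
        up = params.copy(); up[k] += eps
        dn = params.copy(); dn[k] -= eps
        fd = (t.cov(up) - t.cov(dn)) / (2 * eps)
        np.testing.assert_allclose(t.dcov(params, k), fd, atol=1e-5)
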