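from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from phenogp.mm import GRM, NotConvergedError, vanraden_grm
from phenogp.models import (GBLUP, GBLUPFA, RandomRegressionModel, RRMSpec,
                            TruthModel, forward_stepwise,
                            predict_new_environment)
from phenogp.simulate import SimulationConfig, simulate_dataset
from phenogp.stage1 import cell_means


def _toy_blues(rng, n_geno=8, n_env=4, sg=2.0, se=0.5, gei=0.0):
    genos = [f"G{i}" for i in range(n_geno)]
    g = rng.normal(0, sg, n_geno)
    rows = []
    for j in range(n_env):
        e = rng.normal(0, 1.0)
        for i, gn in enumerate(genos):
            y = 10 + e + g[i] + rng.normal(0, gei or 1e-9) \
                + rng.normal(0, se)
            rows.append((f"T{j}", gn, f"E{j}", y, 1.0 / se ** 2))
    blues = pd.DataFrame(rows, columns=["trial", "genotype", "environment",
                                        "blue", "weight"])
    return blues, pd.Series(g, index=genos)


@pytest.fixture(scope="module")
def identity_grm():
    genos = [f"G{i}" for i in range(8)]
    return GRM(genos, np.eye(8))


def test_gblup_identity_K_shrinks_genotype_means(rng, identity_grm):
    blues, g = _toy_blues(rng)
    res = GBLUP(blues, identity_grm).fit(max_iter=60, tol_logl=1e-7,
                                         on_fail="return")
    pred = res.genetic_values(blues.drop_duplicates("genotype"))
    means = blues.groupby("genotype")["blue"].mean()
    means = means - means.mean()
    order = blues.drop_duplicates("genotype")["genotype"]
    # shrinkage: same ordering, predictions strictly inside the means
    got = pd.Series(pred, index=order.to_numpy())
    assert got.corr(means) > 0.99
    assert got.abs().max() <= means.abs().max() + 1e-9


def test_gblup_borrows_for_unphenotyped_relative(rng):
    genos = [f"G{i}" for i in range(6)]
    K = np.eye(6)
    K[4, 5] = K[5, 4] = 0.7
    grm = GRM(genos, K)
    blues, _ = _toy_blues(rng, n_geno=6)
    blues = blues[blues["genotype"] != "G5"]
    res = GBLUP(blues, grm).fit(max_iter=60, on_fail="return")
    cells = pd.DataFrame({"genotype": ["G5"], "trial": ["T0"],
                          "environment": ["E0"]})
    assert res.genetic_values(cells)[0] != 0.0


def test_truth_values_linear_in_the_data(small_blues, small_grm):
    t1 = TruthModel(small_blues, small_grm).fit(
        max_iter=60, tol_logl=1e-6, on_fail="return")
    doubled = small_blues.assign(blue=2 * small_blues["blue"])
    t2 = TruthModel(doubled, small_grm).fit(
        start=_scaled_start(t1.reml), max_iter=60, tol_logl=1e-6,
        on_fail="return")
    v1 = t1.values()["truth"].to_numpy()
    v2 = t2.values()["truth"].to_numpy()
    np.testing.assert_allclose(v2, 2 * v1, rtol=5e-2, atol=1e-3 * v1.std())


def _scaled_start(reml):
    """Parameter vector for data scaled by 2: variances x4, loadings x2."""
    theta = reml.theta.copy()
    mask = reml.model._variance_mask()
    theta[mask] *= 4.0
    theta[~mask] *= 2.0
    return theta


def test_truth_recovers_effects_in_noise_free_limit(rng, identity_grm):
    blues, g = _toy_blues(rng, sg=3.0, se=1e-3, n_env=6)
    res = TruthModel(blues, identity_grm).fit(max_iter=80, tol_logl=1e-7,
                                              on_fail="return")
    vals = res.values()
    per_geno = vals.groupby("genotype")["truth"].mean()
    assert np.corrcoef(per_geno[g.index], g)[0, 1] > 0.999


def test_truth_constant_across_trials_without_gei(rng, identity_grm):
    blues, g = _toy_blues(rng, sg=3.0, se=0.3, gei=0.0, n_env=6)
    res = TruthModel(blues, identity_grm).fit(max_iter=80, tol_logl=1e-6,
                                              on_fail="return")
    vals = res.values()
    spread = vals.groupby("genotype")["truth"].std().mean()
    genetic_sd = vals.groupby("genotype")["truth"].mean().std()
    assert spread < 0.25 * genetic_sd


def test_fa_reduces_to_gblup_without_gei(rng, identity_grm):
    blues, _ = _toy_blues(rng, sg=2.0, se=0.4, gei=0.0, n_env=6)
    g = GBLUP(blues, identity_grm).fit(max_iter=80, tol_logl=1e-7,
                                       on_fail="return")
    f = GBLUPFA(blues, identity_grm, q=2).fit(max_iter=120, tol_logl=1e-7,
                                              on_fail="return")
    # the FA model nests GBLUP-without-GEI; with no GEI the likelihood gain
    # is bounded by chance overfitting of the ~11 extra loading parameters
    assert f.logl >= g.logl - 1e-6
    assert f.logl - g.logl < 8.0
    # genotype main and an all-positive Sigma_E are interchangeable, so only
    # the total genetic variance (main + mean interaction) is identified;
    # it must agree between the two fits
    tot_f = (f.reml.variance_components()["genotype"]
             + np.mean(np.diag(f.sigma_e())))
    tot_g = g.reml.variance_components()["genotype"]
    assert tot_f == pytest.approx(tot_g, rel=0.35)


def test_fa_sigma_e_always_psd(small_blues, small_grm):
    f = GBLUPFA(small_blues, small_grm).fit(max_iter=60, tol_logl=1e-6,
                                            on_fail="return")
    assert np.linalg.eigvalsh(f.sigma_e()).min() >= -1e-8


def test_rrm_intercept_only_matches_gblup_structure(small_blues, small_grm,
                                                    small_ec):
    """With no slopes the coefficient structure is exactly sigma^2 K: the
    reaction-norm machinery must reproduce the plain genomic main-effect
    model's likelihood on the same fixed design."""
    import phenogp.mm as mm

    d = small_blues.reset_index(drop=True)
    y = d["blue"].to_numpy(float)
    X = np.ones((len(d), 1))
    w = d["weight"].to_numpy(float)
    idx = small_grm.indexer(d["genotype"])
    m1 = mm.MixedModel(y, X, [
        ("g", mm.KnownMatrix(idx, small_grm.K)),
        ("trial", mm.IIDGroup(d["trial"]))], weights=w)
    m2 = mm.MixedModel(y, X, [
        ("coef", mm.KroneckerRegression(np.ones((len(d), 1)), idx,
                                        small_grm.K)),
        ("trial", mm.IIDGroup(d["trial"]))], weights=w)
    r1 = m1.fit(max_iter=80, tol_logl=1e-8, on_fail="return")
    r2 = m2.fit(max_iter=80, tol_logl=1e-8, on_fail="return")
    assert r1.logl == pytest.approx(r2.logl, abs=5e-3)
    assert r1.term_params("g")[0] == pytest.approx(
        r2.term_params("coef")[0], rel=0.05)


def test_rrm_slope_scale_equivariance(small_blues, small_grm, small_ec):
    spec = RRMSpec(("RPP",))
    m1 = RandomRegressionModel(small_blues, small_grm, small_ec.df, spec,
                               standardize=False)
    ec10 = small_ec.df.copy()
    ec10["RPP"] = ec10["RPP"] * 10.0
    m2 = RandomRegressionModel(small_blues, small_grm, ec10, spec,
                               standardize=False)
    r1 = m1.fit(max_iter=80, tol_logl=1e-7, on_fail="return")
    theta2 = r1.reml.theta.copy()
    # rescale start: slope-related omega entries shrink by 10 / 100
    r2 = m2.fit(max_iter=80, tol_logl=1e-7, on_fail="return")
    # scaling a fixed-design column by c shifts the restricted logL by -ln c
    assert r1.logl == pytest.approx(r2.logl + np.log(10.0), abs=0.1)
    c1 = r1.coefficients()["RPP"]
    c2 = r2.coefficients()["RPP"]
    np.testing.assert_allclose(c2, c1 / 10.0, rtol=0.05,
                               atol=1e-4 * c1.abs().max())


def test_rrm_diagonal_truth_gives_small_intercept_slope_correlation(
        small_config, small_grm):
    ds = simulate_dataset(replace(small_config,
                                  heading_missing_trial_frac=0.0))
    blues = cell_means(ds.pheno)
    res = RandomRegressionModel(blues, small_grm, ds.ec_true.df,
                                RRMSpec(small_config.active_ecs)).fit(
        max_iter=80, tol_logl=1e-6, on_fail="return")
    om = res.omega
    d = np.sqrt(np.clip(np.diag(om), 1e-12, None))
    corr = om[0, 1:] / (d[0] * d[1:])
    assert np.all(np.abs(corr) < 0.6)


def test_rrm_spec_validation(small_ec):
    with pytest.raises(ValueError, match="1-5"):
        RRMSpec(())
    with pytest.raises(ValueError, match="1-5"):
        RRMSpec(("a", "b", "c", "d", "e", "f"))


def test_predict_new_environment_interpolation_identity(small_blues, small_grm,
                                                        small_ec):
    spec = RRMSpec(("VTmax", "RPP"))
    res = RandomRegressionModel(small_blues, small_grm, small_ec.df,
                                spec).fit(max_iter=60, tol_logl=1e-6,
                                          on_fail="return")
    cells = small_blues[["genotype", "trial", "environment"]].head(30)
    direct = res.genetic_values(cells)
    via_new_env = predict_new_environment(res, cells)
    np.testing.assert_allclose(direct, via_new_env)


# ---------------------------------------------------------------------------
# forward stepwise
# ---------------------------------------------------------------------------

def test_forward_stepwise_picks_active_ec_first():
    truth = {"A": 0.9, "B": 0.3, "C": 0.2}

    def score(combo):
        return sum(truth[c] for c in combo) / len(combo)

    out = forward_stepwise(["A", "B", "C"], score, max_size=2)
    assert out["best_by_size"][1][0] == ("A",)
    assert out["best_by_size"][2][0] == ("A", "B")
    # score table: 3 candidates at size 1 + 2 at size 2
    assert len(out["score_table"]) == 5


def test_forward_stepwise_skips_failures_and_stops():
    def score(combo):
        if "bad" in combo:
            raise NotConvergedError("no")
        if len(combo) >= 2:
            return float("nan")
        return 0.5

    out = forward_stepwise(["bad", "ok1", "ok2"], score, max_size=3)
    assert out["best_by_size"][1][0] in (("ok1",), ("ok2",))
    assert 2 not in out["best_by_size"]
    assert ("bad",) in out["failures"]


def test_forward_stepwise_duplicate_candidate_ties():
    def score(combo):
        return 0.4  # every combination identical

    with pytest.warns(UserWarning, match="tie"):
        out = forward_stepwise(["X", "Y"], score, max_size=1)
    assert out["best_by_size"][1][0] == ("X",)  # lexicographic tie-break
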