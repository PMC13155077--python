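"""End-to-end study workflows on synthetic data.

These functions chain the generator, stage-1 analysis, EC construction,
PLS/VIP selection, stage-2 models and cross-validation into the benchmark
studies the package documents: parameter recovery of reaction-norm slopes,
VIP recovery of active covariates, heading-date prediction, cross-validation
model orderings, and the variance decomposition. Problem sizes are the
package's benchmark defaults (documented in the methods note); every
workflow is deterministic under its seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import PhenotypeTable
from .evaluation import CVResult, characterize, make_folds, run_cv
from .mm import GRM, vanraden_grm
from .models import (GBLUP, GBLUPFA, RandomRegressionModel, RRMSpec,
                     TruthModel)
from .phenology import EC_COLUMNS as ECS
from .phenology import build_ec_matrix, predict_heading
from .pls import pls_fit, select_ecs, vip_scores
from .simulate import SimulationConfig, SimulatedDataset, simulate_dataset
from .stage1 import cell_means, fit_all_trials

#: the seven stress covariates used as the generative actives in the
#: VIP-recovery study; they span distinct meteorological axes (temperature
#: level, thermal amplitude, phase precipitation, radiation, wind, frost)
VIP_ACTIVE_ECS = ("VTmax", "RPP", "VPP", "GSR", "RWS", "VTA", "RFD")


def study_config(seed: int, **overrides) -> SimulationConfig:
    """The default desk-scale study: 300 genotypes, 20 environments
    (5 years x 2 locations x 2 sowing windows), 1000 loci, 3 active ECs with
    per-EC slope variance 30% of the intercept variance."""
    return SimulationConfig(seed=seed, **overrides)


def cv_benchmark_config(seed: int, misspecified: bool = False,
                        **overrides) -> SimulationConfig:
    """Reduced dataset for the cross-validation benchmark: 120 genotypes,
    10 environments (5 years x 2 locations x 1 sowing window), 400 loci.

    Turnover is lowered so each genotype is tested in ~8 environments,
    matching the environments-per-genotype of the full-scale study design
    that this benchmark scales down."""
    kw = dict(n_genotypes=120, n_loci=400, n_founders=25, turnover=0.25,
              locations=("LE", "DO"), sowing_periods=("OPT",),
              misspecified=misspecified)
    kw.update(overrides)
    return SimulationConfig(seed=seed, **kw)


def stage1_blues(ds: SimulatedDataset, method: str = "reml") -> pd.DataFrame:
    """Genotype-by-trial BLUEs with weights.

    ``method="reml"`` runs the per-trial mixed models; ``method="means"`` is
    the fast path (exact for the generator's balanced complete-block
    layouts)."""
    if method == "means":
        return cell_means(ds.pheno)
    blues, _ = fit_all_trials(ds.pheno)
    return blues


def filled_ec_matrix(ds: SimulatedDataset) -> pd.DataFrame:
    """EC matrix from observed + model-predicted heading dates.

    Heading prediction uses no yield information, so the resulting ECs are
    usable inside cross-validation without leakage."""
    if ds.pheno.df["heading_date"].isna().any():
        filled, _ = predict_heading(ds.pheno)
    else:
        filled = ds.pheno
    return build_ec_matrix(filled, ds.weather).df


def fit_truth(blues: pd.DataFrame, grm: GRM, max_iter: int = 150):
    tv = TruthModel(blues, grm).fit(max_iter=max_iter, tol_logl=1e-6,
                                    on_fail="return")
    return tv.values(), tv


# ---------------------------------------------------------------------------
# benchmark studies
# ---------------------------------------------------------------------------

def slope_recovery_study(seed: int, config: SimulationConfig | None = None
                         ) -> dict:
    """Fit the reaction-norm model with the generator's true ECs and compare
    estimated genotype slopes against the generative truth."""
    cfg = config or study_config(seed)
    ds = simulate_dataset(cfg)
    blues = stage1_blues(ds, method="reml")
    ec_df = filled_ec_matrix(ds)
    grm = vanraden_grm(ds.markers)
    model = RandomRegressionModel(blues, grm, ec_df,
                                  RRMSpec(cfg.active_ecs))
    res = model.fit(max_iter=80, tol_logl=1e-6, on_fail="return")
    coefs = res.coefficients()
    tested = sorted(blues["genotype"].unique())
    est = coefs.loc[tested, list(cfg.active_ecs)].to_numpy()
    true = ds.truth.slopes.loc[tested].to_numpy()
    pooled = float(np.corrcoef(est.ravel(), true.ravel())[0, 1])
    per_ec = {ec: float(np.corrcoef(est[:, j], true[:, j])[0, 1])
              for j, ec in enumerate(cfg.active_ecs)}
    g0 = float(np.corrcoef(coefs.loc[tested, "intercept"],
                           ds.truth.g0.loc[tested])[0, 1])
    return {"slope_correlation": pooled, "per_ec": per_ec,
            "intercept_correlation": g0, "converged": res.converged,
            "n_cells": len(blues)}


def vip_recovery_study(seed: int, n_reps: int = 100, k: int = 7,
                       n_components: int = 5, top: int | None = None) -> dict:
    """Replicated VIP check: how often the top-k VIP covariates recover the
    seven active covariates of ``VIP_ACTIVE_ECS``.

    Each replicate simulates a fresh breeding program spanning many
    independent environment-seasons (10 years x 4 locations x 3 sowing
    windows, ~2000 genotype-trial cells), builds its realized 45-column EC
    matrix, and draws a response with an effect of 0.5 SD on each active
    covariate plus unit noise. Covariate selection from yields is only
    well-posed when the environment sample is large — with the default 20
    environments, chance environment-level correlations swamp any selector —
    so this study uses the many-environment regime; the seven actives span
    distinct meteorological axes (temperature level and amplitude, phase
    precipitation, radiation, wind, frost), since recovery of near-collinear
    duplicates is ill-posed for any importance measure.
    """
    act_idx = [ECS.index(c) for c in VIP_ACTIVE_ECS]
    hits = []
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        cfg = study_config(int(rng.integers(2**31)), n_genotypes=75,
                           n_loci=100, n_founders=20, n_years=10,
                           locations=("LE", "DO", "YG", "R2"),
                           sowing_periods=("PRE", "OPT", "POS"),
                           heading_missing_trial_frac=0.0)
        ds = simulate_dataset(cfg)
        X = ds.ec_true.df[ECS].to_numpy()
        sd = X.std(axis=0)
        Xz = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        y = 0.5 * Xz[:, act_idx].sum(axis=1) + rng.normal(0, 1, len(X))
        fit = pls_fit(X, y, n_components=n_components, columns=ECS)
        ranking = vip_scores(fit).ranking
        hits.append(len(set(ranking[: (top or k)]) & set(VIP_ACTIVE_ECS)))
    hits = np.asarray(hits)
    return {"hits": hits, "mean_hits": float(hits.mean()),
            "frac_ge5": float(np.mean(hits >= 5)), "n_reps": n_reps}


def heading_prediction_study(seed: int) -> dict:
    """Mask-and-predict check of the heading-date model at the generator's
    heritability regime; returns the correlation between predicted and true
    heading on the masked cells."""
    cfg = study_config(seed, n_genotypes=160, n_loci=400, n_founders=25,
                       locations=("LE", "DO"), sowing_periods=("OPT",),
                       n_years=4)
    ds = simulate_dataset(cfg)
    filled, report = predict_heading(ds.pheno)
    obs = ds.pheno.df["heading_date"].isna()
    cells = (filled.df[obs].groupby(["genotype", "trial"])["heading_date"]
             .first().reset_index())
    truth = ds.truth.heading_true.set_index(["genotype", "trial"])["heading_day"]
    sow = (ds.pheno.df.groupby(["genotype", "trial"])["sowing_date"]
           .first())
    key = list(zip(cells["genotype"], cells["trial"]))
    pred_days = (pd.to_datetime(cells["heading_date"]).to_numpy()
                 - sow.loc[key].to_numpy()) / np.timedelta64(1, "D")
    true_days = truth.loc[key].to_numpy(float)
    r = float(np.corrcoef(pred_days, true_days)[0, 1])
    return {"correlation": r, "n_masked_cells": len(cells),
            "n_filled": report["n_filled"]}


def _model_builders(grm: GRM, ec_df: pd.DataFrame, rrm_ecs,
                    include_fa: bool = True) -> dict:
    builders = {
        "gblup": lambda tr: GBLUP(tr, grm),
        "rrm": lambda tr: RandomRegressionModel(tr, grm, ec_df,
                                                RRMSpec(rrm_ecs)),
    }
    if include_fa:
        builders["fa"] = (lambda tr: GBLUPFA(tr, grm), "environment")
    return builders


def _warm_starts(blues, builders) -> dict:
    starts = {}
    for name, spec in builders.items():
        build = spec[0] if isinstance(spec, tuple) else spec
        try:
            res = build(blues).fit(max_iter=80, tol_logl=1e-6,
                                   on_fail="return")
            starts[name] = res.reml.theta
        except Exception:
            starts[name] = None
    return starts


def cv_study(seed: int, schemes=("CV1",), misspecified: bool = False,
             n_iter: int = 5, n_folds: int = 5, max_iter: int = 60,
             config: SimulationConfig | None = None) -> dict:
    """Cross-validation benchmark on the reduced dataset.

    Fits GBLUP, the factor-analytic GxE model (CV1/CV2 only) and the
    reaction-norm model with the generator's true ECs under the requested
    schemes, scoring against the full-data truth model.
    """
    cfg = config or cv_benchmark_config(seed, misspecified=misspecified)
    ds = simulate_dataset(cfg)
    blues = stage1_blues(ds, method="reml")
    ec_df = filled_ec_matrix(ds)
    grm = vanraden_grm(ds.markers)
    truth, truth_fit = fit_truth(blues, grm)

    results = {}
    tables = []
    for scheme in schemes:
        include_fa = scheme != "CV0"
        builders = _model_builders(grm, ec_df, cfg.active_ecs, include_fa)
        starts = _warm_starts(blues, builders)
        if scheme == "CV0":
            plans = make_folds("CV0", sorted(blues["environment"].unique()),
                               seed=seed)
        elif scheme == "CV1":
            plans = make_folds("CV1", sorted(blues["genotype"].unique()),
                               n_folds=n_folds, n_iter=n_iter, seed=seed)
        else:
            cells = sorted(set(zip(blues["genotype"], blues["environment"])))
            plans = make_folds("CV2", cells, n_folds=n_folds, n_iter=n_iter,
                               seed=seed)
        cv = run_cv(blues, builders, plans, truth, warm_starts=starts,
                    max_iter=max_iter)
        tables.append(cv.table)
        results[scheme] = cv
    out = {"config": cfg, "results": results, "truth_converged":
           truth_fit.converged, "table": pd.concat(tables, ignore_index=True)}
    return out


def cv0_win_fraction(cv: CVResult) -> float:
    """Fraction of held-out environments where the reaction-norm model beats
    GBLUP in median within-trial ability."""
    t = cv.table.dropna(subset=["ability"])
    unit = (t.groupby(["model", "fold"])["ability"].median().unstack(0))
    ok = unit[["gblup", "rrm"]].dropna()
    return float((ok["rrm"] > ok["gblup"]).mean())


def variance_share_study(seed: int) -> dict:
    """Generate data with zero fixed EC effects and refit the plot-level
    variance decomposition; returns estimated vs configured shares."""
    cfg = SimulationConfig(seed=seed, n_genotypes=120, n_loci=300,
                           n_founders=20, n_years=8, locations=("LE",),
                           sowing_periods=("PRE", "OPT"),
                           fixed_ec_beta=(0.0, 0.0, 0.0))
    ds = simulate_dataset(cfg)
    report = characterize(ds.pheno, seed=seed)
    est = report.percentages
    gei_est = sum(est.get(k, 0.0) for k in ("gxy", "gxl", "gxs", "gxyxlxs"))
    configured = {k: 100 * v for k, v in cfg.variance_fractions().items()}
    estimated = {
        "genotype": est.get("genotype", 0.0),
        "gei": gei_est,
        "year": est.get("year", 0.0),
        "location": est.get("location", 0.0),
        "sowing": est.get("sowing", 0.0),
        "trial": est.get("trial", 0.0),
        "replicate": est.get("replicate", 0.0),
        "block": est.get("block", 0.0),
        "residual": est.get("residual", 0.0),
    }
    # genetic components are drawn with covariance K x Omega, so their
    # realized variances carry the mean diagonal of K (inbred lines: > 1)
    kdiag = vanraden_grm(ds.markers).mean_diag
    comps = {k: v for k, v in zip(
        ("genotype", "gei", "year", "location", "sowing", "trial",
         "replicate", "block", "residual"),
        (cfg.var_g0 * kdiag,
         len(cfg.active_ecs) * cfg.slope_var_frac * cfg.var_g0 * kdiag
         + cfg.var_ge_iid,
         cfg.var_year, cfg.var_loc, cfg.var_sow, cfg.var_trial, cfg.var_rep,
         0.0, cfg.var_plot))}
    tot = sum(comps.values())
    configured_realized = {k: 100.0 * v / tot for k, v in comps.items()}
    realized_year = float(np.var(ds.truth.year_effects.to_numpy(), ddof=1))
    total = sum(report.components.values())
    return {"estimated": estimated, "configured": configured,
            "configured_k_adjusted": configured_realized,
            "realized_year_share": 100.0 * realized_year / total,
            "report": report}
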