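"""Stage-1 per-trial phenotypic analysis.

Each trial is analysed on its own: genotype fixed, replicate (and incomplete
block nested in replicate, for alpha-lattice trials) random. The genotype
BLUEs and their standard errors feed the weighted stage-2 models
(weight = 1/SE^2), and Cullis' broad-sense heritability

    H^2 = 1 - vbar_Delta_BLUP / (2 sigma_g^2)

is computed from a companion fit with genotype random, where vbar_Delta_BLUP
is the mean prediction-error variance of pairwise BLUP differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import PhenotypeTable
from .mm import IIDGroup, MixedModel

MAX_PAIR_SAMPLE = 2000  # pairs sampled for vbar on large trials (fixed seed)


@dataclass
class TrialFit:
    trial: str
    design: str                 # "rcbd" | "alpha"
    blues: pd.DataFrame         # genotype, blue, se, weight
    variance_components: dict
    h2_cullis: float
    h2_flag: str | None
    converged: bool


def _designs(df: pd.DataFrame):
    has_block = df["block"].notna().any()
    return "alpha" if has_block else "rcbd"


def fit_trial(trial_df: pd.DataFrame, compute_h2: bool = True,
              max_iter: int = 100) -> TrialFit:
    """BLUEs with standard errors for one trial's plot data.

    The design is inferred from the presence of incomplete-block labels.
    Raises on singular designs (a genotype confounded with a replicate is
    reported as aliasing) and on non-convergence.
    """
    df = trial_df.reset_index(drop=True)
    trial = str(df["trial"].iloc[0])
    if df["replicate"].nunique() < 2:
        raise ValueError(f"trial {trial}: need >=2 replicates")
    design = _designs(df)
    y = df["yield"].to_numpy(float)
    if np.isnan(y).any():
        keep = ~np.isnan(y)
        df, y = df[keep].reset_index(drop=True), y[keep]
    genos, gidx = np.unique(df["genotype"].astype(str), return_inverse=True)
    X = np.zeros((len(df), len(genos)))
    X[np.arange(len(df)), gidx] = 1.0
    terms = [("replicate", IIDGroup(df["replicate"]))]
    if design == "alpha":
        blk = df["replicate"].astype(str) + ":" + df["block"].astype(str)
        terms.append(("block", IIDGroup(blk)))
    model = MixedModel(y, X, terms)
    if model.X.shape[1] < len(genos):
        raise ValueError(f"trial {trial}: singular design "
                         "(genotype aliased with replicate/block)")
    res = model.fit(max_iter=max_iter)
    se = np.sqrt(np.maximum(np.diag(res.beta_cov), 1e-30))
    blues = pd.DataFrame({
        "trial": trial, "genotype": genos, "blue": res.beta,
        "se": se, "weight": 1.0 / se ** 2,
    })
    h2, flag = (np.nan, None)
    vc = res.variance_components()
    if compute_h2:
        h2, flag, vc_r = cullis_h2(df, y, design, start_vc=vc,
                                   max_iter=max_iter)
        vc = {**vc, **{f"random_fit_{k}": v for k, v in vc_r.items()}}
    return TrialFit(trial, design, blues, vc, h2, flag, res.converged)


def cullis_h2(df: pd.DataFrame, y: np.ndarray, design: str,
              start_vc: dict | None = None, max_iter: int = 100,
              rng_seed: int = 2000) -> tuple[float, str | None, dict]:
    """Cullis heritability from a genotype-random companion fit.

    On large trials the mean pairwise PEV of BLUP differences is estimated
    from a fixed-seed subsample of ``MAX_PAIR_SAMPLE`` genotype pairs.
    """
    terms = [("genotype", IIDGroup(df["genotype"]))]
    terms.append(("replicate", IIDGroup(df["replicate"])))
    if design == "alpha":
        blk = df["replicate"].astype(str) + ":" + df["block"].astype(str)
        terms.append(("block", IIDGroup(blk)))
    model = MixedModel(y, np.ones((len(y), 1)), terms)
    start = None
    if start_vc:  # reuse stage-1 variance scales as starting values
        start = model._default_start()
        for (nm, t), sl in zip(model.terms, model._slices):
            if nm in start_vc:
                start[sl.start] = max(start_vc[nm], 1e-8)
        if "residual" in start_vc:
            start[model._resid_idx] = max(start_vc["residual"], 1e-8)
    res = model.fit(start=start, max_iter=max_iter)
    vc = res.variance_components()
    sg2 = vc["genotype"]
    vary = float(np.var(y))
    if sg2 <= 1e-8 * vary:
        return 0.0, "sigma_g2_zero", vc
    pev = res.pev("genotype")
    m = pev.shape[0]
    if m * (m - 1) // 2 <= MAX_PAIR_SAMPLE:
        iu = np.triu_indices(m, 1)
        vdelta = pev[iu[0], iu[0]] + pev[iu[1], iu[1]] - 2 * pev[iu]
        vbar = float(vdelta.mean())
    else:
        rng = np.random.default_rng(rng_seed)
        i = rng.integers(0, m, MAX_PAIR_SAMPLE)
        j = rng.integers(0, m - 1, MAX_PAIR_SAMPLE)
        j = np.where(j >= i, j + 1, j)
        vbar = float(np.mean(pev[i, i] + pev[j, j] - 2 * pev[i, j]))
    h2 = 1.0 - vbar / (2.0 * sg2)
    return float(np.clip(h2, 0.0, 1.0)), None, vc


def fit_all_trials(pheno: PhenotypeTable, compute_h2: bool = False,
                   max_iter: int = 100) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stage 1 across every trial.

    Returns (blues, summaries): ``blues`` has one row per genotype-trial with
    BLUE, SE and weight plus the trial's environment; ``summaries`` one row
    per trial with design, H^2 and convergence.
    """
    env_of = pheno.environment_of_trial()
    blues, summaries = [], []
    for trial, grp in pheno.df.groupby("trial", sort=True):
        fit = fit_trial(grp, compute_h2=compute_h2, max_iter=max_iter)
        b = fit.blues.copy()
        b["environment"] = env_of[trial]
        blues.append(b)
        summaries.append({
            "trial": trial, "design": fit.design, "h2_cullis": fit.h2_cullis,
            "h2_flag": fit.h2_flag, "converged": fit.converged,
            "n_genotypes": len(fit.blues),
        })
    return (pd.concat(blues, ignore_index=True),
            pd.DataFrame(summaries))


def cell_means(pheno: PhenotypeTable) -> pd.DataFrame:
    """Genotype-trial mean yields with naive SEs.

    For balanced complete-block trials the mean is exactly the fixed-genotype
    BLUE; this is the fast stage-1 path used in large replicate studies.
    """
    env_of = pheno.environment_of_trial()
    g = (pheno.df.groupby(["trial", "genotype"], sort=True)["yield"]
         .agg(["mean", "std", "count"]).reset_index())
    g["se"] = (g["std"] / np.sqrt(g["count"])).fillna(g["std"].mean())
    pooled = float(np.nanmedian(g["se"]))
    g["se"] = g["se"].replace(0.0, pooled).fillna(pooled)
    out = pd.DataFrame({
        "trial": g["trial"], "genotype": g["genotype"], "blue": g["mean"],
        "se": g["se"], "weight": 1.0 / g["se"] ** 2,
        "environment": g["trial"].map(env_of),
    })
    return out
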