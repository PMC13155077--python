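"""Cross-validation schemes, predictive ability and dataset characterization.

Three masking schemes mirror breeders' prediction problems:

* CV1 — new genotypes: five-fold partitions of the genotype set; all records
  of a masked genotype are withheld.
* CV2 — known genotypes in known environments: five-fold partitions of the
  observed (genotype, environment) cells.
* CV0 — new environments: leave-one-environment-out.

Predictions for masked cells are scored against the full-data truth model's
genetic values by Pearson correlation within grouping units (trial within
environment for GBLUP and reaction-norm models, environment for the
factor-analytic model, whose vectors are first centred per group to remove
common environmental effects). Non-converging fold fits are recorded as
missing, never zero-scored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mm import NotConvergedError

logger = logging.getLogger(__name__)

SCHEMES = ("CV0", "CV1", "CV2")


@dataclass(frozen=True)
class FoldPlan:
    scheme: str
    iteration: int
    fold: int
    masked: frozenset          # genotypes | (genotype, environment) | {env}
    seed: int


def make_folds(scheme: str, keys, n_folds: int = 5, n_iter: int = 1,
               seed: int = 0) -> list[FoldPlan]:
    """Exact fold partitions per iteration.

    For CV0, ``keys`` are environments and one plan per environment is
    produced (``n_folds`` and ``n_iter`` are ignored).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme}")
    keys = list(dict.fromkeys(keys))
    if not keys:
        raise ValueError("no keys to partition")
    if scheme == "CV0":
        return [FoldPlan("CV0", 0, f, frozenset([env]), seed)
                for f, env in enumerate(sorted(keys))]
    if len(keys) < n_folds:
        raise ValueError(f"{len(keys)} keys cannot fill {n_folds} folds")
    plans = []
    for it in range(n_iter):
        rng = np.random.default_rng([seed, it])
        perm = rng.permutation(len(keys))
        for f, chunk in enumerate(np.array_split(perm, n_folds)):
            plans.append(FoldPlan(scheme, it, f,
                                  frozenset(keys[i] for i in chunk), seed))
    return plans


def _mask_rows(blues: pd.DataFrame, plan: FoldPlan) -> np.ndarray:
    if plan.scheme == "CV1":
        return blues["genotype"].isin(plan.masked).to_numpy()
    if plan.scheme == "CV2":
        cells = list(zip(blues["genotype"], blues["environment"]))
        return np.asarray([c in plan.masked for c in cells])
    return blues["environment"].isin(plan.masked).to_numpy()


def predictive_ability(pred: np.ndarray, truth: np.ndarray, grouping,
                       centered: bool = False, min_pairs: int = 3
                       ) -> pd.DataFrame:
    """Pearson correlation between predictions and truth per grouping unit.

    Groups with fewer than ``min_pairs`` pairs or zero variance in either
    vector are skipped (flagged in the ``note`` column). When ``centered``,
    group means are subtracted from both vectors first (the factor-analytic
    path; within-group correlations are unchanged but pooled statistics are
    protected from common environmental effects).
    """
    df = pd.DataFrame({"pred": np.asarray(pred, float),
                       "truth": np.asarray(truth, float),
                       "group": np.asarray(grouping)})
    if centered:
        for col in ("pred", "truth"):
            df[col] -= df.groupby("group")[col].transform("mean")
    rows = []
    for g, sub in df.groupby("group", sort=True):
        note = None
        r = np.nan
        if len(sub) < min_pairs:
            note = "too_few_pairs"
        elif sub["pred"].std() == 0 or sub["truth"].std() == 0:
            note = "zero_variance"
        else:
            r = float(np.corrcoef(sub["pred"], sub["truth"])[0, 1])
        rows.append({"group": g, "ability": r, "n": len(sub), "note": note})
    return pd.DataFrame(rows)


@dataclass
class CVResult:
    """Long table of per-(scheme, model, group, iteration, fold) abilities."""

    table: pd.DataFrame
    failures: pd.DataFrame

    def medians(self) -> pd.DataFrame:
        t = self.table.dropna(subset=["ability"])
        return (t.groupby(["scheme", "model"])["ability"]
                .median().rename("median_ability").reset_index())

    def median_for(self, scheme: str, model: str) -> float:
        m = self.medians()
        row = m[(m["scheme"] == scheme) & (m["model"] == model)]
        return float(row["median_ability"].iloc[0]) if len(row) else np.nan


def run_cv(blues: pd.DataFrame, model_builders: dict, plans: list[FoldPlan],
           truth: pd.DataFrame, warm_starts: dict | None = None,
           max_iter: int = 80, tol_logl: float = 1e-6,
           max_fail_frac: float = 0.5) -> CVResult:
    """Refit each model on every plan's training rows and score masked cells.

    ``model_builders`` maps a model name to a callable
    ``build(train_blues) -> model`` whose fitted results expose
    ``genetic_values(cells)``; the dict value may also be a tuple
    ``(build, grouping)`` with grouping "trial" (default) or
    "environment" (centred scoring, the factor-analytic path). ``truth``
    must hold genotype, trial, environment, truth columns computed once from
    the full data. ``warm_starts`` maps model names to full-data parameter
    vectors used as REML starting values.
    """
    truth = truth.set_index(["genotype", "trial"])
    rows, fails = [], []
    n_plans = {name: 0 for name in model_builders}
    for plan in plans:
        mask = _mask_rows(blues, plan)
        if not mask.any() or mask.all():
            raise ValueError(f"plan {plan} masks none/all rows")
        train = blues[~mask]
        cells = blues[mask][["genotype", "trial", "environment"]]
        for name, spec in model_builders.items():
            build, grouping = spec if isinstance(spec, tuple) else (spec, "trial")
            n_plans[name] += 1
            try:
                model = build(train)
                start = (warm_starts or {}).get(name)
                res = model.fit(start=start, max_iter=max_iter,
                                tol_logl=tol_logl)
            except NotConvergedError:
                fails.append({"model": name, "scheme": plan.scheme,
                              "iteration": plan.iteration, "fold": plan.fold})
                continue
            pred = res.genetic_values(cells)
            tr = truth.loc[list(zip(cells["genotype"], cells["trial"])),
                           "truth"].to_numpy()
            group = (cells["trial"] if grouping == "trial"
                     else cells["environment"])
            pa = predictive_ability(pred, tr, group,
                                    centered=grouping == "environment")
            for _, r in pa.iterrows():
                rows.append({"scheme": plan.scheme, "model": name,
                             "iteration": plan.iteration, "fold": plan.fold,
                             "group": r["group"], "ability": r["ability"],
                             "n": r["n"], "note": r["note"]})
    failures = pd.DataFrame(fails, columns=["model", "scheme", "iteration",
                                            "fold"])
    for name, total in n_plans.items():
        nf = (failures["model"] == name).sum() if len(failures) else 0
        if total and nf / total > max_fail_frac:
            raise RuntimeError(
                f"model {name}: {nf}/{total} plans failed to converge")
    return CVResult(pd.DataFrame(rows), failures)


def baseline_deviation(cv: CVResult, baseline: str = "gblup") -> pd.DataFrame:
    """Per-unit median abilities as deviations from the baseline model,
    with counts of units where each model beats the baseline."""
    t = cv.table.dropna(subset=["ability"])
    if baseline not in set(t["model"]):
        raise ValueError(f"baseline {baseline!r} absent from results")
    unit = (t.groupby(["scheme", "model", "group"])["ability"]
            .median().rename("ability").reset_index())
    base = unit[unit["model"] == baseline].set_index(["scheme", "group"])["ability"]
    out = []
    for (scheme, model), sub in unit.groupby(["scheme", "model"]):
        if model == baseline:
            continue
        idx = pd.MultiIndex.from_arrays([sub["scheme"], sub["group"]])
        aligned = base.reindex(idx).to_numpy()
        ok = np.isfinite(aligned)
        if (~ok).any():
            logger.info("%d units missing in baseline; excluded", (~ok).sum())
        dev = sub["ability"].to_numpy()[ok] - aligned[ok]
        for g, d in zip(sub["group"].to_numpy()[ok], dev):
            out.append({"scheme": scheme, "model": model, "group": g,
                        "deviation": d})
    dev = pd.DataFrame(out, columns=["scheme", "model", "group", "deviation"])
    return dev


def beats_baseline_counts(dev: pd.DataFrame) -> pd.DataFrame:
    return (dev.assign(beats=dev["deviation"] > 0)
            .groupby(["scheme", "model"])
            .agg(n_units=("beats", "size"), n_beats=("beats", "sum"))
            .reset_index())


@dataclass
class VarianceReport:
    components: dict[str, float]
    percentages: dict[str, float]
    year_groups: pd.DataFrame          # year, group ("high"|"low"), mean yield
    group_ec_means: pd.DataFrame | None


def characterize(pheno, selected_ecs=None, ec_df=None, seed: int = 0,
                 max_iter: int = 60) -> VarianceReport:
    """Whole-dataset variance decomposition and year clustering.

    Fits the plot-level model with i.i.d. random genotype, year, location,
    sowing period, trial, replicate, block, GxYear, GxLocation, GxSowing and
    GxYearxLocationxSowing effects; reports each component as a percentage
    of the total. Years are split into high- and low-yielding groups by
    k-means (k=2, 25 restarts, fixed seed) on year-mean yields, and the
    groups are summarised by the selected ECs when provided.
    """
    from sklearn.cluster import KMeans

    from .mm import IIDGroup, MixedModel

    df = pheno.df.dropna(subset=["yield"]).reset_index(drop=True)
    y = df["yield"].to_numpy(float)
    g = df["genotype"].astype(str)
    a = df["year"].astype(str)
    l = df["location"].astype(str)
    s = df["sowing_period"].astype(str)
    terms = [
        ("genotype", IIDGroup(g)),
        ("year", IIDGroup(a)),
        ("location", IIDGroup(l)),
        ("sowing", IIDGroup(s)),
        ("trial", IIDGroup(df["trial"])),
        ("replicate", IIDGroup(df["trial"].astype(str) + ":"
                               + df["replicate"].astype(str))),
        ("gxy", IIDGroup(g + "@" + a)),
        ("gxl", IIDGroup(g + "@" + l)),
        ("gxs", IIDGroup(g + "@" + s)),
        ("gxyxlxs", IIDGroup(g + "@" + df["environment"].astype(str))),
    ]
    if df["block"].notna().any():
        terms.insert(6, ("block", IIDGroup(
            df["trial"].astype(str) + ":" + df["replicate"].astype(str)
            + ":" + df["block"].astype(str))))
    res = MixedModel(y, np.ones((len(y), 1)), terms).fit(max_iter=max_iter)
    vc = res.variance_components()
    total = sum(vc.values())
    pct = {k: 100.0 * v / total for k, v in vc.items()}

    year_means = df.groupby("year")["yield"].mean()
    km = KMeans(n_clusters=2, n_init=25, random_state=seed).fit(
        year_means.to_numpy().reshape(-1, 1))
    lab = km.labels_
    hi = int(np.argmax(km.cluster_centers_.ravel()))
    groups = pd.DataFrame({
        "year": year_means.index,
        "group": np.where(lab == hi, "high", "low"),
        "mean_yield": year_means.to_numpy(),
    })
    gmeans = None
    if selected_ecs and ec_df is not None:
        trial_year = df.groupby("trial")["year"].first()
        e = ec_df.copy()
        e["year"] = e["trial"].map(trial_year)
        e = e.merge(groups[["year", "group"]], on="year")
        gmeans = e.groupby("group")[list(selected_ecs)].mean().reset_index()
    return VarianceReport(vc, pct, groups, gmeans)
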