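"""Stage-2 genomic prediction models on trial-level BLUEs.

All models take the stage-1 genotype-by-trial BLUEs with their weights
(1/SE^2) and a genomic relationship matrix, and differ in how they treat
genotype-by-environment interaction (GEI):

* ``TruthModel``  — environment fixed; genotype ~ K; GEI ~ Sigma_E(FA2) x K;
  trial-within-environment and genotype-by-trial i.i.d.; weighted residual.
  Its conditional genotype-by-trial genetic values are the reference
  ("truth") that cross-validation predictions are scored against.
* ``GBLUP``       — baseline: genotype ~ K, i.i.d. GEI, trial term.
* ``GBLUPFA``     — GBLUP with the i.i.d. GEI replaced by Sigma_E(FA q) x K.
* ``RandomRegressionModel`` — fixed mean + fixed EC regressions; random
  genotype intercept and slopes on named ECs with covariance Omega x K;
  i.i.d. GEI and trial terms kept so the model is comparable with the
  others.

Each model's ``fit`` returns a results object carrying the REML solution and
prediction methods for genotype-trial cells (including cells masked during
cross-validation and entirely new environments, for the reaction-norm
model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mm import (FAKronecker, GRM, IIDGroup, KnownMatrix, KroneckerRegression,
                 MixedModel, MixedModelResults, NotConvergedError)

BLUES_COLUMNS = ["trial", "genotype", "environment", "blue", "weight"]


def _check_blues(blues: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in BLUES_COLUMNS if c not in blues.columns]
    if missing:
        raise ValueError(f"blues table missing columns: {missing}")
    return blues.reset_index(drop=True)


def _env_design(env: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(env.unique())
    Z = np.zeros((len(env), len(levels)))
    lut = {e: j for j, e in enumerate(levels)}
    Z[np.arange(len(env)), env.map(lut)] = 1.0
    return Z, levels


class _Stage2Results:
    """Shared plumbing: REML results + the training frame."""

    def __init__(self, model, reml: MixedModelResults, data: pd.DataFrame):
        self.model = model
        self.reml = reml
        self.data = data

    @property
    def converged(self):
        return self.reml.converged

    @property
    def logl(self):
        return self.reml.logl

    def variance_components(self):
        return self.reml.variance_components()

    def summary(self) -> str:
        head = f"{type(self.model).__name__} on {len(self.data)} BLUEs\n"
        return head + self.reml.summary()


class GBLUP:
    """Baseline genomic BLUP with i.i.d. GEI and trial terms."""

    def __init__(self, blues: pd.DataFrame, grm: GRM,
                 fix_residual_scale: bool = False):
        self.data = _check_blues(blues)
        self.grm = grm
        self.fix_residual_scale = fix_residual_scale

    def _terms(self):
        d = self.data
        return [
            ("genotype", KnownMatrix.from_grm(d["genotype"], self.grm)),
            ("gei", IIDGroup(d["genotype"].astype(str) + "@"
                             + d["environment"].astype(str))),
            ("trial", IIDGroup(d["trial"])),
        ]

    def _build(self):
        X, self.env_levels = _env_design(self.data["environment"])
        return MixedModel(self.data["blue"].to_numpy(float), X, self._terms(),
                          weights=self.data["weight"].to_numpy(float),
                          fix_residual_scale=self.fix_residual_scale)

    def fit(self, start=None, max_iter: int = 100,
            on_fail: str = "raise", **fit_kws) -> "GBLUPResults":
        mm = self._build()
        res = mm.fit(start=start, max_iter=max_iter, on_fail=on_fail,
                     **fit_kws)
        return GBLUPResults(self, res, self.data)


class GBLUPResults(_Stage2Results):

    def genetic_values(self, cells: pd.DataFrame) -> np.ndarray:
        """Predicted genetic value per (genotype, trial) cell: the genomic
        main effect (GEI and trial contributions are zero for unobserved
        cells and constant within the scoring groups)."""
        return self.reml.blup_lookup("genotype", cells["genotype"])


class GBLUPFA(GBLUP):
    """GBLUP with factor-analytic GEI: ge ~ MVN(0, Sigma_E(FA q) x K)."""

    def __init__(self, blues, grm, q: int = 2, specific: bool = False,
                 fix_residual_scale: bool = False):
        super().__init__(blues, grm, fix_residual_scale)
        self.q = q
        self.specific = specific

    def _terms(self):
        d = self.data
        idx = self.grm.indexer(d["genotype"])
        return [
            ("genotype", KnownMatrix.from_grm(d["genotype"], self.grm)),
            ("gei", FAKronecker(d["environment"], idx, self.grm.K, q=self.q,
                                specific=self.specific,
                                levels=list(self.grm.genotypes))),
            ("trial", IIDGroup(d["trial"])),
        ]

    def fit(self, start=None, max_iter: int = 150,
            on_fail: str = "raise", **fit_kws) -> "GBLUPFAResults":
        mm = self._build()
        res = mm.fit(start=start, max_iter=max_iter, on_fail=on_fail,
                     **fit_kws)
        return GBLUPFAResults(self, res, self.data)


class GBLUPFAResults(_Stage2Results):

    def sigma_e(self) -> np.ndarray:
        t = self.reml.term("gei")
        return t.sigma_e(self.reml.term_params("gei"))

    def genetic_values(self, cells: pd.DataFrame) -> np.ndarray:
        """Main effect plus the FA interaction BLUP; environments unseen in
        training contribute zero interaction."""
        g = self.reml.blup_lookup("genotype", cells["genotype"])
        t = self.reml.term("gei")
        known = set(t.env_levels)
        env = cells["environment"].astype(str)
        ok = env.isin(known).to_numpy()
        ge = np.zeros(len(cells))
        if ok.any():
            ge[ok] = self.reml.blup_cells("gei", env[ok],
                                          cells["genotype"][ok])
        return g + ge


class TruthModel(GBLUPFA):
    """Full-data reference model whose genotype-by-trial conditional genetic
    values serve as the truth in cross-validation scoring."""

    def _terms(self):
        d = self.data
        terms = super()._terms()
        terms.append(("geno_trial", IIDGroup(d["genotype"].astype(str) + "#"
                                             + d["trial"].astype(str))))
        return terms

    def fit(self, start=None, max_iter: int = 150,
            on_fail: str = "raise", **fit_kws) -> "TruthValues":
        mm = self._build()
        res = mm.fit(start=start, max_iter=max_iter, on_fail=on_fail,
                     **fit_kws)
        return TruthValues(self, res, self.data)


class TruthValues(GBLUPFAResults):

    def values(self) -> pd.DataFrame:
        """Truth genetic value per modeled genotype-trial cell."""
        d = self.data
        v = self.genetic_values(d)
        v = v + self.reml.blup_lookup(
            "geno_trial", d["genotype"].astype(str) + "#" + d["trial"].astype(str))
        return pd.DataFrame({
            "genotype": d["genotype"], "trial": d["trial"],
            "environment": d["environment"], "truth": v,
        })


@dataclass
class RRMSpec:
    """Which ECs enter the reaction norm (1-5 names from the EC matrix)."""

    ec_names: tuple[str, ...]

    def __post_init__(self):
        self.ec_names = tuple(self.ec_names)
        if not 1 <= len(self.ec_names) <= 5:
            raise ValueError("random regressions support 1-5 ECs")


class RandomRegressionModel:
    """Reaction-norm model: random genotype intercept + slopes on ECs.

    EC columns are centred and unit-scaled using the *training* rows only
    (the scaler is stored with the fit, so cross-validation predictions use
    no information from masked cells). The coefficient covariance Omega is
    unstructured (Cholesky-parameterised) and crossed with K; all scale is
    carried by Omega.
    """

    def __init__(self, blues: pd.DataFrame, grm: GRM, ec_df: pd.DataFrame,
                 spec: RRMSpec, fix_residual_scale: bool = False,
                 scaler: pd.DataFrame | None = None,
                 standardize: bool = True):
        self.data = _check_blues(blues)
        self.grm = grm
        self.spec = spec
        self.ec_df = ec_df
        self.fix_residual_scale = fix_residual_scale
        missing = [c for c in spec.ec_names if c not in ec_df.columns]
        if missing:
            raise ValueError(f"ECs not in the EC matrix: {missing}")
        merged = self.data.merge(
            ec_df[["genotype", "trial", *spec.ec_names]],
            on=["genotype", "trial"], how="left")
        if merged[list(spec.ec_names)].isna().any().any():
            raise ValueError("EC values missing for some genotype-trial cells")
        if scaler is not None:
            self.scaler = scaler
        elif standardize:
            m = merged[list(spec.ec_names)].mean()
            s = merged[list(spec.ec_names)].std(ddof=0).replace(0.0, 1.0)
            self.scaler = pd.DataFrame({"mean": m, "sd": s})
        else:
            self.scaler = pd.DataFrame(
                {"mean": 0.0, "sd": 1.0}, index=list(spec.ec_names))
        self._Z = self.standardize_ecs(merged)

    def standardize_ecs(self, df: pd.DataFrame) -> np.ndarray:
        out = np.empty((len(df), len(self.spec.ec_names)))
        for j, name in enumerate(self.spec.ec_names):
            sc = self.scaler.loc[name]
            out[:, j] = (df[name].to_numpy(float) - sc["mean"]) / sc["sd"]
        return out

    def fit(self, start=None, max_iter: int = 150,
            on_fail: str = "raise", **fit_kws) -> "RRMResults":
        d = self.data
        Xc = np.column_stack([np.ones(len(d)), self._Z])
        idx = self.grm.indexer(d["genotype"])
        terms = [
            ("coef", KroneckerRegression(
                Xc, idx, self.grm.K, levels=list(self.grm.genotypes),
                names=["intercept", *self.spec.ec_names])),
            ("gei", IIDGroup(d["genotype"].astype(str) + "@"
                             + d["environment"].astype(str))),
            ("trial", IIDGroup(d["trial"])),
        ]
        mm = MixedModel(d["blue"].to_numpy(float), Xc, terms,
                        weights=d["weight"].to_numpy(float),
                        fix_residual_scale=self.fix_residual_scale)
        try:
            res = mm.fit(start=start, max_iter=max_iter, on_fail=on_fail,
                         **fit_kws)
        except NotConvergedError as e:
            e.ec_names = self.spec.ec_names
            raise
        return RRMResults(self, res, d)


class RRMResults(_Stage2Results):

    @property
    def omega(self) -> np.ndarray:
        t = self.reml.term("coef")
        return t.omega(self.reml.term_params("coef"), bend=True)

    def coefficients(self) -> pd.DataFrame:
        """BLUPs of genotype intercepts and slopes (all K genotypes)."""
        return self.reml.blup("coef")

    def genetic_values(self, cells: pd.DataFrame) -> np.ndarray:
        """Fixed EC regression plus genotype-specific intercept and slopes
        evaluated at the cells' EC values (standardized with the training
        scaler). Works for new environments: only weather/phenology-derived
        ECs are needed."""
        Z = self.model.standardize_ecs(
            cells.merge(self.model.ec_df[["genotype", "trial",
                                          *self.model.spec.ec_names]],
                        on=["genotype", "trial"], how="left")
            if not set(self.model.spec.ec_names) <= set(cells.columns)
            else cells)
        Xc = np.column_stack([np.ones(len(cells)), Z])
        fixed = Xc[:, self.reml.model.kept_columns] @ self.reml.beta
        B = self.coefficients()
        coef = B.loc[[str(g) for g in cells["genotype"]]].to_numpy()
        return fixed + np.sum(coef * Xc, axis=1)


def predict_new_environment(rrm: RRMResults, cells: pd.DataFrame) -> np.ndarray:
    """Per-genotype predictions for an un-phenotyped environment.

    ``cells`` must carry genotype, trial and either the spec's EC columns or
    enough keys to look them up in the model's EC matrix. The i.i.d. GEI and
    environment intercept are unknowable for a new environment and enter as
    zero; within-environment rankings are unaffected.
    """
    return rrm.genetic_values(cells)


def forward_stepwise(candidates, score_fn, max_size: int = 5,
                     start: tuple[str, ...] = ()) -> dict:
    """Greedy forward selection of ECs for the reaction-norm model.

    ``score_fn(ec_names) -> float`` returns a cross-validated median
    predictive ability (NaN or an exception marks a non-converging
    combination, which is recorded and skipped). Returns the best spec of
    each size with the full score table.
    """
    selected = list(start)
    best_by_size: dict[int, tuple[tuple[str, ...], float]] = {}
    table = []
    failures = []
    while len(selected) < max_size:
        scores = {}
        for cand in candidates:
            if cand in selected:
                continue
            combo = tuple(selected) + (cand,)
            try:
                s = float(score_fn(combo))
            except NotConvergedError:
                failures.append(combo)
                continue
            if np.isnan(s):
                failures.append(combo)
                continue
            scores[cand] = s
            table.append({"size": len(combo), "ecs": combo, "score": s})
        if not scores:
            break
        ranked = sorted(scores, key=lambda c: (-scores[c], c))
        if len(ranked) > 1 and np.isclose(scores[ranked[0]], scores[ranked[1]]):
            warnings.warn(f"stepwise tie between {ranked[0]} and {ranked[1]}")
        best = ranked[0]
        selected.append(best)
        best_by_size[len(selected)] = (tuple(selected), scores[best])
    return {"best_by_size": best_by_size,
            "score_table": pd.DataFrame(table),
            "failures": failures}
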