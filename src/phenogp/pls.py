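"""Partial-least-squares selection of environmental covariates.

Yield (stage-1 BLUEs, optionally centred per environment so selection
targets GxE-relevant variation) is regressed on the 45 ECs by univariate-
response PLS; covariates are ranked by variable-importance-in-projection
(VIP) scores

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a )

where SSY_a is the response sum of squares explained by component a. VIP
scores are normalised so their mean square over columns is 1. A
leave-one-environment-out re-selection flags covariates that only become
relevant for particular environment subsets.

The PLS decomposition itself is delegated to scikit-learn's NIPALS
implementation; VIP scoring, ranking and the LOEO protocol are implemented
here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

MAX_COMPONENTS = 10


@dataclass
class PLSFit:
    n_components: int
    columns: list[str]          # retained predictor columns
    dropped: list[str]          # constant columns removed
    weights: np.ndarray         # (p, A) X-weights
    scores: np.ndarray          # (n, A) X-scores
    loadings: np.ndarray        # (p, A) X-loadings
    y_loadings: np.ndarray      # (A,)
    ssy: np.ndarray             # per-component explained SS of (scaled) y
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    _sk: PLSRegression = field(repr=False, default=None)

    def fitted(self, X: np.ndarray | None = None) -> np.ndarray:
        if X is None:
            X = self._X_train
        return self._sk.predict(np.asarray(X, float)[:, self._keep_idx]).ravel()


@dataclass
class VIPResult:
    scores: pd.Series           # VIP per column, in column order
    ranking: list[str]          # columns by decreasing VIP (name tie-break)

    def top(self, k: int) -> list[str]:
        return self.ranking[:k]


def pls_fit(X, y, n_components: int | None = None, columns=None,
            cv_folds: int = 10, random_state: int = 0) -> PLSFit:
    """Univariate-response PLS with internal centring/scaling.

    Constant predictor columns are dropped with a warning; the component
    count is capped at the predictor rank and, when ``n_components`` is
    None, chosen by K-fold cross-validated RMSEP (capped at
    ``MAX_COMPONENTS``).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if columns is None:
        columns = [f"x{j}" for j in range(X.shape[1])]
    columns = list(columns)
    sd = X.std(axis=0)
    keep = sd > 0
    dropped = [c for c, k in zip(columns, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant columns: {dropped}")
    Xk = X[:, keep]
    cols = [c for c, k in zip(columns, keep) if k]
    rank = int(np.linalg.matrix_rank(Xk - Xk.mean(axis=0)))
    cap = max(1, min(rank, Xk.shape[0] - 1))
    if n_components is None:
        n_components = _choose_components(Xk, y, cap, cv_folds, random_state)
    elif n_components > cap:
        warnings.warn(f"n_components {n_components} exceeds rank; using {cap}")
        n_components = cap
    sk = PLSRegression(n_components=n_components, scale=True)
    sk.fit(Xk, y)
    t = sk.x_scores_
    q = sk.y_loadings_.ravel()
    ssy = q ** 2 * np.einsum("ia,ia->a", t, t)
    fit = PLSFit(
        n_components=n_components, columns=cols, dropped=dropped,
        weights=sk.x_weights_, scores=t, loadings=sk.x_loadings_,
        y_loadings=q, ssy=ssy,
        x_mean=sk._x_mean, x_std=sk._x_std,
        y_mean=float(y.mean()), y_std=float(y.std(ddof=1) or 1.0),
        _sk=sk,
    )
    fit._keep_idx = np.nonzero(keep)[0]
    fit._X_train = X
    return fit


def _choose_components(X, y, cap, cv_folds, random_state) -> int:
    amax = min(cap, MAX_COMPONENTS)
    if len(y) < 3 * cv_folds:
        cv_folds = max(2, len(y) // 3)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=random_state)
    press = np.zeros(amax)
    for tr, te in kf.split(X):
        amax_f = min(amax, len(tr) - 1, np.linalg.matrix_rank(X[tr] - X[tr].mean(0)))
        sk = PLSRegression(n_components=amax_f, scale=True).fit(X[tr], y[tr])
        # predictions for every truncated component count from one fit
        for a in range(amax):
            aa = min(a + 1, amax_f)
            coef = _truncated_coef(sk, aa)
            pred = (X[te] - sk._x_mean) / sk._x_std @ coef + sk.intercept_
            press[a] += np.sum((y[te] - pred.ravel()) ** 2)
    return int(np.argmin(press)) + 1


def _truncated_coef(sk: PLSRegression, a: int) -> np.ndarray:
    W, P, q = sk.x_weights_[:, :a], sk.x_loadings_[:, :a], sk.y_loadings_.ravel()[:a]
    R = W @ np.linalg.pinv(P.T @ W)
    return (R * q).sum(axis=1, keepdims=True) * sk._y_std


def vip_scores(fit: PLSFit) -> VIPResult:
    """VIP scores for every retained column (mean squared VIP = 1)."""
    total = float(fit.ssy.sum())
    if total <= 0:
        raise ValueError("zero explained sum of squares; VIP undefined")
    W = fit.weights
    wnorm2 = (W ** 2).sum(axis=0)
    wnorm2 = np.where(wnorm2 > 0, wnorm2, 1.0)
    p = W.shape[0]
    vip = np.sqrt(p * ((W ** 2 / wnorm2) * fit.ssy).sum(axis=1) / total)
    scores = pd.Series(vip, index=fit.columns, name="VIP")
    ranking = sorted(fit.columns, key=lambda c: (-scores[c], c))
    return VIPResult(scores=scores, ranking=ranking)


def select_top(vip: VIPResult, k: int = 7) -> list[str]:
    """The k highest-VIP columns; ties broken by lexicographic name."""
    if k > len(vip.ranking):
        raise ValueError(f"k={k} exceeds {len(vip.ranking)} columns")
    sel = vip.ranking[:k]
    if k < len(vip.ranking):
        cut, nxt = sel[-1], vip.ranking[k]
        if np.isclose(vip.scores[cut], vip.scores[nxt]):
            logger.info("VIP tie at the cut: kept %s over %s", cut, nxt)
    return sel


def loeo_select(X, y, env_labels, k: int = 7, n_components: int | None = None,
                columns=None) -> dict:
    """Leave-one-environment-out re-selection.

    For each environment, PLS+VIP is refit without its rows and the top-k
    set recorded. Reports covariates entering any fold's top-k that are
    absent from the full-data top-k.
    """
    env = np.asarray(env_labels).astype(str)
    levels = sorted(set(env))
    if len(levels) < 3:
        raise ValueError("leave-one-environment-out needs >=3 environments")
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    full = select_top(vip_scores(pls_fit(X, y, n_components, columns)), k)
    per_env = {}
    for lv in levels:
        mask = env != lv
        if mask.mean() < 0.5:
            warnings.warn(f"environment {lv} holds >50% of rows")
        fit = pls_fit(X[mask], y[mask], n_components, columns)
        per_env[lv] = select_top(vip_scores(fit), k)
    extra = sorted({c for sel in per_env.values() for c in sel} - set(full))
    return {"full": full, "per_env": per_env, "extra": extra}


def select_ecs(ec_df: pd.DataFrame, blues: pd.DataFrame, k: int = 7,
               center_by_env: bool = True, n_components: int | None = None,
               force_include: tuple[str, ...] = (),
               loeo: bool = False) -> dict:
    """End-to-end EC selection from an EC matrix and stage-1 BLUEs.

    Rows are matched on (genotype, trial); the response is optionally
    centred per environment before PLS. ``force_include`` pins named ECs
    (e.g. reproductive frost days for frost-prone environments) into the
    selected set regardless of their VIP rank.
    """
    from .phenology import EC_COLUMNS

    merged = blues.merge(ec_df, on=["genotype", "trial"], how="inner")
    y = merged["blue"].to_numpy(float)
    if center_by_env:
        y = y - merged.groupby("environment")["blue"].transform("mean").to_numpy()
    X = merged[EC_COLUMNS].to_numpy(float)
    fit = pls_fit(X, y, n_components, columns=EC_COLUMNS)
    vip = vip_scores(fit)
    selected = select_top(vip, k)
    for name in force_include:
        if name not in selected:
            selected = selected[:-1] + [name]
    out = {"fit": fit, "vip": vip, "selected": selected}
    if loeo:
        out["loeo"] = loeo_select(X, y, merged["environment"], k,
                                  n_components, columns=EC_COLUMNS)
    return out
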