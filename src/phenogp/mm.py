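"""REML machinery for Gaussian linear mixed models.

Supports the covariance structures needed for multi-environment-trial
genomic prediction:

* i.i.d. random effects on a grouping factor (``IIDGroup``),
* a scaled known relationship matrix, e.g. a genomic relationship matrix
  (``KnownMatrix``),
* a factor-analytic environment covariance crossed with a known matrix by
  Kronecker product (``FAKronecker``), reduced-rank by default,
* an unstructured small coefficient covariance crossed with a known matrix
  (``KroneckerRegression``) for random-regression reaction norms,

plus fixed per-record residual weights for two-stage weighted analyses
(residual covariance sigma_e^2 * diag(1/w), the scale free by default).

Estimation maximises the restricted log-likelihood with average-information
(AI) updates, safeguarded by step halving and a gradient line search so the
accepted-iterate likelihood sequence is non-decreasing. Everything is dense;
the engine is meant for datasets up to a few thousand records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "GRM", "vanraden_grm", "bend_psd",
    "IIDGroup", "KnownMatrix", "FAKronecker", "KroneckerRegression",
    "MixedModel", "MixedModelResults", "NotConvergedError",
]


# ---------------------------------------------------------------------------
# genomic relationship matrix
# ---------------------------------------------------------------------------

@dataclass
class GRM:
    """Symmetric PSD genomic relationship matrix with its genotype index."""

    genotypes: list[str]
    K: np.ndarray

    def __post_init__(self):
        self.K = np.asarray(self.K, float)
        n = len(self.genotypes)
        if self.K.shape != (n, n):
            raise ValueError("K shape inconsistent with genotype index")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("K is not symmetric")

    @property
    def mean_diag(self) -> float:
        return float(np.mean(np.diag(self.K)))

    def indexer(self, labels) -> np.ndarray:
        lut = {g: i for i, g in enumerate(self.genotypes)}
        try:
            return np.asarray([lut[str(g)] for g in labels], int)
        except KeyError as e:
            raise KeyError(f"genotype {e} not in the relationship matrix") from e


def vanraden_grm(markers) -> GRM:
    """VanRaden genomic relationship matrix K = ZZ' / (2 sum p(1-p)).

    ``Z`` is the column-centred dosage matrix (dosages minus twice the
    observed allele frequency). Dosages must be imputed (no missing values).
    """
    D = np.asarray(markers.dosage, float)
    if np.isnan(D).any():
        raise ValueError("dosages contain missing values; run qc_markers first")
    p = D.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need >=2 polymorphic loci for a relationship matrix")
    Z = D[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    K = (Z @ Z.T) / denom
    return GRM(list(markers.genotypes), K)


def bend_psd(A: np.ndarray, rel_floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues below ``rel_floor * mean(diag)`` (PSD bending)."""
    w, V = np.linalg.eigh(A)
    floor = rel_floor * float(np.mean(np.diag(A)))
    if w.min() >= floor:
        return A
    w = np.maximum(w, floor)
    return (V * w) @ V.T


# ---------------------------------------------------------------------------
# covariance structures (record-level contributions to V)
# ---------------------------------------------------------------------------

class CovarianceTerm:
    """Base class: a random term's contribution to the phenotypic covariance.

    Subclasses operate directly at record level (n x n dense), exposing the
    covariance, its parameter derivatives, BLUP backsolves and a smart
    starting value.
    """

    n_params: int
    param_names: list[str]
    #: boolean mask of parameters constrained to be non-negative variances
    variance_mask: np.ndarray

    def cov(self, params: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def dcov(self, params: np.ndarray, k: int) -> np.ndarray:
        raise NotImplementedError

    def init_params(self, var_share: float, y_resid: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class IIDGroup(CovarianceTerm):
    """sigma^2 * I over the levels of a grouping factor."""

    def __init__(self, labels):
        codes, levels = pd.factorize(np.asarray(labels).astype(str))
        self.codes = codes
        self.levels = list(levels)
        self._ind = (codes[:, None] == codes[None, :]).astype(float)
        self.n_params = 1
        self.param_names = ["var"]
        self.variance_mask = np.array([True])

    def cov(self, params):
        return params[0] * self._ind

    def dcov(self, params, k):
        return self._ind

    def init_params(self, var_share, y_resid):
        return np.array([var_share])

    def blup(self, params, p) -> pd.Series:
        u = params[0] * np.bincount(self.codes, weights=p,
                                    minlength=len(self.levels))
        return pd.Series(u, index=self.levels)

    def pev(self, params, P) -> np.ndarray:
        """Prediction-error variance matrix of the level BLUPs."""
        m = len(self.levels)
        Z = np.zeros((len(self.codes), m))
        Z[np.arange(len(self.codes)), self.codes] = 1.0
        M = Z.T @ P @ Z
        s2 = params[0]
        return s2 * np.eye(m) - s2 * s2 * M


class KnownMatrix(CovarianceTerm):
    """sigma^2 * A with A a known symmetric PSD matrix (e.g. a GRM).

    ``idx`` maps each record to a row/column of ``A``; BLUPs are returned
    for every level of ``A``, including levels without records.
    """

    def __init__(self, idx: np.ndarray, A: np.ndarray, levels=None):
        self.idx = np.asarray(idx, int)
        A = np.asarray(A, float)
        wmin = float(np.linalg.eigvalsh(A).min())
        if wmin < -1e-8 * max(1.0, np.mean(np.diag(A))):
            warnings.warn(f"known matrix not PSD (min eig {wmin:.3g}); bending")
            A = bend_psd(A)
        self.A = A
        self.levels = levels if levels is not None else list(range(A.shape[0]))
        self._Ag = A[np.ix_(self.idx, self.idx)]
        self.n_params = 1
        self.param_names = ["var"]
        self.variance_mask = np.array([True])

    @classmethod
    def from_grm(cls, labels, grm: GRM) -> "KnownMatrix":
        return cls(grm.indexer(labels), grm.K, levels=list(grm.genotypes))

    def cov(self, params):
        return params[0] * self._Ag

    def dcov(self, params, k):
        return self._Ag

    def init_params(self, var_share, y_resid):
        return np.array([var_share / max(np.mean(np.diag(self.A)), 1e-12)])

    def blup(self, params, p) -> pd.Series:
        s = np.bincount(self.idx, weights=p, minlength=self.A.shape[0])
        return pd.Series(params[0] * (self.A @ s), index=self.levels)

    def pev(self, params, P) -> np.ndarray:
        m = self.A.shape[0]
        Z = np.zeros((len(self.idx), m))
        Z[np.arange(len(self.idx)), self.idx] = 1.0
        G = params[0] * self.A
        GZt = G @ Z.T
        return G - GZt @ P @ GZt.T


class FAKronecker(CovarianceTerm):
    """Factor-analytic environment covariance crossed with a known matrix.

    The random effect for (environment j, level i of ``A``) has covariance
    Sigma_E[j, j'] * A[i, i'] with Sigma_E = Lambda Lambda' (+ diag(psi) when
    ``specific=True``). Reduced rank (psi = 0) is the default. Identifiability
    is imposed by zeroing loadings above the diagonal (Lambda[j, a] = 0 for
    a > j).
    """

    def __init__(self, env_labels, idx: np.ndarray, A: np.ndarray,
                 q: int = 2, specific: bool = False, levels=None):
        env_codes, env_levels = pd.factorize(np.asarray(env_labels).astype(str))
        self.env = env_codes
        self.env_levels = list(env_levels)
        self.J = len(env_levels)
        if self.J < 2 * q + 1:
            raise ValueError(
                f"FA({q}) needs >= {2*q+1} environments, have {self.J}"
            )
        self.q = q
        self.specific = specific
        self.idx = np.asarray(idx, int)
        self.A = np.asarray(A, float)
        self.levels = levels if levels is not None else list(range(A.shape[0]))
        self._Ag = self.A[np.ix_(self.idx, self.idx)]
        self._free = [(j, a) for a in range(q) for j in range(self.J) if j >= a]
        self.n_params = len(self._free) + (self.J if specific else 0)
        self.param_names = [f"lam[{j},{a}]" for j, a in self._free]
        if specific:
            self.param_names += [f"psi[{j}]" for j in range(self.J)]
        self.variance_mask = np.array(
            [False] * len(self._free) + [True] * (self.J if specific else 0)
        )

    def _unpack(self, params):
        Lam = np.zeros((self.J, self.q))
        for k, (j, a) in enumerate(self._free):
            Lam[j, a] = params[k]
        psi = params[len(self._free):] if self.specific else np.zeros(self.J)
        return Lam, psi

    def sigma_e(self, params) -> np.ndarray:
        Lam, psi = self._unpack(params)
        return Lam @ Lam.T + np.diag(psi)

    def cov(self, params):
        S = self.sigma_e(params)
        return S[np.ix_(self.env, self.env)] * self._Ag

    def dcov(self, params, k):
        Lam, _ = self._unpack(params)
        if k < len(self._free):
            j, a = self._free[k]
            b = Lam[self.env, a]
            ind = (self.env == j).astype(float)
            dS = np.outer(ind, b)
            dS += dS.T
            return dS * self._Ag
        j = k - len(self._free)
        ind = (self.env == j).astype(float)
        return np.outer(ind, ind) * self._Ag

    def init_params(self, var_share, y_resid):
        # loadings from the eigenvectors of a crude environment covariance
        df = pd.DataFrame({"env": self.env, "g": self.idx, "y": y_resid})
        wide = df.pivot_table(index="g", columns="env", values="y")
        C = wide.cov(min_periods=2).to_numpy()
        C = np.where(np.isfinite(C), C, 0.0)
        C[np.diag_indices_from(C)] = np.where(
            np.isfinite(np.diag(C)) & (np.diag(C) > 0), np.diag(C), var_share)
        # align to env code order (pivot may drop envs without pairs)
        full = np.eye(self.J) * var_share
        cols = list(wide.columns)
        for a, ja in enumerate(cols):
            for b, jb in enumerate(cols):
                full[ja, jb] = C[a, b]
        full = bend_psd(full, 1e-4)
        w, V = np.linalg.eigh(full)
        order = np.argsort(w)[::-1][: self.q]
        Lam = V[:, order] * np.sqrt(np.maximum(w[order], var_share * 1e-3))
        scale = np.sqrt(max(np.mean(np.diag(self.A)), 1e-12))
        Lam /= scale
        params = np.zeros(self.n_params)
        for k, (j, a) in enumerate(self._free):
            params[k] = Lam[j, a]
        if self.specific:
            params[len(self._free):] = 0.1 * var_share
        return params

    def blup_cells(self, params, p, env_labels_new, labels_new) -> np.ndarray:
        """BLUPs of the interaction effect for arbitrary (env, level) cells."""
        S = np.zeros((self.J, self.A.shape[0]))
        np.add.at(S, (self.env, self.idx), p)
        GE = self.sigma_e(params) @ (S @ self.A)
        lut_e = {e: i for i, e in enumerate(self.env_levels)}
        lut_l = {str(l): i for i, l in enumerate(self.levels)}
        je = np.asarray([lut_e[str(e)] for e in env_labels_new], int)
        ji = np.asarray([lut_l[str(l)] for l in labels_new], int)
        return GE[je, ji]


class KroneckerRegression(CovarianceTerm):
    """Random-regression coefficients with covariance Omega x A.

    Each level i of ``A`` (typically a genotype in a GRM) carries a vector of
    d random coefficients (intercept + slopes on covariate columns ``X``);
    cov(u_{a,i}, u_{b,i'}) = Omega[a, b] * A[i, i']. Omega is parameterised
    directly by its lower-triangle entries (V is then linear in the
    parameters, which gives the average-information update near-quadratic
    convergence); indefinite proposals are rejected by the line search and
    the reported Omega is PSD-bent at readout if numerically indefinite.
    """

    def __init__(self, X: np.ndarray, idx: np.ndarray, A: np.ndarray,
                 levels=None, names=None):
        self.X = np.asarray(X, float)
        self.idx = np.asarray(idx, int)
        self.A = np.asarray(A, float)
        self.levels = levels if levels is not None else list(range(A.shape[0]))
        self.d = self.X.shape[1]
        self.names = names or [f"c{a}" for a in range(self.d)]
        self._Ag = self.A[np.ix_(self.idx, self.idx)]
        self._tri = [(a, b) for a in range(self.d) for b in range(a + 1)]
        self.n_params = len(self._tri)
        self.param_names = [f"omega[{a},{b}]" for a, b in self._tri]
        self.variance_mask = np.array([a == b for a, b in self._tri])

    def omega(self, params, bend: bool = False) -> np.ndarray:
        Om = np.zeros((self.d, self.d))
        for k, (a, b) in enumerate(self._tri):
            Om[a, b] = Om[b, a] = params[k]
        if bend and np.linalg.eigvalsh(Om).min() < 0:
            Om = bend_psd(Om, rel_floor=0.0)
        return Om

    def cov(self, params):
        Om = self.omega(params)
        return (self.X @ Om @ self.X.T) * self._Ag

    def dcov(self, params, k):
        a, b = self._tri[k]
        D = np.outer(self.X[:, a], self.X[:, b])
        if a != b:
            D = D + D.T
        return D * self._Ag

    def init_params(self, var_share, y_resid):
        scale = max(np.mean(np.diag(self.A)), 1e-12)
        params = np.zeros(self.n_params)
        for k, (a, b) in enumerate(self._tri):
            if a == b:
                params[k] = (var_share / 2.0 if a == 0
                             else var_share / (2.0 * self.d)) / scale
        return params

    def coefficients(self, params, p) -> pd.DataFrame:
        """BLUPs of the coefficient matrix (levels of A x d)."""
        nK = self.A.shape[0]
        S = np.zeros((nK, self.d))
        for b in range(self.d):
            S[:, b] = np.bincount(self.idx, weights=self.X[:, b] * p,
                                  minlength=nK)
        B = self.A @ S @ self.omega(params, bend=True)
        return pd.DataFrame(B, index=self.levels, columns=self.names)


# ---------------------------------------------------------------------------
# model and results
# ---------------------------------------------------------------------------

class NotConvergedError(RuntimeError):
    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


def _drop_aliased(X: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Keep a maximal independent set of columns, earlier columns first."""
    keep: list[int] = []
    basis = np.zeros((X.shape[0], 0))
    for j in range(X.shape[1]):
        cand = np.column_stack([basis, X[:, j]])
        if np.linalg.matrix_rank(cand) > basis.shape[1]:
            keep.append(j)
            basis = cand
    return X[:, keep], keep


class MixedModel:
    """Gaussian linear mixed model estimated by average-information REML.

    Parameters
    ----------
    y : response vector.
    X : fixed-effects design (aliased columns dropped with a warning).
    terms : list of (name, CovarianceTerm) random terms.
    weights : optional per-record residual weights w; residual covariance is
        sigma_e^2 * diag(1/w).
    fix_residual_scale : freeze sigma_e^2 at its starting value (strict
        known-weights mode for two-stage analyses).
    """

    def __init__(self, y, X, terms, weights=None, fix_residual_scale=False,
                 residual_start: float | None = None):
        self.y = np.asarray(y, float)
        n = len(self.y)
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] != n:
            raise ValueError("X row count != len(y)")
        X2, keep = _drop_aliased(X)
        if len(keep) < X.shape[1]:
            warnings.warn(
                f"dropped {X.shape[1]-len(keep)} aliased fixed-effect columns")
        if n <= X2.shape[1]:
            raise ValueError("need more records than fixed-effect columns")
        self.X = X2
        self.kept_columns = keep
        self.terms = list(terms)
        self.names = [nm for nm, _ in self.terms]
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate term names")
        self.weights = (np.ones(n) if weights is None
                        else np.asarray(weights, float))
        if np.any(self.weights <= 0):
            raise ValueError("weights must be strictly positive")
        self.fix_residual_scale = fix_residual_scale
        self.residual_start = residual_start
        # parameter layout: term params then residual scale
        self._slices = []
        off = 0
        for _, t in self.terms:
            self._slices.append(slice(off, off + t.n_params))
            off += t.n_params
        self._resid_idx = off
        self.n_params = off + 1

    # -- likelihood machinery ------------------------------------------------

    def _V(self, theta):
        V = np.diag(theta[self._resid_idx] / self.weights)
        for (nm, t), sl in zip(self.terms, self._slices):
            V += t.cov(theta[sl])
        return V

    def _reml_pieces(self, theta):
        V = self._V(theta)
        jitter = 0.0
        base = float(np.mean(np.diag(V)))
        for _ in range(4):
            try:
                c, low = cho_factor(V + (jitter * np.eye(len(V)) if jitter else 0.0),
                                    lower=True)
                break
            except np.linalg.LinAlgError:
                jitter = max(jitter * 10.0, 1e-10 * base)
        else:
            return None
        n = len(self.y)
        Vinv = cho_solve((c, low), np.eye(n))
        XtVi = self.X.T @ Vinv
        C = XtVi @ self.X
        try:
            cC, lowC = cho_factor(C, lower=True)
        except np.linalg.LinAlgError:
            return None
        CinvXtVi = cho_solve((cC, lowC), XtVi)
        beta = CinvXtVi @ self.y
        P = Vinv - XtVi.T @ CinvXtVi
        p = P @ self.y
        logdetV = 2.0 * np.sum(np.log(np.diag(c)))
        logdetC = 2.0 * np.sum(np.log(np.diag(cC)))
        logl = -0.5 * (logdetV + logdetC + float(self.y @ p))
        return {"V": V, "P": P, "p": p, "beta": beta, "logl": logl,
                "beta_cov": cho_solve((cC, lowC), np.eye(C.shape[0]))}

    def _logl(self, theta):
        pieces = self._reml_pieces(theta)
        return -np.inf if pieces is None else pieces["logl"]

    def _default_start(self):
        # OLS residual variance split equally across terms + residual
        Q, _ = np.linalg.qr(self.X)
        resid = self.y - Q @ (Q.T @ self.y)
        vary = float(resid @ resid) / max(len(self.y) - self.X.shape[1], 1)
        vary = max(vary, 1e-12)
        share = vary / (len(self.terms) + 1)
        theta = np.zeros(self.n_params)
        for (nm, t), sl in zip(self.terms, self._slices):
            theta[sl] = t.init_params(share, resid)
        theta[self._resid_idx] = (self.residual_start
                                  if self.residual_start is not None else share)
        self._vary = vary
        return theta

    def _floors(self, theta):
        floor = 1e-10 * getattr(self, "_vary", 1.0)
        out = theta.copy()
        for (nm, t), sl in zip(self.terms, self._slices):
            sub = out[sl]
            sub[t.variance_mask] = np.maximum(sub[t.variance_mask], floor)
            out[sl] = sub
        out[self._resid_idx] = max(out[self._resid_idx], floor)
        return out

    def fit(self, start=None, max_iter: int = 200, tol_logl: float = 1e-8,
            tol_param: float = 1e-6, on_fail: str = "raise",
            verbose: bool = False) -> "MixedModelResults":
        """Maximise the restricted likelihood.

        ``start`` may be a full parameter vector (e.g. a previous fit's
        ``theta`` for warm starts). ``on_fail="return"`` yields a results
        object with ``converged=False`` instead of raising.
        """
        default = self._default_start()  # also sets the _vary scale
        theta = default if start is None else np.asarray(start, float).copy()
        theta = self._floors(theta)
        pieces = self._reml_pieces(theta)
        if pieces is None:
            raise NotConvergedError("restricted likelihood undefined at start")
        trace = [(0, pieces["logl"], np.nan)]
        converged = False
        self._lm = 1e-6
        free = np.ones(self.n_params, bool)
        if self.fix_residual_scale:
            free[self._resid_idx] = False
        var_mask = self._variance_mask()
        for it in range(1, max_iter + 1):
            P, p = pieces["P"], pieces["p"]
            H = np.empty((len(self.y), self.n_params))
            score = np.zeros(self.n_params)
            for (nm, t), sl in zip(self.terms, self._slices):
                for k in range(t.n_params):
                    D = t.dcov(theta[sl], k)
                    j = sl.start + k
                    H[:, j] = D @ p
                    score[j] = -0.5 * (np.sum(P * D) - p @ H[:, j])
            # residual scale derivative: dV = diag(1/w)
            Hr = p / self.weights
            H[:, self._resid_idx] = Hr
            score[self._resid_idx] = -0.5 * (
                np.sum(np.diag(P) / self.weights) - p @ Hr)
            PH = P @ H[:, free]
            AI = 0.5 * H[:, free].T @ PH
            # non-negative variances are updated on the log scale
            # (multiplicative steps cannot overshoot the boundary)
            s = np.where(var_mask, np.abs(theta), 1.0)
            sf = s[free]
            AI_t = AI * np.outer(sf, sf)
            sc_t = score[free] * sf
            # Levenberg-style adaptive damping: grows when steps need
            # halving, shrinks when full steps are accepted
            accepted = False
            self._last_half = 0
            for attempt in range(4):
                ridge = self._lm * max(np.trace(AI_t) / max(AI_t.shape[0], 1),
                                       1e-300)
                try:
                    delta = np.linalg.solve(
                        AI_t + ridge * np.eye(AI_t.shape[0]), sc_t)
                except np.linalg.LinAlgError:
                    self._lm = min(self._lm * 100.0, 1e6)
                    continue
                step = np.zeros(self.n_params)
                step[free] = delta
                new_theta, new_pieces = self._line_search(theta, step,
                                                          var_mask,
                                                          pieces["logl"])
                if new_pieces is not None:
                    accepted = True
                    break
                self._lm = min(self._lm * 100.0, 1e6)
            if not accepted:
                # steepest ascent (transformed scale) as a last resort
                g = np.zeros(self.n_params)
                g[free] = sc_t
                gnorm = np.linalg.norm(g)
                if gnorm > 0:
                    new_theta, new_pieces = self._line_search(
                        theta, g / gnorm, var_mask, pieces["logl"])
                    if new_pieces is not None:
                        accepted = True
            if not accepted:
                converged = True  # no ascent direction improves: optimum/boundary
                trace.append((it, pieces["logl"], 0.0))
                break
            half = self._last_half
            if half >= 2:
                self._lm = min(self._lm * 10.0, 1e6)
            elif half == 0:
                self._lm = max(self._lm / 10.0, 1e-8)
            dl = new_pieces["logl"] - pieces["logl"]
            scale = np.max(np.abs(theta))
            rel_change = np.max(np.abs(new_theta - theta)
                                / np.maximum(np.abs(theta), 1e-2 * scale + 1e-300))
            theta, pieces = new_theta, new_pieces
            trace.append((it, pieces["logl"], rel_change))
            if verbose:
                import sys
                import time as _t
                print(f"iter {it} logl {pieces['logl']:.6f} dl {dl:.3g} "
                      f"half {half} lm {self._lm:.1e} "
                      f"relstep {rel_change:.3g} t {_t.time():.1f}",
                      file=sys.stderr, flush=True)
            if dl < tol_logl * max(1.0, abs(pieces["logl"])) and rel_change < tol_param:
                converged = True
                break
            if dl < tol_logl * max(1.0, abs(pieces["logl"])) and it > 5:
                converged = True  # likelihood flat; parameters at/near boundary
                break
        if not converged and on_fail == "raise":
            raise NotConvergedError(
                f"REML did not converge in {max_iter} iterations", trace)
        return MixedModelResults(self, theta, pieces, converged, trace)

    def _variance_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_params, bool)
        for (nm, t), sl in zip(self.terms, self._slices):
            mask[sl] = t.variance_mask
        mask[self._resid_idx] = True
        return mask

    def _varyish(self):
        return getattr(self, "_vary", 1.0)

    def _apply_step(self, theta, step, var_mask, frac):
        out = theta.copy()
        lin = ~var_mask
        out[lin] = theta[lin] + frac * step[lin]
        out[var_mask] = theta[var_mask] * np.exp(
            np.clip(frac * step[var_mask], -30.0, 30.0))
        return self._floors(out)

    def _line_search(self, theta, step, var_mask, cur_logl):
        """First step fraction 1, 1/2, ... 1/2^10 that improves the
        restricted likelihood."""
        for half in range(11):
            cand = self._apply_step(theta, step, var_mask, 0.5 ** half)
            cp = self._reml_pieces(cand)
            if cp is None or not np.isfinite(cp["logl"]):
                continue
            if cp["logl"] > cur_logl or (
                    cp["logl"] >= cur_logl - 1e-12 and half == 0):
                self._last_half = half
                return cand, cp
        return theta, None


class MixedModelResults:
    """REML solution: variance parameters, fixed effects, BLUP accessors."""

    def __init__(self, model: MixedModel, theta, pieces, converged, trace):
        self.model = model
        self.theta = theta
        self.beta = pieces["beta"]
        self.beta_cov = pieces["beta_cov"]
        self.logl = pieces["logl"]
        self.converged = converged
        self.trace = trace
        self._P = pieces["P"]
        self._p = pieces["p"]

    @property
    def n_iter(self):
        return self.trace[-1][0]

    def term(self, name) -> CovarianceTerm:
        return dict(self.model.terms)[name]

    def term_params(self, name) -> np.ndarray:
        i = self.model.names.index(name)
        return self.theta[self.model._slices[i]]

    @property
    def residual_variance(self) -> float:
        return float(self.theta[self.model._resid_idx])

    def variance_components(self) -> dict[str, float]:
        """Scalar variance per term (structured terms report their average
        implied variance on the diagonal)."""
        out = {}
        for (nm, t), sl in zip(self.model.terms, self.model._slices):
            pars = self.theta[sl]
            if isinstance(t, (IIDGroup, KnownMatrix)):
                scale = (np.mean(np.diag(t.A)) if isinstance(t, KnownMatrix)
                         else 1.0)
                out[nm] = float(pars[0] * scale)
            elif isinstance(t, FAKronecker):
                out[nm] = float(np.mean(np.diag(t.sigma_e(pars)))
                                * np.mean(np.diag(t.A)))
            elif isinstance(t, KroneckerRegression):
                out[nm] = float(np.trace(t.omega(pars))
                                * np.mean(np.diag(t.A)))
            else:
                out[nm] = float(np.nan)
        out["residual"] = self.residual_variance
        return out

    # -- BLUPs ---------------------------------------------------------------

    def blup(self, name):
        t = self.term(name)
        pars = self.term_params(name)
        if isinstance(t, KroneckerRegression):
            return t.coefficients(pars, self._p)
        if isinstance(t, (IIDGroup, KnownMatrix)):
            return t.blup(pars, self._p)
        raise TypeError(f"no direct BLUP accessor for {type(t).__name__}; "
                        "use blup_cells")

    def blup_lookup(self, name, labels) -> np.ndarray:
        """BLUPs for given level labels; unseen levels return 0."""
        u = self.blup(name)
        lut = {str(k): v for k, v in u.items()}
        return np.asarray([lut.get(str(l), 0.0) for l in labels])

    def blup_cells(self, name, env_labels, level_labels) -> np.ndarray:
        t = self.term(name)
        if not isinstance(t, FAKronecker):
            raise TypeError("blup_cells applies to FAKronecker terms")
        return t.blup_cells(self.term_params(name), self._p,
                            env_labels, level_labels)

    def pev(self, name) -> np.ndarray:
        t = self.term(name)
        if not isinstance(t, (IIDGroup, KnownMatrix)):
            raise TypeError("PEV implemented for IID and known-matrix terms")
        return t.pev(self.term_params(name), self._P)

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "REML mixed model",
            f"  records: {len(self.model.y)}   fixed-effect columns: "
            f"{self.model.X.shape[1]}",
            f"  restricted logL: {self.logl:.4f}   iterations: {self.n_iter}"
            f"   converged: {self.converged}",
            "  variance components:",
        ]
        for nm, v in self.variance_components().items():
            lines.append(f"    {nm:<20s} {v:>12.4g}")
        lines.append("  fixed effects (first 10):")
        for j, b in enumerate(self.beta[:10]):
            se = np.sqrt(max(self.beta_cov[j, j], 0.0))
            lines.append(f"    b[{j}] {b:>12.4g}  (se {se:.4g})")
        return "\n".join(lines)

    def __repr__(self):
        return (f"<MixedModelResults logl={self.logl:.3f} "
                f"converged={self.converged}>")
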