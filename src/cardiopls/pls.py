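"""Partial least squares regression: NIPALS and SIMPLS, from scratch.

PLS finds latent variables t_a = X w_a that maximise covariance with the
response block and regresses Y on those scores. Two classic fitting
algorithms are provided: NIPALS (power iteration with data-matrix
deflation) and SIMPLS (deflation of the cross-covariance matrix). For a
single-response Y the two coincide exactly; for multivariate Y they
agree closely on well-conditioned data.

The module follows the statsmodels convention: ``PLS(endog, exog, ...)``
is the model specification and ``PLS.fit()`` returns a
:class:`PLSResults` carrying coefficients, loadings, scores, variance
explained and prediction. Component-count selection via leave-one-out
cross-validation and PRESS (the squared Frobenius norm of the
prediction residual) lives in :func:`select_components`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PLS",
    "PLSResults",
    "SelectionCurve",
    "fit_nipals",
    "fit_simpls",
    "press",
    "select_components",
    "ConvergenceError",
]

# Inner power iteration: converges linearly at (sv2/sv1)^2 of the
# cross-covariance; near-degenerate leading pairs are common on real
# blocks, so the cap allows ~1e4 cheap iterations before giving up.
NIPALS_TOL = 1e-10
NIPALS_MAXITER = 10_000


class ConvergenceError(RuntimeError):
    """NIPALS inner power iteration failed to converge."""


def _as_matrix(a, role: str) -> tuple[np.ndarray, list[str]]:
    if isinstance(a, pd.DataFrame):
        return a.to_numpy(dtype=float), [str(c) for c in a.columns]
    arr = np.asarray(a, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError(f"{role} must be 2-dimensional")
    return arr, [f"{role}{j}" for j in range(arr.shape[1])]


class PLS:
    """Partial least squares regression model.

    Parameters
    ----------
    endog
        Response block Y, samples x responses (array or DataFrame).
    exog
        Predictor block X, samples x predictors.
    n_components
        Number of latent variables (default 4).
    scale
        Scale columns to unit variance after centring (default True).
    algorithm
        ``"nipals"`` or ``"simpls"``.
    """

    def __init__(self, endog, exog, n_components: int = 4,
                 scale: bool = True, algorithm: str = "nipals"):
        self.Y, self.y_names = _as_matrix(endog, "y")
        self.X, self.x_names = _as_matrix(exog, "x")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} samples but Y has {self.Y.shape[0]}"
            )
        n, p = self.X.shape
        if not 1 <= n_components <= min(n - 1, p):
            raise ValueError(
                f"n_components must be in [1, min(n_samples-1, n_predictors)]"
                f" = [1, {min(n - 1, p)}], got {n_components}"
            )
        if algorithm not in ("nipals", "simpls"):
            raise ValueError(f"unknown algorithm {algorithm!r}")
        self.n_components = int(n_components)
        self.scale = bool(scale)
        self.algorithm = algorithm

    @classmethod
    def from_clr(cls, clr, panel, x_block: str = "modifier",
                 y_block: str = "IC", **kwargs) -> "PLS":
        """Build a model from a CLR matrix and gene panel.

        ``x_block``/``y_block`` name panel blocks: ``"modifier"`` for
        the combined HDAC+SIRT+HAT block, or any single block name
        (``"TF"``, ``"IC"``, ...).
        """
        def genes(block):
            return panel.modifier_genes if block == "modifier" \
                else panel.blocks[block]
        return cls(clr.block(genes(y_block)), clr.block(genes(x_block)),
                   **kwargs)

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "PLSResults":
        X0, Y0 = self.X.copy(), self.Y.copy()
        x_mean, y_mean = X0.mean(axis=0), Y0.mean(axis=0)
        X0 -= x_mean
        Y0 -= y_mean
        if self.scale:
            x_scale = X0.std(axis=0, ddof=1)
            y_scale = Y0.std(axis=0, ddof=1)
            if (x_scale == 0).any():
                bad = [self.x_names[j] for j in np.flatnonzero(x_scale == 0)]
                raise ValueError(f"constant predictor columns: {bad}")
            y_scale = np.where(y_scale == 0, 1.0, y_scale)
            X0 /= x_scale
            Y0 /= y_scale
        else:
            x_scale = np.ones(X0.shape[1])
            y_scale = np.ones(Y0.shape[1])
        if self.algorithm == "nipals":
            W, P, Q, T, U = _nipals(X0, Y0, self.n_components)
        else:
            W, P, Q, T, U = _simpls(X0, Y0, self.n_components)
        ssx, ssy = (X0 ** 2).sum(), (Y0 ** 2).sum()
        tt = (T ** 2).sum(axis=0)
        var_x = tt * (P ** 2).sum(axis=0) / ssx if ssx > 0 else tt * 0
        var_y = tt * (Q ** 2).sum(axis=0) / ssy if ssy > 0 else tt * 0
        return PLSResults(
            model=self, x_weights=W, x_loadings=P, y_loadings=Q,
            x_scores=T, y_scores=U, x_center=x_mean, y_center=y_mean,
            x_scale=x_scale, y_scale=y_scale,
            var_explained_x=var_x, var_explained_y=var_y,
        )


def _nipals(X0, Y0, n_comp):
    """NIPALS with data deflation; returns W, P, Q, T, U in deflated space."""
    n, p = X0.shape
    m = Y0.shape[1]
    Xa, Ya = X0.copy(), Y0.copy()
    W = np.zeros((p, n_comp))
    P = np.zeros((p, n_comp))
    Q = np.zeros((m, n_comp))
    T = np.zeros((n, n_comp))
    U = np.zeros((n, n_comp))
    for a in range(n_comp):
        u = Ya[:, np.argmax(Ya.var(axis=0))].copy()
        if np.allclose(u, 0):
            # Y exhausted: fall back to the dominant X direction so the
            # component still deflates X deterministically.
            u = Xa[:, np.argmax(Xa.var(axis=0))].copy()
        t_old = np.zeros(n)
        for _ in range(NIPALS_MAXITER):
            w = Xa.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ConvergenceError(
                    f"component {a + 1}: X weight vector vanished"
                )
            w /= nw
            t = Xa @ w
            c = Ya.T @ t
            nc = np.linalg.norm(c)
            if nc == 0:  # Y orthogonal to t; component is X-only
                break
            c /= nc
            u = Ya @ c
            # squared relative change of the score vector against the
            # inner-loop tolerance
            if (t - t_old) @ (t - t_old) <= NIPALS_TOL * (t @ t):
                break
            t_old = t
        else:
            raise ConvergenceError(
                f"component {a + 1}: inner iteration did not converge "
                f"within {NIPALS_MAXITER} iterations"
            )
        # sign convention: largest-|.| element of w is positive
        j = np.argmax(np.abs(w))
        if w[j] < 0:
            w, t, u = -w, -t, -u
        tt = t @ t
        if tt == 0:
            raise ConvergenceError(f"component {a + 1}: zero-variance score")
        pvec = Xa.T @ t / tt
        qvec = Ya.T @ t / tt
        Xa = Xa - np.outer(t, pvec)
        Ya = Ya - np.outer(t, qvec)
        W[:, a], P[:, a], Q[:, a], T[:, a], U[:, a] = w, pvec, qvec, t, u
    return W, P, Q, T, U


def _simpls(X0, Y0, n_comp):
    """SIMPLS: deflates the cross-covariance S = X'Y instead of the data.

    Scores are scaled to unit norm (de Jong's convention); loadings are
    regression loadings on those scores, so t_a p_a' partitions X as in
    NIPALS.
    """
    n, p = X0.shape
    m = Y0.shape[1]
    S = X0.T @ Y0
    R = np.zeros((p, n_comp))   # weights applying to X0 directly
    P = np.zeros((p, n_comp))
    Q = np.zeros((m, n_comp))
    T = np.zeros((n, n_comp))
    U = np.zeros((n, n_comp))
    V = np.zeros((p, n_comp))   # orthonormal basis of X-loadings
    for a in range(n_comp):
        u_svd, sv, _ = np.linalg.svd(S, full_matrices=False)
        if sv[0] <= np.finfo(float).eps * max(S.shape):
            raise ConvergenceError(
                f"component {a + 1}: cross-covariance exhausted; "
                "reduce n_components"
            )
        r = u_svd[:, 0]
        t = X0 @ r
        t -= t.mean()
        nt = np.linalg.norm(t)
        if nt == 0:
            raise ConvergenceError(f"component {a + 1}: zero-variance score")
        t /= nt
        r /= nt
        j = np.argmax(np.abs(r))
        if r[j] < 0:
            r, t = -r, -t
        pvec = X0.T @ t
        qvec = Y0.T @ t
        uvec = Y0 @ qvec
        v = pvec.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pvec)
            uvec -= T[:, :a] @ (T[:, :a].T @ uvec)
        nv = np.linalg.norm(v)
        if nv == 0:
            raise ConvergenceError(
                f"component {a + 1}: deflation basis collapsed"
            )
        v /= nv
        S = S - np.outer(v, v @ S)
        R[:, a], P[:, a], Q[:, a] = r, pvec, qvec
        T[:, a], U[:, a], V[:, a] = t, uvec, v
    return R, P, Q, T, U


@dataclass
class PLSResults:
    """Fitted PLS model.

    Matrices follow the fitting algorithm's internal (centred/scaled)
    space; :attr:`beta` and :meth:`predict` are expressed in the
    original data units. ``x_weights`` holds NIPALS weights w_a (applied
    to deflated X) or SIMPLS rotations r_a (applied to X directly).
    """

    model: PLS
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    x_center: np.ndarray
    y_center: np.ndarray
    x_scale: np.ndarray
    y_scale: np.ndarray
    var_explained_x: np.ndarray
    var_explained_y: np.ndarray

    @property
    def n_components(self) -> int:
        return self.x_weights.shape[1]

    @property
    def algorithm(self) -> str:
        return self.model.algorithm

    def _rotations(self, k: int | None = None) -> np.ndarray:
        """Weights R with t = X0 @ R for the first k components."""
        k = self.n_components if k is None else k
        W, P = self.x_weights[:, :k], self.x_loadings[:, :k]
        if self.model.algorithm == "simpls":
            return W
        # NIPALS: undo the deflation, R = W (P'W)^-1
        return W @ np.linalg.inv(P.T @ W)

    def beta_for(self, k: int) -> np.ndarray:
        """Coefficient matrix (predictors x responses, original units)
        using only the first ``k`` components."""
        if not 1 <= k <= self.n_components:
            raise ValueError(f"k must be in [1, {self.n_components}]")
        B_std = self._rotations(k) @ self.y_loadings[:, :k].T
        return B_std / self.x_scale[:, None] * self.y_scale[None, :]

    @property
    def beta(self) -> np.ndarray:
        """Coefficients B (predictors x responses) such that
        ``Y_hat = (X - x_center) @ B + y_center``."""
        return self.beta_for(self.n_components)

    @property
    def beta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.beta, index=self.model.x_names,
                            columns=self.model.y_names)

    def predict(self, X_new, n_components: int | None = None) -> np.ndarray:
        """Predict responses for new predictor rows (original units)."""
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new[None, :]
        if X_new.shape[1] != len(self.x_center):
            raise ValueError(
                f"X_new has {X_new.shape[1]} columns, model expects "
                f"{len(self.x_center)}"
            )
        B = self.beta if n_components is None else self.beta_for(n_components)
        return (X_new - self.x_center) @ B + self.y_center

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.X)

    @property
    def resid(self) -> np.ndarray:
        return self.model.Y - self.fittedvalues

    def transform(self, X_new) -> np.ndarray:
        """Project new predictor rows onto the latent variables."""
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new[None, :]
        X0 = (X_new - self.x_center) / self.x_scale
        return X0 @ self._rotations()

    def summary(self) -> str:
        lines = [
            "Partial Least Squares Regression Results",
            "=" * 56,
            f"Algorithm:        {self.model.algorithm.upper()}",
            f"No. samples:      {self.model.X.shape[0]}",
            f"No. predictors:   {self.model.X.shape[1]}",
            f"No. responses:    {self.model.Y.shape[1]}",
            f"No. components:   {self.n_components}",
            f"Column scaling:   {'unit variance' if self.model.scale else 'none'}",
            "-" * 56,
            "Comp   var. expl. X   var. expl. Y   cumulative Y",
        ]
        cum = 0.0
        for a in range(self.n_components):
            cum += self.var_explained_y[a]
            lines.append(
                f"{a + 1:>4}   {self.var_explained_x[a]:>11.4f}   "
                f"{self.var_explained_y[a]:>11.4f}   {cum:>11.4f}"
            )
        lines.append("-" * 56)
        press_val = press(self.model.Y, self.fittedvalues)
        lines.append(f"Training PRESS:   {press_val:.6g}")
        return "\n".join(lines)


def fit_nipals(X, Y, n_components: int = 4, scale: bool = True) -> PLSResults:
    """Convenience wrapper: NIPALS fit of Y on X."""
    return PLS(Y, X, n_components=n_components, scale=scale,
               algorithm="nipals").fit()


def fit_simpls(X, Y, n_components: int = 4, scale: bool = True) -> PLSResults:
    """Convenience wrapper: SIMPLS fit of Y on X."""
    return PLS(Y, X, n_components=n_components, scale=scale,
               algorithm="simpls").fit()


def press(Y_true, Y_pred) -> float:
    """Predicted residual error sum of squares, ``||Y - Y_pred||_F^2``."""
    Y_true = np.asarray(Y_true, dtype=float)
    Y_pred = np.asarray(Y_pred, dtype=float)
    if Y_true.shape != Y_pred.shape:
        raise ValueError(
            f"shape mismatch: {Y_true.shape} vs {Y_pred.shape}"
        )
    return float(((Y_true - Y_pred) ** 2).sum())


@dataclass
class SelectionCurve:
    """LOOCV component-selection curve.

    ``press_values[k-1]`` is the total leave-one-out PRESS using k
    components; ``se_values`` are the standard errors of the per-sample
    mean squared prediction error. ``chosen`` is the smallest component
    count whose LOOCV error is within one standard error of the
    minimum.
    """

    press_values: np.ndarray
    se_values: np.ndarray
    chosen: int
    var_explained_y: np.ndarray

    @property
    def n_evaluated(self) -> int:
        return len(self.press_values)


def select_components(X, Y, max_components: int = 8, scale: bool = True,
                      algorithm: str = "nipals") -> SelectionCurve:
    """Choose the number of PLS components by LOOCV PRESS.

    Each sample is left out once; a single ``max_components`` model per
    left-out sample yields nested predictions for every component count.
    The chosen count is the smallest whose mean LOOCV squared error lies
    within one standard error of the minimum (one-SE rule).
    """
    X, _ = _as_matrix(X, "x")
    Y, _ = _as_matrix(Y, "y")
    n = X.shape[0]
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    cap = min(n - 2, X.shape[1], np.linalg.matrix_rank(X - X.mean(axis=0)))
    if max_components > cap:
        warnings.warn(
            f"max_components={max_components} exceeds usable rank; "
            f"truncated to {cap}", stacklevel=2,
        )
        max_components = cap
    errs = np.zeros((n, max_components))  # per-sample squared error norms
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        res = PLS(Y[mask], X[mask], n_components=max_components,
                  scale=scale, algorithm=algorithm).fit()
        for k in range(1, max_components + 1):
            pred = res.predict(X[i], n_components=k)
            errs[i, k - 1] = ((Y[i] - pred[0]) ** 2).sum()
    press_values = errs.sum(axis=0)
    mean_err = errs.mean(axis=0)
    se = errs.std(axis=0, ddof=1) / np.sqrt(n)
    kmin = int(np.argmin(mean_err))
    within = mean_err <= mean_err[kmin] + se[kmin]
    chosen = int(np.flatnonzero(within)[0]) + 1
    full = PLS(Y, X, n_components=max_components, scale=scale,
               algorithm=algorithm).fit()
    return SelectionCurve(press_values, se * n, chosen,
                          full.var_explained_y)
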