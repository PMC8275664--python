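"""Coordinate-descent solver for L1-penalised least squares.

Minimises, in the penalty parameterisation used throughout this package,

    L(beta) = sum_i (y_i - x_i . beta)^2 + lambda * sum_j |beta_j|

i.e. the sum of squared errors is *unscaled* (no 1/2n factor), so the
coordinate update is ``beta_j = S(rho_j, lambda/2) / (x_j^T x_j)`` with
``rho_j = x_j^T (y - X beta_{-j})`` and S the soft-threshold operator.
Solvers that minimise ``(1/2n) SSE + alpha ||beta||_1`` (e.g.
scikit-learn's Lasso) correspond via ``lambda = 2 n alpha``.

Everything operates on Gram matrices so leave-one-out cross-validation can
rank-1-downdate instead of refitting from raw data. Hot loops are
numba-jitted when numba is importable, with an equivalent pure-Python
fallback.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cd_lasso_gram", "cd_lasso", "loocv_mse_path", "HAVE_NUMBA"]

MAX_ITER = 10_000
TOL = 1e-12


def _cd_gram_py(XtX, Xty, lam, beta, max_iter, tol):
    p = beta.shape[0]
    half = 0.5 * lam
    for _ in range(max_iter):
        dmax = 0.0
        for j in range(p):
            xjj = XtX[j, j]
            if xjj <= 0.0:
                beta[j] = 0.0
                continue
            rho = Xty[j] + xjj * beta[j]
            for k in range(p):
                rho -= XtX[j, k] * beta[k]
            if rho > half:
                bnew = (rho - half) / xjj
            elif rho < -half:
                bnew = (rho + half) / xjj
            else:
                bnew = 0.0
            d = abs(bnew - beta[j])
            if d > dmax:
                dmax = d
            beta[j] = bnew
        if dmax < tol:
            break
    return beta


def _loocv_mse_path_py(X, y, grid_desc, max_iter, tol):
    # grid_desc: penalty grid sorted descending (warm starts run dense->sparse
    # in reverse, i.e. sparse->dense as lambda decreases)
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    Sx = X.sum(axis=0)
    Sy = y.sum()
    G = grid_desc.shape[0]
    sse = np.zeros(G)
    for i in range(n):
        ni = n - 1
        xi = X[i]
        sx = Sx - xi
        sy = Sy - y[i]
        mx = sx / ni
        my = sy / ni
        # Gram of the fold's *centered* data (intercept handled implicitly)
        XtX_i = np.empty((p, p))
        Xty_i = np.empty(p)
        for a in range(p):
            Xty_i[a] = Xty[a] - xi[a] * y[i] - sx[a] * my
            for b in range(p):
                XtX_i[a, b] = XtX[a, b] - xi[a] * xi[b] - ni * mx[a] * mx[b]
        beta = np.zeros(p)
        for g in range(G):
            _cd_gram_py(XtX_i, Xty_i, grid_desc[g], beta, max_iter, tol)
            pred = my
            for a in range(p):
                pred += (xi[a] - mx[a]) * beta[a]
            e = pred - y[i]
            sse[g] += e * e
    return sse / n


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _cd_gram = njit(cache=True)(_cd_gram_py)

    @njit(cache=True)
    def _loocv_mse_path_nb(X, y, grid_desc, max_iter, tol):
        n, p = X.shape
        XtX = np.zeros((p, p))
        Xty = np.zeros(p)
        Sx = np.zeros(p)
        for i in range(n):
            for a in range(p):
                Xty[a] += X[i, a] * y[i]
                Sx[a] += X[i, a]
                for b in range(p):
                    XtX[a, b] += X[i, a] * X[i, b]
        Sy = y.sum()
        G = grid_desc.shape[0]
        sse = np.zeros(G)
        for i in range(n):
            ni = n - 1
            xi = X[i]
            sx = Sx - xi
            sy = Sy - y[i]
            mx = sx / ni
            my = sy / ni
            XtX_i = np.empty((p, p))
            Xty_i = np.empty(p)
            for a in range(p):
                Xty_i[a] = Xty[a] - xi[a] * y[i] - sx[a] * my
                for b in range(p):
                    XtX_i[a, b] = XtX[a, b] - xi[a] * xi[b] - ni * mx[a] * mx[b]
            beta = np.zeros(p)
            for g in range(G):
                _cd_gram(XtX_i, Xty_i, grid_desc[g], beta, max_iter, tol)
                pred = my
                for a in range(p):
                    pred += (xi[a] - mx[a]) * beta[a]
                e = pred - y[i]
                sse[g] += e * e
        return sse / n

    _loocv_mse_path = _loocv_mse_path_nb
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _cd_gram = _cd_gram_py
    _loocv_mse_path = _loocv_mse_path_py
    HAVE_NUMBA = False


def cd_lasso_gram(
    XtX: np.ndarray,
    Xty: np.ndarray,
    lam: float,
    beta0: np.ndarray | None = None,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> np.ndarray:
    """Solve the penalised problem given Gram matrices ``X^T X`` / ``X^T y``."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    p = Xty.shape[0]
    beta = np.zeros(p) if beta0 is None else np.array(beta0, float)
    _cd_gram(np.ascontiguousarray(XtX, float), np.ascontiguousarray(Xty, float),
             float(lam), beta, max_iter, tol)
    return beta


def cd_lasso(X: np.ndarray, y: np.ndarray, lam: float, **kw) -> np.ndarray:
    """Solve the penalised problem from raw (already centered/scaled) data."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    return cd_lasso_gram(X.T @ X, X.T @ y, lam, **kw)


def loocv_mse_path(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> np.ndarray:
    """Leave-one-out mean squared prediction error at each penalty value.

    ``grid`` may be in any order; the returned array is aligned with it.
    Each fold's model is fit on the remaining rows (with per-fold implicit
    intercept via centering) using warm starts along the descending-
    penalty path.
    """
    X = np.ascontiguousarray(X, float)
    y = np.ascontiguousarray(y, float)
    grid = np.asarray(grid, float)
    order = np.argsort(grid)[::-1]
    mse_desc = _loocv_mse_path(X, y, np.ascontiguousarray(grid[order]), max_iter, tol)
    out = np.empty_like(mse_desc)
    out[order] = mse_desc
    return out
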