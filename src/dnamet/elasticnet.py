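"""Elastic-net solver layer.

Objective, for mixing parameter alpha in [0, 1] and strength lam:

    (1/2n) * ||y - b0 - X b||^2  +  lam * (alpha * ||b||_1 + (1-alpha)/2 * ||b||_2^2)

Columns of X are z-standardised internally (population SD) and the
intercept absorbs the centring, so the penalty acts on comparable
scales; returned coefficients are on the original scale.  The cyclic
coordinate-descent solve is delegated to scikit-learn's ``ElasticNet`` /
``enet_path`` whose objective matches the formula above exactly; KKT
optimality is verifiable with :func:`kkt_max_residual`.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import ElasticNet, enet_path


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(0)
    sd = X.std(0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest penalty for which the all-zero solution is optimal."""
    xs, _, _ = _standardize(np.asarray(X, float))
    yc = np.asarray(y, float) - np.mean(y)
    n = len(yc)
    lmax = float(np.max(np.abs(xs.T @ yc)) / n)
    return lmax / max(alpha, 1e-3)


def lambda_grid(lmax: float, n_lambdas: int = 100, min_ratio: float = 1e-4) -> np.ndarray:
    """Decreasing log-spaced grid from lambda_max down to lambda_max * min_ratio."""
    return np.geomspace(lmax, lmax * min_ratio, n_lambdas)


def fit_elastic_net(X: np.ndarray, y: np.ndarray, alpha: float = 0.5, lam: float = 0.0,
                    tol: float = 1e-7, max_iter: int = 100_000) -> tuple[float, np.ndarray]:
    """Solve one elastic-net problem; returns (intercept, coefficients).

    ``lam = 0`` falls back to ordinary least squares via a direct solve.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in X or y")
    xs, mean, sd = _standardize(X)
    ymean = float(np.mean(y))
    yc = y - ymean
    if lam == 0.0:
        coef_std, *_ = np.linalg.lstsq(xs, yc, rcond=None)
    else:
        model = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False,
                           tol=tol, max_iter=max_iter)
        model.fit(xs, yc)
        coef_std = model.coef_
    coef = coef_std / sd
    intercept = ymean - float(mean @ coef)
    return intercept, coef


def enet_coef_path(X: np.ndarray, y: np.ndarray, alpha: float, lambdas: np.ndarray,
                   tol: float = 1e-5, max_iter: int = 10_000) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started coefficient path over a decreasing lambda grid.

    Returns (intercepts, coefs) with coefs of shape (n_features,
    n_lambdas), both on the original scale.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    xs, mean, sd = _standardize(X)
    ymean = float(np.mean(y))
    yc = y - ymean
    lambdas = np.asarray(lambdas, float)
    alphas_out, coefs_std, _ = enet_path(xs, yc, l1_ratio=alpha, alphas=lambdas,
                                         tol=tol, max_iter=max_iter)
    if not np.array_equal(alphas_out, lambdas):  # solver may re-sort the grid
        order = {a: i for i, a in enumerate(alphas_out)}
        coefs_std = coefs_std[:, [order[a] for a in lambdas]]
    coefs = coefs_std / sd[:, None]
    intercepts = ymean - mean @ coefs
    return intercepts, coefs


def kkt_max_residual(X: np.ndarray, y: np.ndarray, coef_orig: np.ndarray,
                     alpha: float, lam: float) -> float:
    """Maximum violation of the elastic-net stationarity conditions.

    On the standardised problem with residual r = y_c - X_s b:
    active coordinates must satisfy (1/n) x_j' r = lam (1-alpha) b_j +
    lam alpha sign(b_j); inactive ones |(1/n) x_j' r| <= lam alpha.
    """
    X = np.asarray(X, float)
    xs, _, sd = _standardize(X)
    yc = np.asarray(y, float) - np.mean(y)
    b = np.asarray(coef_orig, float) * sd  # back to standardised scale
    n = len(yc)
    g = xs.T @ (yc - xs @ b) / n
    active = b != 0
    res_active = np.abs(g[active] - lam * (1 - alpha) * b[active]
                        - lam * alpha * np.sign(b[active]))
    res_inactive = np.maximum(np.abs(g[~active]) - lam * alpha, 0.0)
    candidates = np.concatenate([res_active, res_inactive])
    return float(candidates.max()) if candidates.size else 0.0
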