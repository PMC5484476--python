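"""PLS1 regression by NIPALS.

Single-response partial least squares: spectra X (n x p) and IgG y (n) are
mean-centered; each factor extracts the weight vector w = X'y/||X'y|| (closed
form for one response, no inner iteration), scores t = Xw, loadings
p = X't/(t't), q = y't/(t't), then deflates X and y.  The regression vector
is b = W (P'W)^-1 q, so prediction is yhat = (X_new - x_mean) b + y_mean.

No variance scaling of wavenumbers is applied (standard for spectral
calibration).  If the residual covariance collapses before the requested
number of factors (||X'y|| < 1e-12), extraction stops early and the achieved
count is recorded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["PLSModel", "fit_pls", "predict", "predict_per_factor", "save_model", "load_model"]


@dataclass
class PLSModel:
    x_mean: np.ndarray      # (p,)
    y_mean: float           # mg/dL
    weights: np.ndarray     # W, (p, k)
    loadings: np.ndarray    # P, (p, k)
    y_loadings: np.ndarray  # q, (k,)
    n_factors: int
    coefficients: np.ndarray  # b, (p,), mg/dL per absorbance unit
    grid: np.ndarray        # wavenumbers the model expects

    def __post_init__(self) -> None:
        if self.n_factors < 1:
            raise ValueError("model must have at least one factor")
        k = self.n_factors
        if not (self.weights.shape[1] == self.loadings.shape[1] == self.y_loadings.size == k):
            raise ValueError("per-factor structures must all have length n_factors")


def fit_pls(X: np.ndarray, y: np.ndarray, n_factors: int, grid: np.ndarray | None = None) -> PLSModel:
    """Fit a PLS1 model with up to ``n_factors`` latent factors."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,) or n < 2:
        raise ValueError("X rows must match y length >= 2")
    if not (1 <= n_factors <= min(n - 1, p)):
        raise ValueError(f"n_factors must be in [1, {min(n - 1, p)}]")
    if np.ptp(y) == 0:
        raise ValueError("degenerate y: zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    W = np.zeros((p, n_factors))
    P = np.zeros((p, n_factors))
    q = np.zeros(n_factors)
    achieved = 0
    for k in range(n_factors):
        cov = Xc.T @ yc
        norm = np.linalg.norm(cov)
        if norm < 1e-12:
            break
        w = cov / norm
        t = Xc @ w
        tt = t @ t
        if tt < 1e-300:
            break
        pk = Xc.T @ t / tt
        qk = float(yc @ t / tt)
        W[:, k], P[:, k], q[k] = w, pk, qk
        Xc -= np.outer(t, pk)
        yc = yc - t * qk
        achieved = k + 1
    if achieved == 0:
        raise ValueError("degenerate problem: X carries no covariance with y")
    W, P, q = W[:, :achieved], P[:, :achieved], q[:achieved]
    b = W @ np.linalg.solve(P.T @ W, q)
    if grid is None:
        grid = np.arange(p, dtype=float)[::-1]  # placeholder index grid, descending
    return PLSModel(x_mean, y_mean, W, P, q, achieved, b, np.asarray(grid, dtype=float))


def _check_grid(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.grid.size:
        raise ValueError(
            f"grid mismatch: model expects {model.grid.size} points, got {X_new.shape[1]}"
        )
    return X_new


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted IgG (mg/dL) for rows of ``X_new`` on the model grid."""
    X_new = _check_grid(model, X_new)
    return (X_new - model.x_mean) @ model.coefficients + model.y_mean


def predict_per_factor(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predictions at every factor count 1..n_factors, shape (n, n_factors).

    Scores for new spectra are obtained by the same successive deflation used
    in fitting, so column k equals ``predict`` with a k-factor model.
    """
    X_new = _check_grid(model, X_new)
    Xc = X_new - model.x_mean
    n = X_new.shape[0]
    out = np.empty((n, model.n_factors))
    acc = np.full(n, model.y_mean)
    for k in range(model.n_factors):
        t = Xc @ model.weights[:, k]
        Xc = Xc - np.outer(t, model.loadings[:, k])
        acc = acc + t * model.y_loadings[k]
        out[:, k] = acc
    return out


def save_model(model: PLSModel, path: str | Path) -> None:
    """Serialize to structured text (JSON) at full float precision."""
    payload = {
        "format": "igspec-pls1",
        "n_factors": model.n_factors,
        "y_mean": model.y_mean,
        "grid": model.grid.tolist(),
        "x_mean": model.x_mean.tolist(),
        "coefficients": model.coefficients.tolist(),
        "weights": model.weights.tolist(),
        "loadings": model.loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> PLSModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "igspec-pls1":
        raise ValueError("not an igspec PLS1 model file")
    return PLSModel(
        x_mean=np.asarray(payload["x_mean"]),
        y_mean=float(payload["y_mean"]),
        weights=np.asarray(payload["weights"]),
        loadings=np.asarray(payload["loadings"]),
        y_loadings=np.asarray(payload["y_loadings"]),
        n_factors=int(payload["n_factors"]),
        coefficients=np.asarray(payload["coefficients"]),
        grid=np.asarray(payload["grid"]),
    )
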