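"""Regression models for spectra -> analyte prediction.

Two models are provided:

* PLS1 (partial least squares with a single response) via the NIPALS
  algorithm, with the number of latent variables chosen as the first local
  minimum of a cross-validated PRESS curve (global minimum when the curve is
  monotone decreasing).
* LS-SVM (least-squares support vector machine) with an RBF kernel
  Omega_kl = exp(-||x_k - x_l||^2 / sigma2), solving the bordered dual system

      [[0, 1^T], [1, Omega + I/gamma]] [b; alpha] = [0; y]

  with hyperparameters (gamma, sigma2) tuned by leave-one-out cross
  validation on a log grid.  The LOO residuals use the closed form
  e_i = alpha_i / (A^-1)_ii, which is algebraically identical to refitting
  with sample i held out.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PLSModel",
    "LSSVMModel",
    "pls_fit",
    "pls_predict",
    "lssvm_fit",
    "lssvm_predict",
    "lssvm_tune",
    "lssvm_loo_residuals",
    "DEFAULT_GAMMA_GRID",
    "DEFAULT_SIGMA2_GRID",
]

DEFAULT_GAMMA_GRID = tuple(10.0 ** k for k in range(0, 7))
DEFAULT_SIGMA2_GRID = tuple(10.0 ** k for k in range(-1, 6))


# ---------------------------------------------------------------------------
# PLS1 (NIPALS)
# ---------------------------------------------------------------------------

def nipals_pls1(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    center: bool = True,
) -> list[np.ndarray]:
    """NIPALS PLS1; returns regression coefficient vectors for component
    counts 1..n_components (nested models), on centered data when
    ``center`` is set.

    Used both for analyte regression (centered) and for the per-channel
    window regressions of piecewise direct standardization (centered when
    the transfer keeps an additive correction term, uncentered — through
    the origin — otherwise).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if center:
        Xw = X - X.mean(axis=0)
        yw = y - y.mean()
    else:
        Xw = X.copy()
        yw = y.copy()
    n, p = Xw.shape
    W, P, Q = [], [], []
    tol = 1e-14 * max(1.0, float(np.abs(Xw).max()) ** 2)
    for _ in range(n_components):
        w = Xw.T @ yw
        nw = np.linalg.norm(w)
        if nw <= tol:
            break
        w /= nw
        t = Xw @ w
        tt = float(t @ t)
        if tt <= tol:
            break
        p_load = (Xw.T @ t) / tt
        q = float(yw @ t) / tt
        Xw -= np.outer(t, p_load)
        yw -= q * t
        W.append(w)
        P.append(p_load)
        Q.append(q)
    coefs = []
    if W:
        Wm = np.column_stack(W)
        Pm = np.column_stack(P)
        qv = np.array(Q)
        for a in range(1, len(W) + 1):
            # beta_a = W_a (P_a^T W_a)^-1 q_a
            beta = Wm[:, :a] @ np.linalg.solve(Pm[:, :a].T @ Wm[:, :a], qv[:a])
            coefs.append(beta)
    if not coefs:
        coefs.append(np.zeros(p))
    # pad with the last model if NIPALS stopped early (X residual exhausted)
    while len(coefs) < n_components:
        coefs.append(coefs[-1].copy())
    return coefs


@dataclass
class PLSModel:
    """Fitted PLS1 model: centered regression vector plus the PRESS curve
    that selected the number of latent variables."""

    n_components: int
    coef: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    press: np.ndarray
    max_components: int

    def to_dict(self) -> dict:
        return {
            "kind": "pls",
            "n_components": int(self.n_components),
            "coef": self.coef.tolist(),
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "press": self.press.tolist(),
            "max_components": int(self.max_components),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            n_components=int(d["n_components"]),
            coef=np.asarray(d["coef"], float),
            x_mean=np.asarray(d["x_mean"], float),
            y_mean=float(d["y_mean"]),
            press=np.asarray(d["press"], float),
            max_components=int(d["max_components"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "PLSModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _first_local_minimum(press: np.ndarray) -> int:
    """Smallest 1-based count whose PRESS is lower than both neighbors
    (one neighbor at the ends); falls back to the global minimum."""
    k = press.size
    for a in range(k):
        lower_left = a == 0 or press[a] < press[a - 1]
        lower_right = a == k - 1 or press[a] < press[a + 1]
        if lower_left and lower_right:
            return a + 1
    return int(np.argmin(press)) + 1


def pls_fit(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 15,
    cv_folds: int = 10,
) -> PLSModel:
    """Fit PLS1 with the latent-variable count chosen from the PRESS curve.

    Cross validation uses contiguous blocks (``cv_folds`` of them); PRESS(a)
    is the summed squared out-of-fold prediction error with ``a`` components.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y have inconsistent lengths")
    if np.ptp(y) == 0:
        raise ValueError("constant target: nothing to regress on")
    if not 2 <= cv_folds <= n:
        raise ValueError(f"cv_folds must be in [2, {n}]")
    max_allowed = min(n - max(2, n // cv_folds) - 1, p)
    if max_components > max_allowed:
        warnings.warn(
            f"max_components clipped from {max_components} to {max_allowed}"
        )
        max_components = max_allowed
    if max_components < 1:
        max_components = 1

    folds = np.array_split(np.arange(n), cv_folds)
    press = np.zeros(max_components)
    for val in folds:
        train = np.setdiff1d(np.arange(n), val)
        coefs = nipals_pls1(X[train], y[train], max_components, center=True)
        xm = X[train].mean(axis=0)
        ym = y[train].mean()
        Xv = X[val] - xm
        for a, beta in enumerate(coefs):
            resid = y[val] - (Xv @ beta + ym)
            press[a] += float(resid @ resid)

    n_comp = _first_local_minimum(press)
    coefs = nipals_pls1(X, y, n_comp, center=True)
    return PLSModel(
        n_components=n_comp,
        coef=coefs[n_comp - 1],
        x_mean=X.mean(axis=0),
        y_mean=float(y.mean()),
        press=press,
        max_components=max_components,
    )


def pls_predict(m: PLSModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != m.coef.size:
        raise ValueError(
            f"model expects {m.coef.size} wavelengths, got {X.shape[1]}"
        )
    return (X - m.x_mean) @ m.coef + m.y_mean


# ---------------------------------------------------------------------------
# LS-SVM (RBF kernel)
# ---------------------------------------------------------------------------

def _rbf_kernel(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    a2 = np.einsum("ij,ij->i", A, A)
    b2 = np.einsum("ij,ij->i", B, B)
    d2 = a2[:, None] + b2[None, :] - 2.0 * (A @ B.T)
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-d2 / sigma2)


@dataclass
class LSSVMModel:
    """Fitted LS-SVM: dual coefficients alpha, bias b, and the stored
    training spectra the RBF kernel is evaluated against."""

    gamma: float
    sigma2: float
    alpha: np.ndarray
    b: float
    X_train: np.ndarray
    loo_mse: float | None = None

    def to_dict(self) -> dict:
        return {
            "kind": "lssvm",
            "gamma": float(self.gamma),
            "sigma2": float(self.sigma2),
            "alpha": self.alpha.tolist(),
            "b": float(self.b),
            "X_train": self.X_train.tolist(),
            "loo_mse": None if self.loo_mse is None else float(self.loo_mse),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LSSVMModel":
        return cls(
            gamma=float(d["gamma"]),
            sigma2=float(d["sigma2"]),
            alpha=np.asarray(d["alpha"], float),
            b=float(d["b"]),
            X_train=np.asarray(d["X_train"], float),
            loo_mse=d.get("loo_mse"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "LSSVMModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _lssvm_system(K: np.ndarray, gamma: float) -> np.ndarray:
    n = K.shape[0]
    A = np.empty((n + 1, n + 1))
    A[0, 0] = 0.0
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    return A


def lssvm_fit(
    X: np.ndarray, y: np.ndarray, gamma: float, sigma2: float
) -> LSSVMModel:
    """Solve the LS-SVM dual system for (b, alpha)."""
    if gamma <= 0 or sigma2 <= 0:
        raise ValueError("gamma and sigma2 must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    K = _rbf_kernel(X, X, sigma2)
    A = _lssvm_system(K, gamma)
    rhs = np.concatenate([[0.0], y])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular LS-SVM system; increase gamma-regularization "
            "(smaller gamma) or remove duplicate samples"
        ) from exc
    resid = np.linalg.norm(A @ sol - rhs)
    scale = max(np.linalg.norm(rhs), 1.0)
    if not np.isfinite(sol).all() or resid > 1e-8 * scale:
        raise np.linalg.LinAlgError(
            f"ill-conditioned LS-SVM system (relative residual {resid / scale:.2e}); "
            "try a smaller gamma or larger sigma2"
        )
    return LSSVMModel(gamma=gamma, sigma2=sigma2, alpha=sol[1:], b=float(sol[0]), X_train=X)


def lssvm_predict(m: LSSVMModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != m.X_train.shape[1]:
        raise ValueError(
            f"model expects {m.X_train.shape[1]} wavelengths, got {X.shape[1]}"
        )
    return _rbf_kernel(X, m.X_train, m.sigma2) @ m.alpha + m.b


def lssvm_loo_residuals(
    X: np.ndarray, y: np.ndarray, gamma: float, sigma2: float
) -> np.ndarray:
    """Exact leave-one-out residuals y_i - yhat^(-i)_i in closed form."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    K = _rbf_kernel(X, X, sigma2)
    A = _lssvm_system(K, gamma)
    Ainv = np.linalg.inv(A)
    rhs = np.concatenate([[0.0], y])
    sol = Ainv @ rhs
    alpha = sol[1:]
    diag = np.diag(Ainv)[1:]
    if not np.isfinite(sol).all() or np.any(diag == 0):
        raise np.linalg.LinAlgError("ill-conditioned LS-SVM system in LOOCV")
    return alpha / diag


def lssvm_tune(
    X: np.ndarray,
    y: np.ndarray,
    gamma_grid=DEFAULT_GAMMA_GRID,
    sigma2_grid=DEFAULT_SIGMA2_GRID,
) -> tuple[float, float]:
    """Grid search minimizing the LOOCV mean squared error; returns the
    best (gamma, sigma2).  Ties keep the earlier grid pair."""
    gamma_grid = list(gamma_grid)
    sigma2_grid = list(sigma2_grid)
    if not gamma_grid or not sigma2_grid:
        raise ValueError("hyperparameter grids must be nonempty")
    best = None
    best_mse = np.inf
    for gamma in gamma_grid:
        for sigma2 in sigma2_grid:
            try:
                e = lssvm_loo_residuals(X, y, gamma, sigma2)
            except np.linalg.LinAlgError:
                continue
            mse = float(np.mean(e**2))
            if np.isfinite(mse) and mse < best_mse:
                best_mse = mse
                best = (float(gamma), float(sigma2))
    if best is None:
        raise RuntimeError("LS-SVM tuning failed at every grid point")
    return best
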