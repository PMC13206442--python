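"""Per-wavelength raw importance scorers.

Five linear learners rate every wavelength's contribution to the
reference variable from complementary angles: forward stagewise
regression (sparse, residual-correlation driven), univariate Huber
regression (robust marginal effect), LASSO (L1 sparsity), ridge (L2
stability under collinearity) and PLS-VIP (latent-projection
contribution).  Each returns nonnegative raw scores of length p.

All learners operate on internally autoscaled copies of X (and centered
y); constant columns receive score 0.  The cross-validated learners
(LASSO, ridge, PLS-VIP) share fold assignments derived from one seed so
that differences between them reflect their criteria, not fold luck.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

from .pls import fit_pls, kfold_press_curve, vip

__all__ = [
    "RawImportance", "fsr_importance", "huber_importance",
    "lasso_importance", "ridge_importance", "plsvip_importance",
    "all_importances", "LEARNERS",
]


@dataclass
class RawImportance:
    learner: str
    values: np.ndarray
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all() or np.any(self.values < 0):
            raise ValueError(f"{self.learner}: raw importances must be finite and >= 0")


def _autoscale(X):
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    ok = sd > 0
    Z = np.zeros_like(X)
    Z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    return Z, ok


def fsr_importance(X, y, step: float = 0.01, max_steps: int = 5000,
                   corr_tol: float = 1e-3) -> RawImportance:
    """Forward stagewise regression scores.

    On autoscaled data, repeatedly pick the variable most correlated
    (in absolute value, ties to the lowest index) with the current
    residual, nudge its coefficient by ``step * sign`` and update the
    residual; stop after ``max_steps`` or when the largest absolute
    correlation falls below ``corr_tol``.  Score = |final coefficient|.
    """
    Z, ok = _autoscale(X)
    y = np.asarray(y, dtype=float).ravel()
    ysd = y.std(ddof=1)
    yc = (y - y.mean()) / (ysd if ysd > 0 else 1.0)
    n, p = Z.shape
    beta = np.zeros(p)
    r = yc.copy()
    col_norm = np.sqrt(n - 1.0)
    steps = 0
    for steps in range(1, max_steps + 1):
        c = Z.T @ r
        rnorm = np.linalg.norm(r)
        if rnorm == 0:
            break
        corr = np.abs(c) / (col_norm * rnorm)
        j = int(np.argmax(corr))             # argmax returns the lowest index on ties
        if corr[j] < corr_tol:
            break
        delta = step * np.sign(c[j])
        beta[j] += delta
        r -= delta * Z[:, j]
    beta[~ok] = 0.0
    return RawImportance("FSR", np.abs(beta),
                         {"step": step, "max_steps": max_steps,
                          "corr_tol": corr_tol, "steps_run": steps})


def huber_importance(X, y, epsilon: float = 1.345, tol: float = 1e-8,
                     max_iter: int = 200) -> RawImportance:
    """Univariate Huber regression slope per wavelength.

    For every column j a robust line ``y ~ a_j + b_j x_j`` is fitted by
    iteratively reweighted least squares with Huber weights at
    ``epsilon``, the residual scale re-estimated each pass from the MAD.
    All p fits run as one vectorized iteration.  Score = |b_j| on
    autoscaled data.
    """
    Z, ok = _autoscale(X)
    y = np.asarray(y, dtype=float).ravel()
    ysd = y.std(ddof=1)
    yc = (y - y.mean()) / (ysd if ysd > 0 else 1.0)
    n, p = Z.shape
    a = np.zeros(p)
    b = np.zeros(p)
    Y = yc[:, None]
    converged = False
    for _ in range(max_iter):
        R = Y - a - b * Z                                   # (n, p) residuals
        scale = np.median(np.abs(R - np.median(R, axis=0)), axis=0) / 0.6745
        scale = np.maximum(scale, 1e-12)
        absr = np.abs(R) / scale
        W = np.where(absr <= epsilon, 1.0, epsilon / np.maximum(absr, 1e-300))
        sw = W.sum(axis=0)
        swx = (W * Z).sum(axis=0)
        swxx = (W * Z * Z).sum(axis=0)
        swy = (W * Y).sum(axis=0)
        swxy = (W * Z * Y).sum(axis=0)
        det = sw * swxx - swx ** 2
        det = np.where(np.abs(det) < 1e-300, 1.0, det)
        b_new = (sw * swxy - swx * swy) / det
        a_new = (swy - b_new * swx) / sw
        if np.max(np.abs(b_new - b), initial=0.0) < tol and \
           np.max(np.abs(a_new - a), initial=0.0) < tol:
            a, b = a_new, b_new
            converged = True
            break
        a, b = a_new, b_new
    if not converged:
        warnings.warn("Huber IRLS hit max_iter without full convergence")
    b[~ok] = 0.0
    return RawImportance("Huber", np.abs(b),
                         {"epsilon": epsilon, "converged": converged})


def _lambda_grid(Z, yc, n_lambdas: int, span: float = 1e-4):
    n = Z.shape[0]
    lam_max = np.max(np.abs(Z.T @ yc)) / n
    lam_max = max(lam_max, 1e-12)
    return np.logspace(np.log10(lam_max), np.log10(lam_max * span), n_lambdas)


def lasso_importance(X, y, folds: int = 10, n_lambdas: int = 100,
                     seed: int = 0, lambda_grid=None) -> RawImportance:
    """|LASSO coefficients| at the CV-optimal penalty.

    The penalty grid descends log-uniformly from the data-driven
    ``lambda_max`` (smallest penalty with an all-zero solution); the
    winner minimizes k-fold CV mean squared error, then the model is
    refitted on all samples.
    """
    Z, _ = _autoscale(X)
    y = np.asarray(y, dtype=float).ravel()
    yc = y - y.mean()
    n = len(y)
    if n < folds:
        raise ValueError("fewer samples than folds")
    alphas = _lambda_grid(Z, yc, n_lambdas) if lambda_grid is None \
        else np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sse = np.zeros(len(alphas))
    with warnings.catch_warnings():
        # the tiny-penalty tail of the grid need not converge tightly to be
        # ruled out by CV error
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        for tr, mo in kf.split(Z):
            mu = Z[tr].mean(axis=0)
            _, coefs, _ = lasso_path(Z[tr] - mu, yc[tr] - yc[tr].mean(),
                                     alphas=alphas, max_iter=3000)
            pred = (Z[mo] - mu) @ coefs + yc[tr].mean()
            sse += np.sum((pred - yc[mo, None]) ** 2, axis=0)
        best = alphas[int(np.argmin(sse))]
        model = Lasso(alpha=best, fit_intercept=True, max_iter=20000).fit(Z, yc)
    beta = np.abs(model.coef_)
    if not beta.any():
        warnings.warn("LASSO solution is all-zero at every penalty")
    return RawImportance("LASSO", beta, {"lambda": float(best), "folds": folds})


def ridge_importance(X, y, folds: int = 10, n_lambdas: int = 100,
                     seed: int = 0, lambda_grid=None) -> RawImportance:
    """|ridge coefficients| at the CV-optimal penalty.

    The grid spans eight decades around the data-driven LASSO
    ``lambda_max`` scale.  Per CV fold one SVD of the training block
    yields coefficients at every penalty, so the search is a single
    decomposition per fold.
    """
    Z, _ = _autoscale(X)
    y = np.asarray(y, dtype=float).ravel()
    yc = y - y.mean()
    n = len(y)
    if n < folds:
        raise ValueError("fewer samples than folds")
    if lambda_grid is None:
        scale = max(np.max(np.abs(Z.T @ yc)) / n, 1e-12)
        lambda_grid = scale * np.logspace(-4, 4, n_lambdas)
    alphas = np.asarray(lambda_grid, dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sse = np.zeros(len(alphas))
    for tr, mo in kf.split(Z):
        mu = Z[tr].mean(axis=0)
        Ztr, ytr = Z[tr] - mu, yc[tr] - yc[tr].mean()
        U, s, Vt = np.linalg.svd(Ztr, full_matrices=False)
        uy = U.T @ ytr
        # beta(lam) = V diag(s / (s^2 + lam)) U' y
        shrink = s[:, None] / (s[:, None] ** 2 + alphas[None, :])
        B = Vt.T @ (shrink * uy[:, None])                 # (p, n_lambdas)
        pred = (Z[mo] - mu) @ B + yc[tr].mean()
        sse += np.sum((pred - yc[mo, None]) ** 2, axis=0)
    best = float(alphas[int(np.argmin(sse))])
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    beta = Vt.T @ ((s / (s ** 2 + best)) * (U.T @ (yc - yc.mean())))
    return RawImportance("Ridge", np.abs(beta), {"lambda": best, "folds": folds})


def plsvip_importance(X, y, folds: int = 10, lv_max: int = 20,
                      seed: int = 0) -> RawImportance:
    """PLS VIP scores at the k-fold-CV-optimal LV count."""
    Z, _ = _autoscale(X)
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < folds:
        raise ValueError("fewer samples than folds")
    press = kfold_press_curve(Z, y, lv_max, folds=folds, seed=seed)
    lv = int(np.argmin(press)) + 1
    model = fit_pls(Z, y, lv)
    return RawImportance("PLS-VIP", vip(model), {"lv": lv, "folds": folds})


LEARNERS = {
    "FSR": fsr_importance,
    "Huber": huber_importance,
    "LASSO": lasso_importance,
    "Ridge": ridge_importance,
    "PLS-VIP": plsvip_importance,
}


def all_importances(X, y, seed: int = 0, folds: int = 10,
                    **overrides) -> list[RawImportance]:
    """Run the five learners with shared CV folds (one seed)."""
    out = [
        fsr_importance(X, y, **overrides.get("fsr", {})),
        huber_importance(X, y, **overrides.get("huber", {})),
        lasso_importance(X, y, folds=folds, seed=seed, **overrides.get("lasso", {})),
        ridge_importance(X, y, folds=folds, seed=seed, **overrides.get("ridge", {})),
        plsvip_importance(X, y, folds=folds, seed=seed, **overrides.get("plsvip", {})),
    ]
    return out
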