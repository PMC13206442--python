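"""Partial least squares regression core for spectral calibration.

Single-response PLS (PLS1) fitted by NIPALS with X-deflation.  The fit
exposes the full coefficient path over latent-variable (LV) counts
``1..n_lv`` from a single decomposition, which makes the cross-validation
loops used everywhere else in the package (PRESS curves, Monte-Carlo CV,
forward selection, CARS) cheap: one fit per fold yields predictions at
every LV count.

Model-quality metrics follow the conventions of NIR calibration work:

* ``R2``   — fraction of reference variance explained,
* ``RMSE`` — root-mean-square error in % protein,
* ``rRMSE``— RMSE relative to the set mean, in percent,
* ``RPD``  — residual predictive deviation, sd(reference)/RMSE computed on
  the same evaluation set, hence identically ``(1 - R2)**-0.5``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSModel",
    "MetricsReport",
    "fit_pls",
    "select_lv_mccv",
    "kfold_press_curve",
    "rmsecv_kfold",
    "vip",
    "evaluate",
    "relative_rmse",
    "rpd_from_r2",
]


@dataclass
class PLSModel:
    """A fitted PLS1 calibration model.

    ``coef_path[:, a]`` is the centered-scale regression vector using
    ``a + 1`` latent variables; ``coef`` / ``intercept`` give the original
    scale prediction ``yhat = X @ coef + intercept`` at ``n_lv``.
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray       # W (p, A) deflated-X weights, unit norm
    loadings: np.ndarray      # P (p, A) X-loadings
    y_loadings: np.ndarray    # q (A,)
    scores: np.ndarray        # T (n, A) training scores
    rotations: np.ndarray     # R (p, A): T = Xc @ R
    coef_path: np.ndarray     # (p, A) coefficients for 1..A LVs
    subset: np.ndarray | None = None   # column indices of the parent matrix
    meta: dict = field(default_factory=dict)

    @property
    def coef(self) -> np.ndarray:
        return self.coef_path[:, self.n_lv - 1]

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coef)

    def predict(self, X: np.ndarray, n_lv: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        a = self.n_lv if n_lv is None else int(n_lv)
        if not 1 <= a <= self.coef_path.shape[1]:
            raise ValueError(f"n_lv {a} outside fitted range 1..{self.coef_path.shape[1]}")
        b = self.coef_path[:, a - 1]
        return (X - self.x_mean) @ b + self.y_mean

    def predict_path(self, X: np.ndarray) -> np.ndarray:
        """Predictions at every LV count: shape (n, A)."""
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.coef_path + self.y_mean

    # -- plain-text serialization for CLI round trips ------------------
    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"n_lv\t{self.n_lv}\n")
        buf.write(f"y_mean\t{float(self.y_mean)!r}\n")
        buf.write("x_mean\t" + ",".join(repr(float(v)) for v in self.x_mean) + "\n")
        buf.write("coef\t" + ",".join(repr(float(v)) for v in self.coef) + "\n")
        if self.subset is not None:
            buf.write("subset\t" + ",".join(str(i) for i in self.subset) + "\n")
        return buf.getvalue()

    @staticmethod
    def predict_from_text(text: str, X: np.ndarray) -> np.ndarray:
        fields = dict(line.split("\t", 1) for line in text.strip().splitlines())
        coef = np.array([float(v) for v in fields["coef"].split(",")])
        x_mean = np.array([float(v) for v in fields["x_mean"].split(",")])
        y_mean = float(fields["y_mean"])
        X = np.asarray(X, dtype=float)
        if "subset" in fields:
            idx = [int(i) for i in fields["subset"].split(",")]
            X = X[:, idx]
        return (X - x_mean) @ coef + y_mean


@dataclass
class MetricsReport:
    r2: float
    rmse: float
    rrmse: float   # percent of the evaluation-set mean
    rpd: float
    n: int


def _max_rank(n: int, p: int) -> int:
    return max(1, min(n - 1, p))


def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int,
            subset: np.ndarray | None = None) -> PLSModel:
    """Fit a PLS1 model with ``n_lv`` latent variables.

    With ``n_lv`` equal to the rank of the centered ``X``, the fitted
    values coincide with ordinary least squares.  Requests past the rank
    are truncated where the residual X-y covariance vanishes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y length mismatch")
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance; nothing to regress on")
    if not 1 <= n_lv <= _max_rank(n, p):
        raise ValueError(f"n_lv must lie in 1..{_max_rank(n, p)}, got {n_lv}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    q = np.zeros(n_lv)
    Xd, yd = Xc.copy(), yc.copy()
    tol = 1e-12 * max(1.0, float(np.abs(Xc).max()) * float(np.abs(yc).max()))
    a_eff = 0
    for a in range(n_lv):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= tol:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= tol:
            break
        pa = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd -= np.outer(t, pa)
        yd = yd - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pa, t, qa
        a_eff = a + 1
    if a_eff == 0:
        raise ValueError("no latent variable could be extracted (X'y is zero)")
    W, P, T, q = W[:, :a_eff], P[:, :a_eff], T[:, :a_eff], q[:a_eff]

    # rotations R with T = Xc @ R, built by Gram-Schmidt against loadings
    R = np.zeros((p, a_eff))
    for a in range(a_eff):
        r = W[:, a] - R[:, :a] @ (P[:, :a].T @ W[:, a])
        R[:, a] = r
    coef_path = np.cumsum(R * q, axis=1)

    return PLSModel(n_lv=a_eff, x_mean=x_mean, y_mean=y_mean, weights=W,
                    loadings=P, y_loadings=q, scores=T, rotations=R,
                    coef_path=coef_path,
                    subset=None if subset is None else np.asarray(subset))


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in projection.

    ``VIP_j = sqrt(p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a)`` with
    ``SSY_a = q_a^2 t_a't_a`` the response variance captured by LV ``a``.
    The squares average to 1 over wavelengths.
    """
    W, T, q = model.weights, model.scores, model.y_loadings
    p = W.shape[0]
    ssy = q ** 2 * np.einsum("ij,ij->j", T, T)
    total = ssy.sum()
    if total <= 0:
        raise ValueError("model explains no response variance; VIP undefined")
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    return np.sqrt(p * (wn ** 2) @ ssy / total)


def select_lv_mccv(X: np.ndarray, y: np.ndarray, lv_max: int,
                   n_splits: int = 50, split_fraction: float = 0.8,
                   seed: int = 0, lv_min: int = 1) -> int:
    """Choose the LV count minimizing Monte-Carlo cross-validation PRESS.

    Repeated random ``split_fraction`` train / rest monitor splits; the
    predicted residual sum of squares is accumulated over monitor sets at
    every LV count and the argmin returned (ties go to the smaller count).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    cap = _max_rank(int(n * split_fraction), p)
    if lv_max > cap:
        warnings.warn(f"lv_max {lv_max} exceeds attainable rank; capped to {cap}")
        lv_max = cap
    lv_min = max(1, min(lv_min, lv_max))
    rng = np.random.default_rng(seed)
    press = np.zeros(lv_max)
    for _ in range(n_splits):
        perm = rng.permutation(n)
        cut = int(round(n * split_fraction))
        tr, mo = perm[:cut], perm[cut:]
        model = fit_pls(X[tr], y[tr], lv_max)
        pred = model.predict_path(X[mo])          # (m, a_eff)
        res = pred - y[mo, None]
        sse = np.einsum("ij,ij->j", res, res)
        if sse.size < lv_max:                      # rank-deficient split
            sse = np.concatenate([sse, np.full(lv_max - sse.size, sse[-1])])
        press += sse
    press = press[lv_min - 1:]
    return int(np.argmin(press)) + lv_min


def kfold_press_curve(X: np.ndarray, y: np.ndarray, lv_max: int,
                      folds: int = 10, seed: int = 0) -> np.ndarray:
    """Out-of-fold PRESS at every LV count 1..lv_max (k-fold CV)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cap = min(lv_max, _max_rank(n - n // folds - n % folds, X.shape[1]))
    press = np.zeros(cap)
    for k in range(folds):
        mo = perm[k::folds]
        tr = np.setdiff1d(perm, mo, assume_unique=True)
        model = fit_pls(X[tr], y[tr], cap)
        pred = model.predict_path(X[mo])
        res = pred - y[mo, None]
        sse = np.einsum("ij,ij->j", res, res)
        if sse.size < cap:
            sse = np.concatenate([sse, np.full(cap - sse.size, sse[-1])])
        press += sse
    return press


def rmsecv_kfold(X: np.ndarray, y: np.ndarray, n_lv: int,
                 folds: int = 10, seed: int = 0) -> float:
    """k-fold cross-validated RMSE at a fixed LV count (deterministic per seed)."""
    press = kfold_press_curve(X, y, n_lv, folds=folds, seed=seed)
    a = min(n_lv, len(press))
    return float(np.sqrt(press[a - 1] / len(np.asarray(y).ravel())))


def evaluate(model: PLSModel, X: np.ndarray, y: np.ndarray) -> MetricsReport:
    """R2, RMSE, rRMSE and RPD of ``model`` on an evaluation set."""
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("need at least two samples to evaluate")
    yhat = model.predict(X)
    ss_res = float(np.sum((y - yhat) ** 2))
    ybar = float(y.mean())
    ss_tot = float(np.sum((y - ybar) ** 2))
    if ss_tot == 0:
        raise ValueError("evaluation set has zero reference variance")
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(ss_res / y.size))
    rrmse = relative_rmse(rmse, ybar)
    rpd = float(np.sqrt(ss_tot / ss_res)) if ss_res > 0 else float("inf")
    return MetricsReport(r2=r2, rmse=rmse, rrmse=rrmse, rpd=rpd, n=int(y.size))


def relative_rmse(rmse: float, mean: float) -> float:
    """rRMSE in percent: 100 * RMSE / mean of the evaluation set."""
    return 100.0 * rmse / mean


def rpd_from_r2(r2: float) -> float:
    """RPD implied by R2 on the same set: (1 - R2) ** -0.5."""
    return (1.0 - r2) ** -0.5
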