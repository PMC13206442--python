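"""Classical wavelength selectors: CARS, SPA and UVE.

All three share the PLS core and return a :class:`BaselineResult` with
the selected channel indices, per-iteration diagnostics and the best
cross-validated RMSECV, so they plug into the same comparison report as
the ensemble selector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pls import fit_pls, kfold_press_curve, select_lv_mccv

__all__ = ["BaselineResult", "cars_select", "spa_select", "uve_select",
           "cars_edf_constants"]


@dataclass
class BaselineResult:
    method: str
    selected: np.ndarray
    rmsecv_best: float
    n_lv: int
    diagnostics: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


def cars_edf_constants(p: int, n_runs: int) -> tuple[float, float]:
    """Exponentially-decreasing-function constants.

    The keep ratio ``r(i) = a * exp(-k * i)`` is pinned at ``r(1) = 1``
    and ``r(n_runs) = 2 / p`` (two surviving variables at the last run).
    """
    k = np.log(p / 2.0) / (n_runs - 1)
    a = np.exp(k)          # so that a * exp(-k * 1) = 1
    return float(a), float(k)


def _best_rmsecv(X, y, subset, folds, seed, lv_max):
    Xs = X[:, subset]
    cap = min(lv_max, len(subset))
    press = kfold_press_curve(Xs, y, cap, folds=folds, seed=seed)
    lv = int(np.argmin(press)) + 1
    return float(np.sqrt(press[lv - 1] / len(y))), lv


def cars_select(X, y, n_mc: int = 50, lv_max: int = 20, folds: int = 10,
                seed: int = 0, sample_fraction: float = 0.8) -> BaselineResult:
    """Competitive adaptive reweighted sampling.

    Each Monte-Carlo run fits PLS on a random row sample of the current
    subset, ranks variables by |regression coefficient|, enforces the
    exponentially decreasing keep ratio, and resamples the survivors with
    probability proportional to |coefficient| (adaptive reweighted
    sampling, deduplicated).  Every run's subset is scored by k-fold
    RMSECV with the LV count searched up to ``lv_max``; the subset with
    the overall minimum wins.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    rng = np.random.default_rng(seed)
    a, k = cars_edf_constants(p, n_mc)
    current = np.arange(p)
    records = []
    best = (np.inf, None, 0)
    for i in range(1, n_mc + 1):
        rows = rng.choice(n, size=max(int(round(n * sample_fraction)), 2),
                          replace=False)
        lv_fit = min(lv_max, len(rows) - 1, len(current))
        model = fit_pls(X[np.ix_(rows, current)], y[rows], lv_fit)
        w = np.abs(model.coef)
        keep = max(2, int(round(a * np.exp(-k * i) * p)))
        keep = min(keep, len(current))
        forced = current[np.argsort(w)[::-1][:keep]]
        fw = w[np.argsort(w)[::-1][:keep]]
        if fw.sum() > 0:
            drawn = rng.choice(forced, size=keep, replace=True, p=fw / fw.sum())
            subset = np.unique(drawn)
        else:
            subset = np.unique(forced)
        if len(subset) < 2:
            records.append({"run": i, "n_vars": len(subset), "rmsecv": np.nan,
                            "skipped": True})
            current = forced
            continue
        r, lv = _best_rmsecv(X, y, subset, folds, seed, lv_max)
        records.append({"run": i, "n_vars": len(subset), "rmsecv": r,
                        "skipped": False})
        if r < best[0]:
            best = (r, subset, lv)
        current = subset
    if best[1] is None:
        raise RuntimeError("all CARS runs collapsed below two variables")
    return BaselineResult("CARS", np.sort(best[1]), best[0], best[2],
                          diagnostics=pd.DataFrame(records),
                          meta={"n_mc": n_mc, "edf_a": a, "edf_k": k,
                                "sample_fraction": sample_fraction})


def _spa_chain(Xs: np.ndarray, start: int, max_vars: int) -> list[int]:
    """Greedy projection chain from one start column.

    At each step the candidate with the largest residual norm after
    projection onto the orthogonal complement of the chosen set is added
    (ties to the lowest index).
    """
    n, p = Xs.shape
    Z = Xs.copy()
    chain = [start]
    v = Z[:, start] / np.linalg.norm(Z[:, start])
    for _ in range(min(max_vars, n, p) - 1):
        Z = Z - np.outer(v, v @ Z)
        norms = np.linalg.norm(Z, axis=0)
        norms[chain] = -1.0
        j = int(np.argmax(norms))
        if norms[j] <= 1e-10:      # rank exhausted
            break
        chain.append(j)
        v = Z[:, j] / norms[j]
    return chain


def _mlr_cv_rmse(Xs, y, cols, folds, seed):
    """k-fold CV RMSE of ordinary multiple linear regression on ``cols``."""
    n = len(y)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    sse = 0.0
    A = Xs[:, cols]
    for kf in range(folds):
        mo = perm[kf::folds]
        tr = np.setdiff1d(perm, mo, assume_unique=True)
        Atr = np.column_stack([np.ones(len(tr)), A[tr]])
        beta, *_ = np.linalg.lstsq(Atr, y[tr], rcond=None)
        pred = np.column_stack([np.ones(len(mo)), A[mo]]) @ beta
        sse += float(np.sum((pred - y[mo]) ** 2))
    return np.sqrt(sse / n)


def spa_select(X, y, max_vars: int | None = None, folds: int = 10,
               seed: int = 0, n_starts: int | None = 10) -> BaselineResult:
    """Successive projections algorithm.

    X is autoscaled first.  From each candidate start variable a chain is
    grown by repeated orthogonal projection; every prefix of every chain
    is scored by cross-validated RMSE of a multiple linear regression and
    the global minimum returned.  ``max_vars`` is capped below the
    training-fold size; ``n_starts`` limits the start set to the channels
    most correlated with y (None = all channels).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    n_train = n - n // folds                      # smallest CV training fold
    cap = max(1, min(max_vars or 30, n_train - 1, p))
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    yc = y - y.mean()
    if n_starts is None or n_starts >= p:
        starts = list(range(p))
    else:
        corr = np.abs(Z.T @ yc)
        starts = np.argsort(corr)[::-1][:n_starts].tolist()
    best = (np.inf, None)
    records = []
    for s0 in starts:
        chain = _spa_chain(Z, s0, cap)
        for m in range(1, len(chain) + 1):
            cols = chain[:m]
            r = _mlr_cv_rmse(Z, y, cols, folds, seed)
            records.append({"start": s0, "m": m, "rmsecv": r})
            if r < best[0]:
                best = (r, cols)
    sel = np.sort(np.asarray(best[1]))
    return BaselineResult("SPA", sel, best[0], n_lv=len(sel),
                          diagnostics=pd.DataFrame(records),
                          meta={"max_vars": cap, "n_starts": len(starts)})


def uve_select(X, y, n_mc: int = 150, lv: int | None = None, folds: int = 10,
               seed: int = 0, sample_fraction: float = 0.8,
               cutoff: str = "max", noise_scale: float = 1.0) -> BaselineResult:
    """Uninformative variable elimination.

    ``p`` uniform-noise columns are appended to X; over ``n_mc`` random
    row resamples a PLS model is fitted at a fixed LV count (chosen once
    by Monte-Carlo CV on the augmented matrix when not given) and the
    per-variable coefficient sequences collected.  The stability of a
    variable is mean/sd of its coefficients; real variables whose
    |stability| does not exceed the noise-variable cutoff (``"max"`` or
    ``"q99"``) are eliminated.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    rng = np.random.default_rng(seed)
    noise = rng.uniform(0.0, noise_scale, size=(n, p))
    Xa = np.hstack([X, noise])
    if lv is None:
        lv = select_lv_mccv(Xa, y, lv_max=min(20, n // 2), n_splits=30,
                            seed=seed)
    coefs = np.zeros((n_mc, 2 * p))
    for i in range(n_mc):
        rows = rng.choice(n, size=max(int(round(n * sample_fraction)), lv + 2),
                          replace=False)
        model = fit_pls(Xa[rows], y[rows], min(lv, len(rows) - 1))
        coefs[i] = model.coef
    sd = coefs.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    stability = coefs.mean(axis=0) / sd
    noise_stab = np.abs(stability[p:])
    thr = float(noise_stab.max()) if cutoff == "max" \
        else float(np.quantile(noise_stab, 0.99))
    selected = np.where(np.abs(stability[:p]) > thr)[0]
    if selected.size == 0:
        raise ValueError("UVE eliminated every variable; relax the cutoff "
                         "(cutoff='q99') or lower the noise scale")
    r, lv_best = _best_rmsecv(X, y, selected, folds, seed, lv_max=min(20, n // 2))
    diag = pd.DataFrame({"stability": stability[:p]})
    return BaselineResult("UVE", selected, r, lv_best, diagnostics=diag,
                          meta={"n_mc": n_mc, "lv_fit": lv, "cutoff": cutoff,
                                "cutoff_value": thr})
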