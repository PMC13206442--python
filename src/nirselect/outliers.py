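"""Monte-Carlo cross-validation outlier screening.

Repeated random train/monitor splits are fitted with PLS; the absolute
prediction residual of every monitor sample is recorded across
iterations.  Samples whose residual mean exceeds a threshold (persistent
bias) or whose residual variance exceeds a threshold (prediction
instability) are flagged as outliers.  Default thresholds 0.6 % protein
(mean) and 0.01 %^2 (variance) suit references on the protein-percent
scale but are data-dependent and configurable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import ReferenceTable, SpectraSet
from .pls import fit_pls

__all__ = ["mccv_residuals", "flag_outliers"]


def mccv_residuals(s: SpectraSet | np.ndarray, y, n_iter: int = 1000,
                   lv_min: int = 5, lv_max: int = 20,
                   split_fraction: float = 0.8, seed: int = 0) -> pd.DataFrame:
    """Per-sample residual statistics over Monte-Carlo CV iterations.

    Each iteration draws a random ``split_fraction`` train / rest monitor
    split.  The LV count is picked per iteration by PRESS on an inner
    80/20 split of the train part (searched in ``lv_min..lv_max``), the
    model refit information reused to predict the monitor samples, and
    their absolute residuals accumulated.

    Returns a table indexed like the input with columns ``n_monitor``,
    ``mean_abs_residual``, ``residual_variance``.  Samples that never
    landed in a monitor set carry NaN statistics (flagging skips them).
    """
    if isinstance(s, SpectraSet):
        X = s.X
        ids = s.sample_ids
        if isinstance(y, ReferenceTable):
            y = y.aligned_to(s)
    else:
        X = np.asarray(s, dtype=float)
        ids = [str(i) for i in range(X.shape[0])]
        if isinstance(y, ReferenceTable):
            y = y.y
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 20:
        raise ValueError("MCCV outlier screening needs at least 20 samples")
    rng = np.random.default_rng(seed)
    abs_sums = np.zeros(n)
    sums = np.zeros(n)
    sq_sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for _ in range(n_iter):
        perm = rng.permutation(n)
        cut = int(round(n * split_fraction))
        tr, mo = perm[:cut], perm[cut:]
        # inner split of the train part scores PRESS at every LV count
        inner_cut = int(round(len(tr) * 0.8))
        itr, imo = tr[:inner_cut], tr[inner_cut:]
        cap = min(lv_max, len(itr) - 1, p)
        inner = fit_pls(X[itr], y[itr], cap)
        pred = inner.predict_path(X[imo])
        press = np.sum((pred - y[imo, None]) ** 2, axis=0)
        lo = min(lv_min, len(press))
        lv = int(np.argmin(press[lo - 1:])) + lo
        model = fit_pls(X[tr], y[tr], min(lv, len(tr) - 1, p))
        res = model.predict(X[mo]) - y[mo]
        abs_sums[mo] += np.abs(res)
        sums[mo] += res
        sq_sums[mo] += res ** 2
        counts[mo] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        cnt = np.maximum(counts, 1)
        mean_abs = np.where(counts > 0, abs_sums / cnt, np.nan)
        variance = np.where(counts > 1, sq_sums / cnt - (sums / cnt) ** 2, np.nan)
    variance = np.clip(variance, 0.0, None)
    return pd.DataFrame({"n_monitor": counts, "mean_abs_residual": mean_abs,
                         "residual_variance": variance},
                        index=pd.Index(ids, name="sample_id"))


def flag_outliers(stats: pd.DataFrame, mean_thresh: float = 0.6,
                  var_thresh: float = 0.01) -> np.ndarray:
    """Indices flagged by the OR rule: mean > mean_thresh or variance > var_thresh.

    Samples with undefined statistics (never monitored) are not flagged.
    """
    mean = stats["mean_abs_residual"].to_numpy()
    var = stats["residual_variance"].to_numpy()
    with np.errstate(invalid="ignore"):
        mask = (mean > mean_thresh) | (var > var_thresh)
    mask &= ~(np.isnan(mean) | np.isnan(var))
    return np.where(mask)[0]
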