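"""Exact Shapley attribution for linear calibration models.

For a model linear in its inputs under the interventional
feature-independence convention, the Shapley value of feature j for a
sample x collapses to the closed form

    phi_j(x) = beta_j * (x_j - mu_j),

with mu_j the background-mean response and the base value the prediction
at the background mean.  The general subset-enumeration definition
(weighted marginal contributions over all feature subsets) is provided
as a brute-force oracle for small feature counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

from .pls import PLSModel

__all__ = ["Attribution", "linear_shap", "brute_force_shap", "shap_summary"]


@dataclass
class Attribution:
    phi: np.ndarray              # (n_targets, n_features), % protein units
    base_value: float            # prediction at the background mean
    feature_values: np.ndarray   # the target responses (n_targets, n_features)
    predictions: np.ndarray      # model output per target sample
    feature_axis: np.ndarray | None = None
    sample_ids: list | None = None

    def to_long_frame(self) -> pd.DataFrame:
        n, p = self.phi.shape
        ids = self.sample_ids or [str(i) for i in range(n)]
        feat = (self.feature_axis if self.feature_axis is not None
                else np.arange(p))
        return pd.DataFrame({
            "sample_id": np.repeat(ids, p),
            "feature": np.tile(feat, n),
            "feature_value": self.feature_values.ravel(),
            "shap_value": self.phi.ravel(),
        })


def linear_shap(model: PLSModel, background: np.ndarray,
                targets: np.ndarray, feature_axis=None,
                sample_ids=None) -> Attribution:
    """Exact per-sample Shapley values of a fitted PLS model.

    ``background`` and ``targets`` are intensity matrices restricted to
    the model's input channels (the selected-wavelength subset).
    Efficiency — sum of phi plus the base value equals the model
    prediction — holds exactly for every sample.
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if background.size == 0:
        raise ValueError("empty background set")
    mu = background.mean(axis=0)
    beta = model.coef
    if mu.size != beta.size:
        raise ValueError(f"background has {mu.size} features, model uses {beta.size}")
    phi = (targets - mu) * beta
    base = float(model.predict(mu[None, :])[0])
    preds = model.predict(targets)
    return Attribution(phi=phi, base_value=base, feature_values=targets,
                       predictions=preds,
                       feature_axis=None if feature_axis is None
                       else np.asarray(feature_axis),
                       sample_ids=list(sample_ids) if sample_ids is not None else None)


def brute_force_shap(predict_fn, x, background_mean, n_features_limit: int = 12
                     ) -> np.ndarray:
    """Subset-enumeration Shapley values.

    ``f(S)`` is the prediction with features outside S pinned at the
    background mean; each feature's value is the weighted average of its
    marginal contributions ``f(S + {i}) - f(S)`` over all subsets S with
    weight ``|S|! (M - |S| - 1)! / M!``.  Exponential in the feature
    count, hence capped.
    """
    x = np.asarray(x, dtype=float).ravel()
    mu = np.asarray(background_mean, dtype=float).ravel()
    m = x.size
    if m > n_features_limit:
        raise ValueError(f"{m} features exceed brute-force limit {n_features_limit}")
    fvals = {}
    idx = tuple(range(m))
    for r in range(m + 1):
        for S in combinations(idx, r):
            z = mu.copy()
            z[list(S)] = x[list(S)]
            fvals[S] = float(np.asarray(predict_fn(z[None, :])).ravel()[0])
    phi = np.zeros(m)
    fact = factorial(m)
    for i in idx:
        rest = tuple(j for j in idx if j != i)
        for r in range(m):
            w = factorial(r) * factorial(m - r - 1) / fact
            for S in combinations(rest, r):
                Si = tuple(sorted(S + (i,)))
                phi[i] += w * (fvals[Si] - fvals[S])
    return phi


def shap_summary(attr: Attribution) -> pd.DataFrame:
    """Rank features by mean |phi|, with a direction summary.

    ``direction_corr`` is the correlation between a feature's response
    values and its Shapley values over samples — for a linear model its
    sign equals the sign of the coefficient (the beeswarm color-gradient
    reading).
    """
    if attr.phi.size == 0:
        raise ValueError("empty attribution")
    n, p = attr.phi.shape
    feat = attr.feature_axis if attr.feature_axis is not None else np.arange(p)
    mean_abs = np.abs(attr.phi).mean(axis=0)
    corr = np.zeros(p)
    for j in range(p):
        xv, pv = attr.feature_values[:, j], attr.phi[:, j]
        if n > 1 and xv.std() > 0 and pv.std() > 0:
            corr[j] = float(np.corrcoef(xv, pv)[0, 1])
    df = pd.DataFrame({"feature": feat, "mean_abs_shap": mean_abs,
                       "direction_corr": corr,
                       "mean_shap": attr.phi.mean(axis=0)})
    return df.sort_values("mean_abs_shap", ascending=False,
                          kind="stable").reset_index(drop=True)
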