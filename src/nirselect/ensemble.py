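"""Multi-learner ensemble importance-score wavelength selection.

The selector fuses the five learner scores into one ranking and then
grows a wavelength subset greedily under cross-validated error:

1. each learner's raw scores are min-max normalized to [0, 1];
2. the normalized scores are summed elementwise into an integrated
   ensemble score in [0, K] (K = 5 learners);
3. wavelengths are ranked by descending ensemble score (ties broken by
   ascending channel index) and introduced one at a time; after every
   addition a PLS model is refitted with its LV count re-searched by
   k-fold CV, and the candidate is retained only if RMSECV strictly
   decreases.  The first failure to decrease terminates the scan and the
   subset at the turning point is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .learners import RawImportance, all_importances
from .pls import kfold_press_curve

__all__ = [
    "ImportanceProfile", "SelectionResult", "normalize_scores",
    "ensemble_score", "rank_wavelengths", "forward_select", "ensemble_select",
]


@dataclass
class ImportanceProfile:
    """Raw, normalized and fused per-wavelength importances."""

    raw: dict                 # learner -> raw score vector
    normalized: dict          # learner -> [0, 1] score vector
    ies: np.ndarray           # integrated ensemble score in [0, K]
    axis: np.ndarray | None = None

    @property
    def n_learners(self) -> int:
        return len(self.raw)

    def to_frame(self) -> pd.DataFrame:
        cols = {"channel": np.arange(len(self.ies))}
        if self.axis is not None:
            cols["wavenumber"] = self.axis
        for k, v in self.raw.items():
            cols[f"raw_{k}"] = v
        for k, v in self.normalized.items():
            cols[f"norm_{k}"] = v
        cols["ensemble_score"] = self.ies
        return pd.DataFrame(cols)


@dataclass
class SelectionResult:
    ranking: np.ndarray            # channel indices by descending score
    selected: np.ndarray           # final subset (selection order)
    trajectory: pd.DataFrame       # columns: n_evaluated, channel, rmsecv, retained
    stop_reason: str
    n_lv: int                      # LV count of the final subset model
    rmsecv: float                  # RMSECV at the turning point
    meta: dict = field(default_factory=dict)


def normalize_scores(raw: RawImportance | np.ndarray) -> np.ndarray:
    """Min-max normalization to [0, 1]; a constant vector maps to zeros."""
    v = raw.values if isinstance(raw, RawImportance) else np.asarray(raw, dtype=float)
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        warnings.warn("degenerate importance vector (constant); normalized to zeros")
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def ensemble_score(normalized: list[np.ndarray]) -> np.ndarray:
    """Elementwise sum of normalized learner scores; range [0, K]."""
    if not normalized:
        raise ValueError("no score vectors to fuse")
    lengths = {len(v) for v in normalized}
    if len(lengths) != 1:
        raise ValueError(f"score vectors of unequal length: {sorted(lengths)}")
    return np.sum(normalized, axis=0)


def rank_wavelengths(ies: np.ndarray) -> np.ndarray:
    """Channel indices by descending score, ties by ascending index."""
    ies = np.asarray(ies, dtype=float)
    return np.lexsort((np.arange(len(ies)), -ies))


def _subset_rmsecv(X, y, subset, folds, seed, lv_max):
    """Best k-fold RMSECV over LV counts for a channel subset."""
    Xs = X[:, subset]
    cap = min(lv_max, len(subset))
    press = kfold_press_curve(Xs, y, cap, folds=folds, seed=seed)
    lv = int(np.argmin(press)) + 1
    return float(np.sqrt(press[lv - 1] / len(y))), lv


def forward_select(X, y, ies, folds: int = 10, seed: int = 0,
                   lv_max: int = 20, patience: int = 0, tol: float = 0.0,
                   max_evals: int | None = None) -> SelectionResult:
    """Grow the subset in score order until RMSECV stops decreasing.

    The top-ranked wavelength is always retained.  Each further candidate
    is kept only if it lowers RMSECV by more than ``tol`` (strict
    decrease at the default 0); ``patience`` consecutive failures are
    tolerated before stopping (0 = stop at the first failure).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    ranking = rank_wavelengths(ies)
    if max_evals is not None:
        ranking = ranking[:max_evals]
    selected = [int(ranking[0])]
    best, lv = _subset_rmsecv(X, y, selected, folds, seed, lv_max)
    rows = [{"n_evaluated": 1, "channel": selected[0], "rmsecv": best,
             "retained": True}]
    fails = 0
    stop_reason = "ranking exhausted"
    for k, ch in enumerate(ranking[1:], start=2):
        cand = selected + [int(ch)]
        r, lv_c = _subset_rmsecv(X, y, cand, folds, seed, lv_max)
        retained = r < best - tol
        rows.append({"n_evaluated": k, "channel": int(ch), "rmsecv": r,
                     "retained": retained})
        if retained:
            selected, best, lv = cand, r, lv_c
            fails = 0
        else:
            fails += 1
            if fails > patience:
                stop_reason = "rmsecv stopped decreasing"
                break
    traj = pd.DataFrame(rows)
    return SelectionResult(ranking=ranking, selected=np.array(selected),
                           trajectory=traj, stop_reason=stop_reason,
                           n_lv=lv, rmsecv=best,
                           meta={"folds": folds, "seed": seed,
                                 "patience": patience, "tol": tol})


def ensemble_select(X, y, axis=None, seed: int = 0, folds: int = 10,
                    lv_max: int = 20, patience: int = 25,
                    max_evals: int | None = 200,
                    learner_overrides: dict | None = None,
                    ) -> tuple[ImportanceProfile, SelectionResult]:
    """Full pipeline: five learners -> normalization -> fusion -> selection.

    The orchestrator evaluates the ranked trajectory past local plateaus
    (``patience`` consecutive non-improvements tolerated, default 25)
    and returns the subset at the global RMSECV minimum — the turning
    point of the trajectory curve.  Pass ``patience=0`` for the strict
    stop-at-first-failure scan.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    raws = all_importances(X, y, seed=seed, folds=folds,
                           **(learner_overrides or {}))
    normalized = {r.learner: normalize_scores(r) for r in raws}
    ies = ensemble_score(list(normalized.values()))
    assert float(ies.min()) >= 0.0 and float(ies.max()) <= len(raws) + 1e-9
    profile = ImportanceProfile(raw={r.learner: r.values for r in raws},
                                normalized=normalized, ies=ies,
                                axis=None if axis is None else np.asarray(axis))
    result = forward_select(X, y, ies, folds=folds, seed=seed, lv_max=lv_max,
                            patience=patience, max_evals=max_evals)
    return profile, result
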