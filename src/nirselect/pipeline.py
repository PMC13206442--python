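"""End-to-end calibration workflow.

Order of operations mirrors standard NIR calibration practice:
preprocessing (optionally a full evaluation grid) -> MCCV outlier
screening -> 4:1 train/test split -> wavelength selection (ensemble +
classical baselines) -> PLS calibration per selected subset -> metrics
comparison table -> Shapley attribution of the ensemble model.

Every stage takes an explicit seed and all artifacts are plain-text
tables, so two runs with the same config are identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import baselines as bl
from .dataset import (ReferenceTable, SpectraSet, pca_overlap, split_samples,
                      summarize_reference)
from .ensemble import ensemble_select
from .outliers import flag_outliers, mccv_residuals
from .pls import evaluate, fit_pls, kfold_press_curve
from .preprocess import apply_preprocess, evaluate_grid
from .shap_linear import linear_shap, shap_summary
from .synthetic import SynthConfig, generate

__all__ = ["RunConfig", "run_pipeline", "paired_prediction_test",
           "percent_of_full", "comparison_table"]


@dataclass
class RunConfig:
    spectra_path: str | None = None
    reference_path: str | None = None
    synth: SynthConfig | None = None
    preprocessing: str | None = "WD"      # method name, "grid", or None
    grid_repeats: int = 10
    outlier_screening: bool = True
    outlier_iters: int = 300
    mean_thresh: float = 0.6
    var_thresh: float = 0.01
    split_ratio: tuple[int, int] = (4, 1)
    selectors: tuple[str, ...] = ("ensemble", "CARS", "SPA", "UVE")
    folds: int = 10
    lv_max: int = 20
    seed: int = 0
    out_dir: str | None = None


def percent_of_full(k: int, p: int) -> float:
    """Selected-count share of the full spectrum, percent, 2 decimals."""
    return round(100.0 * k / p, 2)


def paired_prediction_test(y_true, y_pred, alpha: float = 0.05):
    """One-sample two-tailed t test on prediction residuals.

    Equivalent to a paired t test of predictions against measurements.
    Returns (t statistic, p value, critical value at alpha with n-1 df).
    Zero-variance residuals yield t = 0, p = 1 (degenerate, no bias
    detectable) rather than a NaN.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size < 2:
        raise ValueError("need at least two samples")
    res = y_pred - y_true
    crit = float(sps.t.ppf(1.0 - alpha / 2.0, y_true.size - 1))
    if np.std(res, ddof=1) == 0:
        return 0.0, 1.0, crit
    t, pval = sps.ttest_1samp(res, 0.0)
    return float(t), float(pval), crit


def _fit_and_score(X_tr, y_tr, X_te, y_te, subset, folds, lv_max, seed):
    Xs_tr = X_tr[:, subset] if subset is not None else X_tr
    Xs_te = X_te[:, subset] if subset is not None else X_te
    cap = min(lv_max, Xs_tr.shape[1], Xs_tr.shape[0] - 1)
    press = kfold_press_curve(Xs_tr, y_tr, cap, folds=folds, seed=seed)
    lv = int(np.argmin(press)) + 1
    model = fit_pls(Xs_tr, y_tr, lv, subset=subset)
    return model, evaluate(model, Xs_tr, y_tr), evaluate(model, Xs_te, y_te)


def comparison_table(rows: list[dict]) -> pd.DataFrame:
    """Model-comparison table (one row per selection method)."""
    df = pd.DataFrame(rows)
    order = ["method", "n_wavelengths", "pct_of_full", "r2_train", "r2_test",
             "rmse_train", "rmse_test", "rrmse_train_pct", "rrmse_test_pct",
             "rpd_test", "lv"]
    return df[order]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow; returns a dict of result tables/objects."""
    seed = config.seed
    results: dict = {"config": config}

    # ---------------- input ----------------
    if config.synth is not None:
        spectra, ref, truth = generate(config.synth)
        results["ground_truth"] = truth
    elif config.spectra_path and config.reference_path:
        from .dataset import read_reference, read_spectra
        spectra = read_spectra(config.spectra_path)
        ref = read_reference(config.reference_path)
    else:
        raise ValueError("config needs either synth or spectra/reference paths")

    # ---------------- preprocessing ----------------
    if config.preprocessing == "grid":
        grid = evaluate_grid(spectra, ref, repeats=config.grid_repeats,
                             folds=config.folds, seed=seed)
        results["preprocess_grid"] = grid
        best = grid.sort_values("rmsecv").iloc[0]["method"]
        results["preprocessing_used"] = best
        if best != "RAW":
            spectra = apply_preprocess(spectra, best)
    elif config.preprocessing and config.preprocessing != "RAW":
        spectra = apply_preprocess(spectra, config.preprocessing)
        results["preprocessing_used"] = config.preprocessing
    else:
        results["preprocessing_used"] = "RAW"

    y_all = ref.aligned_to(spectra)

    # ---------------- outlier screening ----------------
    if config.outlier_screening:
        stats = mccv_residuals(spectra, y_all, n_iter=config.outlier_iters,
                               seed=seed)
        flagged = flag_outliers(stats, config.mean_thresh, config.var_thresh)
        stats["flagged"] = False
        stats.iloc[flagged, stats.columns.get_loc("flagged")] = True
        results["outlier_stats"] = stats
        if len(flagged) > spectra.n_samples // 2:
            raise ValueError(
                f"outlier rule flagged {len(flagged)} of {spectra.n_samples} "
                "samples; the mean/variance thresholds are scale-dependent — "
                "adjust mean_thresh/var_thresh to this dataset's residual "
                "distribution")
        keep = np.setdiff1d(np.arange(spectra.n_samples), flagged)
        spectra = spectra.select_samples(keep)
        y_all = y_all[keep]

    # ---------------- split ----------------
    split = split_samples(spectra.n_samples, config.split_ratio, seed=seed)
    tr, te = split.train_indices, split.test_indices
    X_tr, X_te = spectra.X[tr], spectra.X[te]
    y_tr, y_te = y_all[tr], y_all[te]
    results["split"] = split
    results["split_summary"] = pd.DataFrame([
        {"set": "all", **summarize_reference(y_all)},
        {"set": "train", **summarize_reference(y_tr)},
        {"set": "test", **summarize_reference(y_te)},
    ])
    results["pca"] = pca_overlap(spectra.select_samples(tr),
                                 spectra.select_samples(te), k=3)

    # ---------------- selection + calibration ----------------
    p = spectra.n_channels
    subsets: dict = {"FULL": None}
    for name in config.selectors:
        if name == "ensemble":
            profile, sel = ensemble_select(X_tr, y_tr, axis=spectra.axis,
                                           seed=seed, folds=config.folds,
                                           lv_max=config.lv_max)
            results["importance_profile"] = profile
            results["ensemble_selection"] = sel
            subsets["ensemble"] = sel.selected
        elif name == "CARS":
            res = bl.cars_select(X_tr, y_tr, folds=config.folds,
                                 lv_max=config.lv_max, seed=seed)
            results["cars"] = res
            subsets["CARS"] = res.selected
        elif name == "SPA":
            res = bl.spa_select(X_tr, y_tr, folds=config.folds, seed=seed)
            results["spa"] = res
            subsets["SPA"] = res.selected
        elif name == "UVE":
            res = bl.uve_select(X_tr, y_tr, folds=config.folds, seed=seed)
            results["uve"] = res
            subsets["UVE"] = res.selected
        else:
            raise ValueError(f"unknown selector {name!r}")

    rows, models = [], {}
    for name, subset in subsets.items():
        model, m_tr, m_te = _fit_and_score(X_tr, y_tr, X_te, y_te, subset,
                                           config.folds, config.lv_max, seed)
        models[name] = model
        k = p if subset is None else len(subset)
        rows.append({"method": name, "n_wavelengths": k,
                     "pct_of_full": percent_of_full(k, p),
                     "r2_train": round(m_tr.r2, 3), "r2_test": round(m_te.r2, 3),
                     "rmse_train": round(m_tr.rmse, 3),
                     "rmse_test": round(m_te.rmse, 3),
                     "rrmse_train_pct": round(m_tr.rrmse, 2),
                     "rrmse_test_pct": round(m_te.rrmse, 2),
                     "rpd_test": round(m_te.rpd, 3), "lv": model.n_lv})
    results["models"] = models
    results["comparison"] = comparison_table(rows)

    # ---------------- bias test + attribution ----------------
    best_name = "ensemble" if "ensemble" in models else "FULL"
    best_model = models[best_name]
    subset = subsets[best_name]
    Xe_te = X_te if subset is None else X_te[:, subset]
    t, pval, crit = paired_prediction_test(y_te, best_model.predict(Xe_te))
    results["bias_test"] = {"method": best_name, "t": t, "p": pval,
                            "critical": crit}
    Xe_tr = X_tr if subset is None else X_tr[:, subset]
    attr = linear_shap(best_model, Xe_tr, Xe_te,
                       feature_axis=None if subset is None
                       else spectra.axis[subset])
    results["shap_summary"] = shap_summary(attr)

    if config.out_dir:
        _write_artifacts(results, Path(config.out_dir))
    return results


def _write_artifacts(results: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for key in ("preprocess_grid", "outlier_stats", "split_summary",
                "comparison", "shap_summary"):
        if key in results:
            results[key].to_csv(out / f"{key}.csv", index=True)
    if "ensemble_selection" in results:
        sel = results["ensemble_selection"]
        sel.trajectory.to_csv(out / "selection_trajectory.csv", index=False)
        results["importance_profile"].to_frame().to_csv(
            out / "importance_scores.csv", index=False)
    summary = {"preprocessing_used": results.get("preprocessing_used"),
               "bias_test": results.get("bias_test")}
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
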