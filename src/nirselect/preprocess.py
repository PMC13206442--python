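"""Spectral preprocessing operators and the cross-validated evaluation grid.

Seven operators common in NIR practice — Savitzky-Golay smoothing (SG),
multiplicative scatter correction (MSC), standard normal variate (SNV),
wavelet denoising (WD), Fourier low-pass denoising (FT), Gaussian
deconvolution (Deconv) and moving-average smoothing (MAS) — plus ordered
two-step combinations.  All operators act row-wise (per spectrum),
preserve the matrix shape and are pure functions of their inputs.

The evaluation grid scores RAW, each single operator and each ordered
pair (29 configurations) by PLS regression under repeated k-fold
cross-validation, mirroring the standard protocol for choosing a
preprocessing scheme before calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import pywt
from scipy.signal import savgol_filter

from .dataset import ReferenceTable, SpectraSet
from .pls import kfold_press_curve, rpd_from_r2, select_lv_mccv

__all__ = [
    "sg_smooth", "msc", "snv", "wavelet_denoise", "fourier_denoise",
    "deconvolve", "moving_average", "PreprocessSpec", "compose",
    "apply_preprocess", "table_grid_specs", "evaluate_grid", "METHODS",
]


def sg_smooth(X, window: int = 7, polyorder: int = 3, deriv: int = 0):
    """Savitzky-Golay filtering per row.

    Edges are handled by polynomial extrapolation of the boundary fits,
    so a polynomial of degree <= polyorder is reproduced exactly over the
    whole row.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if window >= X.shape[1]:
        raise ValueError(f"window {window} >= {X.shape[1]} channels")
    return savgol_filter(X, window, polyorder, deriv=deriv, axis=1, mode="interp")


def msc(X, reference=None):
    """Multiplicative scatter correction against a reference spectrum.

    Each row ``x`` is regressed ``x ~ a + b * ref`` by OLS and replaced by
    ``(x - a) / b``.  Default reference is the mean spectrum.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 2:
        raise ValueError("MSC needs at least two channels")
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    rc = ref - ref.mean()
    denom = float(rc @ rc)
    if denom == 0:
        raise ValueError("MSC reference spectrum has zero variance")
    b = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    a = X.mean(axis=1) - b * ref.mean()
    return (X - a[:, None]) / b[:, None]


def snv(X):
    """Standard normal variate: center and unit-scale each spectrum."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        bad = np.where(sd.ravel() == 0)[0].tolist()
        raise ValueError(f"constant spectra cannot be SNV-scaled: rows {bad}")
    return (X - X.mean(axis=1, keepdims=True)) / sd


def wavelet_denoise(X, wavelet: str = "coif3", level: int = 10,
                    mode: str = "soft", _lineage: dict | None = None):
    """Multilevel wavelet shrinkage per row.

    Detail coefficients are soft-thresholded at the universal threshold
    ``sigma * sqrt(2 ln p)`` with ``sigma`` the median absolute deviation
    of the finest-level details over 0.6745.  A requested decomposition
    level deeper than the signal allows is capped.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    w = pywt.Wavelet(wavelet)
    max_level = pywt.dwt_max_level(p, w.dec_len)
    if max_level < 1:
        raise ValueError(f"signal of length {p} too short for {wavelet}")
    eff_level = min(level, max_level)
    if eff_level < level and _lineage is not None:
        _lineage["wavelet_level_capped"] = eff_level
    out = np.empty_like(X)
    for i, row in enumerate(X):
        coeffs = pywt.wavedec(row, w, level=eff_level)
        finest = coeffs[-1]
        sigma = np.median(np.abs(finest - np.median(finest))) / 0.6745
        thr = sigma * np.sqrt(2.0 * np.log(p))
        if thr > 0:
            den = [coeffs[0]] + [pywt.threshold(c, thr, mode=mode)
                                 for c in coeffs[1:]]
        else:
            den = coeffs

        out[i] = pywt.waverec(den, w)[:p]
    return out


def fourier_denoise(X, cutoff_ratio: float = 0.1):
    """Low-pass Fourier filter: zero coefficients above cutoff_ratio x Nyquist."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    if p < 4:
        raise ValueError("need at least 4 channels for Fourier denoising")
    if not 0 < cutoff_ratio <= 1:
        raise ValueError("cutoff_ratio must lie in (0, 1]")
    F = np.fft.rfft(X, axis=1)
    nyq = F.shape[1] - 1
    keep = int(np.floor(cutoff_ratio * nyq))
    F[:, keep + 1:] = 0
    return np.fft.irfft(F, n=p, axis=1)


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    x = np.arange(size) - (size - 1) / 2.0
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_blur(X, kernel_size: int = 10, sigma: float = 1.0):
    """Circular Gaussian convolution per row (forward model of deconvolve)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    kern = np.zeros(p)
    k = _gaussian_kernel(kernel_size, sigma)
    idx = (np.arange(kernel_size) - (kernel_size - 1) // 2) % p
    np.add.at(kern, idx, k)
    return np.fft.irfft(np.fft.rfft(X, axis=1) * np.fft.rfft(kern), n=p, axis=1)


def deconvolve(X, kernel_size: int = 10, sigma: float = 1.0,
               eps_scale: float = 1e-3):
    """Regularized inverse Gaussian filtering (band-sharpening).

    Frequency-domain division by a unit-sum Gaussian kernel with a ridge
    constant ``eps = eps_scale * max |H|^2`` guarding near-zero kernel
    frequencies.  As ``eps -> inf`` the output approaches the input.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    if p <= kernel_size:
        raise ValueError(f"need more than {kernel_size} channels")
    kern = np.zeros(p)
    k = _gaussian_kernel(kernel_size, sigma)
    idx = (np.arange(kernel_size) - (kernel_size - 1) // 2) % p
    np.add.at(kern, idx, k)
    H = np.fft.rfft(kern)
    power = np.abs(H) ** 2
    eps = eps_scale * power.max()
    G = np.conj(H) / (power + eps)
    G = G / G[0].real          # unit DC gain: mean level preserved exactly
    return np.fft.irfft(np.fft.rfft(X, axis=1) * G, n=p, axis=1)


def moving_average(X, window: int = 3):
    """Centered moving-average smoothing; edges use a shrinking window."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window >= p:
        raise ValueError(f"window {window} >= {p} channels")
    kern = np.ones(window)
    sums = np.apply_along_axis(np.convolve, 1, X, kern, "same")
    counts = np.convolve(np.ones(p), kern, "same")
    return sums / counts


METHODS = {
    "SG": sg_smooth,
    "MSC": msc,
    "SNV": snv,
    "WD": wavelet_denoise,
    "FT": fourier_denoise,
    "Deconv": deconvolve,
    "MAS": moving_average,
}

_METHOD_ORDER = ["SG", "MSC", "SNV", "WD", "FT", "Deconv", "MAS"]


@dataclass
class PreprocessSpec:
    """A named preprocessing step or ordered pair, e.g. ``"SG+MSC"``."""

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        parts = self.steps
        for part in parts:
            if part != "RAW" and part not in METHODS:
                raise ValueError(f"unknown preprocessing method {part!r}")
        if len(parts) == 2 and parts[0] == parts[1]:
            raise ValueError("pair members must be distinct")

    @property
    def steps(self) -> list[str]:
        return self.name.split("+")


def compose(spec: PreprocessSpec | str):
    """Build the operator for a spec; steps apply strictly left to right.

    The returned callable carries ``.lineage`` — the ``"A+B"`` name plus
    any adjustments made while running (e.g. a capped wavelet level).
    """
    if isinstance(spec, str):
        spec = PreprocessSpec(spec)
    lineage: dict = {"name": spec.name}

    def op(X):
        out = np.atleast_2d(np.asarray(X, dtype=float))
        for step in spec.steps:
            if step == "RAW":
                continue
            kwargs = dict(spec.params.get(step, {}))
            if step == "WD":
                kwargs["_lineage"] = lineage
            out = METHODS[step](out, **kwargs)
        return out

    op.lineage = lineage
    op.spec = spec
    return op


def apply_preprocess(s: SpectraSet, spec: PreprocessSpec | str) -> SpectraSet:
    op = compose(spec)
    X = op(s.X)
    meta = dict(s.meta)
    meta["preprocessing"] = meta.get("preprocessing", []) + [op.lineage["name"]]
    return SpectraSet(list(s.sample_ids), s.axis.copy(), X, meta)


def table_grid_specs() -> list[PreprocessSpec]:
    """RAW + 7 singles + 21 ordered pairs = 29 grid configurations."""
    specs = [PreprocessSpec("RAW")]
    specs += [PreprocessSpec(m) for m in _METHOD_ORDER]
    specs += [PreprocessSpec(f"{a}+{b}") for a, b in combinations(_METHOD_ORDER, 2)]
    return specs


def evaluate_grid(s: SpectraSet, ref: ReferenceTable, repeats: int = 100,
                  folds: int = 10, seed: int = 0, lv_max: int = 20,
                  mccv_splits: int = 50,
                  grid: list[PreprocessSpec] | None = None) -> pd.DataFrame:
    """Score every grid configuration by repeated k-fold PLS cross-validation.

    For each configuration the LV count is first fixed by Monte-Carlo CV
    on PRESS, then ``repeats`` independent k-fold partitions are averaged.
    Returns a table (method, r2cv, rmsecv, rpdcv, lv) sorted as listed.
    """
    grid = table_grid_specs() if grid is None else grid
    if not grid:
        raise ValueError("empty preprocessing grid")
    y = ref.aligned_to(s)
    n = len(y)
    if n < folds:
        raise ValueError("fewer samples than folds")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    rows = []
    for spec in grid:
        Xp = compose(spec)(s.X)
        lv = select_lv_mccv(Xp, y, lv_max, n_splits=mccv_splits, seed=seed)
        press = 0.0
        for r in range(repeats):
            curve = kfold_press_curve(Xp, y, lv, folds=folds,
                                      seed=seed + 1000 * r + 1)
            press += curve[min(lv, len(curve)) - 1]
        press /= repeats
        r2cv = 1.0 - press / ss_tot
        rows.append({"method": spec.name, "r2cv": r2cv,
                     "rmsecv": float(np.sqrt(press / n)),
                     "rpdcv": rpd_from_r2(r2cv) if r2cv < 1 else float("inf"),
                     "lv": lv})
    return pd.DataFrame(rows)
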