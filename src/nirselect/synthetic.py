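"""Synthetic NIR spectra with known informative bands.

The generator emulates diffuse-reflectance FT-NIR absorbance spectra of
ground seed powder: a smooth background with per-sample polynomial
baseline drift, overlapping Gaussian absorption bands whose amplitudes
are linear in the reference protein content, independent interferent
bands (moisture/oil-like), per-sample multiplicative scatter and white
noise.  Ground truth — which channels carry protein information — is
recorded before noise is added, so selector recovery can be scored.

Default band positions sit in the five overtone/combination regions
where protein-related C-H and N-H absorptions fall (third and second
overtones around 11,000 and 8,500 cm^-1, N-H second overtone near
6,800 cm^-1, first overtone near 5,900 cm^-1 and combination bands near
4,300 cm^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import ReferenceTable, SpectraSet

__all__ = ["Band", "SynthConfig", "GroundTruth", "generate",
           "inject_outliers", "kjeldahl_protein", "FULL_PROFILE"]


@dataclass(frozen=True)
class Band:
    center: float      # cm^-1
    sigma: float       # Gaussian width, cm^-1
    loading: float     # signed absorbance amplitude per unit (y / 100)
    region: int = 0    # which absorption region the band belongs to


def _region(center: float, sigma: float, loading: float, region: int):
    """Three overlapping sub-bands per absorption region.

    Real protein regions are composites of many overlapping vibrational
    modes whose amplitudes co-vary with protein but also fluctuate
    semi-independently; modelling each region as several sub-bands keeps
    within-region channels informative yet not perfectly collinear.
    """
    return (
        Band(center - sigma, sigma * 0.45, loading * 0.5, region),
        Band(center, sigma * 0.45, loading, region),
        Band(center + 0.8 * sigma, sigma * 0.45, loading * 0.6, region),
    )


# protein-loaded bands in the five characteristic regions
_DEFAULT_BANDS = (
    _region(11064.0, 150.0, 0.55, 0)     # C-H third overtone
    + _region(8523.0, 130.0, 0.45, 1)    # C-H second overtone
    + _region(6780.0, 90.0, -0.35, 2)    # N-H / amide second overtone
    + _region(5891.0, 90.0, 0.50, 3)     # C-H first overtone
    + _region(4315.0, 85.0, 0.40, 4)     # C-H combination bands
)

# spectrally overlapping constituents varying independently of protein
_DEFAULT_INTERFERENTS = (
    Band(9700.0, 200.0, 0.015),
    Band(5200.0, 120.0, 0.020),
    Band(7100.0, 150.0, 0.010),
)


@dataclass
class SynthConfig:
    n_samples: int = 150
    n_channels: int = 400
    axis_span: tuple[float, float] = (11542.0, 3946.0)   # acquisition order
    bands: tuple[Band, ...] = _DEFAULT_BANDS
    interferents: tuple[Band, ...] = _DEFAULT_INTERFERENTS
    noise_sd: float = 0.002                 # additive detector noise, AU
    band_jitter: float = 0.001              # sd of per-sample sub-band amplitude
                                            # variation unrelated to protein
    n_nuisance: int = 80                    # other-constituent components
    nuisance_amp: float = 0.01              # sd of their per-sample factors, AU
    nuisance_width: tuple[float, float] = (50.0, 200.0)
    nuisance_clearance: float = 2.5         # sigmas kept clear of protein bands
    scatter_slope: tuple[float, float] = (0.995, 1.005)
    scatter_offset: tuple[float, float] = (-0.002, 0.002)
    baseline_order: int = 2
    baseline_amp: float = 0.001             # sd of drift polynomial coefficients
    y_mean: float = 37.2                    # % protein
    y_sd: float = 2.0
    y_range: tuple[float, float] = (33.0, 42.0)
    informative_rel_threshold: float = 0.05  # fraction of peak |signal|
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 16:
            raise ValueError("need at least 16 channels")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        lo, hi = sorted(self.axis_span)
        for b in self.bands + self.interferents:
            if not lo <= b.center <= hi:
                raise ValueError(f"band at {b.center} cm^-1 outside the axis span")


FULL_PROFILE = SynthConfig(n_channels=1845)


def bands_for_regions(regions) -> tuple[Band, ...]:
    """Default sub-bands restricted to the given region indices."""
    keep = set(regions)
    return tuple(b for b in _DEFAULT_BANDS if b.region in keep)


@dataclass
class GroundTruth:
    informative_channels: np.ndarray       # union over protein bands
    band_channels: list[np.ndarray]        # per-sub-band channel index sets
    region_channels: list[np.ndarray]      # channel sets per absorption region
    protein_signature: np.ndarray          # signed signal shape over channels
    clean: np.ndarray                      # spectra before scatter and noise
    y: np.ndarray


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    have = 0
    while have < size:
        draw = rng.normal(mean, sd, size=size)
        good = draw[(draw >= lo) & (draw <= hi)]
        take = min(size - have, good.size)
        out[have:have + take] = good[:take]
        have += take
    return out


def generate(config: SynthConfig | None = None,
             seed: int | None = None) -> tuple[SpectraSet, ReferenceTable, GroundTruth]:
    """Draw one synthetic dataset; fully deterministic given the seed."""
    config = config or SynthConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_channels
    lo, hi = sorted(config.axis_span)
    axis = np.linspace(lo, hi, p)              # stored ascending

    y = _truncated_normal(rng, config.y_mean, config.y_sd,
                          *config.y_range, n)

    def gauss(b: Band) -> np.ndarray:
        return b.loading * np.exp(-0.5 * ((axis - b.center) / b.sigma) ** 2)

    signature = np.sum([gauss(b) for b in config.bands], axis=0)
    background = 0.45 + 0.15 * (axis - lo) / (hi - lo)

    clean = background[None, :] + np.outer(y / 100.0, signature)
    if config.band_jitter > 0:
        # band amplitudes fluctuate sample-to-sample beyond the protein
        # level (overlapping constituents, particle-size effects): noise
        # fully correlated within a band, so extra channels from one band
        # do not average it away
        eta = rng.normal(0.0, config.band_jitter, size=(n, len(config.bands)))
        clean = clean + eta @ np.vstack([gauss(b) for b in config.bands])
    if config.interferents:
        G = np.vstack([gauss(b) for b in config.interferents])
        Z = rng.normal(size=(n, len(config.interferents)))
        clean = clean + Z @ G
    if config.n_nuisance > 0 and config.nuisance_amp > 0:
        # many other constituents absorb at their own characteristic
        # positions, concentrated outside the protein regions: a
        # high-rank structured background that penalizes full-spectrum
        # models without masking the informative bands
        protected = [(b.center - config.nuisance_clearance * b.sigma,
                      b.center + config.nuisance_clearance * b.sigma)
                     for b in config.bands]
        centers = []
        guard = 0
        while len(centers) < config.n_nuisance and guard < 100_000:
            c = rng.uniform(lo, hi)
            guard += 1
            if not any(a <= c <= bb for a, bb in protected):
                centers.append(c)
        widths = rng.uniform(*config.nuisance_width, size=len(centers))
        shapes = np.array([np.exp(-0.5 * ((axis - c) / w) ** 2)
                           for c, w in zip(centers, widths)])
        F = rng.normal(0.0, config.nuisance_amp, size=(n, len(centers)))
        clean = clean + F @ shapes
    if config.baseline_order >= 0 and config.baseline_amp > 0:
        u = (axis - lo) / (hi - lo)
        basis = np.vstack([u ** d for d in range(config.baseline_order + 1)])
        C = rng.normal(0.0, config.baseline_amp,
                       size=(n, config.baseline_order + 1))
        clean = clean + C @ basis

    a = rng.uniform(*config.scatter_slope, size=n)
    b_off = rng.uniform(*config.scatter_offset, size=n)
    X = a[:, None] * clean + b_off[:, None]
    if config.noise_sd > 0:
        X = X + rng.normal(0.0, config.noise_sd, size=(n, p))

    # informative channels: signal above a fraction of the strongest peak
    thr = config.informative_rel_threshold * np.abs(signature).max()
    band_channels = []
    for b in config.bands:
        contrib = np.abs(gauss(b))
        band_channels.append(np.where(contrib > thr)[0])
    informative = np.unique(np.concatenate(band_channels)) if band_channels \
        else np.array([], dtype=int)
    if informative.size == 0:
        raise ValueError("no informative channels — check band placement")
    regions = sorted({b.region for b in config.bands})
    region_channels = [
        np.unique(np.concatenate(
            [bc for b, bc in zip(config.bands, band_channels) if b.region == r]
            or [np.array([], dtype=int)]))
        for r in regions
    ]

    ids = [f"S{i + 1:03d}" for i in range(n)]
    spectra = SpectraSet(ids, axis, X,
                         meta={"axis_direction": "descending",
                               "source": "synthetic", "seed": config.seed})
    ref = ReferenceTable(ids, y)
    truth = GroundTruth(informative_channels=informative,
                        band_channels=band_channels,
                        region_channels=region_channels,
                        protein_signature=signature, clean=clean, y=y)
    return spectra, ref, truth


def inject_outliers(s: SpectraSet, ref: ReferenceTable, k: int,
                    mode: str = "reference-shift", magnitude: float = 5.0,
                    seed: int = 0) -> tuple[SpectraSet, ReferenceTable, np.ndarray]:
    """Corrupt ``k`` random samples; returns copies plus the true labels.

    ``reference-shift`` adds ``magnitude`` (% protein) to the reference
    value; ``spectral-spike`` adds a ``magnitude``-scaled spike to a
    random channel block of the spectrum.
    """
    n = s.n_samples
    if k < 0 or k >= n:
        raise ValueError(f"k must lie in 0..{n - 1}")
    rng = np.random.default_rng(seed)
    labels = np.sort(rng.choice(n, size=k, replace=False)) if k else \
        np.array([], dtype=int)
    X = s.X.copy()
    y = ref.y.copy()
    if mode == "reference-shift":
        y[labels] += magnitude
    elif mode == "spectral-spike":
        for i in labels:
            c = rng.integers(0, s.n_channels)
            width = max(2, s.n_channels // 50)
            sl = slice(max(0, c - width), min(s.n_channels, c + width))
            X[i, sl] += magnitude * 0.01
    else:
        raise ValueError(f"unknown outlier mode {mode!r}")
    return (SpectraSet(list(s.sample_ids), s.axis.copy(), X, dict(s.meta)),
            ReferenceTable(list(ref.sample_ids), y), labels)


def kjeldahl_protein(V1: float, V2: float, c: float, m: float,
                     V3: float, V4: float, F: float = 6.25) -> float:
    """Protein % from Kjeldahl titration volumes.

    ``X = (V1 - V2) * c * 0.0140 / (m * V3 / V4) * F * 100`` — titrant
    volumes V1 (sample) and V2 (blank) in mL, acid concentration c in
    mol/L, sample mass m in g, digest aliquot V3 of final volume V4 in
    mL, and F the nitrogen-to-protein conversion factor (6.25).
    """
    if m <= 0 or V3 <= 0 or V4 <= 0:
        raise ValueError("mass and volumes must be positive")
    if V1 < V2:
        raise ValueError("sample titrant volume below blank volume")
    return (V1 - V2) * c * 0.0140 / (m * V3 / V4) * F * 100.0
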