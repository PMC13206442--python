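"""Spectral data containers, delimited-text IO, splitting and summaries.

A :class:`SpectraSet` holds an ``n x p`` intensity matrix over a strictly
monotone wavenumber axis (cm^-1).  FT-NIR instruments acquire descending
wavenumber axes; the axis is stored ascending internally and the original
direction recorded in ``meta`` and restored on write.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "SpectraSet",
    "ReferenceTable",
    "SplitAssignment",
    "read_spectra",
    "write_spectra",
    "read_reference",
    "write_reference",
    "average_replicates",
    "split_samples",
    "summarize_reference",
    "pca_overlap",
]


@dataclass
class SpectraSet:
    """Sample IDs, ascending wavenumber axis and intensity matrix."""

    sample_ids: list[str]
    axis: np.ndarray
    X: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, p = self.X.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} ids for {n} spectra")
        if self.axis.size != p:
            raise ValueError(f"axis length {self.axis.size} != {p} channels")
        if len(set(self.sample_ids)) != n:
            dup = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample IDs: {dup}")
        if not np.isfinite(self.X).all():
            raise ValueError("non-finite intensities in X")
        d = np.diff(self.axis)
        if self.axis.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber axis is not strictly monotone")
        if self.axis.size > 1 and d[0] < 0:       # canonical ascending storage
            self.axis = self.axis[::-1].copy()
            self.X = self.X[:, ::-1].copy()
            self.meta.setdefault("axis_direction", "descending")
        else:
            self.meta.setdefault("axis_direction", "ascending")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    def select_samples(self, indices) -> "SpectraSet":
        idx = np.asarray(indices)
        return SpectraSet([self.sample_ids[i] for i in idx], self.axis.copy(),
                          self.X[idx].copy(), dict(self.meta))

    def select_channels(self, indices) -> "SpectraSet":
        idx = np.asarray(indices)
        return SpectraSet(list(self.sample_ids), self.axis[idx].copy(),
                          self.X[:, idx].copy(), dict(self.meta))


@dataclass
class ReferenceTable:
    """Per-sample reference protein content in % (mass fraction x 100)."""

    sample_ids: list[str]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.y = np.asarray(self.y, dtype=float).ravel()
        if len(self.sample_ids) != self.y.size:
            raise ValueError("ids and y length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs in reference table")
        if not np.isfinite(self.y).all():
            raise ValueError("non-finite reference values")
        if np.any(self.y <= 0):
            raise ValueError("reference protein content must be positive")

    def aligned_to(self, s: SpectraSet) -> np.ndarray:
        """y reordered to match the sample order of ``s`` (1:1 join)."""
        lookup = dict(zip(self.sample_ids, self.y))
        missing = [sid for sid in s.sample_ids if sid not in lookup]
        if missing:
            raise KeyError(f"reference values missing for samples: {missing}")
        return np.array([lookup[sid] for sid in s.sample_ids])


@dataclass
class SplitAssignment:
    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    ratio: tuple[int, int]


def read_spectra(path, sep: str = ",") -> SpectraSet:
    """Read a delimited spectra matrix: first row axis, first column IDs."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    try:
        axis = df.columns.to_numpy(dtype=float)
    except (TypeError, ValueError) as e:
        raise ValueError(f"non-numeric wavenumber header in {path}: {e}") from None
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs in {path}: {dup}")
    X = df.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        bad = np.argwhere(~np.isfinite(X))[0]
        raise ValueError(f"non-numeric or missing cell at row {df.index[bad[0]]!r}, "
                         f"column {df.columns[bad[1]]!r} in {path}")
    return SpectraSet([str(i) for i in df.index], axis, X)


def write_spectra(s: SpectraSet, path, sep: str = ",") -> None:
    """Write in acquisition orientation (descending axis if acquired so)."""
    axis, X = s.axis, s.X
    if s.meta.get("axis_direction") == "descending":
        axis, X = axis[::-1], X[:, ::-1]
    df = pd.DataFrame(X, index=pd.Index(s.sample_ids, name="sample_id"),
                      columns=[format(v, ".6f").rstrip("0").rstrip(".") for v in axis])
    df.to_csv(path, sep=sep, float_format="%.10g")


def read_reference(path, sep: str = ",") -> ReferenceTable:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ReferenceTable([str(i) for i in df.index],
                          df.iloc[:, 0].to_numpy(dtype=float))


def write_reference(r: ReferenceTable, path, sep: str = ",") -> None:
    pd.DataFrame({"protein_pct": r.y},
                 index=pd.Index(r.sample_ids, name="sample_id")).to_csv(path, sep=sep)


def average_replicates(s: SpectraSet, groups: dict) -> SpectraSet:
    """Average replicate scans: one output row per group (arithmetic mean)."""
    if not groups:
        raise ValueError("empty replicate group map")
    missing = [sid for sid in s.sample_ids if sid not in groups]
    if missing:
        raise KeyError(f"samples without a replicate group: {missing}")
    order: list = []
    members: dict = {}
    for i, sid in enumerate(s.sample_ids):
        g = groups[sid]
        if g not in members:
            members[g] = []
            order.append(g)
        members[g].append(i)
    Xm = np.vstack([s.X[members[g]].mean(axis=0) for g in order])
    return SpectraSet([str(g) for g in order], s.axis.copy(), Xm,
                      {**s.meta, "replicates_averaged": True})


def split_samples(n: int, ratio: tuple[int, int] = (4, 1),
                  seed: int = 0) -> SplitAssignment:
    """Random train/test split at ``ratio`` (train:test).

    The test count is ``floor(n * b / (a + b))`` — for the conventional
    4:1 split, ``floor(n / 5)`` (143 samples -> 115 train / 28 test).
    """
    a, b = ratio
    if n < a + b:
        raise ValueError(f"need at least {a + b} samples for a {a}:{b} split")
    n_test = math.floor(n * b / (a + b))
    perm = np.random.default_rng(seed).permutation(n)
    return SplitAssignment(train_indices=np.sort(perm[n_test:]),
                           test_indices=np.sort(perm[:n_test]),
                           seed=seed, ratio=(a, b))


def summarize_reference(y) -> dict:
    """Min/max/mean/sd/CV summary (sd with n-1; CV = 100*sd/mean)."""
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("need at least two samples to summarize")
    sd = float(np.std(y, ddof=1))
    mean = float(y.mean())
    return {"n": int(y.size), "min": float(y.min()), "max": float(y.max()),
            "mean": mean, "sd": sd, "cv_pct": 100.0 * sd / mean}


@dataclass
class PCAOverlap:
    scores_train: np.ndarray
    scores_test: np.ndarray
    explained_variance_ratio: np.ndarray
    cumulative: float


def pca_overlap(train: SpectraSet, test: SpectraSet, k: int = 3) -> PCAOverlap:
    """PCA on pooled mean-centered train+test spectra.

    Returns per-set scores and per-component explained-variance fractions
    (eigenvalues over total variance), used to check that train and test
    cover the same spectral subspace.
    """
    if train.axis.size != test.axis.size or not np.allclose(train.axis, test.axis):
        raise ValueError("train and test spectra are on different axes")
    pooled = np.vstack([train.X, test.X])
    k = min(k, pooled.shape[0] - 1, pooled.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(pooled)
    ratios = pca.explained_variance_ratio_
    return PCAOverlap(scores_train=scores[: train.n_samples],
                      scores_test=scores[train.n_samples:],
                      explained_variance_ratio=ratios,
                      cumulative=float(ratios.sum()))
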