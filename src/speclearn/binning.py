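"""Spectral binning, scaling, splitting and similarity QC.

Profile-mode mass spectra arrive as irregular (m/z, intensity) traces of
unequal length.  Before any classifier can consume them they are projected
("bucketed") onto a fixed-width m/z grid, giving every spectrum the same
number of features; at 0.1 Da this turns e.g. a 100-1600 Da acquisition
into 15,000 features.  Intensities are then scaled linearly into [0, 1]
and the dataset is divided into stratified train/validation/test subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "RawSpectrum",
    "BinGrid",
    "SpectraDataset",
    "SplitIndices",
    "n_bins",
    "bin_spectrum",
    "scale_unit_interval",
    "stratified_split",
    "spectrum_similarity",
    "SpectrumBinner",
    "UnitIntervalScaler",
]


@dataclass(frozen=True)
class RawSpectrum:
    """One acquisition: ordered (m/z, intensity) pairs, unprocessed."""

    mz: np.ndarray
    intensity: np.ndarray
    id: str = ""

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError(
                f"mz and intensity must be 1-D and equal length "
                f"(got {mz.shape} vs {inten.shape})"
            )
        if mz.size >= 2 and not np.all(np.diff(mz) > 0):
            raise ValueError(f"spectrum {self.id!r}: m/z values must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError(f"spectrum {self.id!r}: negative intensities are not allowed")


def n_bins(mass_min: float, mass_max: float, bin_width: float) -> int:
    """Number of fixed-width bins covering [mass_min, mass_max).

    (100, 1600, 0.1) -> 15000 and (100, 2000, 0.1) -> 19000, the two grids
    used for Q-TOF lipid spectra at the conventional 0.1 Da bucket size.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive (got {bin_width})")
    if mass_max <= mass_min:
        raise ValueError(f"mass range is empty: [{mass_min}, {mass_max})")
    return int(round((mass_max - mass_min) / bin_width))


@dataclass(frozen=True)
class BinGrid:
    """Fixed m/z grid with half-open bins [edge_i, edge_{i+1})."""

    mass_min: float
    mass_max: float
    bin_width: float

    def __post_init__(self):
        n_bins(self.mass_min, self.mass_max, self.bin_width)  # validates

    @property
    def n_bins(self) -> int:
        return n_bins(self.mass_min, self.mass_max, self.bin_width)

    @property
    def edges(self) -> np.ndarray:
        return self.mass_min + self.bin_width * np.arange(self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        return self.mass_min + self.bin_width * (np.arange(self.n_bins) + 0.5)


@dataclass
class SpectraDataset:
    """Binned intensity matrix (n_spectra x n_bins) with labels and grid metadata."""

    matrix: np.ndarray
    labels: np.ndarray
    class_names: Sequence[str]
    grid: BinGrid
    sample_ids: Sequence[str] = field(default_factory=list)
    scaled: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"matrix has {self.matrix.shape[0]} rows but {self.labels.shape[0]} labels"
            )
        if self.labels.size and self.labels.max() >= len(self.class_names):
            raise ValueError("label index exceeds class_names")
        if self.grid is not None and self.matrix.shape[1] != self.grid.n_bins:
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} columns but grid has {self.grid.n_bins} bins"
            )
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.matrix.shape[0])]

    @property
    def n_spectra(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset(self, indices: np.ndarray) -> "SpectraDataset":
        indices = np.asarray(indices)
        return SpectraDataset(
            matrix=self.matrix[indices],
            labels=self.labels[indices],
            class_names=list(self.class_names),
            grid=self.grid,
            sample_ids=[self.sample_ids[i] for i in indices],
            scaled=self.scaled,
        )


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint, exhaustive train/validation/test index sets."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int

    def __post_init__(self):
        for name in ("train", "validation", "test"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=int))
        all_idx = np.concatenate([self.train, self.validation, self.test])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split subsets overlap")


def bin_spectrum(
    raw: RawSpectrum,
    grid: BinGrid,
    aggregate: Literal["sum", "mean", "max"] = "sum",
) -> np.ndarray:
    """Project one profile spectrum onto ``grid``.

    Each point with mass_min <= m/z < mass_max lands in exactly one
    half-open bin; points outside the range are dropped.  ``sum`` (default)
    conserves total in-range ion count; ``mean`` and ``max`` are selectable.
    """
    if aggregate not in ("sum", "mean", "max"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    mz, inten = raw.mz, raw.intensity
    inside = (mz >= grid.mass_min) & (mz < grid.mass_max)
    mz, inten = mz[inside], inten[inside]
    idx = np.floor((mz - grid.mass_min) / grid.bin_width).astype(int)
    # float round-off near edges: re-anchor on the exact edge values so a
    # point sitting on edge_k always lands in bin k (half-open convention)
    idx[mz >= grid.mass_min + (idx + 1) * grid.bin_width] += 1
    idx[mz < grid.mass_min + idx * grid.bin_width] -= 1
    idx = np.clip(idx, 0, grid.n_bins - 1)
    out = np.zeros(grid.n_bins)
    if idx.size == 0:
        return out
    if aggregate == "sum":
        np.add.at(out, idx, inten)
    elif aggregate == "mean":
        np.add.at(out, idx, inten)
        counts = np.zeros(grid.n_bins)
        np.add.at(counts, idx, 1.0)
        nz = counts > 0
        out[nz] /= counts[nz]
    else:  # max
        np.maximum.at(out, idx, inten)
    return out


def bin_spectra(
    spectra: Sequence[RawSpectrum],
    grid: BinGrid,
    aggregate: Literal["sum", "mean", "max"] = "sum",
) -> np.ndarray:
    """Stack :func:`bin_spectrum` over many spectra into a matrix."""
    return np.stack([bin_spectrum(s, grid, aggregate) for s in spectra])


def scale_unit_interval(ds: SpectraDataset, per_spectrum: bool = True) -> SpectraDataset:
    """Scale intensities linearly into [0, 1].

    Default is per spectrum (row-wise min-max), which removes the global
    acquisition-intensity nuisance between heterogeneous spectra; a
    dataset-global variant is available.  A constant row maps to zeros.
    """
    X = ds.matrix
    if per_spectrum:
        lo = X.min(axis=1, keepdims=True)
        hi = X.max(axis=1, keepdims=True)
    else:
        lo = X.min()
        hi = X.max()
    span = hi - lo
    span = np.where(span == 0, 1.0, span)
    scaled = (X - lo) / span
    return replace(ds, matrix=scaled, scaled=True, sample_ids=list(ds.sample_ids))


def stratified_split(
    labels: Sequence[int],
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitIndices:
    """Stratified 60/20/20 (by default) train/validation/test split.

    Keeps each subset's per-class proportion within one sample of the
    global target so that minority classes survive into every subset.
    """
    labels = np.asarray(labels)
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise ValueError(f"need three positive ratios, got {ratios}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    counts = np.bincount(labels)
    if (counts[counts > 0] < 3).any():
        warnings.warn("a class has fewer than 3 samples; best-effort assignment", stacklevel=2)

    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n_c = len(idx)
        # largest-remainder apportionment of n_c over the three subsets
        exact = np.array(ratios) * n_c
        base = np.floor(exact).astype(int)
        rem = n_c - base.sum()
        order = np.argsort(-(exact - base))
        base[order[:rem]] += 1
        n_tr, n_va, _ = base
        train.append(idx[:n_tr])
        val.append(idx[n_tr : n_tr + n_va])
        test.append(idx[n_tr + n_va :])
    return SplitIndices(
        train=np.sort(np.concatenate(train)),
        validation=np.sort(np.concatenate(val)),
        test=np.sort(np.concatenate(test)),
        seed=seed,
    )


def spectrum_similarity(
    a: np.ndarray, b: np.ndarray, method: Literal["pearson", "cosine"] = "pearson"
) -> float:
    """Pearson or cosine similarity between two binned spectra."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("inputs must be equal-length 1-D vectors of length >= 2")
    if method == "pearson":
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            raise ValueError("Pearson similarity undefined for a constant input")
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))
    if method == "cosine":
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            raise ValueError("cosine similarity undefined for a zero vector")
        return float(a @ b / (na * nb))
    raise ValueError(f"unknown method {method!r}")


class SpectrumBinner(BaseEstimator, TransformerMixin):
    """sklearn transformer: list of :class:`RawSpectrum` -> binned matrix.

    Parameters
    ----------
    mass_min, mass_max, bin_width
        Grid definition in Da; bins are half-open ``[edge, edge + width)``.
    aggregate
        Within-bin statistic, ``sum`` by default.
    """

    def __init__(self, mass_min=100.0, mass_max=1600.0, bin_width=0.1, aggregate="sum"):
        self.mass_min = mass_min
        self.mass_max = mass_max
        self.bin_width = bin_width
        self.aggregate = aggregate

    def fit(self, X, y=None):
        self.grid_ = BinGrid(self.mass_min, self.mass_max, self.bin_width)
        self.n_features_out_ = self.grid_.n_bins
        return self

    def transform(self, X):
        if not hasattr(self, "grid_"):
            self.fit(X)
        return bin_spectra(X, self.grid_, self.aggregate)


class UnitIntervalScaler(BaseEstimator, TransformerMixin):
    """Row-wise (or global) linear scaling of a binned matrix into [0, 1]."""

    def __init__(self, per_spectrum=True):
        self.per_spectrum = per_spectrum

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if self.per_spectrum:
            lo = X.min(axis=1, keepdims=True)
            hi = X.max(axis=1, keepdims=True)
        else:
            lo, hi = X.min(), X.max()
        span = np.where(hi - lo == 0, 1.0, hi - lo)
        return (X - lo) / span


def cross_validation_splits(labels, n_iterations=10, base_seed=0, ratios=(0.6, 0.2, 0.2)):
    """One stratified 60/20/20 resample per iteration (seed = base_seed + i).

    Emulates repeated cross-validation: each iteration re-draws the three
    subsets so that accuracies can be averaged over independent replicates.
    """
    return [stratified_split(labels, ratios, seed=base_seed + i) for i in range(n_iterations)]
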