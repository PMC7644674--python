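"""Conventional five-step preprocessing for profile mass spectra.

The classical track that SVM/RF/LDA baselines require before they can
classify spectra: (1) log-intensity transform, (2) SNIP baseline
subtraction, (3) total-ion-count normalisation, (4) per-class alignment
through a cubic warp of the m/z axis fitted by weighted least squares to
matched reference peaks, and (5) peak detection thresholded on the median
absolute deviation.  Features fed to the baselines are the intensities at
the union of reference peak positions across classes, which keeps the
feature matrix a fixed width even though peak picking alone would give a
different peak count per spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .binning import SpectraDataset

__all__ = [
    "WarpModel",
    "PeakList",
    "PreprocessConfig",
    "log_transform",
    "snip_baseline",
    "tic_normalize",
    "detect_peaks_mad",
    "match_reference_peaks",
    "fit_cubic_warp",
    "apply_warp",
    "align_by_class",
    "preprocess_pipeline",
    "ConventionalPreprocessor",
]


@dataclass(frozen=True)
class WarpModel:
    """Cubic m/z warp w(x) = a0 + a1*x + a2*x^2 + a3*x^3."""

    alpha: tuple[float, float, float, float]
    residual_rms: float = 0.0
    n_pairs: int = 0

    def __call__(self, x):
        a0, a1, a2, a3 = self.alpha
        x = np.asarray(x, dtype=float)
        return a0 + x * (a1 + x * (a2 + x * a3))

    def derivative(self, x):
        _, a1, a2, a3 = self.alpha
        x = np.asarray(x, dtype=float)
        return a1 + x * (2 * a2 + x * 3 * a3)

    @classmethod
    def identity(cls) -> "WarpModel":
        return cls((0.0, 1.0, 0.0, 0.0))


@dataclass(frozen=True)
class PeakList:
    """Detected apexes: positions (Da or bin index), intensities, SNR."""

    apex_mz: np.ndarray
    apex_intensity: np.ndarray
    snr: np.ndarray

    def __post_init__(self):
        for name in ("apex_mz", "apex_intensity", "snr"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.apex_mz.size > 1 and np.any(np.diff(self.apex_mz) <= 0):
            raise ValueError("apex positions must be strictly increasing")

    def __len__(self):
        return self.apex_mz.size


@dataclass(frozen=True)
class PreprocessConfig:
    snip_iterations: int = 40
    mad_k: float = 3.0
    halfwindow: int = 20
    match_tolerance: float = 0.5  # Da
    log_offset: float = 1.0

    def __post_init__(self):
        if min(self.snip_iterations, self.mad_k, self.halfwindow,
               self.match_tolerance, self.log_offset) <= 0:
            raise ValueError("all preprocessing parameters must be positive")


def log_transform(x: np.ndarray, offset: float = 1.0) -> np.ndarray:
    """Elementwise log(offset + x) - log(offset): zero maps to zero, monotone."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("log transform requires non-negative intensities")
    return np.log(offset + x) - np.log(offset)


def _lls(x):
    return np.log(np.log(np.sqrt(x + 1.0) + 1.0) + 1.0)


def _lls_inv(v):
    return (np.exp(np.exp(v) - 1.0) - 1.0) ** 2 - 1.0


def snip_baseline(x: np.ndarray, iterations: int = 40, lls: bool = True) -> np.ndarray:
    """SNIP baseline estimate by iterative expanding-window peak clipping.

    At pass m each point is clipped to the mean of its neighbours m bins
    away, working (by default) in the log-log-square-root compressed domain;
    the returned baseline never exceeds the signal.
    """
    x = np.asarray(x, dtype=float)
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if iterations >= len(x) / 2:
        raise ValueError(f"iterations={iterations} too large for a {len(x)}-bin spectrum")
    y = _lls(x) if lls else x.copy()
    for m in range(1, iterations + 1):
        mids = 0.5 * (y[: -2 * m] + y[2 * m :])
        y[m:-m] = np.minimum(y[m:-m], mids)
    base = _lls_inv(y) if lls else y
    # the compressed-domain round trip can overshoot by float epsilon
    return np.minimum(base, x)


def tic_normalize(x: np.ndarray) -> np.ndarray:
    """Divide a spectrum by its total ion count; output sums to one."""
    x = np.asarray(x, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("TIC normalisation undefined for an all-zero spectrum")
    return x / total


def detect_peaks_mad(
    x: np.ndarray,
    mad_k: float = 3.0,
    halfwindow: int = 20,
    mz: np.ndarray | None = None,
) -> PeakList:
    """Detect apexes that are strict local maxima above a robust noise floor.

    Noise is estimated as ``1.4826 * median(|x - median(x)|)``; a bin is an
    apex iff it strictly exceeds every neighbour within ``halfwindow`` bins
    and its intensity exceeds ``mad_k`` times the noise estimate.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("spectrum must be finite")
    if halfwindow >= len(x):
        raise ValueError("halfwindow must be smaller than the spectrum length")
    noise = 1.4826 * np.median(np.abs(x - np.median(x)))
    apex = []
    for i in range(len(x)):
        lo, hi = max(0, i - halfwindow), min(len(x), i + halfwindow + 1)
        window = x[lo:hi]
        if x[i] > mad_k * noise and np.sum(window == x[i]) == 1 and x[i] == window.max():
            apex.append(i)
    apex = np.asarray(apex, dtype=int)
    positions = apex.astype(float) if mz is None else np.asarray(mz, dtype=float)[apex]
    snr = x[apex] / noise if noise > 0 else np.full(apex.shape, np.inf)
    return PeakList(positions, x[apex], snr)


def match_reference_peaks(
    peaks: PeakList, reference: PeakList, tolerance: float = 0.5
) -> list[tuple[float, float]]:
    """Greedy one-to-one nearest matching of (observed, reference) apexes.

    Pairs are claimed in order of increasing distance; each observed and
    each reference apex is used at most once; pairs farther apart than
    ``tolerance`` are never formed.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if len(peaks) == 0 or len(reference) == 0:
        return []
    dist = np.abs(peaks.apex_mz[:, None] - reference.apex_mz[None, :])
    cand = np.argwhere(dist <= tolerance)
    order = np.argsort(dist[cand[:, 0], cand[:, 1]], kind="stable")
    used_obs, used_ref, pairs = set(), set(), []
    for i, j in cand[order]:
        if i in used_obs or j in used_ref:
            continue
        used_obs.add(i)
        used_ref.add(j)
        pairs.append((float(peaks.apex_mz[i]), float(reference.apex_mz[j])))
    pairs.sort()
    return pairs


def fit_cubic_warp(
    pairs: list[tuple[float, float]], weights: np.ndarray | None = None
) -> WarpModel:
    """Weighted least-squares fit of the cubic warp to matched positions.

    Minimises sum w_i (reference_i - w(observed_i))^2.  The system is solved
    in a centred/scaled variable for conditioning and expanded back to power
    basis coefficients.
    """
    if len(pairs) < 4:
        raise ValueError(f"need >= 4 matched pairs to fit a cubic warp, got {len(pairs)}")
    obs = np.array([p[0] for p in pairs], dtype=float)
    ref = np.array([p[1] for p in pairs], dtype=float)
    if len(np.unique(obs)) < 4:
        raise ValueError("need >= 4 distinct observed positions")
    w = np.ones_like(obs) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != obs.shape or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative, matching pairs, not all zero")

    center = obs.mean()
    scale = max(obs.std(), np.finfo(float).tiny)
    t = (obs - center) / scale
    design = np.vander(t, 4, increasing=True) * np.sqrt(w)[:, None]
    rhs = ref * np.sqrt(w)
    beta, _, rank, _ = np.linalg.lstsq(design, rhs, rcond=None)
    if rank < 4:
        raise np.linalg.LinAlgError(
            "degenerate design: observed positions are collinear to cubic degree"
        )
    # expand beta over t = (x - center)/scale into power-basis alpha over x
    poly = np.polynomial.Polynomial(beta)(
        np.polynomial.Polynomial([-center / scale, 1.0 / scale])
    )
    alpha = np.zeros(4)
    alpha[: len(poly.coef)] = poly.coef
    model = WarpModel(tuple(alpha),
                      residual_rms=float(np.sqrt(np.average((ref - np.polynomial.polynomial.polyval(obs, alpha)) ** 2, weights=w))),
                      n_pairs=len(pairs))
    if np.any(model.derivative(np.linspace(obs.min(), obs.max(), 64)) <= 0):
        warnings.warn("fitted cubic warp is not monotone over the fitted range", stacklevel=2)
    return model


def apply_warp(mz: np.ndarray, intensity: np.ndarray, warp: WarpModel):
    """Map an m/z axis through a warp; intensities ride along unchanged."""
    new_mz = warp(mz)
    if np.any(np.diff(new_mz) <= 0):
        warnings.warn("warp is not monotone over this spectrum; re-sorting", stacklevel=2)
        order = np.argsort(new_mz, kind="stable")
        return new_mz[order], np.asarray(intensity)[order]
    return new_mz, np.asarray(intensity)


def _warp_binned_row(row, grid, warp):
    """Re-bin a binned spectrum after warping its bin centers (TIC-conserving)."""
    centers = warp(grid.centers)
    eps = grid.bin_width * 1e-9
    centers = np.clip(centers, grid.mass_min, grid.mass_max - eps)
    idx = np.floor((centers - grid.mass_min) / grid.bin_width).astype(int)
    out = np.zeros(grid.n_bins)
    np.add.at(out, idx, row)
    return out


def align_by_class(
    ds: SpectraDataset, config: PreprocessConfig = PreprocessConfig()
) -> tuple[SpectraDataset, dict[int, PeakList], dict[int, WarpModel]]:
    """Align spectra class by class onto each class's average spectrum.

    Per class the reference is the peak list of the class-mean spectrum;
    every member is matched to it, a cubic warp is fitted with reference
    peak intensities as weights, and the member is re-binned through the
    warp.  Classes are never mixed.  Returns the aligned dataset, the
    per-class reference peak lists, and the per-spectrum fitted warps
    (spectra left unwarped for lack of anchors are absent from the map).
    """
    X = ds.matrix.copy()
    references: dict[int, PeakList] = {}
    warps: dict[int, WarpModel] = {}
    centers = ds.grid.centers
    for c in np.unique(ds.labels):
        rows = np.flatnonzero(ds.labels == c)
        mean_spec = X[rows].mean(axis=0)
        ref = detect_peaks_mad(mean_spec, config.mad_k, config.halfwindow, mz=centers)
        if len(ref):
            # keep only prominent reference apexes: weak bumps that clear a
            # near-zero MAD floor would otherwise corrupt anchoring
            keep = ref.apex_intensity >= 0.05 * ref.apex_intensity.max()
            ref = PeakList(ref.apex_mz[keep], ref.apex_intensity[keep], ref.snr[keep])
        references[int(c)] = ref
        if len(rows) < 2:
            warnings.warn(f"class {c} has a single spectrum; passed through unaligned",
                          stacklevel=2)
            continue
        # anchor only on prominent reference peaks: weak apexes (noise bumps
        # surviving a near-zero MAD floor) destabilise the cubic fit
        floor = 0.05 * ref.apex_intensity.max() if len(ref) else 0.0
        for r in rows:
            peaks = detect_peaks_mad(X[r], config.mad_k, config.halfwindow, mz=centers)
            pairs = match_reference_peaks(peaks, ref, config.match_tolerance)
            pairs = [p for p in pairs
                     if np.interp(p[1], ref.apex_mz, ref.apex_intensity) >= floor]
            if len(pairs) < 4 or len({p[0] for p in pairs}) < 4:
                continue  # too few anchors: leave the spectrum as is
            ref_pos = np.array([p[1] for p in pairs])
            w = np.interp(ref_pos, ref.apex_mz, ref.apex_intensity)
            try:
                warp = fit_cubic_warp(pairs, weights=w)
            except np.linalg.LinAlgError:
                continue
            warps[int(r)] = warp
            X[r] = _warp_binned_row(X[r], ds.grid, warp)
    aligned = SpectraDataset(X, ds.labels, list(ds.class_names), ds.grid,
                             list(ds.sample_ids), ds.scaled)
    return aligned, references, warps


def preprocess_pipeline(
    ds: SpectraDataset, config: PreprocessConfig = PreprocessConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Run the five preprocessing steps and extract peak-intensity features.

    Order: log transform, SNIP baseline subtraction, TIC normalisation,
    per-class alignment, MAD peak detection on the class-mean spectra.
    Returns ``(features, feature_bins)`` where features holds the aligned,
    normalised intensities at the union of reference peak bins.
    """
    X = np.stack([log_transform(row, config.log_offset) for row in ds.matrix])
    X = np.stack([row - snip_baseline(row, config.snip_iterations) for row in X])
    X = np.stack([tic_normalize(row) if row.sum() > 0 else row for row in X])
    interim = SpectraDataset(X, ds.labels, list(ds.class_names), ds.grid,
                             list(ds.sample_ids), ds.scaled)
    aligned, references, _ = align_by_class(interim, config)
    bins: set[int] = set()
    for ref in references.values():
        idx = np.floor((ref.apex_mz - ds.grid.mass_min) / ds.grid.bin_width).astype(int)
        bins.update(int(i) for i in idx)
    feature_bins = np.array(sorted(bins), dtype=int)
    if feature_bins.size == 0:
        raise ValueError("no peaks detected in any class-mean spectrum")
    return aligned.matrix[:, feature_bins], feature_bins


class ConventionalPreprocessor(BaseEstimator, TransformerMixin):
    """sklearn transformer wrapping the five-step preprocessing track.

    ``fit_transform(X, y)`` runs the full labelled pipeline (alignment is
    per class, so labels are required at fit time) and fixes the reference
    peak bins; ``transform`` on new, unlabelled spectra applies the three
    per-spectrum steps and reads intensities at the stored bins.
    """

    def __init__(self, snip_iterations=40, mad_k=3.0, halfwindow=20,
                 match_tolerance=0.5, log_offset=1.0):
        self.snip_iterations = snip_iterations
        self.mad_k = mad_k
        self.halfwindow = halfwindow
        self.match_tolerance = match_tolerance
        self.log_offset = log_offset

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(self.snip_iterations, self.mad_k, self.halfwindow,
                                self.match_tolerance, self.log_offset)

    def fit(self, X, y, grid=None):
        ds = self._as_dataset(X, y, grid)
        _, self.feature_bins_ = preprocess_pipeline(ds, self._config())
        self.grid_ = ds.grid
        return self

    def fit_transform(self, X, y, grid=None):
        ds = self._as_dataset(X, y, grid)
        features, self.feature_bins_ = preprocess_pipeline(ds, self._config())
        self.grid_ = ds.grid
        return features

    def transform(self, X):
        if not hasattr(self, "feature_bins_"):
            raise RuntimeError("ConventionalPreprocessor must be fitted first")
        cfg = self._config()
        X = np.asarray(X, dtype=float)
        rows = []
        for row in X:
            row = log_transform(row, cfg.log_offset)
            row = row - snip_baseline(row, cfg.snip_iterations)
            if row.sum() > 0:
                row = tic_normalize(row)
            rows.append(row[self.feature_bins_])
        return np.stack(rows)

    @staticmethod
    def _as_dataset(X, y, grid):
        if isinstance(X, SpectraDataset):
            return X
        from .binning import BinGrid

        X = np.asarray(X, dtype=float)
        if grid is None:
            grid = BinGrid(0.0, float(X.shape[1]), 1.0)
        y = np.asarray(y, dtype=int)
        names = [f"class{c}" for c in range(int(y.max()) + 1)]
        return SpectraDataset(X, y, names, grid)
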