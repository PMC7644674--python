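"""Conventional ML comparison track: SVM, random forest and PCA + LDA.

SVM and RF see chi-square-reduced features; LDA sees principal
components.  Hyperparameters are grid-searched on the validation subset
only, the winner is refit on the training subset and scored once on the
test subset.  Splits use the same stratified 60/20/20 discipline and
seeds as the CNN protocols, so CNN-vs-baseline comparisons are paired on
byte-identical index sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import chi2
from sklearn.svm import SVC

from .binning import SpectraDataset, SplitIndices
from .protocols import Metrics

__all__ = ["BaselineConfig", "chi2_select", "fit_baseline", "DEFAULT_GRIDS"]

DEFAULT_GRIDS = {
    "svm": {"C": [0.1, 1.0, 10.0], "kernel": ["rbf", "linear"]},
    "rf": {"n_estimators": [100, 500], "max_depth": [None, 20]},
    "lda": {},
}


@dataclass
class BaselineConfig:
    """Method, hyperparameter grid and dimensionality-reduction size."""

    method: str  # svm | rf | lda
    grid: dict = field(default_factory=dict)
    n_selected_features: int = 200  # chi-square k (svm/rf) or PCA cap (lda)
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("svm", "rf", "lda"):
            raise ValueError(f"unknown method {self.method!r}")
        if not self.grid:
            self.grid = dict(DEFAULT_GRIDS[self.method])
        if self.n_selected_features < 1:
            raise ValueError("n_selected_features must be positive")


def chi2_select(X: np.ndarray, y, k: int) -> np.ndarray:
    """Indices of the k features with the largest chi-square class score.

    Requires non-negative features (intensities qualify); ties break toward
    the lower index.  Constant features score zero and are selected last.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("chi-square feature scoring requires non-negative features")
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds {X.shape[1]} features")
    scores, _ = chi2(X, np.asarray(y))
    scores = np.nan_to_num(scores, nan=0.0)
    # stable sort on -score -> deterministic lower-index tie-break
    order = np.argsort(-scores, kind="stable")
    return np.sort(order[:k])


def _make_estimator(method, params, seed):
    if method == "svm":
        return SVC(random_state=seed, **params)
    if method == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    return LinearDiscriminantAnalysis(**params)


def _grid_points(grid: dict):
    if not grid:
        yield {}
        return
    keys = sorted(grid)
    for values in product(*(grid[k] for k in keys)):
        yield dict(zip(keys, values))


def fit_baseline(
    ds_or_X,
    split: SplitIndices,
    cfg: BaselineConfig,
    y=None,
) -> tuple[Metrics, dict]:
    """Grid-search, refit and score one conventional baseline.

    Accepts a :class:`SpectraDataset` or an ``(X, y)`` pair.  Returns the
    test-set :class:`Metrics` and the winning hyperparameters.
    """
    if isinstance(ds_or_X, SpectraDataset):
        X, y = ds_or_X.matrix, ds_or_X.labels
        n_classes = ds_or_X.n_classes
    else:
        X = np.asarray(ds_or_X, dtype=float)
        y = np.asarray(y)
        n_classes = len(np.unique(y))
    tr, va, te = split.train, split.validation, split.test
    if len(np.unique(y[tr])) < 2:
        raise ValueError("training subset has fewer than two classes")

    if cfg.method in ("svm", "rf"):
        k = min(cfg.n_selected_features, X.shape[1])
        cols = chi2_select(X[tr], y[tr], k)
        transform = lambda A: A[:, cols]  # noqa: E731
    else:  # lda: PCA fitted on the training subset
        n_comp = min(cfg.n_selected_features, X.shape[1], len(tr) - 1)
        pca = PCA(n_components=n_comp, random_state=cfg.seed).fit(X[tr])
        transform = pca.transform

    Xtr, Xva, Xte = transform(X[tr]), transform(X[va]), transform(X[te])

    best_params, best_score = None, -np.inf
    for params in _grid_points(cfg.grid):
        est = _make_estimator(cfg.method, params, cfg.seed)
        est.fit(Xtr, y[tr])
        score = float(np.mean(est.predict(Xva) == y[va]))
        if score > best_score:
            best_score, best_params = score, params
    est = _make_estimator(cfg.method, best_params, cfg.seed)
    est.fit(Xtr, y[tr])
    y_pred = est.predict(Xte)
    lookup = {c: i for i, c in enumerate(np.unique(y))}
    metrics = Metrics.from_predictions(
        np.array([lookup[v] for v in y[te]]),
        np.array([lookup[v] for v in y_pred]),
        n_classes,
    )
    return metrics, best_params
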