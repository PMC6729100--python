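"""Kernelized radiomics model: variance filter, RBF kernel PCA, random forest.

The classification chain is: raw-feature variance threshold (default 0.8,
applied before any standardization so the threshold is meaningful on the
native feature scales) -> per-feature z-scoring with training statistics ->
kernel PCA with the radial basis function kernel

    k(x_i, x_j) = exp(-||x_i - x_j||^2 / (2 sigma^2))

retaining ``n_components`` eigendirections of the double-centered training
Gram matrix -> a random-forest classifier on the embedding.  The embedding
dimension can be tuned over a 30..200 step-10 grid by cross-validated AUC,
and the forest hyperparameters by a coordinate grid search (one parameter
optimized while the others stay frozen).  Everything is exposed as
sklearn-compatible estimators so the pipeline composes with sklearn model
selection; all fitted state derives from training rows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from kernrad.errors import (
    DimensionError,
    EmptyFeatureSetError,
    LabelError,
    ParameterError,
    StratificationError,
)

DIMENSION_GRID = tuple(range(30, 201, 10))  # 18 candidates
DEFAULT_N_COMPONENTS = 130
DEFAULT_VARIANCE_THRESHOLD = 0.8

FOREST_GRIDS = {
    "n_estimators": (100, 200, 500),
    "max_depth": (3, 5, 10, None),
    "max_features": ("sqrt", "log2", 0.333),
}


def rbf_kernel_matrix(x: np.ndarray, y: np.ndarray, sigma: float) -> np.ndarray:
    """Gram matrix of the RBF kernel exp(-||x - y||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ParameterError("kernel width sigma must be positive")
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    if x.shape[1] != y.shape[1]:
        raise ValueError("feature dimensions differ")
    d2 = cdist(x, y, "sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


def median_heuristic_sigma(x: np.ndarray) -> float:
    """sigma = (median pairwise Euclidean distance) / sqrt(2).

    With this choice the median squared distance satisfies
    d^2 = 2 sigma^2, i.e. the median off-diagonal kernel value is e^-1.
    Falls back to 1.0 when all rows coincide.
    """
    x = np.asarray(x, float)
    if x.shape[0] < 2:
        return 1.0
    d = cdist(x, x, "euclidean")
    med = float(np.median(d[np.triu_indices_from(d, k=1)]))
    return med / np.sqrt(2.0) if med > 0 else 1.0


class RawVarianceThreshold(TransformerMixin, BaseEstimator):
    """Remove features whose *training* variance is lower than ``threshold``.

    The boundary is inclusive: a feature with variance exactly equal to
    the threshold is retained (removal applies to strictly lower
    variances).  Variances are population variances of the raw,
    unstandardized feature columns.
    """

    def __init__(self, threshold: float = DEFAULT_VARIANCE_THRESHOLD):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.variances_ = X.var(axis=0)
        self.support_ = self.variances_ >= self.threshold
        self.n_features_in_ = X.shape[1]
        if not self.support_.any():
            raise EmptyFeatureSetError(
                f"variance threshold {self.threshold} removed every feature"
            )
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = check_array(X, dtype=float)
        return X[:, self.support_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_


def fit_variance_filter(X, threshold: float = DEFAULT_VARIANCE_THRESHOLD):
    """Convenience wrapper: fitted :class:`RawVarianceThreshold`."""
    return RawVarianceThreshold(threshold=threshold).fit(np.asarray(X, float))


class RBFKernelPCA(TransformerMixin, BaseEstimator):
    """Kernel PCA with the RBF kernel and out-of-sample projection.

    Eigendecomposes the double-centered training Gram matrix
    K' = K - 1K - K1 + 1K1, keeps the top ``n_components`` eigenpairs and
    scales eigenvectors by 1/sqrt(lambda) so that projecting the training
    set yields components with variance lambda/n.  Eigenvalues below
    ``eig_tol`` times the largest are dropped (with a warning) and the
    retained dimension reduced accordingly.

    ``sigma="median"`` selects the kernel width by the median pairwise
    distance heuristic on the training rows.  ``kernel="linear"`` swaps in
    the plain dot-product kernel, in which case the embedding coincides
    with ordinary PCA scores (up to per-component sign) — useful as a
    diagnostic cross-check, not as the production kernel.
    """

    def __init__(
        self,
        n_components: int = DEFAULT_N_COMPONENTS,
        sigma: float | str = "median",
        kernel: str = "rbf",
        eig_tol: float = 1e-10,
    ):
        self.n_components = n_components
        self.sigma = sigma
        self.kernel = kernel
        self.eig_tol = eig_tol

    def _kernel(self, x, y):
        if self.kernel == "rbf":
            return rbf_kernel_matrix(x, y, self.sigma_)
        if self.kernel == "linear":
            return np.asarray(x, float) @ np.asarray(y, float).T
        raise ParameterError(f"unknown kernel {self.kernel!r}")

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.X_fit_ = X
        self.sigma_ = (
            median_heuristic_sigma(X) if self.sigma == "median" else float(self.sigma)
        )
        if self.sigma_ <= 0:
            raise ParameterError("sigma must be positive")
        n = X.shape[0]
        K = self._kernel(X, X)
        self._row_means = K.mean(axis=1)
        self._total_mean = K.mean()
        Kc = (
            K
            - self._row_means[:, None]
            - self._row_means[None, :]
            + self._total_mean
        )
        eigvals, eigvecs = eigh(Kc)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        if self.n_components > n:
            raise DimensionError(
                f"n_components={self.n_components} exceeds n_samples={n}"
            )
        usable = eigvals > self.eig_tol * max(eigvals[0], 1.0)
        n_usable = int(usable.sum())
        if n_usable == 0:
            raise DimensionError("centered Gram matrix has no positive eigenvalues")
        m = min(self.n_components, n_usable)
        if m < self.n_components:
            warnings.warn(
                f"retained dimension reduced from {self.n_components} to {m} "
                "(insufficient positive eigenvalues)",
                RuntimeWarning,
                stacklevel=2,
            )
        self.eigenvalues_ = eigvals[:m]
        self.alphas_ = eigvecs[:, :m] / np.sqrt(eigvals[:m])
        self.n_components_ = m
        return self

    def transform(self, X):
        check_is_fitted(self, "alphas_")
        X = check_array(X, dtype=float)
        K = self._kernel(X, self.X_fit_)
        Kc = (
            K
            - K.mean(axis=1)[:, None]
            - self._row_means[None, :]
            + self._total_mean
        )
        return Kc @ self.alphas_

    def fit_transform(self, X, y=None, **fit_params):
        self.fit(X)
        # training embedding straight from the eigensystem: v * sqrt(lambda)
        return self.alphas_ * self.eigenvalues_


def _resolve_positive(classes: np.ndarray, positive_label) -> object:
    if positive_label is not None:
        if positive_label not in classes:
            raise LabelError(f"positive label {positive_label!r} not among classes")
        return positive_label
    if "WD" in classes:
        return "WD"
    return classes[-1]


class KernelizedRadiomicsClassifier(ClassifierMixin, BaseEstimator):
    """Variance filter -> z-score -> RBF kernel PCA -> random forest.

    Parameters
    ----------
    variance_threshold : float or None
        Raw-feature variance cutoff (None disables the filter entirely).
    n_components : int
        Kernel-PCA dimension; capped at the training-fold sample count.
    sigma : "median" or float
        RBF kernel width.
    tune_components : bool
        Select ``n_components`` over ``component_grid`` by inner
        cross-validated AUC (ties broken toward the smallest dimension).
    tune_forest : bool
        Coordinate grid search of the forest hyperparameters by inner
        cross-validated AUC, one full sweep.
    positive_label : optional
        Class treated as positive for AUC-based tuning and
        :meth:`decision_scores`; defaults to ``"WD"`` when present.
    """

    def __init__(
        self,
        variance_threshold: float | None = DEFAULT_VARIANCE_THRESHOLD,
        n_components: int = DEFAULT_N_COMPONENTS,
        sigma: float | str = "median",
        tune_components: bool = False,
        component_grid: tuple = DIMENSION_GRID,
        tune_forest: bool = False,
        forest_grids: dict | None = None,
        n_estimators: int = 200,
        max_depth: int | None = None,
        max_features="sqrt",
        inner_cv: int = 3,
        positive_label=None,
        random_state: int | None = 0,
    ):
        self.variance_threshold = variance_threshold
        self.n_components = n_components
        self.sigma = sigma
        self.tune_components = tune_components
        self.component_grid = component_grid
        self.tune_forest = tune_forest
        self.forest_grids = forest_grids
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.max_features = max_features
        self.inner_cv = inner_cv
        self.positive_label = positive_label
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _preprocess_fit(self, X):
        """Fit filter + scaler on training rows; return transformed X."""
        if self.variance_threshold is not None:
            self.filter_ = RawVarianceThreshold(self.variance_threshold).fit(X)
            X = self.filter_.transform(X)
        else:
            self.filter_ = None
        self.scaler_ = StandardScaler().fit(X)
        return self.scaler_.transform(X)

    def _preprocess(self, X):
        if self.filter_ is not None:
            X = self.filter_.transform(X)
        return self.scaler_.transform(X)

    def _make_forest(self, params=None):
        p = {
            "n_estimators": self.n_estimators,
            "max_depth": self.max_depth,
            "max_features": self.max_features,
        }
        if params:
            p.update(params)
        return RandomForestClassifier(random_state=self.random_state, **p)

    def _cv_auc(self, Z, y, m=None, forest_params=None) -> float:
        """Mean AUC of a KPCA(m)+forest chain over inner stratified folds."""
        y = np.asarray(y)
        pos = _resolve_positive(np.unique(y), self.positive_label)
        skf = StratifiedKFold(
            n_splits=self.inner_cv, shuffle=True, random_state=self.random_state
        )
        aucs = []
        for tr, te in skf.split(Z, y):
            m_eff = min(m if m is not None else self.n_components, len(tr))
            kpca = RBFKernelPCA(n_components=m_eff, sigma=self.sigma)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                E_tr = kpca.fit_transform(Z[tr])
            forest = self._make_forest(forest_params).fit(E_tr, y[tr])
            proba = forest.predict_proba(kpca.transform(Z[te]))
            scores = proba[:, list(forest.classes_).index(pos)]
            aucs.append(roc_auc_score((y[te] == pos).astype(int), scores))
        return float(np.mean(aucs))

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float, ensure_min_samples=2)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise LabelError("training labels contain a single class")
        self.positive_label_ = _resolve_positive(self.classes_, self.positive_label)
        self.n_features_in_ = X.shape[1]

        Z = self._preprocess_fit(X)

        if self.tune_components:
            self.n_components_ = tune_dimension(
                Z, y, grid=self.component_grid, estimator=self
            )
        else:
            self.n_components_ = self.n_components
        m = min(self.n_components_, Z.shape[0])

        self.kpca_ = RBFKernelPCA(n_components=m, sigma=self.sigma)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            E = self.kpca_.fit_transform(Z)

        if self.tune_forest:
            self.forest_params_ = tune_forest(
                E, y, grids=self.forest_grids or FOREST_GRIDS, estimator=self
            )
        else:
            self.forest_params_ = {
                "n_estimators": self.n_estimators,
                "max_depth": self.max_depth,
                "max_features": self.max_features,
            }
        self.forest_ = self._make_forest(self.forest_params_).fit(E, y)
        return self

    def embed(self, X) -> np.ndarray:
        """Kernel-PCA embedding of new rows (filter + scale + project)."""
        check_is_fitted(self, "kpca_")
        X = check_array(X, dtype=float)
        return self.kpca_.transform(self._preprocess(X))

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(self.embed(X))

    def predict(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict(self.embed(X))

    def decision_scores(self, X) -> np.ndarray:
        """Probability of the positive class for each row."""
        proba = self.predict_proba(X)
        idx = list(self.forest_.classes_).index(self.positive_label_)
        return proba[:, idx]


# ---------------------------------------------------------------------------
# tuning


def tune_dimension(
    Z: np.ndarray,
    y: np.ndarray,
    grid=DIMENSION_GRID,
    cv_folds: int = 3,
    estimator: KernelizedRadiomicsClassifier | None = None,
    random_state: int | None = 0,
) -> int:
    """Pick the kernel-PCA dimension maximizing mean CV AUC (ties: smallest).

    ``Z`` must already be filtered and standardized; the candidate grid
    defaults to 30..200 in steps of 10.
    """
    grid = list(grid)
    if not grid:
        raise ParameterError("empty dimension grid")
    if len(np.unique(y)) < 2:
        raise LabelError("dimension tuning needs two classes")
    est = estimator or KernelizedRadiomicsClassifier(
        inner_cv=cv_folds, random_state=random_state
    )
    best_m, best_auc = None, -np.inf
    for m in sorted(grid):
        auc = est._cv_auc(np.asarray(Z, float), y, m=m)
        if auc > best_auc + 1e-12:
            best_m, best_auc = m, auc
    return int(best_m)


def tune_forest(
    E: np.ndarray,
    y: np.ndarray,
    grids: dict = FOREST_GRIDS,
    cv_folds: int = 3,
    estimator: KernelizedRadiomicsClassifier | None = None,
    random_state: int | None = 0,
) -> dict:
    """Coordinate grid search of forest hyperparameters by CV AUC.

    One full sweep: each parameter in turn is optimized over its grid with
    the other parameters frozen at their current values (initialized to
    the first grid entry).  Ties keep the earlier grid entry, so the
    result is deterministic for a fixed seed.
    """
    for name, g in grids.items():
        if not len(g):
            raise ParameterError(f"empty grid for {name}")
    est = estimator or KernelizedRadiomicsClassifier(
        inner_cv=cv_folds, random_state=random_state
    )
    current = {name: g[0] for name, g in grids.items()}
    E = np.asarray(E, float)
    for name, g in grids.items():
        best_v, best_auc = None, -np.inf
        for v in g:
            trial = dict(current, **{name: v})
            # evaluate the forest directly on the fixed embedding
            auc = _forest_cv_auc(E, y, trial, est)
            if auc > best_auc + 1e-12:
                best_v, best_auc = v, auc
        current[name] = best_v
    return current


def _forest_cv_auc(E, y, params, est: KernelizedRadiomicsClassifier) -> float:
    y = np.asarray(y)
    pos = _resolve_positive(np.unique(y), est.positive_label)
    skf = StratifiedKFold(
        n_splits=est.inner_cv, shuffle=True, random_state=est.random_state
    )
    aucs = []
    for tr, te in skf.split(E, y):
        forest = est._make_forest(params).fit(E[tr], y[tr])
        proba = forest.predict_proba(E[te])
        scores = proba[:, list(forest.classes_).index(pos)]
        aucs.append(roc_auc_score((y[te] == pos).astype(int), scores))
    return float(np.mean(aucs))


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class FoldModel:
    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    model: KernelizedRadiomicsClassifier


@dataclass
class CrossvalResult:
    """Out-of-fold positive-class scores plus per-fold fitted state."""

    scores: np.ndarray  # one score per subject, scored exactly once
    predictions: np.ndarray
    fold_of: np.ndarray
    positive_label: object
    models: list = field(default_factory=list)


def crossval_predict(
    X,
    y,
    estimator: KernelizedRadiomicsClassifier | None = None,
    n_splits: int = 3,
    random_state: int | None = 0,
    folds: np.ndarray | None = None,
) -> CrossvalResult:
    """Stratified k-fold out-of-fold scoring of the kernelized pipeline.

    Each fold's filter variances, standardization statistics, kernel-PCA
    eigensystem and forest are fitted on the other folds only; every
    subject receives exactly one out-of-fold score.  An explicit ``folds``
    assignment (array of fold ids) may be supplied, e.g. to share a
    partition across models.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise LabelError("need two classes for cross-validation")
    if counts.min() < n_splits:
        raise StratificationError(
            f"class with {counts.min()} members cannot fill {n_splits} folds"
        )
    base = estimator or KernelizedRadiomicsClassifier(random_state=random_state)
    if folds is None:
        folds = np.empty(len(y), dtype=int)
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=random_state)
        for k, (_, te) in enumerate(skf.split(X, y)):
            folds[te] = k
    folds = np.asarray(folds)
    pos = _resolve_positive(classes, base.positive_label)

    scores = np.empty(len(y), dtype=float)
    predictions = np.empty(len(y), dtype=object)
    models: list[FoldModel] = []
    for k in np.unique(folds):
        te = np.flatnonzero(folds == k)
        tr = np.flatnonzero(folds != k)
        model = clone(base).fit(X[tr], y[tr])
        scores[te] = model.decision_scores(X[te])
        predictions[te] = model.predict(X[te])
        models.append(FoldModel(int(k), tr, te, model))
    return CrossvalResult(scores, predictions, folds, pos, models)
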