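"""Variance filter, RBF kernel PCA, tuning and leakage-free cross-validation."""

import numpy as np
import pytest
from sklearn.decomposition import PCA, KernelPCA
from sklearn.feature_selection import VarianceThreshold

from kernrad.errors import (
    DimensionError,
    EmptyFeatureSetError,
    LabelError,
    ParameterError,
    StratificationError,
)
from kernrad.kernel import (
    DIMENSION_GRID,
    FOREST_GRIDS,
    KernelizedRadiomicsClassifier,
    RBFKernelPCA,
    RawVarianceThreshold,
    _forest_cv_auc,
    crossval_predict,
    fit_variance_filter,
    median_heuristic_sigma,
    rbf_kernel_matrix,
    tune_dimension,
    tune_forest,
)


def _columns_with_variances(variances, n=8):
    """Columns with exact population variances (alternating +/- sqrt(v))."""
    cols = []
    sign = np.resize([1.0, -1.0], n)
    for v in variances:
        cols.append(sign * np.sqrt(v))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# variance filter


def test_variance_filter_retains_at_and_above_threshold():
    X = _columns_with_variances([0.1, 0.8, 5.0])
    # pin the threshold to the middle column's computed variance so the
    # boundary case is exact regardless of float representation
    tau = X[:, 1].var()
    assert tau == pytest.approx(0.8)
    f = fit_variance_filter(X, threshold=tau)
    np.testing.assert_allclose(f.variances_, [0.1, 0.8, 5.0])
    # strict "lower than" removal: variance exactly at the threshold is kept
    assert list(f.support_) == [False, True, True]
    assert f.transform(X).shape[1] == 2
    # sklearn's VarianceThreshold drops the boundary feature instead
    assert not VarianceThreshold(threshold=tau).fit(X).get_support()[1]


def test_variance_filter_removes_constant_and_can_empty():
    X = np.column_stack([np.full(6, 3.0), np.arange(6, dtype=float)])
    f = fit_variance_filter(X, threshold=0.8)
    assert list(f.support_) == [False, True]
    with pytest.raises(EmptyFeatureSetError):
        fit_variance_filter(np.full((5, 3), 2.0), threshold=0.8)


def test_variance_filter_matches_sklearn_off_boundary(rng):
    X = rng.random((20, 15)) * 4
    ours = RawVarianceThreshold(threshold=0.3).fit(X)
    theirs = VarianceThreshold(threshold=0.3).fit(X)
    np.testing.assert_array_equal(ours.get_support(), theirs.get_support())


# ---------------------------------------------------------------------------
# RBF kernel


def test_rbf_kernel_values_and_oracle(rng):
    x = rng.random((3, 5))
    K = rbf_kernel_matrix(x, x, sigma=0.7)
    np.testing.assert_allclose(np.diag(K), 1.0)
    # ||xi - xj||^2 = 2 sigma^2  ->  k = e^-1
    a = np.zeros(4)
    b = np.zeros(4)
    sigma = 1.3
    b[0] = np.sqrt(2) * sigma
    assert rbf_kernel_matrix(a[None], b[None], sigma)[0, 0] == pytest.approx(
        np.exp(-1)
    )
    # element-by-element double loop oracle
    oracle = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            d2 = np.sum((x[i] - x[j]) ** 2)
            oracle[i, j] = np.exp(-d2 / (2 * 0.7**2))
    np.testing.assert_allclose(K, oracle)
    with pytest.raises(ParameterError):
        rbf_kernel_matrix(x, x, sigma=0.0)


def test_rbf_gram_positive_semidefinite(rng):
    X = rng.standard_normal((25, 6))
    K = rbf_kernel_matrix(X, X, sigma=median_heuristic_sigma(X))
    assert np.linalg.eigvalsh(K).min() >= -1e-8


# ---------------------------------------------------------------------------
# kernel PCA


def test_kpca_components_uncorrelated_and_transform_consistent(rng):
    X = rng.standard_normal((30, 8))
    kpca = RBFKernelPCA(n_components=5, sigma=2.0)
    E_fit = kpca.fit_transform(X)
    E_tr = kpca.transform(X)
    np.testing.assert_allclose(E_fit, E_tr, atol=1e-10)
    corr = np.corrcoef(E_fit.T)
    off = corr - np.diag(np.diag(corr))
    assert np.abs(off).max() < 1e-8


def test_kpca_duplicate_row_embeds_identically(rng):
    X = rng.standard_normal((12, 4))
    kpca = RBFKernelPCA(n_components=3, sigma=1.5).fit(X)
    e_row = kpca.transform(X[[4]])
    e_dup = kpca.transform(np.vstack([X[4], X[4]]))
    np.testing.assert_allclose(e_dup[0], e_dup[1])
    np.testing.assert_allclose(e_dup[0], e_row[0])


def test_kpca_two_sample_hand_oracle():
    # X = {0, 2}, sigma = 1: K = [[1, e^-2], [e^-2, 1]]
    # centered Gram = [[d, -d], [-d, d]] with d = (1 - e^-2)/2,
    # eigenvalue 2d on [1, -1]/sqrt(2) -> |embedding| = sqrt(d)
    X = np.array([[0.0], [2.0]])
    kpca = RBFKernelPCA(n_components=1, sigma=1.0)
    E = kpca.fit_transform(X)
    d = (1 - np.exp(-2)) / 2
    np.testing.assert_allclose(np.abs(E[:, 0]), np.sqrt(d))
    assert E[0, 0] == pytest.approx(-E[1, 0])
    np.testing.assert_allclose(kpca.eigenvalues_, [2 * d])


def test_kpca_linear_kernel_matches_pca_up_to_sign(rng):
    X = rng.standard_normal((20, 6)) * np.array([3, 2, 1.5, 1, 0.5, 0.2])
    E = RBFKernelPCA(n_components=4, kernel="linear").fit_transform(X)
    P = PCA(n_components=4).fit_transform(X)
    for k in range(4):
        assert min(
            np.abs(E[:, k] - P[:, k]).max(), np.abs(E[:, k] + P[:, k]).max()
        ) < 1e-8


def test_kpca_cross_check_sklearn_rbf(rng):
    X = rng.standard_normal((18, 5))
    sigma = 1.8
    ours = RBFKernelPCA(n_components=4, sigma=sigma).fit_transform(X)
    theirs = KernelPCA(n_components=4, kernel="rbf", gamma=1 / (2 * sigma**2))
    E_sk = theirs.fit_transform(X)
    for k in range(4):
        assert min(
            np.abs(ours[:, k] - E_sk[:, k]).max(),
            np.abs(ours[:, k] + E_sk[:, k]).max(),
        ) < 1e-8


def test_kpca_dimension_errors_and_reduction(rng):
    X = rng.standard_normal((10, 3))
    with pytest.raises(DimensionError):
        RBFKernelPCA(n_components=11, sigma=1.0).fit(X)
    # rank-deficient input: duplicated rows force eigenvalue dropping
    Xdup = np.repeat(rng.standard_normal((4, 3)), 3, axis=0)
    with pytest.warns(RuntimeWarning):
        kpca = RBFKernelPCA(n_components=10, sigma=1.0).fit(Xdup)
    assert kpca.n_components_ < 10


# ---------------------------------------------------------------------------
# tuning


def _planted(rng, n=36, p=6, shift=2.5):
    y = np.resize(["WD", "MD/PD"], n)
    X = rng.standard_normal((n, p)) * 2.0
    X[y == "WD", :2] += shift
    return X, y


def test_tune_dimension_grid_and_singleton(rng):
    assert len(DIMENSION_GRID) == 18
    assert DIMENSION_GRID[0] == 30 and DIMENSION_GRID[-1] == 200
    X, y = _planted(rng)
    est = KernelizedRadiomicsClassifier(n_estimators=50, random_state=0)
    assert tune_dimension(X, y, grid=[50], estimator=est) == 50
    with pytest.raises(ParameterError):
        tune_dimension(X, y, grid=[])
    with pytest.raises(LabelError):
        tune_dimension(X, np.repeat("WD", len(y)), grid=[2, 4])


def test_tune_dimension_reaches_best_grid_auc(rng):
    """The selected dimension attains the best grid AUC (its own oracle)."""
    gaps = []
    for seed in range(5):
        r = np.random.default_rng(seed)
        X, y = _planted(r, n=30)
        est = KernelizedRadiomicsClassifier(n_estimators=50, random_state=seed)
        grid = [2, 4, 8]
        m_star = tune_dimension(X, y, grid=grid, estimator=est)
        aucs = {m: est._cv_auc(X, y, m=m) for m in grid}
        gaps.append(max(aucs.values()) - aucs[m_star])
    assert max(gaps) <= 0.02


def test_tune_forest_singletons_containment_and_improvement(rng):
    X, y = _planted(rng, n=30)
    est = KernelizedRadiomicsClassifier(n_estimators=50, random_state=1)
    singles = {"n_estimators": (50,), "max_depth": (3,), "max_features": ("sqrt",)}
    assert tune_forest(X, y, grids=singles, estimator=est) == {
        "n_estimators": 50, "max_depth": 3, "max_features": "sqrt",
    }
    grids = {"n_estimators": (25, 50), "max_depth": (2, 5), "max_features": ("sqrt", 1.0)}
    best = tune_forest(X, y, grids=grids, estimator=est)
    assert all(best[k] in grids[k] for k in grids)
    start = {k: g[0] for k, g in grids.items()}
    assert _forest_cv_auc(X, y, best, est) >= _forest_cv_auc(X, y, start, est)
    with pytest.raises(ParameterError):
        tune_forest(X, y, grids={"n_estimators": ()}, estimator=est)


# ---------------------------------------------------------------------------
# cross-validation and hygiene


def _cv_data(rng, n=30, p=8):
    y = np.resize(["WD", "WD", "MD/PD"], n)
    X = rng.standard_normal((n, p)) * 3.0
    X[y == "WD", 0] += 4.0
    return X, y


def test_crossval_partition_and_stratification(rng):
    X, y = _cv_data(rng)
    res = crossval_predict(
        X, y, estimator=KernelizedRadiomicsClassifier(
            n_components=5, n_estimators=50, random_state=0
        ),
    )
    folds = res.fold_of
    assert sorted(np.unique(folds)) == [0, 1, 2]
    # disjoint and exhaustive by construction of the fold array; each subject
    # scored exactly once
    assert len(res.scores) == len(y) and np.isfinite(res.scores).all()
    global_ratio = (y == "WD").mean()
    for k in range(3):
        in_fold = y[folds == k]
        n_wd = (in_fold == "WD").sum()
        expected = global_ratio * len(in_fold)
        assert abs(n_wd - expected) <= 1.0


def test_crossval_errors(rng):
    X, _ = _cv_data(rng)
    with pytest.raises(LabelError):
        crossval_predict(X, np.repeat("WD", len(X)))
    y_rare = np.array(["MD/PD"] * 2 + ["WD"] * (len(X) - 2))
    with pytest.raises(StratificationError):
        crossval_predict(X, y_rare)


def _fold_state(fm):
    m = fm.model
    parts = [
        m.filter_.variances_.tobytes(),
        np.asarray(m.filter_.support_).tobytes(),
        m.scaler_.mean_.tobytes(),
        m.scaler_.scale_.tobytes(),
        np.float64(m.kpca_.sigma_).tobytes(),
        m.kpca_.eigenvalues_.tobytes(),
        m.kpca_.alphas_.tobytes(),
    ]
    return b"".join(parts)


def test_no_test_fold_leakage_into_fitted_state(rng):
    """Perturbing a held-out row leaves that fold's training state identical."""
    X, y = _cv_data(rng, n=24)
    folds = rng.permutation(np.resize([0, 1, 2], len(y)))
    est = KernelizedRadiomicsClassifier(
        n_components=4, n_estimators=50, random_state=0
    )
    res1 = crossval_predict(X, y, estimator=est, folds=folds)
    X2 = X.copy()
    y2 = y.copy()
    probe = np.flatnonzero(folds == 0)[0]  # held out by fold-0 model
    X2[probe] += 100.0
    y2[probe] = "WD" if y2[probe] == "MD/PD" else "MD/PD"
    res2 = crossval_predict(X2, y2, estimator=est, folds=folds)
    m1 = next(m for m in res1.models if m.fold == 0)
    m2 = next(m for m in res2.models if m.fold == 0)
    assert _fold_state(m1) == _fold_state(m2)
    # forests trained on identical data with the same seed predict identically
    probe_grid = rng.standard_normal((5, m1.model.kpca_.n_components_))
    np.testing.assert_array_equal(
        m1.model.forest_.predict_proba(probe_grid),
        m2.model.forest_.predict_proba(probe_grid),
    )


def test_classifier_sklearn_api(rng):
    X, y = _cv_data(rng)
    est = KernelizedRadiomicsClassifier(n_components=5, n_estimators=50,
                                        random_state=0)
    est.fit(X, y)
    assert est.positive_label_ == "WD"
    assert est.embed(X).shape == (len(y), 5)
    scores = est.decision_scores(X)
    assert scores.shape == (len(y),)
    assert ((scores >= 0) & (scores <= 1)).all()
    params = est.get_params()
    assert params["n_components"] == 5
    est.set_params(n_estimators=25)
    assert est.n_estimators == 25
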