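"""Clinical and combined models, compared against the radiomics signature.

The clinical model uses four dichotomized covariates — T classification
(T3-4 vs T1-2), nodal status (N+ vs N0), composite stage (III-IV vs I-II)
and enhancement pattern (heterogeneous vs homogeneous) — encoded as 0/1
indicators with the first-listed category as reference.  The combined
model concatenates the kernel-PCA embedding of the radiomics features with
those indicators.  All three models share one stratified 3-fold partition
so paired comparisons (DeLong, McNemar) are valid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from kernrad.errors import EncodingError, LabelError, MissingDataError, StratificationError
from kernrad.kernel import KernelizedRadiomicsClassifier, _resolve_positive
from kernrad.phantom import CLINICAL_LEVELS
from kernrad.stats import (
    MetricsReport,
    TestResult,
    confusion_metrics,
    mcnemar_test,
    roc_auc,
    safe_delong_test,
)

CLINICAL_COLUMNS = ("T", "N", "stage", "enhancement")


def encode_clinical(records: pd.DataFrame) -> pd.DataFrame:
    """0/1 indicator design matrix for the four clinical dichotomies.

    The risk level (second listed category, e.g. ``T3-4``) codes 1 and the
    reference level 0; unknown levels raise, missing values raise.
    """
    design = {}
    for col in CLINICAL_COLUMNS:
        if col not in records.columns:
            raise MissingDataError(f"missing clinical column {col!r}")
        ref, risk = CLINICAL_LEVELS[col]
        values = records[col]
        if values.isna().any():
            raise MissingDataError(f"missing value in clinical column {col!r}")
        bad = set(values.unique()) - {ref, risk}
        if bad:
            raise EncodingError(f"unknown level(s) {sorted(bad)} in column {col!r}")
        design[col] = (values == risk).astype(int).to_numpy()
    return pd.DataFrame(design, index=records.index, columns=list(CLINICAL_COLUMNS))


@dataclass
class ModelScores:
    name: str
    scores: np.ndarray
    predictions: np.ndarray
    metrics: MetricsReport


@dataclass
class ThreeModelReport:
    """Out-of-fold scores and Table-style comparison for the three models."""

    models: dict[str, ModelScores]
    comparisons: dict[str, dict[str, TestResult]]
    folds: np.ndarray
    positive_label: object


def fit_and_score_models(
    features: pd.DataFrame | np.ndarray,
    clinical_design: pd.DataFrame,
    labels,
    seed: int = 0,
    estimator: KernelizedRadiomicsClassifier | None = None,
    n_splits: int = 3,
    threshold: float = 0.5,
) -> ThreeModelReport:
    """Fit clinical, radiomics and combined models on one shared partition.

    Per fold, the radiomics pipeline (variance filter, scaler, kernel PCA,
    forest) is fitted on the training parts only; the combined model
    concatenates that fold's kernel embedding with the clinical indicator
    columns and fits a fresh forest of the same configuration.
    """
    X = np.asarray(features, float)
    C = np.asarray(clinical_design, float)
    y = np.asarray(labels)
    if not (len(X) == len(C) == len(y)):
        raise MissingDataError("features, clinical design and labels are misaligned")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise LabelError("need two classes")
    if counts.min() < n_splits:
        raise StratificationError("too few members of a class for the folds")

    base = estimator or KernelizedRadiomicsClassifier(random_state=seed)
    pos = _resolve_positive(classes, base.positive_label)

    folds = np.empty(len(y), dtype=int)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for k, (_, te) in enumerate(skf.split(X, y)):
        folds[te] = k

    names = ("clinical", "radiomics", "combined")
    scores = {name: np.empty(len(y)) for name in names}
    preds = {name: np.empty(len(y), dtype=object) for name in names}

    for k in np.unique(folds):
        te = np.flatnonzero(folds == k)
        tr = np.flatnonzero(folds != k)
        radiomics = clone(base).fit(X[tr], y[tr])
        _score_into(radiomics, X[te], te, scores["radiomics"], preds["radiomics"])

        clin_forest = base._make_forest().fit(C[tr], y[tr])
        _forest_score_into(clin_forest, C[te], pos, te,
                           scores["clinical"], preds["clinical"])

        E_tr = radiomics.embed(X[tr])
        E_te = radiomics.embed(X[te])
        comb_forest = base._make_forest().fit(
            np.hstack([E_tr, C[tr]]), y[tr]
        )
        _forest_score_into(comb_forest, np.hstack([E_te, C[te]]), pos, te,
                           scores["combined"], preds["combined"])

    models = {}
    for name in names:
        m = confusion_metrics(y, preds[name], pos)
        m.auc = roc_auc(y, scores[name], pos)
        m.threshold = threshold
        models[name] = ModelScores(name, scores[name], preds[name], m)

    comparisons: dict[str, dict[str, TestResult]] = {}
    for a, b in (("clinical", "radiomics"), ("clinical", "combined"),
                 ("radiomics", "combined")):
        comparisons[f"{a}_vs_{b}"] = {
            "delong": safe_delong_test(y, scores[a], scores[b], positive_class=pos),
            "mcnemar_acc": mcnemar_test(preds[a] == y, preds[b] == y),
        }
    return ThreeModelReport(models, comparisons, folds, pos)


def _score_into(model, X_te, te, scores, preds):
    scores[te] = model.decision_scores(X_te)
    preds[te] = model.predict(X_te)


def _forest_score_into(forest, X_te, pos, te, scores, preds):
    proba = forest.predict_proba(X_te)
    scores[te] = proba[:, list(forest.classes_).index(pos)]
    preds[te] = forest.predict(X_te)
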