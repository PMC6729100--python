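"""One-command orchestration: phantom cohort -> features -> models -> report.

``run_full_study`` chains every stage of the analysis on synthetic data:
cohort generation, annotation scanning, feature extraction, the kernelized
pipeline with and without variance-threshold selection (on a feature
matrix augmented with pure-noise columns, so the selection has something
to reject), the clinical and combined models, and all paired statistics.
One global seed fans out to per-stage substreams, so a report is
reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import kernrad
from kernrad.annotate import segment_subject
from kernrad.clinical import CLINICAL_COLUMNS, encode_clinical, fit_and_score_models
from kernrad.features import extract_table
from kernrad.kernel import KernelizedRadiomicsClassifier, crossval_predict
from kernrad.phantom import MDPD, WD, PhantomConfig, generate_cohort
from kernrad.stats import (
    confusion_metrics,
    mcnemar_test,
    pearson_chi_square,
    roc_auc,
    roc_points,
    safe_delong_test,
)


@dataclass
class StudyConfig:
    """Every knob of the end-to-end study; defaults define the study design."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    mode: str = "centroid"  # window placement
    variance_threshold: float = 0.8
    n_components: int = 130
    sigma: float | str = "median"
    n_estimators: int = 200
    max_depth: int | None = None
    max_features: str | float = "sqrt"
    tune_components: bool = False
    tune_forest: bool = False
    n_splits: int = 3
    n_noise_features: int = 200  # appended pure-noise columns (variance < tau)
    noise_sd: float = 0.5
    threshold: float = 0.5  # classification threshold on the forest score
    positive_label: str = WD


def _stage_seed(root: np.random.SeedSequence, index: int) -> int:
    return int(root.spawn(index + 1)[index].generate_state(1)[0] % (2**31))


def _metrics_dict(y, scores, threshold, pos, neg) -> dict:
    preds = np.where(np.asarray(scores) >= threshold, pos, neg)
    rep = confusion_metrics(y, preds, pos)
    rep.auc = roc_auc(y, scores, pos)
    rep.threshold = threshold
    return rep.as_dict()


def _test_dict(t) -> dict:
    d = {"statistic": t.statistic, "p": t.p, "method": t.method}
    if t.note:
        d["note"] = t.note
    return d


def run_full_study(config: StudyConfig, seed: int) -> dict:
    """Run the whole synthetic study and return the machine-readable report."""
    root = np.random.SeedSequence(seed)
    phantom_seed = _stage_seed(root, 0)
    pipe_seed = _stage_seed(root, 1)
    noise_seed = _stage_seed(root, 2)

    pconf = dataclasses.replace(config.phantom, seed=phantom_seed)
    images, truth = generate_cohort(pconf)
    y = truth["grade"].to_numpy()
    pos = config.positive_label
    neg = MDPD if pos == WD else WD

    patches, masks = [], []
    for im in images:
        patch, mask = segment_subject(
            im.annotated, im.original, mode=config.mode, source_id=im.subject_id
        )
        patches.append(patch.pixels)
        masks.append(mask)
    features = extract_table(patches, masks, index=truth["subject_id"])

    estimator = KernelizedRadiomicsClassifier(
        variance_threshold=config.variance_threshold,
        n_components=config.n_components,
        sigma=config.sigma,
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        max_features=config.max_features,
        tune_components=config.tune_components,
        tune_forest=config.tune_forest,
        positive_label=pos,
        random_state=pipe_seed,
    )

    # Table-2-style section: with vs without variance-threshold selection on
    # a noise-augmented matrix, one shared fold partition for paired tests.
    rng = np.random.default_rng(noise_seed)
    noise = rng.normal(0.0, config.noise_sd, size=(len(y), config.n_noise_features))
    X_aug = np.hstack([features.to_numpy(), noise])
    cv_vt = crossval_predict(
        X_aug, y, estimator=estimator, n_splits=config.n_splits,
        random_state=pipe_seed,
    )
    est_novt = KernelizedRadiomicsClassifier(
        **{**estimator.get_params(), "variance_threshold": None}
    )
    cv_novt = crossval_predict(
        X_aug, y, estimator=est_novt, n_splits=config.n_splits,
        random_state=pipe_seed, folds=cv_vt.fold_of,
    )
    vt_section = {
        "with_vt": _metrics_dict(y, cv_vt.scores, config.threshold, pos, neg),
        "without_vt": _metrics_dict(y, cv_novt.scores, config.threshold, pos, neg),
        "delong": _test_dict(safe_delong_test(y, cv_vt.scores, cv_novt.scores, pos)),
        "mcnemar_acc": _test_dict(
            mcnemar_test(
                np.where(cv_vt.scores >= config.threshold, pos, neg) == y,
                np.where(cv_novt.scores >= config.threshold, pos, neg) == y,
            )
        ),
    }

    # Table-3-style section: clinical vs radiomics vs combined (no noise).
    design = encode_clinical(truth)
    three = fit_and_score_models(
        features, design, y, seed=pipe_seed, estimator=estimator,
        n_splits=config.n_splits, threshold=config.threshold,
    )
    three_section = {
        name: {**ms.metrics.as_dict()} for name, ms in three.models.items()
    }
    three_section["comparisons"] = {
        pair: {k: _test_dict(t) for k, t in tests.items()}
        for pair, tests in three.comparisons.items()
    }

    # Table-1-style cohort summary: covariate counts by grade + chi-square p.
    cohort = {"n_subjects": int(len(y)),
              "n_wd": int((y == WD).sum()), "n_mdpd": int((y == MDPD).sum())}
    for col in CLINICAL_COLUMNS:
        tab = pd.crosstab(truth[col], truth["grade"])
        entry = {
            "counts": {str(k): {str(g): int(v) for g, v in row.items()}
                       for k, row in tab.iterrows()},
        }
        if tab.shape == (2, 2):
            entry["chi_square_p"] = pearson_chi_square(tab.to_numpy()).p
        cohort[col] = entry

    scores_table = pd.DataFrame(
        {
            "subject_id": truth["subject_id"],
            "grade": y,
            "fold": cv_vt.fold_of,
            "score_with_vt": cv_vt.scores,
            "score_without_vt": cv_novt.scores,
            "score_clinical": three.models["clinical"].scores,
            "score_radiomics": three.models["radiomics"].scores,
            "score_combined": three.models["combined"].scores,
        }
    )

    return {
        "provenance": {
            "seed": int(seed),
            "package_version": kernrad.__version__,
            "config": _config_dict(config),
        },
        "cohort": cohort,
        "vt_comparison": vt_section,
        "three_models": three_section,
        "subject_scores": scores_table.to_dict(orient="list"),
    }


def run_vt_benchmark(config: StudyConfig, seed: int) -> dict:
    """Phantom-cohort benchmark of the with-VT vs without-VT pipelines.

    Generates a cohort, extracts features, appends pure-noise columns whose
    variance falls below the threshold, and scores both pipeline variants
    on one shared stratified 3-fold partition.  Returns pooled out-of-fold
    AUC and accuracy for each variant.
    """
    root = np.random.SeedSequence(seed)
    phantom_seed = _stage_seed(root, 0)
    pipe_seed = _stage_seed(root, 1)
    noise_seed = _stage_seed(root, 2)

    pconf = dataclasses.replace(config.phantom, seed=phantom_seed)
    images, truth = generate_cohort(pconf)
    y = truth["grade"].to_numpy()
    pos = config.positive_label
    neg = MDPD if pos == WD else WD

    patches, masks = [], []
    for im in images:
        patch, mask = segment_subject(im.annotated, im.original, mode=config.mode)
        patches.append(patch.pixels)
        masks.append(mask)
    features = extract_table(patches, masks).to_numpy()

    rng = np.random.default_rng(noise_seed)
    noise = rng.normal(0.0, config.noise_sd, size=(len(y), config.n_noise_features))
    X_aug = np.hstack([features, noise])

    est = KernelizedRadiomicsClassifier(
        variance_threshold=config.variance_threshold,
        n_components=config.n_components,
        sigma=config.sigma,
        n_estimators=config.n_estimators,
        positive_label=pos,
        random_state=pipe_seed,
    )
    cv_vt = crossval_predict(X_aug, y, estimator=est, n_splits=config.n_splits,
                             random_state=pipe_seed)
    est_novt = KernelizedRadiomicsClassifier(
        **{**est.get_params(), "variance_threshold": None}
    )
    cv_novt = crossval_predict(X_aug, y, estimator=est_novt,
                               n_splits=config.n_splits,
                               random_state=pipe_seed, folds=cv_vt.fold_of)

    out = {}
    for name, cv in (("with_vt", cv_vt), ("without_vt", cv_novt)):
        preds = np.where(cv.scores >= config.threshold, pos, neg)
        rep = confusion_metrics(y, preds, pos)
        out[f"auc_{name}"] = roc_auc(y, cv.scores, pos)
        out[f"acc_{name}"] = rep.acc
        out[f"sen_{name}"] = rep.sen
        out[f"spe_{name}"] = rep.spe
    out["n_subjects"] = int(len(y))
    return out


def _config_dict(config: StudyConfig) -> dict:
    d = dataclasses.asdict(config)
    d["phantom"]["image_size"] = list(d["phantom"]["image_size"])
    return d


def write_report(report: dict, out_dir: str | Path) -> None:
    """Write report.json plus CSV tables and per-model ROC point files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    scores = pd.DataFrame(report["subject_scores"])
    scores.to_csv(out_dir / "subject_scores.csv", index=False)

    rows = []
    for name in ("with_vt", "without_vt"):
        rows.append({"model": name, **_metric_row(report["vt_comparison"][name])})
    for name in ("clinical", "radiomics", "combined"):
        rows.append({"model": name, **_metric_row(report["three_models"][name])})
    pd.DataFrame(rows).to_csv(out_dir / "metrics.csv", index=False)

    y = np.asarray(report["subject_scores"]["grade"])
    pos = report["provenance"]["config"]["positive_label"]
    for col in ("score_with_vt", "score_without_vt", "score_clinical",
                "score_radiomics", "score_combined"):
        fpr, tpr, thr = roc_points(y, scores[col].to_numpy(), pos)
        pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}).to_csv(
            out_dir / f"roc_{col[6:]}.csv", index=False
        )


def _metric_row(d: dict) -> dict:
    return {k: d[k] for k in ("acc", "sen", "spe", "ppv", "npv", "auc")}


def read_report(out_dir: str | Path) -> dict:
    with open(Path(out_dir) / "report.json") as fh:
        return json.load(fh)
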