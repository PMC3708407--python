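"""End-to-end orchestration of the four feature-extraction methods.

Method 1: bilateral 2D-PCA with d = 7 -> 49 projection features -> mRMR
top 20.  Method 2: six summary statistics of the 49 projection values ->
mRMR top 5.  Method 3: ten geometric mask descriptors -> mRMR top 5.
Method 4 (hybrid): the union of the three selected sets — exactly 30
features — with no further selection.

Everything fitted (projection bases, discretization thresholds, mRMR
ranking, standardization statistics, the classifier) uses the training
split only; the test split is strictly held out and an id audit rejects
overlapping splits.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import mrmr as mrmr_mod
from .classifiers import CLASSIFIER_NAMES, make_classifier, save_model_json
from .evaluation import (ConfusionMatrix, EvaluationReport, metrics, kappa,
                         report_from_scores)
from .patterns import (FeatureTable, PatternSet, normalize_patch,
                       write_feature_table)
from .shape import GEO_NAMES, compute_geometric_features
from .twodpca import STAT_NAMES, BilateralPCA, pca_feature_names, \
    summarize_projection

logger = logging.getLogger("nodulecad")

K_SELECT = {1: 20, 2: 5, 3: 5, 4: 30}


class LeakageError(Exception):
    """Train and test splits share pattern ids."""


@dataclasses.dataclass
class MethodSpec:
    """Configuration of one method x classifier pipeline run."""

    method_id: int = 4
    classifier: str = "ann"
    k_select: int | None = None  # default per method: 20 / 5 / 5 / 30
    criterion: mrmr_mod.Criterion = "difference"
    pca_dim: int = 7
    patch_side: int = 64
    seed: int = 0
    hyperparameters: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method_id not in (1, 2, 3, 4):
            raise ValueError("method_id must be 1..4")
        if self.classifier not in CLASSIFIER_NAMES:
            raise ValueError(
                f"unknown classifier {self.classifier!r}; choose from {CLASSIFIER_NAMES}"
            )
        if self.k_select is None:
            self.k_select = K_SELECT[self.method_id]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _audit_splits(trainset: PatternSet, testset: PatternSet) -> None:
    overlap = set(trainset.ids) & set(testset.ids)
    if overlap:
        raise LeakageError(f"train/test ids overlap: {sorted(overlap)[:5]}...")


def _log_stage(stage: str, t0: float, **info) -> None:
    extras = " ".join(f"{k}={v}" for k, v in info.items())
    logger.info("stage=%s %s wall_s=%.2f", stage, extras, time.perf_counter() - t0)


class FeatureExtractor:
    """Fits the 2D-PCA basis on training patches and emits the per-method
    feature tables for any pattern set."""

    def __init__(self, pca_dim: int = 7, patch_side: int = 64) -> None:
        self.pca_dim = pca_dim
        self.patch_side = patch_side
        self._pca: BilateralPCA | None = None

    def fit(self, trainset: PatternSet) -> "FeatureExtractor":
        images = [
            normalize_patch(p, self.patch_side).image for p in trainset
        ]
        self._pca = BilateralPCA(d=self.pca_dim).fit(images)
        return self

    def _flat_projections(self, pset: PatternSet) -> np.ndarray:
        assert self._pca is not None, "extractor not fitted"
        return np.stack([
            self._pca.transform_flat(normalize_patch(p, self.patch_side).image)
            for p in pset
        ])

    def pca_table(self, pset: PatternSet) -> FeatureTable:
        values = self._flat_projections(pset)
        return FeatureTable(pset.ids, pca_feature_names(self.pca_dim),
                            values, pset.labels)

    def stats_table(self, pset: PatternSet) -> FeatureTable:
        values = np.stack([
            summarize_projection(v) for v in self._flat_projections(pset)
        ])
        return FeatureTable(pset.ids, list(STAT_NAMES), values, pset.labels)

    def geometric_table(self, pset: PatternSet) -> FeatureTable:
        values = np.stack([
            compute_geometric_features(p.mask, p.pixel_spacing_mm).as_vector()
            for p in pset
        ])
        return FeatureTable(pset.ids, list(GEO_NAMES), values, pset.labels)

    def tables_for_method(
        self, method_id: int, pset: PatternSet
    ) -> list[FeatureTable]:
        if method_id == 1:
            return [self.pca_table(pset)]
        if method_id == 2:
            return [self.stats_table(pset)]
        if method_id == 3:
            return [self.geometric_table(pset)]
        return [self.pca_table(pset), self.stats_table(pset),
                self.geometric_table(pset)]


def _select_on_train(
    table: FeatureTable, k: int, criterion: mrmr_mod.Criterion
) -> tuple[list[str], mrmr_mod.MrmrResult]:
    discrete, _ = mrmr_mod.discretize_table(table.values, table.y)
    result = mrmr_mod.mrmr_select(discrete, k, criterion)
    names = [table.feature_names[i] for i in result.ranked_indices]
    return names, result


def select_method_features(
    extractor: FeatureExtractor,
    trainset: PatternSet,
    spec: MethodSpec,
) -> tuple[list[str], list[dict]]:
    """mRMR-selected feature names for a method, fitted on train only.

    Method 4 unions the per-method selections of methods 1-3 (20 + 5 + 5
    namespaced names, necessarily distinct).
    """
    rankings: list[dict] = []
    if spec.method_id in (1, 2, 3):
        table = extractor.tables_for_method(spec.method_id, trainset)[0]
        k = min(spec.k_select, len(table.feature_names))
        names, result = _select_on_train(table, k, spec.criterion)
        rankings.append(result.to_dict(table.feature_names))
        return names, rankings
    names: list[str] = []
    for sub_id in (1, 2, 3):
        table = extractor.tables_for_method(sub_id, trainset)[0]
        k = min(K_SELECT[sub_id], len(table.feature_names))
        sub_names, result = _select_on_train(table, k, spec.criterion)
        rankings.append(result.to_dict(table.feature_names))
        names.extend(sub_names)
    if len(set(names)) != len(names):
        raise RuntimeError("hybrid selection produced duplicate names")
    return names, rankings


def run_method(
    spec: MethodSpec,
    trainset: PatternSet,
    testset: PatternSet,
    out_dir: str | Path | None = None,
) -> EvaluationReport:
    """Train and evaluate one method x classifier combination."""
    _audit_splits(trainset, testset)
    t0 = time.perf_counter()
    extractor = FeatureExtractor(spec.pca_dim, spec.patch_side).fit(trainset)
    train_tables = extractor.tables_for_method(spec.method_id, trainset)
    test_tables = extractor.tables_for_method(spec.method_id, testset)
    train_all = FeatureTable.concat(train_tables)
    test_all = FeatureTable.concat(test_tables)
    _log_stage("extract", t0, n_train=len(trainset), n_test=len(testset),
               n_features=len(train_all.feature_names))

    t0 = time.perf_counter()
    names, rankings = select_method_features(extractor, trainset, spec)
    train_sel = train_all.select(names)
    test_sel = test_all.select(names)
    _log_stage("select", t0, k=len(names), seed=spec.seed)

    # standardization fitted on train only
    mu = train_sel.values.mean(axis=0)
    sd = train_sel.values.std(axis=0)
    sd[sd == 0] = 1.0
    x_train = (train_sel.values - mu) / sd
    x_test = (test_sel.values - mu) / sd

    t0 = time.perf_counter()
    model = make_classifier(spec.classifier, seed=spec.seed,
                            **spec.hyperparameters)
    model.fit(x_train, train_sel.y)
    scores = model.scores(x_test)
    _log_stage("train", t0, classifier=spec.classifier, seed=spec.seed)

    report = report_from_scores(
        test_sel.y, scores, feature_names=names,
        method_id=spec.method_id, classifier=spec.classifier,
    )
    if out_dir is not None:
        _write_artifacts(Path(out_dir), spec, train_sel, test_sel,
                         rankings, model, report)
    return report


def _write_artifacts(out_dir, spec, train_sel, test_sel, rankings, model,
                     report) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_feature_table(train_sel, out_dir / "features_train.csv")
    write_feature_table(test_sel, out_dir / "features_test.csv")
    (out_dir / "ranking.json").write_text(json.dumps(rankings, indent=2))
    (out_dir / "report.json").write_text(report.to_json())
    pd.DataFrame(report.roc_points, columns=["fpr", "tpr"]).to_csv(
        out_dir / "roc_points.csv", index=False
    )
    manifest = {"spec": spec.to_dict(), "n_train": train_sel.n_patterns,
                "n_test": test_sel.n_patterns}
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    try:
        save_model_json(model, out_dir / "model.json")
    except (ValueError, AttributeError):
        pass  # tree-backed models are reproducible from the manifest seed


def run_table(
    trainset: PatternSet,
    testset: PatternSet,
    methods: Sequence[int] = (1, 2, 3, 4),
    classifiers: Sequence[str] = CLASSIFIER_NAMES,
    seed: int = 0,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Evaluate the full method x classifier grid.

    Returns one row per cell with sensitivity, TCA, specificity, AUROC,
    kappa and RMSE (percentage metrics on the 0-100 scale).
    """
    rows = []
    for method_id in methods:
        for clf in classifiers:
            spec = MethodSpec(method_id=method_id, classifier=clf, seed=seed)
            rep = run_method(spec, trainset, testset)
            rows.append({
                "method": method_id,
                "classifier": clf,
                "sensitivity_pct": None if rep.sensitivity is None
                else 100 * rep.sensitivity,
                "tca_pct": None if rep.tca is None else 100 * rep.tca,
                "specificity_pct": None if rep.specificity is None
                else 100 * rep.specificity,
                "auroc": rep.auroc,
                "kappa": rep.kappa,
                "rmse": rep.rmse,
            })
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


@dataclasses.dataclass
class CrossValidationReport:
    """Per-fold reports plus the pooled confusion matrix and metrics."""

    fold_reports: list[EvaluationReport]
    pooled_cm: ConfusionMatrix
    pooled_metrics: dict
    pooled_kappa: float

    @property
    def pooled_tca(self) -> float:
        return self.pooled_metrics["tca"]


def cross_validate(
    spec: MethodSpec,
    dataset: PatternSet,
    folds: int = 5,
    seed: int = 0,
) -> CrossValidationReport:
    """Stratified k-fold cross-validation with selection re-fitted per fold."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = np.array([1 if p.is_nodule else 0 for p in dataset])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_reports = []
    tp = fp = fn = tn = 0
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        sub_train = PatternSet([dataset[i] for i in train_idx])
        sub_test = PatternSet([dataset[i] for i in test_idx])
        rep = run_method(spec, sub_train, sub_test)
        fold_reports.append(rep)
        tp += rep.cm.tp
        fp += rep.cm.fp
        fn += rep.cm.fn
        tn += rep.cm.tn
    pooled = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
    return CrossValidationReport(
        fold_reports=fold_reports,
        pooled_cm=pooled,
        pooled_metrics=metrics(pooled),
        pooled_kappa=kappa(pooled),
    )
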