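"""Confusion-matrix metrics, stratified k-fold CV, threshold sweep, experiments.

The positive class is malignant (label 1).  Percentages are kept at full
precision internally; rounding to two decimals happens only when a report
is formatted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import gnn
from .dataset_io import FEATURE_NAMES
from .graph import pearson_matrix, threshold_edges

METRIC_NAMES = [
    "accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "npv",
    "fpr",
    "fdr",
    "fnr",
    "f1",
    "mcc",
]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """The ten confusion-matrix metrics; NaN marks an undefined ratio."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    npv: float
    fpr: float
    fdr: float
    fnr: float
    f1: float
    mcc: float
    undefined: dict = field(default_factory=dict)  # metric -> reason

    def as_dict(self, percent: bool = False, ndigits: int | None = None) -> dict:
        out = {}
        for name in METRIC_NAMES:
            v = getattr(self, name)
            if percent and not math.isnan(v):
                v = v * 100.0
            if ndigits is not None and not math.isnan(v):
                v = round(v, ndigits)
            out[name] = v
        return out


def _ratio(num, den, name, undefined):
    if den == 0:
        undefined[name] = f"denominator zero ({name})"
        return float("nan")
    return num / den


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def confusion_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Standard metric suite from TP/TN/FP/FN.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    precision = TP/(TP+FP), NPV = TN/(TN+FN), FPR = FP/(FP+TN),
    FDR = FP/(FP+TP), FNR = FN/(FN+TP), F1 = harmonic mean of precision
    and sensitivity, MCC = (TP*TN - FP*FN) / sqrt of the four marginal
    products.  Ratios with a zero denominator are reported as NaN with a
    reason, never silently as zero.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    und: dict = {}
    sens = _ratio(tp, tp + fn, "sensitivity", und)
    spec = _ratio(tn, tn + fp, "specificity", und)
    prec = _ratio(tp, tp + fp, "precision", und)
    npv = _ratio(tn, tn + fn, "npv", und)
    fpr = _ratio(fp, fp + tn, "fpr", und)
    fdr = _ratio(fp, fp + tp, "fdr", und)
    fnr = _ratio(fn, fn + tp, "fnr", und)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "f1", und)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        und["mcc"] = "a confusion-matrix margin is zero"
        mcc = float("nan")
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(
        accuracy=(tp + tn) / counts.total,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        npv=npv,
        fpr=fpr,
        fdr=fdr,
        fnr=fnr,
        f1=f1,
        mcc=mcc,
        undefined=und,
    )


def stratified_kfold(labels, k: int = 5, seed: int = 0, trainer=None):
    """Stratified k-fold evaluation driven by a ``trainer`` callback.

    ``trainer(train_idx, val_idx) -> y_pred`` returns predicted labels for
    the validation indices.  Fold sizes differ by at most one, the class
    ratio is preserved per fold within one sample, and each sample is
    validated exactly once.  Returns (per-fold MetricsReport list,
    summary dict).
    """
    labels = np.asarray(labels, dtype=int)
    _, counts = np.unique(labels, return_counts=True)
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smallest class count {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports = []
    for train_idx, val_idx in skf.split(np.zeros(len(labels)), labels):
        y_pred = trainer(train_idx, val_idx)
        reports.append(
            confusion_metrics(confusion_from_predictions(labels[val_idx], y_pred))
        )
    accs = [r.accuracy for r in reports]
    summary = {
        "mean_accuracy": float(np.mean(accs)),
        "std_accuracy": float(np.std(accs)),
        "fold_accuracies": accs,
    }
    return reports, summary


def _train_eval_once(table, threshold, config, seed, test_size=0.2):
    """Split, build the graph on the training split, train, evaluate."""
    idx = np.arange(len(table))
    labels = table["label"].to_numpy()
    tr, te = train_test_split(idx, test_size=test_size, stratify=labels, random_state=seed)
    train_tab, test_tab = table.iloc[tr], table.iloc[te]
    graph = threshold_edges(pearson_matrix(train_tab), threshold)
    stats = gnn.compute_train_stats(train_tab)
    train_s = gnn.build_graph_samples(train_tab, graph, stats)
    test_s = gnn.build_graph_samples(test_tab, graph, stats)
    trained = gnn.train_model(train_s, config)
    y_pred = np.array([p.predicted_label for p in trained.predict(test_s)])
    report = confusion_metrics(
        confusion_from_predictions(test_tab["label"].to_numpy(), y_pred)
    )
    return graph, trained, report


def threshold_sweep(table: pd.DataFrame, thresholds, config: gnn.ModelConfig, seed: int = 0):
    """Rebuild the graph and retrain at each correlation threshold.

    Returns one row per threshold: (threshold, edge count, test accuracy).
    An edgeless graph is reported and trained with isolated nodes.
    """
    rows = []
    for thr in thresholds:
        graph, _trained, report = _train_eval_once(table, thr, config, seed)
        rows.append(
            {
                "threshold": thr,
                "n_edges": graph.n_edges,
                "test_accuracy": report.accuracy,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ExperimentConfig:
    """End-to-end experiment: synthetic data -> features -> graph -> GCN."""

    n_benign: int = 200
    n_malignant: int = 200
    threshold: float = 0.2
    test_size: float = 0.2
    seed: int = 0
    model: gnn.ModelConfig = None

    def __post_init__(self):
        if self.model is None:
            self.model = gnn.ModelConfig(seed=self.seed)


def run_experiment(config: ExperimentConfig, feature_table: pd.DataFrame | None = None) -> dict:
    """Run the full pipeline and return a report bundle.

    If ``feature_table`` is given the synthetic-generation and feature
    stages are skipped.  Stages are named in any propagated error.
    """
    from . import stats as fstats
    from . import synthetic

    bundle: dict = {}
    try:
        if feature_table is None:
            _samples, feature_table = synthetic.generate_dataset(
                config.n_benign, config.n_malignant, seed=config.seed
            )
        bundle["feature_table"] = feature_table
    except Exception as exc:
        raise RuntimeError(f"stage 'synthetic/features' failed: {exc}") from exc
    try:
        anova = fstats.anova_per_feature(feature_table)
        bundle["anova"] = {a.feature: {"F": a.f_statistic, "p": a.p_value} for a in anova}
        bundle["ranking"] = [
            {"feature": r.feature, "importance_pct": r.importance_pct}
            for r in fstats.svm_feature_ranking(feature_table, seed=config.seed)
        ]
    except Exception as exc:
        raise RuntimeError(f"stage 'feature_stats' failed: {exc}") from exc
    try:
        graph, trained, report = _train_eval_once(
            feature_table, config.threshold, config.model, config.seed, config.test_size
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'graph/train/evaluate' failed: {exc}") from exc
    bundle["graph"] = graph
    bundle["model"] = trained
    bundle["metrics"] = report
    bundle["metrics_pct"] = report.as_dict(percent=True, ndigits=2)
    return bundle
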