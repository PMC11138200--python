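"""Feature-importance statistics: per-feature ANOVA, linear-SVM ranking, summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .dataset_io import FEATURE_NAMES


@dataclass
class AnovaResult:
    feature: str
    f_statistic: float  # NaN when undefined (constant feature)
    p_value: float
    note: str = ""


@dataclass
class FeatureRanking:
    feature: str
    importance_pct: float  # |coef| share of the linear SVM, in percent


def anova_per_feature(table: pd.DataFrame) -> list[AnovaResult]:
    """One-way ANOVA of each feature across the two classes.

    With two groups the F statistic equals the square of the pooled-variance
    two-sample t statistic; a p-value below 0.05 rejects equality of the
    class means.  A feature constant within both classes is flagged rather
    than raising.
    """
    labels = table["label"].to_numpy()
    classes = np.unique(labels)
    if len(classes) < 2 or min((labels == c).sum() for c in classes) < 2:
        raise ValueError("ANOVA needs at least 2 samples in each of 2 classes")
    results = []
    for name in FEATURE_NAMES:
        groups = [table.loc[labels == c, name].to_numpy(dtype=float) for c in classes]
        if all(np.ptp(g) == 0 for g in groups):
            results.append(
                AnovaResult(name, float("nan"), float("nan"), note="constant feature")
            )
            continue
        f, p = sps.f_oneway(*groups)
        results.append(AnovaResult(name, float(f), float(p)))
    return results


def svm_feature_ranking(table: pd.DataFrame, seed: int = 0) -> list[FeatureRanking]:
    """Rank features by absolute coefficient of a linear SVM.

    Features are z-scored, a primal linear SVM (C = 1, tol = 1e-4, up to
    1e4 iterations) is fitted, and importances are the normalized absolute
    coefficients in percent, returned in descending order.
    """
    labels = table["label"].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("feature ranking needs both classes present")
    X = StandardScaler().fit_transform(table[FEATURE_NAMES].to_numpy(dtype=float))
    svm = LinearSVC(C=1.0, tol=1e-4, max_iter=10_000, random_state=seed)
    svm.fit(X, labels)
    coefs = np.abs(svm.coef_.ravel())
    pct = 100.0 * coefs / coefs.sum()
    order = np.argsort(-pct)
    return [FeatureRanking(FEATURE_NAMES[i], float(pct[i])) for i in order]


def class_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Five-number summary (min, q1, median, q3, max) per feature per class.

    Quartiles use linear interpolation.  Rows are indexed by
    (feature, class label).
    """
    rows = []
    for label, sub in table.groupby("label"):
        for name in FEATURE_NAMES:
            v = sub[name].to_numpy(dtype=float)
            q = np.percentile(v, [0, 25, 50, 75, 100])
            rows.append(
                {
                    "feature": name,
                    "label": label,
                    "min": q[0],
                    "q1": q[1],
                    "median": q[2],
                    "q3": q[3],
                    "max": q[4],
                }
            )
    return pd.DataFrame(rows).set_index(["feature", "label"])
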