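"""Pearson-correlation feature graphs.

The seven lesion features become the seven nodes of an undirected graph;
an edge joins two features when the absolute sample Pearson correlation
of their columns exceeds a threshold (default 0.2, strict inequality),
and the signed correlation is stored as the edge weight.  To avoid
information leakage the correlations should be computed on the training
split only and the resulting topology frozen for validation/test data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dataset_io import FEATURE_NAMES

DEFAULT_THRESHOLD = 0.2


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson r matrix over named feature columns."""

    names: list
    values: np.ndarray  # (n, n), diagonal 1

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.names), len(self.names)):
            raise ValueError("correlation matrix shape does not match names")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(v) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = v


@dataclass
class CorrelationGraph:
    """Thresholded feature graph: nodes are features, weights signed r."""

    nodes: list  # ordered feature names; node id = index
    edges: list  # (source, target, weight) with source < target, 0-based
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self):
        for s, t, w in self.edges:
            if not s < t:
                raise ValueError("edges must be stored with source < target")
            if abs(w) <= self.threshold:
                raise ValueError(
                    f"edge ({s},{t}) weight {w} does not exceed threshold {self.threshold}"
                )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        """Dense symmetric weighted adjacency (zero diagonal)."""
        n = len(self.nodes)
        A = np.zeros((n, n))
        for s, t, w in self.edges:
            A[s, t] = A[t, s] = w
        return A


@dataclass
class EdgeRegression:
    """Least-squares line target = m * source + c for one graph edge."""

    source: str
    target: str
    slope: float
    intercept: float

    def equation(self) -> str:
        sign = "+" if self.intercept >= 0 else "-"
        return (
            f"{self.target} = {self.slope:.2f}*{self.source} "
            f"{sign} {abs(self.intercept):.2f}"
        )


def pearson_matrix(table: pd.DataFrame, feature_names=None) -> CorrelationMatrix:
    """Sample Pearson correlation for every feature pair."""
    names = list(feature_names) if feature_names is not None else FEATURE_NAMES
    X = table[names].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples for correlations")
    stds = X.std(axis=0)
    for name, s in zip(names, stds):
        if s == 0:
            raise ValueError(f"feature {name!r} has zero variance")
    r = np.corrcoef(X, rowvar=False)
    r = (r + r.T) / 2.0  # kill last-bit asymmetry
    return CorrelationMatrix(names=names, values=r)


def threshold_edges(
    matrix: CorrelationMatrix, threshold: float = DEFAULT_THRESHOLD
) -> CorrelationGraph:
    """Keep undirected edges with |r| strictly above ``threshold``.

    All nodes are retained even when isolated; ties at the threshold are
    excluded (strict ``>``).
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    n = len(matrix.names)
    edges = [
        (i, j, float(matrix.values[i, j]))
        for i in range(n)
        for j in range(i + 1, n)
        if abs(matrix.values[i, j]) > threshold
    ]
    return CorrelationGraph(nodes=list(matrix.names), edges=edges, threshold=threshold)


def to_graph_table(graph: CorrelationGraph) -> pd.DataFrame:
    """Tabular (feature, node, source, target, weight) rows, 1-based ids.

    Feature rows pair each feature with its node id; edge rows list the
    surviving correlations sorted by (source, target).  Together they are
    bijective with the graph.
    """
    n = len(graph.nodes)
    edges = sorted(graph.edges)
    rows = []
    for i in range(max(n, len(edges))):
        rows.append(
            {
                "feature": graph.nodes[i] if i < n else "",
                "node": i + 1 if i < n else np.nan,
                "source": edges[i][0] + 1 if i < len(edges) else np.nan,
                "target": edges[i][1] + 1 if i < len(edges) else np.nan,
                "weight": edges[i][2] if i < len(edges) else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["feature", "node", "source", "target", "weight"])


def from_graph_table(df: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> CorrelationGraph:
    """Inverse of :func:`to_graph_table`."""
    nodes = [f for f in df["feature"].tolist() if isinstance(f, str) and f]
    edge_rows = df.dropna(subset=["source", "target", "weight"])
    edges = [
        (int(r.source) - 1, int(r.target) - 1, float(r.weight))
        for r in edge_rows.itertuples()
    ]
    return CorrelationGraph(nodes=nodes, edges=edges, threshold=threshold)


def fit_edge_regressions(table: pd.DataFrame, graph: CorrelationGraph) -> list[EdgeRegression]:
    """Ordinary least squares of target on source for every graph edge."""
    if len(table) < 3:
        raise ValueError("need at least 3 samples for regression")
    out = []
    for s, t, _ in sorted(graph.edges):
        x = table[graph.nodes[s]].to_numpy(dtype=float)
        y = table[graph.nodes[t]].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"source feature {graph.nodes[s]!r} has zero variance")
        res = sps.linregress(x, y)
        out.append(
            EdgeRegression(
                source=graph.nodes[s],
                target=graph.nodes[t],
                slope=float(res.slope),
                intercept=float(res.intercept),
            )
        )
    return out
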