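"""Published reference feature graph for the BUSI breast-ultrasound dataset.

The seven-feature correlation graph reported for the public BUSI dataset
survives a |r| > 0.2 threshold with the 17 edges tabulated below (1-based
node ids, node order = canonical feature order).  These printed weights
serve as a fixture for exercising the graph machinery without the image
data itself.
"""

from __future__ import annotations

import numpy as np

from .dataset_io import FEATURE_NAMES
from .graph import CorrelationGraph, CorrelationMatrix

#: (source, target, Pearson r) with 1-based node ids
REFERENCE_EDGE_WEIGHTS = [
    (1, 2, 0.78),
    (1, 3, 0.31),
    (1, 4, 0.81),
    (1, 5, 0.47),
    (1, 6, 0.79),
    (1, 7, 0.25),
    (2, 3, 0.36),
    (2, 4, 0.62),
    (2, 5, 0.70),
    (2, 6, 0.64),
    (2, 7, 0.27),
    (3, 4, 0.22),
    (3, 5, 0.29),
    (3, 6, 0.21),
    (3, 7, 0.43),
    (4, 6, 0.76),
    (5, 6, 0.39),
]


def reference_correlation_matrix() -> CorrelationMatrix:
    """7x7 matrix holding the published weights; unlisted pairs are zero.

    Pairs absent from the published edge list did not survive the 0.2
    threshold, so any value with |r| <= 0.2 is consistent; zero is used.
    """
    n = len(FEATURE_NAMES)
    m = np.eye(n)
    for s, t, w in REFERENCE_EDGE_WEIGHTS:
        m[s - 1, t - 1] = m[t - 1, s - 1] = w
    return CorrelationMatrix(names=list(FEATURE_NAMES), values=m)


def reference_graph(threshold: float = 0.2) -> CorrelationGraph:
    """The published feature graph at the given threshold."""
    from .graph import threshold_edges

    return threshold_edges(reference_correlation_matrix(), threshold)
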