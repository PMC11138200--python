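"""Reading BUSI-style image/mask datasets and serializing feature tables and graphs.

A BUSI-style dataset is a directory with one sub-folder per class
(``benign/``, ``malignant/``) holding 8-bit grayscale PNG ultrasound
images, each paired with one or more binary ground-truth masks whose file
names contain ``_mask``.  Masks are binarized with "any pixel > 0 is
foreground", and multiple masks for one image are merged by pixel-wise OR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

#: canonical feature-column order of the study's tabular representation
FEATURE_NAMES = [
    "solidity",
    "sift_count",
    "wh_ratio",
    "ellipse_ratio",
    "harris_count",
    "circularity",
    "brightness",
]

#: CSV header of a feature table
TABLE_COLUMNS = ["id"] + FEATURE_NAMES + ["label"]

BENIGN, MALIGNANT = 0, 1
CLASS_LABELS = {"benign": BENIGN, "malignant": MALIGNANT}


@dataclass
class UltrasoundSample:
    """One lesion: grayscale image, binary mask, and class label."""

    id: str
    image: np.ndarray  # 2-D uint8
    mask: np.ndarray  # 2-D bool, same shape
    label: int  # 0 = benign, 1 = malignant

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.uint8)
        self.mask = np.asarray(self.mask) > 0
        if self.image.ndim != 2:
            raise ValueError(f"{self.id}: image must be 2-D grayscale")
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"{self.id}: image shape {self.image.shape} != mask shape {self.mask.shape}"
            )
        if self.label not in (BENIGN, MALIGNANT):
            raise ValueError(f"{self.id}: label must be 0 (benign) or 1 (malignant)")
        if not self.mask.any():
            raise ValueError(f"{self.id}: mask has no foreground pixels")


def _read_gray(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("L"), dtype=np.uint8)
    except OSError as exc:  # unreadable / truncated file
        raise OSError(f"cannot read image file {path}") from exc


def load_dataset(root_dir, class_subdirs=("benign", "malignant")) -> list[UltrasoundSample]:
    """Load image/mask pairs from ``root_dir`` for the given class folders.

    Images whose file name contains ``_mask`` are treated as masks of the
    image sharing their stem prefix.  Images without any mask are skipped
    with a logged warning.  Folders for other classes (e.g. ``normal``)
    are ignored.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset directory not found: {root}")
    samples: list[UltrasoundSample] = []
    n_skipped = 0
    for cls in class_subdirs:
        if cls not in CLASS_LABELS:
            raise ValueError(f"unknown class folder {cls!r}; expected benign/malignant")
        cls_dir = root / cls
        if not cls_dir.is_dir():
            logger.warning("class folder missing: %s", cls_dir)
            continue
        files = sorted(p for p in cls_dir.iterdir() if p.suffix.lower() == ".png")
        images = [p for p in files if "_mask" not in p.stem]
        for img_path in images:
            mask_paths = [p for p in files if p.stem.startswith(img_path.stem + "_mask")]
            if not mask_paths:
                logger.warning("no mask for image %s; sample skipped", img_path)
                n_skipped += 1
                continue
            image = _read_gray(img_path)
            mask = np.zeros(image.shape, dtype=bool)
            for mp in mask_paths:
                m = _read_gray(mp)
                if m.shape != image.shape:
                    raise ValueError(f"mask {mp} shape differs from image {img_path}")
                mask |= m > 0
            samples.append(
                UltrasoundSample(
                    id=f"{cls}/{img_path.stem}",
                    image=image,
                    mask=mask,
                    label=CLASS_LABELS[cls],
                )
            )
    if n_skipped:
        logger.warning("%d image(s) skipped for missing masks", n_skipped)
    if not samples:
        logger.warning("no samples loaded from %s", root)
    return samples


def apply_mask(sample: UltrasoundSample) -> np.ndarray:
    """Bitwise-AND the mask onto the image: lesion pixels kept, rest zero."""
    if sample.image.shape != sample.mask.shape:
        raise ValueError("image and mask shapes differ")
    return np.where(sample.mask, sample.image, 0).astype(np.uint8)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table as CSV with the canonical header.

    Floats are written with 12 significant digits so that
    ``read_feature_table(write_feature_table(t))`` round-trips within 1e-9.
    """
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    out = table[TABLE_COLUMNS]
    out.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature-table CSV, validating the exact canonical header."""
    df = pd.read_csv(path)
    if list(df.columns) != TABLE_COLUMNS:
        raise ValueError(
            f"unexpected feature-table header {list(df.columns)}; expected {TABLE_COLUMNS}"
        )
    return df


def export_graph(graph, path, format: str = "edge_csv") -> None:
    """Serialize a :class:`~lesiongraph.graph.CorrelationGraph`.

    ``edge_csv`` writes (source, target, weight) rows with 1-based node ids,
    matching the tabular layout used to feed the GNN.  ``graphml`` writes
    standard GraphML with the Pearson weight as an edge attribute.
    """
    if format == "edge_csv":
        rows = [
            {"source": s + 1, "target": t + 1, "weight": w}
            for s, t, w in sorted(graph.edges)
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
            path, index=False, float_format="%.12g", lineterminator="\n"
        )
    elif format == "graphml":
        g = nx.Graph()
        for i, name in enumerate(graph.nodes):
            g.add_node(i + 1, feature=name)
        for s, t, w in sorted(graph.edges):
            g.add_edge(s + 1, t + 1, weight=float(w))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown graph export format {format!r}")
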