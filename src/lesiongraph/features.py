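"""The seven clinical-marker lesion features.

Radiologists grade breast lesions on shape, orientation and margin
(the BI-RADS lexicon): benign masses tend to be smooth, oval and
wider-than-tall with sharp margins, while malignant masses are irregular,
spiculated, taller-than-wide, with diffuse margins.  This module computes
seven computerized surrogates of those markers from a binary lesion mask
and its grayscale image:

==============  =====================================================
solidity        convex-hull area / lesion area (CHR, >= 1; spikier => larger)
sift_count      number of SIFT keypoints in the lesion region
wh_ratio        bounding-box width / height (WHR)
ellipse_ratio   minimum enclosing-ellipse area / lesion area (ER, >= 1)
harris_count    number of Harris corner-response maxima in the region
circularity     Fcirc = 1 - 4*pi*A/P**2 (0 for a circle)
brightness      mean intensity over a 20-px band straddling the margin
==============  =====================================================

Note the hull ratio here is the *reciprocal* of classical solidity
(TA/CH); the CH/TA convention is kept so that spikier boundaries score
higher, in line with the other curviness features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter
from scipy.spatial import ConvexHull, QhullError
from skimage import measure
from skimage.feature import SIFT, corner_harris, corner_peaks

from .dataset_io import FEATURE_NAMES, UltrasoundSample, apply_mask

# Detector parameters are frozen so feature extraction is deterministic.
HARRIS_K = 0.04
HARRIS_SIGMA = 1.0
HARRIS_REL_THRESHOLD = 0.01  # fraction of the max corner response
DETECTOR_MASK_DILATION_PX = 5  # keypoints within this margin of the lesion count
MARGIN_BAND_PX = 10  # band half-width: 10 px inside + 10 px outside the border
MIN_COMPONENT_AREA_PX = 5
CONTOUR_SMOOTH_SIGMA = 1.0  # px; removes the raster staircase before tracing


@dataclass
class ContourGeometry:
    """Areas and perimeter of a lesion contour (pixel units)."""

    area: float  # polygon (tumor) area TA, px^2
    perimeter: float  # boundary length P, px
    hull_area: float  # convex-hull area CH, px^2


@dataclass
class EllipseFit:
    """Minimum-area enclosing ellipse of a contour."""

    center: tuple  # (row, col)
    semi_axes: tuple  # (a, b), a >= b, px
    angle: float  # orientation of the major axis, radians

    @property
    def area(self) -> float:
        """Ellipse area ECA = pi * a * b."""
        a, b = self.semi_axes
        return math.pi * a * b


@dataclass
class FeatureVector:
    """The seven per-lesion features, in canonical column order."""

    solidity: float
    sift_count: int
    wh_ratio: float
    ellipse_ratio: float
    harris_count: int
    circularity: float
    brightness: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


# ---------------------------------------------------------------------------
# contour geometry
# ---------------------------------------------------------------------------

def extract_contour(mask: np.ndarray) -> np.ndarray:
    """Boundary polygon of the largest 8-connected foreground component.

    The boundary is traced as the 0.5 iso-contour of the component after a
    sigma = 1 px Gaussian smoothing.  The smoothing removes the half-pixel
    staircase of the raster boundary, so perimeters (and hence
    circularity) are accurate rather than systematically inflated; shape
    detail above the one-pixel scale is preserved.  Returns an (n, 2)
    array of (row, col) vertices of a closed simple curve.
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("empty mask: no foreground pixels")
    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    biggest = int(counts.argmax())
    if counts[biggest] < MIN_COMPONENT_AREA_PX:
        raise ValueError(
            f"degenerate lesion: largest component has {counts[biggest]} px"
        )
    component = labels == biggest
    padded = np.pad(component, 2).astype(float)
    smoothed = gaussian_filter(padded, CONTOUR_SMOOTH_SIGMA)
    contours = measure.find_contours(smoothed, 0.5)
    if not contours:
        raise ValueError("degenerate lesion: too small to trace a boundary")
    contour = max(contours, key=len) - 2.0  # undo padding offset
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    if len(contour) < 3:
        raise ValueError("degenerate contour with fewer than 3 vertices")
    return contour


def polygon_area(contour: np.ndarray) -> float:
    """Shoelace area of the closed polygon, px^2."""
    contour = np.asarray(contour, dtype=float)
    if len(contour) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    r, c = contour[:, 0], contour[:, 1]
    return float(abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1))) / 2.0)


def polygon_perimeter(contour: np.ndarray) -> float:
    """Euclidean arc length of the closed polygon, px."""
    contour = np.asarray(contour, dtype=float)
    if len(contour) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    diffs = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    return float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())


def contour_geometry(contour: np.ndarray) -> ContourGeometry:
    area = polygon_area(contour)
    if area <= 0:
        raise ValueError("contour encloses zero area")
    hull = ConvexHull(np.asarray(contour, dtype=float))
    return ContourGeometry(
        area=area, perimeter=polygon_perimeter(contour), hull_area=float(hull.volume)
    )


def convex_hull_ratio(contour: np.ndarray) -> float:
    """CHR = convex-hull area / lesion area; >= 1, = 1 for convex shapes."""
    geom = contour_geometry(contour)
    return geom.hull_area / geom.area


def circularity(geometry: ContourGeometry) -> float:
    """Fcirc = 1 - 4*pi*A/P**2; 0 for a circle, grows with irregularity."""
    if geometry.perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return 1.0 - 4.0 * math.pi * geometry.area / geometry.perimeter**2


def enclosing_ellipse(contour: np.ndarray, tol: float = 1e-3) -> EllipseFit:
    """Minimum-area enclosing ellipse (Khachiyan iteration).

    Only the convex-hull vertices matter for the enclosing ellipse, so the
    iteration runs on the hull, which keeps it fast for pixel-dense
    contours.  Axes are inflated by sqrt(1 + tol) so every vertex is
    enclosed despite the finite iteration tolerance.
    """
    points = np.asarray(contour, dtype=float)
    if len(points) < 5:
        raise ValueError("enclosing ellipse needs at least 5 vertices")
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise ValueError("degenerate (collinear) contour") from exc
    P = points[hull.vertices]  # (m, 2)
    m, d = P.shape
    Q = np.column_stack([P, np.ones(m)]).T  # (3, m)
    u = np.full(m, 1.0 / m)
    err = tol + 1.0
    while err > tol:
        X = Q @ np.diag(u) @ Q.T
        M = np.einsum("ij,ji->i", Q.T @ np.linalg.inv(X), Q)
        j = int(np.argmax(M))
        step = (M[j] - d - 1.0) / ((d + 1.0) * (M[j] - 1.0))
        new_u = (1.0 - step) * u
        new_u[j] += step
        err = float(np.linalg.norm(new_u - u))
        u = new_u
    center = P.T @ u
    sigma = P.T @ np.diag(u) @ P - np.outer(center, center)
    eigvals, eigvecs = np.linalg.eigh(sigma)
    if eigvals[0] <= 0:
        raise ValueError("degenerate (collinear) contour")
    # ellipse matrix is inv(d * sigma); semi-axis = sqrt(d * eigval)
    axes = np.sqrt(d * eigvals * (1.0 + tol))
    a, b = float(axes[1]), float(axes[0])
    major = eigvecs[:, 1]
    angle = math.atan2(major[1], major[0])
    return EllipseFit(center=(float(center[0]), float(center[1])), semi_axes=(a, b), angle=angle)


def ellipse_ratio(fit: EllipseFit, geometry: ContourGeometry) -> float:
    """ER = enclosing-ellipse area / lesion area; ~1 for elliptical lesions."""
    if geometry.area <= 0:
        raise ValueError("tumor area must be positive")
    return fit.area / geometry.area


def width_height_ratio(contour: np.ndarray) -> float:
    """Axis-aligned bounding-box width (columns) over height (rows)."""
    contour = np.asarray(contour, dtype=float)
    if len(contour) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    height = contour[:, 0].max() - contour[:, 0].min()
    width = contour[:, 1].max() - contour[:, 1].min()
    if height <= 0:
        raise ValueError("degenerate contour: zero height")
    return width / height


# ---------------------------------------------------------------------------
# keypoint / corner counts
# ---------------------------------------------------------------------------

def _dilated_mask(mask: np.ndarray, radius: int) -> np.ndarray:
    """Disk dilation via the Euclidean distance transform (exact, fast)."""
    mask = np.asarray(mask) > 0
    return distance_transform_edt(~mask) <= radius


def sift_keypoint_count(masked_image: np.ndarray, mask: np.ndarray) -> int:
    """Number of SIFT keypoints inside the lesion region.

    Standard SIFT detector with library-default parameters; keypoints are
    counted when they fall within the mask dilated by 5 px so boundary
    keypoints are included.  Deterministic for fixed input.
    """
    img = np.asarray(masked_image, dtype=float)
    detector = SIFT()
    try:
        detector.detect(img)
    except RuntimeError:  # no extrema found (e.g. uniform image)
        return 0
    kp = detector.keypoints
    if kp is None or len(kp) == 0:
        return 0
    region = _dilated_mask(mask, DETECTOR_MASK_DILATION_PX)
    rows = np.clip(kp[:, 0], 0, region.shape[0] - 1).astype(int)
    cols = np.clip(kp[:, 1], 0, region.shape[1] - 1).astype(int)
    return int(region[rows, cols].sum())


def harris_corner_count(masked_image: np.ndarray, mask: np.ndarray) -> int:
    """Count of Harris corner-response local maxima in the lesion region.

    Response computed with k = 0.04 and Gaussian window sigma = 1; local
    maxima above 0.01 x max response are kept, restricted to the mask
    dilated by 5 px.
    """
    img = np.asarray(masked_image, dtype=float)
    response = corner_harris(img, method="k", k=HARRIS_K, sigma=HARRIS_SIGMA)
    if response.max() <= 0:
        return 0
    peaks = corner_peaks(
        response, min_distance=1, threshold_rel=HARRIS_REL_THRESHOLD
    )
    if len(peaks) == 0:
        return 0
    region = _dilated_mask(mask, DETECTOR_MASK_DILATION_PX)
    return int(region[peaks[:, 0], peaks[:, 1]].sum())


def margin_brightness(
    image: np.ndarray, mask: np.ndarray, band_px: int = MARGIN_BAND_PX
) -> float:
    """Mean intensity of the original image over the lesion-margin band.

    The band is the set of pixels within ``band_px`` of the lesion border
    on either side (dilation minus erosion by a disk of radius
    ``band_px``), i.e. a 20-px-wide strip straddling the margin by default.
    """
    mask = np.asarray(mask) > 0
    if not mask.any() or mask.all():
        raise ValueError("margin band is empty: mask has no border")
    inner = distance_transform_edt(mask)  # distance to background
    outer = distance_transform_edt(~mask)  # distance to foreground
    band = (mask & (inner <= band_px)) | (~mask & (outer <= band_px))
    if not band.any():
        raise ValueError("margin band is empty")
    return float(np.asarray(image, dtype=float)[band].mean())


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def extract_features(sample: UltrasoundSample) -> FeatureVector:
    """Compute all seven features for one lesion sample."""
    masked = apply_mask(sample)
    steps = {}
    try:
        steps["contour"] = contour = extract_contour(sample.mask)
        geom = contour_geometry(contour)
        solidity = geom.hull_area / geom.area
        fit = enclosing_ellipse(contour)
        return FeatureVector(
            solidity=solidity,
            sift_count=sift_keypoint_count(masked, sample.mask),
            wh_ratio=width_height_ratio(contour),
            ellipse_ratio=ellipse_ratio(fit, geom),
            harris_count=harris_corner_count(masked, sample.mask),
            circularity=circularity(geom),
            brightness=margin_brightness(sample.image, sample.mask),
        )
    except ValueError as exc:
        raise ValueError(f"feature extraction failed for {sample.id}: {exc}") from exc


def extract_feature_table(samples) -> "pd.DataFrame":
    """Feature table (id, 7 features, label) for a batch of samples."""
    import pandas as pd

    rows = []
    for s in samples:
        fv = extract_features(s)
        row = {"id": s.id}
        row.update({n: v for n, v in zip(FEATURE_NAMES, fv.as_array())})
        row["sift_count"] = fv.sift_count
        row["harris_count"] = fv.harris_count
        row["label"] = s.label
        rows.append(row)
    return pd.DataFrame(rows, columns=["id"] + FEATURE_NAMES + ["label"])
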