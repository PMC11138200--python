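"""Synthetic ultrasound-like lesions with controllable clinical-marker statistics.

Real benign breast lesions are smooth, oval and wider-than-tall with
sharp margins; malignant ones are irregular, spiculated, taller-than-wide
with diffuse margins.  The generator emulates exactly these three axes so
the whole feature -> graph -> classifier pipeline can be exercised and
validated offline:

* boundary curviness — a radial cosine perturbation ("star") of an
  ellipse, ``r(theta) = r_ellipse(theta) * (1 + amp * cos(n * theta + phase))``;
* elongation — the width/height bias of the base ellipse;
* margin sharpness — Gaussian blur of the rendered two-level image.

Lesions are rendered as hypoechoic (dark) regions on a brighter
background with multiplicative speckle; no claim of physical ultrasound
realism is made.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon

from .dataset_io import BENIGN, MALIGNANT, UltrasoundSample

DEFAULT_IMAGE_SIZE = 256

#: class-conditional parameter ranges (the study conditions of this package)
BENIGN_RANGES = dict(
    base_radius=(30.0, 55.0),
    wh_bias=(1.25, 1.8),
    n_spikes=(0, 3),
    spike_amplitude=(0.0, 0.04),
    margin_blur=(0.3, 1.0),
)
MALIGNANT_RANGES = dict(
    base_radius=(30.0, 55.0),
    wh_bias=(0.45, 0.85),
    n_spikes=(8, 16),
    spike_amplitude=(0.15, 0.4),
    margin_blur=(3.0, 8.0),
)
INTERIOR_MEAN_RANGE = (50.0, 80.0)
EXTERIOR_MEAN_RANGE = (120.0, 160.0)
SPECKLE_LEVEL = 0.12


@dataclass
class SyntheticParams:
    """Parameters of a single synthetic lesion."""

    label: int  # 0 benign, 1 malignant
    image_size: int = DEFAULT_IMAGE_SIZE
    base_radius: float = 45.0  # geometric-mean semi-axis, px
    wh_bias: float = 1.5  # width/height ratio of the base ellipse
    n_spikes: int = 0  # angular frequency of the boundary perturbation
    spike_amplitude: float = 0.0  # fractional radial amplitude, in [0, 1)
    phase: float = 0.0  # spike phase, radians
    margin_blur: float = 0.5  # Gaussian sigma at the margin, px
    speckle: float = SPECKLE_LEVEL  # multiplicative noise level
    interior_mean: float = 65.0  # lesion intensity (hypoechoic)
    exterior_mean: float = 140.0  # background intensity
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.spike_amplitude < 1.0:
            raise ValueError("spike_amplitude must be in [0, 1)")
        if self.base_radius <= 0 or self.wh_bias <= 0:
            raise ValueError("base_radius and wh_bias must be positive")


def _boundary(params: SyntheticParams, n_theta: int = 720):
    """Polar boundary r(theta) around the image centre."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    a = params.base_radius * np.sqrt(params.wh_bias)  # column (width) semi-axis
    b = params.base_radius / np.sqrt(params.wh_bias)  # row (height) semi-axis
    r_ellipse = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    r = r_ellipse * (
        1.0 + params.spike_amplitude * np.cos(params.n_spikes * theta + params.phase)
    )
    return theta, r


def generate_lesion_mask(params: SyntheticParams) -> np.ndarray:
    """Rasterize the star-perturbed ellipse as a boolean mask."""
    theta, r = _boundary(params)
    centre = params.image_size / 2.0
    if r.max() >= centre - 2:
        raise ValueError(
            f"lesion radius {r.max():.1f} px does not fit in a "
            f"{params.image_size} px frame"
        )
    rows = centre + r * np.sin(theta)
    cols = centre + r * np.cos(theta)
    mask = np.zeros((params.image_size, params.image_size), dtype=bool)
    rr, cc = polygon(rows, cols, mask.shape)
    mask[rr, cc] = True
    return mask


def render_ultrasound_image(mask: np.ndarray, params: SyntheticParams) -> np.ndarray:
    """Two-level image + multiplicative speckle + margin blur, as uint8."""
    rng = np.random.default_rng(params.seed)
    img = np.where(mask, params.interior_mean, params.exterior_mean).astype(float)
    if params.speckle > 0:
        img *= 1.0 + params.speckle * rng.uniform(-1.0, 1.0, size=img.shape)
    if params.margin_blur > 0:
        img = gaussian_filter(img, params.margin_blur)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def sample_params(label: int, rng: np.random.Generator, image_size: int = DEFAULT_IMAGE_SIZE) -> SyntheticParams:
    """Draw class-conditional lesion parameters."""
    ranges = BENIGN_RANGES if label == BENIGN else MALIGNANT_RANGES
    return SyntheticParams(
        label=label,
        image_size=image_size,
        base_radius=rng.uniform(*ranges["base_radius"]),
        wh_bias=rng.uniform(*ranges["wh_bias"]),
        n_spikes=int(rng.integers(ranges["n_spikes"][0], ranges["n_spikes"][1] + 1)),
        spike_amplitude=rng.uniform(*ranges["spike_amplitude"]),
        phase=rng.uniform(0.0, 2.0 * np.pi),
        margin_blur=rng.uniform(*ranges["margin_blur"]),
        speckle=SPECKLE_LEVEL,
        interior_mean=rng.uniform(*INTERIOR_MEAN_RANGE),
        exterior_mean=rng.uniform(*EXTERIOR_MEAN_RANGE),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_samples(
    n_benign: int, n_malignant: int, seed: int = 0, image_size: int = DEFAULT_IMAGE_SIZE
) -> list[UltrasoundSample]:
    """Generate labelled synthetic lesion samples (images + masks)."""
    if n_benign < 1 or n_malignant < 1:
        raise ValueError("need at least one sample per class")
    rng = np.random.default_rng(seed)
    samples = []
    for label, n, prefix in (
        (BENIGN, n_benign, "benign"),
        (MALIGNANT, n_malignant, "malignant"),
    ):
        for i in range(n):
            params = sample_params(label, rng, image_size)
            mask = generate_lesion_mask(params)
            image = render_ultrasound_image(mask, params)
            samples.append(
                UltrasoundSample(
                    id=f"{prefix}/synthetic_{i:04d}", image=image, mask=mask, label=label
                )
            )
    return samples


def generate_dataset(
    n_benign: int, n_malignant: int, seed: int = 0, image_size: int = DEFAULT_IMAGE_SIZE
):
    """Synthetic samples plus their extracted feature table.

    Returns ``(samples, feature_table)`` where the table has the canonical
    (id, 7 features, label) columns.
    """
    from .features import extract_feature_table

    samples = generate_samples(n_benign, n_malignant, seed=seed, image_size=image_size)
    return samples, extract_feature_table(samples)


def write_busi_layout(samples, out_dir) -> None:
    """Write samples to a BUSI-style directory tree of PNGs."""
    from pathlib import Path

    from PIL import Image

    out = Path(out_dir)
    for s in samples:
        cls, name = s.id.split("/", 1)
        d = out / cls
        d.mkdir(parents=True, exist_ok=True)
        Image.fromarray(s.image).save(d / f"{name}.png")
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(d / f"{name}_mask.png")
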