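"""Thyroid-region extraction.

An ultrasound frame has a near-black background, a handful of near-white
annotation artifacts (calipers, text), and one large speckled tissue region.
The tissue is recovered by Otsu binarization, morphological closing,
8-connected labeling, largest-object selection and cropping; the crop (with
off-mask pixels zeroed) feeds the downstream classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .dataio import GrayImage

__all__ = ["RoiParams", "RoiResult", "otsu_threshold", "extract_roi",
           "DegenerateImageError", "NoTissueFoundError"]


class DegenerateImageError(ValueError):
    """Raised for constant images, which have no Otsu threshold."""


class NoTissueFoundError(ValueError):
    """Raised when the largest foreground object is implausibly small."""


@dataclass
class RoiParams:
    closing_radius: int = 5      # px, structuring-element radius for closing
    fill_holes: bool = True
    min_area_fraction: float = 0.05  # reject if largest object < this × frame

    def __post_init__(self) -> None:
        if self.closing_radius < 0:
            raise ValueError("closing_radius must be >= 0")
        if not 0 <= self.min_area_fraction < 1:
            raise ValueError("min_area_fraction must be in [0, 1)")


@dataclass
class RoiResult:
    threshold: int
    mask: np.ndarray              # bool, frame-sized, True = tissue
    bbox: tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max), half-open
    cropped: GrayImage            # bbox crop with off-mask pixels zeroed


def otsu_threshold(image: GrayImage) -> int:
    """Integer Otsu level in [0, 255] maximizing between-class variance.

    The 256-bin histogram is scanned over every candidate level t, with
    classes {pixels < t} and {pixels >= t}; ties break toward the smallest
    level. Constant images raise :class:`DegenerateImageError`.
    """
    px = image.pixels
    if px.max() == px.min():
        raise DegenerateImageError("constant image has no Otsu threshold")
    hist = np.bincount(
        np.clip(px, 0, 255).astype(np.int64).ravel(), minlength=256
    ).astype(np.float64)
    n = hist.sum()
    bins = np.arange(256, dtype=np.float64)
    # cumulative mass/mean of the below-threshold class for every level t:
    # class0 = bins < t, so prefix sums shifted by one.
    w0 = np.concatenate(([0.0], np.cumsum(hist)))[:-1] / n          # weight of class0 at t=0..255
    mu0_sum = np.concatenate(([0.0], np.cumsum(hist * bins)))[:-1] / n
    mu_t = (hist * bins).sum() / n
    w1 = 1.0 - w0
    with np.errstate(invalid="ignore", divide="ignore"):
        m0 = np.where(w0 > 0, mu0_sum / w0, 0.0)
        m1 = np.where(w1 > 0, (mu_t - mu0_sum) / w1, 0.0)
    between = w0 * w1 * (m0 - m1) ** 2
    return int(np.argmax(between))  # argmax takes the first (smallest) maximizer


def extract_roi(image: GrayImage, params: RoiParams | None = None) -> RoiResult:
    """Binarize, close, label (8-connectivity), keep the largest object, crop.

    Foreground is intensity >= the Otsu level (the background sits near zero).
    Ties in component area break toward the component whose centroid is
    nearest the frame center, since the thyroid occupies the central fan.
    """
    params = params or RoiParams()
    level = otsu_threshold(image)
    fg = image.pixels >= level
    if params.closing_radius > 0:
        fg = morphology.closing(
            fg, footprint=morphology.disk(params.closing_radius)
        ).astype(bool)
    labels, n_objects = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n_objects == 0:
        raise NoTissueFoundError("no foreground object after binarization")
    areas = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_objects + 1))
    best_area = areas.max()
    candidates = np.flatnonzero(areas == best_area) + 1
    if len(candidates) > 1:
        center = np.array(image.pixels.shape, dtype=np.float64) / 2.0
        centroids = ndimage.center_of_mass(fg, labels, candidates)
        dists = [np.hypot(*(np.asarray(c) - center)) for c in centroids]
        chosen = candidates[int(np.argmin(dists))]
    else:
        chosen = candidates[0]
    mask = labels == chosen
    if params.fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    if mask.sum() < params.min_area_fraction * image.pixels.size:
        raise NoTissueFoundError(
            f"largest object covers {mask.sum() / image.pixels.size:.3f} "
            f"of the frame, below min_area_fraction={params.min_area_fraction}"
        )
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    bbox = (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)
    r0, c0, r1, c1 = bbox
    cropped = np.where(mask, image.pixels, 0.0)[r0:r1, c0:c1]
    return RoiResult(
        threshold=level,
        mask=mask,
        bbox=bbox,
        cropped=GrayImage(cropped, source_path=image.source_path),
    )
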