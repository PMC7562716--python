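"""Tissue/background separation on slide thumbnails.

Whole slides are mostly empty white glass; analysis is restricted to the
tissue foreground.  The mask is computed on a low-resolution thumbnail by
Otsu thresholding of the luminosity channel (tissue is darker than the
background), followed by a morphological close to fill small holes and
removal of connected regions whose area is too small a fraction of the
tissue.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.measure import label as cc_label
from skimage.morphology import closing, disk


class DegenerateHistogramError(ValueError):
    """Histogram occupies fewer than two distinct gray levels."""


class NoTissueError(ValueError):
    """No tissue foreground could be separated from the background."""


@dataclasses.dataclass
class TissueMask:
    """Binary tissue mask at a stated downsample of level 0."""

    mask: np.ndarray  # 2-D bool
    downsample: int
    threshold: int  # Otsu luminosity cut actually used
    close_radius: int
    min_area_fraction: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def tissue_area(self) -> int:
        return int(self.mask.sum())


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu's threshold from a 256-bin gray-level histogram.

    Returns the cut ``t`` (pixels with value <= t form the dark class)
    maximizing the between-class variance, which is equivalent to
    minimizing the intra-class variance.  Ties are broken by the smallest
    ``t``.  Raises :class:`DegenerateHistogramError` if fewer than two gray
    levels are occupied.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError(
            "histogram occupies fewer than two gray levels"
        )
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)  # pixels with value <= t
    m0 = np.cumsum(hist * levels)  # first moment of the dark class
    mu_total = m0[-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.zeros(256)
    mu0 = np.where(w0 > 0, m0 / np.maximum(w0, 1e-300), 0.0)
    mu1 = np.where(w1 > 0, (mu_total - m0) / np.maximum(w1, 1e-300), 0.0)
    sigma_b[valid] = (w0 * w1)[valid] * (mu0 - mu1)[valid] ** 2
    # argmax returns the first (smallest) maximizing index
    return int(np.argmax(sigma_b))


def luminosity(image: np.ndarray) -> np.ndarray:
    """Unweighted channel mean, the gray level used for thresholding."""
    return np.asarray(image, dtype=np.float64).mean(axis=2)


def compute_tissue_mask(
    thumbnail: np.ndarray,
    close_radius: int = 4,
    min_area_fraction: float = 0.005,
    downsample: int = 1,
) -> TissueMask:
    """Tissue mask of an RGB thumbnail.

    Pipeline: luminosity -> Otsu threshold -> keep the dark (below
    threshold) side -> binary close with a disk of ``close_radius`` ->
    drop connected regions smaller than ``min_area_fraction`` of the total
    tissue area.  ``downsample`` only records the thumbnail's scale
    relative to level 0.
    """
    thumb = np.asarray(thumbnail)
    if thumb.size == 0:
        raise ValueError("thumbnail is empty")
    lum = np.clip(np.rint(luminosity(thumb)), 0, 255).astype(np.int64)
    hist = np.bincount(lum.ravel(), minlength=256)[:256]
    try:
        t = otsu_threshold(hist)
    except DegenerateHistogramError as exc:
        raise NoTissueError("no tissue found") from exc
    tissue = lum <= t
    if not tissue.any() or tissue.all():
        raise NoTissueError("no tissue found")
    if close_radius > 0:
        # pad with background so the close cannot glue tissue to the
        # raster border
        r = close_radius
        padded = np.pad(tissue, r, constant_values=False)
        tissue = closing(padded, disk(r))[r:-r, r:-r]
    total = tissue.sum()
    if total == 0:
        raise NoTissueError("no tissue found")
    labels = cc_label(tissue, connectivity=2)
    keep = np.zeros_like(tissue)
    min_area = min_area_fraction * total
    for region in range(1, labels.max() + 1):
        component = labels == region
        if component.sum() >= min_area:
            keep |= component
    if not keep.any():
        raise NoTissueError("no tissue found")
    return TissueMask(
        mask=keep,
        downsample=downsample,
        threshold=t,
        close_radius=close_radius,
        min_area_fraction=min_area_fraction,
    )


def tissue_mask_for_slide(slide, downsample: int = 32, **kwargs) -> TissueMask:
    """Convenience wrapper: thumbnail a slide and mask it."""
    thumb = slide.thumbnail(downsample)
    return compute_tissue_mask(thumb, downsample=downsample, **kwargs)
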