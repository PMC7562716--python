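"""Multiscale patch extraction, labeling and augmentation.

Patches are cut on a regular grid at several level-0 side lengths
(mimicking a pathologist switching objective magnifications), kept only if
they cover enough tissue, and resized to the classifier input side (299 px)
by area interpolation.  Training augmentation is a bounded random affine
(rotation, shift, flip, shear) with reflection padding; brightness and
contrast are never altered so that stain-normalized colors survive.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterator, Sequence

import numpy as np
from PIL import Image
from skimage.transform import AffineTransform, warp

from .slide_io import SlideImage
from .tissue_mask import TissueMask

#: The multiscale side lengths used for training patches (level-0 pixels).
TRAINING_SCALES = (768, 1024, 1495, 2048)

#: Side of the raster handed to the patch classifier.
OUTPUT_SIDE = 299


@dataclasses.dataclass
class Patch:
    """A square patch cut from a slide.

    ``x, y`` are the level-0 coordinates of the top-left corner and
    ``scale`` the level-0 side length of the footprint; ``raster`` is the
    resized RGB image actually fed to a classifier.
    """

    raster: np.ndarray
    x: int
    y: int
    scale: int
    label: str | None = None
    slide_id: str = ""

    def __post_init__(self) -> None:
        r = np.asarray(self.raster)
        if r.ndim != 3 or r.shape[2] != 3:
            raise ValueError("raster must be (side, side, 3)")
        if r.shape[0] != r.shape[1]:
            raise ValueError("patch raster must be square")
        self.raster = r

    @property
    def side(self) -> int:
        return self.raster.shape[0]


def resize_area(raster: np.ndarray, out_side: int) -> np.ndarray:
    """Resize a square RGB raster by area (box) interpolation."""
    if raster.shape[0] == out_side and raster.shape[1] == out_side:
        return raster.copy()
    img = Image.fromarray(np.ascontiguousarray(raster, dtype=np.uint8))
    return np.asarray(img.resize((out_side, out_side), Image.Resampling.BOX))


def extract_patches(
    slide: SlideImage,
    mask: TissueMask,
    scales: Sequence[int] = TRAINING_SCALES,
    stride_fraction: float = 1.0,
    out_side: int = OUTPUT_SIDE,
    min_tissue_fraction: float = 0.5,
) -> Iterator[Patch]:
    """Yield tissue patches on a grid, one pass per scale.

    For each scale the grid stride is ``stride_fraction * scale``; a patch
    is emitted iff the tissue fraction of its footprint (measured on the
    mask) is at least ``min_tissue_fraction``.  The emitted raster is
    resized to ``out_side``.  The stream is deterministic given the
    inputs.
    """
    if stride_fraction <= 0:
        raise ValueError("stride_fraction must be positive")
    w, h = slide.dimensions
    ds = mask.downsample
    for scale in scales:
        stride = max(1, int(round(stride_fraction * scale)))
        for y in range(0, h - scale + 1, stride):
            for x in range(0, w - scale + 1, stride):
                if _tissue_fraction(mask.mask, x, y, scale, ds) < min_tissue_fraction:
                    continue
                region = slide.read_region((x, y), (scale, scale), level=0)
                yield Patch(
                    raster=resize_area(region, out_side),
                    x=x,
                    y=y,
                    scale=scale,
                    slide_id=slide.slide_id,
                )


def _tissue_fraction(mask: np.ndarray, x: int, y: int, scale: int, ds: float) -> float:
    x0 = int(math.floor(x / ds))
    y0 = int(math.floor(y / ds))
    x1 = max(x0 + 1, int(math.ceil((x + scale) / ds)))
    y1 = max(y0 + 1, int(math.ceil((y + scale) / ds)))
    sub = mask[y0 : min(y1, mask.shape[0]), x0 : min(x1, mask.shape[1])]
    if sub.size == 0:
        return 0.0
    return float(sub.mean())


def label_patch(
    footprint: tuple[int, int, int],
    label_mask: np.ndarray,
    purity_threshold: float = 0.9,
    downsample: float = 1,
) -> str | None:
    """Label a patch footprint from a class-coded mask, or leave unlabeled.

    ``footprint`` is ``(x, y, scale)`` in level-0 pixels; ``label_mask``
    is a class-coded raster at ``downsample``.  The label is the class
    occupying at least ``purity_threshold`` of the footprint's *tissue*
    (non-background) pixels; mixed or empty footprints return ``None``.
    """
    from .slide_io import BACKGROUND_CODE, CODE_LABELS

    x, y, scale = footprint
    x0 = int(math.floor(x / downsample))
    y0 = int(math.floor(y / downsample))
    x1 = max(x0 + 1, int(math.ceil((x + scale) / downsample)))
    y1 = max(y0 + 1, int(math.ceil((y + scale) / downsample)))
    sub = label_mask[y0 : min(y1, label_mask.shape[0]), x0 : min(x1, label_mask.shape[1])]
    tissue = sub[sub != BACKGROUND_CODE]
    if tissue.size == 0:
        return None
    codes, counts = np.unique(tissue, return_counts=True)
    best = int(np.argmax(counts))
    if counts[best] / tissue.size >= purity_threshold:
        return CODE_LABELS[int(codes[best])]
    return None


@dataclasses.dataclass
class AugmentParams:
    """Bounds of the random affine augmentation.

    Defaults mirror the training recipe: rotations up to 30 degrees,
    shifts up to 20% of the side, horizontal/vertical flips, shear up to
    0.2, and no photometric change whatsoever.
    """

    max_rotation_deg: float = 30.0
    max_shift_fraction: float = 0.2
    max_shear: float = 0.2
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5


def augment(
    patch: Patch,
    params: AugmentParams | None = None,
    seed: int | np.random.Generator = 0,
) -> Patch:
    """Apply one random affine draw within ``params`` to a patch.

    Reflection padding fills the exposed borders; brightness and contrast
    are untouched.  Deterministic under ``seed``.  With all bounds at zero
    and flip probabilities at zero the transform is the exact identity.
    """
    params = params or AugmentParams()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    img = patch.raster
    side = img.shape[0]
    angle = rng.uniform(-params.max_rotation_deg, params.max_rotation_deg)
    tx = rng.uniform(-params.max_shift_fraction, params.max_shift_fraction) * side
    ty = rng.uniform(-params.max_shift_fraction, params.max_shift_fraction) * side
    shear = rng.uniform(-params.max_shear, params.max_shear)
    hflip = rng.random() < params.hflip_prob
    vflip = rng.random() < params.vflip_prob

    c = (side - 1) / 2.0
    center = np.array([[1, 0, c], [0, 1, c], [0, 0, 1]], dtype=float)
    back = np.array([[1, 0, -c], [0, 1, -c], [0, 0, 1]], dtype=float)
    th = np.deg2rad(angle)
    rot = np.array(
        [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
    )
    shr = np.array([[1, shear, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    flip = np.diag(
        [-1.0 if hflip else 1.0, -1.0 if vflip else 1.0, 1.0]
    )
    shift = np.array([[1, 0, tx], [0, 1, ty], [0, 0, 1]], dtype=float)
    matrix = shift @ center @ rot @ shr @ flip @ back
    if np.allclose(matrix, np.eye(3)):
        out = img.copy()
    else:
        tform = AffineTransform(matrix=matrix)
        warped = warp(
            img.astype(np.float64),
            tform.inverse,
            order=1,
            mode="reflect",
            preserve_range=True,
        )
        out = np.clip(np.rint(warped), 0, 255).astype(np.uint8)
    return Patch(
        raster=out,
        x=patch.x,
        y=patch.y,
        scale=patch.scale,
        label=patch.label,
        slide_id=patch.slide_id,
    )
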