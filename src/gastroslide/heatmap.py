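"""Malignancy-probability heatmap assembly.

Each slide gets one heatmap ``H``: the tissue canvas is divided into
square cells (default 1024 level-0 pixels, the side of the heatmap
patches, so that non-overlapping patches tile the grid exactly), and the
value of a cell is the *maximum* malignancy probability
``Pr(patch != normal)`` over all patch footprints containing the cell
center.  Cells covered by no patch are no-data, which is distinct from
probability 0.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image


@dataclasses.dataclass
class PatchPrediction:
    """A patch footprint (half-open level-0 rectangle) and its malignancy
    probability."""

    x: int
    y: int
    width: int
    height: int
    probability: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("footprint must have positive size")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")


@dataclasses.dataclass
class Heatmap:
    """Per-cell malignancy probabilities over the tissue canvas.

    ``values`` holds probabilities in [0, 1] with ``NaN`` marking no-data
    cells; ``tissue`` flags which cells belong to tissue (may be None when
    unknown).  ``cell_size`` is the level-0 pixel side of one cell.
    """

    values: np.ndarray
    cell_size: int
    slide_id: str = ""
    tissue: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("heatmap values must be 2-D")
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("heatmap values must lie in [0, 1]")
        self.values = v
        if self.tissue is not None:
            t = np.asarray(self.tissue, dtype=bool)
            if t.shape != v.shape:
                raise ValueError("tissue grid shape must match values")
            self.tissue = t

    @property
    def coverage(self) -> np.ndarray:
        """Boolean grid of cells covered by at least one prediction."""
        return np.isfinite(self.values)

    def tissue_cells(self) -> np.ndarray:
        """Boolean grid of covered tissue cells (all covered cells when no
        tissue grid is attached)."""
        cells = self.coverage
        if self.tissue is not None:
            cells = cells & self.tissue
        return cells


def grid_shape(canvas_size: tuple[int, int], cell_size: int) -> tuple[int, int]:
    w, h = canvas_size
    return (math.ceil(h / cell_size), math.ceil(w / cell_size))


def assemble_heatmap(
    predictions: Sequence[PatchPrediction],
    canvas_size: tuple[int, int],
    cell_size: int = 1024,
    slide_id: str = "",
    tissue: np.ndarray | None = None,
) -> Heatmap:
    """Assemble a heatmap by the per-cell maximum rule.

    A cell's value is the maximum probability over all prediction
    footprints containing its center; the rule makes the result invariant
    to the order of predictions and monotone under adding predictions.
    An empty prediction list yields an all-no-data heatmap with a warning.
    """
    ny, nx = grid_shape(canvas_size, cell_size)
    values = np.full((ny, nx), np.nan)
    if not predictions:
        warnings.warn("no predictions given; heatmap is entirely no-data")
        return Heatmap(values, cell_size, slide_id=slide_id, tissue=tissue)
    w, h = canvas_size
    cx = (np.arange(nx) + 0.5) * cell_size
    cy = (np.arange(ny) + 0.5) * cell_size
    for p in predictions:
        if p.x < 0 or p.y < 0 or p.x + p.width > w or p.y + p.height > h:
            raise ValueError(
                f"footprint ({p.x}, {p.y}, {p.width}, {p.height}) exceeds "
                f"canvas {canvas_size}"
            )
        x0 = int(np.searchsorted(cx, p.x, side="left"))
        x1 = int(np.searchsorted(cx, p.x + p.width, side="left"))
        y0 = int(np.searchsorted(cy, p.y, side="left"))
        y1 = int(np.searchsorted(cy, p.y + p.height, side="left"))
        if x0 >= x1 or y0 >= y1:
            continue
        sub = values[y0:y1, x0:x1]
        values[y0:y1, x0:x1] = np.fmax(sub, p.probability)  # fmax: NaN -> value
    return Heatmap(values, cell_size, slide_id=slide_id, tissue=tissue)


def predict_heatmap(
    slide,
    classifier,
    mask,
    cell_size: int = 1024,
    min_tissue_fraction: float = 0.25,
    out_side: int = 299,
    batch_size: int = 256,
) -> Heatmap:
    """Run a patch classifier over a slide and assemble its heatmap.

    Non-overlapping patches of side ``cell_size`` are cut on the heatmap
    grid (the standard heatmap setting: patches connect by the same side
    length), classified, and assembled.  The tissue grid marks cells whose
    footprint tissue fraction reaches ``min_tissue_fraction``.
    """
    from .patching import extract_patches

    patches = list(
        extract_patches(
            slide,
            mask,
            scales=(cell_size,),
            stride_fraction=1.0,
            out_side=out_side,
            min_tissue_fraction=min_tissue_fraction,
        )
    )
    predictions = []
    for start in range(0, len(patches), batch_size):
        chunk = patches[start : start + batch_size]
        rasters = np.stack([p.raster for p in chunk])
        probs = classifier.predict_proba_batch(rasters)
        malignancy = 1.0 - probs[:, 0]
        for p, m in zip(chunk, malignancy):
            predictions.append(
                PatchPrediction(
                    x=p.x, y=p.y, width=cell_size, height=cell_size,
                    probability=float(np.clip(m, 0.0, 1.0)),
                )
            )
    w, h = slide.dimensions
    ny, nx = grid_shape((w, h), cell_size)
    tissue = np.zeros((ny, nx), dtype=bool)
    from .patching import _tissue_fraction

    for j in range(ny):
        for i in range(nx):
            frac = _tissue_fraction(
                mask.mask, i * cell_size, j * cell_size, cell_size, mask.downsample
            )
            tissue[j, i] = frac >= min_tissue_fraction
    if not predictions:
        return Heatmap(
            np.full((ny, nx), np.nan), cell_size, slide_id=slide.slide_id,
            tissue=tissue,
        )
    return assemble_heatmap(
        predictions, (w, h), cell_size, slide_id=slide.slide_id, tissue=tissue
    )


# -- persistence -----------------------------------------------------------

_NODATA = 65535  # sentinel in the 16-bit PNG; probabilities use 0..65534


def save_heatmap(hm: Heatmap, png_path: str | Path, json_path: str | Path) -> None:
    """Save as a 16-bit PNG (probability x 65534, 65535 = no-data) plus a
    JSON sidecar with grid metadata."""
    enc = np.full(hm.values.shape, _NODATA, dtype=np.uint16)
    cov = hm.coverage
    enc[cov] = np.rint(hm.values[cov] * (_NODATA - 1)).astype(np.uint16)
    Image.fromarray(enc).save(png_path)
    sidecar = {
        "slide_id": hm.slide_id,
        "cell_size": hm.cell_size,
        "shape": list(hm.values.shape),
        "nodata_cells": int((~cov).sum()),
        "tissue": hm.tissue.astype(int).tolist() if hm.tissue is not None else None,
    }
    Path(json_path).write_text(json.dumps(sidecar))


def load_heatmap(png_path: str | Path, json_path: str | Path) -> Heatmap:
    sidecar = json.loads(Path(json_path).read_text())
    enc = np.asarray(Image.open(png_path), dtype=np.uint16)
    values = enc.astype(np.float64) / (_NODATA - 1)
    values[enc == _NODATA] = np.nan
    tissue = sidecar.get("tissue")
    return Heatmap(
        values,
        cell_size=sidecar["cell_size"],
        slide_id=sidecar.get("slide_id", ""),
        tissue=np.asarray(tissue, dtype=bool) if tissue is not None else None,
    )


def render_heatmap(hm: Heatmap, path: str | Path, colormap: str = "inferno") -> None:
    """False-color rendering for visual inspection; no-data cells are
    drawn gray."""
    from matplotlib import colormaps

    cmap = colormaps[colormap]
    vals = np.nan_to_num(hm.values, nan=0.0)
    rgba = (cmap(vals) * 255).astype(np.uint8)
    rgba[~hm.coverage] = (128, 128, 128, 255)
    Image.fromarray(rgba).save(path)
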