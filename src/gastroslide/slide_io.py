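"""Slide raster access and polygon annotations.

Coordinate convention used throughout the package: pixel indices are
0-based, regions are half-open, ``x`` is the column index and ``y`` the row
index.  A pixel ``(x, y)`` occupies the unit square ``[x, x+1) x [y, y+1)``
with its center at ``(x + 0.5, y + 0.5)``.  Rasters are 8-bit RGB arrays of
shape ``(height, width, 3)`` in red/green/blue channel order.

Annotations follow the ASAP XML dialect::

    <ASAP_Annotations>
      <Annotations>
        <Annotation Name="..." Type="Polygon" PartOfGroup="cancer">
          <Coordinates>
            <Coordinate Order="0" X="12.0" Y="34.0"/>
            ...
          </Coordinates>
        </Annotation>
      </Annotations>
      <AnnotationGroups>
        <Group Name="cancer" .../>
      </AnnotationGroups>
    </ASAP_Annotations>

The attributes read are ``PartOfGroup`` on ``Annotation`` and ``Order``,
``X``, ``Y`` on ``Coordinate``; everything else is preserved but ignored.
Polygon vertices are level-0 pixel coordinates and polygons are implicitly
closed (last vertex connects back to the first).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path as FilePath

import numpy as np
import tifffile
from lxml import etree
from matplotlib.path import Path as PolyPath
from PIL import Image

#: Closed vocabulary of lesion classes, in fixed order.
LESION_CLASSES = ("normal", "gastritis", "cancer")

#: Integer codes used in label masks. 0 is background (no annotation).
BACKGROUND_CODE = 0
CLASS_CODES = {label: i + 1 for i, label in enumerate(LESION_CLASSES)}
CODE_LABELS = {code: label for label, code in CLASS_CODES.items()}


class SlideBoundsError(ValueError):
    """A requested region falls outside the slide raster."""


@dataclasses.dataclass(frozen=True)
class Annotation:
    """One labeled closed polygon in level-0 pixel coordinates."""

    label: str
    vertices: np.ndarray  # (n, 2) float array of (x, y)

    def __post_init__(self) -> None:
        if self.label not in LESION_CLASSES:
            raise ValueError(
                f"unknown annotation label {self.label!r}; "
                f"accepted labels are {', '.join(LESION_CLASSES)}"
            )
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y)")
        if verts.shape[0] < 3:
            raise ValueError(
                f"polygon needs at least 3 vertices, got {verts.shape[0]}"
            )
        object.__setattr__(self, "vertices", verts)


@dataclasses.dataclass
class AnnotationSet:
    """All polygon annotations of one slide, in drawing order."""

    slide_id: str
    annotations: list[Annotation] = dataclasses.field(default_factory=list)

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self):
        return iter(self.annotations)


class SlideImage:
    """An RGB raster with a power-of-two resolution pyramid.

    Level 0 is the full-resolution raster; level ``k`` is downsampled by
    ``2**k`` through block averaging.  Levels are materialized lazily.
    """

    def __init__(self, level0: np.ndarray, slide_id: str = "slide"):
        arr = np.asarray(level0)
        if arr.ndim != 3 or arr.shape[2] != 3 or arr.dtype != np.uint8:
            raise ValueError("level0 must be an (H, W, 3) uint8 RGB array")
        self.slide_id = slide_id
        self._levels: list[np.ndarray] = [arr]

    # -- geometry ---------------------------------------------------------

    @property
    def dimensions(self) -> tuple[int, int]:
        """Level-0 (width, height) in pixels."""
        h, w = self._levels[0].shape[:2]
        return (w, h)

    def level_downsample(self, level: int) -> int:
        return 2**level

    def level_dimensions(self, level: int) -> tuple[int, int]:
        ds = self.level_downsample(level)
        w, h = self.dimensions
        return (math.ceil(w / ds), math.ceil(h / ds))

    # -- pyramid ----------------------------------------------------------

    def _level(self, level: int) -> np.ndarray:
        if level < 0:
            raise ValueError("level must be >= 0")
        while len(self._levels) <= level:
            prev = self._levels[-1]
            if min(prev.shape[:2]) < 2:
                raise ValueError(f"level {level} does not exist for this slide")
            self._levels.append(_halve(prev))
        return self._levels[level]

    def read_region(
        self,
        origin: tuple[int, int],
        size: tuple[int, int],
        level: int = 0,
    ) -> np.ndarray:
        """Read a ``(w, h)`` region at ``level``.

        ``origin`` is the level-0 (x, y) of the region's top-left corner
        (floored to the level grid); ``size`` is in level pixels.
        """
        w, h = size
        if w <= 0 or h <= 0:
            raise ValueError("size must be positive")
        arr = self._level(level)
        ds = self.level_downsample(level)
        x0, y0 = origin[0] // ds, origin[1] // ds
        lh, lw = arr.shape[:2]
        if x0 < 0 or y0 < 0:
            raise SlideBoundsError(
                f"origin {origin} is outside the slide (negative coordinate)"
            )
        if x0 + w > lw:
            raise SlideBoundsError(
                f"x extent {x0 + w} exceeds level-{level} width {lw}"
            )
        if y0 + h > lh:
            raise SlideBoundsError(
                f"y extent {y0 + h} exceeds level-{level} height {lh}"
            )
        return arr[y0 : y0 + h, x0 : x0 + w].copy()

    def thumbnail(self, downsample: int) -> np.ndarray:
        """Block-averaged whole-slide raster at an arbitrary downsample."""
        if downsample < 1:
            raise ValueError("downsample must be >= 1")
        level = 0
        while 2 ** (level + 1) <= downsample and min(
            self._level(level).shape[:2]
        ) >= 2:
            level += 1
        arr = self._level(level)
        rest = downsample / 2**level
        if rest == 1.0:
            return arr.copy()
        w = max(1, math.ceil(arr.shape[1] / rest))
        h = max(1, math.ceil(arr.shape[0] / rest))
        img = Image.fromarray(arr).resize((w, h), Image.Resampling.BOX)
        return np.asarray(img)

    # -- file I/O ---------------------------------------------------------

    @classmethod
    def open(cls, path: str | FilePath) -> "SlideImage":
        path = FilePath(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path).convert("RGB"))
        return cls(np.ascontiguousarray(arr, dtype=np.uint8), slide_id=path.stem)

    def save(self, path: str | FilePath) -> None:
        path = FilePath(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, self._levels[0], tile=(256, 256))
        else:
            Image.fromarray(self._levels[0]).save(path)


def _halve(arr: np.ndarray) -> np.ndarray:
    """2x block average with edge replication for odd dimensions."""
    h, w = arr.shape[:2]
    if h % 2:
        arr = np.concatenate([arr, arr[-1:]], axis=0)
    if w % 2:
        arr = np.concatenate([arr, arr[:, -1:]], axis=1)
    h, w = arr.shape[:2]
    blocks = arr.reshape(h // 2, 2, w // 2, 2, 3).astype(np.float64)
    return np.rint(blocks.mean(axis=(1, 3))).astype(np.uint8)


# -- annotations -----------------------------------------------------------


def parse_annotations(path: str | FilePath) -> AnnotationSet:
    """Parse an ASAP-style annotation XML file.

    Raises ``lxml.etree.XMLSyntaxError`` (which carries the line number) on
    malformed XML and ``ValueError`` on labels outside the accepted
    vocabulary or polygons with fewer than 3 vertices.
    """
    path = FilePath(path)
    tree = etree.parse(str(path))
    annotations = []
    for elem in tree.iter("Annotation"):
        label = elem.get("PartOfGroup")
        coords = []
        for c in elem.iter("Coordinate"):
            coords.append((int(c.get("Order")), float(c.get("X")), float(c.get("Y"))))
        coords.sort(key=lambda t: t[0])
        verts = np.array([(x, y) for _, x, y in coords], dtype=float)
        annotations.append(Annotation(label=label, vertices=verts))
    return AnnotationSet(slide_id=path.stem, annotations=annotations)


def write_annotations(annotations: AnnotationSet, path: str | FilePath) -> None:
    """Write an AnnotationSet as ASAP-style XML."""
    root = etree.Element("ASAP_Annotations")
    anns = etree.SubElement(root, "Annotations")
    groups_used = []
    for i, ann in enumerate(annotations):
        el = etree.SubElement(
            anns,
            "Annotation",
            Name=f"Annotation {i}",
            Type="Polygon",
            PartOfGroup=ann.label,
            Color="#F4FA58",
        )
        coords = etree.SubElement(el, "Coordinates")
        for order, (x, y) in enumerate(ann.vertices):
            etree.SubElement(
                coords,
                "Coordinate",
                Order=str(order),
                X=f"{x:.4f}",
                Y=f"{y:.4f}",
            )
        if ann.label not in groups_used:
            groups_used.append(ann.label)
    groups = etree.SubElement(root, "AnnotationGroups")
    for label in groups_used:
        etree.SubElement(
            groups, "Group", Name=label, PartOfGroup="None", Color="#F4FA58"
        )
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="utf-8")


def rasterize_annotations(
    annotations: AnnotationSet,
    canvas_size: tuple[int, int],
    downsample: float = 1,
) -> np.ndarray:
    """Rasterize polygons into a class-coded uint8 label mask.

    A pixel belongs to a polygon iff its *center* lies inside the polygon
    (even-odd rule).  Later polygons overwrite earlier ones; pixels covered
    by no polygon carry ``BACKGROUND_CODE``.

    ``canvas_size`` is the level-0 (width, height); the returned mask has
    shape ``(ceil(h/downsample), ceil(w/downsample))``.
    """
    if downsample < 1:
        raise ValueError("downsample must be >= 1")
    w0, h0 = canvas_size
    nw, nh = math.ceil(w0 / downsample), math.ceil(h0 / downsample)
    mask = np.full((nh, nw), BACKGROUND_CODE, dtype=np.uint8)
    for ann in annotations:
        verts = ann.vertices / downsample
        x_min = max(0, int(np.floor(verts[:, 0].min() - 1)))
        x_max = min(nw, int(np.ceil(verts[:, 0].max() + 1)))
        y_min = max(0, int(np.floor(verts[:, 1].min() - 1)))
        y_max = min(nh, int(np.ceil(verts[:, 1].max() + 1)))
        if x_min >= x_max or y_min >= y_max:
            continue
        xs = np.arange(x_min, x_max) + 0.5
        ys = np.arange(y_min, y_max) + 0.5
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        # the closing vertex must be explicit for the point-in-polygon test
        ring = np.vstack([verts, verts[:1]])
        inside = PolyPath(ring, closed=True).contains_points(pts)
        sub = mask[y_min:y_max, x_min:x_max]
        sub[inside.reshape(sub.shape)] = CLASS_CODES[ann.label]
    return mask
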