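"""Synthetic slides, labeled patches and survival cohorts with known truth.

Real annotated gastric whole-slide cohorts are not redistributable, so
every downstream stage is exercised against a generative stand-in whose
ground truth is known exactly.

Slides are painted *through the stain model itself*: each lesion class has
a procedural gland texture that produces per-pixel hematoxylin and eosin
concentration fields; these are mapped to RGB via ``OD = C x S`` and
exponentiation, so stain estimation on a generated slide can be checked
against the generating stain matrix.  The three classes emulate the
histology being discriminated:

* ``normal`` - a regular lattice of tubular glands with compact epithelium
  and sparse stromal nuclei;
* ``gastritis`` - the same glands deformed and inflamed (denser stromal
  nuclei, higher hematoxylin uptake);
* ``cancer`` - strongly deformed, fused and irregular glands with dense,
  hyperchromatic nuclei.

Deformation amplitude and nuclear density increase monotonically along the
normal -> gastritis -> cancer route, which is what makes the classes
separable by texture and color statistics.

Survival cohorts are drawn from a proportional-hazards model with an
exponential baseline: event time ``T ~ Exp(lambda0 * exp(beta . z))`` where
``z`` are z-scored covariate columns (clinical fields and/or heatmap
features) named by ``hazard_coefficients``.  Censoring is by staggered
administrative follow-up plus an optional independent early-dropout rate.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .patching import Patch
from .slide_io import (
    CLASS_CODES,
    LESION_CLASSES,
    Annotation,
    AnnotationSet,
    SlideImage,
    rasterize_annotations,
)

#: Classic H&E stain vectors in OD space (rows: hematoxylin, eosin),
#: unit-normalized.
DEFAULT_STAIN_MATRIX = np.array(
    [[0.65, 0.70, 0.29], [0.07, 0.99, 0.11]], dtype=np.float64
)
DEFAULT_STAIN_MATRIX /= np.linalg.norm(DEFAULT_STAIN_MATRIX, axis=1, keepdims=True)


@dataclasses.dataclass
class TextureParams:
    """Procedural gland-texture parameters for one lesion class.

    ``gland_spacing`` is the lattice period in pixels, ``gland_deformation``
    the warp amplitude as a fraction of the spacing, and ``nuclear_density``
    the per-pixel rate of stromal nuclei.  Concentrations are in OD units
    of the generating stain matrix.
    """

    gland_spacing: float = 24.0
    gland_deformation: float = 0.15
    lumen_level: float = 1.2
    epithelium_level: float = 0.2
    nuclear_density: float = 0.02
    h_epithelium: float = 0.9
    e_epithelium: float = 0.06
    h_stroma: float = 0.02
    e_stroma: float = 0.35
    h_nucleus: float = 1.1
    noise: float = 0.08


#: Per-class defaults.  Deformation, nuclear density and the epithelial
#: *area fraction* (glands fuse into solid sheets as ``epithelium_level``
#: drops) increase along the normal -> gastritis -> cancer route; the
#: per-pixel stain uptake is kept similar across classes so the class
#: signal is compositional rather than a mere intensity offset.
DEFAULT_TEXTURES: dict[str, TextureParams] = {
    "normal": TextureParams(epithelium_level=0.35),
    "gastritis": TextureParams(
        gland_spacing=20.0,
        gland_deformation=0.55,
        epithelium_level=0.0,
        nuclear_density=0.10,
        h_epithelium=0.95,
        e_stroma=0.40,
    ),
    "cancer": TextureParams(
        gland_spacing=16.0,
        gland_deformation=1.30,
        epithelium_level=-0.45,
        nuclear_density=0.16,
        h_epithelium=1.0,
        e_epithelium=0.10,
        e_stroma=0.30,
    ),
}


@dataclasses.dataclass
class StainParams:
    """Generating stain matrix and the per-class concentration scale range."""

    matrix: np.ndarray = dataclasses.field(
        default_factory=lambda: DEFAULT_STAIN_MATRIX.copy()
    )
    concentration_scale: tuple[float, float] = (0.85, 1.15)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (2, 3):
            raise ValueError("stain matrix must be 2x3")
        self.matrix = m / np.linalg.norm(m, axis=1, keepdims=True)


@dataclasses.dataclass
class SlideSpec:
    """Specification of one synthetic slide.

    ``lesion_polygons`` is a list of (class label, (n, 2) vertex array)
    pairs in level-0 pixel coordinates; polygons drawn later overwrite
    earlier ones.  Identical spec + seed gives a bit-identical slide.
    """

    width: int
    height: int
    lesion_polygons: list[tuple[str, np.ndarray]] = dataclasses.field(
        default_factory=list
    )
    texture_params: Mapping[str, TextureParams] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_TEXTURES)
    )
    stain_params: StainParams = dataclasses.field(default_factory=StainParams)
    background_luminosity: int = 255
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("slide dimensions must be positive")
        if not 0 <= self.background_luminosity <= 255:
            raise ValueError("background_luminosity must be in 0..255")


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    field = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = field.std()
    return field / sd if sd > 0 else field


def _concentration_fields(
    shape: tuple[int, int], params: TextureParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Hematoxylin and eosin concentration fields of one class texture."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    s = params.gland_spacing
    amp = params.gland_deformation * s
    xw = xx + amp * _smooth_noise(rng, shape, s)
    yw = yy + amp * _smooth_noise(rng, shape, s)
    px, py = rng.uniform(0.0, s, size=2)
    g = np.cos(2 * np.pi * (xw + px) / s) + np.cos(2 * np.pi * (yw + py) / s)
    lumen = g > params.lumen_level
    ring = (g > params.epithelium_level) & ~lumen
    stroma = ~(lumen | ring)
    nuclei = (rng.random(shape) < params.nuclear_density) & stroma
    nuclei_field = gaussian_filter(nuclei.astype(np.float64) * 4.0, 0.9)
    c_h = (
        ring * params.h_epithelium
        + stroma * params.h_stroma
        + nuclei_field * params.h_nucleus
    )
    c_e = ring * params.e_epithelium + stroma * params.e_stroma + lumen * 0.02
    for c in (c_h, c_e):
        c *= np.exp(params.noise * _smooth_noise(rng, shape, 2.0))
    return np.clip(c_h, 0.0, None), np.clip(c_e, 0.0, None)


def _render(
    c_h: np.ndarray,
    c_e: np.ndarray,
    stain_matrix: np.ndarray,
    background: float,
) -> np.ndarray:
    od = c_h[..., None] * stain_matrix[0] + c_e[..., None] * stain_matrix[1]
    rgb = background * np.power(10.0, -od)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def generate_synthetic_slide(
    spec: SlideSpec,
) -> tuple[SlideImage, AnnotationSet, np.ndarray]:
    """Generate one slide: RGB raster, annotations and level-0 label mask.

    Lesion polygons are validated against the slide bounds (a polygon
    outside bounds is rejected with its index named).  The returned mask is
    class-coded (see :mod:`gastroslide.slide_io`) and the annotation
    polygons exactly delimit the painted regions: the mask is produced by
    the same rasterization later used when parsing the written XML back.
    """
    w, h = spec.width, spec.height
    annotations = []
    for i, (label, verts) in enumerate(spec.lesion_polygons):
        verts = np.asarray(verts, dtype=float)
        ann = Annotation(label=label, vertices=verts)
        if (
            verts[:, 0].min() < 0
            or verts[:, 1].min() < 0
            or verts[:, 0].max() > w
            or verts[:, 1].max() > h
        ):
            raise ValueError(
                f"polygon {i} ({label}) extends outside the {w}x{h} slide bounds"
            )
        annotations.append(ann)
    annset = AnnotationSet(slide_id=f"synthetic-{spec.seed}", annotations=annotations)
    mask = rasterize_annotations(annset, (w, h), downsample=1)

    c_h = np.zeros((h, w))
    c_e = np.zeros((h, w))
    lo, hi = spec.stain_params.concentration_scale
    for label in LESION_CLASSES:
        code = CLASS_CODES[label]
        sel = mask == code
        if not sel.any():
            continue
        # independent per-class stream: skipping absent classes never
        # perturbs the textures of the present ones
        class_rng = np.random.default_rng([spec.seed, code])
        scale = class_rng.uniform(lo, hi)
        fh, fe = _concentration_fields((h, w), spec.texture_params[label], class_rng)
        c_h[sel] = scale * fh[sel]
        c_e[sel] = scale * fe[sel]
    rgb = _render(
        c_h, c_e, spec.stain_params.matrix, float(spec.background_luminosity)
    )
    bg = mask == 0
    rgb[bg] = spec.background_luminosity
    slide = SlideImage(rgb, slide_id=annset.slide_id)
    return slide, annset, mask


def _jitter_stain_matrix(
    matrix: np.ndarray, max_angle_deg: float, rng: np.random.Generator
) -> np.ndarray:
    """Rotate each stain vector by a random angle up to ``max_angle_deg``."""
    out = []
    for row in matrix:
        r = rng.standard_normal(3)
        perp = r - (r @ row) * row
        n = np.linalg.norm(perp)
        if n < 1e-12:
            out.append(row)
            continue
        perp /= n
        theta = rng.uniform(0.0, np.deg2rad(max_angle_deg))
        v = np.cos(theta) * row + np.sin(theta) * perp
        v = np.clip(v, 0.0, None)
        out.append(v / np.linalg.norm(v))
    return np.vstack(out)


def generate_patch_set(
    n_per_class: int,
    patch_size: int = 299,
    texture_params: Mapping[str, TextureParams] | None = None,
    stain_params: StainParams | None = None,
    seed: int = 0,
    stain_jitter_deg: float = 0.0,
    concentration_jitter: float = 0.0,
    classes: Sequence[str] = LESION_CLASSES,
) -> list[Patch]:
    """Balanced labeled patches from the texture engine.

    ``stain_jitter_deg`` rotates each patch's generating stain vectors by
    an independent random angle and ``concentration_jitter`` scales its
    concentrations, emulating slide-to-slide staining variability; both
    default to off.  Reproducible under ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if patch_size < 8:
        raise ValueError("patch_size must be >= 8")
    textures = dict(texture_params or DEFAULT_TEXTURES)
    stain = stain_params or StainParams()
    rng = np.random.default_rng(seed)
    lo, hi = stain.concentration_scale
    patches = []
    for label in classes:
        for i in range(n_per_class):
            matrix = stain.matrix
            if stain_jitter_deg > 0:
                matrix = _jitter_stain_matrix(matrix, stain_jitter_deg, rng)
            scale = rng.uniform(lo, hi)
            if concentration_jitter > 0:
                scale *= rng.uniform(
                    1.0 - concentration_jitter, 1.0 + concentration_jitter
                )
            c_h, c_e = _concentration_fields(
                (patch_size, patch_size), textures[label], rng
            )
            raster = _render(scale * c_h, scale * c_e, matrix, 255.0)
            patches.append(
                Patch(
                    raster=raster,
                    x=0,
                    y=0,
                    scale=patch_size,
                    label=label,
                    slide_id=f"synthetic-patch-{label}-{i}",
                )
            )
    return patches


# -- survival cohorts ------------------------------------------------------

#: Clinical covariate columns of a cohort frame, with their generating
#: distributions (see :func:`generate_cohort`).
CLINICAL_COLUMNS = (
    "age",
    "macroscopic_type",
    "distant_metastasis",
    "infiltration_depth",
    "positive_lymph_nodes",
)


def _default_covariates() -> dict[str, tuple]:
    return {
        "age": ("normal", 61.9, 11.0),
        "macroscopic_type": ("choice", [0, 1, 2, 3], [0.10, 0.35, 0.35, 0.20]),
        "distant_metastasis": ("bernoulli", 0.12),
        "infiltration_depth": ("choice", [1, 2, 3, 4], [0.15, 0.20, 0.30, 0.35]),
        "positive_lymph_nodes": ("poisson", 4.0),
    }


@dataclasses.dataclass
class CohortSpec:
    """Specification of a synthetic follow-up cohort.

    ``hazard_coefficients`` maps column names (clinical covariates or
    heatmap-feature names) to log-hazard coefficients applied to the
    z-scored column.  ``censoring_rate`` is the probability of independent
    early dropout; ``max_follow_up`` the administrative horizon in months.
    With ``staggered_entry`` each patient's own horizon is uniform on
    (3, max_follow_up), emulating rolling enrollment.
    """

    n_patients: int = 273
    covariates: Mapping[str, tuple] = dataclasses.field(
        default_factory=_default_covariates
    )
    hazard_coefficients: Mapping[str, float] = dataclasses.field(default_factory=dict)
    baseline_hazard: float = 0.012  # events per month
    censoring_rate: float = 0.0
    max_follow_up: float = 144.0
    staggered_entry: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.baseline_hazard <= 0 or self.max_follow_up <= 0:
            raise ValueError("baseline hazard and follow-up must be positive")
        for name, coef in self.hazard_coefficients.items():
            if not np.isfinite(coef):
                raise ValueError(f"hazard coefficient for {name!r} is not finite")


def _draw_covariate(dist: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist[0]
    if kind == "normal":
        return np.clip(rng.normal(dist[1], dist[2], n), 18.0, 95.0)
    if kind == "choice":
        return rng.choice(dist[1], size=n, p=dist[2]).astype(float)
    if kind == "bernoulli":
        return (rng.random(n) < dist[1]).astype(float)
    if kind == "poisson":
        return rng.poisson(dist[1], n).astype(float)
    raise ValueError(f"unknown covariate distribution {kind!r}")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a survival cohort with attached heatmap-feature columns.

    Columns of the returned frame:

    * ``patient_id`` - integer identifier;
    * ``duration_months`` - observed follow-up time (> 0);
    * ``event`` - 1 if the patient died at ``duration_months``, 0 if
      censored (alive at last contact);
    * the clinical covariates in :data:`CLINICAL_COLUMNS`;
    * the 44 heatmap-feature columns named as in
      :data:`gastroslide.wsi_features.FEATURE_NAMES`, drawn independently
      from plausible marginals (proportions from a Beta, counts/areas from
      a log-normal) unless tied to the hazard through a coefficient.

    Event times follow the exponential proportional-hazards model in the
    module docstring; censoring is applied independently.
    """
    from .wsi_features import FEATURE_NAMES, POSITIVE_FEATURE_INDICES

    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    data: dict[str, np.ndarray] = {}
    for name, dist in spec.covariates.items():
        data[name] = _draw_covariate(dist, n, rng)
    for idx, name in enumerate(FEATURE_NAMES, start=1):
        if idx in POSITIVE_FEATURE_INDICES:
            data[name] = np.exp(rng.normal(1.0, 0.8, n))
        else:
            data[name] = rng.beta(1.6, 3.2, n)

    lp = np.zeros(n)
    for name, coef in spec.hazard_coefficients.items():
        if name not in data:
            raise ValueError(f"hazard coefficient refers to unknown column {name!r}")
        col = data[name]
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else np.zeros(n)
        lp += coef * z
    rate = spec.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)

    if spec.staggered_entry:
        horizon = rng.uniform(3.0, spec.max_follow_up, n)
    else:
        horizon = np.full(n, spec.max_follow_up)
    t_censor = np.full(n, np.inf)
    dropout = rng.random(n) < spec.censoring_rate
    t_censor[dropout] = rng.uniform(0.1, np.maximum(t_event[dropout], 0.2))

    observed = np.minimum(np.minimum(t_event, horizon), t_censor)
    event = (t_event <= np.minimum(horizon, t_censor)).astype(int)
    frame = pd.DataFrame({"patient_id": np.arange(n)})
    frame["duration_months"] = np.maximum(observed, 0.05)
    frame["event"] = event
    for name in data:
        frame[name] = data[name]
    return frame
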