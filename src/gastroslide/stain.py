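"""Brightness standardization and H&E stain normalization.

The model is the Beer-Lambert factorization ``OD = C x S``: the per-pixel
optical density (3-vector over RGB) is a nonnegative combination of two
stain color vectors, the rows of the 2x3 stain matrix ``S`` (hematoxylin
and eosin), weighted by the per-pixel concentrations ``C``.  The stain
matrix of an image is estimated from the geometry of its OD point cloud:
tissue OD vectors lie in a 2-D cone whose extreme directions are the pure
stains, so the robust angular extremes of the cloud projected onto the top
two eigenvectors of the OD covariance recover the stain vectors.

Normalizing image A to reference B means: estimate A's own stain matrix,
solve its concentrations, rescale each concentration channel so A's robust
maximum matches B's, then rebuild RGB through B's stain matrix.  Optical
density uses log base 10 with background intensity I0 = 255; the base only
rescales concentrations and cancels in normalization.
"""

from __future__ import annotations

import dataclasses

import numpy as np


class StainEstimationError(ValueError):
    """Stain-matrix estimation failed; skip normalization for this image."""


@dataclasses.dataclass
class StainProfile:
    """Stain matrix and robust maximum concentrations of one image.

    ``matrix`` rows are unit-norm nonnegative OD-space stain vectors; row 0
    is hematoxylin (identified as the row with the larger red-channel OD
    component) and row 1 eosin.
    """

    matrix: np.ndarray  # (2, 3)
    max_concentrations: np.ndarray  # (2,)
    background_intensity: float = 255.0
    source: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (2, 3):
            raise ValueError("stain matrix must be 2x3")
        if (m < -1e-12).any():
            raise ValueError("stain vectors must be nonnegative")
        norms = np.linalg.norm(m, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain vectors must have unit norm")
        self.matrix = m
        mc = np.asarray(self.max_concentrations, dtype=np.float64)
        if mc.shape != (2,) or (mc <= 0).any():
            raise ValueError("max_concentrations must be 2 positive values")
        self.max_concentrations = mc


@dataclasses.dataclass
class NormalizationResult:
    """Output of :func:`normalize_to_reference`.

    ``normalized`` is False when estimation failed and the input was
    passed through unchanged; ``message`` then says why.
    """

    image: np.ndarray
    profile: StainProfile | None
    normalized: bool
    message: str | None = None


def standardize_brightness(image: np.ndarray, percentile: float = 95.0) -> np.ndarray:
    """Rescale each channel so its upper percentile maps to 255.

    Counteracts uniformly faded or dim scans.  Monotone per channel;
    channels whose percentile is 0 (e.g. an all-black image) are left
    untouched to avoid division blow-up.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("image is empty")
    out = img.astype(np.float64).copy()
    for ch in range(img.shape[2]):
        p = np.percentile(img[..., ch], percentile)
        if p > 0:
            out[..., ch] = out[..., ch] * (255.0 / p)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def rgb_to_od(image: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """Beer-Lambert optical density: ``OD = -log10(max(I, 1) / I0)``."""
    arr = np.asarray(image, dtype=np.float64)
    return -np.log10(np.maximum(arr, 1.0) / background_intensity)


def od_to_rgb(od: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`; exact roundtrip for intensities >= 1."""
    arr = background_intensity * np.power(10.0, -np.asarray(od, dtype=np.float64))
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def solve_concentrations(od: np.ndarray, stain_matrix: np.ndarray) -> np.ndarray:
    """Per-pixel least-squares solution of ``OD = C x S``, clipped at 0.

    ``od`` is (..., 3); returns concentrations of shape (..., 2).
    """
    S = np.asarray(stain_matrix, dtype=np.float64)
    if S.shape != (2, 3):
        raise ValueError("stain matrix must be 2x3")
    gram = S @ S.T
    if np.linalg.matrix_rank(gram, tol=1e-8) < 2:
        raise ValueError("stain matrix is rank deficient")
    pinv = S.T @ np.linalg.inv(gram)  # (3, 2) right pseudo-inverse
    flat = np.asarray(od, dtype=np.float64).reshape(-1, 3)
    conc = flat @ pinv
    return np.clip(conc, 0.0, None).reshape(od.shape[:-1] + (2,))


def estimate_stain_matrix(
    image: np.ndarray,
    beta: float = 0.15,
    alpha: float = 0.01,
    background_intensity: float = 255.0,
    min_pixels: int = 100,
    source: str = "",
) -> StainProfile:
    """Estimate an image's stain matrix from robust OD angular extremes.

    Pixels whose OD components are all below ``beta`` (near-white
    background) are discarded.  The retained OD vectors are projected onto
    the top two eigenvectors of their covariance; the stain vectors are the
    directions at the ``alpha`` and ``1 - alpha`` percentiles of the
    angular distribution in that plane, back-projected to OD space,
    sign-fixed nonnegative and unit-normalized.  ``max_concentrations`` are
    the per-stain 99th concentration percentiles.
    """
    od = rgb_to_od(image, background_intensity).reshape(-1, 3)
    tissue = od[od.max(axis=1) >= beta]
    if tissue.shape[0] < min_pixels:
        raise StainEstimationError(
            f"only {tissue.shape[0]} tissue pixels above OD {beta}; "
            "skip normalization for this image"
        )
    cov = np.cov(tissue.T)
    evals, evecs = np.linalg.eigh(cov)
    basis = evecs[:, -2:]  # (3, 2), columns are the top-2 eigenvectors
    proj = tissue @ basis
    mean_dir = proj.mean(axis=0)
    theta0 = float(np.arctan2(mean_dir[1], mean_dir[0]))
    phi = np.arctan2(proj[:, 1], proj[:, 0]) - theta0
    phi = np.mod(phi + np.pi, 2 * np.pi) - np.pi  # wrap to (-pi, pi]
    lo = float(np.percentile(phi, 100.0 * alpha))
    hi = float(np.percentile(phi, 100.0 * (1.0 - alpha)))
    if hi - lo < np.deg2rad(1.0):
        raise StainEstimationError(
            "degenerate angular spread: the image appears to contain a "
            "single stain; skip normalization for this image"
        )
    rows = []
    for ang in (lo, hi):
        v = basis @ np.array([np.cos(ang + theta0), np.sin(ang + theta0)])
        if v.sum() < 0:
            v = -v
        v = np.clip(v, 0.0, None)
        n = np.linalg.norm(v)
        if n < 1e-8:
            raise StainEstimationError("degenerate stain direction")
        rows.append(v / n)
    S = np.vstack(rows)
    # Hematoxylin (blue-purple) absorbs red strongly while eosin (pink)
    # transmits it, so the red-OD component separates the rows much more
    # widely (0.65 vs 0.07 for classic H&E) than the blue one; identify
    # the hematoxylin row as the one with the larger red-OD component.
    if S[0, 0] < S[1, 0]:
        S = S[::-1]
    conc = solve_concentrations(tissue, S)
    max_conc = np.percentile(conc, 99.0, axis=0)
    if (max_conc <= 0).any():
        raise StainEstimationError("degenerate concentrations")
    return StainProfile(
        matrix=S,
        max_concentrations=max_conc,
        background_intensity=background_intensity,
        source=source,
    )


def normalize_to_reference(
    image: np.ndarray,
    reference: StainProfile,
    beta: float = 0.15,
    alpha: float = 0.01,
    background_cutoff: float = 0.94,
) -> NormalizationResult:
    """Map an image's stain appearance onto a reference profile.

    Background pixels (luminosity above ``background_cutoff`` times the
    background intensity) pass through unchanged.  If stain estimation
    fails (too little tissue, single stain), the image is returned
    unchanged with ``normalized=False``.
    """
    img = np.asarray(image)
    i0 = reference.background_intensity
    try:
        profile = estimate_stain_matrix(
            img, beta=beta, alpha=alpha, background_intensity=i0
        )
    except StainEstimationError as exc:
        return NormalizationResult(
            image=img.copy(), profile=None, normalized=False, message=str(exc)
        )
    od = rgb_to_od(img, i0)
    conc = solve_concentrations(od, profile.matrix)
    conc = conc * (reference.max_concentrations / profile.max_concentrations)
    od_new = conc @ reference.matrix
    out = od_to_rgb(od_new, i0)
    bg = img.astype(np.float64).mean(axis=2) >= background_cutoff * i0
    out[bg] = img[bg]
    return NormalizationResult(image=out, profile=profile, normalized=True)


def stain_vector_angles(estimated: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Per-row angular distance in degrees between two 2x3 stain matrices."""
    a = np.asarray(estimated, dtype=np.float64)
    b = np.asarray(truth, dtype=np.float64)
    a = a / np.linalg.norm(a, axis=1, keepdims=True)
    b = b / np.linalg.norm(b, axis=1, keepdims=True)
    cos = np.clip((a * b).sum(axis=1), -1.0, 1.0)
    return np.degrees(np.arccos(cos))
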