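"""Background suppression and the six preprocessing arms.

Reconstructed DBT slices carry signal contamination outside the breast.
``suppress_background`` builds a breast mask in four steps — threshold
binarization, hole filling, largest-component selection and region
growing — and zeroes everything outside it.  On top of that, six
preprocessing arms combine total-variation (TV) denoising, CLAHE
contrast enhancement and a squared-normalization contrast stretch:

======== ==========================================
original identity
p1       TV denoising
p2       CLAHE
p3       TV denoising, then CLAHE
p4       CLAHE, then TV denoising
p5       squared normalization
p6       squared normalization, then TV denoising
======== ==========================================

Background suppression is applied to every arm's output, always with
the mask computed from the *original* image (intensity transforms such
as CLAHE amplify the contamination and would corrupt a recomputed mask).

All images are unit-float (values in [0, 1]) unless explicitly converted
to 8 bits for storage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, filters, transform

from dbtmc.exceptions import ParameterError

ARMS = ("original", "p1", "p2", "p3", "p4", "p5", "p6")

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structure


@dataclass(frozen=True)
class SliceImage:
    """A 2-D slice with pixel size and provenance/range tags."""

    pixels: np.ndarray
    pixel_size_mm: float = 0.085
    range_tag: str = "unit_float"  # or "uint8"
    provenance: str = "original"  # or the preprocessing arm name


@dataclass(frozen=True)
class PreprocessSpec:
    """Parameters of one preprocessing arm.

    Defaults are the study's stated values: TV fidelity multiplier 14,
    CLAHE clip limit 0.01 with a uniform target histogram (the
    distribution parameter 0.4 is stored for fidelity but inert under a
    uniform target), and a 512-px network input at full scale.
    """

    method: str = "original"
    tv_lambda: float = 14.0
    clahe_clip: float = 0.01
    clahe_dist: str = "uniform"
    clahe_alpha: float = 0.4
    clahe_tiles: tuple[int, int] = (8, 8)
    target_size: int = 512

    def __post_init__(self) -> None:
        if self.method not in ARMS:
            raise ParameterError(f"unknown preprocessing arm {self.method!r}")
        if self.tv_lambda <= 0:
            raise ParameterError("tv_lambda must be positive")
        if not (0 < self.clahe_clip <= 1):
            raise ParameterError("clahe_clip must be in (0, 1]")


# ---------------------------------------------------------------------------
# the four-step breast mask

def binarize(image: np.ndarray, threshold_strategy="otsu") -> tuple[np.ndarray, bool]:
    """Threshold the slice into foreground/background.

    ``threshold_strategy`` is ``"otsu"`` (default), a fixed float
    threshold, or a callable ``image -> threshold``.  Returns the mask
    and a degenerate flag; a constant image cannot be thresholded and
    yields an all-zeros mask with the flag set.
    """
    image = np.asarray(image, dtype=float)
    if np.ptp(image) < 1e-12:
        return np.zeros(image.shape, dtype=bool), True
    if threshold_strategy == "otsu":
        thr = filters.threshold_otsu(image)
    elif callable(threshold_strategy):
        thr = float(threshold_strategy(image))
    else:
        thr = float(threshold_strategy)
    return image >= thr, False


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not connected to the grid border."""
    return ndimage.binary_fill_holes(np.asarray(mask, dtype=bool))


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    Ties are broken by label order, i.e. first component in scan order.
    An empty mask is returned unchanged.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return mask.copy()
    counts = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(counts)) + 1)


def region_grow(
    mask: np.ndarray,
    image: np.ndarray,
    admit_fraction: float = 0.10,
    max_iter: int | None = None,
) -> np.ndarray:
    """Grow the mask into faint breast-edge pixels.

    Starting from the current boundary, neighbors whose intensity
    exceeds ``admit_fraction`` times the initial in-mask mean are
    admitted, ring by ring, until no pixel changes.  Growth by dilation
    preserves single-connectedness.  ``admit_fraction=inf`` admits
    nothing and returns the input mask.
    """
    mask = np.asarray(mask, dtype=bool)
    image = np.asarray(image, dtype=float)
    if not mask.any():
        return mask.copy()
    threshold = admit_fraction * image[mask].mean()
    grown = mask.copy()
    limit = max_iter if max_iter is not None else mask.shape[0] + mask.shape[1]
    for _ in range(limit):
        frontier = ndimage.binary_dilation(grown, structure=_EIGHT) & ~grown
        admit = frontier & (image > threshold)
        if not admit.any():
            break
        grown |= admit
    return grown


def suppress_background(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Zero everything outside the breast.

    The mask is ``region_grow(largest_component(fill_holes(binarize(
    image))))``; in-mask pixels are unchanged.  Returns
    ``(suppressed, mask, degenerate_flag)``; a constant input propagates
    the degenerate flag with an all-zeros mask.
    """
    raw, degenerate = binarize(image)
    if degenerate:
        return np.zeros_like(np.asarray(image, dtype=float)), raw, True
    mask = region_grow(largest_component(fill_holes(raw)), image)
    return np.asarray(image, dtype=float) * mask, mask, False


# ---------------------------------------------------------------------------
# intensity operators

def total_variation(image: np.ndarray) -> float:
    """Isotropic total variation (forward differences, zero at border)."""
    gy = np.diff(image, axis=0, append=image[-1:, :])
    gx = np.diff(image, axis=1, append=image[:, -1:])
    return float(np.sqrt(gx**2 + gy**2).sum())


def tv_denoise(
    image: np.ndarray,
    tv_lambda: float = 14.0,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> np.ndarray:
    """Rudin–Osher–Fatemi denoising by Chambolle's dual projection.

    Minimizes ``(tv_lambda / 2) * ||u - f||^2 + TV(u)``; larger
    ``tv_lambda`` keeps the output closer to the data, smaller values
    smooth more.  Iterates the dual update with step 1/4 until the
    relative change of ``u`` falls below ``tol`` (or ``max_iter``), then
    clips to [0, 1].
    """
    if tv_lambda <= 0:
        raise ParameterError("tv_lambda must be positive")
    f = np.asarray(image, dtype=float)
    weight = 1.0 / tv_lambda  # TV weight in the unit-fidelity form
    px = np.zeros_like(f)
    py = np.zeros_like(f)
    tau = 0.25
    u = f.copy()
    for it in range(max_iter):
        # divergence of the dual field p (adjoint of forward differences)
        div = np.zeros_like(f)
        div[:-1, :] += px[:-1, :]
        div[1:, :] -= px[:-1, :]
        div[:, :-1] += py[:, :-1]
        div[:, 1:] -= py[:, :-1]
        u_new = f + weight * div
        gy = np.diff(u_new, axis=0, append=u_new[-1:, :]) / weight
        gx = np.diff(u_new, axis=1, append=u_new[:, -1:]) / weight
        norm = np.sqrt(gx**2 + gy**2)
        denom = 1.0 + tau * norm
        px = (px + tau * gy) / denom
        py = (py + tau * gx) / denom
        change = np.abs(u_new - u).max()
        u = u_new
        if it > 0 and change < tol * max(np.abs(f).max(), 1e-12):
            break
    return np.clip(u, 0.0, 1.0)


def clahe(
    image: np.ndarray,
    clip: float = 0.01,
    dist: str = "uniform",
    alpha: float = 0.4,
    tiles: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Per-tile equalization with bilinear blending between neighboring
    tiles; the clip limit bounds contrast amplification in homogeneous
    areas.  Only the uniform target histogram is supported (``alpha`` is
    kept for interface fidelity but has no effect under it).  A constant
    image has no contrast to redistribute and is returned unchanged.
    """
    if dist != "uniform":
        raise ParameterError(f"only the uniform target histogram is supported, got {dist!r}")
    image = np.asarray(image, dtype=float)
    if tiles[0] > image.shape[0] or tiles[1] > image.shape[1]:
        raise ParameterError(f"tile grid {tiles} larger than image {image.shape}")
    if np.ptp(image) < 1e-12:
        return image.copy()
    kernel = (
        max(1, image.shape[0] // tiles[0]),
        max(1, image.shape[1] // tiles[1]),
    )
    out = exposure.equalize_adapthist(
        np.clip(image, 0.0, 1.0), kernel_size=kernel, clip_limit=clip, nbins=256
    )
    return np.clip(out, 0.0, 1.0)


def square_normalize(image: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1], then square.

    Squaring attenuates low intensities and highlights the brightest
    structures (the microcalcifications).  Monotone in the input; a
    constant image degenerates to all zeros.
    """
    image = np.asarray(image, dtype=float)
    rng = np.ptp(image)
    if rng < 1e-12:
        return np.zeros_like(image)
    return ((image - image.min()) / rng) ** 2


def apply_preprocessing(
    image: np.ndarray, spec: PreprocessSpec, mask: np.ndarray | None = None
) -> np.ndarray:
    """Run one arm end to end on a unit-float slice.

    The breast mask is computed from the original image (or passed in,
    e.g. cached by the pipeline) and applied to the arm's output, so
    every arm returns exact zeros outside the breast.
    """
    image = np.asarray(image, dtype=float)
    if mask is None:
        _, mask, degenerate = suppress_background(image)
        if degenerate:
            return np.zeros_like(image)

    if spec.method == "original":
        out = image
    elif spec.method == "p1":
        out = tv_denoise(image, spec.tv_lambda)
    elif spec.method == "p2":
        out = clahe(image, spec.clahe_clip, spec.clahe_dist, spec.clahe_alpha, spec.clahe_tiles)
    elif spec.method == "p3":
        out = tv_denoise(image, spec.tv_lambda)
        out = clahe(out, spec.clahe_clip, spec.clahe_dist, spec.clahe_alpha, spec.clahe_tiles)
    elif spec.method == "p4":
        out = clahe(image, spec.clahe_clip, spec.clahe_dist, spec.clahe_alpha, spec.clahe_tiles)
        out = tv_denoise(out, spec.tv_lambda)
    elif spec.method == "p5":
        out = square_normalize(image)
    elif spec.method == "p6":
        out = tv_denoise(square_normalize(image), spec.tv_lambda)
    else:  # pragma: no cover - guarded by PreprocessSpec
        raise ParameterError(f"unknown preprocessing arm {spec.method!r}")
    return np.clip(out, 0.0, 1.0) * mask


def resize_to(image: np.ndarray, target_size: int, is_mask: bool = False) -> np.ndarray:
    """Resize a slice (antialiased) or mask (nearest-neighbor) in-plane.

    Never touches the z-direction: the pipeline is strictly
    slice-by-slice.  An input already at the target size is returned
    pixel-identical.
    """
    image = np.asarray(image)
    if image.shape == (target_size, target_size):
        return image.copy()
    if is_mask:
        out = transform.resize(
            image.astype(float), (target_size, target_size), order=0, anti_aliasing=False
        )
        return out > 0.5
    return transform.resize(
        image.astype(float), (target_size, target_size), anti_aliasing=True
    )


def to_8bit_and_center(images: list[np.ndarray]) -> tuple[list[np.ndarray], list[float]]:
    """Quantize unit-float slices to 8 bits and record centering offsets.

    Each image is linearly scaled to integers 0–255 for storage; the
    per-image mean (on the 0–1 scale of the quantized image) is the
    offset subtracted at model-input time by :func:`zero_center`.
    """
    quantized = [np.clip(np.round(np.asarray(im, dtype=float) * 255), 0, 255).astype(np.uint8)
                 for im in images]
    offsets = [float(q.mean() / 255.0) for q in quantized]
    return quantized, offsets


def zero_center(image_uint8: np.ndarray, offset: float | None = None) -> np.ndarray:
    """Scale an 8-bit slice back to [0, 1] and subtract its mean."""
    x = np.asarray(image_uint8, dtype=float) / 255.0
    return x - (x.mean() if offset is None else offset)
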