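"""Specimen delimitation: separate the chewed gum from the image background.

The study photographs chromatic gum on an achromatic (white/grey) field, so
the specimen is recovered by thresholding HSI saturation, keeping the largest
connected candidate component and filling its interior holes. The procedure
is fully deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .errors import EmptySpecimenError, SegmentationError
from .image_io import HSIImage, to_hsi

DEFAULT_SAT_THRESHOLD = 0.15
DEFAULT_MIN_AREA_FRACTION = 0.05


def segment_specimen(
    img: np.ndarray,
    sat_threshold: float = DEFAULT_SAT_THRESHOLD,
    min_area_fraction: float = DEFAULT_MIN_AREA_FRACTION,
    connectivity: int = 1,
    erosion_radius: int = 0,
) -> np.ndarray:
    """Return a boolean specimen mask for an RGB image.

    Parameters
    ----------
    img
        ``(H, W, 3)`` RGB array in [0, 1].
    sat_threshold
        HSI saturation above which a pixel is a candidate foreground pixel.
        Raising it never grows the candidate set.
    min_area_fraction
        Smallest acceptable specimen area as a fraction of the image area.
    connectivity
        1 for 4-connectivity (default; avoids diagonal leakage through
        JPEG artefacts), 2 for 8-connectivity.
    erosion_radius
        Optional radius (pixels) by which to erode the final mask, trimming
        specimen borders before feature extraction. 0 disables.

    Raises
    ------
    SegmentationError
        If no connected chromatic component reaches ``min_area_fraction``
        of the image area (background and foreground not separable).
    """
    hsi = to_hsi(img, undefined_sat_threshold=0.0)
    candidates = hsi.saturation > sat_threshold
    if not candidates.any():
        raise SegmentationError("no chromatic pixels above the saturation threshold")

    labels = measure.label(candidates, connectivity=connectivity)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background label
    best = int(np.argmax(counts))
    mask = labels == best
    mask = ndimage.binary_fill_holes(mask)

    if erosion_radius > 0:
        mask = morphology.erosion(mask, morphology.disk(erosion_radius))

    area = int(mask.sum())
    min_area = min_area_fraction * mask.size
    if area < min_area:
        raise SegmentationError(
            f"largest chromatic component has {area} px, "
            f"below the minimum of {min_area:.0f} px "
            f"({min_area_fraction:.0%} of the image)"
        )
    return mask


def apply_mask(img: np.ndarray | HSIImage, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Extract in-mask pixels with their grid coordinates.

    Returns ``(coords, values)`` where ``coords`` is an ``(n, 2)`` array of
    (row, col) indices in C order and ``values`` the corresponding pixel
    values (scalars for a grey image, hue angles for an :class:`HSIImage`).

    Raises
    ------
    ValueError
        If image and mask dimensions differ.
    """
    mask = np.asarray(mask, dtype=bool)
    grid = img.hue if isinstance(img, HSIImage) else np.asarray(img)
    if grid.shape[:2] != mask.shape:
        raise ValueError(f"image shape {grid.shape[:2]} != mask shape {mask.shape}")
    coords = np.argwhere(mask)
    return coords, grid[mask]


def mask_overlay(img: np.ndarray, mask: np.ndarray, alpha: float = 0.4) -> np.ndarray:
    """QC overlay: specimen boundary and excluded region tinted red."""
    out = np.asarray(img, dtype=float).copy()
    excluded = ~np.asarray(mask, dtype=bool)
    out[excluded] = (1 - alpha) * out[excluded] + alpha * np.array([1.0, 0.0, 0.0])
    return out


def require_nonempty(mask: np.ndarray) -> np.ndarray:
    """Validate that a mask has at least one member pixel."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptySpecimenError("mask has no member pixels")
    return mask
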