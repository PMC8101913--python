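"""Raster image loading and colour-space conversions.

Images are held as ``float64`` arrays with channel values in ``[0, 1]``,
independent of the source bit depth (8- or 16-bit), so downstream texture
features depend on bit depth only through explicit grey-level quantization.

An RGB image is an ``(H, W, 3)`` array; a grey image is an ``(H, W)`` array.
The HSI (hue / saturation / intensity) decomposition used for the colour
mixing analysis is returned as an :class:`HSIImage`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ImageFormatError

#: Rec. 601 luma weights — the default grayscale convention of common
#: image-analysis tools.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Saturation below which a pixel is treated as achromatic and its hue is
#: flagged undefined rather than being assigned an arbitrary angle.
DEFAULT_UNDEFINED_SAT = 0.05


@dataclass(frozen=True)
class HSIImage:
    """Per-pixel hue/saturation/intensity decomposition of an RGB image.

    Attributes
    ----------
    hue
        Hue angle in radians, in ``[0, 2*pi)``. Values at achromatic pixels
        are meaningless; consult :attr:`defined`.
    saturation
        ``1 - min(R,G,B)/I`` for ``I > 0``, else 0. In ``[0, 1]``.
    intensity
        ``(R + G + B) / 3``. In ``[0, 1]``.
    defined
        Boolean grid, True where the hue angle is meaningful (saturation
        above the achromatic threshold used at conversion).
    """

    hue: np.ndarray
    saturation: np.ndarray
    intensity: np.ndarray
    defined: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.hue.shape


def _validate_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ImageFormatError(f"expected (H, W, 3) RGB array, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ImageFormatError("zero-size image")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("channel values must lie in [0, 1]")
    return img


def load_image(path: str | Path) -> np.ndarray:
    """Load a JPEG/PNG/TIFF raster as an ``(H, W, 3)`` float array in [0, 1].

    Grayscale files are promoted to three equal channels; an alpha channel,
    if present, is dropped. 8-bit and 16-bit integer rasters are scaled by
    their full code range.

    Raises
    ------
    OSError
        If the file is missing or cannot be decoded.
    ImageFormatError
        If the decoded object is not a usable raster image.
    """
    arr = iio.imread(path)
    if arr.ndim == 0 or arr.size == 0:
        raise ImageFormatError(f"{path}: empty or non-raster image")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3:
        raise ImageFormatError(f"{path}: unsupported image layout {arr.shape}")
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    if arr.shape[2] != 3:
        raise ImageFormatError(f"{path}: expected 1, 3 or 4 channels, got {arr.shape[2]}")
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        out = arr.astype(np.float64) / scale
    else:
        out = arr.astype(np.float64)
        if out.max() > 1.0:  # float TIFFs occasionally store 0..255
            out = out / 255.0
    return np.clip(out, 0.0, 1.0)


def save_image(path: str | Path, img: np.ndarray) -> None:
    """Write an RGB [0,1] float array (or boolean mask) as an 8-bit PNG/TIFF."""
    arr = np.asarray(img)
    if arr.dtype == bool:
        data = (arr * np.uint8(255))
    else:
        data = np.round(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
    iio.imwrite(path, data)


def to_grayscale(img: np.ndarray, weights: tuple[float, float, float] = LUMA_WEIGHTS) -> np.ndarray:
    """Convert RGB to a single luma channel.

    The default weights are the Rec. 601 luma coefficients
    ``0.299 R + 0.587 G + 0.114 B``. Weights must sum to 1 so the output is a
    convex combination of the channels and stays in [0, 1].
    """
    img = _validate_rgb(img)
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or not np.isclose(w.sum(), 1.0):
        raise ValueError("grayscale weights must be three values summing to 1")
    return img @ w


def to_hsi(img: np.ndarray, undefined_sat_threshold: float = DEFAULT_UNDEFINED_SAT) -> HSIImage:
    """Decompose RGB into hue / saturation / intensity.

    Uses the geometric (arccos) hue definition: intensity is the channel
    mean, saturation ``1 - min/I``, and hue the angle of the pixel's
    projection onto the chromatic plane, reflected into ``(pi, 2*pi)`` when
    ``B > G``. Pixels with saturation at or below ``undefined_sat_threshold``
    are flagged undefined (a hue angle is still stored but carries no
    information there).
    """
    img = _validate_rgb(img)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]

    intensity = (r + g + b) / 3.0
    minc = np.minimum(np.minimum(r, g), b)
    with np.errstate(divide="ignore", invalid="ignore"):
        saturation = np.where(intensity > 0, 1.0 - minc / np.where(intensity > 0, intensity, 1.0), 0.0)
    saturation = np.clip(saturation, 0.0, 1.0)

    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    with np.errstate(divide="ignore", invalid="ignore"):
        cosang = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
    theta = np.arccos(np.clip(cosang, -1.0, 1.0))
    hue = np.where(b > g, 2.0 * np.pi - theta, theta)
    hue = np.mod(hue, 2.0 * np.pi)

    defined = saturation > undefined_sat_threshold
    return HSIImage(hue=hue, saturation=saturation, intensity=intensity, defined=defined)


def hsi_to_rgb(hue: np.ndarray, saturation: np.ndarray, intensity: np.ndarray) -> np.ndarray:
    """Inverse HSI conversion (sector form); exact for in-gamut inputs.

    Accepts scalars or broadcastable arrays; returns an ``(..., 3)`` RGB
    array clipped to [0, 1]. Used by the specimen simulator to construct
    colours with exactly specified hue, and by tests as the round-trip
    oracle for :func:`to_hsi`.
    """
    h = np.mod(np.asarray(hue, dtype=float), 2.0 * np.pi)
    s = np.asarray(saturation, dtype=float)
    i = np.asarray(intensity, dtype=float)
    h, s, i = np.broadcast_arrays(h, s, i)

    sector = np.floor(h / (2.0 * np.pi / 3.0)).astype(int)  # 0, 1, 2
    h_local = h - sector * (2.0 * np.pi / 3.0)

    lo = i * (1.0 - s)
    with np.errstate(divide="ignore", invalid="ignore"):
        hi = i * (1.0 + s * np.cos(h_local) / np.cos(np.pi / 3.0 - h_local))
    mid = 3.0 * i - (lo + hi)

    rgb = np.empty(h.shape + (3,), dtype=float)
    for sec, order in ((0, (0, 1, 2)), (1, (1, 2, 0)), (2, (2, 0, 1))):
        m = sector == sec
        rgb[m, order[0]] = hi[m]
        rgb[m, order[1]] = mid[m]
        rgb[m, order[2]] = lo[m]
    return np.clip(rgb, 0.0, 1.0)
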