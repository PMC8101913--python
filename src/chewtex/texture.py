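"""Grey-level co-occurrence matrix (GLCM) texture features over a masked region.

The GLCM tabulates how often pairs of quantized grey levels co-occur at a
fixed pixel offset. Four second-order features summarise it:

* uniformity (angular second moment): ``sum p(i,j)^2``
* contrast: ``sum (i-j)^2 p(i,j)``
* homogeneity (inverse difference moment): ``sum p(i,j) / (1 + (i-j)^2)``
* entropy: ``-sum p log p`` (bits with the default base 2)

Low contrast/entropy and high uniformity/homogeneity indicate locally
similar grey levels — for a chewed two-colour gum specimen, colours merged
by effective mastication. Pairs are counted only when *both* pixels lie
inside the specimen mask, so the background never leaks into the features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientPairsError
from .segmentation import require_nonempty

#: Offsets (drow, dcol) per unit distance for the four standard GLCM angles.
ANGLE_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}

EXCLUDED = -1  # sentinel level for out-of-mask pixels in a quantized grid


@dataclass(frozen=True)
class GLCMConfig:
    """Parameters of the co-occurrence computation.

    levels
        Number of grey levels G after quantization (>= 2). Default 256,
        matching the common texture-plugin convention of one level per
        8-bit code.
    distance
        Pixel offset d between the two pixels of a pair (>= 1).
    angles
        Subset of {0, 45, 90, 135} degrees. Features are computed per angle
        and averaged.
    symmetric
        Count each ordered pair in both directions, making p(i,j) = p(j,i).
    log_base
        2 (entropy in bits) or e (nats).
    homogeneity_form
        "squared" for 1/(1+(i-j)^2) (inverse difference moment, default) or
        "abs" for 1/(1+|i-j|).
    """

    levels: int = 256
    distance: int = 1
    angles: tuple[int, ...] = (0,)
    symmetric: bool = True
    log_base: float = 2.0
    homogeneity_form: str = "squared"

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if not self.angles:
            raise ValueError("at least one angle is required")
        bad = set(self.angles) - set(ANGLE_OFFSETS)
        if bad:
            raise ValueError(f"unsupported angles {sorted(bad)}; choose from {sorted(ANGLE_OFFSETS)}")
        if self.log_base not in (2.0, math.e):
            raise ValueError("log_base must be 2 or e")
        if self.homogeneity_form not in ("squared", "abs"):
            raise ValueError('homogeneity_form must be "squared" or "abs"')


@dataclass(frozen=True)
class GLCMatrix:
    """Normalized co-occurrence matrix for one angle.

    ``counts`` are raw pair counts; ``p = counts / counts.sum()``.
    """

    p: np.ndarray
    counts: np.ndarray
    config: GLCMConfig


@dataclass
class TextureFeatures:
    """The four GLCM scalars plus the colorimetric VOH for one specimen side."""

    uniformity: float
    contrast: float
    homogeneity: float
    entropy: float
    voh: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "uniformity": self.uniformity,
            "contrast": self.contrast,
            "homogeneity": self.homogeneity,
            "entropy": self.entropy,
            "voh": self.voh,
        }


def quantize(gray: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Map grey values in [0, 1] to integer levels ``0 .. levels-1``.

    Level = ``floor(value * levels)`` clamped to ``levels - 1`` so that 1.0
    lands in the top bin. Out-of-mask pixels receive the sentinel ``-1``.

    Raises
    ------
    EmptySpecimenError
        If the mask has no member pixels.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    mask = require_nonempty(mask)
    gray = np.asarray(gray, dtype=float)
    if gray.shape != mask.shape:
        raise ValueError(f"image shape {gray.shape} != mask shape {mask.shape}")
    q = np.minimum((gray * levels).astype(np.int64), levels - 1)
    q[~mask] = EXCLUDED
    return q


def cooccurrence(q: np.ndarray, config: GLCMConfig) -> list[GLCMatrix]:
    """Accumulate co-occurrence counts for each configured angle.

    A pair contributes only if both of its pixels are in-mask (level != -1).
    In symmetric mode the transposed pair is added as well, so the matrix is
    exactly symmetric. Returns one :class:`GLCMatrix` per angle, in the
    order of ``config.angles``.

    Raises
    ------
    InsufficientPairsError
        If an angle yields no valid pair (mask too small or thin).
    """
    q = np.asarray(q)
    g = config.levels
    d = config.distance
    out = []
    for angle in config.angles:
        dr, dc = ANGLE_OFFSETS[angle]
        dr, dc = dr * d, dc * d
        h, w = q.shape
        # slice the grid into the "from" and "to" pixel of every offset pair
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = q[r0:r1, c0:c1]
        b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = (a != EXCLUDED) & (b != EXCLUDED)
        ai, bi = a[valid], b[valid]
        counts = np.bincount(ai * g + bi, minlength=g * g).reshape(g, g).astype(np.int64)
        if config.symmetric:
            counts = counts + counts.T
        total = counts.sum()
        if total == 0:
            raise InsufficientPairsError(
                f"no valid pixel pair at angle {angle} deg, distance {d}"
            )
        out.append(GLCMatrix(p=counts / total, counts=counts, config=config))
    return out


def _level_diff_sq(g: int) -> np.ndarray:
    i = np.arange(g)
    return (i[:, None] - i[None, :]) ** 2


def uniformity(m: GLCMatrix) -> float:
    """Angular second moment: sum of squared co-occurrence probabilities."""
    return float((m.p**2).sum())


def contrast(m: GLCMatrix) -> float:
    """Mean squared grey-level difference of co-occurring pairs."""
    return float((_level_diff_sq(m.config.levels) * m.p).sum())


def homogeneity(m: GLCMatrix) -> float:
    """Inverse difference moment (or 1/(1+|i-j|) if configured)."""
    g = m.config.levels
    if m.config.homogeneity_form == "squared":
        wts = 1.0 / (1.0 + _level_diff_sq(g))
    else:
        i = np.arange(g)
        wts = 1.0 / (1.0 + np.abs(i[:, None] - i[None, :]))
    return float((wts * m.p).sum())


def entropy(m: GLCMatrix) -> float:
    """Shannon entropy of the co-occurrence distribution (bits by default)."""
    p = m.p[m.p > 0]
    return float(-(p * (np.log(p) / np.log(m.config.log_base))).sum())


def features_of_matrix(m: GLCMatrix) -> TextureFeatures:
    return TextureFeatures(
        uniformity=uniformity(m),
        contrast=contrast(m),
        homogeneity=homogeneity(m),
        entropy=entropy(m),
    )


def texture_features(gray: np.ndarray, mask: np.ndarray, config: GLCMConfig | None = None) -> TextureFeatures:
    """GLCM features of the masked grey image, averaged over configured angles.

    The per-angle scalar features (not the matrices) are averaged, so the
    result with a single angle equals the individual feature functions
    composed.
    """
    config = config or GLCMConfig()
    q = quantize(gray, mask, config.levels)
    mats = cooccurrence(q, config)
    feats = [features_of_matrix(m) for m in mats]
    return TextureFeatures(
        uniformity=float(np.mean([f.uniformity for f in feats])),
        contrast=float(np.mean([f.contrast for f in feats])),
        homogeneity=float(np.mean([f.homogeneity for f in feats])),
        entropy=float(np.mean([f.entropy for f in feats])),
    )
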