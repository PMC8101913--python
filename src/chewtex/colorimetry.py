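"""Variance of hue (VOH): the colour-mixing score of a chewed specimen.

A two-colour gum bolus that has been kneaded well converges to a single
intermediate colour; its hue distribution tightens and VOH falls. The default
estimator is the circular variance ``1 - R_bar``, where ``R_bar`` is the
length of the mean unit vector of the hue angles — hue is an angle, so
linear variance would depend on where the 0/2pi cut falls. A linear mode
(sample variance of hue expressed as a fraction of a turn) is provided for
comparability with tools that treat hue as a plain number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoChromaticPixelsError
from .image_io import HSIImage
from .segmentation import require_nonempty

DEFAULT_SAT_THRESHOLD = 0.15  # shared with segmentation: one chromaticity knob


@dataclass(frozen=True)
class HueSample:
    """Defined hue angles of the chromatic in-mask pixels.

    ``n + excluded`` equals the mask area; ``excluded`` counts in-mask
    pixels whose saturation fell at or below the threshold.
    """

    hues: np.ndarray
    n: int
    excluded: int


def hue_field(hsi: HSIImage, mask: np.ndarray, sat_threshold: float = DEFAULT_SAT_THRESHOLD) -> HueSample:
    """Collect hue angles of in-mask pixels with saturation above threshold.

    Raises
    ------
    NoChromaticPixelsError
        If every in-mask pixel is achromatic at this threshold.
    """
    mask = require_nonempty(mask)
    if hsi.shape != mask.shape:
        raise ValueError(f"HSI shape {hsi.shape} != mask shape {mask.shape}")
    chromatic = mask & (hsi.saturation > sat_threshold)
    n = int(chromatic.sum())
    if n == 0:
        raise NoChromaticPixelsError(
            f"no in-mask pixel with saturation > {sat_threshold}"
        )
    return HueSample(hues=hsi.hue[chromatic], n=n, excluded=int(mask.sum()) - n)


def voh(sample: HueSample, method: str = "circular") -> float:
    """Variance of hue of a :class:`HueSample`.

    circular (default)
        ``1 - R_bar`` with ``R_bar = |mean(exp(i * h))|``; in [0, 1],
        0 iff all hues coincide, 1 when the mean hue vector vanishes.
    linear
        Sample variance (n-1 denominator) of hue mapped to [0, 1) turns.

    Raises
    ------
    ValueError
        On an empty sample or unknown method.
    """
    hues = np.asarray(sample.hues, dtype=float)
    if hues.size == 0:
        raise ValueError("empty hue sample")
    if method == "circular":
        rbar = float(np.hypot(np.cos(hues).mean(), np.sin(hues).mean()))
        return 1.0 - min(rbar, 1.0)
    if method == "linear":
        turns = np.mod(hues, 2.0 * np.pi) / (2.0 * np.pi)
        return float(turns.var(ddof=1)) if turns.size > 1 else 0.0
    raise ValueError(f"unknown VOH method {method!r}")


def unmixed_voh(hue_gap: float) -> float:
    """Closed-form circular VOH of an equal-area two-colour specimen.

    Two hues separated by ``hue_gap`` radians in equal proportion have mean
    vector length ``cos(hue_gap / 2)``, hence VOH ``1 - cos(hue_gap / 2)``.
    """
    return 1.0 - np.cos(hue_gap / 2.0)
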