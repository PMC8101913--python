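"""Seeded simulator of two-colour chewing-gum specimens.

The real measurement chain photographs a flattened gum bolus whose two
colour layers have been kneaded together to a degree that reflects
masticatory efficiency. No study images are deposited, so this module
generates specimens with a *known* ground-truth mixing degree, which is what
makes every downstream stage (segmentation, GLCM texture, variance of hue,
longitudinal statistics) testable end to end.

Model
-----
An unchewed specimen is a rounded-rectangle slab of two equal colour layers
joined lengthwise (pink above, green below) on an achromatic background.
The gum surface is given a fine multiplicative intensity mottle — real gum
is embossed and granular, not optically flat. The mottle scales all three
RGB channels by the same factor, so it perturbs brightness while leaving
hue exactly unchanged: the unchewed specimen contains exactly two hues.

Chewing is emulated as ``cycles`` repetitions of

1. a feathered swap of two random in-specimen patches (bulk transport of
   material, colour mass conserved exactly), then
2. a masked Gaussian blur (local colour diffusion / smearing),

followed by one addition of clipped Gaussian sensor noise. Diffusion
monotonically erodes both the surface mottle and the colour boundary, so in
expectation GLCM contrast falls and homogeneity rises with cycles, while
the hue distribution tightens and VOH falls — the directions the texture
and colorimetric analyses are designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ChewtexError
from .image_io import save_image

#: Green (peppermint) layer: hue exactly 120 deg (R = B forces it).
DEFAULT_COLOR_A = (0.1463, 0.6974, 0.1463)
#: Pink (strawberry) layer: hue exactly 330 deg. The two layer colours are
#: constructed with (a) the same chroma radius (distance from the grey
#: axis), so convex blends keep the circular mean hue on their bisector —
#: colour mixing changes hue dispersion, not direction — and (b) the same
#: Rec. 601 luma, so the grey-level texture reflects the gum's surface
#: relief rather than a brightness difference between the two colours.
DEFAULT_COLOR_B = (0.8797, 0.2433, 0.5615)


def _hue_of(rgb: tuple[float, float, float]) -> float:
    r, g, b = rgb
    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    theta = np.arccos(np.clip(num / den, -1, 1))
    return float(2 * np.pi - theta if b > g else theta)


@dataclass(frozen=True)
class SpecimenSpec:
    """Geometry, colours and surface texture of a gum specimen.

    Dimensions follow the physical test sample: two 30 mm strips joined
    lengthwise into a 30 x 18 mm slab (the 3 mm thickness is irrelevant to
    a photograph of the flattened piece). ``px_per_mm`` sets the rendering
    resolution; 10 px/mm keeps a full study under a minute to generate.

    ``surface_texture_amp`` is the standard deviation of the multiplicative
    intensity mottle (0 disables it and the layers become two flat colours);
    ``surface_texture_scale_mm`` its correlation length.
    """

    width_mm: float = 30.0
    height_mm: float = 18.0
    px_per_mm: float = 10.0
    corner_radius_mm: float = 2.0
    margin_mm: float = 3.0
    color_a: tuple[float, float, float] = DEFAULT_COLOR_A
    color_b: tuple[float, float, float] = DEFAULT_COLOR_B
    background: tuple[float, float, float] = (1.0, 1.0, 1.0)
    surface_texture_amp: float = 0.06
    surface_texture_scale_mm: float = 1.0

    @property
    def hue_gap(self) -> float:
        """Angular separation of the two layer hues, in (0, pi]."""
        d = abs(_hue_of(self.color_a) - _hue_of(self.color_b))
        return float(min(d, 2 * np.pi - d))


@dataclass(frozen=True)
class MixingParams:
    """Parameters of the emulated chewing process.

    ``cycles`` is the number of effective kneading strokes (the clinical
    protocol prescribes 20 chew cycles; an inefficient chewer realises
    fewer *effective* ones). Each cycle performs ``swaps_per_cycle``
    feathered patch swaps — chewing folds material wholesale, so transport
    per stroke is substantial — followed by one diffusion pass.
    ``patch_fraction`` sizes each transported patch relative to the
    specimen's short axis, ``blur_sigma`` (in mm — a physical smearing
    scale, converted to pixels at rendering time so mixing dynamics do not
    depend on image resolution) is the per-cycle diffusion scale, and
    ``noise_sd`` the per-channel sensor noise added once at the end. With
    the defaults, 20 cycles reduce the specimen to a nearly single-colour
    bolus (VOH of order 0.1, down from 0.74 unmixed).
    """

    cycles: int = 20
    swaps_per_cycle: int = 4
    patch_fraction: float = 0.35
    blur_sigma: float = 0.15
    noise_sd: float = 0.005
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _rounded_rect_mask(h: int, w: int, r: float) -> np.ndarray:
    rows, cols = np.ogrid[:h, :w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    dy = np.maximum(np.abs(rows - cy) - (h / 2.0 - r), 0.0)
    dx = np.maximum(np.abs(cols - cx) - (w / 2.0 - r), 0.0)
    return dy**2 + dx**2 <= r**2


def make_unchewed(spec: SpecimenSpec = SpecimenSpec(), seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Render an unchewed two-layer specimen.

    Returns ``(image, mask)``: the RGB image (specimen on background, with
    surface mottle if configured) and the painted ground-truth boolean mask.

    Raises
    ------
    ChewtexError
        If the resolution yields fewer than 100 specimen pixels.
    """
    ppm = spec.px_per_mm
    sh, sw = int(round(spec.height_mm * ppm)), int(round(spec.width_mm * ppm))
    margin = int(round(spec.margin_mm * ppm))
    r = spec.corner_radius_mm * ppm

    smask = _rounded_rect_mask(sh, sw, r)
    if smask.sum() < 100:
        raise ChewtexError(
            f"resolution too low: specimen has {int(smask.sum())} px (< 100)"
        )

    h, w = sh + 2 * margin, sw + 2 * margin
    mask = np.zeros((h, w), dtype=bool)
    mask[margin : margin + sh, margin : margin + sw] = smask

    img = np.empty((h, w, 3), dtype=float)
    img[:] = spec.background
    # two layers joined lengthwise: pink (color_b) above, green (color_a) below
    upper = np.zeros_like(mask)
    upper[: h // 2] = True
    img[mask & upper] = spec.color_b
    img[mask & ~upper] = spec.color_a

    if spec.surface_texture_amp > 0:
        rng = np.random.default_rng(seed)
        sigma = max(spec.surface_texture_scale_mm * ppm, 0.5)
        field_ = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma)
        sd = field_.std()
        if sd > 0:
            field_ *= spec.surface_texture_amp / sd
        # clip the factor so no channel can leave [0,1]: hue stays exact
        headroom = 1.0 / max(max(spec.color_a), max(spec.color_b)) - 1.0
        lim = min(2.0 * spec.surface_texture_amp, headroom)
        factor = 1.0 + np.clip(field_, -lim, lim)
        img[mask] *= factor[mask, None]

    return img, mask


def _masked_blur(img: np.ndarray, mask: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian diffusion confined to the mask (normalized convolution)."""
    weight = ndimage.gaussian_filter(mask.astype(float), sigma)
    out = img.copy()
    for c in range(3):
        num = ndimage.gaussian_filter(np.where(mask, img[..., c], 0.0), sigma)
        out[..., c] = np.where(mask & (weight > 0), num / np.where(weight > 0, weight, 1.0), img[..., c])
    return out


def apply_mixing(
    img: np.ndarray, mask: np.ndarray, params: MixingParams, px_per_mm: float = 10.0
) -> np.ndarray:
    """Emulate chewing on an unchewed specimen image.

    ``px_per_mm`` must match the resolution the image was rendered at; it
    converts the physical diffusion scale ``params.blur_sigma`` (mm) to
    pixels. ``cycles = 0`` with ``noise_sd = 0`` returns the image
    unchanged. Colour mass inside the mask is conserved exactly by patch
    swaps and approximately (boundary renormalisation only) by the
    diffusion steps.
    """
    img = np.asarray(img, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if img.shape[:2] != mask.shape:
        raise ValueError("image and mask dimensions differ")

    rng = np.random.default_rng(params.seed)
    out = img.copy()
    h, w = mask.shape

    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    short_axis = min(rows.size, cols.size)
    side = max(2, int(round(params.patch_fraction * short_axis)))
    side = min(side, h, w)
    # feathered blend window (separable Hann), peak weight < 1
    hann = np.hanning(side + 2)[1:-1]
    alpha = 0.9 * hann[:, None] * hann[None, :]

    in_rows, in_cols = np.nonzero(mask)
    n_px = in_rows.size
    sigma_px = params.blur_sigma * px_per_mm

    for _ in range(params.cycles):
        for _ in range(params.swaps_per_cycle):
            idx = rng.integers(0, n_px, size=2)
            patches = []
            for k in idx:
                r0 = int(np.clip(in_rows[k] - side // 2, 0, h - side))
                c0 = int(np.clip(in_cols[k] - side // 2, 0, w - side))
                patches.append((r0, c0))
            (r1, c1), (r2, c2) = patches
            m1 = mask[r1 : r1 + side, c1 : c1 + side]
            m2 = mask[r2 : r2 + side, c2 : c2 + side]
            a = (alpha * (m1 & m2))[..., None]
            p1 = out[r1 : r1 + side, c1 : c1 + side].copy()
            p2 = out[r2 : r2 + side, c2 : c2 + side].copy()
            out[r1 : r1 + side, c1 : c1 + side] = (1 - a) * p1 + a * p2
            out[r2 : r2 + side, c2 : c2 + side] = (1 - a) * p2 + a * p1

        if sigma_px > 0:
            out = _masked_blur(out, mask, sigma_px)

    if params.noise_sd > 0:
        out = out + rng.normal(0.0, params.noise_sd, size=out.shape)
    return np.clip(out, 0.0, 1.0)


def chewed_specimen(
    spec: SpecimenSpec, params: MixingParams, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: render an unchewed specimen and chew it in one call.

    ``seed`` drives the surface mottle; ``params.seed`` the chewing; pass
    one integer via :func:`numpy.random.SeedSequence` spawning for full
    determinism across both.
    """
    ss = np.random.SeedSequence(seed)
    s_surf, s_mix = ss.spawn(2)
    img, mask = make_unchewed(spec, seed=s_surf.generate_state(1)[0])
    if params.seed is None:
        params = replace(params, seed=int(s_mix.generate_state(1)[0] % (2**31)))
    return apply_mixing(img, mask, params, px_per_mm=spec.px_per_mm), mask


#: Effective kneading strokes (mean, sd) per follow-up time. At denture
#: delivery (T0) little of the prescribed 20-cycle chewing is effective;
#: by 6 months (T2) most of it is.
IMPROVING_PROFILE: dict[str, tuple[float, float]] = {
    "T0": (4.0, 2.0),
    "T1": (12.0, 3.0),
    "T2": (20.0, 4.0),
}

#: No change over time: every visit draws from the T0 distribution.
NULL_PROFILE: dict[str, tuple[float, float]] = {
    "T0": (8.0, 3.0),
    "T1": (8.0, 3.0),
    "T2": (8.0, 3.0),
}


def generate_study(
    out_dir: str | Path,
    n_subjects: int = 18,
    times: tuple[str, ...] = ("T0", "T1", "T2"),
    effect_profile: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    spec: SpecimenSpec = SpecimenSpec(),
    mixing: MixingParams = MixingParams(),
    replicates: int = 2,
    sides: tuple[str, ...] = ("upper", "lower"),
    subject_sd: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full longitudinal study and write its images to disk.

    Every subject chews ``replicates`` gum samples at each time point; each
    chewed sample is photographed from both sides. A sample's effective
    cycle count is ``mu_t + a_s + e`` (rounded, floored at 0) with a
    per-subject ability ``a_s ~ N(0, subject_sd)`` shared across visits and
    ``e ~ N(0, sd_t)`` per sample; the two sides are two independent mixing
    realizations of that same count. With the defaults this yields
    18 x 3 x 2 = 108 chewed samples and 216 images.

    Writes ``<subject>_<time>_r<rep>_<side>.png`` files plus
    ``manifest.csv`` (subject, time, side, replicate, path) and
    ``ground_truth.csv`` (adds the realized cycle count). Returns the two
    tables. Deterministic under ``seed``.

    Raises
    ------
    ValueError
        If ``n_subjects < 2`` or the profile does not cover every time.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    profile = effect_profile or IMPROVING_PROFILE
    missing = [t for t in times if t not in profile]
    if missing:
        raise ValueError(f"effect_profile missing times: {missing}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(seed)
    ability_rng = np.random.default_rng(root_ss.spawn(1)[0])
    abilities = ability_rng.normal(0.0, subject_sd, size=n_subjects)

    manifest_rows, truth_rows = [], []
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        subj_ss = np.random.SeedSequence(entropy=seed, spawn_key=(1, s))
        subj_rng = np.random.default_rng(subj_ss)
        for t in times:
            mu, sd = profile[t]
            for rep in range(1, replicates + 1):
                cycles = max(0, int(round(subj_rng.normal(mu + abilities[s], sd))))
                for side in sides:
                    img_seed = int(subj_rng.integers(0, 2**31))
                    img, _ = chewed_specimen(
                        spec, replace(mixing, cycles=cycles, seed=None), seed=img_seed
                    )
                    name = f"{subject}_{t}_r{rep}_{side}.png"
                    save_image(out_dir / name, img)
                    row = {
                        "subject": subject,
                        "time": t,
                        "side": side,
                        "replicate": rep,
                        "path": name,
                    }
                    manifest_rows.append(row)
                    truth_rows.append({**row, "cycles": cycles})

    manifest = pd.DataFrame(manifest_rows)
    truth = pd.DataFrame(truth_rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return manifest, truth
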