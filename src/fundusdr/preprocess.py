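"""Fundus-region masking and the three image-enhancement pipelines.

Three complementary enhancement methods are provided, each with per-stage
on/off flags so the contribution of every stage can be ablated without a
separate code path:

``ASE`` (adaptive sigmoid enhancement)
    Grayscale conversion, tile-based contrast-limited adaptive histogram
    equalization (CLAHE), Gaussian smoothing, a pixelwise sigmoid contrast
    map centered on the local (per-tile) median, additive blending of
    morphological top-hat / bottom-hat edge-and-spot maps, and a final
    percentile contrast stretch.

``LAB_ACE`` (lightness-channel adaptive contrast enhancement)
    CLAHE applied to the L channel of the LAB color space, restricted to the
    fundus mask; chromatic channels and all pixels outside the mask are left
    byte-identical to the input.

``MIE`` (multi-channel image enhancement)
    Per-channel processing: green-channel gain, percentile contrast stretch
    of each channel within a circular fundus mask, recombination and a final
    gamma adjustment; everything outside the mask is set to black.

All intermediate arithmetic is floating point; quantization to bytes happens
only at the output, which keeps the masked-identity and stretch-endpoint
contracts exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import exposure, morphology
from skimage.transform import resize

from .types import (
    EmptyMaskError,
    EnhancedImage,
    FundusImage,
    FundusMask,
    InvalidSpecError,
    as_rgb_array,
    image_id,
)

__all__ = [
    "ASEParams",
    "LabAceParams",
    "MIEParams",
    "EnhanceParams",
    "estimate_fundus_mask",
    "adaptive_sigmoid_enhance",
    "lab_ace_enhance",
    "multichannel_enhance",
    "enhance",
    "to_grayscale",
    "percentile_stretch",
]

_CLAHE_NBINS = 256


@dataclass
class ASEParams:
    """Parameters of the adaptive sigmoid enhancement pipeline.

    ``clip_limit`` follows the common convention of multiples of the uniform
    histogram bin height (2.0 clips at twice the flat-histogram level).
    ``blend_weights`` are the additive weights of (image, top-hat,
    bottom-hat); the negative bottom-hat weight darkens small dark spots.
    """

    tile_grid: tuple[int, int] = (8, 8)
    clip_limit: float = 2.0
    smooth_sigma: float = 1.0
    sigmoid_gain: float = 8.0
    sigmoid_center_policy: str = "tile_median"  # "tile_median" | "global_median" | "fixed"
    sigmoid_center_fixed: float = 127.5
    morph_element_radius: int = 7
    blend_weights: tuple[float, float, float] = (1.0, 0.5, -0.5)
    final_stretch_percentiles: tuple[float, float] = (1.0, 99.0)
    # stage flags (grayscale conversion is always applied)
    clahe: bool = True
    smooth: bool = True
    sigmoid: bool = True
    morphology: bool = True
    stretch: bool = True

    def validate(self) -> None:
        _check_common(self.clip_limit, self.final_stretch_percentiles)
        for v in (self.smooth_sigma, self.sigmoid_gain):
            if not np.isfinite(v):
                raise InvalidSpecError("ASE parameters must be finite")
        if self.sigmoid_gain <= 0:
            raise InvalidSpecError("sigmoid_gain must be > 0")
        if self.sigmoid_center_policy not in ("tile_median", "global_median", "fixed"):
            raise InvalidSpecError(
                f"unknown sigmoid_center_policy {self.sigmoid_center_policy!r}"
            )


@dataclass
class LabAceParams:
    """Parameters of the LAB lightness-channel CLAHE pipeline."""

    mask_threshold: str = "otsu"
    clip_limit: float = 2.0
    tile_grid: tuple[int, int] = (8, 8)
    clahe: bool = True

    def validate(self) -> None:
        _check_common(self.clip_limit, (0.0, 100.0))


@dataclass
class MIEParams:
    """Parameters of the multi-channel enhancement pipeline."""

    green_gain: float = 1.2
    stretch_percentiles: tuple[float, float] = (1.0, 99.0)
    final_gamma: float = 0.9
    mask_threshold: str = "otsu"
    gain_stage: bool = True
    stretch: bool = True
    gamma_stage: bool = True

    def validate(self) -> None:
        _check_common(1.0, self.stretch_percentiles)
        if not (np.isfinite(self.green_gain) and self.green_gain > 0):
            raise InvalidSpecError("green_gain must be finite and > 0")
        if not (np.isfinite(self.final_gamma) and self.final_gamma > 0):
            raise InvalidSpecError("final_gamma must be finite and > 0")


@dataclass
class EnhanceParams:
    """Bundle of the per-method parameter records."""

    ase: ASEParams = field(default_factory=ASEParams)
    lab_ace: LabAceParams = field(default_factory=LabAceParams)
    mie: MIEParams = field(default_factory=MIEParams)


def _check_common(clip_limit: float, percentiles: tuple[float, float]) -> None:
    if not (np.isfinite(clip_limit) and clip_limit > 0):
        raise InvalidSpecError("clip limit must be finite and > 0")
    lo, hi = percentiles
    if not (0 <= lo < hi <= 100):
        raise InvalidSpecError("percentiles must satisfy 0 <= low < high <= 100")


def to_grayscale(image: FundusImage | EnhancedImage | np.ndarray) -> np.ndarray:
    """Luma grayscale conversion to a float array on the [0, 255] scale."""
    rgb = as_rgb_array(image)
    return skcolor.rgb2gray(rgb) * 255.0


def estimate_fundus_mask(image: FundusImage | EnhancedImage | np.ndarray,
                         threshold_policy: str = "otsu") -> FundusMask:
    """Locate the bright circular retina region of a fundus photograph.

    The red channel (brightest over the retina) is thresholded at Otsu's
    level, the largest connected component is kept and hole-filled, and the
    largest inscribed circle is reported via a Euclidean distance transform.
    """
    if threshold_policy != "otsu":
        raise InvalidSpecError(f"unknown mask threshold policy {threshold_policy!r}")
    rgb = as_rgb_array(image)
    red = rgb[:, :, 0].astype(float)
    if red.max() == red.min():
        if red.max() == 0:
            raise EmptyMaskError("image is uniformly black; no fundus foreground")
        fg = np.ones_like(red, dtype=bool)
    else:
        from skimage.filters import threshold_otsu

        fg = red > threshold_otsu(red)
    if not fg.any():
        raise EmptyMaskError("no pixels above the foreground threshold")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        fg = labels == (int(np.argmax(sizes)) + 1)
    fg = ndimage.binary_fill_holes(fg)
    dist = ndimage.distance_transform_edt(fg)
    idx = np.unravel_index(int(np.argmax(dist)), dist.shape)
    return FundusMask(mask=fg, center=(float(idx[0]), float(idx[1])),
                      radius=float(dist[idx]))


def _tile_map(values: np.ndarray, tile_grid: tuple[int, int],
              stat=np.median) -> np.ndarray:
    """Per-tile statistic bilinearly resampled back to full resolution."""
    h, w = values.shape
    gy, gx = tile_grid
    gy, gx = min(gy, h), min(gx, w)
    stats = np.empty((gy, gx))
    ys = np.linspace(0, h, gy + 1).astype(int)
    xs = np.linspace(0, w, gx + 1).astype(int)
    for i in range(gy):
        for j in range(gx):
            stats[i, j] = stat(values[ys[i]:ys[i + 1], xs[j]:xs[j + 1]])
    return resize(stats, values.shape, order=1, mode="edge", anti_aliasing=False)


def _clahe(values01: np.ndarray, tile_grid: tuple[int, int],
           clip_limit: float) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0,1] raster."""
    h, w = values01.shape
    kernel = (max(h // tile_grid[0], 1), max(w // tile_grid[1], 1))
    if values01.max() == values01.min():
        # histogram equalization of a flat field is a flat field
        return values01.copy()
    return exposure.equalize_adapthist(
        np.clip(values01, 0, 1), kernel_size=kernel,
        clip_limit=clip_limit / _CLAHE_NBINS, nbins=_CLAHE_NBINS,
    )


def adaptive_sigmoid_enhance(image: FundusImage | EnhancedImage | np.ndarray,
                             params: ASEParams | None = None) -> EnhancedImage:
    """Adaptive sigmoid enhancement; output is a single grayscale channel.

    Stage order: grayscale -> CLAHE -> Gaussian smoothing -> pixelwise
    sigmoid ``s(x) = 255 / (1 + exp(-g (x - c) / 255))`` with the center ``c``
    taken from the local tile median -> additive top-hat / bottom-hat
    blending -> percentile contrast stretch. Any optional stage can be
    disabled; it is then recorded as skipped in the stage trace.
    """
    params = params or ASEParams()
    params.validate()
    x = to_grayscale(image)
    trace = ["grayscale"]

    if params.clahe:
        x = _clahe(x / 255.0, params.tile_grid, params.clip_limit) * 255.0
        trace.append("clahe")
    else:
        trace.append("skipped:clahe")

    if params.smooth:
        x = ndimage.gaussian_filter(x, params.smooth_sigma)
        trace.append("smooth")
    else:
        trace.append("skipped:smooth")

    if params.sigmoid:
        if params.sigmoid_center_policy == "tile_median":
            c = _tile_map(x, params.tile_grid)
        elif params.sigmoid_center_policy == "global_median":
            c = np.full_like(x, np.median(x))
        else:
            c = np.full_like(x, params.sigmoid_center_fixed)
        x = 255.0 / (1.0 + np.exp(-params.sigmoid_gain * (x - c) / 255.0))
        trace.append("sigmoid")
    else:
        trace.append("skipped:sigmoid")

    if params.morphology:
        footprint = morphology.disk(params.morph_element_radius)
        tophat = morphology.white_tophat(x, footprint=footprint)
        bothat = morphology.black_tophat(x, footprint=footprint)
        w_img, w_top, w_bot = params.blend_weights
        x = w_img * x + w_top * tophat + w_bot * bothat
        trace.append("morphology")
    else:
        trace.append("skipped:morphology")

    if params.stretch:
        lo, hi = np.percentile(x, params.final_stretch_percentiles)
        if hi > lo:
            x = (x - lo) / (hi - lo) * 255.0
        trace.append("stretch")
    else:
        trace.append("skipped:stretch")

    return EnhancedImage(pixels=np.clip(np.round(x), 0, 255).astype(np.uint8),
                         method="ASE", params=asdict(params), stage_trace=trace,
                         id=image_id(image))


def lab_ace_enhance(image: FundusImage | EnhancedImage | np.ndarray,
                    params: LabAceParams | None = None) -> EnhancedImage:
    """CLAHE on the LAB lightness channel, restricted to the fundus mask.

    Chromatic (a, b) channels are untouched and every pixel outside the mask
    is byte-identical to the input — the enhancement never leaks into the
    dark camera surround.
    """
    params = params or LabAceParams()
    params.validate()
    rgb = as_rgb_array(image)
    fmask = estimate_fundus_mask(rgb, params.mask_threshold)
    trace = ["mask"]

    lab = skcolor.rgb2lab(rgb / 255.0)  # D65 reference white
    trace.append("rgb2lab")
    L = lab[:, :, 0]
    if params.clahe:
        L_eq = _clahe(L / 100.0, params.tile_grid, params.clip_limit) * 100.0
        lab[:, :, 0] = np.where(fmask.mask, L_eq, L)
        trace.append("clahe_L")
    else:
        trace.append("skipped:clahe_L")
    out = skcolor.lab2rgb(lab)
    trace.append("lab2rgb")
    out = np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)
    out[~fmask.mask] = rgb[~fmask.mask]  # exact byte identity outside the fundus
    return EnhancedImage(pixels=out, method="LAB_ACE", params=asdict(params),
                         stage_trace=trace, id=image_id(image))


def percentile_stretch(channel: np.ndarray, mask: np.ndarray,
                       percentiles: tuple[float, float]
                       ) -> tuple[np.ndarray, tuple[float, float]]:
    """Linear contrast stretch of a float channel within a mask.

    The masked ``percentiles[0]`` value maps to 0 and the ``percentiles[1]``
    value to 255, linearly in between and clipped outside; the anchor values
    are returned so callers can audit the mapping. Pixels outside the mask
    are passed through unchanged (the caller decides their fate).
    """
    vals = channel[mask]
    lo, hi = np.percentile(vals, percentiles)
    out = channel.astype(float).copy()
    if hi > lo:
        out[mask] = np.clip((channel[mask] - lo) / (hi - lo) * 255.0, 0, 255)
    return out, (float(lo), float(hi))


def multichannel_enhance(image: FundusImage | EnhancedImage | np.ndarray,
                         params: MIEParams | None = None) -> EnhancedImage:
    """Per-channel enhancement centered on the vessel-rich green channel.

    Channels are separated, the green channel amplified, each channel
    percentile-stretched within the circular fundus mask, recombined, and a
    final gamma adjustment applied; pixels outside the mask are black.
    """
    params = params or MIEParams()
    params.validate()
    rgb = as_rgb_array(image).astype(float)
    fmask = estimate_fundus_mask(rgb.astype(np.uint8), params.mask_threshold)
    if fmask.area == 0:
        raise EmptyMaskError("degenerate fundus mask")
    trace = ["split", "mask"]

    channels = [rgb[:, :, k].copy() for k in range(3)]
    if params.gain_stage:
        channels[1] = np.clip(channels[1] * params.green_gain, 0, 255)
        trace.append("green_gain")
    else:
        trace.append("skipped:green_gain")

    if params.stretch:
        channels = [percentile_stretch(ch, fmask.mask, params.stretch_percentiles)[0]
                    for ch in channels]
        trace.append("stretch")
    else:
        trace.append("skipped:stretch")

    out = np.stack(channels, axis=2)
    trace.append("recombine")

    if params.gamma_stage:
        out = 255.0 * np.power(np.clip(out, 0, 255) / 255.0, params.final_gamma)
        trace.append("gamma")
    else:
        trace.append("skipped:gamma")

    out[~fmask.mask] = 0.0
    out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    return EnhancedImage(pixels=out, method="MIE", params=asdict(params),
                         stage_trace=trace, id=image_id(image))


_METHODS = {
    "ase": adaptive_sigmoid_enhance,
    "labace": lab_ace_enhance,
    "mie": multichannel_enhance,
}


def enhance(image, method: str, params: EnhanceParams | None = None) -> EnhancedImage:
    """Dispatch to one of the enhancement pipelines by short method name."""
    key = method.lower().replace("_", "").replace("-", "")
    if key not in _METHODS:
        raise InvalidSpecError(f"unknown enhancement method {method!r}")
    params = params or EnhanceParams()
    sub = {"ase": params.ase, "labace": params.lab_ace, "mie": params.mie}[key]
    return _METHODS[key](image, sub)
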