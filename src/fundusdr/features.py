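"""Handcrafted descriptors for diabetic-retinopathy grading.

Three families of descriptors are computed:

* texture — uniform local binary pattern (LBP) histograms, gray-level
  co-occurrence (GLCM/Haralick) statistics, and Gabor filter-bank response
  statistics;
* morphological / lesion-specific — circular Hough detection of small dark
  lesions (microaneurysm and hemorrhage analogues), thresholded bright-blob
  (exudate) area, and bottom-hat vessel area;
* intensity and edge — the classical seven order statistics per channel plus
  Canny edge density and Sobel gradient-magnitude statistics.

``extract_handcrafted`` assembles these into one of three fixed, named
layouts; ``CUSTOM90`` is the 90-dimensional custom vector used for fusion
with the deep backbone. Every extractor is deterministic and operates on a
standardized square resize of the input so fragment lengths never depend on
the source resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sstats
from skimage import feature as skfeature
from skimage import filters as skfilters
from skimage import morphology as skmorph
from skimage import transform as sktransform

from .types import (
    EmptyMaskError,
    EnhancedImage,
    FeatureVector,
    FundusImage,
    FundusMask,
    InvalidSpecError,
    as_rgb_array,
    image_id,
)
from .preprocess import estimate_fundus_mask, to_grayscale

__all__ = [
    "FeatureConfig",
    "LesionDetections",
    "lbp_histogram",
    "glcm_features",
    "gabor_features",
    "hog_features",
    "detect_circular_lesions",
    "exudate_area",
    "vessel_area",
    "intensity_statistics",
    "edge_features",
    "extract_handcrafted",
    "GLCM_STAT_NAMES",
]


@dataclass
class FeatureConfig:
    """Free parameters of the handcrafted extractor.

    ``standardize_size`` is the square side every image is resized to before
    extraction, making all fragment lengths input-size independent. Circle
    detection, exudate and vessel parameters are expressed at that scale.
    """

    standardize_size: int = 512
    glcm_levels: int = 32
    glcm_offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))
    gabor_frequencies: tuple[float, ...] = (0.1, 0.2, 0.3)
    gabor_orientations: tuple[float, ...] = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
    hog_cell: int = 8
    hog_block: int = 2
    hog_bins: int = 9
    circle_radius_range: tuple[int, int] = (3, 12)
    circle_sensitivity: float = 0.6
    circle_inside_dark_min: float = 0.6
    circle_annulus_dark_max: float = 0.10
    exudate_threshold_offset: float = 20.0
    exudate_open_radius: int = 1
    exudate_close_radius: int = 2
    vessel_element_radius: int = 7
    vessel_min_size: int = 30


@dataclass
class LesionDetections:
    """Detected circular lesions plus area-based lesion measurements."""

    circles: list[tuple[int, int, int, float]]  # (row, col, radius, score)
    exudate_area_px: int = 0
    vessel_area_px: int = 0


# ---------------------------------------------------------------------------
# texture descriptors


def lbp_histogram(gray: np.ndarray, radius: int = 1, n_points: int = 8
                  ) -> tuple[np.ndarray, list[str]]:
    """Normalized uniform-LBP code histogram of length ``n_points + 2``.

    Codes are collected over interior pixels only (those with a complete
    neighborhood), so the histogram matches a direct per-pixel enumeration.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2:
        raise InvalidSpecError("lbp_histogram expects a 2-D grayscale raster")
    if min(gray.shape) < 2 * radius + 1:
        raise InvalidSpecError(
            f"image smaller than {2 * radius + 1} px cannot support LBP radius {radius}"
        )
    # integer codes: LBP comparisons on rounded byte intensities
    codes = skfeature.local_binary_pattern(
        np.round(gray).astype(np.int64), n_points, radius, method="uniform"
    )
    interior = codes[radius:gray.shape[0] - radius, radius:gray.shape[1] - radius]
    hist, _ = np.histogram(interior, bins=np.arange(n_points + 3) - 0.5)
    hist = hist.astype(float)
    hist /= hist.sum()
    names = [f"lbp_r{radius}_p{n_points}_u{k}" for k in range(n_points + 2)]
    return hist, names


GLCM_STAT_NAMES = (
    "contrast", "correlation", "energy", "homogeneity", "entropy",
    "dissimilarity", "asm", "cluster_shade", "cluster_prominence",
    "max_probability", "sum_average", "difference_variance",
)


def _quantize(gray: np.ndarray, levels: int) -> np.ndarray:
    g = np.asarray(gray, dtype=float)
    lo, hi = g.min(), g.max()
    if hi == lo:
        return np.zeros_like(g, dtype=np.intp)
    q = np.floor((g - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def _cooccurrence(q: np.ndarray, offset: tuple[int, int], levels: int) -> np.ndarray:
    """Symmetric, normalized gray-level co-occurrence matrix for one offset."""
    dr, dc = offset
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    mat = np.zeros((levels, levels))
    np.add.at(mat, (a, b), 1.0)
    mat = mat + mat.T  # symmetrize
    total = mat.sum()
    if total == 0:
        raise InvalidSpecError(f"offset {offset} yields no pixel pairs")
    return mat / total


def _haralick_stats(p: np.ndarray) -> dict[str, float]:
    levels = p.shape[0]
    i = np.arange(levels)[:, None] * np.ones((1, levels))
    j = i.T
    diff = i - j
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    var_i = float(((i - mu_i) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())
    asm = float((p**2).sum())
    if var_i > 0 and var_j > 0:
        corr = float((((i - mu_i) * (j - mu_j) * p).sum()) / np.sqrt(var_i * var_j))
    else:
        corr = 1.0  # degenerate single-level matrix: perfectly correlated
    nz = p[p > 0]
    # difference-index distribution P(|i-j| = k)
    k = np.arange(levels)
    p_diff = np.array([p[np.abs(diff) == kk].sum() for kk in k])
    diff_mean = float((k * p_diff).sum())
    return {
        "contrast": float((diff**2 * p).sum()),
        "correlation": corr,
        "energy": float(np.sqrt(asm)),
        "homogeneity": float((p / (1.0 + diff**2)).sum()),
        "entropy": float(-(nz * np.log2(nz)).sum()),
        "dissimilarity": float((np.abs(diff) * p).sum()),
        "asm": asm,
        "cluster_shade": float((((i - mu_i) + (j - mu_j)) ** 3 * p).sum()),
        "cluster_prominence": float((((i - mu_i) + (j - mu_j)) ** 4 * p).sum()),
        "max_probability": float(p.max()),
        "sum_average": float(((i + j) * p).sum()),
        "difference_variance": float(((k - diff_mean) ** 2 * p_diff).sum()),
    }


def glcm_features(gray: np.ndarray,
                  offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1)),
                  levels: int = 32,
                  average: bool = True) -> tuple[np.ndarray, list[str]]:
    """Haralick statistics of symmetric normalized co-occurrence matrices.

    Twelve statistics per offset; with ``average=True`` (the default) they
    are averaged over offsets, otherwise reported per offset.
    """
    if levels < 2:
        raise InvalidSpecError("GLCM requires at least 2 gray levels")
    q = _quantize(gray, levels)
    per_offset = []
    for off in offsets:
        p = _cooccurrence(q, off, levels)
        st = _haralick_stats(p)
        per_offset.append([st[name] for name in GLCM_STAT_NAMES])
    arr = np.asarray(per_offset)
    if average:
        values = arr.mean(axis=0)
        names = [f"glcm_{name}" for name in GLCM_STAT_NAMES]
    else:
        values = arr.ravel()
        names = [f"glcm_{name}_off{dr}_{dc}"
                 for (dr, dc) in offsets for name in GLCM_STAT_NAMES]
        # reorder: per_offset rows are offset-major already
        names = [f"glcm_{name}_off{dr}_{dc}"
                 for (dr, dc) in offsets for name in GLCM_STAT_NAMES]
    return values, names


def glcm_cooccurrence(gray: np.ndarray, offset: tuple[int, int],
                      levels: int) -> np.ndarray:
    """Expose the symmetric normalized co-occurrence matrix (for auditing)."""
    return _cooccurrence(_quantize(gray, levels), offset, levels)


def gabor_features(gray: np.ndarray,
                   frequencies: tuple[float, ...] = (0.1, 0.2, 0.3),
                   orientations: tuple[float, ...] = (0.0, np.pi / 4, np.pi / 2,
                                                      3 * np.pi / 4)
                   ) -> tuple[np.ndarray, list[str]]:
    """Mean and standard deviation of Gabor response magnitude per (f, theta)."""
    if len(frequencies) == 0 or len(orientations) == 0:
        raise InvalidSpecError("need at least one frequency and one orientation")
    if any(f <= 0 for f in frequencies):
        raise InvalidSpecError("Gabor frequencies must be positive")
    g = np.asarray(gray, dtype=float)
    values, names = [], []
    for f in frequencies:
        for theta in orientations:
            real, imag = skfilters.gabor(g, frequency=f, theta=theta)
            mag = np.hypot(real, imag)
            deg = int(round(np.degrees(theta)))
            values.extend([float(mag.mean()), float(mag.std())])
            names.extend([f"gabor_f{f:g}_o{deg}_mean", f"gabor_f{f:g}_o{deg}_std"])
    return np.asarray(values), names


def hog_features(gray: np.ndarray, cell: int = 8, block: int = 2, bins: int = 9,
                 pooled: bool = False) -> tuple[np.ndarray, list[str]]:
    """Block-normalized histogram-of-oriented-gradients descriptor.

    With ``pooled=True`` the per-block histograms are averaged over the
    spatial block grid, giving a fixed ``block * block * bins`` vector
    regardless of image size.
    """
    g = np.asarray(gray, dtype=float)
    if min(g.shape) < cell:
        raise InvalidSpecError("HOG cell larger than the image")
    vec = skfeature.hog(
        g, orientations=bins, pixels_per_cell=(cell, cell),
        cells_per_block=(block, block), block_norm="L2-Hys",
        feature_vector=False,
    )
    if pooled:
        pooled_vec = vec.mean(axis=(0, 1)).ravel()  # average over block positions
        names = [f"hog_pooled_{k}" for k in range(pooled_vec.size)]
        return pooled_vec, names
    flat = vec.ravel()
    names = [f"hog_{k}" for k in range(flat.size)]
    return flat, names


# ---------------------------------------------------------------------------
# morphological / lesion descriptors


def _green(image) -> np.ndarray:
    return as_rgb_array(image)[:, :, 1].astype(float)


def _require_mask(mask: FundusMask) -> None:
    if mask.area == 0:
        raise EmptyMaskError("empty fundus mask")


def detect_circular_lesions(image, mask: FundusMask,
                            radius_range: tuple[int, int] = (3, 12),
                            sensitivity: float = 0.6,
                            inside_dark_min: float = 0.6,
                            annulus_dark_max: float = 0.10
                            ) -> list[tuple[int, int, int, float]]:
    """Circular Hough detection of small dark lesions on the green channel.

    Canny edges of the inverted green channel vote in a circular Hough
    accumulator over ``radius_range``; normalized peaks above ``sensitivity``
    inside the mask are then validated as blob-like: relative to the local
    mid-level, at least ``inside_dark_min`` of the circle interior must be
    dark while at most ``annulus_dark_max`` of the surrounding annulus is —
    a vessel arc fails this because the vessel continues through the
    annulus. Survivors undergo non-maximum suppression within one radius
    and are returned sorted by score (descending).
    """
    _require_mask(mask)
    green = _green(image)
    inv = 255.0 - green
    edges = skfeature.canny(inv / 255.0, sigma=1.2)
    edges &= ndimage.binary_erosion(mask.mask, iterations=2)
    radii = np.arange(radius_range[0], radius_range[1] + 1)
    accum = sktransform.hough_circle(edges, radii)
    yy, xx = np.mgrid[0:green.shape[0], 0:green.shape[1]]
    peaks = []
    for ridx, radius in enumerate(radii):
        acc = accum[ridx]
        # local maxima above the sensitivity threshold
        maxed = ndimage.maximum_filter(acc, size=3)
        cand = np.argwhere((acc >= sensitivity) & (acc == maxed))
        for r, c in cand:
            if not mask.mask[r, c]:
                continue
            d = np.hypot(yy - r, xx - c)
            inside = green[(d <= radius - 0.5) & mask.mask]
            annulus = green[(d > radius + 1.5) & (d <= radius + 4) & mask.mask]
            if inside.size == 0 or annulus.size == 0:
                continue
            if inside.mean() >= annulus.mean():
                continue  # interior not darker than surround
            mid = (inside.mean() + annulus.mean()) / 2.0
            if ((inside < mid).mean() >= inside_dark_min
                    and (annulus < mid).mean() <= annulus_dark_max):
                peaks.append((float(acc[r, c]), int(r), int(c), int(radius)))
    peaks.sort(reverse=True)
    kept: list[tuple[int, int, int, float]] = []
    for score, r, c, radius in peaks:
        if all(np.hypot(r - kr, c - kc) > max(radius, krad)
               for kr, kc, krad, _ in kept):
            kept.append((r, c, radius, score))
    return kept


def exudate_area(image, mask: FundusMask,
                 threshold_offset: float = 20.0,
                 open_radius: int = 1, close_radius: int = 2) -> int:
    """Bright-lesion (exudate analogue) pixel area inside the fundus mask.

    Bright regions are segmented by thresholding the masked green channel at
    Otsu's level plus a fixed offset, cleaned with a morphological opening
    (speck removal) and closing (hole filling). The optic disc — identified
    as the single largest bright component touching the top 0.1% brightest
    pixels — is excluded before counting.
    """
    _require_mask(mask)
    green = _green(image)
    vals = green[mask.mask]
    thr = skfilters.threshold_otsu(vals) + threshold_offset if vals.max() > vals.min() \
        else np.inf
    bright = (green > thr) & mask.mask
    if open_radius > 0:
        bright = skmorph.opening(bright, skmorph.disk(open_radius))
    if close_radius > 0:
        bright = skmorph.closing(bright, skmorph.disk(close_radius))
    if not bright.any():
        return 0
    # optic-disc exclusion: drop every component touching the very brightest
    # pixels (the disc outshines exudates; vessels may split it into several
    # components, all of which carry near-saturated pixels)
    top_cut = np.percentile(vals, 99.9)
    hottest = (green >= top_cut) & mask.mask
    labels, n = ndimage.label(bright)
    if n > 0 and hottest.any():
        touching = np.unique(labels[hottest & (labels > 0)])
        if touching.size:
            bright &= ~np.isin(labels, touching)
    return int(bright.sum())


def vessel_area(image, mask: FundusMask,
                element_radius: int = 7, min_size: int = 30
                ) -> tuple[int, np.ndarray]:
    """Vessel pixel count (and map) from a green-channel bottom-hat transform.

    Dark elongated structures narrower than the disc structuring element
    respond to the morphological bottom-hat; the response is thresholded at
    Otsu's level over the mask, specks below ``min_size`` px removed, and
    the surviving pixel count inside the mask returned with the binary map.
    """
    _require_mask(mask)
    green = _green(image)
    bothat = skmorph.black_tophat(green, footprint=skmorph.disk(element_radius))
    vals = bothat[mask.mask]
    if vals.max() <= vals.min():
        return 0, np.zeros_like(mask.mask)
    thr = max(skfilters.threshold_otsu(vals), 8.0)
    vmap = (bothat > thr) & ndimage.binary_erosion(mask.mask, iterations=2)
    # drop speck components of at most min_size pixels
    labels, n = ndimage.label(vmap)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        small = np.flatnonzero(sizes <= min_size) + 1
        vmap &= ~np.isin(labels, small)
    return int(vmap.sum()), vmap


# ---------------------------------------------------------------------------
# intensity and edge descriptors


def intensity_statistics(gray: np.ndarray, mask: FundusMask | np.ndarray,
                         prefix: str = "gray") -> tuple[np.ndarray, list[str]]:
    """Seven order statistics of masked intensities.

    Mean, population variance, skewness, kurtosis (excess), median, mode
    (most frequent byte value, smallest on ties) and population standard
    deviation. Skewness and kurtosis are 0 by convention for degenerate
    (constant) distributions.
    """
    m = mask.mask if isinstance(mask, FundusMask) else np.asarray(mask, dtype=bool)
    vals = np.asarray(gray, dtype=float)[m]
    if vals.size < 2:
        raise EmptyMaskError("intensity statistics require >= 2 masked pixels")
    var = float(np.var(vals))  # population variance
    if var > 0:
        skew = float(sstats.skew(vals, bias=True))
        kurt = float(sstats.kurtosis(vals, bias=True))
    else:
        skew = kurt = 0.0
    byte_vals = np.clip(np.round(vals), 0, 255).astype(int)
    counts = np.bincount(byte_vals, minlength=256)
    mode = int(np.argmax(counts))  # argmax returns the smallest tied index
    values = np.array([
        float(np.mean(vals)), var, skew, kurt,
        float(np.median(vals)), float(mode), float(np.sqrt(var)),
    ])
    names = [f"{prefix}_{s}" for s in
             ("mean", "variance", "skewness", "kurtosis", "median", "mode", "std")]
    return values, names


def edge_features(gray: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Canny edge density plus mean/std/max Sobel gradient magnitude.

    Sobel gradients use the unnormalized 3x3 kernels (row [1,2,1] smoothing,
    [-1,0,1] difference), so a unit step edge responds with magnitude 4.
    """
    g = np.asarray(gray, dtype=float)
    edges = skfeature.canny(g / 255.0, sigma=1.0)
    gx = ndimage.sobel(g, axis=1, mode="reflect")
    gy = ndimage.sobel(g, axis=0, mode="reflect")
    mag = np.hypot(gx, gy)
    values = np.array([float(edges.mean()), float(mag.mean()),
                       float(mag.std()), float(mag.max())])
    names = ["canny_density", "sobel_mean", "sobel_std", "sobel_max"]
    return values, names


# ---------------------------------------------------------------------------
# assembly


def standardize(image, size: int) -> np.ndarray:
    """Aspect-preserving resize to a ``size x size`` RGB raster, zero-padded."""
    rgb = as_rgb_array(image).astype(float)
    h, w = rgb.shape[:2]
    if h == w == size:
        return rgb
    scale = size / max(h, w)
    nh, nw = max(int(round(h * scale)), 1), max(int(round(w * scale)), 1)
    resized = sktransform.resize(rgb, (nh, nw, 3), order=1, mode="edge",
                                 anti_aliasing=scale < 1.0, preserve_range=True)
    out = np.zeros((size, size, 3))
    r0 = (size - nh) // 2
    c0 = (size - nw) // 2
    out[r0:r0 + nh, c0:c0 + nw] = resized
    return out


def _lesion_block(rgb: np.ndarray, mask: FundusMask, config: FeatureConfig
                  ) -> tuple[np.ndarray, list[str]]:
    circles = detect_circular_lesions(rgb, mask, config.circle_radius_range,
                                      config.circle_sensitivity,
                                      config.circle_inside_dark_min,
                                      config.circle_annulus_dark_max)
    ex_area = exudate_area(rgb, mask, config.exudate_threshold_offset,
                           config.exudate_open_radius, config.exudate_close_radius)
    v_area, _ = vessel_area(rgb, mask, config.vessel_element_radius,
                            config.vessel_min_size)
    n = len(circles)
    mean_radius = float(np.mean([c[2] for c in circles])) if n else 0.0
    mean_score = float(np.mean([c[3] for c in circles])) if n else 0.0
    area = float(mask.area)
    values = np.array([float(n), mean_radius, mean_score,
                       ex_area / area, v_area / area])
    names = ["lesion_circle_count", "lesion_circle_mean_radius",
             "lesion_circle_mean_score", "exudate_area_frac", "vessel_area_frac"]
    return values, names


def extract_handcrafted(image, set_id: str = "CUSTOM90",
                        config: FeatureConfig | None = None) -> FeatureVector:
    """Assemble one of the fixed handcrafted feature layouts.

    ``CUSTOM90`` (90 features): LBP(r=1, 8 pts) 10 + LBP(r=2, 16 pts) 18 +
    12 Haralick statistics averaged over 4 offsets + Gabor bank
    (3 frequencies x 4 orientations x mean/std) 24 + lesion block 5 +
    per-channel masked intensity statistics 21.

    ``HOG_LBP_BASIC`` (57): pooled HOG 36 + LBP(1, 8) 10 + grayscale
    intensity statistics 7 + edge features 4.

    ``GLCM_HARALICK`` (48): the 12 Haralick statistics per offset, unaveraged.
    """
    config = config or FeatureConfig()
    rgb = standardize(image, config.standardize_size)
    gray = to_grayscale(rgb.astype(np.uint8))
    values: list[float] = []
    names: list[str] = []

    if set_id == "CUSTOM90":
        mask = estimate_fundus_mask(rgb.astype(np.uint8))
        for radius, pts in ((1, 8), (2, 16)):
            v, n = lbp_histogram(gray, radius, pts)
            values.extend(v); names.extend(n)
        v, n = glcm_features(gray, config.glcm_offsets, config.glcm_levels,
                             average=True)
        values.extend(v); names.extend(n)
        v, n = gabor_features(gray, config.gabor_frequencies,
                              config.gabor_orientations)
        values.extend(v); names.extend(n)
        v, n = _lesion_block(rgb, mask, config)
        values.extend(v); names.extend(n)
        for k, ch in enumerate("rgb"):
            v, n = intensity_statistics(rgb[:, :, k], mask, prefix=ch)
            values.extend(v); names.extend(n)
    elif set_id == "HOG_LBP_BASIC":
        mask = estimate_fundus_mask(rgb.astype(np.uint8))
        v, n = hog_features(gray, config.hog_cell, config.hog_block,
                            config.hog_bins, pooled=True)
        values.extend(v); names.extend(n)
        v, n = lbp_histogram(gray, 1, 8)
        values.extend(v); names.extend(n)
        v, n = intensity_statistics(gray, mask, prefix="gray")
        values.extend(v); names.extend(n)
        v, n = edge_features(gray)
        values.extend(v); names.extend(n)
    elif set_id == "GLCM_HARALICK":
        v, n = glcm_features(gray, config.glcm_offsets, config.glcm_levels,
                             average=False)
        values.extend(v); names.extend(n)
    else:
        raise InvalidSpecError(f"unknown handcrafted set_id {set_id!r}")

    return FeatureVector(values=np.asarray(values), names=names, set_id=set_id,
                         source_image_id=image_id(image))
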