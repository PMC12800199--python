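"""Handcrafted-feature contracts, with brute-force oracles on tiny images."""

import numpy as np
import pytest

from fundusdr.features import (
    FeatureConfig,
    detect_circular_lesions,
    edge_features,
    exudate_area,
    extract_handcrafted,
    gabor_features,
    glcm_cooccurrence,
    glcm_features,
    hog_features,
    intensity_statistics,
    lbp_histogram,
    vessel_area,
)
from fundusdr.preprocess import estimate_fundus_mask
from fundusdr.synth import generate_fundus
from fundusdr.types import EmptyMaskError, FundusMask, InvalidSpecError

from conftest import clean_spec, desk_spec


# --------------------------------------------------------------------------
# LBP


def lbp_oracle(img: np.ndarray, R: int, P: int) -> np.ndarray:
    """Independent nested-loop uniform LBP with bilinear sampling."""
    img = np.round(np.asarray(img, dtype=float))
    h, w = img.shape
    codes = []
    for r in range(R, h - R):
        for c in range(R, w - R):
            bits = []
            for k in range(P):
                ang = 2 * np.pi * k / P
                rr, cc = r - R * np.sin(ang), c + R * np.cos(ang)
                r0, c0 = int(np.floor(rr)), int(np.floor(cc))
                fr, fc = rr - r0, cc - c0
                if fr < 1e-6:
                    fr = 0.0
                elif fr > 1 - 1e-6:
                    fr, r0 = 0.0, r0 + 1
                if fc < 1e-6:
                    fc = 0.0
                elif fc > 1 - 1e-6:
                    fc, c0 = 0.0, c0 + 1
                v = (img[r0, c0] * (1 - fr) * (1 - fc)
                     + img[r0, min(c0 + 1, w - 1)] * (1 - fr) * fc
                     + img[min(r0 + 1, h - 1), c0] * fr * (1 - fc)
                     + img[min(r0 + 1, h - 1), min(c0 + 1, w - 1)] * fr * fc)
                bits.append(1 if v >= img[r, c] else 0)
            trans = sum(bits[k] != bits[(k + 1) % P] for k in range(P))
            codes.append(sum(bits) if trans <= 2 else P + 1)
    hist, _ = np.histogram(codes, bins=np.arange(P + 3) - 0.5)
    return hist / hist.sum()


def test_lbp_constant_image_single_bin():
    hist, names = lbp_histogram(np.full((9, 9), 57.0), 1, 8)
    assert len(hist) == 10
    assert hist.max() == pytest.approx(1.0)
    assert (hist > 0).sum() == 1


def test_lbp_histogram_is_normalized(noisy_image_truth):
    img, _ = noisy_image_truth
    hist, _ = lbp_histogram(img.pixels[:, :, 1].astype(float), 2, 16)
    assert hist.sum() == pytest.approx(1.0, abs=1e-9)
    assert len(hist) == 18


def test_lbp_matches_bruteforce_oracle_on_small_images():
    cb = (np.indices((5, 5)).sum(axis=0) % 2) * 255.0
    assert np.allclose(lbp_histogram(cb, 1, 8)[0], lbp_oracle(cb, 1, 8))
    rng = np.random.default_rng(1)
    for _ in range(5):
        img = rng.integers(0, 256, size=(7, 8)).astype(float)
        assert np.allclose(lbp_histogram(img, 1, 8)[0], lbp_oracle(img, 1, 8))


def test_lbp_rejects_too_small_image():
    with pytest.raises(InvalidSpecError):
        lbp_histogram(np.zeros((2, 2)), 1, 8)


# --------------------------------------------------------------------------
# GLCM / Haralick


def test_glcm_constant_image_degenerate_values():
    values, names = glcm_features(np.full((8, 8), 42.0))
    stats = dict(zip(names, values))
    assert stats["glcm_contrast"] == 0.0
    assert stats["glcm_homogeneity"] == pytest.approx(1.0)
    assert stats["glcm_energy"] == pytest.approx(1.0)


def test_glcm_two_by_two_hand_oracle():
    # [[0,1],[0,1]] offset (0,1): the two horizontal pairs are both (0,1);
    # symmetrized P(0,1)=P(1,0)=0.5, so contrast = sum P(i,j)(i-j)^2 = 1
    img = np.array([[0.0, 1.0], [0.0, 1.0]])
    p = glcm_cooccurrence(img, (0, 1), 2)
    assert p[0, 1] == pytest.approx(0.5)
    assert p[1, 0] == pytest.approx(0.5)
    assert p[0, 0] == p[1, 1] == 0.0
    values, names = glcm_features(img, offsets=((0, 1),), levels=2)
    assert dict(zip(names, values))["glcm_contrast"] == pytest.approx(1.0)


def test_glcm_matrix_normalized(noisy_image_truth):
    img, _ = noisy_image_truth
    p = glcm_cooccurrence(img.pixels[:, :, 1].astype(float), (1, 1), 32)
    assert p.sum() == pytest.approx(1.0, abs=1e-9)


def test_glcm_bruteforce_pair_enumeration_on_small_images():
    rng = np.random.default_rng(2)
    for offset in [(0, 1), (1, 0), (1, 1), (1, -1)]:
        img = rng.integers(0, 4, size=(6, 6)).astype(float)
        levels = 4
        q = np.floor((img - img.min()) / (img.max() - img.min()) * levels)
        q = np.clip(q, 0, levels - 1).astype(int)
        expected = np.zeros((levels, levels))
        dr, dc = offset
        for r in range(6):
            for c in range(6):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < 6 and 0 <= c2 < 6:
                    expected[q[r, c], q[r2, c2]] += 1
                    expected[q[r2, c2], q[r, c]] += 1
        expected /= expected.sum()
        assert np.allclose(glcm_cooccurrence(img, offset, levels), expected)


def test_glcm_core_stats_agree_with_skimage():
    """Cross-check the hand-rolled Haralick core against skimage graycoprops."""
    from skimage.feature import graycomatrix, graycoprops

    rng = np.random.default_rng(3)
    raw = rng.integers(0, 8, size=(8, 8))
    img = np.arange(8, dtype=float)[raw]  # quantizes bin k -> level k
    sk = graycomatrix(raw.astype(np.uint8), [1], [0], levels=8,
                      symmetric=True, normed=True)
    values, names = glcm_features(img, offsets=((0, 1),), levels=8)
    stats = dict(zip(names, values))
    for mine, theirs in [("glcm_contrast", "contrast"),
                         ("glcm_correlation", "correlation"),
                         ("glcm_energy", "energy"),
                         ("glcm_homogeneity", "homogeneity"),
                         ("glcm_dissimilarity", "dissimilarity")]:
        assert stats[mine] == pytest.approx(float(graycoprops(sk, theirs)[0, 0]),
                                            abs=1e-9)


def test_glcm_rejects_degenerate_levels():
    with pytest.raises(InvalidSpecError):
        glcm_features(np.zeros((4, 4)), levels=1)


# --------------------------------------------------------------------------
# Gabor


def test_gabor_constant_image_zero_std():
    values, names = gabor_features(np.full((32, 32), 90.0))
    stds = [v for v, n in zip(values, names) if n.endswith("_std")]
    assert np.allclose(stds, 0.0, atol=1e-6)


def test_gabor_grating_orientation_argmax():
    # vertical grating (intensity varies along columns) at frequency 0.2
    x = np.arange(64)
    grating = np.tile(127.5 + 127.5 * np.sin(2 * np.pi * 0.2 * x), (64, 1))
    values, names = gabor_features(grating, frequencies=(0.2,),
                                   orientations=(0.0, np.pi / 4, np.pi / 2,
                                                 3 * np.pi / 4))
    means = {n: v for v, n in zip(values, names) if n.endswith("_mean")}
    best = max(means, key=means.get)
    assert "_o0_" in best  # theta=0 responds to horizontal-axis variation


def test_gabor_output_length_and_validation():
    values, _ = gabor_features(np.zeros((16, 16)), frequencies=(0.1, 0.3),
                               orientations=(0.0, np.pi / 2))
    assert len(values) == 2 * 2 * 2
    with pytest.raises(InvalidSpecError):
        gabor_features(np.zeros((16, 16)), frequencies=(-0.1,))


# --------------------------------------------------------------------------
# HOG


def test_hog_constant_image_zero_vector():
    values, _ = hog_features(np.full((64, 64), 100.0))
    assert np.allclose(values, 0.0)


def test_hog_length_64px_unpooled_and_pooled():
    rng = np.random.default_rng(4)
    img = rng.uniform(0, 255, size=(64, 64))
    full, _ = hog_features(img, cell=8, block=2, bins=9)
    assert len(full) == 9 * 2 * 2 * 7 * 7  # 1764
    pooled, names = hog_features(img, cell=8, block=2, bins=9, pooled=True)
    assert len(pooled) == 36 and len(set(names)) == 36


def test_hog_step_edge_dominant_orientation():
    img = np.zeros((64, 64))
    img[32:, :] = 200.0  # horizontal edge: gradient points down image rows
    values, _ = hog_features(img, cell=8, block=2, bins=9, pooled=True)
    hist = values.reshape(2, 2, 9).sum(axis=(0, 1))
    # direct gradient-angle oracle: vertical gradient -> orientation bin 0
    gy, gx = np.gradient(img)
    angles = np.rad2deg(np.arctan2(gy, gx)) % 180
    oracle_bin = int(np.median(angles[np.hypot(gx, gy) > 0]) // 20)
    assert int(np.argmax(hist)) == oracle_bin


def test_hog_cell_larger_than_image_rejected():
    with pytest.raises(InvalidSpecError):
        hog_features(np.zeros((4, 4)), cell=8)


# --------------------------------------------------------------------------
# lesion detectors (scored against generator ground truth)


def test_hough_recovers_all_planted_circles_at_zero_noise():
    spec = clean_spec(n_dark_lesions=4, dark_lesion_radius_range=(4, 4), seed=7)
    img, truth = generate_fundus(spec)
    mask = estimate_fundus_mask(img)
    circles = detect_circular_lesions(img, mask, (3, 8))
    assert len(circles) == 4
    for tr, tc, _trad in truth.dark_lesion_centers_radii:
        assert any(np.hypot(tr - r, tc - c) <= 2 for r, c, _rad, _s in circles)


def test_hough_no_detections_on_lesion_free_image():
    img, _ = generate_fundus(clean_spec(seed=11))
    mask = estimate_fundus_mask(img)
    assert detect_circular_lesions(img, mask, (3, 8)) == []


def test_hough_detection_is_deterministic(clean_image_truth):
    img, _ = clean_image_truth
    mask = estimate_fundus_mask(img)
    assert (detect_circular_lesions(img, mask, (3, 8))
            == detect_circular_lesions(img, mask, (3, 8)))


def test_exudate_area_within_ten_percent_of_truth():
    spec = clean_spec(n_bright_lesions=1, bright_lesion_radius_range=(5, 5), seed=3)
    img, truth = generate_fundus(spec)
    mask = estimate_fundus_mask(img)
    area = exudate_area(img, mask)
    truth_area = truth.bright_lesion_pixels.sum()
    assert abs(area - truth_area) <= 0.10 * truth_area


def test_exudate_area_zero_without_blobs():
    img, _ = generate_fundus(clean_spec(seed=5))
    mask = estimate_fundus_mask(img)
    assert exudate_area(img, mask) == 0


def test_exudate_two_disjoint_blobs_close_to_truth_total():
    spec = clean_spec(n_bright_lesions=2, bright_lesion_radius_range=(5, 6), seed=8)
    img, truth = generate_fundus(spec)
    mask = estimate_fundus_mask(img)
    truth_area = truth.bright_lesion_pixels.sum()
    assert abs(exudate_area(img, mask) - truth_area) <= 0.10 * truth_area


def test_vessel_false_positive_rate_low_without_vessels():
    for seed in range(10):
        img, _ = generate_fundus(clean_spec(seed=100 + seed, n_vessels=0))
        mask = estimate_fundus_mask(img)
        area, _ = vessel_area(img, mask, 5, 15)
        assert area <= 0.01 * mask.area


def test_vessel_map_overlaps_truth_at_zero_noise():
    img, truth = generate_fundus(clean_spec(seed=4))
    mask = estimate_fundus_mask(img)
    _, vmap = vessel_area(img, mask, 5, 15)
    jaccard = (vmap & truth.vessel_mask).sum() / (vmap | truth.vessel_mask).sum()
    assert jaccard >= 0.5


def test_vessel_area_grows_with_vessel_count():
    img4, _ = generate_fundus(clean_spec(seed=9, n_vessels=4))
    img8, _ = generate_fundus(clean_spec(seed=9, n_vessels=8))
    mask4, mask8 = estimate_fundus_mask(img4), estimate_fundus_mask(img8)
    a4, _ = vessel_area(img4, mask4, 5, 15)
    a8, _ = vessel_area(img8, mask8, 5, 15)
    assert a8 > a4


# --------------------------------------------------------------------------
# intensity and edge statistics


def _full_mask(shape):
    return FundusMask(mask=np.ones(shape, dtype=bool),
                      center=(shape[0] / 2, shape[1] / 2), radius=shape[0] / 2)


def test_intensity_stats_constant_image_convention():
    values, names = intensity_statistics(np.full((8, 8), 77.0), _full_mask((8, 8)))
    stats = dict(zip(names, values))
    assert stats["gray_mean"] == stats["gray_median"] == stats["gray_mode"] == 77.0
    assert stats["gray_variance"] == stats["gray_std"] == 0.0
    assert stats["gray_skewness"] == stats["gray_kurtosis"] == 0.0


def test_intensity_stats_hand_computed_example():
    img = np.array([[1.0, 2.0], [2.0, 5.0]])
    values, names = intensity_statistics(img, _full_mask((2, 2)))
    stats = dict(zip(names, values))
    assert stats["gray_mean"] == pytest.approx(2.5)
    assert stats["gray_median"] == pytest.approx(2.0)
    assert stats["gray_mode"] == 2.0
    assert stats["gray_variance"] == pytest.approx(2.25)  # population


def test_intensity_stats_affine_equivariance():
    rng = np.random.default_rng(5)
    img = rng.integers(0, 100, size=(10, 10)).astype(float)
    v1, names = intensity_statistics(img, _full_mask((10, 10)))
    v2, _ = intensity_statistics(img * 2, _full_mask((10, 10)))
    s1, s2 = dict(zip(names, v1)), dict(zip(names, v2))
    assert s2["gray_mean"] == pytest.approx(2 * s1["gray_mean"])
    assert s2["gray_std"] == pytest.approx(2 * s1["gray_std"])
    assert s2["gray_skewness"] == pytest.approx(s1["gray_skewness"])


def test_intensity_stats_requires_two_pixels():
    mask = np.zeros((4, 4), dtype=bool)
    mask[0, 0] = True
    with pytest.raises(EmptyMaskError):
        intensity_statistics(np.zeros((4, 4)),
                             FundusMask(mask=mask, center=(0, 0), radius=1))


def test_edge_features_constant_zero_and_length():
    values, names = edge_features(np.full((32, 32), 50.0))
    assert len(values) == len(names) == 4
    assert np.allclose(values, 0.0)


def test_edge_features_step_response_closed_form():
    # vertical step of height h: unnormalized 3x3 Sobel responds with 4h
    h = 37.0
    img = np.zeros((16, 16))
    img[:, 8:] = h
    values, names = edge_features(img)
    assert dict(zip(names, values))["sobel_max"] == pytest.approx(4 * h)


# --------------------------------------------------------------------------
# assembly


def test_custom90_has_exactly_90_unique_names(noisy_image_truth, desk_config):
    img, _ = noisy_image_truth
    fv = extract_handcrafted(img, "CUSTOM90", desk_config)
    assert len(fv) == 90
    assert len(set(fv.names)) == 90
    assert np.all(np.isfinite(fv.values))


def test_extraction_is_deterministic(noisy_image_truth, desk_config):
    img, _ = noisy_image_truth
    fv1 = extract_handcrafted(img, "CUSTOM90", desk_config)
    fv2 = extract_handcrafted(img, "CUSTOM90", desk_config)
    assert np.array_equal(fv1.values, fv2.values)
    assert fv1.names == fv2.names


@pytest.mark.parametrize("set_id,length", [("HOG_LBP_BASIC", 57),
                                           ("GLCM_HARALICK", 48)])
def test_table_feature_set_lengths(set_id, length, noisy_image_truth, desk_config):
    img, _ = noisy_image_truth
    fv = extract_handcrafted(img, set_id, desk_config)
    assert len(fv) == length
    assert len(set(fv.names)) == length


def test_fragment_lengths_independent_of_input_size(desk_config):
    imgA, _ = generate_fundus(desk_spec(seed=1))
    imgB, _ = generate_fundus(desk_spec(seed=1, image_size=96))
    fvA = extract_handcrafted(imgA, "CUSTOM90", desk_config)
    fvB = extract_handcrafted(imgB, "CUSTOM90", desk_config)
    assert len(fvA) == len(fvB) == 90
    assert fvA.names == fvB.names


def test_unknown_set_id_rejected(noisy_image_truth):
    img, _ = noisy_image_truth
    with pytest.raises(InvalidSpecError):
        extract_handcrafted(img, "NOT_A_SET")
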