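"""Shared fixtures: small synthetic images at desk scale (128 px)."""

from __future__ import annotations

import numpy as np
import pytest

from fundusdr.synth import SyntheticSpec, generate_fundus
from fundusdr.features import FeatureConfig


def desk_spec(**kwargs) -> SyntheticSpec:
    """A 128-px spec with detector-friendly lesion/vessel scales."""
    defaults = dict(
        image_size=128,
        dark_lesion_radius_range=(3, 5),
        bright_lesion_radius_range=(4, 7),
        vessel_width_range=(1.5, 3.5),
    )
    defaults.update(kwargs)
    return SyntheticSpec(**defaults)


def clean_spec(**kwargs) -> SyntheticSpec:
    """Desk-scale spec with noise and illumination disabled (exact truth)."""
    defaults = dict(noise_sigma=0.0, illumination_gain_range=(1.0, 1.0))
    defaults.update(kwargs)
    return desk_spec(**defaults)


@pytest.fixture(scope="session")
def desk_config() -> FeatureConfig:
    """Feature extractor config matched to the 128-px desk scale."""
    return FeatureConfig(standardize_size=128, circle_radius_range=(3, 8),
                         vessel_element_radius=5, vessel_min_size=15)


@pytest.fixture(scope="session")
def noisy_image_truth():
    """One default-noise synthetic image with lesions, plus its truth."""
    return generate_fundus(desk_spec(n_dark_lesions=5, n_bright_lesions=3, seed=42))


@pytest.fixture(scope="session")
def clean_image_truth():
    """One noiseless, flat-illumination image with lesions, plus its truth."""
    return generate_fundus(clean_spec(n_dark_lesions=4, n_bright_lesions=2, seed=7))


@pytest.fixture(scope="session")
def ten_noisy_images():
    """Ten seeded default-condition images with dark lesions."""
    return [generate_fundus(desk_spec(n_dark_lesions=5, n_bright_lesions=2, seed=s))
            for s in range(10)]
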