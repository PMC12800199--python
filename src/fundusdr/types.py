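"""Core domain containers shared across the grading pipeline.

Everything downstream of the camera is expressed in terms of a handful of
small, explicit containers: a raw RGB fundus photograph (:class:`FundusImage`),
the boolean retina-disc mask (:class:`FundusMask`), the output of an
enhancement pipeline (:class:`EnhancedImage`), an ordered named descriptor
vector (:class:`FeatureVector`) and the five-level severity label
(:class:`GradingLabel`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

__all__ = [
    "FundusImage",
    "FundusMask",
    "EnhancedImage",
    "FeatureVector",
    "GradingLabel",
    "GRADE_NAMES",
    "FundusDRError",
    "InvalidSpecError",
    "EmptyMaskError",
]


class FundusDRError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(FundusDRError, ValueError):
    """A generation spec or parameter record violates its invariants."""


class EmptyMaskError(FundusDRError, ValueError):
    """No fundus foreground could be located in the image."""


#: Severity grades in the standard five-level clinical ordering.
GRADE_NAMES: tuple[str, ...] = ("No DR", "Mild", "Moderate", "Severe", "PDR")


@dataclass(frozen=True)
class GradingLabel:
    """Diabetic-retinopathy severity grade, 0 (healthy) through 4 (proliferative)."""

    grade: int
    name: str

    def __post_init__(self) -> None:
        if not 0 <= self.grade <= 4:
            raise InvalidSpecError(f"grade must be in 0..4, got {self.grade}")
        if self.name != GRADE_NAMES[self.grade]:
            raise InvalidSpecError(
                f"grade {self.grade} must be named {GRADE_NAMES[self.grade]!r}, "
                f"got {self.name!r}"
            )

    @classmethod
    def from_grade(cls, grade: int) -> "GradingLabel":
        return cls(grade=int(grade), name=GRADE_NAMES[int(grade)])


@dataclass
class FundusImage:
    """An RGB color fundus photograph with byte intensities.

    ``pixels`` is an ``(H, W, 3)`` uint8 array in fixed RGB channel order,
    whatever the on-disk layout was.
    """

    pixels: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InvalidSpecError(
                f"FundusImage requires an (H, W, 3) raster, got {self.pixels.shape}"
            )
        if min(self.pixels.shape[:2]) < 32:
            raise InvalidSpecError("FundusImage sides must be >= 32 pixels")
        if self.pixels.dtype != np.uint8:
            self.pixels = np.clip(np.round(self.pixels), 0, 255).astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class FundusMask:
    """Boolean raster marking the circular retina region of an image.

    ``center``/``radius`` describe the largest circle inscribed in the mask's
    foreground; the mask itself may deviate slightly from a perfect disc.
    """

    mask: np.ndarray
    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise InvalidSpecError("FundusMask must be a 2-D boolean raster")

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class EnhancedImage:
    """Output of one of the enhancement pipelines.

    ``pixels`` is ``(H, W, 3)`` for the color methods or ``(H, W)`` for the
    grayscale one; ``stage_trace`` records, in order, which stages actually
    ran (disabled stages appear with a ``skipped:`` prefix).
    """

    pixels: np.ndarray
    method: str  # one of {"ASE", "LAB_ACE", "MIE"}
    params: Any
    stage_trace: list[str] = field(default_factory=list)
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            self.pixels = np.clip(np.round(self.pixels), 0, 255).astype(np.uint8)
        if not self.stage_trace:
            raise InvalidSpecError("stage_trace must record at least one stage")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def as_rgb(self) -> np.ndarray:
        """Pixels promoted to (H, W, 3), replicating a grayscale raster."""
        if self.pixels.ndim == 2:
            return np.repeat(self.pixels[:, :, None], 3, axis=2)
        return self.pixels


#: Recognized feature-set identifiers.
FEATURE_SET_IDS = ("HOG_LBP_BASIC", "GLCM_HARALICK", "CUSTOM90", "DEEP", "FUSED")


@dataclass
class FeatureVector:
    """An ordered, named numeric descriptor vector for one image."""

    values: np.ndarray
    names: list[str]
    set_id: str
    source_image_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.names = list(self.names)
        if len(self.values) != len(self.names):
            raise InvalidSpecError(
                f"values/names length mismatch: {len(self.values)} vs {len(self.names)}"
            )
        if self.set_id not in FEATURE_SET_IDS:
            raise InvalidSpecError(f"unknown set_id {self.set_id!r}")
        if not np.all(np.isfinite(self.values)):
            bad = [n for n, v in zip(self.names, self.values) if not np.isfinite(v)]
            raise InvalidSpecError(f"non-finite feature values: {bad[:5]}")
        if self.set_id == "CUSTOM90" and len(self.values) != 90:
            raise InvalidSpecError(
                f"CUSTOM90 must have exactly 90 entries, got {len(self.values)}"
            )

    def __len__(self) -> int:
        return len(self.values)


def as_rgb_array(image: "FundusImage | EnhancedImage | np.ndarray") -> np.ndarray:
    """Return an (H, W, 3) uint8 view of any image-like input."""
    if isinstance(image, FundusImage):
        return image.pixels
    if isinstance(image, EnhancedImage):
        return image.as_rgb()
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.dtype != np.uint8:
        arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    return arr


def image_id(image: "FundusImage | EnhancedImage | np.ndarray") -> str:
    return getattr(image, "id", "") or ""
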