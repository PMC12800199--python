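"""Seeded generator of fundus-like images with planted ground truth.

The generator paints, on a near-black background, the bright circular retina
disc, an optic disc, curvilinear vessels radiating from it, small dark
circular lesions (microaneurysm / hemorrhage analogues) and bright yellowish
blobs (exudate analogues); it then applies a smooth multiplicative
illumination field inside the disc and additive Gaussian sensor noise.
Every planted structure is recorded in a :class:`GroundTruth` so detectors
can be scored without manual annotation, and five severity grades are
emulated by increasing lesion load.

All randomness flows from ``SyntheticSpec.seed`` through a single
``numpy`` generator, so identical specs produce byte-identical images.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk

from .types import (
    FundusImage,
    GradingLabel,
    InvalidSpecError,
    GRADE_NAMES,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_fundus",
    "generate_dataset",
    "default_lesion_schedule",
]

# Flat base colors (R, G, B); the illumination field and noise perturb them.
_BACKGROUND = np.array([6.0, 5.0, 4.0])
_FUNDUS = np.array([185.0, 92.0, 38.0])
_OPTIC_DISC = np.array([250.0, 245.0, 190.0])
_VESSEL = np.array([95.0, 30.0, 18.0])
_DARK_LESION = np.array([110.0, 32.0, 20.0])
_BRIGHT_LESION = np.array([235.0, 215.0, 95.0])


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters for one synthetic fundus image.

    Lesion counts, radii and noise are in pixels / byte-intensity units.
    ``illumination_gain_range`` bounds the smooth multiplicative field applied
    inside the fundus disc (a subset of (0, 2]).
    """

    image_size: int = 512
    fundus_radius_frac: float = 0.9
    n_dark_lesions: int = 0
    dark_lesion_radius_range: tuple[int, int] = (4, 9)
    n_bright_lesions: int = 0
    bright_lesion_radius_range: tuple[int, int] = (5, 11)
    n_vessels: int = 4
    vessel_width_range: tuple[float, float] = (2.0, 5.0)
    illumination_gain_range: tuple[float, float] = (0.6, 1.4)
    noise_sigma: float = 5.0
    optic_disc: bool = True
    optic_disc_radius_frac: float = 0.14  # fraction of the fundus radius
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 32:
            raise InvalidSpecError("image_size must be >= 32")
        if not 0.0 < self.fundus_radius_frac <= 1.0:
            raise InvalidSpecError("fundus_radius_frac must lie in (0, 1]")
        for name in ("n_dark_lesions", "n_bright_lesions", "n_vessels"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be >= 0")
        for name in (
            "dark_lesion_radius_range",
            "bright_lesion_radius_range",
            "vessel_width_range",
            "illumination_gain_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise InvalidSpecError(f"{name} must satisfy low <= high")
        lo, hi = self.illumination_gain_range
        if not (0.0 < lo and hi <= 2.0):
            raise InvalidSpecError("illumination_gain_range must be within (0, 2]")
        if self.noise_sigma < 0:
            raise InvalidSpecError("noise_sigma must be >= 0")
        fundus_r = self.fundus_radius_frac * self.image_size / 2.0
        for name in ("dark_lesion_radius_range", "bright_lesion_radius_range"):
            n = self.n_dark_lesions if name.startswith("dark") else self.n_bright_lesions
            if n > 0 and getattr(self, name)[1] >= fundus_r:
                raise InvalidSpecError(
                    f"{name} upper bound {getattr(self, name)[1]} exceeds the "
                    f"fundus radius {fundus_r:.1f}"
                )


@dataclass
class GroundTruth:
    """Planted truth for one generated image."""

    fundus_mask: np.ndarray
    vessel_mask: np.ndarray
    dark_lesion_centers_radii: list[tuple[int, int, int]]
    bright_lesion_pixels: np.ndarray
    label: int = 0

    def to_json_dict(self) -> dict:
        """JSON-serializable summary (masks are written separately as PNG)."""
        return {
            "label": int(self.label),
            "label_name": GRADE_NAMES[int(self.label)],
            "dark_lesion_centers_radii": [
                [int(r), int(c), int(rad)] for r, c, rad in self.dark_lesion_centers_radii
            ],
            "n_bright_lesion_pixels": int(self.bright_lesion_pixels.sum()),
        }


def _paint_disk(canvas: np.ndarray, center: tuple[float, float], radius: float,
                color: np.ndarray) -> np.ndarray:
    rr, cc = draw_disk(center, radius, shape=canvas.shape[:2])
    canvas[rr, cc] = color
    mask = np.zeros(canvas.shape[:2], dtype=bool)
    mask[rr, cc] = True
    return mask

def _quadratic_bezier(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _draw_vessel(canvas: np.ndarray, vessel_mask: np.ndarray, fundus_mask: np.ndarray,
                 p0: np.ndarray, p2: np.ndarray, rng: np.random.Generator,
                 width_range: tuple[float, float]) -> None:
    """One quadratic Bezier stroke with linearly tapering width."""
    mid = (p0 + p2) / 2.0
    chord = p2 - p0
    normal = np.array([-chord[1], chord[0]])
    norm = np.linalg.norm(normal)
    if norm > 0:
        normal = normal / norm
    p1 = mid + normal * rng.uniform(-0.35, 0.35) * np.linalg.norm(chord)
    length = np.linalg.norm(chord)
    pts = _quadratic_bezier(p0, p1, p2, max(int(2 * length), 16))
    w0 = rng.uniform(*width_range)
    w1 = max(1.0, 0.35 * w0)  # taper toward the periphery
    stroke = np.zeros(canvas.shape[:2], dtype=bool)
    for i, (r, c) in enumerate(pts):
        w = w0 + (w1 - w0) * i / (len(pts) - 1)
        rr, cc = draw_disk((r, c), max(w / 2.0, 0.8), shape=canvas.shape[:2])
        stroke[rr, cc] = True
    stroke &= fundus_mask
    canvas[stroke] = _VESSEL
    vessel_mask |= stroke


def _place_nonoverlapping(rng: np.random.Generator, n: int,
                          radius_range: tuple[int, int],
                          center: tuple[float, float], fundus_r: float,
                          occupied: list[tuple[float, float, float]],
                          clear_dist: np.ndarray | None = None,
                          max_attempts: int = 1000) -> list[tuple[int, int, int]]:
    """Rejection-sample n non-overlapping disks inside the fundus.

    ``occupied`` holds (row, col, radius) exclusion disks (optic disc, lesions
    already placed) and ``clear_dist`` a distance map to painted structures
    (vessels); a margin of 2 px keeps truth counts unambiguous.
    """
    placed: list[tuple[int, int, int]] = []
    for _ in range(n):
        for attempt in range(max_attempts):
            rad = int(rng.integers(radius_range[0], radius_range[1] + 1))
            # keep whole disk inside the fundus with a small margin
            rho = rng.uniform(0, fundus_r - rad - 3)
            theta = rng.uniform(0, 2 * np.pi)
            r = center[0] + rho * np.sin(theta)
            c = center[1] + rho * np.cos(theta)
            ok = all(
                np.hypot(r - orow, c - ocol) > rad + orad + 2
                for orow, ocol, orad in occupied
            )
            if ok and clear_dist is not None:
                ok = clear_dist[int(round(r)), int(round(c))] > rad + 2
            if ok:
                placed.append((int(round(r)), int(round(c)), rad))
                occupied.append((r, c, float(rad)))
                break
        else:
            raise InvalidSpecError(
                f"could not place {n} non-overlapping lesions after "
                f"{max_attempts} attempts; reduce counts or radii"
            )
    return placed


def _illumination_field(rng: np.random.Generator, size: int,
                        gain_range: tuple[float, float]) -> np.ndarray:
    """Smooth low-order 2-D polynomial gain rescaled into ``gain_range``."""
    lo, hi = gain_range
    y, x = np.mgrid[0:size, 0:size].astype(float)
    x = x / size - 0.5
    y = y / size - 0.5
    coef = rng.uniform(-1.0, 1.0, size=6)
    f = (coef[0] + coef[1] * x + coef[2] * y
         + coef[3] * x * x + coef[4] * x * y + coef[5] * y * y)
    fmin, fmax = f.min(), f.max()
    if fmax - fmin < 1e-12:
        return np.full_like(f, (lo + hi) / 2.0)
    return lo + (f - fmin) / (fmax - fmin) * (hi - lo)


def generate_fundus(spec: SyntheticSpec) -> tuple[FundusImage, GroundTruth]:
    """Render one synthetic fundus image and its planted ground truth.

    The paint order is: retina disc, optic disc, vessels, dark lesions,
    bright blobs, then the multiplicative illumination field (inside the
    fundus only) and additive Gaussian noise. Lesions are placed by
    rejection sampling so they overlap neither each other nor the optic
    disc, which keeps connected-component counts of the truth rasters equal
    to the requested lesion counts.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    canvas = np.tile(_BACKGROUND, (size, size, 1))
    center = ((size - 1) / 2.0, (size - 1) / 2.0)
    fundus_r = spec.fundus_radius_frac * size / 2.0

    fundus_mask = _paint_disk(canvas, center, fundus_r, _FUNDUS)
    occupied: list[tuple[float, float, float]] = []

    # Optic disc: a bright disc at mid-eccentricity, random azimuth.
    od_center = center
    od_radius = spec.optic_disc_radius_frac * fundus_r
    if spec.optic_disc:
        theta = rng.uniform(0, 2 * np.pi)
        rho = 0.55 * fundus_r
        od_center = (center[0] + rho * np.sin(theta), center[1] + rho * np.cos(theta))
        _paint_disk(canvas, od_center, od_radius, _OPTIC_DISC)
        occupied.append((od_center[0], od_center[1], od_radius))

    # Vessels radiate from the optic disc toward the fundus rim.
    vessel_mask = np.zeros((size, size), dtype=bool)
    p0 = np.array(od_center)
    for _ in range(spec.n_vessels):
        theta = rng.uniform(0, 2 * np.pi)
        rho = rng.uniform(0.75, 0.95) * fundus_r
        p2 = np.array([center[0] + rho * np.sin(theta), center[1] + rho * np.cos(theta)])
        _draw_vessel(canvas, vessel_mask, fundus_mask, p0, p2, rng,
                     spec.vessel_width_range)

    # lesions stay clear of vessels too, so each planted disk is visually
    # unambiguous in the truth rasters
    vessel_dist = ndi.distance_transform_edt(~vessel_mask) if vessel_mask.any() \
        else None
    dark = _place_nonoverlapping(rng, spec.n_dark_lesions,
                                 spec.dark_lesion_radius_range, center, fundus_r,
                                 occupied, clear_dist=vessel_dist)
    for r, c, rad in dark:
        _paint_disk(canvas, (r, c), rad, _DARK_LESION)

    bright_pixels = np.zeros((size, size), dtype=bool)
    bright = _place_nonoverlapping(rng, spec.n_bright_lesions,
                                   spec.bright_lesion_radius_range, center, fundus_r,
                                   occupied, clear_dist=vessel_dist)
    for r, c, rad in bright:
        bright_pixels |= _paint_disk(canvas, (r, c), rad, _BRIGHT_LESION)

    gain = _illumination_field(rng, size, spec.illumination_gain_range)
    canvas[fundus_mask] *= gain[fundus_mask][:, None]

    if spec.noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sigma, size=canvas.shape)

    pixels = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
    truth = GroundTruth(
        fundus_mask=fundus_mask,
        vessel_mask=vessel_mask & fundus_mask,
        dark_lesion_centers_radii=dark,
        bright_lesion_pixels=bright_pixels,
    )
    return FundusImage(pixels=pixels, id=f"synth-{spec.seed:010d}"), truth


def default_lesion_schedule() -> dict[int, tuple[int, int]]:
    """Grade -> (dark lesions, bright blobs): grade g plants 3g dark, 2g bright."""
    return {g: (3 * g, 2 * g) for g in range(5)}


def generate_dataset(
    base_spec: SyntheticSpec,
    n_per_class: int,
    class_lesion_schedule: dict[int, tuple[int, int]] | None = None,
    seed: int = 0,
) -> list[tuple[FundusImage, GradingLabel, GroundTruth]]:
    """Generate ``5 * n_per_class`` labelled images with lesion load by grade.

    Per-image seeds are drawn deterministically from ``seed`` so the whole
    dataset is reproducible. A schedule whose total lesion count is not
    monotone non-decreasing in grade is accepted with a warning.
    """
    schedule = class_lesion_schedule or default_lesion_schedule()
    totals = [sum(schedule[g]) for g in range(5)]
    if any(b < a for a, b in zip(totals, totals[1:])):
        warnings.warn("lesion schedule is not monotone non-decreasing in grade",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    out = []
    for grade in range(5):
        n_dark, n_bright = schedule[grade]
        for _ in range(n_per_class):
            child_seed = int(rng.integers(0, 2**31 - 1))
            spec = SyntheticSpec(**{
                **asdict(base_spec),
                "n_dark_lesions": int(n_dark),
                "n_bright_lesions": int(n_bright),
                "seed": child_seed,
            })
            image, truth = generate_fundus(spec)
            label = GradingLabel.from_grade(grade)
            truth.label = grade
            image.id = f"g{grade}-{child_seed:010d}"
            out.append((image, label, truth))
    return out


def write_dataset(dataset, out_dir: str | Path) -> Path:
    """Persist a generated dataset: PNGs, truth JSON + mask PNGs, manifest CSV."""
    from .io import write_image  # local import: io depends on types only

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["image_id,grade,path"]
    for image, label, truth in dataset:
        img_path = out / f"{image.id}.png"
        write_image(image, img_path)
        from PIL import Image as _PILImage

        for suffix, mask in (
            ("fundus_mask", truth.fundus_mask),
            ("vessel_mask", truth.vessel_mask),
            ("bright_lesion_pixels", truth.bright_lesion_pixels),
        ):
            _PILImage.fromarray((mask * 255).astype(np.uint8)).save(
                out / f"{image.id}.{suffix}.png"
            )
        (out / f"{image.id}.truth.json").write_text(
            json.dumps(truth.to_json_dict(), indent=2)
        )
        rows.append(f"{image.id},{label.grade},{img_path.name}")
    manifest = out / "manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
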