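"""Image and feature-table readers/writers."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image as PILImage

from .types import FundusImage, EnhancedImage, InvalidSpecError, FundusDRError
from .grading import Dataset

__all__ = ["read_image", "write_image", "read_feature_table", "write_feature_table"]


def read_image(path: str | Path) -> FundusImage:
    """Read a PNG/JPEG file into a fixed-RGB-order byte raster.

    Grayscale files are promoted to three identical channels; alpha channels
    are dropped.
    """
    path = Path(path)
    try:
        with PILImage.open(path) as im:
            im = im.convert("RGB")
            pixels = np.asarray(im, dtype=np.uint8)
    except (OSError, ValueError) as exc:
        raise FundusDRError(f"cannot read image {path}: {exc}") from exc
    return FundusImage(pixels=pixels, id=path.stem)


def write_image(image: FundusImage | EnhancedImage | np.ndarray,
                path: str | Path) -> Path:
    path = Path(path)
    pixels = image.pixels if hasattr(image, "pixels") else np.asarray(image)
    PILImage.fromarray(pixels).save(path)
    return path


def write_feature_table(data: Dataset, path: str | Path) -> Path:
    """Write a feature table as CSV: image_id, features..., optional label.

    Values are written with 17 significant digits so the round-trip through
    text is lossless for double precision.
    """
    path = Path(path)
    df = pd.DataFrame(data.X, columns=data.names)
    df.insert(0, "image_id", data.ids)
    if data.labels is not None:
        df["label"] = data.labels
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_feature_table(path: str | Path, set_id: str = "CUSTOM90") -> Dataset:
    """Read a feature-table CSV back into a :class:`Dataset`.

    Duplicate image ids are rejected; a missing ``label`` column yields a
    dataset without labels (training will refuse it downstream).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "image_id" not in df.columns:
        raise InvalidSpecError(f"{path} has no image_id column")
    ids = df["image_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise InvalidSpecError(f"{path} contains duplicate image ids")
    labels = None
    feature_cols = [c for c in df.columns if c != "image_id"]
    if "label" in df.columns:
        labels = df["label"].astype(int).tolist()
        feature_cols.remove("label")
    X = df[feature_cols].to_numpy(dtype=float)
    return Dataset(X=X, names=feature_cols, set_id=set_id, ids=ids, labels=labels)
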