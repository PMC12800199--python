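"""Deep image embeddings with a pluggable backbone.

The grading pipeline consumes the penultimate-layer activations of a
pretrained convolutional network as a fixed image embedding. Two backbones
are provided:

* ``stub`` — a deterministic random-projection embedding (grayscale 32x32
  downsample, flatten, fixed seeded projection, rectification). It needs no
  weights or network access and exercises every downstream stage (fusion,
  training, metrics) exactly as a real network would; only the output
  dimension differs.
* ``resnet50`` — the ImageNet-pretrained ResNet-50, whose globally pooled
  2048-vector before the classification head serves as the embedding.
  Requires the optional ``torch`` extra and downloaded weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .types import FeatureVector, FundusDRError, InvalidSpecError, as_rgb_array, image_id
from .preprocess import to_grayscale

__all__ = ["Backbone", "stub_backbone", "resnet50_backbone", "extract_deep"]


class BackboneUnavailableError(FundusDRError, RuntimeError):
    """The requested backbone cannot run in this environment."""


@dataclass
class Backbone:
    """A deterministic image -> vector embedding."""

    name: str
    input_size: int
    output_dim: int
    preprocessing_recipe: dict
    _apply: "callable" = field(repr=False, default=None)

    def apply(self, rgb: np.ndarray) -> np.ndarray:
        return self._apply(rgb)


def stub_backbone(seed: int = 0, output_dim: int = 128) -> Backbone:
    """Seeded random-projection backbone; identical across processes.

    The image is converted to grayscale, resized (aspect-preserving, padded)
    to 32x32, flattened to [0, 1] and multiplied by a fixed Gaussian
    projection matrix scaled by 1/sqrt(1024), then rectified. Distinct
    images map to distinct embeddings with overwhelming probability.
    """
    if output_dim < 1:
        raise InvalidSpecError("output_dim must be >= 1")
    side = 32
    rng = np.random.default_rng(seed)
    projection = rng.standard_normal((output_dim, side * side)) / np.sqrt(side * side)

    def _apply(rgb: np.ndarray) -> np.ndarray:
        gray = to_grayscale(rgb) / 255.0
        h, w = gray.shape
        scale = side / max(h, w)
        nh, nw = max(int(round(h * scale)), 1), max(int(round(w * scale)), 1)
        small = resize(gray, (nh, nw), order=1, mode="edge",
                       anti_aliasing=scale < 1.0, preserve_range=True)
        canvas = np.zeros((side, side))
        r0, c0 = (side - nh) // 2, (side - nw) // 2
        canvas[r0:r0 + nh, c0:c0 + nw] = small
        return np.maximum(projection @ canvas.ravel(), 0.0)

    return Backbone(
        name="stub",
        input_size=side,
        output_dim=output_dim,
        preprocessing_recipe={
            "resize": "aspect-preserving, zero-padded", "size": side,
            "grayscale": True, "scale": "[0,1]", "seed": int(seed),
        },
        _apply=_apply,
    )


def resnet50_backbone() -> Backbone:
    """ImageNet-pretrained ResNet-50 penultimate (global-pooled 2048) features.

    Optional: needs the ``torch`` extra and local pretrained weights.
    """
    try:
        import torch
        import torchvision.models as tvm
        import torchvision.transforms as T
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise BackboneUnavailableError(
            "torch/torchvision are not installed; install the 'torch' extra "
            "or use the offline stub backbone (fundusdr.deep.stub_backbone)"
        ) from exc

    model = tvm.resnet50(weights=tvm.ResNet50_Weights.IMAGENET1K_V2)
    model.fc = torch.nn.Identity()
    model.eval()
    normalize = T.Normalize(mean=[0.485, 0.456, 0.406], std=[0.229, 0.224, 0.225])

    def _apply(rgb: np.ndarray) -> np.ndarray:  # pragma: no cover
        x = torch.from_numpy(rgb.astype(np.float32) / 255.0).permute(2, 0, 1)
        x = T.functional.resize(x, [224, 224], antialias=True)
        with torch.no_grad():
            out = model(normalize(x)[None])
        return out.numpy().ravel()

    return Backbone(
        name="resnet50", input_size=224, output_dim=2048,
        preprocessing_recipe={
            "resize": 224, "normalize_mean": [0.485, 0.456, 0.406],
            "normalize_std": [0.229, 0.224, 0.225],
        },
        _apply=_apply,
    )


def get_backbone(name: str, seed: int = 0, output_dim: int = 128) -> Backbone:
    if name == "stub":
        return stub_backbone(seed=seed, output_dim=output_dim)
    if name == "resnet50":
        return resnet50_backbone()
    raise InvalidSpecError(f"unknown backbone {name!r}")


def extract_deep(image, backbone: Backbone) -> FeatureVector:
    """Embed an (enhanced) image through the backbone's penultimate layer."""
    rgb = as_rgb_array(image)
    vec = backbone.apply(rgb)
    names = [f"deep_{backbone.name}_{k}" for k in range(backbone.output_dim)]
    return FeatureVector(values=vec, names=names, set_id="DEEP",
                         source_image_id=image_id(image))
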