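"""Frozen per-image feature extractors (the image encoder φ).

The classifier never trains the image encoder: features are extracted
once by a frozen backbone and the graph aggregate encoder is trained on
top. Production backbones (DenseNet-121, ResNet-50, ViT-16; embedding
dims 1024, 2048, 1024) require a deep-learning runtime and pretrained
weights and are registered here by name and dimension only — asking for
one without the runtime raises an explicit error rather than silently
downloading anything. Desk-scale work uses:

* ``tinycnn`` — a small randomly-initialised (seeded) two-layer
  convolutional extractor; random convolutional features are a standard
  cheap stand-in for a pretrained backbone in pipeline testing.
* ``identity`` — block-averages the image to a small grid and flattens
  it, giving exact, interpretable features for arithmetic-level tests.

Both are deterministic: the same image always maps to the same vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

from .synthetic import SubjectRecord

__all__ = ["EncoderSpec", "FeatureMatrix", "make_encoder", "encode_subject", "ENCODER_DIMS"]

# Embedding dimension per registered encoder; None = configurable.
ENCODER_DIMS = {
    "densenet121": 1024,
    "resnet50": 2048,
    "vit16": 1024,
    "tinycnn": None,
    "identity": None,
}

_PRETRAINED = {"densenet121", "resnet50", "vit16"}


@dataclass
class EncoderSpec:
    """Configuration of a frozen image encoder."""

    name: str = "tinycnn"
    input_size: tuple[int, int] = (64, 64)
    d: int = 32  # tinycnn output dim; ignored for identity/pretrained
    weights_source: str = "random"
    frozen: bool = True


@dataclass
class FeatureMatrix:
    """S x d matrix of per-image embeddings; row s is h_s = φ(x_s)."""

    features: np.ndarray
    encoder_name: str

    @property
    def S(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]


class IdentityEncoder:
    """Block-average to `input_size` then flatten; d = H*W."""

    def __init__(self, input_size: tuple[int, int]):
        self.input_size = input_size
        self.d = input_size[0] * input_size[1]
        self.name = "identity"

    def __call__(self, image: np.ndarray) -> np.ndarray:
        img = _ensure_size(image, self.input_size)
        return img.ravel().astype(np.float64)


class TinyCNNEncoder:
    """Two seeded random conv layers (stride 2) + ReLU, average-pooled
    to a 2x2 grid, normalised by frozen per-feature statistics, then a
    fixed random linear projection to d.

    The frozen statistics play the role that batch-norm running stats
    play in a pretrained backbone: without them every output shares the
    channel-bias response and all embeddings correlate near 1 regardless
    of content, which would make a correlation-thresholded graph
    meaningless. They are estimated once at construction from seeded
    speckle calibration images and never updated, so the encoder stays a
    frozen deterministic map.
    """

    _N_CALIBRATION = 64

    def __init__(self, input_size: tuple[int, int], d: int, seed: int):
        self.input_size = input_size
        self.d = d
        self.name = "tinycnn"
        rng = np.random.default_rng(seed)
        self.w1 = rng.normal(0, 1.0 / 3.0, size=(8, 3, 3))
        self.b1 = rng.normal(0, 0.1, size=8)
        self.w2 = rng.normal(0, 1.0 / np.sqrt(8 * 9), size=(16, 8, 3, 3))
        self.b2 = rng.normal(0, 0.1, size=16)
        self.proj = rng.normal(0, 1.0 / 8.0, size=(64, d))
        cal = np.stack([
            self._pooled(np.clip(
                rng.uniform(0.2, 0.7)
                * rng.rayleigh(np.sqrt(2.0 / np.pi), size=input_size), 0.0, 1.0))
            for _ in range(self._N_CALIBRATION)
        ])
        self.feat_mean = cal.mean(axis=0)
        sd = cal.std(axis=0)
        self.feat_scale = np.where(sd > 0, sd, 1.0)

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
        # x: (C_in, H, W); w: (C_out, C_in, 3, 3); valid conv, stride 2
        win = sliding_window_view(x, (3, 3), axis=(1, 2))[:, ::2, ::2]  # (C,h,w,3,3)
        return np.einsum("chwij,ocij->ohw", win, w) + b[:, None, None]

    def _pooled(self, image: np.ndarray) -> np.ndarray:
        img = _ensure_size(image, self.input_size)
        # light despeckling, as a B-mode pipeline would apply before analysis
        img = gaussian_filter(img, sigma=1.0)
        x = self._conv(img[None], self.w1[:, None], self.b1)
        x = np.maximum(x, 0.0)
        x = self._conv(x, self.w2, self.b2)
        x = np.maximum(x, 0.0)
        # average-pool each channel on a 2x2 grid -> 16*4 = 64 features
        h, w = x.shape[1], x.shape[2]
        pooled = x[:, : h - h % 2, : w - w % 2]
        return pooled.reshape(16, 2, h // 2, 2, w // 2).mean(axis=(2, 4)).ravel()

    def __call__(self, image: np.ndarray) -> np.ndarray:
        z = (self._pooled(image) - self.feat_mean) / self.feat_scale
        return (z @ self.proj).astype(np.float64)


def _ensure_size(image: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Resize with bilinear interpolation (anti-aliased) if needed."""
    image = np.asarray(image, dtype=np.float64)
    if image.shape == tuple(size):
        return image
    return resize(image, size, order=1, anti_aliasing=True, preserve_range=True)


def make_encoder(spec: EncoderSpec, seed: int = 0):
    """Build a deterministic image -> R^d map from an encoder spec."""
    if spec.name not in ENCODER_DIMS:
        raise ValueError(f"unknown encoder {spec.name!r}; known: {sorted(ENCODER_DIMS)}")
    if spec.name in _PRETRAINED:
        raise RuntimeError(
            f"encoder {spec.name!r} (d={ENCODER_DIMS[spec.name]}) needs a deep-learning "
            "runtime and pretrained weights; supply precomputed feature matrices "
            "instead, or use 'tinycnn'/'identity' for self-contained runs"
        )
    if spec.name == "identity":
        return IdentityEncoder(spec.input_size)
    return TinyCNNEncoder(spec.input_size, spec.d, seed)


def encode_subject(subject: SubjectRecord, encoder) -> FeatureMatrix:
    """Encode every image of a subject; row order follows image order."""
    if subject.S == 0:
        raise ValueError(f"subject {subject.subject_id} has no images")
    rows = np.stack([encoder(img) for img in subject.images])
    if not np.all(np.isfinite(rows)):
        raise ValueError("non-finite features produced")
    return FeatureMatrix(features=rows, encoder_name=encoder.name)
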