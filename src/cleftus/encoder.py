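"""Image-to-embedding feature extractors.

One encoder — one parameter set — serves both modality branches: the
ultrasound chunk image and the aligned spectrogram image pass through the
same network, which is what makes the architecture Siamese.  Two backbones
are supported:

``vit_trainable``
    A vision transformer implemented in this package, trainable end to end
    or frozen at initialization with only the projection head trainable.
    The desk-scale default (2 layers, 64 hidden units) keeps CPU runs in
    seconds; the full configuration (12 layers, 12 heads, 768 hidden) is a
    preset.

``biomedclip_frozen``
    An adapter for a pretrained biomedical CLIP vision tower used zero-shot
    as a frozen feature extractor.  It requires the optional ``open_clip``
    / ``torch`` stack and a resolvable weight reference, and raises a
    dependency error with an actionable message otherwise.

Per-modality embeddings are fused by concatenation into a joint embedding
of twice the projection dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import DependencyError
from .nn import Linear, Module, Parameter, VisionTransformer

__all__ = [
    "ViTConfig",
    "VIT_FULL",
    "EncoderSpec",
    "Embedding",
    "SiameseEncoder",
    "encode",
    "make_joint_embedding",
]


@dataclass
class ViTConfig:
    """Vision-transformer hyperparameters.

    Defaults are the desk-scale test configuration; :data:`VIT_FULL` holds
    the full-size configuration (patch 16, 12 layers, 12 heads, 768 hidden,
    dropout 0.1).
    """

    patch_size: int = 16
    n_layers: int = 2
    n_heads: int = 4
    hidden_dim: int = 64
    dropout: float = 0.1
    image_size: int = 224
    pool: Literal["cls", "mean"] = "mean"

    def __post_init__(self) -> None:
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be divisible by patch_size")
        if self.hidden_dim % self.n_heads:
            raise ValueError("hidden_dim must be divisible by n_heads")


#: The full-size configuration used for the published architecture scale.
VIT_FULL = ViTConfig(n_layers=12, n_heads=12, hidden_dim=768)


@dataclass
class EncoderSpec:
    """What encoder to build and how large its output embedding is."""

    backbone: Literal["vit_trainable", "biomedclip_frozen"] = "vit_trainable"
    projection_dim: int = 128
    weights_ref: str | None = None
    freeze_backbone: bool = False
    vit: ViTConfig = field(default_factory=ViTConfig)

    def __post_init__(self) -> None:
        if self.projection_dim < 2:
            raise ValueError("projection_dim must be >= 2")
        if self.backbone == "biomedclip_frozen" and not self.weights_ref:
            raise ValueError("biomedclip_frozen requires a weights_ref")


@dataclass
class Embedding:
    vector: np.ndarray
    modality: Literal["ultrasound", "spectrogram", "joint"]

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if self.vector.ndim != 1:
            raise ValueError("embedding vector must be 1-D")
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("embedding contains non-finite values")


class _BiomedClipBackbone:
    """Adapter for a frozen pretrained CLIP-style vision tower."""

    def __init__(self, weights_ref: str):
        try:
            import open_clip  # noqa: F401
            import torch  # noqa: F401
        except ImportError as exc:
            raise DependencyError(
                "the biomedclip_frozen backbone needs the optional 'torch' and "
                "'open_clip_torch' packages plus downloadable pretrained "
                f"weights ({weights_ref!r}); install them or select the "
                "self-contained 'vit_trainable' backbone instead"
            ) from exc
        import open_clip
        import torch

        self._torch = torch
        model, _, _ = open_clip.create_model_and_transforms(weights_ref)
        model.eval()
        self._visual = model.visual
        self.feature_dim = int(getattr(self._visual, "output_dim"))

    def features(self, images: np.ndarray) -> np.ndarray:
        torch = self._torch
        with torch.no_grad():
            x = torch.from_numpy(np.asarray(images, dtype=np.float32))
            return self._visual(x).double().numpy()


class SiameseEncoder(Module):
    """Shared-weight encoder: frozen-or-trainable backbone + projection head.

    The same instance encodes both modalities, so weight sharing between
    the Siamese branches holds by construction.  ``encode`` is
    deterministic in evaluation mode (dropout off).
    """

    def __init__(self, spec: EncoderSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        if spec.backbone == "vit_trainable":
            c = spec.vit
            self.backbone = VisionTransformer(
                image_size=c.image_size,
                patch_size=c.patch_size,
                n_layers=c.n_layers,
                n_heads=c.n_heads,
                hidden_dim=c.hidden_dim,
                dropout=c.dropout,
                pool=c.pool,
                rng=rng,
            )
            feature_dim = c.hidden_dim
        elif spec.backbone == "biomedclip_frozen":
            self.backbone = _BiomedClipBackbone(spec.weights_ref)
            feature_dim = self.backbone.feature_dim
        else:
            raise ValueError(f"unknown backbone {spec.backbone!r}")
        self.feature_dim = feature_dim
        self.head = Linear(feature_dim, spec.projection_dim, rng)
        if self.backbone_frozen and isinstance(self.backbone, VisionTransformer):
            # frozen weights never see a gradient: single precision halves
            # the cost of feature extraction at no loss that matters here
            for p in self.backbone.parameters().values():
                p.value = p.value.astype(np.float32)

    # -- properties ----------------------------------------------------
    @property
    def backbone_frozen(self) -> bool:
        return self.spec.freeze_backbone or self.spec.backbone == "biomedclip_frozen"

    def trainable_parameters(self) -> dict[str, Parameter]:
        if self.backbone_frozen:
            return {f"head.{k}": p for k, p in self.head.parameters().items()}
        return self.parameters()

    def parameters(self) -> dict[str, Parameter]:
        out = {}
        if isinstance(self.backbone, Module):
            out.update(
                {f"backbone.{k}": p for k, p in self.backbone.parameters().items()}
            )
        out.update({f"head.{k}": p for k, p in self.head.parameters().items()})
        return out

    # -- forward / backward -------------------------------------------
    def features(self, images: np.ndarray) -> np.ndarray:
        """Penultimate-layer features, always in evaluation mode."""
        images = self._check_images(images)
        if isinstance(self.backbone, VisionTransformer):
            return self.backbone.forward(images, train=False)
        return self.backbone.features(images)

    def project(self, feats: np.ndarray) -> np.ndarray:
        return self.head.forward(feats)

    def encode_batch(
        self,
        images: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Encode (B, 3, H, W) images to (B, projection_dim) embeddings."""
        images = self._check_images(images)
        if isinstance(self.backbone, VisionTransformer):
            feats = self.backbone.forward(images, train=train and not self.backbone_frozen, rng=rng)
        else:
            feats = self.backbone.features(images)
        return self.head.forward(feats)

    def backward(self, g_embeddings: np.ndarray) -> None:
        """Backpropagate from embedding gradients into parameter grads.

        In frozen-backbone mode only the projection head accumulates
        gradients; otherwise the gradient continues through the backbone.
        """
        g_feats = self.head.backward(g_embeddings)
        if not self.backbone_frozen and isinstance(self.backbone, VisionTransformer):
            self.backbone.backward(g_feats)

    def _check_images(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 3:
            images = images[None]
        size = self.spec.vit.image_size if self.spec.backbone == "vit_trainable" else 224
        if images.ndim != 4 or images.shape[1] != 3 or images.shape[2:] != (size, size):
            raise ValueError(
                f"expected (B, 3, {size}, {size}) images, got {images.shape}"
            )
        return images


def encode(
    image: np.ndarray,
    encoder: SiameseEncoder,
    modality: Literal["ultrasound", "spectrogram"] = "ultrasound",
) -> Embedding:
    """Encode one normalized chunk image into a per-modality embedding."""
    vec = encoder.encode_batch(image[None] if image.ndim == 3 else image)[0]
    return Embedding(vector=vec, modality=modality)


def make_joint_embedding(e_us: Embedding, e_sp: Embedding) -> Embedding:
    """Fuse per-modality embeddings by concatenation [ultrasound; spectrogram].

    No renormalization: the joint squared norm is the sum of the two
    modality squared norms.
    """
    if e_us.modality != "ultrasound" or e_sp.modality != "spectrogram":
        raise ValueError(
            "make_joint_embedding expects (ultrasound, spectrogram) embeddings, "
            f"got ({e_us.modality}, {e_sp.modality})"
        )
    if e_us.vector.shape != e_sp.vector.shape:
        raise ValueError("modality embeddings must share projection_dim")
    return Embedding(
        vector=np.concatenate([e_us.vector, e_sp.vector]), modality="joint"
    )
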