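"""Embedding backbones for raw-channel image features.

A backbone is a pure, deterministic function from a single-channel image
to a fixed-length vector.  Two backbones are registered:

``testhash``
    A download-free deterministic backbone: multi-scale grid-pooled
    intensity and gradient statistics, projected to 2,048 dimensions by
    a fixed Gaussian random projection (seeded from the backbone id).
    It captures coarse spatial texture -- enough for clustered versus
    dispersed cell arrangements to separate -- with no learned weights.

``resnet50-imagenet``
    The reference transfer-learning backbone: ResNet-50 pretrained on
    ImageNet, the single channel replicated across the three input
    planes, features taken before the classification layers (2,048-d).
    Requires torch + torchvision and downloaded weights; constructing it
    without them raises with instructions.
"""

from __future__ import annotations

import hashlib

import numpy as np


def _block_reduce_mean(img: np.ndarray, factor: int) -> np.ndarray:
    """Mean-pool by an integer factor, edge-padding to a multiple."""
    if factor == 1:
        return img
    h, w = img.shape
    ph = (-h) % factor
    pw = (-w) % factor
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="edge")
    h, w = img.shape
    return img.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def _grid_stats(img: np.ndarray, grid: int) -> np.ndarray:
    """Per-grid-cell mean/std/max of intensity and mean/std of gradient
    magnitude over a grid x grid partition."""
    h, w = img.shape
    gy, gx = np.gradient(img)
    gmag = np.hypot(gy, gx)
    stats = []
    rs = np.linspace(0, h, grid + 1).astype(int)
    cs = np.linspace(0, w, grid + 1).astype(int)
    for i in range(grid):
        for j in range(grid):
            cell = img[rs[i] : rs[i + 1], cs[j] : cs[j + 1]]
            gcell = gmag[rs[i] : rs[i + 1], cs[j] : cs[j + 1]]
            if cell.size == 0:
                stats.extend([0.0] * 5)
                continue
            stats.extend(
                [cell.mean(), cell.std(), cell.max(), gcell.mean(), gcell.std()]
            )
    return np.array(stats)


class HashProjectionBackbone:
    """Deterministic multi-scale statistics + fixed random projection."""

    def __init__(self, output_dim: int = 2048, scales: tuple[int, ...] = (1, 2, 4, 8), grid: int = 4):
        self.id = "testhash"
        self.output_dim = output_dim
        self.scales = scales
        self.grid = grid
        self._projection: np.ndarray | None = None

    def _features(self, img: np.ndarray) -> np.ndarray:
        feats = []
        for s in self.scales:
            scaled = _block_reduce_mean(img, s)
            feats.append(_grid_stats(scaled, self.grid))
            hist, _ = np.histogram(scaled, bins=16, range=(0.0, 1.0))
            feats.append(hist / max(scaled.size, 1))
        return np.concatenate(feats)

    def _proj(self, in_dim: int) -> np.ndarray:
        if self._projection is None or self._projection.shape[1] != in_dim:
            digest = hashlib.sha256(self.id.encode()).digest()
            rng = np.random.default_rng(int.from_bytes(digest[:4], "big"))
            self._projection = rng.standard_normal((self.output_dim, in_dim)) / np.sqrt(in_dim)
        return self._projection

    def embed(self, img: np.ndarray) -> np.ndarray:
        img = np.asarray(img, dtype=np.float64)
        if img.ndim != 2:
            raise ValueError("backbone input must be a 2-D image")
        f = self._features(img)
        return self._proj(len(f)) @ f


class ResNet50Backbone:
    """ImageNet-pretrained ResNet-50 feature extractor (optional)."""

    def __init__(self):
        self.id = "resnet50-imagenet"
        self.output_dim = 2048
        try:
            import torch  # noqa: F401
            import torchvision  # noqa: F401
        except ImportError as err:
            raise ImportError(
                "the resnet50-imagenet backbone needs torch and torchvision "
                "with downloaded ImageNet weights; use the 'testhash' backbone "
                "for a download-free deterministic alternative"
            ) from err
        import torch
        from torchvision.models import ResNet50_Weights, resnet50

        model = resnet50(weights=ResNet50_Weights.IMAGENET1K_V2)
        self._model = torch.nn.Sequential(*list(model.children())[:-1]).eval()
        self._torch = torch

    def embed(self, img: np.ndarray) -> np.ndarray:
        torch = self._torch
        x = torch.as_tensor(np.asarray(img, dtype=np.float32))
        x = x[None, None].repeat(1, 3, 1, 1)  # replicate across RGB planes
        with torch.no_grad():
            z = self._model(x)
        return z.squeeze().numpy()


_REGISTRY = {
    "testhash": HashProjectionBackbone,
    "resnet50-imagenet": ResNet50Backbone,
}


def get_backbone(backbone_id: str):
    if backbone_id not in _REGISTRY:
        raise KeyError(
            f"unknown backbone {backbone_id!r}; registered: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[backbone_id]()
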