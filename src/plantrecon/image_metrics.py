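"""Rendered-image quality metrics: MSE, PSNR, SSIM, and LPIPS.

PSNR and SSIM are the classical fidelity measures::

    PSNR = 10 log10(MAX_I^2 / MSE)
    SSIM(x, y) = (2 mu_x mu_y + C1)(2 sigma_xy + C2)
                 / ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2))

LPIPS is a layer-feature distance: a backbone network maps each image to
``L`` feature stacks ``y^l`` of shape ``(H_l, W_l, C_l)``; features are
unit-normalized along the channel axis at every spatial location,
differenced, weighted channel-wise by ``w_l``, squared-l2-summed over
channels, averaged over ``H_l x W_l``, and summed over layers.  With
``w_l = 1/C_l`` the per-location summand reduces to a (scaled) cosine
distance of the normalized feature vectors.

The backbone is a pluggable contract (:class:`FeatureBackbone`).  The
default :class:`ConvBankBackbone` is a deterministic fixed-seed bank of
random convolutions — no trained weights, no downloads — which satisfies
every structural property of the distance (symmetry, identity-of-
indiscernibles at the feature level, normalization invariance).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "Raster",
    "FeatureBackbone",
    "ToyBackbone",
    "ConvBankBackbone",
    "mse",
    "psnr",
    "ssim",
    "lpips",
    "average_image_metrics",
    "load_raster",
]

_NORM_EPS = 1e-10  # guards channel normalization against zero-norm features


@dataclass
class Raster:
    """An image grid of intensities in ``[0, max_value]``.

    ``pixels`` is ``(m, n)`` grayscale or ``(m, n, 3)`` color, float64.
    """

    pixels: np.ndarray
    max_value: float = 255.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim not in (2, 3) or self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError(f"pixels must be (m,n) or (m,n,3), got {self.pixels.shape}")
        if self.pixels.min() < 0 or self.pixels.max() > self.max_value:
            raise ValueError("intensities must lie in [0, max_value]")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.pixels.shape

    def grayscale(self) -> np.ndarray:
        """Channel-mean grayscale plane."""
        if self.pixels.ndim == 2:
            return self.pixels
        return self.pixels.mean(axis=2)


def load_raster(path: Union[str, Path]) -> Raster:
    """Read a PNG/JPEG raster; 16-bit PNG maps to ``max_value=65535``."""
    img = Image.open(path)
    if img.mode == "I;16":
        return Raster(np.asarray(img, dtype=np.float64), 65535.0)
    if img.mode not in ("L", "RGB"):
        img = img.convert("RGB")
    return Raster(np.asarray(img, dtype=np.float64), 255.0)


def _check_shapes(a: Raster, b: Raster) -> None:
    if a.pixels.shape != b.pixels.shape:
        raise ValueError(f"image shapes differ: {a.pixels.shape} vs {b.pixels.shape}")


def mse(reference: Raster, test: Raster) -> float:
    """Mean squared intensity difference over all pixels and channels."""
    _check_shapes(reference, test)
    diff = reference.pixels - test.pixels
    return float(np.mean(diff * diff))


def psnr(reference: Raster, test: Raster) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images are identical."""
    err = mse(reference, test)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(reference.max_value**2 / err))


def ssim(
    x: Raster,
    y: Raster,
    k1: float = 0.01,
    k2: float = 0.03,
    mode: str = "global",
    window: int = 11,
) -> float:
    """Structural similarity index.

    ``global`` mode applies the SSIM formula once over the whole image
    (channel-mean grayscale for color inputs) with stabilizers
    ``C1 = (k1 MAX_I)^2`` and ``C2 = (k2 MAX_I)^2``.  ``windowed`` mode
    averages the same formula over sliding uniform windows.
    """
    _check_shapes(x, y)
    if k1 <= 0 or k2 <= 0:
        raise ValueError("stabilizers k1, k2 must be > 0")
    gx, gy = x.grayscale(), y.grayscale()
    c1 = (k1 * x.max_value) ** 2
    c2 = (k2 * x.max_value) ** 2
    if mode == "global":
        mu_x, mu_y = gx.mean(), gy.mean()
        var_x, var_y = gx.var(), gy.var()
        cov = ((gx - mu_x) * (gy - mu_y)).mean()
        return float(((2 * mu_x * mu_y + c1) * (2 * cov + c2))
                     / ((mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)))
    if mode == "windowed":
        u = lambda im: ndimage.uniform_filter(im, size=window, mode="reflect")
        mu_x, mu_y = u(gx), u(gy)
        var_x = u(gx * gx) - mu_x**2
        var_y = u(gy * gy) - mu_y**2
        cov = u(gx * gy) - mu_x * mu_y
        smap = ((2 * mu_x * mu_y + c1) * (2 * cov + c2)) / (
            (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2))
        return float(smap.mean())
    raise ValueError("mode must be 'global' or 'windowed'")


class FeatureBackbone:
    """Contract for LPIPS feature extractors.

    Subclasses implement :meth:`extract`, returning one ``(H_l, W_l, C_l)``
    float array per layer, deterministically for a fixed instance.
    ``channel_weights`` holds one non-negative weight vector of length
    ``C_l`` per layer; the default is the uniform ``1/C_l``.
    """

    channel_weights: List[np.ndarray]

    def extract(self, raster: Raster) -> List[np.ndarray]:  # pragma: no cover
        raise NotImplementedError

    @property
    def layer_count(self) -> int:
        return len(self.channel_weights)


class ToyBackbone(FeatureBackbone):
    """Backbone built from explicit per-layer feature functions (for tests)."""

    def __init__(self, layer_fns, channel_weights):
        self._fns = list(layer_fns)
        self.channel_weights = [np.asarray(w, dtype=float) for w in channel_weights]
        if len(self._fns) != len(self.channel_weights):
            raise ValueError("one weight vector per layer required")

    def extract(self, raster: Raster) -> List[np.ndarray]:
        return [np.asarray(fn(raster), dtype=np.float64) for fn in self._fns]


class ConvBankBackbone(FeatureBackbone):
    """Deterministic multi-scale random-convolution feature bank.

    Layer ``l`` applies a fixed bank of seeded Gaussian 3x3 kernels to the
    previous layer's activations, a ReLU nonlinearity, and 2x average
    pooling.  No training is involved; the bank is a pure function of its
    seed.  Inputs are normalized to ``[0, 1]`` so the distance is
    independent of bit depth.
    """

    def __init__(self, channels: Sequence[int] = (8, 16, 32), seed: int = 0):
        rng = np.random.default_rng(seed)
        self._kernels: List[np.ndarray] = []
        prev = 3
        for c in channels:
            k = rng.normal(size=(c, prev, 3, 3)) / np.sqrt(9 * prev)
            self._kernels.append(k)
            prev = c
        self.channel_weights = [np.full(c, 1.0 / c) for c in channels]

    def extract(self, raster: Raster) -> List[np.ndarray]:
        px = raster.pixels / raster.max_value
        if px.ndim == 2:
            px = np.stack([px] * 3, axis=2)
        act = px  # (H, W, C)
        feats: List[np.ndarray] = []
        for bank in self._kernels:
            out = np.empty(act.shape[:2] + (bank.shape[0],))
            for j in range(bank.shape[0]):
                acc = np.zeros(act.shape[:2])
                for i in range(act.shape[2]):
                    acc += ndimage.correlate(act[:, :, i], bank[j, i], mode="reflect")
                out[:, :, j] = acc
            out = np.maximum(out, 0.0)  # ReLU
            feats.append(out)
            # 2x average pooling (trailing row/col dropped on odd sizes)
            h, w = out.shape[0] // 2 * 2, out.shape[1] // 2 * 2
            act = out[:h, :w].reshape(h // 2, 2, w // 2, 2, -1).mean(axis=(1, 3))
        return feats


def _normalize_channels(feat: np.ndarray) -> np.ndarray:
    norm = np.sqrt(np.sum(feat * feat, axis=2, keepdims=True))
    return feat / (norm + _NORM_EPS)


def lpips(x: Raster, x0: Raster, backbone: FeatureBackbone) -> float:
    """Layer-feature perceptual distance between two images (>= 0).

    Features are unit-normalized along channels per spatial location,
    differenced, channel-weighted, squared-l2-summed over channels,
    averaged spatially, and summed over layers.
    """
    _check_shapes(x, x0)
    fx = backbone.extract(x)
    f0 = backbone.extract(x0)
    total = 0.0
    for feat_x, feat_0, w in zip(fx, f0, backbone.channel_weights):
        if feat_x.shape != feat_0.shape:
            raise ValueError("backbone returned mismatched feature shapes")
        diff = _normalize_channels(feat_x) - _normalize_channels(feat_0)
        weighted = diff * w  # broadcast over channel axis
        sq = np.sum(weighted * weighted, axis=2)
        total += float(sq.mean())
    return total


def average_image_metrics(
    rendered: Sequence[Raster],
    validation: Sequence[Raster],
    backbone: FeatureBackbone,
) -> Tuple[Optional[float], float, float, int]:
    """Mean PSNR / SSIM / LPIPS over paired image lists.

    Infinite PSNR values (identical pairs) are excluded from the PSNR
    mean; the count of excluded pairs is returned as the fourth element.
    The mean PSNR is ``None`` when every pair was identical.
    """
    if len(rendered) != len(validation):
        raise ValueError("rendered and validation lists differ in length")
    if len(rendered) == 0:
        raise ValueError("need at least one image pair")
    psnrs = [psnr(v, r) for r, v in zip(rendered, validation)]
    ssims = [ssim(v, r) for r, v in zip(rendered, validation)]
    lpipss = [lpips(r, v, backbone) for r, v in zip(rendered, validation)]
    finite = [p for p in psnrs if np.isfinite(p)]
    n_inf = len(psnrs) - len(finite)
    mean_psnr = float(np.mean(finite)) if finite else None
    return mean_psnr, float(np.mean(ssims)), float(np.mean(lpipss)), n_inf
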