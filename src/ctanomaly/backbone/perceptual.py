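"""Feature-space image distance with an injectable extractor.

The default extractor is a handcrafted Gaussian-pyramid feature stack:
deterministic, dependency-free, and differentiable through the autodiff
engine, so it can serve both as a training loss and as a standalone
metric.  A learned convolutional extractor can be injected through the
same interface when pretrained weights are available.
"""

from __future__ import annotations

import numpy as np

from .autograd import (
    DTYPE,
    Tensor,
    as_tensor,
    conv2d,
    downsample2x,
    tmean,
    upsample2x,
)

__all__ = ["GaussianPyramidFeatures", "PerceptualDistance", "perceptual_distance"]

_BINOMIAL3 = np.outer([1.0, 2.0, 1.0], [1.0, 2.0, 1.0]) / 16.0


class GaussianPyramidFeatures:
    """Multi-scale features: the image plus successively blurred and
    2x-downsampled copies, each scale weighted equally."""

    def __init__(self, levels: int = 3):
        if levels < 1:
            raise ValueError("levels must be >= 1")
        self.levels = levels
        self._kernel = Tensor(_BINOMIAL3.reshape(1, 1, 3, 3).astype(DTYPE))

    def __call__(self, x: Tensor) -> list[Tensor]:
        feats = [x]
        cur = x
        for _ in range(self.levels - 1):
            if cur.shape[-1] < 4:
                break
            blurred = conv2d(cur, self._kernel, padding=1)
            cur = downsample2x(blurred)
            feats.append(cur)
        return feats


def _resample(x: Tensor, work_resolution: int) -> Tensor:
    cur = x.shape[-1]
    if cur == work_resolution:
        return x
    if cur % work_resolution and work_resolution % cur:
        raise ValueError(
            f"work_resolution {work_resolution} must be a power-of-two "
            f"multiple or divisor of the input resolution {cur}"
        )
    while cur > work_resolution:
        x = downsample2x(x)
        cur //= 2
    while cur < work_resolution:
        x = upsample2x(x)
        cur *= 2
    return x


class PerceptualDistance:
    """Symmetric feature-space distance; images are resampled to
    ``work_resolution`` before feature extraction."""

    def __init__(self, work_resolution: int, extractor=None):
        if work_resolution < 4:
            raise ValueError("work_resolution must be >= 4")
        self.work_resolution = work_resolution
        self.extractor = extractor or GaussianPyramidFeatures()

    def __call__(self, x, y) -> Tensor:
        x, y = as_tensor(x), as_tensor(y)
        if x.shape != y.shape:
            raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
        if x.ndim == 2:
            x = x.reshape(1, 1, *x.shape)
            y = y.reshape(1, 1, *y.shape)
        x = _resample(x, self.work_resolution)
        y = _resample(y, self.work_resolution)
        fx = self.extractor(x)
        fy = self.extractor(y)
        total = None
        for a, b in zip(fx, fy):
            d = tmean((a - b) * (a - b))
            total = d if total is None else total + d
        return total * Tensor(1.0 / len(fx))


def perceptual_distance(x: np.ndarray, y: np.ndarray, work_resolution: int, extractor=None) -> float:
    """NumPy-facing wrapper returning a plain float."""
    return PerceptualDistance(work_resolution, extractor)(
        np.asarray(x, dtype=DTYPE), np.asarray(y, dtype=DTYPE)
    ).item()
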