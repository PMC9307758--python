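"""Scale-configurable style-based generator, encoder, and discriminator.

The generator synthesises from a learned constant through a stack of
style-modulated convolutions with per-layer spatial noise; the extended
latent code holds one style vector per modulated convolution, so a scan
slice is represented by ``n_layers x style_dim`` numbers (8192 at the
full 512-px scale: 16 layers of 512).  The encoder mirrors the
discriminator trunk and ends in a fully connected layer producing the
extended code, followed by a leaky ReLU with slope 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import (
    DTYPE,
    Tensor,
    add,
    as_tensor,
    broadcast_to,
    leaky_relu,
    mul,
    reshape,
    take_layer,
    upsample2x,
)
from .layers import Conv2d, Linear, Module

__all__ = [
    "BackboneConfig",
    "Generator",
    "Encoder",
    "Discriminator",
    "MappingNetwork",
    "hu_to_unit",
    "unit_to_hu",
    "HU_CLIP",
]

# HU are clipped to this window and affinely mapped to [-1, 1] before the
# networks; masks and thresholds are applied in HU space after inversion.
HU_CLIP = (-100.0, 1000.0)


def hu_to_unit(x: np.ndarray) -> np.ndarray:
    lo, hi = HU_CLIP
    x = np.clip(x, lo, hi)
    return ((x - lo) / (hi - lo) * 2.0 - 1.0).astype(DTYPE)


def unit_to_hu(x: np.ndarray) -> np.ndarray:
    lo, hi = HU_CLIP
    return (np.asarray(x, dtype=np.float64) + 1.0) / 2.0 * (hi - lo) + lo


def _default_channels(resolution: int) -> dict[int, int]:
    # shallow at high resolution so desk-scale CPU training stays cheap
    table = {4: 32, 8: 24, 16: 16, 32: 8, 64: 6, 128: 6, 256: 6, 512: 6}
    res, chans = 4, {}
    while res <= resolution:
        chans[res] = table[res]
        res *= 2
    return chans


@dataclass(frozen=True)
class BackboneConfig:
    """Geometry of the three networks; ``n_layers * style_dim`` is the
    extended-code size (16 * 512 = 8192 at full scale)."""

    resolution: int = 64
    style_dim: int = 16
    z_dim: int = 16
    channels: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        r = self.resolution
        if r < 8 or (r & (r - 1)) != 0:
            raise ValueError("resolution must be a power of two >= 8")
        if not self.channels:
            object.__setattr__(self, "channels", _default_channels(r))

    @property
    def n_layers(self) -> int:
        return 2 * int(np.log2(self.resolution)) - 2

    @property
    def code_size(self) -> int:
        return self.n_layers * self.style_dim

    @property
    def resolutions(self) -> list[int]:
        out, r = [], 4
        while r <= self.resolution:
            out.append(r)
            r *= 2
        return out

    def noise_shapes(self) -> list[tuple[int, int]]:
        """Spatial shape of the noise map feeding each styled layer."""
        return [(r, r) for r in self.resolutions for _ in (0, 1)]

    def to_dict(self) -> dict:
        return {
            "resolution": self.resolution,
            "style_dim": self.style_dim,
            "z_dim": self.z_dim,
            "channels": {str(k): v for k, v in self.channels.items()},
        }

    @staticmethod
    def from_dict(d: dict) -> "BackboneConfig":
        return BackboneConfig(
            resolution=int(d["resolution"]),
            style_dim=int(d["style_dim"]),
            z_dim=int(d["z_dim"]),
            channels={int(k): int(v) for k, v in d.get("channels", {}).items()},
        )


class StyledConv(Module):
    """3x3 conv with channel-wise style modulation and additive noise."""

    def __init__(self, c_in: int, c_out: int, style_dim: int, rng: np.random.Generator):
        self.conv = Conv2d(c_in, c_out, 3, rng, padding=1)
        self.scale_affine = Linear(style_dim, c_out, rng, gain=0.1)
        self.shift_affine = Linear(style_dim, c_out, rng, gain=0.1)
        # non-zero init keeps the noise path alive for noise-map optimization
        self.noise_strength = Tensor(np.full(1, 0.1), requires_grad=True)
        self.c_out = c_out

    def __call__(self, x: Tensor, w: Tensor, noise: Tensor) -> Tensor:
        n = x.shape[0]
        h = self.conv(x)
        scale = reshape(self.scale_affine(w), (n, self.c_out, 1, 1))
        shift = reshape(self.shift_affine(w), (n, self.c_out, 1, 1))
        h = add(mul(h, add(scale, Tensor(1.0))), shift)
        h = add(h, mul(noise, self.noise_strength))
        return leaky_relu(h, 0.2)


class Generator(Module):
    """Synthesis network: learned 4x4 constant -> styled conv stack -> image
    in [-1, 1] units (use :func:`unit_to_hu` to get HU)."""

    def __init__(self, config: BackboneConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        chans = config.channels
        self.const = Tensor(rng.standard_normal((1, chans[4], 4, 4)), requires_grad=True)
        self.layers: list[StyledConv] = []
        prev = chans[4]
        for r in config.resolutions:
            c = chans[r]
            self.layers.append(StyledConv(prev, c, config.style_dim, rng))
            self.layers.append(StyledConv(c, c, config.style_dim, rng))
            prev = c
        self.to_image = Conv2d(prev, 1, 1, rng, gain=1.0)

    def _check(self, w_plus: Tensor, noises: list[Tensor]) -> None:
        cfg = self.config
        if w_plus.ndim != 3 or w_plus.shape[1:] != (cfg.n_layers, cfg.style_dim):
            raise ValueError(
                f"latent code must be (N, {cfg.n_layers}, {cfg.style_dim}); "
                f"got {tuple(w_plus.shape)}"
            )
        shapes = cfg.noise_shapes()
        if len(noises) != len(shapes):
            raise ValueError(f"expected {len(shapes)} noise maps, got {len(noises)}")
        for k, (nz, sh) in enumerate(zip(noises, shapes)):
            if nz.shape[-2:] != sh:
                raise ValueError(f"noise map {k} must have spatial shape {sh}")

    def __call__(self, w_plus, noises) -> Tensor:
        w_plus = as_tensor(w_plus)
        noises = [as_tensor(nz) for nz in noises]
        self._check(w_plus, noises)
        n = w_plus.shape[0]
        x = broadcast_to(self.const, (n,) + self.const.shape[1:])
        li = 0
        for ri, _ in enumerate(self.config.resolutions):
            if ri > 0:
                x = upsample2x(x)
            for _ in (0, 1):
                x = self.layers[li](x, take_layer(w_plus, li), noises[li])
                li += 1
        return self.to_image(x)

    def sample_noise(self, n: int, rng: np.random.Generator) -> list[np.ndarray]:
        return [
            rng.standard_normal((n, 1, h, w)).astype(DTYPE)
            for h, w in self.config.noise_shapes()
        ]


class _Trunk(Module):
    """Shared conv trunk for the encoder and discriminator: stride-2 convs
    from full resolution down to 4x4, leaky ReLU 0.2 throughout."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator):
        chans = config.channels
        res = list(reversed(config.resolutions))  # e.g. [64, 32, 16, 8, 4]
        self.from_image = Conv2d(1, chans[res[0]], 1, rng)
        self.convs: list[Conv2d] = []
        for r_hi, r_lo in zip(res[:-1], res[1:]):
            self.convs.append(
                Conv2d(chans[r_hi], chans[r_lo], 3, rng, stride=2, padding=1)
            )
        self.out_features = chans[4] * 4 * 4
        self.resolution = config.resolution

    def __call__(self, x: Tensor) -> Tensor:
        r = self.resolution
        if x.ndim != 4 or x.shape[1] != 1 or x.shape[-2:] != (r, r):
            raise ValueError(
                f"input must be (N, 1, {r}, {r}); got {tuple(x.shape)}"
            )
        h = leaky_relu(self.from_image(x), 0.2)
        for conv in self.convs:
            h = leaky_relu(conv(h), 0.2)
        return reshape(h, (h.shape[0], self.out_features))


class Encoder(Module):
    """Maps an image to an extended latent code (one vector per G layer)."""

    def __init__(self, config: BackboneConfig, seed: int = 1):
        rng = np.random.default_rng(seed)
        self.config = config
        self.trunk = _Trunk(config, rng)
        self.head = Linear(self.trunk.out_features, config.code_size, rng)

    def __call__(self, x) -> Tensor:
        x = as_tensor(x)
        h = self.trunk(x)
        code = leaky_relu(self.head(h), 0.2)
        cfg = self.config
        return reshape(code, (x.shape[0], cfg.n_layers, cfg.style_dim))


class Discriminator(Module):
    def __init__(self, config: BackboneConfig, seed: int = 2):
        rng = np.random.default_rng(seed)
        self.config = config
        self.trunk = _Trunk(config, rng)
        self.head = Linear(self.trunk.out_features, 1, rng)

    def __call__(self, x) -> Tensor:
        return self.head(self.trunk(as_tensor(x)))


class MappingNetwork(Module):
    """z -> w mapper used only for phase-1 sampling of fake images."""

    def __init__(self, config: BackboneConfig, seed: int = 3, depth: int = 3):
        rng = np.random.default_rng(seed)
        self.config = config
        dims = [config.z_dim] + [config.style_dim] * depth
        self.fcs = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, z) -> Tensor:
        """Returns a broadcast extended code (N, L, d)."""
        h = as_tensor(z)
        for fc in self.fcs:
            h = leaky_relu(fc(h), 0.2)
        cfg = self.config
        n = h.shape[0]
        h = reshape(h, (n, 1, cfg.style_dim))
        return broadcast_to(h, (n, cfg.n_layers, cfg.style_dim))
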