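"""Training losses: non-saturating adversarial pair with scheduled R1
gradient penalty, domain-guided code consistency, and random erasing."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import DTYPE, Tensor, grad, softplus, tabs, tmean, tsum

__all__ = [
    "code_l1",
    "domain_guided_loss",
    "r1_penalty",
    "adversarial_step_losses",
    "RandomEraseParams",
    "random_erase",
]


def code_l1(a: Tensor, b: Tensor) -> Tensor:
    """Mean absolute difference between two latent codes."""
    return tmean(tabs(a - b))


def domain_guided_loss(encoder, generator, x, noises) -> Tensor:
    """L1 distance between E(x) and E(G(E(x))): keeps codes in-domain."""
    w = encoder(x)
    recon = generator(w, noises)
    w2 = encoder(recon)
    return code_l1(w2, w)


def r1_penalty(discriminator, real: np.ndarray) -> Tensor:
    """Mean squared gradient norm of D at real samples (differentiable
    w.r.t. D's parameters via double backprop)."""
    x = Tensor(np.asarray(real, dtype=DTYPE), requires_grad=True)
    out = tsum(discriminator(x))
    (gx,) = grad(out, [x], create_graph=True, allow_unused=True)
    if gx is None:  # discriminator ignores its input entirely
        return Tensor(0.0)
    sq = gx * gx
    n = real.shape[0]
    return tsum(sq) * Tensor(1.0 / n)


def adversarial_step_losses(
    discriminator,
    real: np.ndarray,
    fake,
    step_index: int,
    r1_interval: int = 16,
) -> tuple[Tensor, Tensor, Tensor]:
    """Non-saturating GAN losses.

    Returns ``(g_loss, d_loss, r1_term)`` where the R1 term is non-zero
    only on steps that are multiples of ``r1_interval``; ``fake`` may be a
    graph tensor (for generator/encoder updates) or a plain array.
    """
    real = np.asarray(real, dtype=DTYPE)
    fake_data = fake.data if isinstance(fake, Tensor) else np.asarray(fake, dtype=DTYPE)
    if real.shape[0] == 0 or fake_data.shape[0] == 0:
        raise ValueError("adversarial_step_losses: empty batch")
    d_fake = discriminator(fake)
    d_fake_detached = discriminator(Tensor(fake_data))
    d_real = discriminator(Tensor(real))
    g_loss = tmean(softplus(-d_fake))
    d_loss = tmean(softplus(d_fake_detached)) + tmean(softplus(-d_real))
    if step_index % r1_interval == 0:
        r1_term = r1_penalty(discriminator, real)
    else:
        r1_term = Tensor(0.0)
    return g_loss, d_loss, r1_term


@dataclass(frozen=True)
class RandomEraseParams:
    area_range: tuple[float, float] = (0.02, 0.25)
    aspect_range: tuple[float, float] = (0.5, 2.0)
    fill: float = -1.0

    def __post_init__(self):
        lo, hi = self.area_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("erase-area fraction range must lie inside (0, 1)")


def random_erase(
    x: np.ndarray, seed: int, params: RandomEraseParams = RandomEraseParams()
) -> np.ndarray:
    """Replace exactly one axis-aligned rectangle of ``x`` (H, W last two
    axes) by the fill value; every other pixel is returned bit-identically."""
    x = np.asarray(x)
    rng = np.random.default_rng(seed)
    h, w = x.shape[-2:]
    area_fr = rng.uniform(*params.area_range)
    aspect = rng.uniform(*params.aspect_range)
    area = area_fr * h * w
    eh = int(np.clip(round(np.sqrt(area * aspect)), 1, h))
    ew = int(np.clip(round(area / eh), 1, w))
    # keep the realised fraction inside the configured range despite rounding
    lo, hi = params.area_range
    while eh * ew > hi * h * w and (eh > 1 or ew > 1):
        if ew > 1:
            ew -= 1
        else:
            eh -= 1
    while eh * ew < lo * h * w and (eh < h or ew < w):
        if ew < w:
            ew += 1
        else:
            eh += 1
    top = int(rng.integers(0, h - eh + 1))
    left = int(rng.integers(0, w - ew + 1))
    out = x.copy()
    out[..., top : top + eh, left : left + ew] = params.fill
    return out
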