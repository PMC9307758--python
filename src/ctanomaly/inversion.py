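"""Closest-normal reconstruction of query slices.

Two stages per slice: (1) latent optimization of the extended code,
starting from the encoder output, under L1 + perceptual + conditional
in-domain losses; (2) masked noise-map optimization, where at each step
a binary lesion mask is recomputed from the current residual
(brain-extracted, median-filtered, thresholded in HU, intersected with
the mask history) and the optimization target keeps the original pixels
outside the mask and the initial-noise synthesis inside it.  The final
mask doubles as the lesion attention map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .backbone.autograd import DTYPE, Tensor, mul, tabs, tmean
from .backbone.layers import Adam
from .backbone.networks import hu_to_unit, unit_to_hu
from .backbone.perceptual import PerceptualDistance
from .latent_stats import LatentGaussian

__all__ = [
    "InversionConfig",
    "LesionMask",
    "brain_extract",
    "compute_lesion_mask",
    "masked_target",
    "invert_latent",
    "masked_noise_optimization",
    "invert_scan",
    "ScanInversion",
]


@dataclass(frozen=True)
class InversionConfig:
    latent_epochs: int = 100
    noise_iters: int = 100
    latent_lr: float = 0.01
    noise_lr: float = 0.05
    beta1: float = 0.9
    beta2: float = 0.999
    median_window_full_scale: int = 17  # window at 512-px acquisition scale
    residual_threshold_hu: float = 5.0
    indomain_weight: float = 0.1
    perceptual_weight: float = 1.0
    perceptual_resolution: int = 32
    score_with_optimized_noise: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.median_window_full_scale % 2 == 0:
            raise ValueError("median-filter window must be odd")
        if self.residual_threshold_hu <= 0:
            raise ValueError("residual threshold must be positive")

    def median_window(self, width: int) -> int:
        """Window scaled to the working resolution, kept odd and >= 3."""
        w = int(round(self.median_window_full_scale * width / 512.0))
        if w % 2 == 0:
            w += 1
        return max(w, 3)


@dataclass
class LesionMask:
    """Final binary mask plus the per-step history (an intersection
    chain, so pixel counts never increase)."""

    mask: np.ndarray
    history: list[np.ndarray] = field(default_factory=list)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def brain_extract(slice_hu: np.ndarray) -> np.ndarray:
    """Soft-tissue mask: HU window, largest connected component, filled."""
    x = np.asarray(slice_hu)
    cand = (x > -50) & (x < 150)
    if not cand.any():
        return np.zeros_like(cand)
    labels, n = ndimage.label(cand)
    largest = np.argmax(ndimage.sum_labels(cand, labels, index=range(1, n + 1))) + 1
    return ndimage.binary_fill_holes(labels == largest)


def compute_lesion_mask(
    x: np.ndarray,
    recon: np.ndarray,
    brain_mask: np.ndarray,
    prev_masks: list[np.ndarray],
    cfg: InversionConfig,
    window: int | None = None,
) -> np.ndarray:
    """Residual-based lesion mask for one slice (HU inputs)."""
    x = np.asarray(x, dtype=np.float64)
    recon = np.asarray(recon, dtype=np.float64)
    if x.shape != recon.shape:
        raise ValueError("slice and reconstruction shapes differ")
    if window is None:
        window = cfg.median_window(x.shape[-1])
    if window % 2 == 0:
        raise ValueError("median-filter window must be odd")
    residual = brain_mask * np.abs(x - recon)
    filtered = ndimage.median_filter(residual, size=window)
    mask = filtered > cfg.residual_threshold_hu
    for prev in prev_masks:
        mask &= prev.astype(bool)
    return mask


def masked_target(mask: np.ndarray, inside: np.ndarray, outside: np.ndarray) -> np.ndarray:
    """Optimization target: ``mask * inside + (1 - mask) * outside``.

    Agrees exactly with ``outside`` where the mask is 0 and with
    ``inside`` where it is 1.
    """
    m = np.asarray(mask).astype(inside.dtype if hasattr(inside, "dtype") else float)
    return m * inside + (1.0 - m) * outside


def _per_slice_l1(a: Tensor, b: Tensor) -> Tensor:
    return tmean(tabs(a - b), axis=(1, 2, 3))


def _per_slice_perceptual(percep: PerceptualDistance, a: Tensor, b: Tensor) -> Tensor:
    from .backbone.perceptual import _resample

    a = _resample(a, percep.work_resolution)
    b = _resample(b, percep.work_resolution)
    fa, fb = percep.extractor(a), percep.extractor(b)
    total = None
    for u, v in zip(fa, fb):
        d = tmean((u - v) * (u - v), axis=(1, 2, 3))
        total = d if total is None else total + d
    return total * Tensor(1.0 / len(fa))


def _stack_stats(stats: LatentGaussian, slice_orders) -> tuple[np.ndarray, np.ndarray]:
    mus, whs = [], []
    for s in slice_orders:
        s = int(s)
        if s not in stats.means:
            raise ValueError(f"slice order {s} not represented in latent statistics")
        mus.append(stats.means[s])
        whs.append(stats.whitener(s))
    return np.asarray(mus, dtype=np.float64), np.asarray(whs, dtype=np.float64)


def _batch_deviation(w: np.ndarray, mus: np.ndarray, whs: np.ndarray) -> np.ndarray:
    """Summed per-layer Mahalanobis deviation for a (B, L, d) code batch."""
    diff = np.asarray(w, dtype=np.float64) - mus  # (B, L, d)
    z = np.einsum("bld,blde->ble", diff, whs)
    return np.sqrt((z**2).sum(axis=2)).sum(axis=1)


def _deviation_tensor(w: Tensor, mus: np.ndarray, whs: np.ndarray) -> Tensor:
    """Differentiable version of :func:`_batch_deviation`."""
    from .backbone.autograd import matmul, reshape, sqrt, tsum

    b, L, d = w.shape
    diff = w - Tensor(mus.astype(DTYPE))
    diff4 = reshape(diff, (b, L, 1, d))
    z = matmul(diff4, Tensor(whs.astype(DTYPE)))  # (B, L, 1, d)
    sq = tsum(z * z, axis=(2, 3))  # (B, L)
    return tsum(sqrt(sq, eps=1e-12), axis=1)  # (B,)


def invert_latent(
    x_hu: np.ndarray,
    encoder,
    generator,
    stats: LatentGaussian,
    cfg: InversionConfig,
    slice_orders=None,
    noises=None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Optimize extended codes for one slice or a batch of slices.

    Starts from ``E(x)``; minimises per-slice L1 + perceptual loss plus a
    conditional in-domain deviation term that is active only while the
    code deviates more than the reference code ``E(G(E(x), n_init))``
    does.  Returns the best-loss iterate per slice.
    """
    single = np.asarray(x_hu).ndim == 2
    x_hu = np.atleast_3d(np.asarray(x_hu, dtype=np.float64))
    if single:
        x_hu = x_hu.reshape((1,) + x_hu.shape[:2])
    b = x_hu.shape[0]
    if slice_orders is None:
        slice_orders = [min(s + 1, 32) for s in range(b)]
    rng = rng or np.random.default_rng(cfg.seed)
    x_unit = hu_to_unit(x_hu)[:, None]

    w_init = encoder(Tensor(x_unit)).data
    if noises is None:
        noises = generator.sample_noise(b, rng)
    noises = [Tensor(np.asarray(nz, dtype=DTYPE)) for nz in noises]

    if cfg.latent_epochs == 0:
        return w_init[0] if single else w_init

    mus, whs = _stack_stats(stats, slice_orders)
    # reference deviation: code of the reconstructed (in-domain) image
    recon0 = generator(Tensor(w_init), noises)
    ref_code = encoder(recon0).data
    ref_dev = np.maximum(_batch_deviation(ref_code, mus, whs), 1e-6)

    percep = PerceptualDistance(min(cfg.perceptual_resolution, x_unit.shape[-1]))
    w = Tensor(w_init.copy(), requires_grad=True)
    opt = Adam([w], cfg.latent_lr, cfg.beta1, cfg.beta2)
    best_w = w_init.copy()
    best_loss = np.full(b, np.inf)
    x_t = Tensor(x_unit)
    for epoch in range(cfg.latent_epochs):
        recon = generator(w, noises)
        l1 = _per_slice_l1(recon, x_t)
        pl = _per_slice_perceptual(percep, recon, x_t)
        dev = _deviation_tensor(w, mus, whs)
        # conditional regularizer: the relative excess deviation beyond the
        # in-domain reference code's deviation, per slice (scale-free)
        gate = (dev.data > ref_dev).astype(DTYPE)
        excess = mul(dev - Tensor(ref_dev.astype(DTYPE)), Tensor((1.0 / ref_dev).astype(DTYPE)))
        per_slice = l1 + Tensor(cfg.perceptual_weight) * pl + Tensor(
            cfg.indomain_weight
        ) * (Tensor(gate) * excess)
        loss = per_slice.sum()
        if not np.isfinite(loss.item()):
            raise FloatingPointError(f"non-finite inversion loss at epoch {epoch}")
        improved = per_slice.data < best_loss
        best_loss = np.where(improved, per_slice.data, best_loss)
        best_w[improved] = w.data[improved]
        opt.zero_grad()
        loss.backward()
        opt.step()
    return best_w[0] if single else best_w


def masked_noise_optimization(
    x_hu: np.ndarray,
    w_star: np.ndarray,
    generator,
    brain_mask: np.ndarray,
    cfg: InversionConfig,
    rng: np.random.Generator | None = None,
    noises_init=None,
):
    """Noise-map optimization with per-step lesion masking.

    Returns ``(noises, masks, recon_hu)`` where ``masks`` is a list of
    :class:`LesionMask` (one per slice, final mask + history) and
    ``recon_hu`` the final reconstruction in HU.
    """
    single = np.asarray(x_hu).ndim == 2
    x_hu = np.asarray(x_hu, dtype=np.float64)
    if single:
        x_hu = x_hu[None]
        brain_mask = np.asarray(brain_mask)[None]
        w_star = np.asarray(w_star)[None]
    b = x_hu.shape[0]
    rng = rng or np.random.default_rng(cfg.seed)
    x_unit = hu_to_unit(x_hu)[:, None]
    window = cfg.median_window(x_hu.shape[-1])

    if noises_init is None:
        noises_init = generator.sample_noise(b, rng)
    init_data = [np.asarray(nz, dtype=DTYPE).copy() for nz in noises_init]
    noises = [Tensor(nz.copy(), requires_grad=True) for nz in init_data]
    w_t = Tensor(np.asarray(w_star, dtype=DTYPE))

    base_unit = generator(w_t, [Tensor(nz) for nz in init_data]).data  # G(w*, n_init)
    opt = Adam(noises, cfg.noise_lr, cfg.beta1, cfg.beta2)
    histories: list[list[np.ndarray]] = [[] for _ in range(b)]

    def current_masks(recon_unit: np.ndarray) -> np.ndarray:
        recon_hu = unit_to_hu(recon_unit[:, 0])
        out = np.empty((b,) + x_hu.shape[1:], dtype=bool)
        for k in range(b):
            out[k] = compute_lesion_mask(
                x_hu[k], recon_hu[k], brain_mask[k], histories[k], cfg, window=window
            )
            histories[k].append(out[k])
        return out

    for step in range(cfg.noise_iters):
        recon = generator(w_t, noises)
        m = current_masks(recon.data)[:, None].astype(DTYPE)
        target = masked_target(m, base_unit, x_unit)
        loss = tmean(tabs(recon - Tensor(target.astype(DTYPE))))
        if not np.isfinite(loss.item()):
            raise FloatingPointError(f"non-finite noise-optimization loss at step {step}")
        opt.zero_grad()
        loss.backward()
        opt.step()

    final_recon = generator(w_t, noises).data
    final_m = current_masks(final_recon)
    masks = [LesionMask(final_m[k], histories[k]) for k in range(b)]
    recon_hu = unit_to_hu(final_recon[:, 0])
    if single:
        return [n.data[0] for n in noises], masks[0], recon_hu[0]
    return [n.data for n in noises], masks, recon_hu


@dataclass
class ScanInversion:
    """Per-scan inversion output: reconstructions, masks, codes."""

    case_id: str
    slice_orders: np.ndarray
    recon_hu: np.ndarray  # (n_slices, H, W)
    masks: list[LesionMask]
    codes: np.ndarray  # (n_slices, L, d)
    brain_mask: np.ndarray


def invert_scan(
    scan,
    encoder,
    generator,
    stats: LatentGaussian,
    cfg: InversionConfig,
    seed: int | None = None,
) -> ScanInversion:
    """Full inversion of a scan: latent then masked-noise optimization,
    batched over the scan's slices."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    x_hu = np.asarray(scan.slices, dtype=np.float64)
    brain = scan.brain_mask()
    if brain is None:
        brain = np.stack([brain_extract(s) for s in x_hu])
    b = x_hu.shape[0]
    noises_init = generator.sample_noise(b, rng)
    w_star = invert_latent(
        x_hu,
        encoder,
        generator,
        stats,
        cfg,
        slice_orders=scan.slice_orders,
        noises=noises_init,
        rng=rng,
    )
    noises, masks, recon_hu = masked_noise_optimization(
        x_hu, w_star, generator, brain, cfg, rng=rng, noises_init=noises_init
    )
    if not cfg.score_with_optimized_noise:
        recon_hu = unit_to_hu(
            generator(
                Tensor(np.asarray(w_star, dtype=DTYPE)),
                [Tensor(np.asarray(nz, dtype=DTYPE)) for nz in noises_init],
            ).data[:, 0]
        )
    return ScanInversion(
        case_id=scan.case_id,
        slice_orders=np.asarray(scan.slice_orders),
        recon_hu=recon_hu,
        masks=masks,
        codes=np.asarray(w_star),
        brain_mask=brain,
    )
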