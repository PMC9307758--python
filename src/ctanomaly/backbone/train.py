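"""Two-phase training of the style-based backbone.

Phase 1 trains the generator and discriminator adversarially from
sampled latents.  Phase 2 freezes the generator and trains the encoder
and discriminator with perceptual, domain-guided, and adversarial
losses, feeding the encoder randomly-erased inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .autograd import DTYPE, Tensor, softplus, tabs, tmean
from .layers import Adam
from .losses import (
    RandomEraseParams,
    adversarial_step_losses,
    code_l1,
    r1_penalty,
    random_erase,
)
from .networks import (
    BackboneConfig,
    Discriminator,
    Encoder,
    Generator,
    MappingNetwork,
    hu_to_unit,
)
from .perceptual import PerceptualDistance

__all__ = ["TrainConfig", "TrainedBackbone", "train_backbone", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of the two training phases.

    The phase-2 optimizer settings default to the published values
    (Adam beta1=0, beta2=0.99, eps=1e-8, lr 1e-5 for E / 1e-6 for D,
    minibatch 32, R1 every 16th step); desk-scale presets override the
    iteration counts, minibatch, and learning rates so that a CPU run
    finishes in minutes.
    """

    phase1_iters: int = 160_000
    phase2_iters: int = 200_000
    batch_size: int = 32
    beta1: float = 0.0
    beta2: float = 0.99
    eps: float = 1e-8
    lr_encoder: float = 1e-5
    lr_disc: float = 1e-6
    lr_gen_phase1: float = 2e-3
    lr_disc_phase1: float = 2e-3
    r1_interval: int = 16
    r1_weight: float = 10.0
    style_mix_prob: float = 0.9
    # reconstruction anchor for reduced-scale phase 1: learnable per-image
    # codes regressed through G (L1 + perceptual) alongside the adversarial
    # loss.  0 disables it (full-scale default); the desk preset enables it
    # because a few thousand adversarial-only iterations cannot shape the
    # generator manifold.
    recon_anchor_weight: float = 0.0
    anchor_code_lr: float = 0.05
    # encoder warm-up: regress the phase-1 anchor codes before phase 2 so
    # the encoder starts phase 2 (and inference) in the basin the anchored
    # generator actually reconstructs from; active only with the anchor
    encoder_warmup_iters: int = 0
    perceptual_resolution: int = 256
    erase_prob: float = 0.5
    erase_area: tuple[float, float] = (0.02, 0.25)
    w_perceptual: float = 1.0
    w_domain: float = 1.0
    w_adversarial: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("phase1_iters", "phase2_iters", "batch_size", "r1_interval"):
            if getattr(self, name) < 0 or (name != "phase1_iters" and name != "phase2_iters" and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        for name in ("lr_encoder", "lr_disc", "lr_gen_phase1", "lr_disc_phase1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def desk_train_config(
    phase1_iters: int = 2000, phase2_iters: int = 400, seed: int = 0
) -> TrainConfig:
    """CPU-friendly preset used by the reduced-scale tests.

    Differs from the published full-scale settings: larger learning
    rates, minibatch 8, the phase-1 reconstruction anchor enabled, and a
    down-weighted phase-1 adversarial term — a few thousand iterations of
    pure adversarial training cannot shape the generator manifold.
    """
    return TrainConfig(
        phase1_iters=phase1_iters,
        phase2_iters=phase2_iters,
        batch_size=8,
        lr_encoder=2e-3,
        lr_disc=2e-4,
        lr_gen_phase1=5e-3,
        lr_disc_phase1=2e-3,
        perceptual_resolution=32,
        recon_anchor_weight=1.0,
        anchor_code_lr=0.1,
        encoder_warmup_iters=800,
        w_adversarial=0.1,
        seed=seed,
    )


@dataclass
class TrainedBackbone:
    generator: Generator
    encoder: Encoder
    discriminator: Discriminator
    mapping: MappingNetwork
    config: BackboneConfig
    train_config: TrainConfig
    log: pd.DataFrame = field(repr=False, default=None)


def _as_slice_array(dataset, resolution: int) -> np.ndarray:
    """Accepts an (N, H, W) HU array or a sequence of scans; returns
    normalised (N, 1, H, W) images in [-1, 1]."""
    if hasattr(dataset, "slices"):
        dataset = [dataset]
    if isinstance(dataset, (list, tuple)) and dataset and hasattr(dataset[0], "slices"):
        arrs = [np.asarray(s.slices) for s in dataset]
        data = np.concatenate(arrs, axis=0)
    else:
        data = np.asarray(dataset)
    if data.ndim != 3:
        raise ValueError("dataset must stack to (n_slices, H, W)")
    if data.shape[0] == 0:
        raise ValueError("empty training dataset")
    if data.shape[-1] != resolution or data.shape[-2] != resolution:
        raise ValueError(
            f"training slices must be {resolution}x{resolution}; got {data.shape[-2:]}"
        )
    return hu_to_unit(data)[:, None]


class _CodeTable:
    """Learnable per-training-image codes for the phase-1 reconstruction
    anchor, updated with per-row Adam."""

    def __init__(self, n: int, bcfg: BackboneConfig, lr: float, rng: np.random.Generator):
        self.codes = (
            rng.standard_normal((n, bcfg.n_layers, bcfg.style_dim)) * 0.1
        ).astype(DTYPE)
        self.m = np.zeros_like(self.codes)
        self.v = np.zeros_like(self.codes)
        self.t = np.zeros(n, dtype=np.int64)
        self.lr = lr

    def apply_grad(self, idx: np.ndarray, grad: np.ndarray) -> None:
        b1, b2 = 0.9, 0.999
        for k in np.unique(idx):
            rows = np.flatnonzero(idx == k)
            g = grad[rows].mean(axis=0)
            self.t[k] += 1
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mh = self.m[k] / (1 - b1 ** self.t[k])
            vh = self.v[k] / (1 - b2 ** self.t[k])
            self.codes[k] -= (self.lr * mh / (np.sqrt(vh) + 1e-8)).astype(DTYPE)


def train_backbone(
    dataset,
    config: TrainConfig,
    backbone_config: BackboneConfig | None = None,
    perceptual_extractor=None,
) -> TrainedBackbone:
    """Run both training phases on a dataset of normal scans.

    Phase 1 updates only G/D; phase 2 updates only E/D (G stays frozen,
    verified by the checkpoint tests).  Every loss term is logged per
    step and the whole run is deterministic given ``config.seed``.
    """
    bcfg = backbone_config or BackboneConfig()
    x_all = _as_slice_array(dataset, bcfg.resolution)
    n_total = x_all.shape[0]
    rng = np.random.default_rng(config.seed)

    G = Generator(bcfg, seed=int(rng.integers(2**31)))
    E = Encoder(bcfg, seed=int(rng.integers(2**31)))
    D = Discriminator(bcfg, seed=int(rng.integers(2**31)))
    M = MappingNetwork(bcfg, seed=int(rng.integers(2**31)))

    records: list[dict] = []
    bs = min(config.batch_size, n_total)

    # ---- phase 1: adversarial training of G and D --------------------
    opt_g = Adam(
        G.parameters() + M.parameters(),
        config.lr_gen_phase1,
        config.beta1,
        config.beta2,
        config.eps,
    )
    opt_d = Adam(
        D.parameters(), config.lr_disc_phase1, config.beta1, config.beta2, config.eps
    )
    anchor = (
        _CodeTable(n_total, bcfg, config.anchor_code_lr, rng)
        if config.recon_anchor_weight > 0
        else None
    )
    percep1 = PerceptualDistance(
        min(config.perceptual_resolution, bcfg.resolution), perceptual_extractor
    )
    for step in range(config.phase1_iters):
        # cosine decay to 10% of the base rate over the phase
        frac = step / max(config.phase1_iters - 1, 1)
        decay = 0.55 + 0.45 * np.cos(np.pi * frac)
        opt_g.lr = config.lr_gen_phase1 * decay
        opt_d.lr = config.lr_disc_phase1 * decay
        idx = rng.integers(0, n_total, size=bs)
        real = x_all[idx]
        z = rng.standard_normal((bs, bcfg.z_dim)).astype(DTYPE)
        noises = G.sample_noise(bs, rng)

        w = M(Tensor(z))
        if config.style_mix_prob > 0 and rng.random() < config.style_mix_prob:
            # mixing regularisation: two codes split at a random layer, so
            # the generator stays well-behaved for free per-layer codes
            z2 = rng.standard_normal((bs, bcfg.z_dim)).astype(DTYPE)
            w2 = M(Tensor(z2))
            cross = int(rng.integers(1, bcfg.n_layers))
            sel = np.zeros((1, bcfg.n_layers, 1), dtype=DTYPE)
            sel[:, :cross] = 1.0
            w = w * Tensor(sel) + w2 * Tensor(1.0 - sel)
        fake = G(w, noises)
        g_loss, d_loss, r1_term = adversarial_step_losses(
            D, real, fake, step, config.r1_interval
        )
        # D update
        opt_d.zero_grad()
        d_total = d_loss + Tensor(config.r1_weight) * r1_term
        d_total.backward()
        opt_d.step()
        # G update (the pre-step D graph suffices for the non-saturating loss)
        opt_g.zero_grad()
        for p in D.parameters():
            p.grad = None
        g_total = g_loss
        rec_val = 0.0
        if anchor is not None:
            # anchored mode: regression is the workhorse, adversarial term
            # is down-weighted for stability at regression-friendly rates
            w_b = Tensor(anchor.codes[idx], requires_grad=True)
            recon = G(w_b, G.sample_noise(bs, rng))
            rec = tmean(tabs(recon - Tensor(real))) + percep1(recon, Tensor(real))
            rec_val = rec.item()
            g_total = Tensor(config.w_adversarial) * g_loss + Tensor(
                config.recon_anchor_weight
            ) * rec
        g_total.backward()
        opt_g.step()
        if anchor is not None:
            anchor.apply_grad(idx, w_b.grad.data)

        records.append(
            {
                "phase": 1,
                "step": step,
                "g_loss": g_loss.item(),
                "d_loss": d_loss.item(),
                "r1": r1_term.item(),
                "recon_anchor": rec_val,
            }
        )

    # ---- encoder warm-up on the anchor codes -------------------------
    if anchor is not None and config.encoder_warmup_iters > 0:
        opt_w = Adam(E.parameters(), config.lr_encoder, config.beta1, config.beta2)
        for step in range(config.encoder_warmup_iters):
            idx = rng.integers(0, n_total, size=bs)
            diff = E(Tensor(x_all[idx])) - Tensor(anchor.codes[idx])
            wloss = tmean(diff * diff)
            opt_w.zero_grad()
            wloss.backward()
            opt_w.step()
            records.append({"phase": 1.5, "step": step, "warmup_mse": wloss.item()})

    # ---- phase 2: train E and D, G frozen ----------------------------
    percep = PerceptualDistance(
        min(config.perceptual_resolution, bcfg.resolution), perceptual_extractor
    )
    erase_params = RandomEraseParams(area_range=config.erase_area)
    opt_e = Adam(E.parameters(), config.lr_encoder, config.beta1, config.beta2, config.eps)
    opt_d2 = Adam(D.parameters(), config.lr_disc, config.beta1, config.beta2, config.eps)
    for step in range(config.phase2_iters):
        idx = rng.integers(0, n_total, size=bs)
        real = x_all[idx]
        erased = real.copy()
        for k in range(bs):
            if rng.random() < config.erase_prob:
                erased[k] = random_erase(
                    real[k], seed=int(rng.integers(2**31)), params=erase_params
                )
        noises = G.sample_noise(bs, rng)

        w = E(Tensor(erased))
        recon = G(w, noises)
        w2 = E(recon)
        p_loss = percep(recon, Tensor(real))
        dg_loss = code_l1(w2, w)
        g_adv, d_loss, r1_term = adversarial_step_losses(
            D, real, recon, step, config.r1_interval
        )
        # E update
        e_total = (
            Tensor(config.w_perceptual) * p_loss
            + Tensor(config.w_domain) * dg_loss
            + Tensor(config.w_adversarial) * g_adv
        )
        opt_e.zero_grad()
        for p in D.parameters() + G.parameters():
            p.grad = None
        e_total.backward()
        # G frozen: discard any gradient that reached it
        for p in G.parameters():
            p.grad = None
        opt_e.step()
        # D update
        opt_d2.zero_grad()
        for p in E.parameters() + G.parameters():
            p.grad = None
        d_total = d_loss + Tensor(config.r1_weight) * r1_term
        d_total.backward()
        for p in E.parameters() + G.parameters():
            p.grad = None
        opt_d2.step()

        records.append(
            {
                "phase": 2,
                "step": step,
                "perceptual": p_loss.item(),
                "domain_guided": dg_loss.item(),
                "g_adv": g_adv.item(),
                "d_loss": d_loss.item(),
                "r1": r1_term.item(),
            }
        )

    log = pd.DataFrame.from_records(records)
    return TrainedBackbone(G, E, D, M, bcfg, config, log)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def config_hash(bcfg: BackboneConfig) -> str:
    import hashlib

    blob = json.dumps(bcfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_checkpoint(path, trained: TrainedBackbone) -> None:
    """Single-file archive holding all weights plus the config."""
    arrays: dict[str, np.ndarray] = {}
    for tag, mod in (
        ("G", trained.generator),
        ("E", trained.encoder),
        ("D", trained.discriminator),
        ("M", trained.mapping),
    ):
        for k, v in mod.state_dict().items():
            arrays[f"{tag}/{k}"] = v
    meta = {
        "backbone": trained.config.to_dict(),
        "train": asdict(trained.train_config),
        "hash": config_hash(trained.config),
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> TrainedBackbone:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        bcfg = BackboneConfig.from_dict(meta["backbone"])
        tcfg_d = meta["train"]
        tcfg_d["erase_area"] = tuple(tcfg_d["erase_area"])
        tcfg = TrainConfig(**tcfg_d)
        G, E = Generator(bcfg), Encoder(bcfg)
        D, M = Discriminator(bcfg), MappingNetwork(bcfg)
        for tag, mod in (("G", G), ("E", E), ("D", D), ("M", M)):
            state = {
                k[len(tag) + 1 :]: z[k] for k in z.files if k.startswith(tag + "/")
            }
            mod.load_state_dict(state)
    return TrainedBackbone(G, E, D, M, bcfg, tcfg, None)
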