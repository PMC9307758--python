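"""Backbone networks, losses, and the two-phase training loop."""

import dataclasses

import numpy as np
import pytest

from ctanomaly.backbone import autograd as ag
from ctanomaly.backbone.losses import (
    RandomEraseParams,
    adversarial_step_losses,
    code_l1,
    domain_guided_loss,
    random_erase,
)
from ctanomaly.backbone.networks import (
    BackboneConfig,
    Discriminator,
    Encoder,
    Generator,
    hu_to_unit,
    unit_to_hu,
)
from ctanomaly.backbone.perceptual import perceptual_distance
from ctanomaly.backbone.train import (
    TrainConfig,
    desk_train_config,
    load_checkpoint,
    save_checkpoint,
    train_backbone,
)
from ctanomaly.phantom import generate_cohort

LN2 = float(np.log(2.0))


def _rand_inputs(cfg, n=2, seed=0):
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((n, cfg.n_layers, cfg.style_dim)).astype(np.float32)
    return w, rng


class TestGenerator:
    def test_deterministic(self, small_cfg):
        G = Generator(small_cfg, seed=0)
        w, rng = _rand_inputs(small_cfg)
        noises = G.sample_noise(2, rng)
        a = G(w, noises).data
        b = G(w, noises).data
        np.testing.assert_array_equal(a, b)

    def test_zero_weights_constant_output(self, small_cfg):
        G = Generator(small_cfg, seed=0)
        state = {k: np.zeros_like(v) for k, v in G.state_dict().items()}
        G.load_state_dict(state)
        w, rng = _rand_inputs(small_cfg)
        out = G(w, G.sample_noise(2, rng)).data
        assert np.ptp(out) == 0.0

    def test_perturbing_one_layer_changes_output(self, small_cfg):
        G = Generator(small_cfg, seed=1)
        w, rng = _rand_inputs(small_cfg)
        noises = G.sample_noise(2, rng)
        base = G(w, noises).data
        w2 = w.copy()
        w2[:, 3] += 0.5
        assert not np.array_equal(G(w2, noises).data, base)

    def test_shape_validation(self, small_cfg):
        G = Generator(small_cfg, seed=0)
        w, rng = _rand_inputs(small_cfg)
        with pytest.raises(ValueError, match="latent code"):
            G(w[:, :2], G.sample_noise(2, rng))
        noises = G.sample_noise(2, rng)
        noises[0] = noises[0][:, :, :2, :2]
        with pytest.raises(ValueError, match="noise map"):
            G(w, noises)


class TestEncoder:
    def test_deterministic(self, small_cfg):
        E = Encoder(small_cfg, seed=0)
        x = np.random.default_rng(0).standard_normal((2, 1, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(E(x).data, E(x).data)

    def test_code_size_matches_config(self, small_cfg):
        E = Encoder(small_cfg, seed=0)
        x = np.zeros((1, 1, 16, 16), np.float32)
        code = E(x).data
        assert code.shape == (1, small_cfg.n_layers, small_cfg.style_dim)
        assert code.size == small_cfg.code_size

    def test_full_scale_code_size_is_8192(self):
        cfg = BackboneConfig(resolution=512, style_dim=512)
        assert cfg.n_layers == 16
        assert cfg.code_size == 8192

    def test_distinct_inputs_distinct_codes(self, small_cfg):
        E = Encoder(small_cfg, seed=0)
        rng = np.random.default_rng(1)
        a = rng.standard_normal((1, 1, 16, 16)).astype(np.float32)
        b = rng.standard_normal((1, 1, 16, 16)).astype(np.float32)
        assert not np.array_equal(E(a).data, E(b).data)

    def test_resolution_mismatch(self, small_cfg):
        E = Encoder(small_cfg, seed=0)
        with pytest.raises(ValueError, match="must be"):
            E(np.zeros((1, 1, 8, 8), np.float32))


class TestHuNormalization:
    def test_roundtrip(self):
        hu = np.array([[-100.0, 0.0, 35.0, 1000.0]])
        np.testing.assert_allclose(unit_to_hu(hu_to_unit(hu)), hu, atol=1e-3)

    def test_clipping(self):
        assert hu_to_unit(np.array([-2000.0]))[0] == -1.0
        assert hu_to_unit(np.array([3000.0]))[0] == 1.0


class TestPerceptualDistance:
    def test_identity_zero(self):
        x = np.random.default_rng(0).standard_normal((32, 32)).astype(np.float32)
        assert perceptual_distance(x, x, 32) <= 1e-6

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((32, 32)).astype(np.float32)
        y = rng.standard_normal((32, 32)).astype(np.float32)
        assert perceptual_distance(x, y, 32) == pytest.approx(
            perceptual_distance(y, x, 32), rel=1e-6
        )

    def test_monotone_in_noise_amplitude(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((32, 32)).astype(np.float32)
        noise = rng.standard_normal((32, 32)).astype(np.float32)
        ds = [perceptual_distance(x, x + a * noise, 32) for a in (0.1, 0.4, 1.0)]
        assert ds[0] < ds[1] < ds[2]

    def test_downsampling_applied(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((64, 64)).astype(np.float32)
        y = x + 0.5
        d64 = perceptual_distance(x, y, 64)
        d16 = perceptual_distance(x, y, 16)
        assert d64 > 0 and d16 > 0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            perceptual_distance(np.zeros((8, 8)), np.zeros((16, 16)), 8)


class TestDomainGuidedLoss:
    def test_identity_generator_gives_zero(self, small_cfg):
        E = Encoder(small_cfg, seed=0)

        class IdentityG:
            def __call__(self, w, noises):
                return self._x

        G = IdentityG()
        x = np.random.default_rng(0).standard_normal((1, 1, 16, 16)).astype(np.float32)
        G._x = ag.Tensor(x)
        loss = domain_guided_loss(E, G, ag.Tensor(x), noises=None)
        assert loss.item() == pytest.approx(0.0, abs=1e-7)

    def test_hand_computed_stub(self):
        a = ag.Tensor(np.array([[1.0, 2.0]], np.float32))
        b = ag.Tensor(np.array([[0.0, 4.0]], np.float32))
        assert code_l1(a, b).item() == pytest.approx(1.5)

    def test_nonnegative(self, small_cfg):
        E = Encoder(small_cfg, seed=0)
        G = Generator(small_cfg, seed=1)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 1, 16, 16)).astype(np.float32)
        loss = domain_guided_loss(E, G, ag.Tensor(x), G.sample_noise(2, rng))
        assert loss.item() >= 0.0


class _ConstantD:
    def __init__(self, c):
        self.c = c

    def __call__(self, x):
        n = x.shape[0]
        return ag.Tensor(np.full((n, 1), self.c, np.float32))


class _ZeroThroughD:
    """D(x) = 0 for all x, but built through the graph of x."""

    def __call__(self, x):
        x = ag.as_tensor(x)
        return ag.tsum(x * ag.Tensor(0.0), axis=(1, 2, 3)) if x.ndim == 4 else x * 0


class TestAdversarialLosses:
    def test_constant_discriminator_zero_r1(self):
        real = np.zeros((3, 1, 8, 8), np.float32)
        _, _, r1 = adversarial_step_losses(_ConstantD(1.3), real, real, step_index=0)
        assert r1.item() == 0.0

    def test_r1_schedule(self, small_cfg):
        D = Discriminator(small_cfg, seed=0)
        rng = np.random.default_rng(0)
        real = rng.standard_normal((2, 1, 16, 16)).astype(np.float32)
        _, _, r1_off = adversarial_step_losses(D, real, real, step_index=5)
        assert r1_off.item() == 0.0
        _, _, r1_on = adversarial_step_losses(D, real, real, step_index=16)
        assert r1_on.item() > 0.0

    def test_zero_discriminator_gives_ln2(self):
        real = np.ones((4, 1, 8, 8), np.float32)
        g_loss, d_loss, _ = adversarial_step_losses(_ZeroThroughD(), real, real, 1)
        assert g_loss.item() == pytest.approx(LN2, rel=1e-6)
        assert d_loss.item() == pytest.approx(2 * LN2, rel=1e-6)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            adversarial_step_losses(
                _ConstantD(0.0), np.zeros((0, 1, 8, 8), np.float32),
                np.zeros((1, 1, 8, 8), np.float32), 0,
            )


class TestRandomErase:
    def test_outside_rectangle_untouched(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((32, 32)).astype(np.float32)
        out = random_erase(x, seed=5)
        changed = out != x
        rows = np.flatnonzero(changed.any(axis=1))
        cols = np.flatnonzero(changed.any(axis=0))
        # changed region is exactly one filled rectangle
        assert changed[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1].all()
        assert changed.sum() == len(rows) * len(cols)

    def test_area_fraction_in_range(self):
        params = RandomEraseParams(area_range=(0.05, 0.2))
        x = np.zeros((64, 64), np.float32) + 7.0
        for seed in range(10):
            out = random_erase(x, seed=seed, params=params)
            frac = (out != 7.0).sum() / x.size
            assert 0.05 <= frac <= 0.2

    def test_deterministic(self):
        x = np.random.default_rng(1).standard_normal((16, 16)).astype(np.float32)
        np.testing.assert_array_equal(random_erase(x, 3), random_erase(x, 3))

    def test_invalid_area_range(self):
        with pytest.raises(ValueError):
            RandomEraseParams(area_range=(0.0, 0.5))


@pytest.fixture(scope="module")
def tiny_setup():
    scans, _ = generate_cohort(2, 0.0, seed=0, shape=(16, 16), n_slices=4)
    cfg = BackboneConfig(resolution=16, style_dim=4, z_dim=4)
    return scans, cfg


def tiny_train_config(p1, p2, seed=0):
    return dataclasses.replace(
        desk_train_config(p1, p2, seed=seed), encoder_warmup_iters=2
    )


class TestTraining:
    def test_smoke_losses_finite(self, tiny_setup):
        scans, cfg = tiny_setup
        tcfg = tiny_train_config(5, 5)
        trained = train_backbone(scans, tcfg, cfg)
        assert np.isfinite(trained.log.drop(columns=["phase", "step"]).fillna(0).to_numpy()).all()
        assert (trained.log["phase"] == 1).sum() == 5
        assert (trained.log["phase"] == 2).sum() == 5

    def test_generator_frozen_in_phase2(self, tiny_setup):
        scans, cfg = tiny_setup
        t_a = train_backbone(scans, tiny_train_config(2, 0, seed=3), cfg)
        t_b = train_backbone(scans, tiny_train_config(2, 4, seed=3), cfg)
        for k, v in t_a.generator.state_dict().items():
            np.testing.assert_array_equal(v, t_b.generator.state_dict()[k])

    def test_r1_only_on_schedule(self, tiny_setup):
        scans, cfg = tiny_setup
        trained = train_backbone(scans, tiny_train_config(18, 0, seed=1), cfg)
        log = trained.log[trained.log["phase"] == 1]
        off_schedule = log[log["step"] % 16 != 0]
        assert (off_schedule["r1"] == 0.0).all()
        assert (log[log["step"] % 16 == 0]["r1"] != 0.0).any()

    def test_seeded_reproducibility(self, tiny_setup):
        scans, cfg = tiny_setup
        a = train_backbone(scans, tiny_train_config(4, 4, seed=7), cfg)
        b = train_backbone(scans, tiny_train_config(4, 4, seed=7), cfg)
        import pandas.testing as pdt

        pdt.assert_frame_equal(a.log, b.log)

    def test_checkpoint_roundtrip_bit_exact(self, tiny_setup, tmp_path):
        scans, cfg = tiny_setup
        trained = train_backbone(scans, tiny_train_config(3, 3, seed=2), cfg)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, trained)
        reloaded = load_checkpoint(path)
        rng = np.random.default_rng(0)
        w = rng.standard_normal((2, cfg.n_layers, cfg.style_dim)).astype(np.float32)
        noises = trained.generator.sample_noise(2, rng)
        np.testing.assert_array_equal(
            trained.generator(w, noises).data, reloaded.generator(w, noises).data
        )

    def test_empty_dataset_rejected(self, tiny_setup):
        _, cfg = tiny_setup
        with pytest.raises(ValueError, match="empty"):
            train_backbone(np.zeros((0, 16, 16)), tiny_train_config(1, 0), cfg)


class TestDeskBackboneProperty:
    def test_normal_recon_better_than_lesioned(self, desk_backbone):
        """Core premise: the trained model reconstructs held-out normal
        slices better (perceptually) than lesioned slices."""
        from ctanomaly.backbone.autograd import Tensor
        from ctanomaly.phantom import LesionSpec, generate_normal_scan, inject_lesion

        G, E = desk_backbone.generator, desk_backbone.encoder
        rng = np.random.default_rng(99)
        d_normal, d_lesion = [], []
        for seed in range(200, 210):
            scan = generate_normal_scan(seed, (64, 64), 8)
            spec = LesionSpec("hyperdense", (4, 32, 26), 12.0, 70.0)
            lesioned, _ = inject_lesion(scan, spec)
            for scan_k, bucket in ((scan, d_normal), (lesioned, d_lesion)):
                x = hu_to_unit(scan_k.slices[4:5])[:, None]
                noises = G.sample_noise(1, rng)
                recon = G(E(Tensor(x)), noises).data
                d = float(np.mean(np.abs(recon - x)))
                bucket.append(d)
        assert np.mean(d_normal) < np.mean(d_lesion)
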