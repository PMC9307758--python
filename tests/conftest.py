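"""Shared fixtures.

The trained desk-scale backbone and the end-to-end detection experiment
are expensive (minutes of CPU), so they are session-scoped and shared by
the backbone property tests, the inversion property tests, and the
acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from ctanomaly.backbone.networks import BackboneConfig
from ctanomaly.phantom import LesionSpec, generate_normal_scan, inject_lesion

SMALL_CFG = BackboneConfig(resolution=16, style_dim=4, z_dim=4)


@pytest.fixture(scope="session")
def small_cfg() -> BackboneConfig:
    return SMALL_CFG


@pytest.fixture()
def normal_scan():
    return generate_normal_scan(7, (64, 64), 8)


@pytest.fixture()
def lesioned_scan(normal_scan):
    spec = LesionSpec("hyperdense", center=(4, 32, 26), radius_px=6.0, delta_hu=60.0)
    return inject_lesion(normal_scan, spec)


@pytest.fixture(scope="session")
def desk_backbone():
    """Desk-scale backbone trained once per session (~64x64, ~200 normal
    phantom slices, ~2000 iterations total)."""
    from ctanomaly.pipeline import train_desk_backbone

    return train_desk_backbone(seed=1)


@pytest.fixture(scope="session")
def desk_experiment(desk_backbone):
    """Calibrated scoring run over 30 normal + 30 lesioned phantoms."""
    from ctanomaly.pipeline import run_detection_experiment

    return run_detection_experiment(seed=1, trained=desk_backbone)
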