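"""Masked reconstruction errors and the scan-level anomaly score.

The raw per-slice error is the L1 norm of the mask-weighted density
difference (HU).  Errors are z-normalised per slice order against
statistics fitted on normal scans, and the z-scores of a scan's slices
(up to 32) are summed into the anomaly score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReconStats",
    "AnomalyResult",
    "slice_reconstruction_error",
    "fit_error_stats",
    "anomaly_score",
    "score_inversion",
]


def slice_reconstruction_error(
    x_i: np.ndarray, recon: np.ndarray, mask: np.ndarray, norm: str = "l1"
) -> float:
    """Masked density error between a slice and its reconstruction (HU)."""
    x_i = np.asarray(x_i, dtype=np.float64)
    recon = np.asarray(recon, dtype=np.float64)
    mask = np.asarray(mask)
    if x_i.shape != recon.shape or x_i.shape != mask.shape:
        raise ValueError("slice, reconstruction, and mask shapes must agree")
    diff = mask * (x_i - recon)
    if norm == "l1":
        return float(np.abs(diff).sum())
    if norm == "l2":
        return float(np.sqrt((diff**2).sum()))
    raise ValueError(f"unknown norm {norm!r}")


@dataclass
class ReconStats:
    """Per-slice-order mean/SD of normal-scan reconstruction errors."""

    mean: dict[int, float]
    sd: dict[int, float]
    count: dict[int, int]
    sigma_floor: dict[int, float] = field(default_factory=dict)
    backbone_hash: str = ""

    def save(self, path) -> None:
        payload = {
            "mean": self.mean,
            "sd": self.sd,
            "count": self.count,
            "backbone_hash": self.backbone_hash,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @staticmethod
    def load(path, expected_backbone_hash: str | None = None) -> "ReconStats":
        with open(path) as fh:
            payload = json.load(fh)
        if (
            expected_backbone_hash is not None
            and payload.get("backbone_hash")
            and payload["backbone_hash"] != expected_backbone_hash
        ):
            raise ValueError("error statistics were fitted against a different backbone")
        return ReconStats(
            mean={int(k): float(v) for k, v in payload["mean"].items()},
            sd={int(k): float(v) for k, v in payload["sd"].items()},
            count={int(k): int(v) for k, v in payload["count"].items()},
            backbone_hash=payload.get("backbone_hash", ""),
        )


def _sigma_floor(mu: float) -> float:
    return 1e-6 * max(mu, 1.0)


def fit_error_stats(
    errors_by_scan: list[dict[int, float]],
    n_scans: int | None = None,
    seed: int = 0,
    backbone_hash: str = "",
) -> ReconStats:
    """Fit per-slice-order error statistics on normal scans.

    ``errors_by_scan`` maps slice order to raw error per calibration
    scan.  When ``n_scans`` is smaller than the cohort, a seeded random
    subset of that size is used.
    """
    scans = list(errors_by_scan)
    if n_scans is not None and n_scans < len(scans):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(scans), size=n_scans, replace=False)
        scans = [scans[i] for i in sorted(idx)]
    pooled: dict[int, list[float]] = {}
    for per_scan in scans:
        for order, err in per_scan.items():
            pooled.setdefault(int(order), []).append(float(err))
    mean, sd, count = {}, {}, {}
    for order, vals in sorted(pooled.items()):
        if len(vals) < 2:
            raise ValueError(
                f"slice order {order} has only {len(vals)} sample(s); need at least 2"
            )
        mu = float(np.mean(vals))
        sigma = float(np.std(vals, ddof=1))
        mean[order] = mu
        sd[order] = max(sigma, _sigma_floor(mu))
        count[order] = len(vals)
    return ReconStats(mean, sd, count, backbone_hash=backbone_hash)


@dataclass
class AnomalyResult:
    case_id: str
    slice_orders: np.ndarray
    raw_errors: np.ndarray
    z_scores: np.ndarray
    score: float
    masks: list = field(default_factory=list, repr=False)
    recon_hu: np.ndarray | None = field(default=None, repr=False)


def anomaly_score(
    per_slice_errors: dict[int, float], stats: ReconStats, case_id: str = ""
) -> AnomalyResult:
    """Sum of per-slice-order z-normalised errors over the scan's slices."""
    orders = sorted(int(o) for o in per_slice_errors)
    if len(orders) > 32:
        raise ValueError("a scan holds at most 32 slices")
    raw = np.array([float(per_slice_errors[o]) for o in orders])
    z = np.empty_like(raw)
    for k, o in enumerate(orders):
        if o not in stats.mean:
            raise ValueError(f"slice order {o} missing from reconstruction statistics")
        z[k] = (raw[k] - stats.mean[o]) / stats.sd[o]
    return AnomalyResult(
        case_id=case_id,
        slice_orders=np.asarray(orders),
        raw_errors=raw,
        z_scores=z,
        score=float(z.sum()),
    )


def errors_from_inversion(scan, inversion, norm: str = "l1") -> dict[int, float]:
    """Per-slice-order raw errors of an inverted scan."""
    out: dict[int, float] = {}
    for k, order in enumerate(np.asarray(scan.slice_orders)):
        out[int(order)] = slice_reconstruction_error(
            scan.slices[k], inversion.recon_hu[k], inversion.masks[k].mask, norm=norm
        )
    return out


def score_inversion(
    scan, inversion, stats: ReconStats, norm: str = "l1"
) -> AnomalyResult:
    """Convenience: raw errors then anomaly score for one inverted scan."""
    errors = errors_from_inversion(scan, inversion, norm=norm)
    result = anomaly_score(errors, stats, case_id=scan.case_id)
    result.masks = inversion.masks
    result.recon_hu = inversion.recon_hu
    return result
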