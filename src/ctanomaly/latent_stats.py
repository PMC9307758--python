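"""Gaussian model of normal-scan latent codes, per slice order and layer.

Codes of normal scans are accumulated slice-by-slice; for every
(slice order, layer) pair a mean vector and a shrunk sample covariance
are stored (block-diagonal across layers).  The deviation of a code is
the per-layer Mahalanobis distance summed over layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky

__all__ = ["LatentGaussian", "fit_latent_gaussian", "gaussian_deviation"]


@dataclass
class LatentGaussian:
    """means[s] : (L, d); covs[s] : (L, d, d) with shrinkage applied."""

    means: dict[int, np.ndarray]
    covs: dict[int, np.ndarray]
    shrinkage: float
    backbone_hash: str = ""
    _whiteners: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def slice_orders(self) -> list[int]:
        return sorted(self.means)

    def whitener(self, slice_order: int) -> np.ndarray:
        """(L, d, d) matrices W with W @ W.T = Sigma^-1 (inverse Cholesky)."""
        if slice_order not in self._whiteners:
            covs = self.covs[slice_order]
            out = np.empty_like(covs)
            for l in range(covs.shape[0]):
                c = cholesky(covs[l], lower=True)
                out[l] = np.linalg.inv(c).T  # W = L^-T, W W^T = Sigma^-1
            self._whiteners[slice_order] = out
        return self._whiteners[slice_order]

    def save(self, path) -> None:
        arrays = {}
        for s in self.means:
            arrays[f"mean/{s}"] = self.means[s]
            arrays[f"cov/{s}"] = self.covs[s]
        meta = {"shrinkage": self.shrinkage, "backbone_hash": self.backbone_hash}
        arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @staticmethod
    def load(path, expected_backbone_hash: str | None = None) -> "LatentGaussian":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            if (
                expected_backbone_hash is not None
                and meta["backbone_hash"]
                and meta["backbone_hash"] != expected_backbone_hash
            ):
                raise ValueError(
                    "latent statistics were fitted against a different backbone "
                    f"config (stored {meta['backbone_hash']}, "
                    f"expected {expected_backbone_hash})"
                )
            means = {
                int(k.split("/")[1]): z[k] for k in z.files if k.startswith("mean/")
            }
            covs = {int(k.split("/")[1]): z[k] for k in z.files if k.startswith("cov/")}
        return LatentGaussian(means, covs, float(meta["shrinkage"]), meta["backbone_hash"])


def fit_latent_gaussian(
    codes_by_order: dict[int, np.ndarray],
    shrinkage_scale: float = 1e-4,
    backbone_hash: str = "",
) -> LatentGaussian:
    """Fit per-(slice order, layer) Gaussians to latent codes.

    ``codes_by_order[s]`` is an (n_s, L, d) array of codes of slices with
    order ``s``.  The covariance receives ridge shrinkage
    ``eps * I`` with ``eps = shrinkage_scale * trace(Sigma) / d`` (floored
    away from zero) so it is always positive definite.
    """
    means: dict[int, np.ndarray] = {}
    covs: dict[int, np.ndarray] = {}
    for s, codes in sorted(codes_by_order.items()):
        codes = np.asarray(codes, dtype=np.float64)
        if codes.ndim != 3:
            raise ValueError(f"codes for slice order {s} must be (n, L, d)")
        n, L, d = codes.shape
        if n < 2:
            raise ValueError(
                f"slice order {s} has only {n} sample(s); need at least 2"
            )
        mu = codes.mean(axis=0)
        cov = np.empty((L, d, d))
        for l in range(L):
            xc = codes[:, l, :] - mu[l]
            sigma = xc.T @ xc / (n - 1)
            eps = max(shrinkage_scale * np.trace(sigma) / d, 1e-12)
            cov[l] = sigma + eps * np.eye(d)
        means[s] = mu
        covs[s] = cov
    return LatentGaussian(means, covs, shrinkage_scale, backbone_hash)


def gaussian_deviation(
    w: np.ndarray, stats: LatentGaussian, slice_order: int
) -> float:
    """Per-layer Mahalanobis distance of a code from the normal-data mean,
    summed over layers."""
    if slice_order not in stats.means:
        raise ValueError(f"slice order {slice_order} not represented in statistics")
    w = np.asarray(w, dtype=np.float64)
    mu = stats.means[slice_order]
    if w.shape != mu.shape:
        raise ValueError(f"code shape {w.shape} does not match stats {mu.shape}")
    W = stats.whitener(slice_order)
    total = 0.0
    for l in range(mu.shape[0]):
        z = (w[l] - mu[l]) @ W[l]
        total += float(np.sqrt(z @ z))
    return total
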