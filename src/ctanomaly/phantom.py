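"""Seeded synthetic head-CT phantoms in Hounsfield units.

Slices emulate the statistical structure the detection method relies on:
an elliptical skull ring around brain parenchyma with near left-right
symmetry, ventricles whose size changes monotonically with slice order
(so per-slice-order calibration is non-trivial), mild seeded texture,
and air background.  Lesions (hyperdense, hypodense, or mass with
midline shift) are injected with exact ground-truth masks.

All HU values are integers so that int16 serialisation round-trips
bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "CTScan",
    "LesionSpec",
    "CohortManifest",
    "generate_normal_scan",
    "inject_lesion",
    "generate_cohort",
]

MAX_SLICES = 32

HU_AIR = -1000.0
HU_SKULL = 1000.0
HU_PARENCHYMA = 35.0
HU_VENTRICLE = 6.0


@dataclass
class CTScan:
    """Ordered stack of axial HU slices, bottom-to-top."""

    case_id: str
    slices: np.ndarray  # (n_slices, H, W) float32, HU
    slice_orders: np.ndarray  # strictly increasing ints in [1, 32]
    pixel_size_mm: float = 3.0
    regions: dict[str, np.ndarray] | None = None  # phantom ground-truth labels

    def __post_init__(self):
        self.slices = np.asarray(self.slices, dtype=np.float32)
        self.slice_orders = np.asarray(self.slice_orders, dtype=np.int64)
        n = self.slices.shape[0]
        if not (1 <= n <= MAX_SLICES):
            raise ValueError(f"scan must hold 1..{MAX_SLICES} slices, got {n}")
        if self.slices.ndim != 3:
            raise ValueError("slices must be a 3-d stack")
        if self.slice_orders.shape != (n,):
            raise ValueError("slice_orders must match the number of slices")
        if np.any(np.diff(self.slice_orders) <= 0):
            raise ValueError("slice_orders must be strictly increasing")
        if self.slice_orders[0] < 1 or self.slice_orders[-1] > MAX_SLICES:
            raise ValueError(f"slice_orders must lie in [1, {MAX_SLICES}]")
        if not np.all(np.isfinite(self.slices)):
            raise ValueError("HU values must be finite")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices.shape[1:]

    def brain_mask(self) -> np.ndarray | None:
        if self.regions is None:
            return None
        return self.regions["brain"]


@dataclass(frozen=True)
class LesionSpec:
    """Parametric lesion: a uniform density offset on a spherical
    footprint; ``mass`` additionally displaces tissue laterally."""

    kind: str  # hyperdense | hypodense | mass
    center: tuple[int, int, int]  # (slice index, row, col)
    radius_px: float
    delta_hu: float
    midline_shift_px: float = 0.0

    def __post_init__(self):
        if self.kind not in ("hyperdense", "hypodense", "mass"):
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")
        if self.kind == "hyperdense" and self.delta_hu <= 0:
            raise ValueError("hyperdense lesions require delta_hu > 0")
        if self.kind == "hypodense" and self.delta_hu >= 0:
            raise ValueError("hypodense lesions require delta_hu < 0")
        if self.midline_shift_px < 0:
            raise ValueError("midline_shift_px must be non-negative")


@dataclass
class CohortManifest:
    """Per-case labels; emergency iff category is urgent or immediate."""

    case_ids: list[str]
    categories: list[str]
    ground_truth_masks: dict[str, np.ndarray] = field(default_factory=dict)

    CATEGORIES = ("normal", "benign", "indeterminate", "urgent", "immediate")
    EMERGENCY = ("urgent", "immediate")

    def __post_init__(self):
        for c in self.categories:
            if c not in self.CATEGORIES:
                raise ValueError(f"unknown category {c!r}")

    @property
    def is_emergency(self) -> list[bool]:
        return [c in self.EMERGENCY for c in self.categories]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "case_id": self.case_ids,
                "category": self.categories,
                "is_emergency": self.is_emergency,
            }
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _slice_geometry(order: int, shape: tuple[int, int], rng_off: np.ndarray):
    """Ellipse parameters for one slice order (1-based, 1..32)."""
    h, w = shape
    t = (order - 1) / (MAX_SLICES - 1)  # 0 at skull base, 1 at vertex
    # head narrows toward the vertex
    a = (0.42 - 0.10 * t) * h  # semi-axis rows
    b = (0.36 - 0.08 * t) * w  # semi-axis cols
    # ventricle size decreases monotonically with slice order
    vent = (0.16 - 0.10 * t) * min(h, w)
    return a + rng_off[0], b + rng_off[1], max(vent, 1.5)


def generate_normal_scan(
    seed: int,
    shape: tuple[int, int] = (64, 64),
    n_slices: int = 8,
    case_id: str | None = None,
) -> CTScan:
    """Deterministic normal head phantom.

    Slice orders are spread over [1, 32] so the slice stack spans the
    skull base to the vertex regardless of ``n_slices``.
    """
    if not (1 <= n_slices <= MAX_SLICES):
        raise ValueError(f"n_slices must be in [1, {MAX_SLICES}], got {n_slices}")
    rng = np.random.default_rng(seed)
    h, w = shape
    orders = np.unique(np.round(np.linspace(1, MAX_SLICES, n_slices)).astype(int))
    rows, cols = np.mgrid[0:h, 0:w]
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    rng_off = rng.uniform(-0.6, 0.6, size=2)

    slices = np.empty((len(orders), h, w), dtype=np.float32)
    brain = np.zeros((len(orders), h, w), dtype=bool)
    skull = np.zeros_like(brain)
    vent_mask = np.zeros_like(brain)
    for i, order in enumerate(orders):
        a, b, vent = _slice_geometry(int(order), shape, rng_off)
        r2 = ((rows - cr) / a) ** 2 + ((cols - cc) / b) ** 2
        inner = r2 <= 1.0
        ring = (r2 > 1.0) & (r2 <= 1.35)
        # ventricles: two para-midline ellipses, mirrored left/right
        voff_r = 0.06 * h
        voff_c = 0.11 * w
        vr2a = ((rows - cr + voff_r) / (1.6 * vent)) ** 2 + (
            (cols - cc + voff_c) / (0.55 * vent)
        ) ** 2
        vr2b = ((rows - cr + voff_r) / (1.6 * vent)) ** 2 + (
            (cols - cc - voff_c) / (0.55 * vent)
        ) ** 2
        vm = ((vr2a <= 1.0) | (vr2b <= 1.0)) & inner

        img = np.full((h, w), HU_AIR, dtype=np.float64)
        # smooth parenchymal shading, symmetric left/right
        shade = 6.0 * np.cos(np.pi * (rows - cr) / h) * np.cos(np.pi * (cols - cc) / w)
        img[inner] = HU_PARENCHYMA + shade[inner]
        img[vm] = HU_VENTRICLE
        img[ring] = HU_SKULL + 150.0 * np.cos(np.pi * (rows[ring] - cr) / h)
        # smooth anatomical texture plus per-pixel quantum mottle
        texture = gaussian_filter(rng.standard_normal((h, w)), 1.2) * 2.0
        mottle = rng.standard_normal((h, w)) * 2.5
        img[inner & ~vm] += texture[inner & ~vm]
        img[inner] += mottle[inner]
        # keep tissue HU inside their nominal windows despite noise tails
        img[inner & ~vm] = np.clip(img[inner & ~vm], 20.0, 50.0)
        img[vm] = np.clip(img[vm], 0.0, 12.0)
        slices[i] = np.rint(img)
        brain[i] = inner
        skull[i] = ring
        vent_mask[i] = vm

    return CTScan(
        case_id=case_id or f"phantom-{seed}",
        slices=slices,
        slice_orders=orders,
        regions={"brain": brain, "skull": skull, "ventricle": vent_mask},
    )


def _footprint(
    scan: CTScan, spec: LesionSpec, slice_spacing_px: float = 4.0
) -> np.ndarray:
    """Spherical footprint of a lesion, clipped to the brain region."""
    s0, r0, c0 = spec.center
    n, h, w = scan.slices.shape
    rows, cols = np.mgrid[0:h, 0:w]
    fp = np.zeros((n, h, w), dtype=bool)
    for i in range(n):
        dz = (i - s0) * slice_spacing_px
        rad2 = spec.radius_px**2 - dz**2
        if rad2 <= 0:
            continue
        fp[i] = (rows - r0) ** 2 + (cols - c0) ** 2 <= rad2
    brain = scan.brain_mask()
    if brain is not None:
        fp &= brain
    return fp


def inject_lesion(
    scan: CTScan, spec: LesionSpec, seed: int = 0
) -> tuple[CTScan, np.ndarray]:
    """Returns a lesioned copy of the scan and the exact binary footprint
    of modified voxels.

    For non-mass kinds the lesion adds exactly ``delta_hu`` inside the
    footprint, so subtracting it recovers the original bit-exactly.
    """
    s0, r0, c0 = spec.center
    if not (0 <= s0 < scan.n_slices):
        raise ValueError("lesion center slice outside the scan")
    brain = scan.brain_mask()
    if brain is not None and not brain[s0, r0, c0]:
        raise ValueError("lesion center must lie inside the brain region")

    new = scan.slices.copy()
    fp = _footprint(scan, spec)
    if spec.kind == "mass":
        shift = int(round(spec.midline_shift_px))
        if shift > 0:
            # displace tissue toward the midline on the lesion's slices
            direction = 1 if c0 < (scan.shape[1] // 2) else -1
            for i in np.flatnonzero(fp.any(axis=(1, 2))):
                region = brain[i] if brain is not None else np.ones(scan.shape, bool)
                shifted = np.roll(scan.slices[i], shift * direction, axis=1)
                blend = region & np.roll(region, shift * direction, axis=1)
                new[i][blend] = shifted[blend]
        new[fp] += spec.delta_hu
        mask = new != scan.slices
    else:
        if not fp.any():
            fp[s0, r0, c0] = True
        new[fp] += spec.delta_hu
        mask = fp
    lesioned = CTScan(
        case_id=scan.case_id + "-lesion",
        slices=new,
        slice_orders=scan.slice_orders.copy(),
        pixel_size_mm=scan.pixel_size_mm,
        regions=scan.regions,
    )
    return lesioned, mask


def _random_lesion_spec(
    scan: CTScan, rng: np.random.Generator, severe: bool
) -> LesionSpec:
    brain = scan.brain_mask()
    s0 = scan.n_slices // 2
    cand = np.argwhere(brain[s0])
    # keep away from the brain edge so the center test is stable
    h, w = scan.shape
    cr, cc = h / 2, w / 2
    cand = cand[np.hypot(cand[:, 0] - cr, cand[:, 1] - cc) < 0.22 * min(h, w)]
    r0, c0 = cand[rng.integers(len(cand))]
    kind = rng.choice(["hyperdense", "hypodense", "mass"], p=[0.5, 0.3, 0.2])
    base_radius = 0.09 * min(h, w)
    if severe:
        radius = base_radius * rng.uniform(1.5, 2.0)
        mag = rng.uniform(60, 85)
    else:
        radius = base_radius * rng.uniform(1.0, 1.4)
        mag = rng.uniform(45, 65)
    delta = -mag if kind == "hypodense" else mag
    shift = float(rng.integers(2, 5)) if kind == "mass" else 0.0
    return LesionSpec(
        kind=str(kind),
        center=(int(s0), int(r0), int(c0)),
        radius_px=float(radius),
        delta_hu=float(np.rint(delta)),
        midline_shift_px=shift,
    )


def generate_cohort(
    n: int,
    prevalence: float,
    seed: int,
    shape: tuple[int, int] = (64, 64),
    n_slices: int = 8,
) -> tuple[list[CTScan], CohortManifest]:
    """Cohort of phantoms with about ``prevalence * n`` emergency cases.

    Larger/denser lesions are labelled immediate, the rest urgent;
    lesion-free scans are labelled normal or benign.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= prevalence <= 1.0):
        raise ValueError("prevalence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    scans: list[CTScan] = []
    case_ids: list[str] = []
    categories: list[str] = []
    masks: dict[str, np.ndarray] = {}
    for i in range(n):
        case_id = f"case-{i:04d}"
        scan_seed = int(rng.integers(2**31))
        scan = generate_normal_scan(scan_seed, shape, n_slices, case_id=case_id)
        if rng.random() < prevalence:
            severe = bool(rng.random() < 0.4)
            spec = _random_lesion_spec(scan, rng, severe)
            scan, mask = inject_lesion(scan, spec, seed=scan_seed)
            scan.case_id = case_id
            masks[case_id] = mask
            categories.append("immediate" if severe else "urgent")
        else:
            categories.append("normal" if rng.random() < 0.7 else "benign")
        scans.append(scan)
        case_ids.append(case_id)
    return scans, CohortManifest(case_ids, categories, masks)
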