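"""Scan, manifest, and overlay readers/writers.

Scans are stored either as NIfTI (HU as int16, scl_slope=1, scl_inter=0,
slice axis last, bottom-to-top) or as an ``.npz`` archive with a JSON
sidecar carrying case id, slice orders, and pixel size.  Writes are
atomic (temp file + rename).
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from ..phantom import MAX_SLICES, CTScan, CohortManifest

__all__ = [
    "read_scan",
    "write_scan",
    "read_manifest",
    "write_manifest",
    "save_attention_overlay",
    "atomic_write_bytes",
]


def atomic_write_bytes(path, payload: bytes) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_scan(scan: CTScan, path) -> None:
    path = Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        data = np.rint(scan.slices).astype(np.int16)
        vol = np.transpose(data, (1, 2, 0))  # slice axis last, bottom-to-top
        affine = np.diag(
            [scan.pixel_size_mm, scan.pixel_size_mm, 5.0, 1.0]
        )
        img = nib.Nifti1Image(vol, affine)
        img.header.set_slope_inter(1.0, 0.0)
        img.header.set_data_dtype(np.int16)
        nib.save(img, str(path))
    elif path.suffix == ".npz":
        import io as _io

        buf = _io.BytesIO()
        np.savez(buf, slices=scan.slices)
        atomic_write_bytes(path, buf.getvalue())
        sidecar = {
            "case_id": scan.case_id,
            "slice_orders": [int(s) for s in scan.slice_orders],
            "pixel_size_mm": float(scan.pixel_size_mm),
        }
        atomic_write_bytes(
            path.with_suffix(".json"), json.dumps(sidecar, indent=1).encode()
        )
    else:
        raise ValueError(f"unsupported scan format {path.suffix!r} (use .nii or .npz)")


def read_scan(path) -> CTScan:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        img = nib.load(str(path))
        vol = np.asanyarray(img.get_fdata(dtype=np.float64))  # slope/inter applied
        if vol.ndim != 3:
            raise ValueError(f"{path.name}: expected a 3-d volume")
        n = vol.shape[2]
        if n > MAX_SLICES:
            raise ValueError(
                f"{path.name}: {n} slices exceeds the {MAX_SLICES}-slice limit"
            )
        slices = np.transpose(vol, (2, 0, 1)).astype(np.float32)
        pix = float(img.header.get_zooms()[0])
        return CTScan(
            case_id=path.name.split(".")[0],
            slices=slices,
            slice_orders=np.arange(1, n + 1),
            pixel_size_mm=pix,
        )
    if path.suffix == ".npz":
        sidecar_path = path.with_suffix(".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(f"missing sidecar {sidecar_path.name} for {path.name}")
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        with np.load(path) as z:
            slices = z["slices"]
        if slices.shape[0] > MAX_SLICES:
            raise ValueError(
                f"{path.name}: {slices.shape[0]} slices exceeds the "
                f"{MAX_SLICES}-slice limit"
            )
        return CTScan(
            case_id=str(sidecar["case_id"]),
            slices=slices,
            slice_orders=np.asarray(sidecar["slice_orders"]),
            pixel_size_mm=float(sidecar["pixel_size_mm"]),
        )
    raise ValueError(f"unsupported scan format {path.suffix!r}")


def write_manifest(manifest: CohortManifest, path) -> None:
    df = manifest.to_frame()
    atomic_write_bytes(path, df.to_csv(index=False).encode())


def read_manifest(path) -> CohortManifest:
    df = pd.read_csv(path)
    required = {"case_id", "category", "is_emergency"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing column(s) {sorted(missing)}")
    manifest = CohortManifest(
        case_ids=[str(c) for c in df["case_id"]],
        categories=[str(c) for c in df["category"]],
    )
    stored = df["is_emergency"].astype(bool).tolist()
    if stored != manifest.is_emergency:
        raise ValueError("is_emergency column contradicts the categories")
    return manifest


def save_attention_overlay(scan: CTScan, inversion, path, slice_index: int | None = None) -> None:
    """Input / reconstruction / mask-overlay triptych as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if slice_index is None:
        slice_index = int(
            np.argmax([m.mask.sum() for m in inversion.masks])
        )
    x = scan.slices[slice_index]
    recon = inversion.recon_hu[slice_index]
    mask = inversion.masks[slice_index].mask
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    for ax, img, title in zip(axes, (x, recon, x), ("input", "reconstruction", "attention")):
        ax.imshow(img, cmap="gray", vmin=-100, vmax=150)
        ax.set_axis_off()
        ax.set_title(title, fontsize=9)
    axes[2].imshow(
        np.ma.masked_where(~mask, mask), cmap="autumn", alpha=0.6, vmin=0, vmax=1
    )
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
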