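"""File formats: point-cloud CSV, NIfTI-1 and MetaImage volumes.

Point clouds travel as UTF-8 CSV with header ``x_mm,y_mm,z_mm,value``.
Volumes are written as NIfTI-1 (``.nii`` / ``.nii.gz``, via nibabel) or
MetaImage (``.mha`` / ``.mhd``, via SimpleITK) with spacing and origin in
the header and voxel data in float32.  Missing voxels are stored as NaN in
the intensity file plus an explicit uint8 mask in a sibling file with the
``_mask`` suffix, so the missing-data channel round-trips losslessly.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

from .errors import FormatError
from .grid import VoxelGrid
from .kernels import PointCloud

__all__ = [
    "read_cloud_csv",
    "write_cloud_csv",
    "read_volume",
    "write_volume",
    "mask_path",
]

CLOUD_COLUMNS = ["x_mm", "y_mm", "z_mm", "value"]


def read_cloud_csv(path) -> PointCloud:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"could not parse {path} as CSV: {exc}") from exc
    missing = [c for c in CLOUD_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path} lacks required column(s) {missing}")
    return PointCloud(
        positions=df[CLOUD_COLUMNS[:3]].to_numpy(dtype=float),
        values=df["value"].to_numpy(dtype=float),
    )


def write_cloud_csv(cloud: PointCloud, path) -> None:
    df = pd.DataFrame(cloud.positions, columns=CLOUD_COLUMNS[:3])
    df["value"] = cloud.values
    df.to_csv(path, index=False)


def mask_path(path) -> Path:
    """Sibling path carrying the missing mask: vol.nii.gz -> vol_mask.nii.gz."""
    p = Path(path)
    suffix = "".join(p.suffixes[-2:]) if p.name.endswith(".nii.gz") else p.suffix
    stem = p.name[: -len(suffix)] if suffix else p.name
    return p.with_name(f"{stem}_mask{suffix}")


def _format_of(path) -> str:
    name = str(path)
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".mha", ".mhd")):
        return "metaimage"
    raise FormatError(f"unrecognized volume extension on {path}")


def write_volume(vol: VoxelGrid, path, with_mask: bool = True) -> None:
    fmt = _format_of(path)
    _write_array(vol.data.astype(np.float32), vol, path, fmt)
    if with_mask and vol.n_missing:
        _write_array(vol.missing_mask.astype(np.uint8), vol, mask_path(path), fmt)


def _write_array(arr: np.ndarray, vol: VoxelGrid, path, fmt: str) -> None:
    if fmt == "nifti":
        affine = np.diag(np.append(vol.spacing, 1.0))
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(arr, affine), str(path))
    else:
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in vol.spacing))
        img.SetOrigin(tuple(float(o) for o in vol.origin))
        sitk.WriteImage(img, str(path))


def read_volume(path) -> VoxelGrid:
    """Read a volume (and its ``_mask`` sibling, if present) back to a grid."""
    fmt = _format_of(path)
    data, spacing, origin = _read_array(path, fmt)
    mask = None
    mp = mask_path(path)
    if mp.exists():
        mdata, mspacing, morigin = _read_array(mp, fmt)
        if mdata.shape != data.shape:
            raise FormatError(f"mask {mp} does not match the geometry of {path}")
        mask = mdata.astype(bool)
    return VoxelGrid(data=data.astype(float), spacing=spacing, origin=origin,
                     missing_mask=mask)


def _read_array(path, fmt: str):
    try:
        if fmt == "nifti":
            img = nib.load(str(path))
            affine = img.affine
            rot = affine[:3, :3]
            if not np.allclose(rot, np.diag(np.diag(rot))):
                raise FormatError(f"{path}: only axis-aligned volumes are supported")
            data = np.asarray(img.dataobj)
            return data, np.abs(np.diag(rot)), affine[:3, 3]
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return data, np.asarray(img.GetSpacing()), np.asarray(img.GetOrigin())
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"could not read {path} as {fmt}: {exc}") from exc
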