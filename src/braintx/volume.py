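"""Volumetric containers and NIfTI I/O.

A :class:`VolumeMap` couples a 3-D scalar array with its affine (mapping
0-based voxel indices to MNI mm coordinates) and a binary analysis mask.
All coordinates in this package are MNI millimetres; voxel indices are
0-based and converted through the affine only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VolumeMap", "read_volume", "write_volume"]


@dataclass
class VolumeMap:
    """3-D scalar grid with affine and binary analysis mask.

    Parameters
    ----------
    data : ndarray, shape (i, j, k)
        Scalar values per voxel.
    affine : ndarray, shape (4, 4)
        Voxel-index -> mm homogeneous transform.
    mask : ndarray of bool, same shape as ``data``
        Analysis mask; operations ignore voxels outside it.
    """

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if self.mask is None:
            self.mask = np.ones(self.data.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape must match data shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Edge length per axis in mm (norm of the affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to (n, 3) mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (n, 3) mm coordinates to fractional voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def contains_mm(self, xyz: np.ndarray) -> np.ndarray:
        """True where the nearest voxel to each mm point is inside the mask."""
        ijk = np.rint(self.mm_to_voxel(xyz)).astype(int)
        ok = np.all((ijk >= 0) & (ijk < np.array(self.shape)), axis=1)
        out = np.zeros(len(ijk), dtype=bool)
        idx = ijk[ok]
        out[ok] = self.mask[idx[:, 0], idx[:, 1], idx[:, 2]]
        return out

    def mask_coordinates_mm(self) -> np.ndarray:
        """mm coordinates of the centres of all in-mask voxels, (n, 3)."""
        ijk = np.argwhere(self.mask)
        return self.voxel_to_mm(ijk)

    def with_data(self, data: np.ndarray) -> "VolumeMap":
        """New VolumeMap sharing this grid's affine and mask."""
        return VolumeMap(np.asarray(data, dtype=float), self.affine.copy(), self.mask.copy())


def read_volume(path, mask_path=None) -> VolumeMap:
    """Read a 3-D NIfTI volume (and optional mask volume) into a VolumeMap."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - surface the file name
        raise ValueError(f"cannot read NIfTI volume {path!r}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path!r}: expected a 3-D volume, got shape {data.shape}")
    mask = None
    if mask_path is not None:
        mask = read_volume(mask_path).data > 0.5
    return VolumeMap(data, np.asarray(img.affine), mask)


def write_volume(vmap: VolumeMap, path, what: str = "data") -> None:
    """Write the data (or mask) of a VolumeMap as NIfTI-1."""
    arr = vmap.data if what == "data" else vmap.mask.astype(np.uint8)
    nib.Nifti1Image(np.asarray(arr, dtype=np.float64 if what == "data" else np.uint8),
                    vmap.affine).to_filename(str(path))
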