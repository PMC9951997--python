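"""3D image container used throughout the package.

Volumes are stored as ``values[z, y, x]`` (transversal slices along the
first axis) with ``spacing``/``origin`` given in millimetres in the same
(z, y, x) order.  CT volumes carry Hounsfield units, MRI volumes arbitrary
non-negative intensities, dose volumes Gy(RBE).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

HU_MIN = -1000.0
HU_MAX = 1047.0

Modality = str  # one of {"CT", "MRI", "DOSE", "LABEL"}

_MODALITIES = ("CT", "MRI", "DOSE", "LABEL")


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical metadata.

    Parameters
    ----------
    values:
        ``(nz, ny, nx)`` array of voxel values.
    spacing:
        Voxel size in mm, ``(dz, dy, dx)``.
    origin:
        Physical position of voxel ``(0, 0, 0)`` in mm, ``(z, y, x)``.
    modality:
        One of ``"CT"``, ``"MRI"``, ``"DOSE"``, ``"LABEL"``.
    background_mask:
        Optional boolean grid flagging non-patient voxels.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = "CT"
    background_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if self.modality not in _MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.background_mask is not None:
            self.background_mask = np.asarray(self.background_mask, dtype=bool)
            if self.background_mask.shape != self.values.shape:
                raise ValueError("background_mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def body_mask(self) -> np.ndarray:
        """Boolean grid of patient voxels (inverse of the background)."""
        if self.background_mask is None:
            return np.ones(self.values.shape, dtype=bool)
        return ~self.background_mask

    def copy_with(self, **kwargs) -> "ImageVolume":
        out = replace(self, **kwargs)
        return out

    def same_grid(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


def write_nifti(vol: ImageVolume, path: str | Path) -> None:
    """Write a volume to NIfTI; axes are stored in (x, y, z) order."""
    data = np.ascontiguousarray(np.transpose(vol.values, (2, 1, 0)))
    dz, dy, dx = vol.spacing
    oz, oy, ox = vol.origin
    affine = np.diag([dx, dy, dz, 1.0])
    affine[:3, 3] = [ox, oy, oz]
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_nifti(path: str | Path, modality: Modality = "CT") -> ImageVolume:
    """Read a NIfTI file written by :func:`write_nifti` (diagonal affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    affine = img.affine
    spacing = (abs(affine[2, 2]), abs(affine[1, 1]), abs(affine[0, 0]))
    origin = (affine[2, 3], affine[1, 3], affine[0, 3])
    values = np.transpose(data, (2, 1, 0))
    return ImageVolume(values=values, spacing=spacing, origin=origin, modality=modality)
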