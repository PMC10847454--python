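"""Core image containers and NIfTI I/O.

A head CT scan is represented as a :class:`CtVolume` — a 3D grid of
Hounsfield units (HU) with per-axis voxel spacing in millimetres; the axial
(slice) axis is the last array axis. Lesion masks are binary grids congruent
with their scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


@dataclass
class CtVolume:
    """3D scalar grid in Hounsfield units with voxel spacing metadata."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError(f"CT volume must be 3D, got shape {self.values.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing_mm}")
        if self.values.shape[2] < 1:
            raise ValueError("volume needs at least one axial slice")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class LesionMask:
    """Binary 3D grid aligned voxel-for-voxel with a :class:`CtVolume`."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    id: str = ""

    def __post_init__(self):
        arr = np.asarray(self.values)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be 0/1, found {uniq[:5]}")
        self.values = arr.astype(np.uint8)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing_mm}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def volume_mL(self) -> float:
        return float(self.values.sum()) * self.voxel_volume_mm3 / 1000.0


@dataclass
class DualInput:
    """The classifier's image input: windowed CT crop + dilated lesion mask.

    ``ct`` is in [0,1] (brain-windowed); ``mask`` is binary; both share one
    fixed shape. ``mask`` is the *dilated* mask and therefore a superset of
    the cropped lesion.
    """

    ct: np.ndarray
    mask: np.ndarray
    id: str = ""

    def __post_init__(self):
        self.ct = np.asarray(self.ct, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.ct.shape != self.mask.shape:
            raise ValueError(
                f"channel shapes differ: {self.ct.shape} vs {self.mask.shape}"
            )
        if self.ct.min() < 0 or self.ct.max() > 1:
            raise ValueError("CT channel must be windowed into [0,1]")

    def stacked(self, channels: str = "ct+mask") -> np.ndarray:
        """Return (C, D, H, W)-style array (channels first, axial last)."""
        if channels == "ct":
            return self.ct[None]
        if channels == "ct+mask":
            return np.stack([self.ct, self.mask.astype(np.float32)])
        raise ValueError(f"unknown channel selection {channels!r}")


@dataclass
class ExpansionLabel:
    baseline_mL: float
    followup_mL: float
    delta_mL: float = field(init=False)
    he3: bool = field(init=False)
    he6: bool = field(init=False)

    def __post_init__(self):
        if self.baseline_mL < 0 or self.followup_mL < 0:
            raise ValueError("volumes must be non-negative")
        self.delta_mL = self.followup_mL - self.baseline_mL
        self.he3 = self.delta_mL >= 3.0
        self.he6 = self.delta_mL >= 6.0


def _affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def save_nifti(path, values: np.ndarray, spacing_mm) -> None:
    img = nib.Nifti1Image(np.asarray(values), _affine(spacing_mm))
    img.header.set_zooms(tuple(spacing_mm))
    nib.save(img, str(path))


def load_ct(path, id: str = "") -> CtVolume:
    img = nib.load(str(path))
    return CtVolume(
        values=np.asanyarray(img.dataobj, dtype=np.float32),
        spacing_mm=tuple(float(z) for z in img.header.get_zooms()[:3]),
        id=id or str(path),
    )


def load_mask(path, id: str = "") -> LesionMask:
    img = nib.load(str(path))
    return LesionMask(
        values=np.rint(np.asanyarray(img.dataobj)).astype(np.uint8),
        spacing_mm=tuple(float(z) for z in img.header.get_zooms()[:3]),
        id=id or str(path),
    )
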