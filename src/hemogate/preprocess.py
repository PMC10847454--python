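"""Deterministic image pipeline from raw head CT to the classifier input.

Stages, in pipeline order: brain window-level normalization (level 40,
width 80 HU), Hounsfield-threshold + morphology skull stripping, isotropic
1 mm resampling to a fixed grid, and a lesion-centered fixed-size crop that
produces the dual-channel classifier input (windowed CT + dilated lesion
mask). Also hosts ground-truth volume computation and expansion labeling.

All grid sizes default to the clinical-scale values — resample grid
(214, 214, 98), lesion box (192, 192, 96), final crop (128, 128, 96) — and
every size is overridable so miniature profiles can run the identical code
path at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import CtVolume, DualInput, ExpansionLabel, LesionMask
from .errors import DegenerateScanError, NoLesionError, OutOfFieldError


@dataclass(frozen=True)
class WindowSpec:
    """Linear display window: HU in [level-width/2, level+width/2] -> [0,1]."""

    level: float = 40.0
    width: float = 80.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError(f"window width must be positive, got {self.width}")


BRAIN_WINDOW = WindowSpec(level=40.0, width=80.0)


def apply_window(volume: CtVolume, window: WindowSpec = BRAIN_WINDOW) -> CtVolume:
    """Map HU linearly into [0,1] over the window, clamping outside it."""
    lo = window.level - window.width / 2.0
    out = np.clip((volume.values - lo) / window.width, 0.0, 1.0)
    return CtVolume(out, volume.spacing_mm, id=volume.id)


def _edt_erode(mask: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    if radius_mm <= 0:
        return mask
    d = ndimage.distance_transform_edt(mask, sampling=spacing)
    return d > radius_mm


def _edt_dilate(mask: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    if radius_mm <= 0:
        return mask
    d = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return mask | (d <= radius_mm)


def strip_skull(volume: CtVolume, morph_radius_mm: float = 2.0,
                min_component_mm3: float = 1000.0,
                background_hu: float = -1000.0) -> tuple[CtVolume, np.ndarray]:
    """Remove skull and background, returning (brain-only volume, brain mask).

    Voxels outside (0, 200) HU are excluded outright (air, bone, metal);
    erosion then disconnects residual boundary tissue, small components are
    discarded, dilation restores the brain boundary (constrained to the
    thresholded support so no out-of-range voxel re-enters), components
    touching the image border are dropped as boundary shell, and the largest
    remaining connected component is kept as brain.
    """
    vals = volume.values
    keep = (vals > 0.0) & (vals < 200.0)
    if not keep.any():
        raise DegenerateScanError("no voxels in (0, 200) HU — not a head CT?")
    sp = volume.spacing_mm
    m = _edt_erode(keep, morph_radius_mm, sp)
    lab, nlab = ndimage.label(m)
    if nlab == 0:
        raise DegenerateScanError("brain mask empty after erosion")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, nlab + 1))
    min_vox = min_component_mm3 / volume.voxel_volume_mm3
    small = np.flatnonzero(sizes < min_vox) + 1
    if small.size:
        m[np.isin(lab, small)] = False
    m = _edt_dilate(m, morph_radius_mm, sp) & keep

    # drop any component forming an outer boundary shell (touches image edge)
    lab, nlab = ndimage.label(m)
    if nlab == 0:
        raise DegenerateScanError("brain mask empty after morphology")
    border_labels = np.unique(np.concatenate([
        lab[0].ravel(), lab[-1].ravel(),
        lab[:, 0].ravel(), lab[:, -1].ravel(),
        lab[:, :, 0].ravel(), lab[:, :, -1].ravel(),
    ]))
    interior = [i for i in range(1, nlab + 1) if i not in border_labels]
    if interior:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=interior)
        brain = lab == interior[int(np.argmax(sizes))]
    else:  # every component touches the border; fall back to the largest
        sizes = ndimage.sum_labels(np.ones_like(lab), lab,
                                   index=np.arange(1, nlab + 1))
        brain = lab == (1 + int(np.argmax(sizes)))
    if not brain.any():
        raise DegenerateScanError("brain mask empty after boundary removal")

    out = np.where(brain, vals, np.float32(background_hu))
    return CtVolume(out, volume.spacing_mm, id=volume.id), brain


def _center_pad_crop(arr: np.ndarray, target: tuple[int, int, int],
                     fill: float = 0.0) -> np.ndarray:
    """Symmetrically pad and/or crop ``arr`` to ``target`` shape."""
    out = arr
    for ax, t in enumerate(target):
        n = out.shape[ax]
        if n < t:
            before = (t - n) // 2
            pad = [(0, 0)] * out.ndim
            pad[ax] = (before, t - n - before)
            out = np.pad(out, pad, constant_values=fill)
        elif n > t:
            start = (n - t) // 2
            sl = [slice(None)] * out.ndim
            sl[ax] = slice(start, start + t)
            out = out[tuple(sl)]
    return out


def resample_isotropic(volume: CtVolume, mask: LesionMask | None = None,
                       target_shape: tuple[int, int, int] = (214, 214, 98),
                       background: float = 0.0):
    """Resample to 1 mm isotropic voxels and pad/crop to a fixed grid.

    The image is interpolated trilinearly, the mask by nearest neighbor (so
    it stays binary); both are then symmetrically padded/cropped to
    ``target_shape``. Raises :class:`OutOfFieldError` if lesion voxels would
    be cut off by the fixed grid.
    """
    zoom = np.asarray(volume.spacing_mm, dtype=float)
    if np.allclose(zoom, 1.0):
        img = volume.values
    else:
        img = ndimage.zoom(volume.values, zoom, order=1, mode="nearest")
    img = _center_pad_crop(img, target_shape, fill=background)
    out_vol = CtVolume(img, (1.0, 1.0, 1.0), id=volume.id)

    if mask is None:
        return out_vol, None
    mzoom = np.asarray(mask.spacing_mm, dtype=float)
    if np.allclose(mzoom, 1.0):
        mk = mask.values
    else:
        mk = ndimage.zoom(mask.values, mzoom, order=0, mode="grid-constant", cval=0)
    n_before = int(mk.sum())
    mk = _center_pad_crop(mk, target_shape, fill=0)
    if int(mk.sum()) < n_before:
        raise OutOfFieldError(
            f"{n_before - int(mk.sum())} lesion voxels fall outside the "
            f"fixed grid {target_shape}"
        )
    return out_vol, LesionMask(mk, (1.0, 1.0, 1.0), id=mask.id)


def dilate_mask(mask: LesionMask, radius_mm: float) -> LesionMask:
    """Dilate by a spherical element (anisotropy-aware, via distance transform)."""
    if radius_mm <= 0:
        return mask
    d = ndimage.distance_transform_edt(mask.values == 0, sampling=mask.spacing_mm)
    return LesionMask(((mask.values == 1) | (d <= radius_mm)).astype(np.uint8),
                      mask.spacing_mm, id=mask.id)


def crop_dual_input(volume: CtVolume, mask: LesionMask,
                    dilation_radius_mm: float = 10.0,
                    box_shape: tuple[int, int, int] = (192, 192, 96),
                    crop_shape: tuple[int, int, int] = (128, 128, 96),
                    channel2: str = "dilated_mask") -> DualInput:
    """Build the classifier's dual-channel input from a resampled scan.

    A ``box_shape`` subvolume is centered on the lesion's center of mass
    (covering the contiguous axial slab that contains mask voxels) and then
    center-cropped to ``crop_shape``; out-of-field regions are zero-padded.
    Channel 1 is the windowed CT crop; channel 2 the lesion mask dilated by a
    spherical element of ``dilation_radius_mm`` (or the raw mask, for the
    input-ablation arms), cropped identically.
    """
    if mask.values.sum() == 0:
        raise NoLesionError("cannot crop around an empty lesion mask")
    if channel2 not in ("dilated_mask", "mask"):
        raise ValueError(f"unknown channel2 mode {channel2!r}")

    zs = np.flatnonzero(mask.values.any(axis=(0, 1)))
    if zs[-1] - zs[0] + 1 > box_shape[2]:
        raise OutOfFieldError(
            f"lesion axial slab spans {zs[-1] - zs[0] + 1} slices, "
            f"more than the box depth {box_shape[2]}"
        )
    com = ndimage.center_of_mass(mask.values)

    ch2_full = dilate_mask(mask, dilation_radius_mm) if channel2 == "dilated_mask" else mask

    # window start chosen so that an axial flip of the input flips the output
    # exactly (rint is odd-symmetric), with the COM at the box center
    src_lo = [int(np.rint(c - (t - 1) / 2.0)) for c, t in zip(com, box_shape)]

    def extract(arr, fill=0.0):
        out = np.full(box_shape, fill, dtype=np.float32)
        for_src, for_dst = [], []
        for ax in range(3):
            a = max(src_lo[ax], 0)
            b = min(src_lo[ax] + box_shape[ax], arr.shape[ax])
            for_src.append(slice(a, b))
            for_dst.append(slice(a - src_lo[ax], b - src_lo[ax]))
        out[tuple(for_dst)] = arr[tuple(for_src)]
        return out

    ct_box = extract(volume.values)
    mk_box = extract(ch2_full.values.astype(np.float32))
    raw_box = extract(mask.values.astype(np.float32))

    ct_crop = _center_pad_crop(ct_box, crop_shape)
    mk_crop = _center_pad_crop(mk_box, crop_shape) >= 0.5
    raw_crop = _center_pad_crop(raw_box, crop_shape)
    if raw_crop.sum() < raw_box.sum():
        raise OutOfFieldError("lesion extends beyond the fixed crop box")

    return DualInput(ct=np.clip(ct_crop, 0.0, 1.0), mask=mk_crop.astype(np.uint8),
                     id=volume.id)


def lesion_volume_mL(mask: LesionMask) -> float:
    """Voxel count × voxel volume (mm³) / 1000."""
    return mask.volume_mL()


def label_expansion(baseline_mL: float, followup_mL: float) -> ExpansionLabel:
    """Inclusive ≥3 mL / ≥6 mL absolute-growth expansion labels."""
    return ExpansionLabel(baseline_mL=baseline_mL, followup_mL=followup_mL)


def preprocess_case(ct: CtVolume, mask: LesionMask,
                    window: WindowSpec = BRAIN_WINDOW,
                    resample_shape: tuple[int, int, int] = (214, 214, 98),
                    dilation_radius_mm: float = 10.0,
                    box_shape: tuple[int, int, int] = (192, 192, 96),
                    crop_shape: tuple[int, int, int] = (128, 128, 96),
                    channel2: str = "dilated_mask",
                    morph_radius_mm: float = 2.0,
                    min_component_mm3: float = 1000.0) -> DualInput:
    """Full pipeline: skull strip -> resample -> window -> dual-input crop."""
    stripped, _ = strip_skull(ct, morph_radius_mm=morph_radius_mm,
                              min_component_mm3=min_component_mm3)
    vol_r, mask_r = resample_isotropic(stripped, mask, target_shape=resample_shape,
                                       background=-1000.0)
    windowed = apply_window(vol_r, window)
    return crop_dual_input(windowed, mask_r, dilation_radius_mm=dilation_radius_mm,
                           box_shape=box_shape, crop_shape=crop_shape,
                           channel2=channel2)
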