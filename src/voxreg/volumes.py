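"""Domain containers for 3D volumes, label maps and displacement fields,
NIfTI I/O, and the standard preprocessing pipeline.

Conventions
-----------
Array axes (i, j, k) map to physical axes through the per-axis voxel
spacing only; no orientation matrices are interpreted.  Voxel centres are
zero-based: voxel (0, 0, 0) sits at ``origin`` mm and voxel i at
``origin + i * spacing``.  Displacement fields store per-voxel offsets in
voxel units, channel order matching axis order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.interpolate import CubicSpline, RegularGridInterpolator


def _check_spacing(spacing) -> tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing)
    if len(sp) != 3 or any(s <= 0 for s in sp):
        raise ValueError(f"spacing must be a positive triple, got {spacing!r}")
    return sp


@dataclass
class Volume:
    """3D scalar image with physical spacing (mm).

    Holds fixed, moving and predicted intensity images.  All values must
    be finite; after :func:`normalize_intensity` they lie in [0, 1].
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume contains non-finite voxels")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """3D categorical label map stored as 8-bit unsigned integers.

    Label 0 is background.  All warping/resampling of labels uses
    nearest-neighbour sampling, so the label set never grows.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"LabelVolume data must be 3D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.round(arr)):
                raise ValueError("labels must be integer-valued")
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("labels must lie in [0, 255]")
        self.data = arr.astype(np.uint8)
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def labels(self) -> np.ndarray:
        return np.unique(self.data)


@dataclass
class DisplacementField:
    """Dense backward displacement field, shape (3, D, H, W), voxel units.

    Component c gives the offset along array axis c at which the moving
    image is sampled (pull convention).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[0] != 3:
            raise ValueError(
                f"DisplacementField data must have shape (3, D, H, W), got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("DisplacementField contains non-finite components")
        self.spacing = _check_spacing(self.spacing)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def magnitude_mm(self) -> np.ndarray:
        """Per-voxel Euclidean displacement magnitude in millimetres."""
        sp = np.asarray(self.spacing)[:, None, None, None]
        return np.sqrt(((self.data * sp) ** 2).sum(axis=0))


# -- NIfTI I/O -----------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([*spacing, 1.0])
    aff[:3, 3] = origin
    return aff


def read_nifti(path, as_labels: bool = False) -> Volume | LabelVolume:
    """Read a 3D single-channel NIfTI file.

    ``as_labels`` forces integer dtype and nearest-neighbour semantics in
    every downstream operation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    arr = np.squeeze(arr) if arr.ndim == 4 and arr.shape[-1] == 1 else arr
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D single-channel image, got shape {arr.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    if as_labels:
        return LabelVolume(arr, spacing, origin)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path}: volume contains non-finite voxels")
    return Volume(arr.astype(np.float64), spacing, origin)


def write_nifti(vol: Volume | LabelVolume, path) -> None:
    """Write a volume or label map as NIfTI (.nii / .nii.gz)."""
    path = Path(path)
    if isinstance(vol, LabelVolume):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data.astype(np.float64)
    img = nib.Nifti1Image(data, _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_field(path) -> DisplacementField:
    """Read a displacement field stored as 4D NIfTI with last dim 3."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"{path}: expected 4D NIfTI with last dimension 3, got {arr.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DisplacementField(np.moveaxis(arr, -1, 0), spacing)


def write_field(fld: DisplacementField, path) -> None:
    """Write a field as 4D NIfTI, last dimension 3, voxel units."""
    arr = np.moveaxis(fld.data, 0, -1)
    img = nib.Nifti1Image(arr, _affine(fld.spacing, (0.0, 0.0, 0.0)))
    img.header["descrip"] = b"displacement field, voxel units, axis order (i,j,k)"
    nib.save(img, str(path))


# -- preprocessing -------------------------------------------------------

def _interp_to_coords(data: np.ndarray, coords: list[np.ndarray], cubic: bool) -> np.ndarray:
    """Tensor-grid interpolation of ``data`` at per-axis output coords.

    Cubic resampling is the exact tensor-product not-a-knot cubic spline,
    applied one axis at a time (the 1D operators commute on a regular
    grid); nearest uses a regular-grid lookup.
    """
    if cubic:
        out = data.astype(np.float64)
        for axis in range(3):
            pts = np.arange(out.shape[axis], dtype=np.float64)
            if len(pts) < 4:
                # too few samples for a cubic segment: fall back to linear
                out = np.apply_along_axis(
                    lambda v: np.interp(coords[axis], pts, v), axis, out
                )
            else:
                out = CubicSpline(pts, out, axis=axis)(coords[axis])
        return out
    axes = [np.arange(n, dtype=np.float64) for n in data.shape]
    rgi = RegularGridInterpolator(axes, data.astype(np.float64), method="nearest",
                                  bounds_error=False, fill_value=None)
    mesh = np.meshgrid(*coords, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    return rgi(pts).reshape(tuple(len(c) for c in coords))


def resample_isotropic(vol: Volume | LabelVolume, target: float,
                       scheme: str | None = None) -> Volume | LabelVolume:
    """Resample to isotropic ``target`` mm spacing.

    Intensity images use cubic spline interpolation, label maps nearest
    neighbour.  New axis length = round(old_len * old_spacing / target),
    sampling at zero-based voxel centres.
    """
    if target <= 0:
        raise ValueError("target spacing must be positive")
    is_labels = isinstance(vol, LabelVolume)
    if scheme is None:
        scheme = "nearest" if is_labels else "cubic"
    if is_labels and scheme == "cubic":
        raise ValueError("cubic interpolation is not valid for label volumes")
    if all(abs(s - target) < 1e-12 for s in vol.spacing):
        return replace(vol, data=vol.data.copy())
    new_shape = tuple(
        max(1, int(round(n * s / target))) for n, s in zip(vol.data.shape, vol.spacing)
    )
    coords = [
        np.arange(m, dtype=np.float64) * (target / s)
        for m, s in zip(new_shape, vol.spacing)
    ]
    out = _interp_to_coords(vol.data, coords, cubic=(scheme == "cubic"))
    if is_labels:
        return LabelVolume(np.rint(out).astype(np.uint8), (target,) * 3, vol.origin)
    return Volume(out, (target,) * 3, vol.origin)


def resize_to_shape(vol: Volume | LabelVolume, shape: tuple[int, int, int]) -> Volume | LabelVolume:
    """Resize to an exact voxel shape, preserving the physical extent.

    The effective spacing after the resize (old_len * old_spacing /
    new_len per axis) is recorded on the output and should be used for
    all mm-denominated metrics downstream.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ValueError(f"shape must be a positive triple, got {shape!r}")
    is_labels = isinstance(vol, LabelVolume)
    if vol.data.shape == shape:
        return replace(vol, data=vol.data.copy())
    new_spacing = tuple(
        n * s / m for n, s, m in zip(vol.data.shape, vol.spacing, shape)
    )
    coords = [
        np.arange(m, dtype=np.float64) * (n / m)
        for m, n in zip(shape, vol.data.shape)
    ]
    out = _interp_to_coords(vol.data, coords, cubic=not is_labels)
    if is_labels:
        return LabelVolume(np.rint(out).astype(np.uint8), new_spacing, vol.origin)
    return Volume(out, new_spacing, vol.origin)


def crop_to_mask(vol: Volume | LabelVolume, mask: LabelVolume, margin: int = 0):
    """Crop to the bounding box of mask > 0, expanded by ``margin`` voxels.

    The crop is clipped to the volume bounds and the origin updated so
    physical coordinates are preserved.
    """
    if mask.data.shape != vol.data.shape:
        raise ValueError("mask shape must match volume shape")
    fg = np.argwhere(mask.data > 0)
    if fg.size == 0:
        raise ValueError("mask is empty")
    lo = np.maximum(fg.min(axis=0) - margin, 0)
    hi = np.minimum(fg.max(axis=0) + margin + 1, vol.data.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    new_origin = tuple(o + a * s for o, a, s in zip(vol.origin, lo, vol.spacing))
    return replace(vol, data=vol.data[sl].copy(), origin=new_origin)


def normalize_intensity(vol: Volume) -> Volume:
    """Linearly rescale intensities to [0, 1]; a constant volume maps to zeros."""
    lo, hi = float(vol.data.min()), float(vol.data.max())
    if hi == lo:
        return replace(vol, data=np.zeros_like(vol.data))
    return replace(vol, data=(vol.data - lo) / (hi - lo))


def one_hot(labels: LabelVolume, num_classes: int) -> np.ndarray:
    """One-hot encode a label map, returning (num_classes, D, H, W) floats.

    Channel c is the indicator of label c; channels partition unity.
    """
    if int(labels.data.max()) >= num_classes:
        raise ValueError(
            f"label {int(labels.data.max())} out of range for {num_classes} classes"
        )
    out = np.zeros((num_classes,) + labels.data.shape, dtype=np.float64)
    for c in range(num_classes):
        out[c] = labels.data == c
    return out


def preprocess(vol: Volume, mask: LabelVolume | None = None, *,
               iso_mm: float = 1.0, shape: tuple[int, int, int] = (128, 128, 128),
               margin: int = 4) -> Volume:
    """Standard preprocessing chain: optional crop around a mask, resample
    to isotropic resolution, resize to the target shape, normalise to [0, 1].
    """
    if mask is not None:
        vol = crop_to_mask(vol, mask, margin)
    vol = resample_isotropic(vol, iso_mm)
    vol = resize_to_shape(vol, shape)
    return normalize_intensity(vol)
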