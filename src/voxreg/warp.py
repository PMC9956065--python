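"""Dense displacement-field warping in the backward (pull) convention.

Every operation here works on plain NumPy arrays; the differentiable
counterpart used during training lives in :mod:`voxreg.autodiff`
(``grid_sample``).  A field Phi maps fixed-grid voxel positions into
moving-image coordinates: out(x) = moving(x + Phi(x)).  Out-of-bounds
sample positions clamp to the volume edge.
"""

from __future__ import annotations

import numpy as np

from .volumes import DisplacementField, LabelVolume, Volume


def _base_grid(shape) -> np.ndarray:
    return np.stack(
        np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    )


def sample_channels(data: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Trilinear sampling of (C, D, H, W) data at positions (3, D', H', W').

    Positions are in voxel units of ``data``'s grid and clamp to the edge.
    """
    D, H, W = data.shape[1:]
    hi = np.array([D - 1, H - 1, W - 1], dtype=np.float64)
    cl = np.stack([np.clip(pos[a], 0.0, hi[a]) for a in range(3)])
    p0 = np.minimum(np.floor(cl), hi[:, None, None, None] - 1).astype(np.int64)
    p0 = np.maximum(p0, 0)
    f = cl - p0
    i0, j0, k0 = p0
    out = np.zeros((data.shape[0],) + pos.shape[1:])
    for di in (0, 1):
        wi = f[0] if di else 1.0 - f[0]
        for dj in (0, 1):
            wj = f[1] if dj else 1.0 - f[1]
            for dk in (0, 1):
                wk = f[2] if dk else 1.0 - f[2]
                out += (wi * wj * wk) * data[:, i0 + di, j0 + dj, k0 + dk]
    return out


def warp_volume(moving: Volume, field: DisplacementField) -> Volume:
    """Trilinearly resample the moving image at x + Phi(x)."""
    if field.spatial_shape != moving.data.shape:
        raise ValueError(
            f"field shape {field.spatial_shape} does not match volume {moving.data.shape}"
        )
    pos = _base_grid(moving.data.shape) + field.data
    out = sample_channels(moving.data[None], pos)[0]
    return Volume(out, moving.spacing, moving.origin)


def warp_labels(labels: LabelVolume, field: DisplacementField) -> LabelVolume:
    """Nearest-neighbour resample of a label map; never invents labels."""
    if field.spatial_shape != labels.data.shape:
        raise ValueError(
            f"field shape {field.spatial_shape} does not match labels {labels.data.shape}"
        )
    shape = labels.data.shape
    pos = _base_grid(shape) + field.data
    idx = [
        np.clip(np.rint(pos[a]), 0, shape[a] - 1).astype(np.int64) for a in range(3)
    ]
    return LabelVolume(labels.data[idx[0], idx[1], idx[2]], labels.spacing, labels.origin)


def rotation_matrix(angles_deg) -> np.ndarray:
    """Rotation about axes 0, 1, 2 composed as R0 @ R1 @ R2."""
    a, b, c = np.deg2rad(np.asarray(angles_deg, dtype=np.float64))
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    r0 = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    r1 = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    r2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return r0 @ r1 @ r2


def rigid_to_field(transform, shape, spacing=(1.0, 1.0, 1.0)) -> DisplacementField:
    """Dense backward field of a rigid motion about the volume centre.

    The sample position for output voxel x is A(x) = R (x - c) + c + t,
    computed in physical mm and converted back to voxel units per axis,
    so Phi(x) = A(x) - x.  A pure translation by t mm at 1 mm spacing
    yields the constant field +t (the moving image appears shifted by -t).
    """
    shape = tuple(int(s) for s in shape)
    sp = np.asarray(spacing, dtype=np.float64)
    centre = transform.centre
    if centre is None:
        centre = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0
    c_mm = np.asarray(centre, dtype=np.float64) * sp
    R = rotation_matrix(transform.angles_deg)
    t_mm = np.asarray(transform.translation_mm, dtype=np.float64)
    grid = _base_grid(shape)
    x_mm = grid * sp[:, None, None, None]
    rel = x_mm - c_mm[:, None, None, None]
    rot = np.einsum("ab,bijk->aijk", R, rel)
    a_mm = rot + (c_mm + t_mm)[:, None, None, None]
    phi = a_mm / sp[:, None, None, None] - grid
    return DisplacementField(phi, tuple(sp))


def compose_fields(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Compose so that warp(v, compose(outer, inner)) == warp(warp(v, outer), inner).

    Phi(x) = inner(x) + outer(x + inner(x)), sampling outer trilinearly.
    """
    if outer.spatial_shape != inner.spatial_shape:
        raise ValueError("fields must share a spatial shape")
    pos = _base_grid(inner.spatial_shape) + inner.data
    outer_at = sample_channels(outer.data, pos)
    return DisplacementField(inner.data + outer_at, inner.spacing)


def resample_field(field: DisplacementField, to_shape, to_spacing) -> DisplacementField:
    """Piecewise-linearly resample a field onto a new grid/spacing.

    Each component is interpolated at the new voxel centres and rescaled
    from old-voxel units to new-voxel units (component c is multiplied by
    old_spacing_c / new_spacing_c).
    """
    to_shape = tuple(int(s) for s in to_shape)
    to_spacing = tuple(float(s) for s in to_spacing)
    if any(s <= 0 for s in to_spacing):
        raise ValueError("spacing must be positive")
    if to_shape == field.spatial_shape and to_spacing == tuple(field.spacing):
        return DisplacementField(field.data.copy(), to_spacing)
    # new voxel i sits at i*new_sp mm -> old index i*new_sp/old_sp
    coords = np.stack(
        np.meshgrid(
            *[
                np.arange(m, dtype=np.float64) * (ns / os)
                for m, ns, os in zip(to_shape, to_spacing, field.spacing)
            ],
            indexing="ij",
        )
    )
    comps = sample_channels(field.data, coords)
    scale = np.array(
        [os / ns for os, ns in zip(field.spacing, to_spacing)]
    )[:, None, None, None]
    return DisplacementField(comps * scale, to_spacing)


def jacobian_sign_counts(field: DisplacementField) -> dict[str, int]:
    """Diagnostic: counts of positive/non-positive Jacobian determinants.

    The plain displacement output does not guarantee invertibility; this
    reports how many interior voxels have a non-positive determinant of
    the deformation gradient (forward differences).
    """
    phi = field.data
    grads = np.stack(
        [np.stack(np.gradient(phi[c], axis=(0, 1, 2))) for c in range(3)]
    )  # (comp, axis, D, H, W)
    jac = grads + np.eye(3)[:, :, None, None, None]
    det = (
        jac[0, 0] * (jac[1, 1] * jac[2, 2] - jac[1, 2] * jac[2, 1])
        - jac[0, 1] * (jac[1, 0] * jac[2, 2] - jac[1, 2] * jac[2, 0])
        + jac[0, 2] * (jac[1, 0] * jac[2, 1] - jac[1, 1] * jac[2, 0])
    )
    return {"positive": int((det > 0).sum()), "nonpositive": int((det <= 0).sum())}
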