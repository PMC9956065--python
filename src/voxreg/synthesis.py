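"""On-the-fly generation of synthetic fixed/moving training pairs.

A moving image is manufactured from a fixed image by composing a sampled
rigid motion with a thin-plate-spline (TPS) non-rigid deformation, then
applying intensity augmentation (gamma and brightness jitter).  Caps on
the deformation magnitudes keep the synthetic motion within clinically
plausible bounds: by default 30 mm of rigid translation, 10 degrees of
rotation per axis, and 6 mm of non-rigid displacement on an 8x8x8
control grid.  Everything happens in memory; no augmented copies are
ever written to disk.

The module also provides a multi-organ phantom generator used by the
test-suite and the CLI demos.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy import ndimage

from .volumes import DisplacementField, LabelVolume, Volume
from .warp import compose_fields, rigid_to_field, warp_labels, warp_volume


@dataclass
class AugmentationConfig:
    """Caps and ranges of the synthetic-pair generator.

    gamma_range : exponent range of the gamma augmentation
    brightness_frac : additive brightness jitter, fraction of the [0,1] range
    max_rotation_deg : per-axis rotation cap in degrees
    max_rigid_translation_mm : cap on the translation vector norm (mm)
    max_nonrigid_disp_mm : cap on the voxelwise non-rigid magnitude (mm)
    control_grid : TPS control-point counts per axis
    """

    gamma_range: tuple[float, float] = (0.5, 2.0)
    brightness_frac: float = 0.20
    max_rotation_deg: float = 10.0
    max_rigid_translation_mm: float = 30.0
    max_nonrigid_disp_mm: float = 6.0
    control_grid: tuple[int, int, int] = (8, 8, 8)
    seed: int = 0

    def __post_init__(self):
        self.gamma_range = tuple(float(g) for g in self.gamma_range)
        self.control_grid = tuple(int(c) for c in self.control_grid)
        if self.gamma_range[0] > self.gamma_range[1]:
            raise ValueError("gamma_range must be (lo, hi) with lo <= hi")
        for cap in (self.brightness_frac, self.max_rotation_deg,
                    self.max_rigid_translation_mm, self.max_nonrigid_disp_mm):
            if cap < 0:
                raise ValueError("caps must be non-negative")
        if any(c < 2 for c in self.control_grid):
            raise ValueError("control_grid entries must be >= 2")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def desk_augmentation(seed: int = 0) -> AugmentationConfig:
    """Reduced preset for small (~32^3) phantom experiments.

    Scales the motion caps to the small field of view (3 mm translation,
    4 deg rotation, 2 mm non-rigid on a 4^3 control grid) and keeps the
    intensity jitter mild so geometry dominates the learning signal.
    """
    return AugmentationConfig(
        gamma_range=(0.9, 1.1),
        brightness_frac=0.05,
        max_rotation_deg=4.0,
        max_rigid_translation_mm=3.0,
        max_nonrigid_disp_mm=2.0,
        control_grid=(4, 4, 4),
        seed=seed,
    )


@dataclass
class RigidTransform:
    """Rotation (degrees, per axis) plus translation (mm) about a centre.

    ``centre`` is in voxel coordinates; None means the volume centre.
    """

    angles_deg: tuple[float, float, float]
    translation_mm: tuple[float, float, float]
    centre: tuple[float, float, float] | None = None


def sample_rigid(cfg: AugmentationConfig, rng: np.random.Generator) -> RigidTransform:
    """Draw a rigid transform respecting the configured caps.

    Angles are uniform per axis in [-cap, +cap]; the translation direction
    is uniform on the sphere with magnitude uniform in [0, cap].
    """
    angles = rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg, size=3)
    direction = rng.normal(size=3)
    nrm = np.linalg.norm(direction)
    direction = direction / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
    magnitude = rng.uniform(0.0, cfg.max_rigid_translation_mm)
    return RigidTransform(tuple(angles), tuple(direction * magnitude))


# -- thin-plate splines --------------------------------------------------

class TPSModel:
    """3D thin-plate spline interpolant through control-point displacements.

    Uses the kernel U(r) = r (the triharmonic-consistent choice in 3D)
    plus an affine part.  ``coefficients`` holds the (P+4, 3) solution of
    the interpolation system: kernel weights stacked over the affine part.
    """

    def __init__(self, control_points: np.ndarray, control_displacements: np.ndarray):
        pts = np.asarray(control_points, dtype=np.float64)
        disp = np.asarray(control_displacements, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape != disp.shape:
            raise ValueError("expected matching (P, 3) points and displacements")
        P = pts.shape[0]
        if P < 4:
            raise ValueError("TPS needs at least 4 control points")
        K = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        Q = np.hstack([np.ones((P, 1)), pts])
        A = np.zeros((P + 4, P + 4))
        A[:P, :P] = K
        A[:P, P:] = Q
        A[P:, :P] = Q.T
        rhs = np.zeros((P + 4, 3))
        rhs[:P] = disp
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as err:
            raise ValueError("degenerate control-point set (singular TPS system)") from err
        resid = K @ sol[:P] + Q @ sol[P:] - disp
        if not np.all(np.isfinite(sol)) or np.abs(resid).max() > 1e-6:
            raise ValueError("degenerate control-point set (TPS system not solvable)")
        self.control_points = pts
        self.control_displacements = disp
        self.coefficients = sol

    def __call__(self, points: np.ndarray, chunk: int = 2048) -> np.ndarray:
        """Evaluate the interpolated displacement at (Q, 3) points."""
        points = np.asarray(points, dtype=np.float64)
        w, a = self.coefficients[:-4], self.coefficients[-4:]
        out = np.empty((points.shape[0], 3))
        for s in range(0, points.shape[0], chunk):
            blk = points[s:s + chunk]
            r = np.linalg.norm(blk[:, None, :] - self.control_points[None, :, :], axis=-1)
            out[s:s + chunk] = r @ w + np.hstack([np.ones((blk.shape[0], 1)), blk]) @ a
        return out

    def dense_field(self, shape) -> np.ndarray:
        """Evaluate on every voxel of a grid, returning (3, D, H, W)."""
        shape = tuple(int(s) for s in shape)
        grid = np.stack(
            np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
        )
        pts = grid.reshape(3, -1).T
        return self(pts).T.reshape((3,) + shape)


def tps_fit(control_points, control_displacements) -> TPSModel:
    """Fit a 3D TPS through the given control displacements."""
    return TPSModel(control_points, control_displacements)


def control_grid_points(shape, grid: tuple[int, int, int]) -> np.ndarray:
    """Regular control lattice spanning the full volume extent, boundary
    planes included; returns (prod(grid), 3) voxel coordinates."""
    axes = [np.linspace(0.0, n - 1.0, g) for n, g in zip(shape, grid)]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=-1)


def sample_nonrigid(cfg: AugmentationConfig, shape, rng: np.random.Generator,
                    spacing=(1.0, 1.0, 1.0)) -> DisplacementField:
    """Draw a TPS non-rigid field whose voxelwise magnitude never exceeds
    the configured cap (mm).

    Control displacements are sampled per-axis uniform and clipped to the
    cap in vector norm; because the spline can overshoot between control
    points, the dense field is globally rescaled if its maximum magnitude
    exceeds the cap, so the bound holds exactly.
    """
    shape = tuple(int(s) for s in shape)
    sp = np.asarray(spacing, dtype=np.float64)
    cap = cfg.max_nonrigid_disp_mm
    pts = control_grid_points(shape, cfg.control_grid)
    disp_mm = rng.uniform(-cap, cap, size=pts.shape)
    norms = np.linalg.norm(disp_mm, axis=1, keepdims=True)
    over = norms[:, 0] > cap
    if cap > 0 and np.any(over):
        disp_mm[over] *= cap / norms[over]
    elif cap == 0:
        disp_mm[:] = 0.0
    disp_vox = disp_mm / sp
    model = tps_fit(pts, disp_vox)
    dense = model.dense_field(shape)
    return cap_field(DisplacementField(dense, tuple(sp)), cap)


def cap_field(field: DisplacementField, cap_mm: float) -> DisplacementField:
    """Enforce a voxelwise magnitude cap (mm) by global rescaling.

    If the maximum magnitude exceeds the cap the whole field is scaled so
    the maximum equals the cap exactly; a zero cap zeroes the field.
    """
    if cap_mm == 0.0:
        return DisplacementField(np.zeros_like(field.data), field.spacing)
    max_mm = float(field.magnitude_mm().max())
    if max_mm > cap_mm:
        return DisplacementField(field.data * (cap_mm / max_mm), field.spacing)
    return field


# -- intensity augmentation ---------------------------------------------

def sample_intensity_params(cfg: AugmentationConfig,
                            rng: np.random.Generator) -> tuple[float, float]:
    """Draw (gamma, brightness) for one augmentation call."""
    gamma = rng.uniform(*cfg.gamma_range)
    b = cfg.brightness_frac
    brightness = rng.uniform(-b, b) if b > 0 else 0.0
    return float(gamma), float(brightness)


def intensity_augment(vol: Volume, cfg: AugmentationConfig,
                      rng: np.random.Generator) -> Volume:
    """Gamma then brightness jitter, clipped back into [0, 1].

    v <- clip(v**gamma + b, 0, 1).  Requires a normalised input.
    """
    if vol.data.min() < 0.0 or vol.data.max() > 1.0:
        raise ValueError("intensity_augment expects a volume normalised to [0, 1]")
    gamma, brightness = sample_intensity_params(cfg, rng)
    out = np.clip(vol.data ** gamma + brightness, 0.0, 1.0)
    return Volume(out, vol.spacing, vol.origin)


# -- pair generation -----------------------------------------------------

def generate_pair(fixed: Volume, fixed_labels: LabelVolume, cfg: AugmentationConfig,
                  rng: np.random.Generator, augment_intensity: bool = True
                  ) -> tuple[Volume, LabelVolume, DisplacementField]:
    """Manufacture one (moving, moving_labels, ground-truth field) triple.

    The ground-truth field composes the rigid motion (applied first) with
    the TPS non-rigid deformation into a single dense backward field;
    moving = warp(fixed, field) with intensity augmentation applied to the
    moving image only, and labels follow with nearest-neighbour sampling.
    Nothing is written to disk.
    """
    if fixed.data.shape != fixed_labels.data.shape:
        raise ValueError("fixed image and labels must share a shape")
    if fixed.data.min() < 0.0 or fixed.data.max() > 1.0:
        raise ValueError("fixed image must be normalised to [0, 1]")
    rigid = sample_rigid(cfg, rng)
    rigid_field = rigid_to_field(rigid, fixed.data.shape, fixed.spacing)
    nonrigid = sample_nonrigid(cfg, fixed.data.shape, rng, fixed.spacing)
    gt_field = compose_fields(rigid_field, nonrigid)
    moving = warp_volume(fixed, gt_field)
    if augment_intensity:
        moving = intensity_augment(moving, cfg, rng)
    else:
        # keep the draw count identical so seeds stay comparable
        sample_intensity_params(cfg, rng)
    moving_labels = warp_labels(fixed_labels, gt_field)
    return moving, moving_labels, gt_field


# -- phantoms ------------------------------------------------------------

def generate_phantom(shape, n_organs: int, rng: np.random.Generator
                     ) -> tuple[Volume, LabelVolume]:
    """Generate a smooth multi-organ phantom with matching labels.

    The intensity image contains a low-frequency background, ``n_organs``
    ellipsoidal structures of distinct intensity and one tubular
    structure; labels run 1..n_organs for the ellipsoids, n_organs + 1
    for the tube, 0 for background.  Intensities lie in [0, 1] and the
    result is reproducible for a given generator state.
    """
    shape = tuple(int(s) for s in shape)
    if n_organs < 1:
        raise ValueError("n_organs must be >= 1")
    if min(shape) < 12:
        raise ValueError(f"shape {shape} too small to place structures")
    dims = np.asarray(shape, dtype=np.float64)
    bg = ndimage.gaussian_filter(rng.normal(size=shape), sigma=min(shape) / 6.0)
    bg = (bg - bg.min()) / max(np.ptp(bg), 1e-12) * 0.2 + 0.05
    data = bg
    labels = np.zeros(shape, dtype=np.uint8)
    grid = np.stack(
        np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    )
    placed: list[tuple[np.ndarray, float]] = []
    intensities = np.linspace(0.45, 0.85, n_organs)
    for organ in range(n_organs):
        radius = None
        for _ in range(200):
            r = rng.uniform(min(shape) / 9.0, min(shape) / 6.0)
            centre = np.array([rng.uniform(0.25 * n, 0.75 * n) for n in dims])
            if all(np.linalg.norm(centre - c) > 0.9 * (r + pr) for c, pr in placed):
                radius = r
                break
        if radius is None:
            raise ValueError(f"could not place organ {organ + 1} in shape {shape}")
        placed.append((centre, radius))
        semi = radius * rng.uniform(0.7, 1.3, size=3)
        q = (((grid - centre[:, None, None, None]) / semi[:, None, None, None]) ** 2).sum(axis=0)
        mask = q <= 1.0
        data = np.where(mask, intensities[organ] * (1.0 - 0.3 * q), data)
        labels[mask] = organ + 1
    # tubular structure: a sinusoidally curved tube along axis 0
    c1 = 0.28 * dims[1]
    c2 = 0.72 * dims[2]
    amp = 0.08 * min(dims[1], dims[2])
    tube_r = max(1.5, min(shape) / 14.0)
    path1 = c1 + amp * np.sin(2.0 * np.pi * grid[0] / dims[0] + rng.uniform(0, 2 * np.pi))
    path2 = c2 + amp * np.cos(2.0 * np.pi * grid[0] / dims[0])
    dist2 = (grid[1] - path1) ** 2 + (grid[2] - path2) ** 2
    tube = dist2 <= tube_r**2
    data = np.where(tube, 0.95, data)
    labels[tube] = n_organs + 1
    data = ndimage.gaussian_filter(data, sigma=0.6)
    data = np.clip(data, 0.0, 1.0)
    return Volume(data), LabelVolume(labels)


def phantom_dataset(n: int, shape, seed: int, n_organs: int = 3
                    ) -> list[tuple[Volume, LabelVolume]]:
    """Generate a reproducible list of phantom (volume, labels) pairs."""
    rng = np.random.default_rng(seed)
    return [generate_phantom(shape, n_organs, rng) for _ in range(n)]


@dataclass
class EvalPair:
    """One pre-generated fixed/moving pair used for evaluation."""

    pair_id: str
    fixed: Volume
    fixed_labels: LabelVolume
    moving: Volume
    moving_labels: LabelVolume


def make_eval_pairs(dataset, cfg: AugmentationConfig, n_pairs: int, seed: int,
                    augment_intensity: bool = False) -> list[EvalPair]:
    """Pre-generate a fixed set of evaluation pairs from a dataset.

    The same pair set can then be reused across model variants so that
    metric contrasts are paired.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_pairs):
        fixed, labels = dataset[i % len(dataset)]
        moving, moving_labels, _ = generate_pair(
            fixed, labels, cfg, rng, augment_intensity=augment_intensity
        )
        pairs.append(EvalPair(f"pair{i:03d}", fixed, labels, moving, moving_labels))
    return pairs
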