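"""Registration metric suite, pairwise evaluation reports, and the
rank-based statistics used to compare model variants.

Metrics follow the usual conventions of the registration literature:
global NCC and SSIM for intensity similarity; Dice, Hausdorff distance
(HD) and its 95th percentile (HD95, in mm) on one-hot segmentations with
the background class excluded; and a centroid-based target registration
error (TRE, mm) between corresponding masks of the fixed and predicted
images.  Per-class values are averaged with equal class weight.

The Mann-Whitney U test (one-sided) and Benjamini-Hochberg step-up
correction are implemented here directly: they gate the headline
contrasts, are small, and are verified against independent oracles in
the test-suite.
"""

from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from . import autodiff as ad
from .losses import global_ncc, ssim3d
from .network import RegistrationNetwork, predict_displacement
from .synthesis import EvalPair
from .volumes import DisplacementField, LabelVolume, Volume
from .warp import resample_field, warp_labels, warp_volume


@dataclass
class PairReport:
    """Metric row for one evaluated pair."""

    pair_id: str
    ncc: float
    ssim: float
    dsc: float
    hd_mm: float
    hd95_mm: float
    tre_mm: float
    inference_seconds: float


# -- segmentation metrics ------------------------------------------------

def _foreground_classes(a: LabelVolume, b: LabelVolume) -> np.ndarray:
    classes = np.union1d(a.labels(), b.labels())
    return classes[classes != 0]


def dice_metric(a: LabelVolume, b: LabelVolume, exclude_background: bool = True) -> float:
    """Mean hard Dice over classes present in either volume.

    A class present in only one of the two volumes scores 0.
    """
    if a.data.shape != b.data.shape:
        raise ValueError("label volumes must share a shape")
    classes = _foreground_classes(a, b) if exclude_background else np.union1d(a.labels(), b.labels())
    if classes.size == 0:
        raise ValueError("no classes to score")
    scores = []
    for c in classes:
        ma = a.data == c
        mb = b.data == c
        denom = int(ma.sum()) + int(mb.sum())
        scores.append(2.0 * int((ma & mb).sum()) / denom if denom else 0.0)
    return float(np.mean(scores))


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels under 6-connectivity (volume border counts)."""
    struct = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    return np.argwhere(mask & ~eroded)


def hausdorff_mm(a: LabelVolume, b: LabelVolume,
                 spacing=None) -> tuple[float, float]:
    """(HD, HD95) in mm, averaged over foreground classes.

    Per class the symmetric surface-distance set pools nearest-surface
    distances in both directions; HD is its maximum and HD95 its 95th
    percentile.  Classes empty in either volume are skipped with a
    warning.
    """
    if a.data.shape != b.data.shape:
        raise ValueError("label volumes must share a shape")
    sp = np.asarray(spacing if spacing is not None else a.spacing, dtype=np.float64)
    hds, hd95s = [], []
    for c in _foreground_classes(a, b):
        ma = a.data == c
        mb = b.data == c
        if not ma.any() or not mb.any():
            warnings.warn(f"class {int(c)} empty in one volume, skipped in HD")
            continue
        sa = _surface_voxels(ma) * sp
        sb = _surface_voxels(mb) * sp
        d_ab = cKDTree(sb).query(sa)[0]
        d_ba = cKDTree(sa).query(sb)[0]
        pooled = np.concatenate([d_ab, d_ba])
        hds.append(float(pooled.max()))
        hd95s.append(float(np.percentile(pooled, 95)))
    if not hds:
        raise ValueError("no nonempty shared classes for Hausdorff computation")
    return float(np.mean(hds)), float(np.mean(hd95s))


def tre_centroids(fixed_labels: LabelVolume, pred_labels: LabelVolume,
                  spacing=None) -> float:
    """Mean centroid-to-centroid distance (mm) over shared classes."""
    if fixed_labels.data.shape != pred_labels.data.shape:
        raise ValueError("label volumes must share a shape")
    sp = np.asarray(spacing if spacing is not None else fixed_labels.spacing,
                    dtype=np.float64)
    shared = np.intersect1d(fixed_labels.labels(), pred_labels.labels())
    shared = shared[shared != 0]
    if shared.size == 0:
        raise ValueError("no shared foreground classes for TRE")
    dists = []
    for c in shared:
        ca = np.argwhere(fixed_labels.data == c).mean(axis=0) * sp
        cb = np.argwhere(pred_labels.data == c).mean(axis=0) * sp
        dists.append(float(np.linalg.norm(ca - cb)))
    return float(np.mean(dists))


# -- pairwise evaluation -------------------------------------------------

def _metrics_row(pair_id: str, fixed: Volume, fixed_labels: LabelVolume,
                 pred: Volume, pred_labels: LabelVolume,
                 seconds: float) -> PairReport:
    with ad.no_grad():
        ssim_val = float(ssim3d(fixed, pred).data)
    hd, hd95 = hausdorff_mm(fixed_labels, pred_labels)
    return PairReport(
        pair_id=pair_id,
        ncc=global_ncc(fixed, pred),
        ssim=ssim_val,
        dsc=dice_metric(fixed_labels, pred_labels),
        hd_mm=hd,
        hd95_mm=hd95,
        tre_mm=tre_centroids(fixed_labels, pred_labels),
        inference_seconds=seconds,
    )


def evaluate_pairs(net: RegistrationNetwork | None, pairs: list[EvalPair],
                   eval_spacing=None) -> pd.DataFrame:
    """Evaluate a model (or the unregistered baseline) on a fixed pair set.

    With ``net=None`` the metrics compare fixed to moving directly (the
    unregistered row).  Otherwise the field is predicted, resampled to
    the evaluation spacing (1 mm isotropic by default if the pair grid
    differs), and applied to the moving image and labels; the timing
    covers prediction and warping only, so rows are comparable across
    variants sharing an architecture.
    """
    if not pairs:
        raise ValueError("pairs must be nonempty")
    rows = []
    for pair in pairs:
        if net is None:
            rows.append(_metrics_row(pair.pair_id, pair.fixed, pair.fixed_labels,
                                     pair.moving, pair.moving_labels, 0.0))
            continue
        t0 = time.perf_counter()
        field = predict_displacement(net, pair.fixed, pair.moving)
        if eval_spacing is not None and tuple(eval_spacing) != tuple(field.spacing):
            new_shape = tuple(
                int(round(n * s / t))
                for n, s, t in zip(field.spatial_shape, field.spacing, eval_spacing)
            )
            field = resample_field(field, new_shape, eval_spacing)
        pred = warp_volume(pair.moving, field)
        pred_labels = warp_labels(pair.moving_labels, field)
        seconds = time.perf_counter() - t0
        rows.append(_metrics_row(pair.pair_id, pair.fixed, pair.fixed_labels,
                                 pred, pred_labels, seconds))
    return pd.DataFrame([r.__dict__ for r in rows])


# -- statistics ----------------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=np.float64)
    i = 0
    sv = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def mann_whitney_u(x, y, alternative: str = "less") -> tuple[float, float]:
    """One-sided Mann-Whitney U test.

    Returns (U_x, p).  U_x = R_x - n(n+1)/2 with midrank ties.  For
    sample sizes up to 8 apiece the p-value is exact (enumeration over
    all rank assignments, conditional on the observed ties); larger
    samples use the normal approximation with tie correction and
    continuity correction.  alternative='less' tests whether x tends to
    be smaller than y.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    n, m = x.size, y.size
    ranks = _midranks(np.concatenate([x, y]))
    u_x = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    if n <= 8 and m <= 8:
        total = 0
        hits = 0
        base = n * (n + 1) / 2.0
        for comb in combinations(range(n + m), n):
            u = float(ranks[list(comb)].sum() - base)
            total += 1
            if alternative == "less" and u <= u_x + 1e-12:
                hits += 1
            elif alternative == "greater" and u >= u_x - 1e-12:
                hits += 1
        return u_x, hits / total
    mu = n * m / 2.0
    counts = np.unique(ranks, return_counts=True)[1].astype(np.float64)
    N = float(n + m)
    tie_term = ((counts**3 - counts).sum()) / (N * (N - 1.0))
    sigma2 = n * m / 12.0 * ((N + 1.0) - tie_term)
    if sigma2 <= 0:
        return u_x, 0.5
    sigma = math.sqrt(sigma2)
    if alternative == "less":
        z = (u_x - mu + 0.5) / sigma
    else:
        z = -(u_x - mu - 0.5) / sigma
    p = 0.5 * math.erfc(-z / math.sqrt(2.0))
    return u_x, float(p)


def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up FDR adjustment; monotone and clipped at 1."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a nonempty 1D sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out
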