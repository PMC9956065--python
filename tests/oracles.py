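"""Independent brute-force oracles used by the unit and acceptance tests.

Each function here recomputes a quantity by the most direct possible
means (per-voxel loops, explicit linear solves, exhaustive enumeration)
and deliberately shares no code with the package implementation.
"""

from itertools import combinations

import numpy as np


def tps_dense_oracle(points: np.ndarray, disps: np.ndarray, shape) -> np.ndarray:
    """Direct TPS solve (kernel U(r)=r + affine) and per-voxel kernel sum."""
    P = points.shape[0]
    A = np.zeros((P + 4, P + 4))
    for i in range(P):
        for j in range(P):
            A[i, j] = np.linalg.norm(points[i] - points[j])
        A[i, P] = 1.0
        A[i, P + 1:] = points[i]
        A[P, i] = 1.0
        A[P + 1:, i] = points[i]
    rhs = np.vstack([disps, np.zeros((4, 3))])
    sol = np.linalg.solve(A, rhs)
    out = np.zeros((3,) + tuple(shape))
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                x = np.array([i, j, k], dtype=float)
                val = sol[P] + sol[P + 1:].T @ x
                for p in range(P):
                    val = val + sol[p] * np.linalg.norm(x - points[p])
                out[:, i, j, k] = val
    return out


def trilinear_oracle(img: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Scalar per-voxel trilinear interpolation with edge clamping."""
    D, H, W = img.shape
    out = np.zeros_like(img, dtype=float)
    for i in range(D):
        for j in range(H):
            for k in range(W):
                p = np.array([i, j, k], dtype=float) + field[:, i, j, k]
                p = np.clip(p, 0.0, [D - 1, H - 1, W - 1])
                f0 = np.minimum(np.floor(p).astype(int), [D - 2, H - 2, W - 2])
                f0 = np.maximum(f0, 0)
                t = p - f0
                acc = 0.0
                for di in (0, 1):
                    for dj in (0, 1):
                        for dk in (0, 1):
                            w = ((t[0] if di else 1 - t[0])
                                 * (t[1] if dj else 1 - t[1])
                                 * (t[2] if dk else 1 - t[2]))
                            acc += w * img[f0[0] + di, f0[1] + dj, f0[2] + dk]
                out[i, j, k] = acc
    return out


def nearest_oracle(labels: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Per-voxel nearest-neighbour label sampling with edge clamping."""
    D, H, W = labels.shape
    out = np.zeros_like(labels)
    for i in range(D):
        for j in range(H):
            for k in range(W):
                p = np.array([i, j, k], dtype=float) + field[:, i, j, k]
                q = np.clip(np.rint(p).astype(int), 0, [D - 1, H - 1, W - 1])
                out[i, j, k] = labels[q[0], q[1], q[2]]
    return out


def window_sums_oracle(a: np.ndarray, window: int) -> np.ndarray:
    """Per-voxel centred-window sums with zero padding, by direct loops."""
    m = window // 2
    D, H, W = a.shape
    out = np.zeros_like(a, dtype=float)
    for i in range(D):
        for j in range(H):
            for k in range(W):
                s = 0.0
                for di in range(-m, m + 1):
                    for dj in range(-m, m + 1):
                        for dk in range(-m, m + 1):
                            ii, jj, kk = i + di, j + dj, k + dk
                            if 0 <= ii < D and 0 <= jj < H and 0 <= kk < W:
                                s += a[ii, jj, kk]
                out[i, j, k] = s
    return out


def local_ncc_oracle(a: np.ndarray, b: np.ndarray, window: int) -> float:
    """Windowed squared-correlation loss by direct window gathering,
    averaged over fully interior (valid) windows."""
    n = window**3
    sa = window_sums_oracle(a, window)
    sb = window_sums_oracle(b, window)
    saa = window_sums_oracle(a * a, window)
    sbb = window_sums_oracle(b * b, window)
    sab = window_sums_oracle(a * b, window)
    cross = sab - sa * sb / n
    va = saa - sa**2 / n
    vb = sbb - sb**2 / n
    cc = cross**2 / np.maximum(va * vb, 1e-9)
    m = window // 2
    return 1.0 - cc[m:-m, m:-m, m:-m].mean()


def smoothness_oracle(field: np.ndarray) -> float:
    """Mean over (component, axis) of mean squared forward differences."""
    vals = []
    for c in range(3):
        for axis in range(3):
            d = np.diff(field[c], axis=axis)
            vals.append((d**2).mean())
    return float(np.mean(vals))


def hausdorff_oracle(mask_a: np.ndarray, mask_b: np.ndarray,
                     spacing=(1.0, 1.0, 1.0)) -> tuple[float, float]:
    """All-pairs boundary-distance HD and HD95 for a single class pair."""
    sp = np.asarray(spacing, dtype=float)

    def surface(mask):
        pts = []
        D, H, W = mask.shape
        for i in range(D):
            for j in range(H):
                for k in range(W):
                    if not mask[i, j, k]:
                        continue
                    on_border = i in (0, D - 1) or j in (0, H - 1) or k in (0, W - 1)
                    has_bg = False
                    for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                       (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                        ii, jj, kk = i + di, j + dj, k + dk
                        if 0 <= ii < D and 0 <= jj < H and 0 <= kk < W:
                            if not mask[ii, jj, kk]:
                                has_bg = True
                    if on_border or has_bg:
                        pts.append((i, j, k))
        return np.array(pts, dtype=float) * sp

    sa, sb = surface(mask_a), surface(mask_b)
    d_ab = [min(np.linalg.norm(p - q) for q in sb) for p in sa]
    d_ba = [min(np.linalg.norm(p - q) for q in sa) for p in sb]
    pooled = np.array(d_ab + d_ba)
    return float(pooled.max()), float(np.percentile(pooled, 95))


def mwu_exact_oracle(x, y, alternative: str = "less") -> tuple[float, float]:
    """Exhaustive permutation distribution of the Mann-Whitney U statistic."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    allv = np.concatenate([x, y])
    order = np.argsort(allv, kind="mergesort")
    ranks = np.empty(n + m)
    sv = allv[order]
    i = 0
    while i < n + m:
        j = i
        while j + 1 < n + m and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    us = [
        sum(ranks[list(c)]) - n * (n + 1) / 2.0
        for c in combinations(range(n + m), n)
    ]
    if alternative == "less":
        p = np.mean([u <= u_obs + 1e-12 for u in us])
    else:
        p = np.mean([u >= u_obs - 1e-12 for u in us])
    return float(u_obs), float(p)


def bh_oracle(pvals) -> np.ndarray:
    """Step-up rule applied literally: adj_(i) = min_{j>=i} p_(j) * N / j."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    adj_sorted = np.empty(n)
    for i in range(n):
        adj_sorted[i] = min(
            min(sorted_p[j] * n / (j + 1) for j in range(i, n)), 1.0
        )
    out = np.empty(n)
    out[order] = adj_sorted
    return out


def invert_field_oracle(field: np.ndarray, n_iter: int = 30) -> np.ndarray:
    """Fixed-point numeric inversion of a backward displacement field."""
    D, H, W = field.shape[1:]
    base = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in (D, H, W)],
                                indexing="ij"))
    inv = np.zeros_like(field)

    def sample(data, pos):
        out = np.zeros_like(data)
        hi = np.array([D - 1, H - 1, W - 1], dtype=float)
        cl = np.stack([np.clip(pos[a], 0, hi[a]) for a in range(3)])
        p0 = np.maximum(
            np.minimum(np.floor(cl).astype(int),
                       (hi - 1).astype(int)[:, None, None, None]),
            0,
        )
        t = cl - p0
        for di in (0, 1):
            for dj in (0, 1):
                for dk in (0, 1):
                    w = ((t[0] if di else 1 - t[0]) * (t[1] if dj else 1 - t[1])
                         * (t[2] if dk else 1 - t[2]))
                    out += w * data[:, p0[0] + di, p0[1] + dj, p0[2] + dk]
        return out

    for _ in range(n_iter):
        inv = -sample(field, base + inv)
    return inv
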