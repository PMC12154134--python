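"""Independent brute-force oracles used by the test suite.

Everything here is written with plain loops and direct textbook formulas,
deliberately sharing no code with the package implementation — only the
documented conventions (edge-replication padding, symmetric offset pooling,
log base 2, face-adjacent surface voxels, linear-interpolated percentile).
"""

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# GLCM / Haralick


def naive_glcm(patch, levels, offsets):
    """Symmetric normalized co-occurrence matrix by explicit loops."""

    patch = np.asarray(patch)
    if patch.ndim == 2:
        patch = patch[..., None]
    G = np.zeros((levels, levels))
    nx, ny, nz = patch.shape
    for dx, dy, dz in offsets:
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    X, Y, Z = x + dx, y + dy, z + dz
                    if 0 <= X < nx and 0 <= Y < ny and 0 <= Z < nz:
                        a, b = patch[x, y, z], patch[X, Y, Z]
                        if a > 0 and b > 0:
                            G[a - 1, b - 1] += 1
    G = G + G.T
    s = G.sum()
    return G / s if s > 0 else G


def naive_haralick(P):
    """The 13 classic statistics by direct summation (log base 2)."""

    P = np.asarray(P, dtype=float)
    L = P.shape[0]
    i1 = lambda i: i + 1  # 1-based levels
    px = [P[i].sum() for i in range(L)]
    py = [P[:, j].sum() for j in range(L)]
    mux = sum(i1(i) * px[i] for i in range(L))
    muy = sum(i1(j) * py[j] for j in range(L))
    sx = math.sqrt(max(sum(i1(i) ** 2 * px[i] for i in range(L)) - mux**2, 0.0))
    sy = math.sqrt(max(sum(i1(j) ** 2 * py[j] for j in range(L)) - muy**2, 0.0))

    energy = contrast = idm = variance = entropy = 0.0
    cov = 0.0
    for i in range(L):
        for j in range(L):
            p = P[i, j]
            energy += p * p
            contrast += p * (i - j) ** 2
            idm += p / (1.0 + (i - j) ** 2)
            variance += p * (i1(i) - mux) ** 2
            cov += p * i1(i) * i1(j)
            if p > 0:
                entropy -= p * math.log2(p)
    correlation = (cov - mux * muy) / (sx * sy) if sx * sy > 0 else 0.0

    psum = {k: 0.0 for k in range(2, 2 * L + 1)}
    pdiff = {k: 0.0 for k in range(L)}
    for i in range(L):
        for j in range(L):
            psum[i1(i) + i1(j)] += P[i, j]
            pdiff[abs(i - j)] += P[i, j]
    sum_average = sum(k * v for k, v in psum.items())
    sum_variance = sum((k - sum_average) ** 2 * v for k, v in psum.items())
    sum_entropy = -sum(v * math.log2(v) for v in psum.values() if v > 0)
    mud = sum(k * v for k, v in pdiff.items())
    difference_variance = sum((k - mud) ** 2 * v for k, v in pdiff.items())
    difference_entropy = -sum(v * math.log2(v) for v in pdiff.values() if v > 0)

    hxy1 = hxy2 = 0.0
    for i in range(L):
        for j in range(L):
            o = px[i] * py[j]
            if o > 0:
                hxy2 -= o * math.log2(o)
                if P[i, j] > 0:
                    hxy1 -= P[i, j] * math.log2(o)
    hx = -sum(p * math.log2(p) for p in px if p > 0)
    hy = -sum(p * math.log2(p) for p in py if p > 0)
    imc1 = (entropy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))

    return np.array(
        [energy, contrast, correlation, variance, idm, sum_average, sum_variance,
         sum_entropy, entropy, difference_variance, difference_entropy, imc1, imc2]
    )


def naive_haralick_maps(q, mask, levels, window, offsets, mode="3D"):
    """Per-voxel recomputation: edge-pad, extract patch, naive GLCM + stats."""

    q = np.asarray(q)
    r = window // 2
    rz = 0 if mode == "2D" else r
    wz = 1 if mode == "2D" else window
    qpad = np.pad(q, ((r, r), (r, r), (rz, rz)), mode="edge")
    out = np.zeros((13, *q.shape))
    for x, y, z in np.argwhere(mask):
        patch = qpad[x : x + window, y : y + window, z : z + wz]
        G = naive_glcm(patch, levels, offsets)
        if G.sum() == 0:
            G = np.zeros((levels, levels))
            G[0, 0] = 1.0
        out[:, x, y, z] = naive_haralick(G)
    return out


# ---------------------------------------------------------------------------
# Gray and Laws


def naive_gray_maps(data, window):
    data = np.asarray(data, dtype=float)
    r = window // 2
    pad = np.pad(data, r, mode="edge")
    med = np.zeros_like(data)
    mean = np.zeros_like(data)
    std = np.zeros_like(data)
    rng = np.zeros_like(data)
    for x, y, z in itertools.product(*map(range, data.shape)):
        w = pad[x : x + window, y : y + window, z : z + window].ravel()
        med[x, y, z] = np.median(w)
        mean[x, y, z] = w.mean()
        std[x, y, z] = w.std()
        rng[x, y, z] = w.max() - w.min()
    return {"median": med, "mean": mean, "std": std, "range": rng}


def naive_separable_correlate(data, kernels_by_axis):
    """Direct correlation with the assembled outer-product kernel,
    edge-replication padding, explicit loops."""

    data = np.asarray(data, dtype=float)
    ks = [np.asarray(k, dtype=float) for k in kernels_by_axis]
    full = ks[0][:, None, None] * ks[1][None, :, None] * ks[2][None, None, :]
    r = [len(k) // 2 for k in ks]
    pad = np.pad(data, [(r[0], r[0]), (r[1], r[1]), (r[2], r[2])], mode="edge")
    out = np.zeros_like(data)
    for x, y, z in itertools.product(*map(range, data.shape)):
        w = pad[x : x + len(ks[0]), y : y + len(ks[1]), z : z + len(ks[2])]
        out[x, y, z] = (w * full).sum()
    return out


# ---------------------------------------------------------------------------
# HD95


def brute_hd95(a, b, spacing):
    """All-pairs surface distances with loop-detected boundary voxels."""

    def boundary(m):
        pts = []
        nx, ny, nz = m.shape
        for x, y, z in np.argwhere(m):
            for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                               (0, 0, 1), (0, 0, -1)):
                X, Y, Z = x + dx, y + dy, z + dz
                if not (0 <= X < nx and 0 <= Y < ny and 0 <= Z < nz) or not m[X, Y, Z]:
                    pts.append((x * spacing[0], y * spacing[1], z * spacing[2]))
                    break
        return np.array(pts)

    pa, pb = boundary(a), boundary(b)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return float(np.percentile(pooled, 95)), float(pooled.max())


# ---------------------------------------------------------------------------
# rater statistics


def direct_weighted_kappa(a, b, n_levels=3, quadratic=False):
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    num = den = 0.0
    for i in range(n_levels):
        for j in range(n_levels):
            w = (i - j) ** 2 if quadratic else abs(i - j)
            o = np.sum((a == i) & (b == j)) / n
            e = np.sum(a == i) / n * np.sum(b == j) / n
            num += w * o
            den += w * e
    return 1.0 - num / den


def direct_cochran_q(X):
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    T = X.sum()
    cj = X.sum(axis=0)
    ri = X.sum(axis=1)
    num = (k - 1) * (k * (cj**2).sum() - T**2)
    den = k * T - (ri**2).sum()
    return num / den


# ---------------------------------------------------------------------------
# mRMR exhaustive search


def exhaustive_mrmr(mi_y, mi_ff, n_select):
    """Stepwise-exhaustive mRMR: at every step scan *all* remaining features
    and take the argmax of the MID objective, by direct formula."""

    p = len(mi_y)
    chosen = []
    remaining = list(range(p))
    for _ in range(n_select):
        best_f, best_score = None, -np.inf
        for f in remaining:
            if chosen:
                score = mi_y[f] - np.mean([mi_ff[f, s] for s in chosen])
            else:
                score = mi_y[f]
            if score > best_score + 1e-12:
                best_score, best_f = score, f
        chosen.append(best_f)
        remaining.remove(best_f)
    return chosen
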