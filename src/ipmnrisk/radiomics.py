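"""Six-family 2D/3D radiomic feature bank over a cyst ROI.

Families: Raw (original intensities), Gray (sliding median/mean/std/range),
Gradient (Sobel and finite-difference responses), Laws (separable 5-tap
texture-energy masks), Haralick (sliding-window GLCM statistics), and
CoLlAGe (co-occurrence of local dominant gradient orientations).  Every
per-voxel map is summarised over the in-mask voxels by four statistics:
median, standard deviation, skewness, and kurtosis.

Conventions (fixed; documented in the methods note):

* GLCM windows are odd cubes (3D) or in-plane squares (2D); offsets are the
  13 (3D) / 4 (2D) unique symmetric distance-1 directions pooled into one
  matrix per (window, gray-levels) pair.
* Gray levels quantized by equal-width binning between the ROI min and max,
  so features are invariant to positive affine intensity rescaling.
* Haralick set is the classic 13 statistics, log base 2; degenerate
  denominators (e.g. zero marginal variance in the correlation) yield 0.
* Maps use edge-replication padding; only in-mask voxels are aggregated;
  windows with no valid co-occurring pair fall back to the degenerate
  single-entry matrix.
* skewness/kurtosis are the Fisher, bias-uncorrected moments with the
  constant-input value defined as 0.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .grids import MaskVolume, VolumeGrid

__all__ = [
    "FeatureSpec",
    "FeatureConfig",
    "HARALICK_NAMES",
    "quantize_roi",
    "glcm_window",
    "haralick_stats",
    "compute_haralick_maps",
    "compute_collage_maps",
    "compute_laws_maps",
    "compute_gradient_maps",
    "compute_gray_maps",
    "aggregate_map",
    "extract_features",
    "extract_cohort_features",
]

HARALICK_NAMES = (
    "energy",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)

OFFSETS_3D = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, -1, 1), (1, 1, -1), (1, -1, -1),
)
OFFSETS_2D = ((1, 0, 0), (0, 1, 0), (1, 1, 0), (1, -1, 0))

LAWS_KERNELS = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
}

STATISTICS = ("median", "std", "skewness", "kurtosis")


@dataclass(frozen=True)
class FeatureSpec:
    """Metadata identifying one extracted feature column."""

    family: str
    filter_name: str
    window: int | None
    gray_levels: int | None
    statistic: str
    dim: str  # "2D" or "3D"

    @property
    def name(self) -> str:
        parts = [self.dim, self.family, self.filter_name]
        if self.window is not None:
            parts.append(f"w{self.window}")
        if self.gray_levels is not None:
            parts.append(f"g{self.gray_levels}")
        parts.append(self.statistic)
        return "_".join(parts)


@dataclass
class FeatureConfig:
    """Which families/windows/levels to extract.

    Defaults follow the study protocol: GLCM windows 3/5/7 and gray levels
    4/8/16/32/64 for the co-occurrence families.  ``FeatureConfig.small()``
    is the desk-scale bank used by the synthetic experiments.
    """

    families: tuple[str, ...] = ("Raw", "Gray", "Gradient", "Laws", "Haralick", "CoLlAGe")
    haralick_windows: tuple[int, ...] = (3, 5, 7)
    gray_levels: tuple[int, ...] = (4, 8, 16, 32, 64)
    gray_window: int = 3
    collage_window: int = 5
    collage_bins: int = 64
    collage_stats: tuple[str, ...] = ("entropy",)
    statistics: tuple[str, ...] = STATISTICS

    def __post_init__(self) -> None:
        for w in (*self.haralick_windows, self.gray_window, self.collage_window):
            if w % 2 == 0 or w < 3:
                raise ValueError(f"windows must be odd and >= 3, got {w}")
        for g in self.gray_levels:
            if g < 2:
                raise ValueError("gray_levels entries must be >= 2")

    @classmethod
    def small(cls) -> "FeatureConfig":
        """Reduced bank for desk-scale synthetic experiments."""
        return cls(haralick_windows=(3,), gray_levels=(8, 16), collage_bins=16)

    def n_features(self, mode: str) -> int:
        return len(self.expand_specs(mode))

    def expand_specs(self, mode: str) -> list[FeatureSpec]:
        """Deterministic column order: the FeatureSpec list extract_features emits."""
        mode = mode.upper()
        specs: list[FeatureSpec] = []

        def add(family, filt, w=None, g=None):
            for stat in self.statistics:
                specs.append(FeatureSpec(family, filt, w, g, stat, mode))

        for fam in self.families:
            if fam == "Raw":
                add("Raw", "intensity")
            elif fam == "Gray":
                for f in ("median", "mean", "std", "range"):
                    add("Gray", f, w=self.gray_window)
            elif fam == "Gradient":
                axes = ("x", "y") if mode == "2D" else ("x", "y", "z")
                for a in axes:
                    add("Gradient", f"sobel_{a}")
                add("Gradient", "sobel_magnitude")
                add("Gradient", "fd_magnitude")
            elif fam == "Laws":
                names = sorted(LAWS_KERNELS)
                combos = (
                    itertools.product(names, names)
                    if mode == "2D"
                    else itertools.product(names, names, names)
                )
                for combo in combos:
                    add("Laws", "".join(combo))
            elif fam == "Haralick":
                for w in self.haralick_windows:
                    for g in self.gray_levels:
                        for h in HARALICK_NAMES:
                            add("Haralick", h, w=w, g=g)
            elif fam == "CoLlAGe":
                angles = ("theta",) if mode == "2D" else ("theta", "phi")
                for ang in angles:
                    for h in self.collage_stats:
                        add("CoLlAGe", f"{ang}_{h}", w=self.collage_window,
                            g=self.collage_bins)
            else:
                raise ValueError(f"unknown family {fam!r}")
        return specs

    def specs_to_json(self, mode: str, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps([vars(s) | {"name": s.name} for s in self.expand_specs(mode)],
                       indent=1)
        )


# ---------------------------------------------------------------------------
# quantization and GLCM primitives


def _as_array(vol) -> np.ndarray:
    return vol.data if isinstance(vol, VolumeGrid) else np.asarray(vol, dtype=float)


def _as_mask(mask, shape) -> np.ndarray:
    if mask is None:
        return np.ones(shape, dtype=bool)
    if isinstance(mask, MaskVolume):
        return mask.as_bool()
    return np.asarray(mask).astype(bool)


def quantize_roi(vol, mask, levels: int) -> np.ndarray:
    """Equal-width quantization of ROI intensities into labels 1..levels.

    Bin edges span [ROI min, ROI max]; a constant ROI maps to label 1
    everywhere.  Outside-mask voxels get the ignore label 0.
    """

    if levels < 2:
        raise ValueError("levels must be >= 2")
    data = _as_array(vol)
    m = _as_mask(mask, data.shape)
    if not m.any():
        raise ValueError("empty mask")
    lo, hi = float(data[m].min()), float(data[m].max())
    q = np.zeros(data.shape, dtype=np.int32)
    if hi <= lo:
        q[m] = 1
        return q
    scaled = (data - lo) / (hi - lo) * levels
    labels = np.clip(np.floor(scaled), 0, levels - 1).astype(np.int32) + 1
    q[m] = labels[m]
    return q


def glcm_window(
    patch: np.ndarray,
    levels: int,
    offsets: tuple[tuple[int, int, int], ...] = OFFSETS_3D,
    symmetric: bool = True,
) -> np.ndarray:
    """Normalized gray-level co-occurrence matrix of one label patch.

    ``patch`` holds integer labels 1..levels with 0 = ignore.  Counts are
    accumulated over all offsets (symmetrically by default) and normalized
    to sum 1.  Raises if no valid pair exists.
    """

    patch = np.asarray(patch)
    if patch.ndim == 2:
        patch = patch[..., None]
    glcm = np.zeros((levels, levels), dtype=float)
    nx, ny, nz = patch.shape
    for dx, dy, dz in offsets:
        xs = slice(max(0, -dx), min(nx, nx - dx))
        ys = slice(max(0, -dy), min(ny, ny - dy))
        zs = slice(max(0, -dz), min(nz, nz - dz))
        a = patch[xs, ys, zs]
        b = patch[
            slice(xs.start + dx, xs.stop + dx),
            slice(ys.start + dy, ys.stop + dy),
            slice(zs.start + dz, zs.stop + dz),
        ]
        valid = (a > 0) & (b > 0)
        np.add.at(glcm, (a[valid] - 1, b[valid] - 1), 1.0)
    if symmetric:
        glcm = glcm + glcm.T
    total = glcm.sum()
    if total == 0:
        raise ValueError("no valid co-occurring pair in patch")
    return glcm / total


def _haralick_batch(P: np.ndarray) -> np.ndarray:
    """All 13 Haralick statistics for a batch of normalized GLCMs (N, L, L)."""

    N, L, _ = P.shape
    ii = np.arange(1, L + 1, dtype=float)
    I = ii[:, None]
    J = ii[None, :]

    def xlog2(p):
        out = np.zeros_like(p)
        pos = p > 0
        out[pos] = p[pos] * np.log2(p[pos])
        return out

    px = P.sum(axis=2)  # (N, L)
    py = P.sum(axis=1)
    mux = (px * ii).sum(axis=1)
    muy = (py * ii).sum(axis=1)
    sx = np.sqrt(np.maximum((px * ii**2).sum(axis=1) - mux**2, 0.0))
    sy = np.sqrt(np.maximum((py * ii**2).sum(axis=1) - muy**2, 0.0))

    energy = (P**2).sum(axis=(1, 2))
    contrast = (P * (I - J) ** 2).sum(axis=(1, 2))
    cov = (P * I * J).sum(axis=(1, 2)) - mux * muy
    denom = sx * sy
    correlation = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    variance = (P * (I - mux[:, None, None]) ** 2).sum(axis=(1, 2))
    idm = (P / (1.0 + (I - J) ** 2)).sum(axis=(1, 2))

    # sum (i+j) and difference |i-j| distributions
    pxy_sum = np.zeros((N, 2 * L - 1))  # index k-2, k = 2..2L
    for k in range(2, 2 * L + 1):
        lo = max(1, k - L)
        hi = min(L, k - 1)
        i_idx = np.arange(lo, hi + 1) - 1
        j_idx = (k - np.arange(lo, hi + 1)) - 1
        pxy_sum[:, k - 2] = P[:, i_idx, j_idx].sum(axis=1)
    pxy_diff = np.zeros((N, L))  # index d = 0..L-1
    for d in range(L):
        tr = np.trace(P, offset=d, axis1=1, axis2=2)
        if d > 0:
            tr = tr + np.trace(P, offset=-d, axis1=1, axis2=2)
        pxy_diff[:, d] = tr

    ksum = np.arange(2, 2 * L + 1, dtype=float)
    sum_average = (pxy_sum * ksum).sum(axis=1)
    sum_variance = (pxy_sum * (ksum - sum_average[:, None]) ** 2).sum(axis=1)
    sum_entropy = -xlog2(pxy_sum).sum(axis=1)
    entropy = -xlog2(P).sum(axis=(1, 2))
    kdiff = np.arange(L, dtype=float)
    mud = (pxy_diff * kdiff).sum(axis=1)
    difference_variance = (pxy_diff * (kdiff - mud[:, None]) ** 2).sum(axis=1)
    difference_entropy = -xlog2(pxy_diff).sum(axis=1)

    outer = px[:, :, None] * py[:, None, :]
    log_outer = np.zeros_like(outer)
    pos = outer > 0
    log_outer[pos] = np.log2(outer[pos])
    hxy1 = -(P * log_outer).sum(axis=(1, 2))
    hxy2 = -(outer * log_outer).sum(axis=(1, 2))
    hx = -xlog2(px).sum(axis=1)
    hy = -xlog2(py).sum(axis=1)
    hmax = np.maximum(hx, hy)
    imc1 = np.where(hmax > 0, (entropy - hxy1) / np.where(hmax > 0, hmax, 1.0), 0.0)
    imc2 = np.sqrt(np.maximum(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy))))

    return np.stack(
        [energy, contrast, correlation, variance, idm, sum_average, sum_variance,
         sum_entropy, entropy, difference_variance, difference_entropy, imc1, imc2],
        axis=1,
    )


def haralick_stats(glcm: np.ndarray) -> np.ndarray:
    """The classic 13 Haralick statistics of one normalized GLCM (log base 2)."""

    glcm = np.asarray(glcm, dtype=float)
    if glcm.ndim != 2 or glcm.shape[0] != glcm.shape[1]:
        raise ValueError("GLCM must be square")
    if not np.isclose(glcm.sum(), 1.0, atol=1e-8):
        raise ValueError("GLCM must be normalized to sum 1")
    return _haralick_batch(glcm[None])[0]


# ---------------------------------------------------------------------------
# sliding-window co-occurrence maps (shared by Haralick and CoLlAGe)


def _pair_indices(w: tuple[int, int, int], offsets) -> tuple[np.ndarray, np.ndarray]:
    """Flat (source, target) index pairs inside a patch for all offsets."""

    a_all, b_all = [], []
    idx = np.arange(int(np.prod(w))).reshape(w)
    for dx, dy, dz in offsets:
        xs = slice(max(0, -dx), min(w[0], w[0] - dx))
        ys = slice(max(0, -dy), min(w[1], w[1] - dy))
        zs = slice(max(0, -dz), min(w[2], w[2] - dz))
        a = idx[xs, ys, zs]
        b = idx[
            slice(xs.start + dx, xs.stop + dx),
            slice(ys.start + dy, ys.stop + dy),
            slice(zs.start + dz, zs.stop + dz),
        ]
        a_all.append(a.ravel())
        b_all.append(b.ravel())
    return np.concatenate(a_all), np.concatenate(b_all)


def _cooccurrence_stat_maps(
    q: np.ndarray,
    mask: np.ndarray,
    levels: int,
    window: int,
    mode: str,
    chunk: int = 512,
) -> np.ndarray:
    """Per-voxel Haralick statistics of windowed co-occurrence matrices.

    ``q``: integer label volume (0 = ignore).  Returns (13, *q.shape) with
    zeros outside the mask.  Edge-replication padding; windows are cubes in
    3D and in-plane squares in 2D.
    """

    r = window // 2
    wz = 1 if mode == "2D" else window
    rz = 0 if mode == "2D" else r
    offsets = OFFSETS_2D if mode == "2D" else OFFSETS_3D
    qpad = np.pad(q, ((r, r), (r, r), (rz, rz)), mode="edge")
    view = sliding_window_view(qpad, (window, window, wz))
    a_idx, b_idx = _pair_indices((window, window, wz), offsets)

    voxels = np.argwhere(mask)
    out = np.zeros((13, *q.shape))
    L2 = levels * levels
    for start in range(0, len(voxels), chunk):
        vx = voxels[start:start + chunk]
        patches = view[vx[:, 0], vx[:, 1], vx[:, 2]].reshape(len(vx), -1)
        la = patches[:, a_idx]
        lb = patches[:, b_idx]
        valid = (la > 0) & (lb > 0)
        code = np.where(valid, (la - 1) * levels + (lb - 1), L2)
        code = code + (np.arange(len(vx)) * (L2 + 1))[:, None]
        counts = np.bincount(code.ravel(), minlength=len(vx) * (L2 + 1))
        counts = counts.reshape(len(vx), L2 + 1)[:, :L2].astype(float)
        P = counts.reshape(len(vx), levels, levels)
        P = P + np.transpose(P, (0, 2, 1))
        tot = P.sum(axis=(1, 2))
        empty = tot == 0
        if empty.any():  # no valid pair: degenerate single-entry matrix
            P[empty, 0, 0] = 1.0
            tot = P.sum(axis=(1, 2))
        P /= tot[:, None, None]
        stats = _haralick_batch(P)  # (n, 13)
        out[:, vx[:, 0], vx[:, 1], vx[:, 2]] = stats.T
    return out


def compute_haralick_maps(
    vol,
    mask=None,
    windows: tuple[int, ...] = (3, 5, 7),
    levels_list: tuple[int, ...] = (4, 8, 16, 32, 64),
    mode: str = "3D",
) -> dict[str, np.ndarray]:
    """Sliding-window GLCM statistic maps for every (window, levels) pair.

    Map count = len(windows) * len(levels_list) * 13.  Quantization is over
    the pooled ROI; 2D mode slides in-plane windows with the 4 symmetric
    in-plane offsets, 3D mode cubic windows with the 13 directions.
    """

    data = _as_array(vol)
    m = _as_mask(mask, data.shape)
    mode = mode.upper()
    if any(w > min(data.shape[:2]) for w in windows):
        raise ValueError("window larger than volume")
    maps: dict[str, np.ndarray] = {}
    for L in levels_list:
        q = quantize_roi(data, m, L)
        for w in windows:
            stack = _cooccurrence_stat_maps(q, m, L, w, mode)
            for s, name in enumerate(HARALICK_NAMES):
                maps[f"{name}_w{w}_g{L}"] = stack[s]
    return maps


# ---------------------------------------------------------------------------
# CoLlAGe


def _dominant_orientation_2d(gx: np.ndarray, gy: np.ndarray, window: int):
    """Principal gradient orientation per pixel from the windowed gradient
    second-moment matrix; returns angle in [0, pi) and a validity mask."""

    size = (window, window, 1)
    jxx = ndimage.uniform_filter(gx * gx, size=size, mode="nearest")
    jyy = ndimage.uniform_filter(gy * gy, size=size, mode="nearest")
    jxy = ndimage.uniform_filter(gx * gy, size=size, mode="nearest")
    theta = 0.5 * np.arctan2(2.0 * jxy, jxx - jyy)
    theta = np.mod(theta, np.pi)
    ok = (jxx + jyy) > 1e-12
    return theta, ok


def compute_collage_maps(
    vol,
    mask=None,
    window: int = 5,
    bins: int = 64,
    mode: str = "3D",
    stats: tuple[str, ...] = ("entropy",),
) -> dict[str, np.ndarray]:
    """Co-occurrence of local anisotropic gradient orientations.

    Per voxel: (1) intensity gradients, (2) dominant local orientation from
    the principal direction of the windowed gradient vectors, (3) angles
    quantized into ``bins`` bins (zero-gradient voxels take a reserved
    bin), (4) co-occurrence of quantized orientations in the window,
    (5) Haralick statistics of that matrix.  3D volumes yield separate maps
    for the azimuth (theta) and polar (phi) angles.
    """

    data = _as_array(vol)
    m = _as_mask(mask, data.shape)
    mode = mode.upper()
    stat_idx = {s: HARALICK_NAMES.index(s) for s in stats}
    maps: dict[str, np.ndarray] = {}

    if mode == "2D":
        gx, gy = np.gradient(data, axis=0), np.gradient(data, axis=1)
        theta, ok = _dominant_orientation_2d(gx, gy, window)
        labels = np.ones(data.shape, dtype=np.int32)  # reserved bin = 1
        binned = np.clip((theta / np.pi * bins).astype(np.int32), 0, bins - 1)
        labels[ok] = binned[ok] + 2
        stack = _cooccurrence_stat_maps(labels, m, bins + 1, window, "2D")
        for s, k in stat_idx.items():
            maps[f"theta_{s}"] = stack[k]
        return maps

    gx = np.gradient(data, axis=0)
    gy = np.gradient(data, axis=1)
    gz = np.gradient(data, axis=2)
    size = (window, window, window)
    J = np.empty((*data.shape, 3, 3))
    comps = {(0, 0): gx * gx, (0, 1): gx * gy, (0, 2): gx * gz,
             (1, 1): gy * gy, (1, 2): gy * gz, (2, 2): gz * gz}
    for (i, j), prod in comps.items():
        f = ndimage.uniform_filter(prod, size=size, mode="nearest")
        J[..., i, j] = f
        J[..., j, i] = f
    trace = J[..., 0, 0] + J[..., 1, 1] + J[..., 2, 2]
    ok = trace > 1e-12
    # principal eigenvector only where needed (mask dilated by the window)
    need = ndimage.binary_dilation(m, iterations=window // 2)
    vecs = np.zeros((*data.shape, 3))
    vecs[..., 2] = 1.0
    sel = need & ok
    if sel.any():
        _, ev = np.linalg.eigh(J[sel])
        v = ev[:, :, 2]  # largest eigenvalue
        flip = v[:, 2] < 0
        v[flip] *= -1.0  # orientation: pick the z >= 0 hemisphere
        vecs[sel] = v
    theta = np.mod(np.arctan2(vecs[..., 1], vecs[..., 0]), np.pi)
    phi = np.arccos(np.clip(vecs[..., 2], -1.0, 1.0))  # in [0, pi/2]

    for angle, arr, span in (("theta", theta, np.pi), ("phi", phi, np.pi / 2)):
        labels = np.ones(data.shape, dtype=np.int32)
        binned = np.clip((arr / span * bins).astype(np.int32), 0, bins - 1)
        labels[ok] = binned[ok] + 2
        stack = _cooccurrence_stat_maps(labels, m, bins + 1, window, "3D")
        for s, k in stat_idx.items():
            maps[f"{angle}_{s}"] = stack[k]
    return maps


# ---------------------------------------------------------------------------
# convolutional families


def compute_laws_maps(vol, mode: str = "3D") -> dict[str, np.ndarray]:
    """Texture-energy magnitude maps from separable Laws 5-tap masks.

    2D mode: 25 in-plane outer products; 3D mode: 125 triple products.
    Edge-replication boundary handling; the absolute response is emitted.
    """

    data = _as_array(vol)
    mode = mode.upper()
    names = sorted(LAWS_KERNELS)
    maps: dict[str, np.ndarray] = {}
    if mode == "2D":
        for a, b in itertools.product(names, names):
            out = ndimage.correlate1d(data, LAWS_KERNELS[a], axis=0, mode="nearest")
            out = ndimage.correlate1d(out, LAWS_KERNELS[b], axis=1, mode="nearest")
            maps[f"{a}{b}"] = np.abs(out)
    else:
        for a, b, c in itertools.product(names, names, names):
            out = ndimage.correlate1d(data, LAWS_KERNELS[a], axis=0, mode="nearest")
            out = ndimage.correlate1d(out, LAWS_KERNELS[b], axis=1, mode="nearest")
            out = ndimage.correlate1d(out, LAWS_KERNELS[c], axis=2, mode="nearest")
            maps[f"{a}{b}{c}"] = np.abs(out)
    return maps


_SOBEL_D = np.array([-1.0, 0.0, 1.0])
_SOBEL_S = np.array([1.0, 2.0, 1.0])


def _sobel_2d(data: np.ndarray, axis: int) -> np.ndarray:
    """In-plane Sobel (derivative along axis, smoothing along the other
    in-plane axis only — no cross-slice coupling)."""

    other = 1 - axis
    out = ndimage.correlate1d(data, _SOBEL_D, axis=axis, mode="nearest")
    return ndimage.correlate1d(out, _SOBEL_S, axis=other, mode="nearest")


def compute_gradient_maps(vol, mode: str = "3D") -> dict[str, np.ndarray]:
    """Sobel per-axis responses, Sobel magnitude, and finite-difference
    gradient magnitude."""

    data = _as_array(vol)
    mode = mode.upper()
    maps: dict[str, np.ndarray] = {}
    if mode == "2D":
        sx, sy = _sobel_2d(data, 0), _sobel_2d(data, 1)
        maps["sobel_x"], maps["sobel_y"] = sx, sy
        maps["sobel_magnitude"] = np.sqrt(sx**2 + sy**2)
        gx, gy = np.gradient(data, axis=0), np.gradient(data, axis=1)
        maps["fd_magnitude"] = np.sqrt(gx**2 + gy**2)
    else:
        sob = [ndimage.sobel(data, axis=a, mode="nearest") for a in range(3)]
        for a, name in enumerate(("sobel_x", "sobel_y", "sobel_z")):
            maps[name] = sob[a]
        maps["sobel_magnitude"] = np.sqrt(sum(s**2 for s in sob))
        g = np.gradient(data)
        maps["fd_magnitude"] = np.sqrt(sum(gi**2 for gi in g))
    return maps


def compute_gray_maps(vol, window: int = 3, mode: str = "3D") -> dict[str, np.ndarray]:
    """Sliding-window median, mean, standard deviation, and range maps."""

    data = _as_array(vol)
    size = (window, window, 1 if mode.upper() == "2D" else window)
    mean = ndimage.uniform_filter(data, size=size, mode="nearest")
    sq = ndimage.uniform_filter(data**2, size=size, mode="nearest")
    return {
        "median": ndimage.median_filter(data, size=size, mode="nearest"),
        "mean": mean,
        "std": np.sqrt(np.maximum(sq - mean**2, 0.0)),
        "range": ndimage.maximum_filter(data, size=size, mode="nearest")
        - ndimage.minimum_filter(data, size=size, mode="nearest"),
    }


# ---------------------------------------------------------------------------
# aggregation and orchestration


def aggregate_map(map_values: np.ndarray, mask) -> tuple[float, float, float, float]:
    """(median, std, skewness, kurtosis) over in-mask voxels.

    Fisher (excess) kurtosis, bias-uncorrected moments; a constant map
    yields skewness = kurtosis = 0 rather than NaN.
    """

    m = _as_mask(mask, np.asarray(map_values).shape)
    if not m.any():
        raise ValueError("empty mask")
    v = np.asarray(map_values, dtype=float)[m]
    med = float(np.median(v))
    mu = v.mean()
    m2 = ((v - mu) ** 2).mean()
    std = float(np.sqrt(m2))
    if m2 < 1e-300:
        return med, 0.0, 0.0, 0.0
    m3 = ((v - mu) ** 3).mean()
    m4 = ((v - mu) ** 4).mean()
    skew = float(m3 / m2**1.5)
    kurt = float(m4 / m2**2 - 3.0)
    return med, std, skew, kurt


def extract_features(
    vol,
    mask,
    mode: str = "3D",
    config: FeatureConfig | None = None,
) -> tuple[np.ndarray, list[FeatureSpec]]:
    """Extract the configured feature vector for one subject.

    2D mode computes every map slice-wise (in-plane kernels/windows) and
    aggregates over the pooled in-mask pixels of all slices.  The returned
    order matches :meth:`FeatureConfig.expand_specs` exactly.
    """

    config = config or FeatureConfig()
    mode = mode.upper()
    data = _as_array(vol)
    m = _as_mask(mask, data.shape)
    if not m.any():
        raise ValueError("empty mask")

    maps: dict[tuple[str, str], np.ndarray] = {}
    for fam in config.families:
        if fam == "Raw":
            maps[("Raw", "intensity")] = data
        elif fam == "Gray":
            for k, v in compute_gray_maps(data, config.gray_window, mode).items():
                maps[("Gray", k)] = v
        elif fam == "Gradient":
            for k, v in compute_gradient_maps(data, mode).items():
                maps[("Gradient", k)] = v
        elif fam == "Laws":
            for k, v in compute_laws_maps(data, mode).items():
                maps[("Laws", k)] = v
        elif fam == "Haralick":
            har = compute_haralick_maps(
                data, m, config.haralick_windows, config.gray_levels, mode
            )
            for k, v in har.items():
                name, rest = k.split("_w")
                w, g = rest.split("_g")
                maps[("Haralick", name, int(w), int(g))] = v
        elif fam == "CoLlAGe":
            col = compute_collage_maps(
                data, m, config.collage_window, config.collage_bins, mode,
                config.collage_stats,
            )
            for k, v in col.items():
                maps[("CoLlAGe", k)] = v

    agg_cache: dict[tuple, tuple[float, float, float, float]] = {}
    stat_pos = {"median": 0, "std": 1, "skewness": 2, "kurtosis": 3}
    row = []
    specs = config.expand_specs(mode)
    for spec in specs:
        if spec.family == "Haralick":
            key = ("Haralick", spec.filter_name, spec.window, spec.gray_levels)
        else:
            key = (spec.family, spec.filter_name)
        if key not in agg_cache:
            agg_cache[key] = aggregate_map(maps[key], m)
        row.append(agg_cache[key][stat_pos[spec.statistic]])
    vec = np.asarray(row, dtype=float)
    if not np.all(np.isfinite(vec)):
        raise RuntimeError("non-finite feature value extracted")
    return vec, specs


def extract_cohort_features(
    cohort,
    mode: str = "3D",
    config: FeatureConfig | None = None,
    preprocess_fn=None,
) -> tuple[pd.DataFrame, list[FeatureSpec]]:
    """Feature table (subjects x features) for a cohort.

    ``preprocess_fn(vol, mask) -> (vol, mask)`` is applied per subject
    before extraction (identity if None); preprocessing is strictly
    per-subject, so the table is reusable across leave-center-out trials
    without leakage.
    """

    config = config or FeatureConfig()
    rows, ids = [], []
    specs: list[FeatureSpec] = []
    for s in cohort.subjects:
        vol = cohort.volumes[s.subject_id]
        msk = cohort.cyst_masks[s.subject_id]
        if preprocess_fn is not None:
            vol, msk = preprocess_fn(vol, msk)
        vec, specs = extract_features(vol, msk, mode, config)
        rows.append(vec)
        ids.append(s.subject_id)
    df = pd.DataFrame(np.vstack(rows), index=ids, columns=[sp.name for sp in specs])
    return df, specs
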