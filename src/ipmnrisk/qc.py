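"""Scan-level image-quality indicators, normalization, and 2D embedding.

A fixed, ordered vector of 21 quality indicators per scan — foreground
intensity statistics (mean, range, variance, ...), contrast per pixel,
the entropy focus criterion, foreground-background energy ratio, and
signal-/contrast-to-noise ratios — mirroring the indicator families of
published MRI quality-control tooling.  The foreground/background
partition is an Otsu intensity threshold unless a mask is supplied.
Indicator matrices can be normalized (z-score, min-max, whitening) and
projected to 2D (UMAP by default, PCA as the pluggable alternative) to
visualize center-driven batch structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import kurtosis, skew
from skimage.filters import threshold_otsu

from .grids import VolumeGrid

__all__ = [
    "INDICATOR_NAMES",
    "QCVector",
    "compute_quality_indicators",
    "normalize_indicator_matrix",
    "embed_2d",
]

INDICATOR_NAMES = (
    "fg_mean", "fg_median", "fg_range", "fg_variance", "fg_std", "fg_cv",
    "fg_skewness", "fg_kurtosis", "fg_entropy", "fg_iqr",
    "cpp", "efc", "fber",
    "snr1", "snr2", "snr3", "snr4", "cnr", "cjv", "psnr", "bg_mean",
)


@dataclass
class QCVector:
    values: pd.Series
    nan_reasons: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.values.index) != INDICATOR_NAMES:
            raise ValueError("indicator order must match INDICATOR_NAMES")


def _entropy_of(values: np.ndarray, bins: int = 256) -> float:
    h, _ = np.histogram(values, bins=bins)
    p = h[h > 0] / h.sum()
    return float(-(p * np.log2(p)).sum())


def compute_quality_indicators(
    vol: VolumeGrid, fg_mask: np.ndarray | None = None
) -> QCVector:
    """The 21-indicator quality vector for one scan.

    Background-dependent indicators are NaN (with a recorded reason) when
    the background partition is empty.
    """

    data = vol.data if isinstance(vol, VolumeGrid) else np.asarray(vol, float)
    if fg_mask is None:
        try:
            thr = threshold_otsu(data)
            fg = data > thr
        except ValueError:  # constant image
            fg = np.ones_like(data, dtype=bool)
    else:
        fg = np.asarray(fg_mask).astype(bool)
    if not fg.any():
        raise ValueError("empty foreground")
    bg = ~fg

    f = data[fg]
    vals: dict[str, float] = {}
    reasons: dict[str, str] = {}
    f_mean, f_std = float(f.mean()), float(f.std())
    vals["fg_mean"] = f_mean
    vals["fg_median"] = float(np.median(f))
    vals["fg_range"] = float(f.max() - f.min())
    vals["fg_variance"] = f_std**2
    vals["fg_std"] = f_std
    vals["fg_cv"] = f_std / f_mean if f_mean != 0 else float("nan")
    vals["fg_skewness"] = float(skew(f)) if f_std > 0 else 0.0
    vals["fg_kurtosis"] = float(kurtosis(f)) if f_std > 0 else 0.0
    vals["fg_entropy"] = _entropy_of(f) if f_std > 0 else 0.0
    q75, q25 = np.percentile(f, [75, 25])
    vals["fg_iqr"] = float(q75 - q25)

    # contrast per pixel: mean |voxel - mean of its neighborhood| on the fg
    local_mean = ndimage.uniform_filter(data, size=3, mode="nearest")
    vals["cpp"] = float(np.abs(data - local_mean)[fg].mean())

    # entropy focus criterion on the whole volume (scale-invariant)
    energy = np.sqrt((data.astype(float) ** 2).sum())
    if energy > 0:
        x = np.abs(data) / energy
        pos = x > 0
        vals["efc"] = float(-(x[pos] * np.log(x[pos])).sum())
    else:
        vals["efc"] = 0.0

    med = ndimage.median_filter(data, size=3, mode="nearest")
    mse = float(((data - med) ** 2).mean())
    peak = float(np.abs(data).max())
    vals["psnr"] = float(10 * np.log10(peak**2 / mse)) if mse > 0 and peak > 0 \
        else float("inf") if peak > 0 else 0.0
    if not np.isfinite(vals["psnr"]):
        vals["psnr"] = float("nan")
        reasons["psnr"] = "zero residual against median filter"

    vals["snr3"] = f_mean / f_std if f_std > 0 else float("nan")
    if f_std == 0:
        reasons["snr3"] = "constant foreground"

    if bg.any():
        b = data[bg]
        b_mean, b_std = float(b.mean()), float(b.std())
        b_med_sq = float(np.median(b.astype(float) ** 2))
        vals["fber"] = float(np.median(f.astype(float) ** 2) / b_med_sq) \
            if b_med_sq > 0 else float("nan")
        if b_med_sq <= 0:
            reasons["fber"] = "zero background energy"
        for name, num in (("snr1", f_mean), ("snr2", float(np.median(f))),
                          ("snr4", f_std), ("cnr", f_mean - b_mean)):
            vals[name] = num / b_std if b_std > 0 else float("nan")
            if b_std == 0:
                reasons[name] = "zero background variance"
        diff = abs(f_mean - b_mean)
        vals["cjv"] = (f_std + b_std) / diff if diff > 0 else float("nan")
        if diff == 0:
            reasons["cjv"] = "equal foreground/background means"
        vals["bg_mean"] = b_mean
    else:
        for name in ("fber", "snr1", "snr2", "snr4", "cnr", "cjv", "bg_mean"):
            vals[name] = float("nan")
            reasons[name] = "empty background"

    series = pd.Series([vals[n] for n in INDICATOR_NAMES], index=list(INDICATOR_NAMES))
    return QCVector(series, reasons)


def normalize_indicator_matrix(matrix, method: str = "zscore") -> np.ndarray:
    """Column-wise normalization: zscore, minmax, or whitening (ZCA)."""

    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 scans")
    const = X.std(axis=0) == 0
    if method == "zscore":
        if const.any():
            raise ValueError("constant column: z-score undefined")
        return (X - X.mean(axis=0)) / X.std(axis=0)
    if method == "minmax":
        rng = X.max(axis=0) - X.min(axis=0)
        out = np.zeros_like(X)
        ok = rng > 0
        out[:, ok] = (X[:, ok] - X.min(axis=0)[ok]) / rng[ok]
        return out
    if method == "whiten":
        if const.any():
            raise ValueError("constant column: whitening is singular")
        Xc = X - X.mean(axis=0)
        cov = np.cov(Xc, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        if evals.min() <= 1e-12:
            raise ValueError("singular covariance: whitening undefined")
        W = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T
        return Xc @ W
    raise ValueError(f"unknown normalization method {method!r}")


def embed_2d(
    matrix, seed: int = 0, method: str = "umap", n_neighbors: int = 15
) -> np.ndarray:
    """Deterministic 2D embedding of the (scans x indicators) matrix.

    The algorithm is pluggable: manifold projection (``umap``) or
    principal components (``pca``).
    """

    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 scans to embed")
    if method == "umap":
        if X.shape[0] <= n_neighbors:
            raise ValueError(
                f"{X.shape[0]} rows but n_neighbors={n_neighbors}: too few scans"
            )
        import umap

        reducer = umap.UMAP(
            n_components=2, n_neighbors=n_neighbors, random_state=seed, n_jobs=1
        )
        return np.asarray(reducer.fit_transform(X), dtype=float)
    if method == "pca":
        from sklearn.decomposition import PCA

        return PCA(n_components=2, random_state=seed).fit_transform(X)
    raise ValueError(f"unknown embedding method {method!r}")
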