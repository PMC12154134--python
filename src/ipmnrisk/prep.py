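"""Preprocessing chain: isotropic resampling, bias-field correction,
min-max normalization, and ROI crop/resize for the CNN stage.

Pipeline order is fixed: resample -> bias-correct -> normalize.  Bias
correction is a pluggable contract — either a fitted smooth-field surrogate
(log-domain least-squares polynomial, default, fully deterministic) or
SimpleITK's N4 routine (``method="n4"``).  Both divide the input by a
strictly positive low-frequency field estimate and preserve the mean
foreground intensity up to a global scale.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grids import MaskVolume, VolumeGrid

__all__ = [
    "resample_isotropic",
    "correct_bias_field",
    "normalize_minmax",
    "crop_resize_roi",
    "preprocess",
]


def _zoom_to_shape(data: np.ndarray, out_shape: tuple[int, ...], order: int) -> np.ndarray:
    factors = [o / s for o, s in zip(out_shape, data.shape)]
    out = ndimage.zoom(data, factors, order=order, mode="nearest", grid_mode=True)
    # grid_mode zoom can be off by one voxel for awkward factors; pad/crop
    slices = tuple(slice(0, n) for n in out_shape)
    if out.shape != tuple(out_shape):
        pad = [(0, max(0, n - s)) for n, s in zip(out_shape, out.shape)]
        out = np.pad(out, pad, mode="edge")[slices]
    return out


def resample_isotropic(
    vol: VolumeGrid,
    mask: MaskVolume | None = None,
    target_mm: float = 1.0,
    mode: str = "3D",
) -> tuple[VolumeGrid, MaskVolume | None]:
    """Resample to isotropic ``target_mm`` spacing (3D) or in-plane only (2D).

    Intensities are linearly interpolated; the mask is resampled
    nearest-neighbor and re-binarized.  In 2D mode the slice spacing is
    preserved, matching per-slice (axial) analysis.
    """

    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    if mode not in ("3D", "2D", "3d", "2d"):
        raise ValueError(f"mode must be 3D or 2D, got {mode!r}")
    if any(n < 2 for n in vol.shape):
        raise ValueError(f"degenerate volume shape {vol.shape}: single-voxel axis")
    three_d = mode.upper() == "3D"
    sx, sy, sz = vol.spacing
    if three_d:
        new_spacing = (target_mm, target_mm, target_mm)
    else:
        new_spacing = (target_mm, target_mm, sz)
    out_shape = tuple(
        max(1, int(round(n * s / t)))
        for n, s, t in zip(vol.shape, vol.spacing, new_spacing)
    )
    if vol.shape == out_shape and vol.spacing == new_spacing:
        return vol.copy(), None if mask is None else mask.copy()
    data = _zoom_to_shape(vol.data, out_shape, order=1)
    out_vol = VolumeGrid(data, new_spacing)
    out_mask = None
    if mask is not None:
        mvals = _zoom_to_shape(mask.values.astype(float), out_shape, order=0)
        out_mask = MaskVolume((mvals > 0.5).astype(np.uint8), new_spacing)
    return out_vol, out_mask


def _fit_log_poly_field(
    data: np.ndarray, fg: np.ndarray, order: int = 3
) -> np.ndarray:
    """Least-squares order-``order`` polynomial fit to log intensities on the
    foreground, evaluated everywhere; returns the positive field exp(fit)."""

    eps = 1e-6 * max(float(data[fg].mean()), 1e-12)
    logv = np.log(np.maximum(data, eps))
    coords = [np.linspace(-1.0, 1.0, n) for n in data.shape]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij")
    cols = [np.ones_like(gx)]
    for total in range(1, order + 1):
        for i in range(total + 1):
            for j in range(total + 1 - i):
                k = total - i - j
                cols.append(gx ** i * gy ** j * gz ** k)
    A = np.stack([c[fg] for c in cols], axis=1)
    beta, *_ = np.linalg.lstsq(A, logv[fg], rcond=None)
    field = np.zeros_like(gx)
    for b, c in zip(beta, cols):
        field += b * c
    return np.exp(field)


def correct_bias_field(
    vol: VolumeGrid,
    mask: MaskVolume | None = None,
    method: str = "poly",
    order: int = 3,
) -> VolumeGrid:
    """Remove low-frequency multiplicative shading.

    ``method="poly"`` fits a log-domain polynomial (default order 3) to the
    foreground and divides by its exponential; ``method="n4"`` delegates to
    SimpleITK's N4 implementation.  Either way, the output is the input
    divided by a strictly positive smooth field, rescaled so the mean
    foreground intensity is preserved.
    """

    data = vol.data
    if not np.any(data != 0):
        raise ValueError("all-zero volume: nothing to correct")
    if mask is not None:
        fg = mask.as_bool()
        if not fg.any():
            raise ValueError("empty foreground mask")
    else:
        fg = data > data.mean()  # crude intensity split; adequate for shading fit
        if not fg.any():
            fg = np.ones_like(data, dtype=bool)

    if method == "poly":
        field = _fit_log_poly_field(data, fg, order=order)
        out = data / field
    elif method == "n4":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(data.T))
        img.SetSpacing(vol.spacing)
        msk = sitk.GetImageFromArray(np.ascontiguousarray(fg.T.astype(np.uint8)))
        msk.SetSpacing(vol.spacing)
        corrected = sitk.N4BiasFieldCorrection(sitk.Cast(img, sitk.sitkFloat32), msk)
        out = sitk.GetArrayFromImage(corrected).T.astype(np.float64)
    else:
        raise ValueError(f"unknown bias-correction method {method!r}")

    # preserve mean foreground intensity up to a global scale
    m_in, m_out = float(data[fg].mean()), float(out[fg].mean())
    if m_out > 0:
        out = out * (m_in / m_out)
    if not np.all(np.isfinite(out)):
        raise RuntimeError("bias correction produced non-finite values")
    return VolumeGrid(out, vol.spacing)


def normalize_minmax(
    vol: VolumeGrid,
    region: MaskVolume | None = None,
    subject_id: str | None = None,
) -> VolumeGrid:
    """Min-max normalize to [0, 1] over the stated region (default: whole volume)."""

    data = vol.data
    sel = data if region is None else data[region.as_bool()]
    lo, hi = float(sel.min()), float(sel.max())
    if hi <= lo:
        who = f" for subject {subject_id}" if subject_id else ""
        raise ValueError(f"constant region{who}: min-max normalization undefined")
    return VolumeGrid(np.clip((data - lo) / (hi - lo), 0.0, 1.0), vol.spacing)


def crop_resize_roi(
    vol: VolumeGrid,
    mask: MaskVolume,
    margin_voxels: int = 4,
    out_shape: tuple[int, int, int] = (96, 96, 96),
) -> VolumeGrid:
    """Crop the mask's bounding box (expanded by ``margin_voxels``, clipped to
    the volume) and linearly resize to ``out_shape``.

    Default output is 96x96x96; desk-scale experiments use 32x32x32.
    Crop intervals are 0-based half-open voxel indices.
    """

    m = mask.as_bool()
    if not m.any():
        raise ValueError("empty mask: nothing to crop")
    idx = np.argwhere(m)
    lo = np.maximum(idx.min(axis=0) - margin_voxels, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + margin_voxels, vol.shape)
    sub = vol.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    data = _zoom_to_shape(sub, tuple(out_shape), order=1)
    return VolumeGrid(data, (1.0, 1.0, 1.0))


def preprocess(
    vol: VolumeGrid,
    mask: MaskVolume,
    mode: str = "3D",
    target_mm: float = 1.0,
    bias_method: str = "poly",
    normalize_region: str = "volume",
) -> tuple[VolumeGrid, MaskVolume]:
    """Full chain in the fixed order resample -> bias-correct -> normalize."""

    rvol, rmask = resample_isotropic(vol, mask, target_mm=target_mm, mode=mode)
    cvol = correct_bias_field(rvol, method=bias_method)
    region = rmask if normalize_region == "roi" else None
    nvol = normalize_minmax(cvol, region=region)
    return nvol, rmask
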