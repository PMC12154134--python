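"""Segmentation-agreement metrics and rater statistics.

Segmentation: Dice similarity coefficient and the 95th-percentile
symmetric surface distance (HD95, in mm).  Rater statistics over ordinal
{no, low, high} scores against binary reference labels: per-rater and
majority-vote sensitivity/specificity/accuracy, pairwise weighted Cohen's
kappa (linear disagreement weights by default), and Cochran's Q for
heterogeneity of matched binary calls.

Binarization convention: positive = "high" only ("no" and "low" are both
negative), configurable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import chi2

from .grids import MaskVolume

logger = logging.getLogger(__name__)

__all__ = [
    "dice_coefficient",
    "hausdorff95",
    "weighted_kappa",
    "rater_metrics",
    "cochran_q",
]

LEVEL_ORDER = {"no": 0, "low": 1, "high": 2}


def _check_same_grid(A: MaskVolume, B: MaskVolume) -> None:
    if A.shape != B.shape:
        raise ValueError(f"grid mismatch: shapes {A.shape} vs {B.shape}")
    if not np.allclose(A.spacing, B.spacing):
        raise ValueError(f"grid mismatch: spacings {A.spacing} vs {B.spacing}")


def dice_coefficient(A: MaskVolume, B: MaskVolume) -> float:
    """2|A n B| / (|A| + |B|); two empty masks 1.0, one empty 0.0."""

    _check_same_grid(A, B)
    a, b = A.as_bool(), B.as_bool()
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        logger.warning("both masks empty: Dice defined as 1.0")
        return 1.0
    if na == 0 or nb == 0:
        logger.warning("one mask empty: Dice defined as 0.0")
        return 0.0
    inter = int((a & b).sum())
    return 2.0 * inter / (na + nb)


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


def _boundary_coords(mask: np.ndarray, spacing) -> np.ndarray:
    """Physical (mm) coordinates of boundary voxel centers: mask voxels with
    at least one face-adjacent background neighbor (volume edge counts)."""

    interior = ndimage.binary_erosion(mask, structure=_FACE_STRUCT, border_value=0)
    boundary = mask & ~interior
    return np.argwhere(boundary) * np.asarray(spacing, dtype=float)


def hausdorff95(A: MaskVolume, B: MaskVolume, spacing=None) -> float:
    """95th percentile of the pooled symmetric surface-to-surface nearest
    distances, in mm."""

    _check_same_grid(A, B)
    a, b = A.as_bool(), B.as_bool()
    if not a.any() or not b.any():
        raise ValueError("HD95 undefined for an empty mask")
    sp = A.spacing if spacing is None else spacing
    ca, cb = _boundary_coords(a, sp), _boundary_coords(b, sp)
    d_ab = cKDTree(cb).query(ca)[0]
    d_ba = cKDTree(ca).query(cb)[0]
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


def _to_ordinal(scores) -> np.ndarray:
    arr = np.asarray(scores)
    if arr.dtype.kind in "iu":
        return arr.astype(int)
    return np.array([LEVEL_ORDER[str(s)] for s in arr], dtype=int)


def weighted_kappa(
    scores_r1, scores_r2, weights: str = "linear", n_levels: int = 3
) -> float:
    """Weighted Cohen's kappa over the ordered rating levels.

    kappa = 1 - sum(w * O) / sum(w * E) with disagreement weights
    w_ij = |i - j| (linear) or (i - j)^2 (quadratic).
    """

    a, b = _to_ordinal(scores_r1), _to_ordinal(scores_r2)
    if len(a) != len(b):
        raise ValueError("raters must score the same subjects")
    if len(np.unique(np.concatenate([a, b]))) < 2:
        raise ValueError("need at least 2 observed categories")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("degenerate marginals: one rater is constant")
    L = n_levels
    O = np.zeros((L, L))
    np.add.at(O, (a, b), 1.0)
    O /= O.sum()
    E = np.outer(O.sum(axis=1), O.sum(axis=0))
    d = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :]).astype(float)
    if weights == "quadratic":
        d = d**2
    elif weights != "linear":
        raise ValueError("weights must be 'linear' or 'quadratic'")
    denom = (d * E).sum()
    if denom == 0:
        raise ValueError("degenerate marginals: expected disagreement is zero")
    return float(1.0 - (d * O).sum() / denom)


def _binary_stats(calls: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    tp = int(((calls == 1) & (truth == 1)).sum())
    tn = int(((calls == 0) & (truth == 0)).sum())
    fp = int(((calls == 1) & (truth == 0)).sum())
    fn = int(((calls == 0) & (truth == 1)).sum())
    return {
        "sens": tp / (tp + fn) if tp + fn else float("nan"),
        "spec": tn / (tn + fp) if tn + fp else float("nan"),
        "acc": (tp + tn) / len(truth),
        "n": len(truth),
    }


def rater_metrics(
    ratings: pd.DataFrame,
    positive_levels: tuple[str, ...] = ("high",),
) -> dict:
    """Per-rater and majority sens/spec/acc against binary reference labels.

    ``ratings`` has a ``label`` column (0/1) plus one column per rater with
    {no, low, high} scores.  Majority = the score given by more than half
    of the raters; subjects with no majority score (e.g. three-way
    disagreement among 3 raters) are excluded from the majority row, and
    the excluded count is returned.  Requires >= 3 raters for the majority
    row.
    """

    rater_cols = [c for c in ratings.columns if c != "label"]
    if len(rater_cols) < 3:
        raise ValueError("majority vote needs at least 3 raters")
    clean = ratings.dropna(subset=rater_cols + ["label"])
    if len(clean) < len(ratings):
        logger.warning("excluded %d subject(s) with missing cells",
                       len(ratings) - len(clean))
    truth = clean["label"].astype(int).to_numpy()
    pos = set(positive_levels)
    out: dict = {"per_rater": {}, "n_rated": len(clean)}
    for c in rater_cols:
        calls = clean[c].isin(pos).astype(int).to_numpy()
        out["per_rater"][c] = _binary_stats(calls, truth)

    scores = clean[rater_cols].to_numpy()
    half = len(rater_cols) / 2.0
    maj_scores, keep = [], []
    for row in scores:
        vals, cnts = np.unique(row, return_counts=True)
        if cnts.max() > half:
            maj_scores.append(vals[np.argmax(cnts)])
            keep.append(True)
        else:
            keep.append(False)
    keep = np.asarray(keep)
    out["n_majority_excluded"] = int((~keep).sum())
    maj_calls = np.array([s in pos for s in maj_scores], dtype=int)
    out["majority"] = _binary_stats(maj_calls, truth[keep])
    return out


def cochran_q(calls: np.ndarray) -> tuple[float, float]:
    """Cochran's Q over matched binary calls (subjects x raters).

    Returns (Q, p) with a chi-square reference on raters - 1 degrees of
    freedom; identical calls across raters give Q = 0, p = 1.
    """

    X = np.asarray(calls, dtype=int)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a subjects x raters matrix with >= 2 raters")
    if X.shape[0] < 2:
        raise ValueError("need >= 2 subjects")
    k = X.shape[1]
    col = X.sum(axis=0).astype(float)
    row = X.sum(axis=1).astype(float)
    denom = k * row.sum() - (row**2).sum()
    if denom == 0:
        return 0.0, 1.0
    q = k * (k - 1) * ((col - col.mean()) ** 2).sum() / denom
    return float(q), float(chi2.sf(q, k - 1))
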