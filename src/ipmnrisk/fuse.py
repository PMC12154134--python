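"""Decision-level radiomics-DL probability fusion.

The rule has two hyperparameters, a threshold ``t`` and a weight ``k``,
both in [0, 1]: when the radiomics probability exceeds ``t`` the fused
output is the radiomics probability alone; otherwise it is the blend
``(1 - k) * p_rad + k * p_dl``.  The hyperparameters are chosen by
exhaustive grid search maximizing mean-fold AUC on stratified five-fold
cross-validation, with deterministic tie-breaking (smaller k, then
smaller t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classify import compute_metrics

__all__ = ["FusionParams", "fuse_probabilities", "grid_search_fusion", "DEFAULT_GRID"]

DEFAULT_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))


@dataclass(frozen=True)
class FusionParams:
    t: float
    k: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.t <= 1.0 and 0.0 <= self.k <= 1.0):
            raise ValueError("t and k must lie in [0, 1]")


def fuse_probabilities(p_rad, p_dl, params: FusionParams) -> np.ndarray:
    """Apply the t/k rule elementwise; output stays in [0, 1]."""

    p_rad = np.asarray(p_rad, dtype=float)
    p_dl = np.asarray(p_dl, dtype=float)
    if np.any((p_rad < 0) | (p_rad > 1) | (p_dl < 0) | (p_dl > 1)):
        raise ValueError("input probabilities must lie in [0, 1]")
    blend = (1.0 - params.k) * p_rad + params.k * p_dl
    return np.where(p_rad > params.t, p_rad, blend)


def _mean_fold_auc(p_rad, p_dl, labels, params, folds) -> float:
    fused = fuse_probabilities(p_rad, p_dl, params)
    aucs = [
        compute_metrics(fused[idx], labels[idx]).auc
        for _, idx in folds
        if len(np.unique(labels[idx])) == 2
    ]
    if not aucs:
        raise ValueError("no fold contains both classes")
    return float(np.mean(aucs))


def grid_search_fusion(
    p_rad_cv,
    p_dl_cv,
    labels,
    t_grid=DEFAULT_GRID,
    k_grid=DEFAULT_GRID,
    n_folds: int = 5,
    seed: int = 0,
) -> FusionParams:
    """Exhaustive (t, k) search maximizing mean-fold fused AUC.

    Ties break toward smaller k, then smaller t, so the result is a pure
    function of the inputs.
    """

    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("single-class labels")
    if len(t_grid) == 0 or len(k_grid) == 0:
        raise ValueError("grids must be non-empty")
    p_rad_cv = np.asarray(p_rad_cv, dtype=float)
    p_dl_cv = np.asarray(p_dl_cv, dtype=float)
    skf = StratifiedKFold(n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(p_rad_cv.reshape(-1, 1), labels))

    best: FusionParams | None = None
    best_auc = -np.inf
    for k in sorted(k_grid):
        for t in sorted(t_grid):
            params = FusionParams(float(t), float(k))
            auc = _mean_fold_auc(p_rad_cv, p_dl_cv, labels, params, folds)
            if auc > best_auc + 1e-12:
                best_auc, best = auc, params
    assert best is not None
    return best
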