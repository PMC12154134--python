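"""Stability-based feature selection.

Three stages, applied to training-set subjects only:

1. A greedy Spearman redundancy filter drops one member of every feature
   pair whose |rho| reaches the threshold (default 0.6).
2. mRMR (MID difference form, mutual information on equal-frequency-binned
   features) ranks candidates by relevance to the binary label minus mean
   redundancy to the already-selected set.
3. Stability selection repeats the ranking over reshuffled stratified
   5-fold splits for 50 iterations and retains features recorded in at
   least 70% of the training subsets.

A feature's *selection frequency* is the fraction of all iteration x fold
training subsets whose mRMR top list contained it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionConfig",
    "spearman_redundancy_filter",
    "mutual_information",
    "mrmr_rank",
    "stability_select",
]


@dataclass
class SelectionConfig:
    spearman_threshold: float = 0.6
    n_folds: int = 5
    n_iterations: int = 50
    stability_threshold: float = 0.7
    n_candidates: int | str = 30  # or "auto": per-iteration RF-CV choice
    auto_grid: tuple[int, ...] = (10, 20, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.spearman_threshold <= 1):
            raise ValueError("spearman_threshold must be in (0, 1]")
        if not (0 <= self.stability_threshold <= 1):
            raise ValueError("stability_threshold must be in [0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def spearman_redundancy_filter(
    X: np.ndarray, threshold: float = 0.6
) -> list[int]:
    """Greedy removal of correlated features; returns kept column indices.

    Repeatedly find the pair with the largest |rho| >= threshold and drop
    the member with the larger mean absolute correlation to all remaining
    features (ties broken by column order: the later column is dropped).
    Constant columns have undefined rho and are dropped with a warning.
    """

    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    p = X.shape[1]
    const = X.std(axis=0) == 0
    if const.any():
        logger.warning("dropping %d constant column(s): rho undefined", const.sum())
    alive = [j for j in range(p) if not const[j]]
    if len(alive) < 2:
        return alive
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(X[:, alive]).statistic
    rho = np.abs(np.nan_to_num(np.atleast_2d(rho)))
    if rho.shape != (len(alive), len(alive)):  # scipy collapses the 2-column case
        r = float(rho.ravel()[0])
        rho = np.array([[0.0, r], [r, 0.0]])
    np.fill_diagonal(rho, 0.0)

    active = np.ones(len(rho), dtype=bool)
    while True:
        sub = np.where(active)[0]
        if len(sub) < 2:
            break
        block = rho[np.ix_(sub, sub)]
        mx = block.max()
        if mx < threshold:
            break
        a, b = np.unravel_index(np.argmax(block), block.shape)  # first max in order
        mean_a = block[a].sum() / (len(sub) - 1)
        mean_b = block[b].sum() / (len(sub) - 1)
        # drop the more globally redundant member; tie -> later column
        drop = b if mean_b >= mean_a else a
        active[sub[drop]] = False
    return [alive[i] for i in range(len(alive)) if active[i]]


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, x, side="right")


def _bin_matrix(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    n_bins = min(10, max(2, int(np.ceil(np.sqrt(n)))))
    return np.stack(
        [_equal_frequency_bins(X[:, j], n_bins) for j in range(X.shape[1])], axis=1
    ).astype(np.int64)


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI in bits between two small-alphabet integer sequences."""

    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    ka, kb = a.max() + 1, b.max() + 1
    joint = np.bincount(a * kb + b, minlength=ka * kb).reshape(ka, kb).astype(float)
    joint /= joint.sum()
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    pos = joint > 0
    return float((joint[pos] * np.log2(joint[pos] / (pa[:, None] * pb[None, :])[pos])).sum())


def mrmr_rank(
    X: np.ndarray,
    y: np.ndarray,
    n_select: int,
    _binned: np.ndarray | None = None,
) -> list[int]:
    """Greedy mRMR forward selection (MID: relevance minus mean redundancy).

    Relevance and redundancy are mutual information on equal-frequency
    binned features (ceil(sqrt(n)) bins, capped at 10).  Ties break toward
    the lower column index.
    """

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class y: mRMR relevance undefined")
    p = X.shape[1]
    n_select = min(n_select, p)
    B = _binned if _binned is not None else _bin_matrix(X)
    relevance = np.array([mutual_information(B[:, j], y) for j in range(p)])

    selected: list[int] = []
    remaining = list(range(p))
    red_sum = np.zeros(p)
    red_cache: dict[tuple[int, int], float] = {}
    while len(selected) < n_select and remaining:
        if not selected:
            scores = relevance[remaining]
        else:
            last = selected[-1]
            for j in remaining:
                key = (min(last, j), max(last, j))
                if key not in red_cache:
                    red_cache[key] = mutual_information(B[:, last], B[:, j])
                red_sum[j] += red_cache[key]
            scores = relevance[remaining] - red_sum[np.array(remaining)] / len(selected)
        best = remaining[int(np.argmax(scores))]
        selected.append(best)
        remaining.remove(best)
    return selected


def _auto_n_candidates(
    X: np.ndarray, y: np.ndarray, ranking: list[int], grid, seed: int
) -> int:
    """Pick the candidate-list size by small-grid RF cross-validated AUC."""

    best_n, best_auc = grid[0], -np.inf
    for n in grid:
        idx = ranking[: min(n, len(ranking))]
        rf = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
        cv = StratifiedKFold(3, shuffle=True, random_state=seed)
        probs = cross_val_predict(rf, X[:, idx], y, cv=cv, method="predict_proba")[:, 1]
        auc = roc_auc_score(y, probs)
        if auc > best_auc:
            best_auc, best_n = auc, n
    return best_n


def stability_select(
    X: np.ndarray,
    y: np.ndarray,
    config: SelectionConfig | None = None,
) -> tuple[list[int], np.ndarray]:
    """Cross-validated stability selection.

    Returns (selected column indices, per-feature selection frequency).
    Iteration r reshuffles the stratified fold assignment with seed
    ``config.seed + r``; each fold's training subset contributes one mRMR
    top-``n_candidates`` list.  Features recorded in at least
    ``stability_threshold`` of the subsets are selected; an empty selection
    falls back to the top-frequency set with a warning.
    """

    config = config or SelectionConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    p = X.shape[1]
    counts = np.zeros(p)
    n_runs = 0
    for r in range(config.n_iterations):
        skf = StratifiedKFold(
            config.n_folds, shuffle=True, random_state=config.seed + r
        )
        for train_idx, _ in skf.split(X, y):
            Xt, yt = X[train_idx], y[train_idx]
            binned = _bin_matrix(Xt)
            if config.n_candidates == "auto":
                full = mrmr_rank(Xt, yt, max(config.auto_grid), _binned=binned)
                n_cand = _auto_n_candidates(
                    Xt, yt, full, config.auto_grid, config.seed + r
                )
                top = full[:n_cand]
            else:
                top = mrmr_rank(Xt, yt, int(config.n_candidates), _binned=binned)
            counts[top] += 1
            n_runs += 1
    freq = counts / n_runs
    selected = [j for j in range(p) if freq[j] >= config.stability_threshold]
    if not selected:
        top_freq = freq.max()
        selected = [j for j in range(p) if freq[j] == top_freq]
        logger.warning(
            "no feature reached stability %.2f; falling back to the %d "
            "top-frequency feature(s) at %.2f",
            config.stability_threshold, len(selected), top_freq,
        )
    return selected, freq
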