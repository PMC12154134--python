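"""Random-forest risk classification with leave-center(s)-out trials.

The four-trial design holds out all subjects of one or two centers per
trial (T1: AHN+MCA, T2: EMC, T3: IU, T4: NYU) and cross-validates on the
rest.  Feature redundancy filtering, stability selection, and RF training
consume cross-validation subjects only; held-out centers are scored once.

Per-trial metrics (AUC by pairwise concordance with ties counting 1/2;
accuracy/sensitivity/specificity/PPV/F1 at a probability threshold,
default 0.5) are aggregated either by the unweighted arithmetic mean or by
a test-size-weighted mean.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .featselect import SelectionConfig, spearman_redundancy_filter, stability_select
from .radiomics import FeatureConfig, extract_cohort_features

__all__ = [
    "TrialSplit",
    "MetricSet",
    "PAPER_TRIAL_DESIGN",
    "make_center_trials",
    "train_rf",
    "compute_metrics",
    "aggregate_metrics",
    "run_radiomics_experiment",
]

# Held-out center sets of trials T1-T4.
PAPER_TRIAL_DESIGN: tuple[tuple[str, ...], ...] = (
    ("AHN", "MCA"), ("EMC",), ("IU",), ("NYU",),
)


@dataclass(frozen=True)
class TrialSplit:
    trial_id: str
    cv_centers: frozenset[str]
    test_centers: frozenset[str]
    cv_n: int
    test_n: int

    def __post_init__(self) -> None:
        if self.cv_centers & self.test_centers:
            raise ValueError("cv and test centers overlap")
        if not self.test_centers:
            raise ValueError("test center set is empty")


@dataclass(frozen=True)
class MetricSet:
    auc: float
    acc: float
    sens: float
    spec: float
    ppv: float
    f1: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0 or np.isnan(v)):
                raise ValueError(f"{f.name}={v} outside [0, 1]")

    def as_percent(self) -> dict[str, float]:
        return {f.name: 100.0 * getattr(self, f.name) for f in fields(self)}


def make_center_trials(
    subject_table: pd.DataFrame,
    design: list[tuple[str, ...]] | tuple[tuple[str, ...], ...] = PAPER_TRIAL_DESIGN,
) -> list[TrialSplit]:
    """One TrialSplit per held-out center set, with counts from the table."""

    counts = subject_table.groupby("center_id").size().to_dict()
    all_centers = set(counts)
    trials = []
    for i, test_set in enumerate(design, start=1):
        test = frozenset(test_set)
        if not test:
            raise ValueError("empty test-center set")
        unknown = test - all_centers
        if unknown:
            raise ValueError(f"unknown center(s): {sorted(unknown)}")
        cv = frozenset(all_centers - test)
        trials.append(
            TrialSplit(
                trial_id=f"T{i}",
                cv_centers=cv,
                test_centers=test,
                cv_n=int(sum(counts[c] for c in cv)),
                test_n=int(sum(counts[c] for c in test)),
            )
        )
    return trials


class RFScorer:
    """Seeded random-forest probability scorer: rows -> P(high risk)."""

    def __init__(self, model: RandomForestClassifier):
        self.model = model

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(np.asarray(X, dtype=float))[:, 1]


def train_rf(
    X_train: np.ndarray,
    y_train: np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
) -> RFScorer:
    """Fit the final random forest (default 500 trees, sqrt(p) features per
    split, fixed seed) on the full training set."""

    y_train = np.asarray(y_train, dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("single-class training data")
    model = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )
    model.fit(np.asarray(X_train, dtype=float), y_train)
    return RFScorer(model)


def compute_metrics(
    probs: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricSet:
    """AUC by pairwise concordance (ties 1/2) plus thresholded metrics."""

    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present: AUC undefined")
    ranks = rankdata(probs)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    pred = (probs >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    acc = (tp + tn) / len(labels)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = 2 * ppv * sens / (ppv + sens) if (ppv + sens) else 0.0
    return MetricSet(float(auc), acc, sens, spec, ppv, f1)


def aggregate_metrics(
    per_trial: list[MetricSet], weights: list[float] | None = None
) -> MetricSet:
    """Unweighted arithmetic mean or count-weighted mean, field by field."""

    if not per_trial:
        raise ValueError("need at least one trial")
    if weights is not None and len(weights) != len(per_trial):
        raise ValueError("weights length must match number of trials")
    w = np.ones(len(per_trial)) if weights is None else np.asarray(weights, float)
    vals = {}
    for f in fields(MetricSet):
        x = np.array([getattr(m, f.name) for m in per_trial])
        vals[f.name] = float((x * w).sum() / w.sum())
    return MetricSet(**vals)


@dataclass
class TrialResult:
    split: TrialSplit
    metrics: MetricSet
    selected_columns: list[str]
    selection_frequency: np.ndarray
    test_probs: np.ndarray
    test_labels: np.ndarray
    cv_probs: np.ndarray
    cv_labels: np.ndarray


@dataclass
class ExperimentResult:
    trials: list[TrialResult]
    mean: MetricSet
    weighted_mean: MetricSet
    feature_table: pd.DataFrame


def run_radiomics_experiment(
    cohort,
    trials: list[TrialSplit] | None = None,
    mode: str = "3D",
    feature_config: FeatureConfig | None = None,
    selection_config: SelectionConfig | None = None,
    spearman_threshold: float = 0.6,
    n_trees: int = 500,
    seed: int = 0,
    target_mm: float = 1.0,
    bias_method: str = "poly",
    feature_table: pd.DataFrame | None = None,
    threshold: float = 0.5,
) -> ExperimentResult:
    """Full leave-center-out radiomics pipeline.

    Per trial: preprocess -> extract (per subject, trial-independent) ->
    Spearman redundancy filter (training only) -> stability selection
    (training only) -> train RF (training only) -> score held-out centers.
    A precomputed ``feature_table`` (subjects x features, index = subject
    id) skips extraction.
    """

    manifest = cohort.manifest
    if trials is None:
        centers = set(manifest["center_id"])
        if all(c in centers for d in PAPER_TRIAL_DESIGN for c in d):
            design = PAPER_TRIAL_DESIGN
        else:
            design = tuple((c,) for c in sorted(centers))
        trials = make_center_trials(manifest, design)

    if feature_table is None:
        from .prep import preprocess

        def pf(v, m):
            return preprocess(v, m, mode=mode, target_mm=target_mm,
                              bias_method=bias_method)

        feature_table, _ = extract_cohort_features(cohort, mode, feature_config, pf)

    labels = manifest.set_index("subject_id")["label"]
    center = manifest.set_index("subject_id")["center_id"]
    selection_config = selection_config or SelectionConfig(seed=seed)

    results: list[TrialResult] = []
    for split in trials:
        cv_ids = [i for i in feature_table.index if center[i] in split.cv_centers]
        test_ids = [i for i in feature_table.index if center[i] in split.test_centers]
        X_cv = feature_table.loc[cv_ids].to_numpy()
        y_cv = labels[cv_ids].to_numpy()
        X_te = feature_table.loc[test_ids].to_numpy()
        y_te = labels[test_ids].to_numpy()

        kept = spearman_redundancy_filter(X_cv, spearman_threshold)
        sel, freq = stability_select(X_cv[:, kept], y_cv, selection_config)
        cols = [kept[j] for j in sel]
        scorer = train_rf(X_cv[:, cols], y_cv, n_trees=n_trees, seed=seed)
        probs_te = scorer(X_te[:, cols])
        probs_cv = scorer(X_cv[:, cols])
        results.append(
            TrialResult(
                split=split,
                metrics=compute_metrics(probs_te, y_te, threshold),
                selected_columns=[feature_table.columns[c] for c in cols],
                selection_frequency=freq,
                test_probs=probs_te,
                test_labels=y_te,
                cv_probs=probs_cv,
                cv_labels=y_cv,
            )
        )

    per = [r.metrics for r in results]
    wts = [r.split.test_n for r in results]
    return ExperimentResult(
        trials=results,
        mean=aggregate_metrics(per),
        weighted_mean=aggregate_metrics(per, wts),
        feature_table=feature_table,
    )
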