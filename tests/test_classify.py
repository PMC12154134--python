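"""Trial construction, RF training, metric computation and aggregation,
and the leave-center-out experiment incl. the leakage guard."""

import numpy as np
import pandas as pd
import pytest

from ipmnrisk import (
    MetricSet,
    SelectionConfig,
    aggregate_metrics,
    compute_metrics,
    make_center_trials,
    run_radiomics_experiment,
    train_rf,
)
from ipmnrisk.classify import PAPER_TRIAL_DESIGN


def _paper_like_table():
    """Subject table with the per-center totals implied by the trial design
    (AHN+MCA=29, EMC=36, IU=35, NYU=71, MCF+NMH=188; total 359)."""
    counts = {"AHN": 14, "MCA": 15, "EMC": 36, "IU": 35, "NYU": 71,
              "MCF": 94, "NMH": 94}
    rows = []
    i = 0
    for c, n in counts.items():
        for _ in range(n):
            rows.append({"subject_id": f"S{i:04d}", "center_id": c,
                         "cyst_type": "BD", "label": i % 2})
            i += 1
    return pd.DataFrame(rows)


class TestMakeCenterTrials:
    def test_four_trial_design_counts(self):
        trials = make_center_trials(_paper_like_table(), PAPER_TRIAL_DESIGN)
        test_ns = [t.test_n for t in trials]
        assert test_ns == [29, 36, 35, 71]
        t4 = trials[3]
        assert t4.test_centers == frozenset({"NYU"})
        assert t4.cv_n == 288  # 359 - 71

    def test_singleton_designs_partition_total(self):
        table = _paper_like_table()
        centers = sorted(table["center_id"].unique())
        trials = make_center_trials(table, [(c,) for c in centers])
        assert len(trials) == len(centers)
        for t in trials:
            assert t.cv_n + t.test_n == len(table)
            assert not (t.cv_centers & t.test_centers)

    def test_empty_test_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            make_center_trials(_paper_like_table(), [()])

    def test_unknown_center_raises(self):
        with pytest.raises(ValueError, match="unknown center"):
            make_center_trials(_paper_like_table(), [("XXX",)])


class TestTrainRf:
    def test_separable_toy_reaches_perfect_training_auc(self, rng):
        n = 40
        y = np.repeat([0, 1], n // 2)
        X = np.column_stack([y + 0.01 * rng.standard_normal(n),
                             rng.standard_normal(n)])
        scorer = train_rf(X, y, n_trees=100, seed=0)
        assert compute_metrics(scorer(X), y).auc == 1.0

    def test_permuted_labels_give_chance_level_cv_auc(self):
        from sklearn.model_selection import cross_val_predict
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((60, 5))
            y = rng.permutation(np.repeat([0, 1], 30))
            scorer = train_rf(X, y, n_trees=50, seed=seed)
            probs = cross_val_predict(scorer.model, X, y, cv=5,
                                      method="predict_proba")[:, 1]
            aucs.append(compute_metrics(probs, y).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_same_seed_identical_predictions(self, rng):
        X = rng.standard_normal((30, 4))
        y = np.tile([0, 1], 15)
        Xt = rng.standard_normal((10, 4))
        assert np.array_equal(train_rf(X, y, seed=5)(Xt), train_rf(X, y, seed=5)(Xt))

    def test_single_class_raises(self, rng):
        with pytest.raises(ValueError, match="single-class"):
            train_rf(rng.standard_normal((10, 2)), np.ones(10), seed=0)


class TestComputeMetrics:
    def test_perfect_separation(self):
        m = compute_metrics([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0])
        assert m.auc == m.acc == m.sens == m.spec == m.ppv == m.f1 == 1.0

    def test_interleaved_example(self):
        # positive-negative pairs: (.9,.8)+, (.9,.6)+, (.7,.8)-, (.7,.6)+ -> 3/4
        m = compute_metrics([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert m.auc == pytest.approx(0.75)

    def test_all_tied_probs_give_half_auc(self):
        m = compute_metrics([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert m.auc == pytest.approx(0.5)

    def test_auc_invariant_under_monotone_transform(self, rng):
        probs = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        a1 = compute_metrics(probs, labels).auc
        a2 = compute_metrics(1 / (1 + np.exp(-7 * (probs - 0.3))), labels).auc
        assert a1 == pytest.approx(a2)

    def test_f1_consistent_with_sens_and_ppv(self, rng):
        probs = rng.random(80)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        m = compute_metrics(probs, labels)
        if m.ppv + m.sens > 0:
            assert m.f1 == pytest.approx(2 * m.ppv * m.sens / (m.ppv + m.sens))

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            compute_metrics([0.5, 0.6], [1, 1])


def _ms(**kw):
    base = dict(auc=0.5, acc=0.5, sens=0.5, spec=0.5, ppv=0.5, f1=0.5)
    base.update(kw)
    return MetricSet(**base)


class TestAggregateMetrics:
    def test_unweighted_mean_of_reported_trial_accuracies(self):
        per = [_ms(acc=a / 100) for a in (53.1, 63.7, 76.3, 70.6)]
        agg = aggregate_metrics(per)
        assert agg.acc * 100 == pytest.approx(65.9, abs=0.05)

    def test_weighted_mean_of_reported_trial_accuracies(self):
        per = [_ms(acc=a / 100) for a in (48.3, 54.9, 68.0, 67.3)]
        agg = aggregate_metrics(per, weights=[29, 36, 35, 71])
        assert agg.acc * 100 == pytest.approx(61.6, abs=0.05)

    def test_equal_weights_match_unweighted(self):
        per = [_ms(auc=0.6), _ms(auc=0.8)]
        assert aggregate_metrics(per, [3, 3]).auc == pytest.approx(
            aggregate_metrics(per).auc)

    def test_singleton_is_identity(self):
        m = _ms(auc=0.71)
        assert aggregate_metrics([m]) == m

    def test_weight_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            aggregate_metrics([_ms()], weights=[1, 2])


class TestRunRadiomicsExperiment:
    """End-to-end behavior on a precomputed feature table (fast path); the
    image-level pipeline is exercised in the acceptance suite."""

    @staticmethod
    def _table_and_cohort(small_cohort, effect=3.0, leak=None, seed=0):
        rng = np.random.default_rng(seed)
        man = small_cohort.manifest
        n = len(man)
        X = rng.standard_normal((n, 12))
        X[:, 0] += effect * man["label"].to_numpy()
        X[:, 1] += effect * man["label"].to_numpy()
        if leak is not None:
            X[:, 5] = leak
        return pd.DataFrame(X, index=man["subject_id"])

    SEL = SelectionConfig(n_iterations=5, n_candidates=4, stability_threshold=0.5,
                          seed=0)

    def test_strong_effect_recovers_high_heldout_auc(self, small_cohort):
        ft = self._table_and_cohort(small_cohort)
        res = run_radiomics_experiment(small_cohort, feature_table=ft,
                                       selection_config=self.SEL, n_trees=100)
        assert res.mean.auc > 0.8

    def test_no_test_information_enters_training(self, small_cohort):
        man = small_cohort.manifest
        test_rows = man["center_id"] == sorted(man["center_id"].unique())[0]
        leak_a = np.where(test_rows, man["label"], 0.123)
        leak_b = np.where(test_rows, 1 - man["label"], 0.123)
        trials = make_center_trials(man, [(sorted(man["center_id"].unique())[0],)])
        res_a = run_radiomics_experiment(
            small_cohort, trials, feature_table=self._table_and_cohort(
                small_cohort, leak=leak_a), selection_config=self.SEL, n_trees=50)
        res_b = run_radiomics_experiment(
            small_cohort, trials, feature_table=self._table_and_cohort(
                small_cohort, leak=leak_b), selection_config=self.SEL, n_trees=50)
        ta, tb = res_a.trials[0], res_b.trials[0]
        assert ta.selected_columns == tb.selected_columns
        assert np.array_equal(ta.selection_frequency, tb.selection_frequency)
        assert np.array_equal(ta.cv_probs, tb.cv_probs)

    def test_end_to_end_seeded_reproducibility(self, small_cohort):
        ft = self._table_and_cohort(small_cohort)
        r1 = run_radiomics_experiment(small_cohort, feature_table=ft,
                                      selection_config=self.SEL, n_trees=50, seed=3)
        r2 = run_radiomics_experiment(small_cohort, feature_table=ft,
                                      selection_config=self.SEL, n_trees=50, seed=3)
        assert r1.mean == r2.mean
        for a, b in zip(r1.trials, r2.trials):
            assert np.array_equal(a.test_probs, b.test_probs)
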