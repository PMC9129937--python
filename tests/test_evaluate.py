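"""Cross-validation plans, metrics, ROC/R-squared oracles, leakage canary."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from mseeg.evaluate import (
    ConfusionMatrix,
    EvalConfig,
    EvaluationError,
    ModelVariant,
    confusion,
    cross_validate_matrix,
    kfold_split,
    r_squared,
    roc_auc,
)
from mseeg.features import FeatureMatrix


def mann_whitney_auc(scores, y, positive="MS"):
    """Rank-statistic oracle: AUC = U / (n+ * n-)."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(y) == positive
    ranks = rankdata(scores)
    n_pos, n_neg = pos.sum(), (~pos).sum()
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


class TestKfoldSplit:
    def test_balanced_forty_recordings_two_per_class_per_fold(self):
        y = np.array(["healthy"] * 20 + ["MS"] * 20)
        plan = kfold_split(y, K=10, seed=0)
        for fold in range(10):
            test = plan.test_indices(fold)
            assert len(test) == 4
            assert (y[test] == "MS").sum() == 2

    def test_folds_partition_recordings(self):
        y = np.array(["healthy"] * 15 + ["MS"] * 15)
        plan = kfold_split(y, K=5, seed=3)
        seen = np.concatenate([plan.test_indices(f) for f in range(5)])
        assert sorted(seen) == list(range(30))

    def test_same_seed_same_plan(self):
        y = np.array(["healthy"] * 12 + ["MS"] * 12)
        a = kfold_split(y, K=4, seed=7)
        b = kfold_split(y, K=4, seed=7)
        assert np.array_equal(a.assignments, b.assignments)

    def test_class_smaller_than_k_rejected(self):
        y = np.array(["healthy"] * 12 + ["MS"] * 3)
        with pytest.raises(EvaluationError):
            kfold_split(y, K=5)


class TestConfusion:
    def test_perfect_agreement(self):
        y = np.array(["MS", "healthy", "MS"])
        cm = confusion(y, y)
        assert (cm.FP, cm.FN) == (0, 0)
        assert cm.accuracy == 1.0

    def test_hand_counts(self):
        y_true = ["MS"] * 10 + ["healthy"] * 10
        y_pred = ["MS"] * 9 + ["healthy"] + ["healthy"] * 9 + ["MS"]
        cm = confusion(np.array(y_true), np.array(y_pred))
        assert (cm.TP, cm.FN, cm.TN, cm.FP) == (9, 1, 9, 1)
        assert cm.sensitivity == 0.9 and cm.specificity == 0.9 and cm.accuracy == 0.9

    def test_swapping_positive_class_swaps_rates(self):
        y_true = np.array(["MS"] * 8 + ["healthy"] * 4)
        y_pred = np.array(["MS"] * 6 + ["healthy"] * 2 + ["healthy"] * 3 + ["MS"])
        a = confusion(y_true, y_pred, positive="MS")
        b = confusion(y_true, y_pred, positive="healthy")
        assert a.sensitivity == b.specificity and a.specificity == b.sensitivity

    def test_unknown_label_rejected(self):
        with pytest.raises(EvaluationError):
            confusion(np.array(["MS", "sick"]), np.array(["MS", "MS"]))


class TestRocAuc:
    def test_perfect_separation(self):
        y = np.array(["healthy"] * 5 + ["MS"] * 5)
        scores = np.concatenate([np.arange(5), np.arange(10, 15)])
        assert roc_auc(scores, y).auc == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        y = np.array(["healthy", "MS"] * 250)
        auc = roc_auc(rng.standard_normal(500), y).auc
        assert 0.42 <= auc <= 0.58

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_rank_statistic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 80))
        y = np.array(["MS" if v else "healthy" for v in rng.integers(0, 2, n)])
        if len(set(y)) < 2:
            y[0], y[1] = "MS", "healthy"
        scores = rng.standard_normal(n)
        assert abs(roc_auc(scores, y).auc - mann_whitney_auc(scores, y)) < 1e-12

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(1)
        y = np.array(["healthy", "MS"] * 20)
        roc = roc_auc(rng.standard_normal(40), y)
        assert tuple(roc.points[0]) == (0.0, 0.0)
        assert tuple(roc.points[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc.points[:, 0]) >= 0)
        assert np.all(np.diff(roc.points[:, 1]) >= 0)

    def test_constant_scores_degenerate(self):
        y = np.array(["healthy", "MS"] * 5)
        with pytest.warns(UserWarning):
            assert roc_auc(np.ones(10), y).auc == 0.5


class TestRSquared:
    def test_perfect_prediction(self):
        fq = r_squared([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        assert fq.mse == 0.0 and fq.r2 == 1.0

    def test_mean_predictor_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        fq = r_squared(y, np.full(4, y.mean()))
        assert fq.r2 == 0.0

    def test_hand_arithmetic(self):
        fq = r_squared([0.0, 1.0, 2.0], [0.0, 1.0, 1.0])
        assert fq.mse == pytest.approx(1.0 / 3.0)
        assert fq.r2 == pytest.approx(0.5)

    def test_constant_y_rejected(self):
        with pytest.raises(EvaluationError):
            r_squared([1.0, 1.0, 1.0], [1.0, 1.0, 2.0])


class TestModelVariant:
    def test_ladder_definitions(self):
        assert ModelVariant.from_id(1).feature_domains == ("time",)
        assert ModelVariant.from_id(2).feature_domains == ("frequency",)
        m5 = ModelVariant.from_id(5)
        assert m5.use_selection == "maco" and m5.use_tuning == "goa"

    def test_unknown_id_rejected(self):
        with pytest.raises(EvaluationError):
            ModelVariant.from_id(6)


def _matrix_from_arrays(x, y, rec_ids, domains="time"):
    cols = [f"alpha.avg.f{i}" for i in range(x.shape[1])]
    df = pd.DataFrame(x, columns=cols, index=rec_ids)
    return FeatureMatrix(
        values=df,
        groups={c: "statistical" for c in cols},
        domains={c: domains for c in cols},
        labels=pd.Series(y, index=df.index),
        recording_ids=pd.Series(rec_ids, index=df.index),
    )


class TestCrossValidation:
    def test_separable_matrix_classified_perfectly(self):
        rng = np.random.default_rng(0)
        y = np.array(["healthy"] * 10 + ["MS"] * 10)
        x = np.where(y[:, None] == "MS", 2.0, -2.0) + rng.normal(0, 0.3, (20, 3))
        fm = _matrix_from_arrays(x, y, [f"r{i}" for i in range(20)])
        rep = cross_validate_matrix(fm, ModelVariant.from_id(1), EvalConfig(K=5), rng)
        assert rep.accuracy == 1.0 and rep.auc == 1.0

    def test_testfold_only_signal_cannot_be_exploited(self):
        """Leakage canary: a feature that is discriminative only on test
        rows must not lift performance above chance, because every fit
        happens on training rows where it is pure noise."""
        rng = np.random.default_rng(1)
        y = np.array(["healthy"] * 15 + ["MS"] * 15)
        rec_ids = [f"r{i}" for i in range(30)]
        x = rng.normal(size=(30, 4))
        base_cfg = EvalConfig(K=5)
        # run once to learn the fold assignment deterministically
        cv_rng = np.random.default_rng(77)
        seed_peek = np.random.default_rng(77).integers(0, 2**31 - 1)
        plan = kfold_split(y, K=5, seed=int(seed_peek))
        canary = x.copy()
        test_of_fold0 = plan.test_indices(0)
        canary[test_of_fold0, 0] = np.where(y[test_of_fold0] == "MS", 10.0, -10.0)
        fm_canary = _matrix_from_arrays(canary, y, rec_ids)
        rep = cross_validate_matrix(fm_canary, ModelVariant.from_id(1), base_cfg, cv_rng)
        assert rep.accuracy <= 0.75  # stays near chance; leakage would hit ~1.0

    def test_segment_rows_majority_vote_invariant_to_order(self):
        rng = np.random.default_rng(2)
        y_rec = np.array(["healthy"] * 6 + ["MS"] * 6)
        rec_ids = np.repeat([f"r{i}" for i in range(12)], 5)
        y_rows = np.repeat(y_rec, 5)
        x = np.where(y_rows[:, None] == "MS", 1.5, -1.5) + rng.normal(0, 0.5, (60, 3))
        fm = _matrix_from_arrays(x, y_rows, rec_ids)
        rep_a = cross_validate_matrix(fm, ModelVariant.from_id(1), EvalConfig(K=3), np.random.default_rng(5))
        perm = rng.permutation(60)
        fm_b = _matrix_from_arrays(x[perm], y_rows[perm], rec_ids[perm])
        rep_b = cross_validate_matrix(fm_b, ModelVariant.from_id(1), EvalConfig(K=3), np.random.default_rng(5))
        assert rep_a.accuracy == rep_b.accuracy

    def test_full_pipeline_on_small_dataset(self, small_dataset, small_config, small_features):
        rng = np.random.default_rng(0)
        rep = cross_validate_matrix(small_features, ModelVariant.from_id(3), small_config, rng)
        assert rep.accuracy >= 0.9
        assert 0.0 <= rep.auc <= 1.0
        assert len(rep.fold_accuracies) == small_config.K
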