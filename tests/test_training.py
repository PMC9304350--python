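"""InfoNCE closed forms, optimization contracts, and the CV harness."""

import numpy as np
import pandas as pd
import pytest

from dynamilc import (
    CohortSpec,
    MilcModel,
    TrainConfig,
    cross_validate,
    finetune,
    generate_cohort,
    generate_pretraining_pool,
    infonce_loss,
    pretrain,
    subject_probabilities,
)


def softmax_ce_oracle(S):
    """Direct softmax-cross-entropy computation, row by row (independent oracle)."""
    total = 0.0
    N, T, _ = S.shape
    for i in range(N):
        for t in range(T):
            row = np.exp(S[i, t] - S[i, t].max())
            total -= np.log(row[i] / row.sum())
    return total


class TestInfoNCE:
    def test_uniform_scores_closed_form(self):
        S = np.full((4, 3, 4), 0.7)
        assert infonce_loss(S) == pytest.approx(12 * np.log(4), abs=1e-6)

    def test_saturated_positives_drive_loss_to_zero(self):
        S = np.zeros((4, 3, 4))
        for i in range(4):
            S[i, :, i] = 50.0
        assert infonce_loss(S) < 1e-3

    def test_two_by_one_hand_case_matches_oracle(self):
        S = np.array([[[2.0, 0.0]], [[1.0, 3.0]]])  # N=2, T=1
        expected = -(np.log(np.e**2 / (np.e**2 + 1)) + np.log(np.e**3 / (np.e + np.e**3)))
        assert infonce_loss(S) == pytest.approx(expected, rel=1e-12)
        assert infonce_loss(S) == pytest.approx(softmax_ce_oracle(S), rel=1e-12)

    def test_random_scores_match_oracle(self, rng):
        S = rng.standard_normal((5, 4, 5)) * 3
        assert infonce_loss(S) == pytest.approx(softmax_ce_oracle(S), rel=1e-10)

    def test_loss_nonnegative(self, rng):
        for _ in range(10):
            assert infonce_loss(rng.standard_normal((3, 2, 3))) >= 0

    def test_single_sequence_errors(self):
        with pytest.raises(ValueError):
            infonce_loss(np.zeros((1, 3, 1)))


def _small_pool(n=10):
    return generate_pretraining_pool(n, C=8, T=60, seed=4)


def _small_cohort(**kw):
    defaults = dict(n_per_class=10, n_components=8, n_timepoints=60,
                    affected_components=(1, 3, 5), event_window=(25, 45),
                    effect_size=3.0, seed=21)
    defaults.update(kw)
    return generate_cohort(CohortSpec(**defaults))[0]


def _small_model(seed=0):
    return MilcModel(n_components=8, window_length=10, d_enc=24, d_top=16,
                     enc_attn_hidden=8, top_attn_hidden=8, d_head=16, seed=seed)


class TestPretrain:
    def test_zero_learning_rate_freezes_weights_and_loss(self):
        pool = _small_pool()
        model = _small_model()
        before = {k: v.copy() for k, v in model.params.items()}
        cfg = TrainConfig(batch_size=4, epochs=3, learning_rate=0.0, seed=0)
        _, hist = pretrain(pool, model, cfg)
        for k in before:
            np.testing.assert_array_equal(model.params[k], before[k])
        assert hist[0]["loss"] == pytest.approx(hist[-1]["loss"], abs=1e-9)

    def test_seeded_runs_are_identical(self):
        pool = _small_pool()
        cfg = TrainConfig(batch_size=4, epochs=2, learning_rate=1e-3, seed=5)
        _, h1 = pretrain(pool, _small_model(), cfg)
        _, h2 = pretrain(pool, _small_model(), cfg)
        assert h1[-1]["loss"] == pytest.approx(h2[-1]["loss"], abs=1e-6)

    def test_loss_decreases_and_heldout_accuracy_beats_chance(self):
        pool = _small_pool(16)
        model = _small_model()
        cfg = TrainConfig(batch_size=4, epochs=10, learning_rate=1e-3, seed=0)
        _, hist = pretrain(pool, model, cfg)
        assert hist[-1]["loss"] < hist[0]["loss"]
        # chance level for batches of 4 sequences is 1/4
        assert hist[-1]["heldout_accuracy"] > 0.25

    def test_pool_smaller_than_batch_errors(self):
        with pytest.raises(ValueError):
            pretrain(_small_pool(3), _small_model(), TrainConfig(batch_size=8, epochs=1))


class TestFinetune:
    def test_single_class_training_set_errors(self):
        recs = [r for r in _small_cohort() if r.label == 0]
        with pytest.raises(ValueError):
            finetune(_small_model(), recs, TrainConfig(epochs=1, mode="finetune_from_scratch"))

    def test_zero_lr_from_pretrained_equals_checkpoint_except_head(self):
        pool = _small_pool(8)
        pre = _small_model(seed=1)
        pretrain(pool, pre, TrainConfig(batch_size=4, epochs=1, learning_rate=1e-3, seed=0))
        model = _small_model(seed=2)
        cfg = TrainConfig(epochs=1, learning_rate=0.0, seed=0, mode="finetune_from_pretrained")
        finetune(model, _small_cohort(), cfg, pretrained=pre)
        for k, v in pre.params.items():
            if not k.startswith("head."):
                np.testing.assert_array_equal(model.params[k], v)

    def test_strongly_separable_cohort_reaches_high_training_auc(self):
        from sklearn.metrics import roc_auc_score

        recs = _small_cohort(effect_size=4.0)
        model = _small_model()
        cfg = TrainConfig(batch_size=4, epochs=8, learning_rate=2e-3, seed=0,
                          mode="finetune_from_scratch")
        finetune(model, recs, cfg)
        p = subject_probabilities(model, recs)
        assert roc_auc_score([r.label for r in recs], p) > 0.95

    def test_label_permuted_cohort_stays_near_chance_on_heldout(self, rng):
        from dataclasses import replace
        from sklearn.metrics import roc_auc_score

        recs = _small_cohort(n_per_class=12)
        perm = rng.permutation([r.label for r in recs])
        shuffled = [replace(r, label=int(l)) for r, l in zip(recs, perm)]
        train, test = shuffled[::2], shuffled[1::2]
        model = _small_model()
        finetune(model, train, TrainConfig(batch_size=4, epochs=4, learning_rate=1e-3,
                                           seed=0, mode="finetune_from_scratch"))
        auc = roc_auc_score([r.label for r in test], subject_probabilities(model, test))
        assert 0.15 < auc < 0.85  # chance band at n=12 test subjects


@pytest.fixture(scope="module")
def cv_result():
    recs = _small_cohort(n_per_class=15)
    return recs, cross_validate(
        recs, k=3, train_sizes=[3, 5], repeats=2, base_seed=7,
        epochs=1, learning_rate=1e-3,
        model_kwargs=dict(window_length=10, d_enc=24, d_top=16,
                          enc_attn_hidden=8, top_attn_hidden=8, d_head=16),
    )


class TestCrossValidate:

    def test_grid_is_complete_and_aucs_valid(self, cv_result):
        _, res = cv_result
        assert len(res.table) == 3 * 2 * 2  # folds × sizes × repeats
        assert res.table["auc"].between(0, 1).all()

    def test_test_folds_partition_cohort(self, cv_result):
        recs, res = cv_result
        seen = [sid for fold in res.fold_test_ids for sid in fold]
        assert sorted(seen) == sorted(r.subject_id for r in recs)

    def test_no_test_subject_in_any_training_cell(self, cv_result):
        _, res = cv_result
        for cell in res.manifest:
            assert not set(cell["train_ids"]) & set(cell["test_ids"])

    def test_oversized_train_size_errors(self):
        recs = _small_cohort(n_per_class=6)
        with pytest.raises(ValueError):
            cross_validate(recs, k=3, train_sizes=[10], repeats=1, epochs=1)

    def test_summary_and_mode_comparison_shapes(self, cv_result):
        _, res = cv_result
        s = res.summary()
        assert set(s.columns) == {"mode", "train_size", "mean", "std", "count"}


class TestLeakageAudit:
    """No test-fold subject influences training, masks, or SVM selection."""

    def test_cv_training_pools_exclude_test_folds_everywhere(self):
        recs = _small_cohort(n_per_class=9)
        res = cross_validate(
            recs, k=3, train_sizes=[3], repeats=2, base_seed=1, epochs=1,
            model_kwargs=dict(window_length=10, d_enc=24, d_top=16,
                              enc_attn_hidden=8, top_attn_hidden=8, d_head=16),
        )
        by_fold = {}
        for cell in res.manifest:
            by_fold.setdefault(cell["fold"], set()).update(cell["train_ids"])
        for fold, train_ids in by_fold.items():
            assert not train_ids & set(res.fold_test_ids[fold])

    def test_rar_grid_search_sees_training_folds_only(self):
        from dynamilc import rar_auc

        recs = _small_cohort(n_per_class=9)
        report = rar_auc(recs, folds=3, seed=0)
        for cell in report.manifest:
            assert not set(cell["train_idx"]) & set(cell["test_idx"])
        # all test indices together cover the cohort exactly once
        all_test = sorted(i for cell in report.manifest for i in cell["test_idx"])
        assert all_test == list(range(len(recs)))
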