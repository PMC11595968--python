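"""Fold assignment, metrics (against scikit-learn), and cross-validation."""

from __future__ import annotations

import numpy as np
import pytest

from cleftus.evaluate import (
    aggregate_metrics,
    compute_metrics,
    confusion_matrix,
    precision_recall_f1,
    run_cross_validation,
    stratified_group_kfold,
)
from cleftus.io import CleftLabel, Manifest, Participant, Sex
from cleftus.siamese import TrainConfig

CP, UCLP, BCLP = CleftLabel.CP, CleftLabel.UCLP, CleftLabel.BCLP


def _manifest(n_per_class, sexes=None):
    participants = []
    for c in CleftLabel:
        for k in range(n_per_class):
            sex = sexes[k % len(sexes)] if sexes else Sex.UNKNOWN
            participants.append(
                Participant(id=f"{c.name}{k}", label=c, sex=sex)
            )
    return Manifest(participants=participants, utterances=[])


class TestStratifiedGroupKFold:
    def test_two_per_class_two_folds_exact_stratification(self):
        m = _manifest(2)
        fa = stratified_group_kfold(m, 2, seed=0)
        for fold in (0, 1):
            members = fa.participants_in_fold(fold)
            labels = [m.participant(p).label for p in members]
            assert sorted(int(l) for l in labels) == [0, 1, 2]

    def test_leave_one_participant_out_limit(self):
        m = _manifest(2)  # 6 participants
        fa = stratified_group_kfold(m, 6, seed=1)
        assert sorted(fa.fold_of_participant.values()) == list(range(6))

    def test_every_participant_assigned_exactly_once(self):
        m = _manifest(5)
        fa = stratified_group_kfold(m, 4, seed=2)
        assert set(fa.fold_of_participant) == {p.id for p in m.participants}

    def test_class_proportions_within_one_participant(self):
        m = _manifest(7)
        fa = stratified_group_kfold(m, 3, seed=3)
        for c in CleftLabel:
            per_fold = [
                sum(
                    1
                    for p in fa.participants_in_fold(f)
                    if m.participant(p).label == c
                )
                for f in range(3)
            ]
            assert max(per_fold) - min(per_fold) <= 1

    def test_sex_interleaving_balances_folds(self):
        m = _manifest(4, sexes=[Sex.M, Sex.F])  # 2M/2F per class
        fa = stratified_group_kfold(m, 2, seed=4)
        for f in range(2):
            males = sum(
                1
                for p in fa.participants_in_fold(f)
                if m.participant(p).sex == Sex.M
            )
            assert males == 3  # half of the 6 males

    def test_invalid_fold_counts_rejected(self):
        m = _manifest(2)
        with pytest.raises(ValueError):
            stratified_group_kfold(m, 1)
        with pytest.raises(ValueError):
            stratified_group_kfold(m, 7)

    def test_small_class_warns_best_effort(self):
        m = _manifest(2)
        with pytest.warns(UserWarning, match="best-effort"):
            stratified_group_kfold(m, 4, seed=0)


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = [CP, UCLP, BCLP, CP]
        cm = confusion_matrix(y, y)
        assert np.array_equal(cm.counts, np.diag([2, 1, 1]))

    def test_all_predicted_cp_fills_one_column(self):
        cm = confusion_matrix([CP, UCLP, BCLP], [CP, CP, CP])
        assert cm.counts[:, 0].sum() == 3
        assert cm.counts[:, 1:].sum() == 0

    def test_trace_counts_agreements(self):
        rng = np.random.default_rng(0)
        t = rng.integers(0, 3, size=29)
        p = t.copy()
        p[:5] = (t[:5] + 1) % 3  # 24 agreements
        cm = confusion_matrix(t, p)
        assert np.trace(cm.counts) == 24
        assert cm.total == 29

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion_matrix([CP], [CP, CP])


class TestMetrics:
    def test_zero_everything_is_zero_by_convention(self):
        cm = confusion_matrix([UCLP], [BCLP])  # CP has TP=FP=FN=0
        with pytest.warns(UserWarning, match="zero denominator"):
            m = precision_recall_f1(cm, CP)
        assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)
        assert m.degenerate

    def test_equal_supports_make_macro_equal_weighted(self):
        t = [CP, CP, UCLP, UCLP, BCLP, BCLP]
        p = [CP, UCLP, UCLP, UCLP, BCLP, CP]
        rep = compute_metrics(t, p)
        assert rep.macro_f1 == pytest.approx(rep.weighted_f1)
        assert rep.macro_precision == pytest.approx(rep.weighted_precision)

    def test_micro_recall_identity_with_accuracy(self):
        rng = np.random.default_rng(5)
        t = rng.integers(0, 3, size=60)
        p = rng.integers(0, 3, size=60)
        cm = confusion_matrix(t, p)
        micro_recall = np.trace(cm.counts) / cm.counts.sum()
        rep = compute_metrics(t, p)
        assert rep.accuracy == pytest.approx(micro_recall)

    def test_agrees_with_sklearn_on_random_confusions(self):
        """Independent cross-check: 100 random prediction vectors scored by
        scikit-learn must match to 1e-12 in every reported figure."""
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(6, 80))
            t = rng.integers(0, 3, size=n)
            p = rng.integers(0, 3, size=n)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = compute_metrics(t, p)
                P, R, F, S = precision_recall_fscore_support(
                    t, p, labels=[0, 1, 2], zero_division=0
                )
                Pm, Rm, Fm, _ = precision_recall_fscore_support(
                    t, p, labels=[0, 1, 2], average="macro", zero_division=0
                )
                Pw, Rw, Fw, _ = precision_recall_fscore_support(
                    t, p, labels=[0, 1, 2], average="weighted", zero_division=0
                )
            for k, c in enumerate(CleftLabel):
                assert abs(rep.per_class[c].precision - P[k]) < 1e-12
                assert abs(rep.per_class[c].recall - R[k]) < 1e-12
                assert abs(rep.per_class[c].f1 - F[k]) < 1e-12
                assert rep.per_class[c].support == S[k]
            assert abs(rep.macro_f1 - Fm) < 1e-12
            assert abs(rep.weighted_f1 - Fw) < 1e-12
            assert abs(rep.macro_precision - Pm) < 1e-12
            assert abs(rep.weighted_recall - Rw) < 1e-12

    def test_zero_total_rejected(self):
        from cleftus.evaluate import ConfusionMatrix

        cm = ConfusionMatrix(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="zero"):
            aggregate_metrics({}, cm)


class TestRunCrossValidation:
    def test_two_fold_beats_chance_and_is_deterministic(self, small_manifest, small_chunks):
        cfg = TrainConfig(n_epochs=5, pairs_per_epoch=256, seed=1)
        results = [
            run_cross_validation(
                small_manifest,
                train_config=cfg,
                n_folds=2,
                seed=21,
                chunks=small_chunks,
            )
            for _ in range(2)
        ]
        assert results[0].pooled.accuracy > 1 / 3
        assert results[0].pooled.to_dict() == results[1].pooled.to_dict()
        for a, b in zip(results[0].predictions, results[1].predictions):
            assert a.predicted_label == b.predicted_label

    def test_no_participant_straddles_folds(self, small_manifest, small_chunks):
        cfg = TrainConfig(n_epochs=2, pairs_per_epoch=128, seed=1)
        res = run_cross_validation(
            small_manifest, train_config=cfg, n_folds=3, seed=5, chunks=small_chunks
        )
        seen = {}
        for p in res.predictions:
            fold = res.fold_assignment.fold_of_participant[p.participant_id]
            assert seen.setdefault(p.participant_id, fold) == fold
        # every out-of-fold unit is scored exactly once at participant level
        assert len(res.predictions) == len(small_manifest.participants)

    def test_untrainable_manifest_rejected(self):
        m = _manifest(2)  # no utterances
        with pytest.raises(ValueError, match="trainable"):
            run_cross_validation(m, n_folds=2, seed=0)
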