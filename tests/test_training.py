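"""Cross-validation, determinism and supervision contracts of training."""

import dataclasses

import numpy as np
import pytest

from mpkb.metrics import dsc
from mpkb.model import ModelConfig
from mpkb.training import (AXIAL_ONLY, MULTI_PLANAR, CrossValidatedEnsemble,
                           FoldEnsemble, KnowledgeBasedSegmenter, ScenarioSpec,
                           assign_folds, predict_ensemble, run_experiment)

from .conftest import TINY_NET

FAST = dict(TINY_NET, epochs=3, random_state=11)


class _NoPeeking(dict):
    """Mapping that refuses to serve non-axial masks."""

    def __getitem__(self, key):
        if key != "axial":
            raise AssertionError(f"non-axial mask {key!r} was read")
        return super().__getitem__(key)

    def get(self, key, default=None):
        if key != "axial":
            raise AssertionError(f"non-axial mask {key!r} was read")
        return super().get(key, default)


class TestFoldAssignment:
    def test_even_partition(self):
        ids = [f"e{i}" for i in range(10)]
        folds = assign_folds(ids, 5, seed=0)
        counts = np.bincount(list(folds.values()), minlength=5)
        assert counts.tolist() == [2] * 5

    def test_union_disjoint(self):
        ids = [f"e{i}" for i in range(13)]
        folds = assign_folds(ids, 5, seed=2)
        assert set(folds) == set(ids)  # every exam in exactly one fold

    def test_invariant_to_input_order(self, rng):
        ids = [f"exam-{i:03d}" for i in range(12)]
        shuffled = list(rng.permutation(ids))
        assert assign_folds(ids, 4, seed=9) == assign_folds(shuffled, 4, seed=9)

    def test_fewer_exams_than_folds_rejected(self, tiny_cohort):
        exams = [e for e, _ in tiny_cohort[:3]]
        with pytest.raises(ValueError, match="folds"):
            CrossValidatedEnsemble(KnowledgeBasedSegmenter(**FAST),
                                   folds=5).fit(exams)


class TestSegmenterFit:
    def test_zero_epochs_returns_initialization(self, tiny_cohort):
        est = KnowledgeBasedSegmenter(**dict(FAST, epochs=0))
        exams = [e for e, _ in tiny_cohort[:3]]
        est.fit(exams)
        from mpkb.model import build_model
        init = build_model(est.to_model_config())
        assert est.model_.state_checksum() == init.state_checksum()

    def test_same_seed_identical_history(self, tiny_cohort):
        exams = [e for e, _ in tiny_cohort[:4]]
        h1 = KnowledgeBasedSegmenter(**FAST).fit(exams).loss_history_
        h2 = KnowledgeBasedSegmenter(**FAST).fit(exams).loss_history_
        assert h1 == h2

    def test_training_reduces_dice_loss(self, tiny_cohort):
        exams = [e for e, _ in tiny_cohort]
        est = KnowledgeBasedSegmenter(**dict(FAST, epochs=6)).fit(exams)
        hist = est.loss_history_
        assert hist[-1]["dice"] < hist[0]["dice"]

    def test_missing_axial_mask_listed(self, tiny_cohort):
        exam = dataclasses.replace(tiny_cohort[0][0], axial_mask=None)
        with pytest.raises(ValueError, match=exam.exam_id):
            KnowledgeBasedSegmenter(**FAST).fit([exam])

    def test_kb_training_never_reads_non_axial_masks(self, tiny_cohort):
        exams = [dataclasses.replace(e, view_masks=_NoPeeking(e.view_masks))
                 for e, _ in tiny_cohort[:3]]
        KnowledgeBasedSegmenter(**FAST).fit(exams)  # must not trip the trap

    def test_fully_supervised_requires_view_masks(self, tiny_cohort):
        exam = dataclasses.replace(tiny_cohort[0][0], view_masks={})
        est = KnowledgeBasedSegmenter(**dict(FAST, fully_supervised=True))
        with pytest.raises(ValueError, match="fully supervised"):
            est.fit([exam])

    def test_fully_supervised_variant_trains(self, tiny_cohort):
        exams = [e for e, _ in tiny_cohort[:3]]
        est = KnowledgeBasedSegmenter(
            **dict(FAST, fully_supervised=True, epochs=2)).fit(exams)
        assert est.to_model_config().lambda_contrastive == 0.0
        assert len(est.loss_history_) == 2

    def test_sklearn_param_interface(self):
        est = KnowledgeBasedSegmenter(**FAST)
        params = est.get_params()
        assert params["lambda_contrastive"] == 0.25
        clone_params = KnowledgeBasedSegmenter().set_params(**params).get_params()
        assert clone_params == params


@pytest.fixture(scope="module")
def fitted(tiny_cohort):
    exams = [e for e, _ in tiny_cohort]
    return KnowledgeBasedSegmenter(**dict(FAST, epochs=6)).fit(exams)


class TestPrediction:
    def test_mask_on_axial_grid(self, fitted, tiny_cohort):
        exam = tiny_cohort[0][0]
        pred = fitted.predict([exam])[0]
        assert pred.shape == exam.axial_mask.shape
        assert pred.spacing == exam.axial_mask.spacing

    def test_axial_only_equals_views_deleted(self, fitted, tiny_cohort):
        exam = tiny_cohort[1][0]
        only_ax = fitted.predict_proba_volume(exam, views=("axial",))
        stripped = dataclasses.replace(
            exam, views={"axial": exam.views["axial"]}, view_masks={})
        deleted = fitted.predict_proba_volume(stripped)
        np.testing.assert_array_equal(only_ax, deleted)

    def test_learned_model_beats_untrained(self, fitted, tiny_cohort):
        exam = tiny_cohort[2][0]
        untrained = KnowledgeBasedSegmenter(**dict(FAST, epochs=0)).fit([exam])
        d_trained = dsc(fitted.predict([exam])[0], exam.axial_mask)
        d_init = dsc(untrained.predict([exam])[0], exam.axial_mask)
        assert d_trained > d_init


class TestEnsemble:
    def test_identical_members_equal_single_model(self, tiny_cohort):
        exams = [e for e, _ in tiny_cohort[:3]]
        member = KnowledgeBasedSegmenter(**FAST).fit(exams)
        ens = FoldEnsemble([member] * 5, member.to_model_config(),
                           {f"x{i}": i for i in range(5)})
        exam = tiny_cohort[3][0]
        combined = predict_ensemble(ens, exam, MULTI_PLANAR)
        single = member.predict([exam])[0]
        np.testing.assert_array_equal(combined.labels, single.labels)

    def test_scenario_ignores_extra_views(self, tiny_cohort):
        exams = [e for e, _ in tiny_cohort[:2]]
        member = KnowledgeBasedSegmenter(**FAST).fit(exams)
        ens = FoldEnsemble([member], member.to_model_config(), {"a": 0})
        exam = tiny_cohort[2][0]
        ax_only = predict_ensemble(ens, exam, AXIAL_ONLY)
        stripped = dataclasses.replace(
            exam, views={"axial": exam.views["axial"]}, view_masks={})
        np.testing.assert_array_equal(
            ax_only.labels, predict_ensemble(ens, stripped, AXIAL_ONLY).labels)

    def test_missing_scenario_view_rejected(self, tiny_cohort):
        exams = [e for e, _ in tiny_cohort[:2]]
        member = KnowledgeBasedSegmenter(**FAST).fit(exams)
        ens = FoldEnsemble([member], member.to_model_config(), {"a": 0})
        stripped = dataclasses.replace(
            tiny_cohort[2][0], views={"axial": tiny_cohort[2][0].views["axial"]},
            view_masks={})
        with pytest.raises(ValueError, match="lacks"):
            predict_ensemble(ens, stripped, MULTI_PLANAR)

    def test_out_of_fold_members_never_saw_their_exams(self, tiny_cohort):
        exams = [e for e, _ in tiny_cohort]
        cv = CrossValidatedEnsemble(KnowledgeBasedSegmenter(**FAST),
                                    folds=2, random_state=4).fit(exams)
        assert len(cv.members_) == 2
        # fold partition covers all exams exactly once
        assert set(cv.fold_assignments_) == {e.exam_id for e in exams}
        preds = cv.predict_out_of_fold(exams[:2])
        assert all(p.shape == e.axial_mask.shape
                   for p, e in zip(preds, exams[:2]))


class TestScenarioSpec:
    def test_axial_required(self):
        with pytest.raises(ValueError, match="axial"):
            ScenarioSpec(("sagittal",), "bad")


class TestRunExperiment:
    def test_reports_per_variant_and_scenario(self, tiny_cohort, tmp_path):
        cfg = ModelConfig(**TINY_NET, epochs=2, folds=2, seed=0)
        train, test = tiny_cohort[:4], tiny_cohort[4:]  # 6 held-out exams
        reports = run_experiment(train, test, cfg,
                                 [MULTI_PLANAR, AXIAL_ONLY], seed=21,
                                 variants=("kb", "baseline"),
                                 out_dir=tmp_path)
        assert set(reports) == {("kb", "multi_planar"), ("kb", "axial_only"),
                                ("baseline", "multi_planar"),
                                ("baseline", "axial_only")}
        assert (tmp_path / "per_case.csv").exists()
        assert (tmp_path / "summary.csv").exists()
        rep = reports[("kb", "multi_planar")]
        assert len(rep.results) == len(test)
        assert rep.icc.category in ("poor", "moderate", "good", "excellent")

    def test_empty_cohort_rejected(self, tiny_cohort):
        cfg = ModelConfig(**TINY_NET, epochs=1, folds=2, seed=0)
        with pytest.raises(ValueError, match="empty"):
            run_experiment([], tiny_cohort[:1], cfg, [AXIAL_ONLY], seed=0)
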