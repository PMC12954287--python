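"""Cross-validated training, ensemble inference and scenario experiments.

The trainable objects are scikit-learn style estimators:

* :class:`KnowledgeBasedSegmenter` — one network trained with axial-only
  supervision plus the cosine alignment terms (or, with
  ``fully_supervised=True``, the reference variant supervised on all views
  through the weight-tied decoder, with the alignment weight forced to 0).
* :class:`CrossValidatedEnsemble` — exam-level k-fold cross-validation
  producing one fitted member per fold; inference averages the members'
  per-pixel probabilities before thresholding.

Module-level functions (``train_fold``, ``train_cv``, ``predict_ensemble``,
``run_experiment``) are thin wrappers over the estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, clone

from .agreement import AgreementReport, VolumetryResult, build_agreement_report
from .exam import MultiPlanarExam
from .image import SegmentationMask, normalize_intensity
from .losses import (cosine_alignment_loss, infonce_alignment_loss,
                     kb_total_loss, segmentation_loss_from_logits)
from .metrics import asd, dsc, ellipsoid_formula_volume, mask_volume, rvd
from .model import ModelConfig, build_model
from .nn import SGD
from .nn.autograd import Tensor


@dataclass(frozen=True)
class ScenarioSpec:
    """Plane availability at inference; the axial view is always required."""

    views_at_inference: tuple[str, ...] = ("axial", "sagittal", "coronal")
    name: str = "multi_planar"

    def __post_init__(self) -> None:
        if "axial" not in self.views_at_inference:
            raise ValueError("axial must be part of views_at_inference")


MULTI_PLANAR = ScenarioSpec(("axial", "sagittal", "coronal"), "multi_planar")
AXIAL_ONLY = ScenarioSpec(("axial",), "axial_only")


def _resize_stack(vol3d: np.ndarray, size: int, order: int) -> np.ndarray:
    """(H, W, S) -> (S, size, size) with per-slice in-plane resizing."""
    h, w, s = vol3d.shape
    moved = np.moveaxis(vol3d, -1, 0).astype(np.float32)
    return ndimage.zoom(moved, (1, size / h, size / w), order=order,
                        mode="nearest", grid_mode=True, prefilter=order > 1)


def _central_indices(n: int) -> np.ndarray:
    lo, hi = n // 4, max(n // 4 + 1, (3 * n) // 4)
    return np.arange(lo, min(hi, n))


class KnowledgeBasedSegmenter(BaseEstimator):
    """2D multi-planar segmentation model trained with axial supervision.

    Parameters mirror :class:`~mpkb.model.ModelConfig`.  ``lambda_contrastive``
    weighs the axial<->sagittal and axial<->coronal cosine alignment terms
    (0 disables them); ``fully_supervised=True`` instead supervises every
    available view through the shared decoder (the reference-model variant)
    and forces the alignment weight to 0.

    Fitted attributes: ``model_`` (the network), ``loss_history_`` (one dict
    of mean loss terms per epoch), ``n_params_``.
    """

    def __init__(self, encoder_depth: int = 3, base_channels: int = 6,
                 latent_dim: int = 32, in_plane_size: int = 64,
                 lambda_contrastive: float = 0.25, learning_rate: float = 0.01,
                 momentum: float = 0.99, epochs: int = 20,
                 slices_per_step: int = 4, contrastive_mode: str = "align",
                 infonce_temperature: float = 0.1, dice_eps: float = 1e-5,
                 fully_supervised: bool = False, random_state: int = 0):
        self.encoder_depth = encoder_depth
        self.base_channels = base_channels
        self.latent_dim = latent_dim
        self.in_plane_size = in_plane_size
        self.lambda_contrastive = lambda_contrastive
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.epochs = epochs
        self.slices_per_step = slices_per_step
        self.contrastive_mode = contrastive_mode
        self.infonce_temperature = infonce_temperature
        self.dice_eps = dice_eps
        self.fully_supervised = fully_supervised
        self.random_state = random_state

    # -- configuration --------------------------------------------------------
    def to_model_config(self) -> ModelConfig:
        return ModelConfig(
            encoder_depth=self.encoder_depth, base_channels=self.base_channels,
            latent_dim=self.latent_dim, in_plane_size=self.in_plane_size,
            lambda_contrastive=0.0 if self.fully_supervised else self.lambda_contrastive,
            learning_rate=self.learning_rate, momentum=self.momentum,
            epochs=self.epochs, slices_per_step=self.slices_per_step,
            contrastive_mode=self.contrastive_mode,
            infonce_temperature=self.infonce_temperature,
            dice_eps=self.dice_eps, seed=self.random_state)

    # -- data preparation ------------------------------------------------------
    def _prepare_exam(self, exam: MultiPlanarExam,
                      axial_mask: SegmentationMask | None) -> dict:
        size = self.in_plane_size
        prep: dict = {"id": exam.exam_id, "imgs": {}, "targets": {}}
        for view in exam.views_present:
            vol = normalize_intensity(exam.views[view])
            prep["imgs"][view] = _resize_stack(vol.intensities, size, order=1)[:, None]
        mask = axial_mask if axial_mask is not None else exam.axial_mask
        if mask is None:
            raise ValueError(f"exam {exam.exam_id} has no axial training mask")
        prep["targets"]["axial"] = (
            _resize_stack(mask.labels.astype(np.float32), size, order=1) >= 0.5
        ).astype(np.float32)[:, None]
        if self.fully_supervised:
            # the reference variant additionally reads the non-axial masks
            for view in exam.views_present:
                if view == "axial":
                    continue
                vm = exam.view_masks.get(view)
                if vm is None:
                    raise ValueError(f"exam {exam.exam_id} lacks a {view} mask "
                                     "required for fully supervised training")
                prep["targets"][view] = (
                    _resize_stack(vm.labels.astype(np.float32), size, order=1) >= 0.5
                ).astype(np.float32)[:, None]
        return prep

    # -- training --------------------------------------------------------------
    def fit(self, X, y=None):
        exams: list[MultiPlanarExam] = list(X)
        if not exams:
            raise ValueError("cannot fit on an empty list of exams")
        masks = list(y) if y is not None else [None] * len(exams)
        missing = [e.exam_id for e, m in zip(exams, masks)
                   if m is None and e.axial_mask is None]
        if missing:
            raise ValueError(f"exams missing axial masks: {missing}")
        cfg = self.to_model_config()
        self.model_ = build_model(cfg)
        self.n_params_ = self.model_.n_parameters()
        prepared = [self._prepare_exam(e, m) for e, m in zip(exams, masks)]
        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.random_state), 13]))
        opt = SGD(self.model_.parameters(), lr=self.learning_rate,
                  momentum=self.momentum, nesterov=True)
        total_steps = max(1, self.epochs * len(prepared))
        lam = cfg.lambda_contrastive
        self.loss_history_ = []
        step = 0
        for _epoch in range(self.epochs):
            order = rng.permutation(len(prepared))
            epoch_bundles = []
            for idx in order:
                opt.lr = self.learning_rate * (1.0 - step / total_steps) ** 0.9
                bundle = self._train_step(prepared[idx], opt, rng, lam)
                epoch_bundles.append(bundle)
                step += 1
            self.loss_history_.append(self._mean_bundle(epoch_bundles))
        return self

    @staticmethod
    def _mean_bundle(bundles) -> dict:
        keys = ("dice", "ce", "con_ax_sag", "con_ax_cor", "total")
        out = {}
        for k in keys:
            vals = [b.as_dict()[k] for b in bundles if b.as_dict()[k] is not None]
            out[k] = float(np.mean(vals)) if vals else None
        return out

    def _alignment(self, z_ax, z_ctx):
        if self.contrastive_mode == "infonce":
            return infonce_alignment_loss(z_ax, z_ctx, self.infonce_temperature)
        return cosine_alignment_loss(z_ax, z_ctx)

    def _train_step(self, prep: dict, opt: SGD, rng, lam: float):
        model = self.model_
        k = self.slices_per_step
        ax = prep["imgs"]["axial"]
        n_ax = ax.shape[0]
        idx = rng.choice(n_ax, size=min(k, n_ax), replace=False)
        ax_batch = Tensor(ax[idx])
        targets = prep["targets"]["axial"][idx]

        ctx_latents, con_terms = [], {}
        for view in ("sagittal", "coronal"):
            if view not in prep["imgs"]:
                continue
            stack = prep["imgs"][view]
            central = _central_indices(stack.shape[0])
            j = rng.choice(central, size=1)
            z_ctx = model.encode(stack[j])
            ctx_latents.append(z_ctx)
            con_terms[view] = z_ctx

        logits, z_ax = model.forward_logits(ax_batch, ctx_latents)
        seg = segmentation_loss_from_logits(logits, targets, eps=self.dice_eps)
        con_sag = con_cor = None
        if lam > 0:
            if "sagittal" in con_terms:
                con_sag = self._alignment(z_ax, con_terms["sagittal"])
            if "coronal" in con_terms:
                con_cor = self._alignment(z_ax, con_terms["coronal"])
        total, bundle = kb_total_loss(seg, con_sag, con_cor, lam)

        if self.fully_supervised:
            for view in ("sagittal", "coronal"):
                if view not in prep["targets"]:
                    continue
                stack = prep["imgs"][view]
                n_v = stack.shape[0]
                jv = rng.choice(n_v, size=min(k, n_v), replace=False)
                logits_v, _ = model.forward_logits(Tensor(stack[jv]), None)
                d_v, c_v = segmentation_loss_from_logits(
                    logits_v, prep["targets"][view][jv], eps=self.dice_eps)
                total = total + d_v + c_v

        if self.epochs > 0:
            opt.zero_grad()
            total.backward()
            opt.step()
        return bundle

    # -- inference ---------------------------------------------------------------
    def _context_latents(self, exam: MultiPlanarExam,
                         views: tuple[str, ...]) -> list[Tensor]:
        latents = []
        for view in views:
            if view == "axial":
                continue
            if view not in exam.views:
                raise ValueError(f"exam {exam.exam_id} lacks requested view {view!r}")
            vol = normalize_intensity(exam.views[view])
            stack = _resize_stack(vol.intensities, self.in_plane_size, order=1)[:, None]
            central = _central_indices(stack.shape[0])
            z = self.model_.encode(stack[central])
            latents.append(Tensor(z.data.mean(axis=0, keepdims=True)))
        return latents

    def predict_proba_volume(self, exam: MultiPlanarExam,
                             views: tuple[str, ...] | None = None,
                             batch_slices: int = 8) -> np.ndarray:
        """Foreground probabilities on the exam's axial grid."""
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        views = tuple(views) if views is not None else exam.views_present
        if "axial" not in views:
            raise ValueError("axial view is required at inference")
        ctx = self._context_latents(exam, views)
        axial = exam.views["axial"]
        vol = normalize_intensity(axial)
        stack = _resize_stack(vol.intensities, self.in_plane_size, order=1)[:, None]
        probs = []
        for lo in range(0, stack.shape[0], batch_slices):
            logits, _ = self.model_.forward_logits(
                Tensor(stack[lo:lo + batch_slices]), ctx)
            x = logits.data
            probs.append(1.0 / (1.0 + np.exp(-x)))
        p = np.concatenate(probs, axis=0)[:, 0]          # (S, size, size)
        h, w, _ = axial.intensities.shape
        p_full = ndimage.zoom(p, (1, h / p.shape[1], w / p.shape[2]), order=1,
                              mode="nearest", grid_mode=True, prefilter=False)
        return np.moveaxis(p_full, 0, -1)                 # (H, W, S)

    def predict(self, X, views: tuple[str, ...] | None = None
                ) -> list[SegmentationMask]:
        out = []
        for exam in X:
            p = self.predict_proba_volume(exam, views)
            ax = exam.views["axial"]
            out.append(SegmentationMask((p >= 0.5).astype(np.uint8), ax.spacing,
                                        ax.origin, ax.axis_labels))
        return out


@dataclass
class FoldEnsemble:
    """One fitted member per cross-validation fold plus the exam->fold map."""

    members: list[KnowledgeBasedSegmenter]
    cfg: ModelConfig
    fold_assignments: dict[str, int]

    def __post_init__(self) -> None:
        folds = set(self.fold_assignments.values())
        if len(self.members) != len(folds):
            raise ValueError("members must match the number of folds")


def assign_folds(exam_ids: list[str], folds: int, seed: int) -> dict[str, int]:
    """Reproducible exam-level fold assignment, invariant to input order."""
    ids = sorted(exam_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("exam ids must be unique")
    perm = np.random.default_rng(
        np.random.SeedSequence([int(seed), 3])).permutation(len(ids))
    return {eid: int(perm[rank] % folds) for rank, eid in enumerate(ids)}


class CrossValidatedEnsemble(BaseEstimator):
    """Exam-level k-fold cross-validation ensemble.

    ``fit`` partitions exams into ``folds`` disjoint groups (reproducibly
    from ``random_state`` and the sorted exam ids, so shuffling the input
    order does not change membership), trains one member per fold on the
    exams outside it, and exposes probability-averaged ensemble prediction.
    """

    def __init__(self, estimator: KnowledgeBasedSegmenter | None = None,
                 folds: int = 5, random_state: int = 0):
        self.estimator = estimator
        self.folds = folds
        self.random_state = random_state

    def fit(self, X, y=None):
        exams = list(X)
        if len(exams) < self.folds:
            raise ValueError(f"need at least folds={self.folds} exams, "
                             f"got {len(exams)}")
        proto = self.estimator if self.estimator is not None \
            else KnowledgeBasedSegmenter()
        self.fold_assignments_ = assign_folds([e.exam_id for e in exams],
                                              self.folds, self.random_state)
        self.members_ = []
        for fold in range(self.folds):
            train = [e for e in exams if self.fold_assignments_[e.exam_id] != fold]
            member = clone(proto)
            member.set_params(random_state=int(
                np.random.SeedSequence([int(self.random_state), 41, fold])
                .generate_state(1)[0] % (2**31 - 1)))
            member.fit(train)
            self.members_.append(member)
        self.ensemble_ = FoldEnsemble(self.members_, proto.to_model_config(),
                                      self.fold_assignments_)
        return self

    def predict_proba_volume(self, exam: MultiPlanarExam,
                             views: tuple[str, ...] | None = None) -> np.ndarray:
        probs = [m.predict_proba_volume(exam, views) for m in self.members_]
        return np.mean(probs, axis=0)

    def predict(self, X, views: tuple[str, ...] | None = None
                ) -> list[SegmentationMask]:
        out = []
        for exam in X:
            p = self.predict_proba_volume(exam, views)
            ax = exam.views["axial"]
            out.append(SegmentationMask((p >= 0.5).astype(np.uint8), ax.spacing,
                                        ax.origin, ax.axis_labels))
        return out

    def predict_out_of_fold(self, X) -> list[SegmentationMask]:
        """Single-member predictions from the fold that held each exam out."""
        out = []
        for exam in X:
            fold = self.fold_assignments_.get(exam.exam_id)
            if fold is None:
                raise ValueError(f"exam {exam.exam_id} was not part of fit()")
            member = self.members_[fold]
            p = member.predict_proba_volume(exam)
            ax = exam.views["axial"]
            out.append(SegmentationMask((p >= 0.5).astype(np.uint8), ax.spacing,
                                        ax.origin, ax.axis_labels))
        return out


# ---------------------------------------------------------------------------
# thin functional wrappers

def _estimator_from_config(cfg: ModelConfig, seed: int,
                           fully_supervised: bool = False
                           ) -> KnowledgeBasedSegmenter:
    return KnowledgeBasedSegmenter(
        encoder_depth=cfg.encoder_depth, base_channels=cfg.base_channels,
        latent_dim=cfg.latent_dim, in_plane_size=cfg.in_plane_size,
        lambda_contrastive=cfg.lambda_contrastive,
        learning_rate=cfg.learning_rate, momentum=cfg.momentum,
        epochs=cfg.epochs, slices_per_step=cfg.slices_per_step,
        contrastive_mode=cfg.contrastive_mode,
        infonce_temperature=cfg.infonce_temperature, dice_eps=cfg.dice_eps,
        fully_supervised=fully_supervised, random_state=int(seed))


def train_fold(train_exams, cfg: ModelConfig, fold_idx: int, seed: int,
               fully_supervised: bool = False) -> KnowledgeBasedSegmenter:
    member_seed = int(np.random.SeedSequence([int(seed), 41, int(fold_idx)])
                      .generate_state(1)[0] % (2**31 - 1))
    est = _estimator_from_config(cfg, member_seed, fully_supervised)
    return est.fit(train_exams)


def train_cv(exams, cfg: ModelConfig, seed: int,
             fully_supervised: bool = False) -> FoldEnsemble:
    proto = _estimator_from_config(cfg, seed, fully_supervised)
    cv = CrossValidatedEnsemble(proto, folds=cfg.folds, random_state=int(seed))
    cv.fit(exams)
    return cv.ensemble_


def predict_ensemble(ens: FoldEnsemble, exam: MultiPlanarExam,
                     scenario: ScenarioSpec) -> SegmentationMask:
    """Probability-averaged, 0.5-thresholded ensemble mask on the axial grid.

    Views outside the scenario are ignored even if the exam provides them;
    a scenario view the exam lacks raises an availability error.
    """
    for view in scenario.views_at_inference:
        if view not in exam.views:
            raise ValueError(f"scenario {scenario.name!r} requests view {view!r} "
                             f"that exam {exam.exam_id} lacks")
    probs = [m.predict_proba_volume(exam, scenario.views_at_inference)
             for m in ens.members]
    p = np.mean(probs, axis=0)
    ax = exam.views["axial"]
    return SegmentationMask((p >= 0.5).astype(np.uint8), ax.spacing, ax.origin,
                            ax.axis_labels)


def evaluate_cohort(ens: FoldEnsemble, cohort, scenario: ScenarioSpec,
                    model_label: str) -> AgreementReport:
    """Per-exam DSC/ASD/RVD/PV against the exam's ground truth, aggregated
    into an agreement report.  The reference volume is the ellipsoid-formula
    volume from the ground-truth diameters (the reference-standard role),
    kept independent of the segmentation under test."""
    if not cohort:
        raise ValueError("empty cohort")
    results = []
    for exam, gt in cohort:
        pred = predict_ensemble(ens, exam, scenario)
        ref = exam.axial_mask
        pv_pred = mask_volume(pred)
        pv_ref = ellipsoid_formula_volume(*gt.ellipsoid_diameters_mm)
        results.append(VolumetryResult(
            exam_id=exam.exam_id, pv_pred_ml=pv_pred, pv_ref_ml=pv_ref,
            rvd_percent=rvd(pv_pred, pv_ref), dsc=dsc(pred, ref),
            asd_mm=asd(pred, ref) if pred.labels.any() else float("inf")))
    return build_agreement_report(scenario.name, model_label, results)


def run_experiment(train_cohort, test_cohort, cfg: ModelConfig,
                   scenarios: list[ScenarioSpec], seed: int,
                   variants: tuple[str, ...] = ("kb", "baseline"),
                   out_dir=None) -> dict[tuple[str, str], AgreementReport]:
    """Train the requested model variants and evaluate them per scenario.

    ``train_cohort``/``test_cohort`` are lists of (exam, ground-truth) pairs;
    only the exams are used for training.  Returns
    ``{(variant, scenario_name): AgreementReport}`` and, when ``out_dir`` is
    given, writes per-case and summary CSV tables.
    """
    if not train_cohort or not test_cohort:
        raise ValueError("empty cohort")
    train_exams = [exam for exam, _ in train_cohort]
    reports: dict[tuple[str, str], AgreementReport] = {}
    for variant in variants:
        if variant not in ("kb", "baseline"):
            raise ValueError(f"unknown variant {variant!r}")
        ens = train_cv(train_exams, cfg, seed,
                       fully_supervised=(variant == "baseline"))
        for scenario in scenarios:
            reports[(variant, scenario.name)] = evaluate_cohort(
                ens, test_cohort, scenario, variant)
    if out_dir is not None:
        write_report_tables(reports, out_dir)
    return reports


def summarize_reports(reports: dict[tuple[str, str], AgreementReport]
                      ) -> pd.DataFrame:
    rows = [rep.summary() for rep in reports.values()]
    df = pd.DataFrame(rows)
    # paired cross-variant comparison per scenario (KB vs baseline), matching
    # the usual two-model comparison tables
    from .agreement import paired_compare
    extra = []
    scen_names = {s for (_v, s) in reports}
    for scen in sorted(scen_names):
        kb = reports.get(("kb", scen))
        base = reports.get(("baseline", scen))
        if kb is None or base is None:
            continue
        for metric, get in (("dsc", lambda r: r.dsc),
                            ("rvd_percent", lambda r: r.rvd_percent),
                            ("pv_pred_ml", lambda r: r.pv_pred_ml)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p, test = paired_compare([get(r) for r in kb.results],
                                         [get(r) for r in base.results])
            extra.append({"scenario": scen, "metric": metric,
                          "p_kb_vs_baseline": p, "test_used": test})
    df.attrs["cross_variant_tests"] = pd.DataFrame(extra)
    return df


def write_report_tables(reports, out_dir) -> None:
    from pathlib import Path
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_case = pd.concat([rep.per_case_frame() for rep in reports.values()],
                         ignore_index=True)
    per_case.to_csv(out_dir / "per_case.csv", index=False, float_format="%.8f")
    summary = summarize_reports(reports)
    summary.to_csv(out_dir / "summary.csv", index=False, float_format="%.8f")
    tests = summary.attrs.get("cross_variant_tests")
    if tests is not None and len(tests):
        tests.to_csv(out_dir / "cross_variant_tests.csv", index=False,
                     float_format="%.8f")
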