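"""The per-subject exam container shared by simulation, training and evaluation."""

from __future__ import annotations

from dataclasses import dataclass, field

from .image import SegmentationMask, VolumeImage

VIEWS = ("axial", "sagittal", "coronal")


@dataclass
class MultiPlanarExam:
    """One subject's multi-planar T2w-like study.

    ``views`` maps view name -> volume sliced in that view (any subset of
    axial/sagittal/coronal that contains ``axial``, the canonical plane).
    ``axial_mask`` is the whole-gland training mask on the axial grid.
    ``view_masks`` optionally carries ground-truth masks resliced to the
    sagittal/coronal grids; only the fully supervised reference model reads
    them — the knowledge-based training path never does.
    """

    exam_id: str
    views: dict[str, VolumeImage]
    axial_mask: SegmentationMask | None = None
    pv_ref_ml: float | None = None
    view_masks: dict[str, SegmentationMask] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.views) - set(VIEWS)
        if unknown:
            raise ValueError(f"exam {self.exam_id}: unknown views {sorted(unknown)}")
        if "axial" not in self.views:
            raise ValueError(f"exam {self.exam_id}: the axial view is required "
                             "(canonical plane)")

    @property
    def views_present(self) -> tuple[str, ...]:
        return tuple(v for v in VIEWS if v in self.views)
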