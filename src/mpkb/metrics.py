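"""Segmentation and volumetry metrics: mask volume, ellipsoid-formula volume,
Dice overlap, average surface distance, relative volume difference."""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .image import SegmentationMask

log = logging.getLogger(__name__)


def mask_volume(mask: SegmentationMask) -> float:
    """Volume enclosed by a binary mask in ml (voxel count x voxel volume)."""
    if not isinstance(mask, SegmentationMask):
        raise TypeError("mask_volume expects a SegmentationMask with spacing")
    return float(mask.labels.sum() * mask.voxel_volume_mm3() / 1000.0)


def ellipsoid_formula_volume(w_mm: float, h_mm: float, l_mm: float) -> float:
    """PI-RADS 2.1 ellipsoid-formula volume pi/6 * W * H * L in ml.

    W, H, L are the three orthogonal maximal diameters (mm); the formula is
    symmetric in its arguments.
    """
    for name, v in (("w_mm", w_mm), ("h_mm", h_mm), ("l_mm", l_mm)):
        if not v > 0:
            raise ValueError(f"diameter {name} must be positive, got {v}")
    lo, mid, hi = sorted((w_mm, h_mm, l_mm))  # exact permutation invariance
    return float(np.pi / 6.0 * lo * mid * hi / 1000.0)


def _check_same_grid(pred: SegmentationMask, ref: SegmentationMask) -> None:
    if pred.shape != ref.shape:
        raise ValueError(f"grid mismatch: pred {pred.shape} vs ref {ref.shape}")
    if not np.allclose(pred.spacing, ref.spacing):
        raise ValueError(f"spacing mismatch: {pred.spacing} vs {ref.spacing}")


def dsc(pred: SegmentationMask, ref: SegmentationMask) -> float:
    """Dice score coefficient 2|A n B| / (|A| + |B|).

    Both-empty masks score 1.0 by convention (logged); empty-vs-nonempty is 0.
    """
    _check_same_grid(pred, ref)
    a = pred.labels.astype(bool)
    b = ref.labels.astype(bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        log.info("dsc: both masks empty; returning 1.0 by convention")
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """6-connectivity boundary voxels of a binary mask."""
    structure = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


def asd(pred: SegmentationMask, ref: SegmentationMask) -> float:
    """Symmetric average surface distance in mm.

    Surfaces are the 6-connectivity boundary voxel sets; distances are
    physical (spacing-aware) nearest-surface distances, and the two
    directional means (pred->ref, ref->pred) are averaged.
    """
    _check_same_grid(pred, ref)
    a = pred.labels.astype(bool)
    b = ref.labels.astype(bool)
    if not a.any():
        raise ValueError("asd undefined: predicted mask is empty")
    if not b.any():
        raise ValueError("asd undefined: reference mask is empty")
    surf_a = _surface_voxels(a)
    surf_b = _surface_voxels(b)
    spacing = pred.spacing
    dist_to_b = ndimage.distance_transform_edt(~surf_b, sampling=spacing)
    dist_to_a = ndimage.distance_transform_edt(~surf_a, sampling=spacing)
    d_ab = dist_to_b[surf_a]
    d_ba = dist_to_a[surf_b]
    return float(0.5 * (d_ab.mean() + d_ba.mean()))


def rvd(pv_pred_ml: float, pv_ref_ml: float) -> float:
    """Signed relative volume difference in percent.

    Negative values reflect underestimation of the reference volume,
    positive values overestimation.
    """
    if not pv_ref_ml > 0:
        raise ValueError(f"reference volume must be positive, got {pv_ref_ml}")
    return 100.0 * (pv_pred_ml - pv_ref_ml) / pv_ref_ml
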