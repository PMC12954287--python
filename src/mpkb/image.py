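"""Volume containers, NIfTI I/O and T2w-style preprocessing.

Conventions used throughout the package
---------------------------------------
* A volume is a 3D array plus per-axis voxel spacing (mm) and a physical
  origin (mm).  Voxel indices are 0-based; the physical coordinate of voxel
  ``(i, j, k)`` is ``origin + index * spacing`` along each array axis.
* ``axis_labels`` names the anatomical axis that each *array axis* runs
  along: ``"sagittal"`` (left-right), ``"coronal"`` (anterior-posterior),
  ``"axial"`` (inferior-superior).  A view named V slices perpendicular to
  the axis labelled V, and :func:`reslice_view` permutes axes so that this
  slicing axis comes last.
* On disk, volumes are NIfTI-1 with an RAS affine built from spacing,
  origin and the axis labels (sagittal axis -> x, coronal -> y, axial -> z).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

ANATOMICAL_AXES = ("sagittal", "coronal", "axial")

#: array-axis order (which anatomical axis each array axis runs along) for
#: a stack sliced in the given view; the slicing axis is always last.
VIEW_AXIS_ORDER = {
    "axial": ("sagittal", "coronal", "axial"),
    "sagittal": ("coronal", "axial", "sagittal"),
    "coronal": ("sagittal", "axial", "coronal"),
}

# NIfTI axis codes -> anatomical axis label (direction sign is not retained;
# spacing is stored positive and the label records orientation only).
_AXCODE_TO_LABEL = {"R": "sagittal", "L": "sagittal",
                    "A": "coronal", "P": "coronal",
                    "S": "axial", "I": "axial"}
_LABEL_TO_RAS_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the expected image format."""


@dataclass
class VolumeImage:
    """3D intensity grid with physical metadata."""

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_labels: tuple[str, str, str] = ANATOMICAL_AXES

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.intensities.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.axis_labels = tuple(self.axis_labels)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if sorted(self.axis_labels) != sorted(ANATOMICAL_AXES):
            raise ValueError(f"axis_labels must be a permutation of {ANATOMICAL_AXES}, "
                             f"got {self.axis_labels}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def copy_with(self, **kw) -> "VolumeImage":
        return replace(self, **kw)


@dataclass
class SegmentationMask:
    """Binary label grid sharing the metadata conventions of VolumeImage."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_labels: tuple[str, str, str] = ANATOMICAL_AXES

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"mask values must be in {{0,1}}, got {uniq[:10]}")
        self.labels = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.axis_labels = tuple(self.axis_labels)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if sorted(self.axis_labels) != sorted(ANATOMICAL_AXES):
            raise ValueError(f"axis_labels must be a permutation of {ANATOMICAL_AXES}, "
                             f"got {self.axis_labels}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def copy_with(self, **kw) -> "SegmentationMask":
        return replace(self, **kw)


def _grid_of(obj):
    return obj.intensities if isinstance(obj, VolumeImage) else obj.labels


def _affine_from_metadata(spacing, origin, axis_labels) -> np.ndarray:
    aff = np.zeros((4, 4))
    aff[3, 3] = 1.0
    for array_axis, label in enumerate(axis_labels):
        ras = _LABEL_TO_RAS_AXIS[label]
        aff[ras, array_axis] = spacing[array_axis]
        aff[ras, 3] = origin[array_axis]
    return aff


def write_volume(vol: VolumeImage | SegmentationMask, path: str | Path) -> None:
    """Write a volume or mask to a NIfTI-1 file (.nii or .nii.gz)."""
    arr = _grid_of(vol)
    if isinstance(vol, SegmentationMask):
        data = arr.astype(np.uint8)
    else:
        data = np.asarray(arr, dtype=np.float32)
    aff = _affine_from_metadata(vol.spacing, vol.origin, vol.axis_labels)
    img = nib.Nifti1Image(data, aff)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI file into a :class:`VolumeImage`.

    ``axis_labels`` are derived from the header orientation codes, so files
    with flipped or permuted axes report the anatomical axis each array axis
    runs along.  Spacing is always positive.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
        affine = img.affine
    except Exception as exc:  # nibabel raises several error types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    axcodes = nib.aff2axcodes(affine)
    labels = tuple(_AXCODE_TO_LABEL[c] for c in axcodes)
    if sorted(labels) != sorted(ANATOMICAL_AXES):
        raise FormatError(f"{path}: degenerate orientation {axcodes}")
    spacing = tuple(float(abs(z)) for z in img.header.get_zooms()[:3])
    origin = tuple(float(affine[_LABEL_TO_RAS_AXIS[l], 3]) for l in labels)
    return VolumeImage(data, spacing, origin, labels)


def read_mask(path: str | Path) -> SegmentationMask:
    v = read_volume(path)
    return SegmentationMask(np.rint(v.intensities).astype(np.uint8),
                            v.spacing, v.origin, v.axis_labels)


def normalize_intensity(v: VolumeImage,
                        clip_percentiles: tuple[float, float] = (0.5, 99.5)
                        ) -> VolumeImage:
    """Percentile-clipped per-volume z-score normalization.

    Intensities are clipped to the ``clip_percentiles`` band and then
    standardized to zero mean / unit SD over the clipped volume.  The mapping
    is monotone non-decreasing and invariant to positive affine rescaling of
    the input.
    """
    lo_p, hi_p = clip_percentiles
    data = np.asarray(v.intensities, dtype=np.float64)
    if np.unique(data).size < 2:
        raise ValueError("cannot normalize a constant image (undefined SD)")
    lo, hi = np.percentile(data, [lo_p, hi_p])
    clipped = np.clip(data, lo, hi)
    sd = clipped.std()
    if sd == 0:
        raise ValueError("image is constant after percentile clipping")
    out = (clipped - clipped.mean()) / sd
    return v.copy_with(intensities=out.astype(np.float32))


def _resample_grid(data: np.ndarray, spacing, target_spacing, order: int) -> np.ndarray:
    factors, eff_orders = [], []
    for ax in range(3):
        n_out = max(1, int(round(data.shape[ax] * spacing[ax] / target_spacing[ax])))
        factors.append(n_out / data.shape[ax])
        o = order
        if data.shape[ax] == 1 and order > 1:
            o = 1
            log.warning("degenerate single-slice axis %d: falling back to linear "
                        "interpolation", ax)
        eff_orders.append(o)
    order_eff = min(eff_orders)
    if order_eff != order:
        log.warning("resampling with interpolation order %d instead of %d "
                    "(degenerate axis)", order_eff, order)
    out = ndimage.zoom(data.astype(np.float32), factors, order=order_eff,
                       mode="nearest", grid_mode=True, prefilter=order_eff > 1)
    return out


def resample_to_reference(obj: VolumeImage | SegmentationMask,
                          target_spacing: tuple[float, float, float],
                          image_order: int = 3):
    """Resample a volume or mask to ``target_spacing`` (mm, per array axis).

    Images use third-order spline interpolation; masks use linear
    interpolation followed by a 0.5 threshold, returning a binary mask.
    The physical field of view is preserved to within one voxel per axis,
    and the origin is shifted to the new first-voxel centre so physical
    coordinates stay consistent across resolutions.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    # edge-aligned resampling: the field of view is kept, so the first voxel
    # centre moves by (s_new - s_old) / 2 along each axis
    origin = tuple(o - s_old / 2.0 + s_new / 2.0
                   for o, s_old, s_new in zip(obj.origin, obj.spacing,
                                              target_spacing))
    if isinstance(obj, SegmentationMask):
        out = _resample_grid(obj.labels, obj.spacing, target_spacing, order=1)
        return obj.copy_with(labels=(out >= 0.5).astype(np.uint8),
                             spacing=target_spacing, origin=origin)
    out = _resample_grid(obj.intensities, obj.spacing, target_spacing,
                         order=image_order)
    return obj.copy_with(intensities=out, spacing=target_spacing, origin=origin)


def resample_onto(obj: VolumeImage | SegmentationMask,
                  reference: VolumeImage | SegmentationMask,
                  image_order: int = 3):
    """Resample ``obj`` onto the exact grid of ``reference`` (same anatomical
    axis order, shape, spacing and origin), honouring physical coordinates.

    Masks use linear interpolation with a 0.5 threshold; images use spline
    interpolation of the requested order.
    """
    perm = tuple(obj.axis_labels.index(lbl) for lbl in reference.axis_labels)
    grid = np.transpose(_grid_of(obj), perm).astype(np.float32)
    spacing = tuple(obj.spacing[p] for p in perm)
    origin = tuple(obj.origin[p] for p in perm)
    coords = np.meshgrid(*[
        (reference.origin[ax] + np.arange(reference.shape[ax])
         * reference.spacing[ax] - origin[ax]) / spacing[ax]
        for ax in range(3)], indexing="ij", sparse=True)
    is_mask = isinstance(obj, SegmentationMask)
    order = 1 if is_mask else image_order
    out = ndimage.map_coordinates(grid, np.broadcast_arrays(*coords),
                                  order=order, mode="nearest",
                                  prefilter=order > 1)
    if is_mask:
        return SegmentationMask((out >= 0.5).astype(np.uint8), reference.spacing,
                                reference.origin, reference.axis_labels)
    return VolumeImage(out, reference.spacing, reference.origin,
                       reference.axis_labels)


def reslice_view(obj: VolumeImage | SegmentationMask, view: str):
    """Permute axes so the stack is sliced in ``view`` (slicing axis last).

    Pure axis permutation: spacing, origin and axis labels are permuted
    consistently and no interpolation happens, so reslicing round-trips
    exactly.
    """
    if view not in VIEW_AXIS_ORDER:
        raise ValueError(f"unknown view {view!r}; expected one of "
                         f"{sorted(VIEW_AXIS_ORDER)}")
    target = VIEW_AXIS_ORDER[view]
    perm = tuple(obj.axis_labels.index(lbl) for lbl in target)
    grid = np.transpose(_grid_of(obj), perm)
    spacing = tuple(obj.spacing[p] for p in perm)
    origin = tuple(obj.origin[p] for p in perm)
    if isinstance(obj, SegmentationMask):
        return SegmentationMask(grid, spacing, origin, target)
    return VolumeImage(grid, spacing, origin, target)


def physical_coordinates(obj, index: tuple[float, float, float]) -> np.ndarray:
    """Physical (mm) coordinate of a (possibly fractional) voxel index,
    expressed in the canonical (sagittal, coronal, axial) axis order."""
    phys = {lbl: obj.origin[ax] + index[ax] * obj.spacing[ax]
            for ax, lbl in enumerate(obj.axis_labels)}
    return np.array([phys[lbl] for lbl in ANATOMICAL_AXES])
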