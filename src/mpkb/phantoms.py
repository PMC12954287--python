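"""Synthetic multi-planar gland phantoms with analytically known volume.

The gland is an ellipsoid (semi-axes ``a, b, c`` mm) whose boundary is
optionally perturbed by a smooth, even, zero-mean radial field built from
real degree-2 spherical harmonics: a point with ellipsoidal coordinate
``q = (x/a, y/b, z/c)`` is inside the gland iff

    ||q|| <= 1 + d * f(q / ||q||),        |f| <= 1,

where ``d`` is the deformation amplitude.  At ``d = 0`` the volume is the
closed-form ``4/3 pi a b c``; for ``d > 0`` it is obtained by high-order
spherical quadrature of ``(abc/3) * (1 + d f)^3``, which is exact for the
undeformed case and accurate to ~1e-10 relative otherwise.

Intensities follow a two-class piecewise-constant model (bright gland on a
darker background by default) modulated by a smooth multiplicative bias
field plus additive Gaussian noise — the kind of contrast heterogeneity
that motivates percentile/z-score normalization on clinical T2w images.
Each requested view (axial always present) is rendered by reslicing the
fine isotropic grid into that view's axis order and resampling to the
view's anisotropic spacing.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy import ndimage

from .exam import VIEWS, MultiPlanarExam
from .image import SegmentationMask, VolumeImage, reslice_view, resample_to_reference, write_volume


def ellipsoid_true_volume(a_mm: float, b_mm: float, c_mm: float) -> float:
    """Closed-form ellipsoid volume in ml: (4/3) pi a b c / 1000."""
    for name, v in (("a_mm", a_mm), ("b_mm", b_mm), ("c_mm", c_mm)):
        if not v > 0:
            raise ValueError(f"semi-axis {name} must be positive, got {v}")
    # multiply in sorted order so the result is exactly permutation-invariant
    lo, mid, hi = sorted((a_mm, b_mm, c_mm))
    return (4.0 / 3.0) * np.pi * lo * mid * hi / 1000.0


@dataclass
class PhantomSpec:
    """Parametric description of one synthetic gland exam."""

    semi_axes: tuple[float, float, float] = (15.0, 13.0, 16.0)
    center_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    deform_amplitude: float = 0.05
    noise_sd: float = 10.0
    bias_amplitude: float = 0.15
    fg_intensity: float = 150.0
    bg_intensity: float = 60.0
    view_spacings: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"axial": (0.5, 3.0),
                                 "sagittal": (0.5, 3.0),
                                 "coronal": (0.5, 3.0)})
    views_present: tuple[str, ...] = VIEWS
    fine_spacing: float = 0.5
    margin_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.semi_axes = tuple(float(v) for v in self.semi_axes)
        self.center_offset = tuple(float(v) for v in self.center_offset)
        self.views_present = tuple(self.views_present)
        if any(v <= 0 for v in self.semi_axes):
            raise ValueError(f"semi_axes must be positive, got {self.semi_axes}")
        if not 0.0 <= self.deform_amplitude <= 0.3:
            raise ValueError(f"deform_amplitude must be in [0, 0.3], "
                             f"got {self.deform_amplitude}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.bias_amplitude < 0:
            raise ValueError(f"bias_amplitude must be >= 0, got {self.bias_amplitude}")
        if self.fine_spacing <= 0:
            raise ValueError(f"fine_spacing must be positive, got {self.fine_spacing}")
        unknown = set(self.views_present) - set(VIEWS)
        if unknown:
            raise ValueError(f"views_present has unknown views {sorted(unknown)}")
        if "axial" not in self.views_present:
            raise ValueError("views_present must contain 'axial' (canonical plane)")
        for v in self.views_present:
            if v not in self.view_spacings:
                raise ValueError(f"view_spacings missing entry for view {v!r}")
            ip, sl = self.view_spacings[v]
            if ip <= 0 or sl <= 0:
                raise ValueError(f"view_spacings[{v!r}] must be positive, got {(ip, sl)}")


@dataclass
class GroundTruth:
    """Reference standard for one phantom: fine-grid mask, analytic volume,
    and the maximal extents (W, H, L) mm along the three anatomical axes
    that feed the ellipsoid-formula reference volume."""

    mask3d: SegmentationMask
    true_volume_ml: float
    ellipsoid_diameters_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.true_volume_ml > 0:
            raise ValueError("true_volume_ml must be positive")
        if not self.mask3d.labels.any():
            raise ValueError("ground-truth mask is empty")


# ---------------------------------------------------------------------------
# deformation field (even, zero-mean, degree-2 real spherical harmonics)

def _harmonic_basis(ux, uy, uz):
    return np.stack([ux * uy, uy * uz, ux * uz,
                     ux * ux - uy * uy, 3.0 * uz * uz - 1.0], axis=-1)


def _sphere_quadrature(n_theta: int = 64, n_phi: int = 128):
    """Nodes/weights for integration over the unit sphere (exact for the
    polynomial integrands used here)."""
    mu, w_mu = leggauss(n_theta)          # mu = cos(theta)
    phi = (np.arange(n_phi) + 0.5) * (2.0 * np.pi / n_phi)
    sin_t = np.sqrt(1.0 - mu**2)
    ux = sin_t[:, None] * np.cos(phi)[None, :]
    uy = sin_t[:, None] * np.sin(phi)[None, :]
    uz = np.broadcast_to(mu[:, None], ux.shape)
    w = np.broadcast_to(w_mu[:, None], ux.shape) * (2.0 * np.pi / n_phi)
    return ux.ravel(), uy.ravel(), uz.ravel(), w.ravel()


class _RadialDeformation:
    """f(u) = normalized degree-2 harmonic combination with max |f| = 1."""

    def __init__(self, rng: np.random.Generator):
        coeffs = rng.standard_normal(5)
        ux, uy, uz, _ = _sphere_quadrature()
        vals = _harmonic_basis(ux, uy, uz) @ coeffs
        peak = np.abs(vals).max()
        self.coeffs = coeffs / peak if peak > 0 else coeffs

    def __call__(self, ux, uy, uz):
        return _harmonic_basis(ux, uy, uz) @ self.coeffs


def _analytic_volume_ml(semi_axes, deform_amplitude, deform) -> float:
    a, b, c = semi_axes
    if deform_amplitude == 0.0:
        return ellipsoid_true_volume(a, b, c)
    ux, uy, uz, w = _sphere_quadrature()
    r = 1.0 + deform_amplitude * deform(ux, uy, uz)
    return float(a * b * c / 3.0 * np.sum(w * r**3) / 1000.0)


def _diameters_mm(semi_axes, deform_amplitude, deform):
    a, b, c = semi_axes
    if deform_amplitude == 0.0:
        return (2.0 * a, 2.0 * b, 2.0 * c)
    axes_u = np.eye(3)
    f = deform(axes_u[:, 0], axes_u[:, 1], axes_u[:, 2])  # even field: f(u)=f(-u)
    scale = 1.0 + deform_amplitude * f
    return tuple(float(2.0 * s * k) for s, k in zip((a, b, c), scale))


def rasterize_gland(spec: PhantomSpec, spacing: float | None = None
                    ) -> tuple[SegmentationMask, _RadialDeformation]:
    """Voxelize the gland on an isotropic grid sized to cover it with margin."""
    fs = float(spacing if spacing is not None else spec.fine_spacing)
    if fs <= 0:
        raise ValueError("spacing must be positive")
    deform = _RadialDeformation(np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), 17])))
    a, b, c = spec.semi_axes
    d = spec.deform_amplitude
    shape = tuple(int(np.ceil((2.0 * s * (1.0 + d) + 2.0 * spec.margin_mm) / fs))
                  for s in (a, b, c))
    center = tuple((n - 1) / 2.0 * fs + off
                   for n, off in zip(shape, spec.center_offset))
    coords = [np.arange(n) * fs - c0 for n, c0 in zip(shape, center)]
    qx = (coords[0] / a)[:, None, None]
    qy = (coords[1] / b)[None, :, None]
    qz = (coords[2] / c)[None, None, :]
    r = np.sqrt(qx**2 + qy**2 + qz**2)
    if d == 0.0:
        inside = r <= 1.0
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            ux, uy, uz = qx / r, qy / r, qz / r
        f = (ux * uy) * deform.coeffs[0]
        f += (uy * uz) * deform.coeffs[1]
        f += (ux * uz) * deform.coeffs[2]
        f += (ux * ux - uy * uy) * deform.coeffs[3]
        f += (3.0 * uz * uz - 1.0) * deform.coeffs[4]
        f = np.nan_to_num(f)
        inside = r <= 1.0 + d * f
    mask = SegmentationMask(inside.astype(np.uint8), (fs, fs, fs))
    return mask, deform


def _bias_field(shape, amplitude, rng):
    if amplitude == 0.0:
        return 1.0
    coords = [np.linspace(0.0, 1.0, n) for n in shape]
    g = np.zeros(shape, dtype=np.float64)
    for _ in range(3):
        k = rng.integers(1, 3, size=3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        g += (np.cos(2 * np.pi * k[0] * coords[0] + phase[0])[:, None, None]
              * np.cos(2 * np.pi * k[1] * coords[1] + phase[1])[None, :, None]
              * np.cos(2 * np.pi * k[2] * coords[2] + phase[2])[None, None, :])
    peak = np.abs(g).max()
    if peak > 0:
        g /= peak
    return 1.0 + amplitude * g


def generate_phantom(spec: PhantomSpec) -> tuple[MultiPlanarExam, GroundTruth]:
    """Render one phantom exam (per-view volumes + axial mask) and its truth."""
    mask_fine, deform = rasterize_gland(spec)
    true_vol = _analytic_volume_ml(spec.semi_axes, spec.deform_amplitude, deform)
    diameters = _diameters_mm(spec.semi_axes, spec.deform_amplitude, deform)

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 29]))
    soft = ndimage.gaussian_filter(mask_fine.labels.astype(np.float32), sigma=0.8)
    img = spec.bg_intensity + (spec.fg_intensity - spec.bg_intensity) * soft
    img = img * _bias_field(img.shape, spec.bias_amplitude, rng)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    fine_vol = VolumeImage(img.astype(np.float32),
                           (spec.fine_spacing,) * 3)

    views: dict[str, VolumeImage] = {}
    view_masks: dict[str, SegmentationMask] = {}
    for view in spec.views_present:
        ip, sl = spec.view_spacings[view]
        views[view] = resample_to_reference(reslice_view(fine_vol, view),
                                            (ip, ip, sl))
        view_masks[view] = resample_to_reference(reslice_view(mask_fine, view),
                                                 (ip, ip, sl))
    exam = MultiPlanarExam(
        exam_id=f"phantom-{spec.seed:06d}",
        views=views,
        axial_mask=view_masks["axial"],
        pv_ref_ml=np.pi / 6.0 * np.prod(diameters) / 1000.0,
        view_masks=view_masks,
    )
    gt = GroundTruth(mask3d=mask_fine, true_volume_ml=true_vol,
                     ellipsoid_diameters_mm=diameters)
    return exam, gt


# ---------------------------------------------------------------------------
# cohorts

DEFAULT_VARIABILITY: dict[str, tuple[float, float]] = {
    "semi_axis_mm": (12.0, 17.0),
    "deform_amplitude": (0.02, 0.08),
    "noise_sd": (8.0, 15.0),
    "bias_amplitude": (0.05, 0.2),
    "in_plane_mm": (0.4, 0.6),
    "slice_mm": (2.5, 3.5),
}

SCENARIOS = ("full", "axial_only", "mixed")


def make_cohort(n: int,
                base_spec: PhantomSpec | None = None,
                variability: dict[str, tuple[float, float]] | None = None,
                seed: int = 0,
                scenario: str = "full",
                ) -> list[tuple[MultiPlanarExam, GroundTruth]]:
    """Draw ``n`` phantoms with per-exam anatomy, noise and spacing.

    ``scenario`` controls plane availability: ``full`` renders all three
    views, ``axial_only`` just the canonical plane, ``mixed`` axial plus a
    random subset of the orthogonal views.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    base = base_spec or PhantomSpec()
    var = dict(DEFAULT_VARIABILITY)
    if variability:
        var.update(variability)
    for key, (lo, hi) in var.items():
        if not lo <= hi:
            raise ValueError(f"variability range for {key!r} is empty: {(lo, hi)}")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    cohort = []
    for i in range(n):
        axes = tuple(rng.uniform(*var["semi_axis_mm"], size=3))
        ip = float(rng.uniform(*var["in_plane_mm"]))
        sl = float(rng.uniform(*var["slice_mm"]))
        if scenario == "full":
            present: tuple[str, ...] = VIEWS
        elif scenario == "axial_only":
            present = ("axial",)
        else:
            extra = [v for v in ("sagittal", "coronal") if rng.random() < 0.5]
            present = ("axial", *extra)
        spec = replace(
            base,
            semi_axes=axes,
            deform_amplitude=float(rng.uniform(*var["deform_amplitude"])),
            noise_sd=float(rng.uniform(*var["noise_sd"])),
            bias_amplitude=float(rng.uniform(*var["bias_amplitude"])),
            view_spacings={v: (ip, sl) for v in VIEWS},
            views_present=present,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        exam, gt = generate_phantom(spec)
        exam = replace(exam, exam_id=f"phantom-{seed:04d}-{i:03d}")
        cohort.append((exam, gt))
    return cohort


def cohort_checksum(cohort) -> str:
    """Stable digest of all exam grids and ground-truth volumes."""
    h = hashlib.sha256()
    for exam, gt in cohort:
        h.update(exam.exam_id.encode())
        for view in exam.views_present:
            h.update(np.ascontiguousarray(exam.views[view].intensities).tobytes())
        h.update(np.ascontiguousarray(exam.axial_mask.labels).tobytes())
        h.update(np.float64(gt.true_volume_ml).tobytes())
    return h.hexdigest()


def write_cohort(cohort, out_dir: str | Path) -> Path:
    """Write per-view NIfTI volumes, masks and a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for exam, gt in cohort:
        exam_dir = out_dir / exam.exam_id
        exam_dir.mkdir(exist_ok=True)
        for view in exam.views_present:
            write_volume(exam.views[view], exam_dir / f"{view}.nii.gz")
        write_volume(exam.axial_mask, exam_dir / "axial_mask.nii.gz")
        W, H, L = gt.ellipsoid_diameters_mm
        rows.append({"exam_id": exam.exam_id,
                     "views": "+".join(exam.views_present),
                     "true_volume_ml": gt.true_volume_ml,
                     "pv_ref_ml": exam.pv_ref_ml,
                     "diameter_w_mm": W, "diameter_h_mm": H, "diameter_l_mm": L})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
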