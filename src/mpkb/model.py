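"""Multi-planar segmentation network with weight-shared view encoders.

Architecture
------------
One 2D U-Net-style encoder (conv3x3-ReLU x2 per level, x2 average-pool
between levels) serves all three view roles — axial, sagittal and coronal
slices pass through the *same* parameter set, which is what makes the
latent spaces comparable.  The deepest feature map of each view is global-
average-pooled and linearly projected to a fixed-dimension latent vector;
latents of the available views are fused by an arithmetic mean, so axial-
only inference is the exact single-view special case and no retraining is
needed when orthogonal views are missing.

Only the axial pass feeds the decoder: its pre-pool feature maps are the
skip connections, and the fused latent is broadcast spatially and
concatenated onto the deepest axial feature map before decoding.  Sagittal
and coronal inputs can therefore influence the output only through the
fused bottleneck, never through the skip paths.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exam import VIEWS
from .nn import Conv2d, Linear, Module, Tensor
from .nn import autograd as ag


@dataclass
class ModelConfig:
    """Network and training hyper-parameters.

    Desk-scale defaults (20 epochs, 64x64 in-plane, depth 3) train in
    minutes on one CPU; :func:`paper_preset` switches to the full-scale
    settings (300 epochs).
    """

    encoder_depth: int = 3
    base_channels: int = 8
    latent_dim: int = 32
    in_plane_size: int = 64
    lambda_contrastive: float = 0.25
    learning_rate: float = 0.01
    momentum: float = 0.99
    epochs: int = 20
    folds: int = 5
    slices_per_step: int = 4
    contrastive_mode: str = "align"
    infonce_temperature: float = 0.1
    dice_eps: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_contrastive < 0:
            raise ValueError(f"lambda_contrastive must be >= 0, "
                             f"got {self.lambda_contrastive}")
        if self.folds < 2:
            raise ValueError(f"folds must be >= 2, got {self.folds}")
        if self.encoder_depth < 2:
            raise ValueError(f"encoder_depth must be >= 2, got {self.encoder_depth}")
        stride = 2 ** (self.encoder_depth - 1)
        if self.in_plane_size % stride != 0:
            raise ValueError(
                f"in_plane_size {self.in_plane_size} is not divisible by "
                f"2**(encoder_depth-1) = {stride}")
        if self.contrastive_mode not in ("align", "infonce"):
            raise ValueError(f"unknown contrastive_mode {self.contrastive_mode!r}")


def paper_preset(**overrides) -> ModelConfig:
    """Full-scale training settings: 300 epochs, 5 folds, lambda 0.25."""
    cfg = ModelConfig(epochs=300, folds=5, lambda_contrastive=0.25)
    return replace(cfg, **overrides)


@dataclass
class LatentFeatures:
    """Per-sample bottleneck representations from one view encoder."""

    vectors: np.ndarray  # (n_samples, latent_dim)
    view: str

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors))
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("latent vectors must be finite")


@dataclass
class SliceBatch:
    """A batch of 2D normalized slices from a single view."""

    images: np.ndarray  # (n, H, W) or (n, 1, H, W)
    view: str
    exam_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.images, dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[:, None]
        if arr.ndim != 4 or arr.shape[1] != 1:
            raise ValueError(f"expected (n, H, W) or (n, 1, H, W) slices, "
                             f"got shape {np.asarray(self.images).shape}")
        if arr.shape[2] != arr.shape[3]:
            raise ValueError(f"slices must be square, got {arr.shape[2:]} ")
        self.images = arr
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}")
        self.exam_ids = tuple(self.exam_ids)


class MultiPlanarKBNet(Module):
    """Weight-shared multi-view encoder + axial-skip decoder."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 7]))
        depth = cfg.encoder_depth
        ch = [cfg.base_channels * 2 ** l for l in range(depth)]
        self.channels = ch
        # one parameter set serves the axial, sagittal and coronal roles
        self.enc_blocks = []
        cin = 1
        for l in range(depth):
            self.enc_blocks.append([Conv2d(cin, ch[l], 3, rng),
                                    Conv2d(ch[l], ch[l], 3, rng)])
            cin = ch[l]
        self.proj = Linear(ch[-1], cfg.latent_dim, rng)
        self.inject = Conv2d(ch[-1] + cfg.latent_dim, ch[-1], 1, rng)
        self.dec_blocks = []
        for l in range(depth - 2, -1, -1):
            self.dec_blocks.append([Conv2d(ch[l + 1] + ch[l], ch[l], 3, rng),
                                    Conv2d(ch[l], ch[l], 3, rng)])
        self.out_conv = Conv2d(ch[0], 1, 1, rng)

    # -- building blocks ----------------------------------------------------
    def _check_size(self, x) -> None:
        n = self.cfg.in_plane_size
        if x.shape[-2:] != (n, n):
            raise ValueError(f"expected {n}x{n} slices, got {x.shape[-2:]}")

    def encoder_forward(self, x: Tensor) -> tuple[list[Tensor], Tensor]:
        """Shared encoder pass; returns (skip features, deepest feature map)."""
        self._check_size(x)
        skips: list[Tensor] = []
        depth = self.cfg.encoder_depth
        for l, (c1, c2) in enumerate(self.enc_blocks):
            x = ag.relu(c1(x))
            x = ag.relu(c2(x))
            if l < depth - 1:
                skips.append(x)
                x = ag.avg_pool2x(x)
        return skips, x

    def latent_from_deep(self, deep: Tensor) -> Tensor:
        return self.proj(ag.global_avg_pool(deep))

    def encode(self, images: np.ndarray | Tensor) -> Tensor:
        x = images if isinstance(images, Tensor) else Tensor(images)
        _, deep = self.encoder_forward(x)
        return self.latent_from_deep(deep)

    def decode(self, skips: list[Tensor], deep: Tensor, fused: Tensor) -> Tensor:
        h, w = deep.shape[-2:]
        d = ag.relu(self.inject(ag.concat([deep, ag.expand_spatial(fused, h, w)], 1)))
        for blk, skip in zip(self.dec_blocks, reversed(skips)):
            d = ag.upsample2x(d)
            d = ag.concat([d, skip], axis=1)
            d = ag.relu(blk[0](d))
            d = ag.relu(blk[1](d))
        return self.out_conv(d)

    def forward_logits(self, axial: Tensor,
                       context_latents: list[Tensor] | None = None
                       ) -> tuple[Tensor, Tensor]:
        """Segment axial slices given optional fused-view context.

        Returns (logits, axial latent).  ``context_latents`` entries are
        (1, latent_dim) exam-level latents; fusion is the arithmetic mean of
        the axial latent and all provided context latents.
        """
        skips, deep = self.encoder_forward(axial)
        z_ax = self.latent_from_deep(deep)
        fused = z_ax
        if context_latents:
            for z in context_latents:
                fused = fused + z
            fused = fused * (1.0 / (1 + len(context_latents)))
        logits = self.decode(skips, deep, fused)
        return logits, z_ax


def build_model(cfg: ModelConfig) -> MultiPlanarKBNet:
    """Construct the network; encoder weights are shared across view roles
    by design (a single parameter set, so the sharing survives training)."""
    return MultiPlanarKBNet(cfg)


def encode_view(model: MultiPlanarKBNet, batch: SliceBatch) -> LatentFeatures:
    """Per-slice latent vectors (global-average-pooled deepest features,
    linearly projected).  The view label is provenance only: all views run
    through the same weights."""
    z = model.encode(batch.images)
    return LatentFeatures(vectors=z.data.copy(), view=batch.view)


def fuse_latents(latents: list[LatentFeatures]) -> np.ndarray:
    """Arithmetic mean of the available views' latents (axial required).

    The output dimension is the latent dimension regardless of how many
    views are present, which is what lets inference adapt to axial-only
    protocols without retraining.
    """
    if not latents:
        raise ValueError("no latents to fuse")
    if not any(lf.view == "axial" for lf in latents):
        raise ValueError("axial latent is required (canonical plane)")
    dims = {lf.vectors.shape[-1] for lf in latents}
    if len(dims) != 1:
        raise ValueError(f"latent dimensions differ across views: {sorted(dims)}")
    stacked = [np.atleast_2d(lf.vectors) for lf in latents]
    return np.mean(np.broadcast_arrays(*stacked), axis=0) if len(stacked) > 1 \
        else stacked[0].copy()


def forward_segment(model: MultiPlanarKBNet, axial_batch: SliceBatch,
                    context: dict[str, SliceBatch] | None = None) -> np.ndarray:
    """Foreground probabilities for a batch of axial slices.

    ``context`` maps view name -> SliceBatch of sagittal/coronal slices from
    the *same* exams; their latents are averaged per view and fused with the
    axial latent.  With no context the call degrades exactly to axial-only
    inference.
    """
    ctx_latents: list[Tensor] = []
    if context:
        ax_ids = set(axial_batch.exam_ids)
        for view, cb in context.items():
            if view == "axial":
                continue
            if cb.exam_ids and ax_ids and set(cb.exam_ids) - ax_ids:
                raise ValueError(
                    f"context exam ids {sorted(set(cb.exam_ids) - ax_ids)} do not "
                    "match the axial batch")
            z = model.encode(cb.images)
            ctx_latents.append(Tensor(z.data.mean(axis=0, keepdims=True)))
    logits, _ = model.forward_logits(Tensor(axial_batch.images), ctx_latents)
    probs = ag.sigmoid(logits)
    return probs.data.copy()
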