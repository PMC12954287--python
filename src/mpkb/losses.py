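"""Knowledge-based training objective.

The total loss is the standard segmentation loss (soft Dice + binary
cross-entropy) plus weighted cosine-distance alignment terms that pull the
sagittal and coronal latent representations toward the axial ones:

    L = L_dice + L_ce + lambda * (d_cos(z_ax, z_sag) + d_cos(z_ax, z_cor))

with ``d_cos(u, v) = 1 - cos(u, v)`` averaged over paired samples, and
``lambda`` defaulting to 0.25.  Missing views simply drop their term (the
weight is not rescaled), so axial-only training recovers the plain
segmentation loss.

All operations accept either NumPy arrays (returning floats, for
evaluation/reporting) or autodiff tensors (returning tensors, for
training); both code paths evaluate the same formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor

DEFAULT_LAMBDA = 0.25
DICE_EPS = 1e-5


def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _maybe_item(x):
    return x.item() if _is_tensor(x) else float(x)


@dataclass
class LossBundle:
    """Decomposed knowledge-based loss for one step or one epoch."""

    dice_term: float
    ce_term: float
    contrastive_ax_sag: float | None
    contrastive_ax_cor: float | None
    lam: float
    total: float

    def as_dict(self) -> dict:
        return {"dice": self.dice_term, "ce": self.ce_term,
                "con_ax_sag": self.contrastive_ax_sag,
                "con_ax_cor": self.contrastive_ax_cor,
                "lambda": self.lam, "total": self.total}


def dice_ce_loss(probs, target_mask, eps: float = DICE_EPS):
    """Soft Dice loss and mean binary cross-entropy from probabilities.

    dice = 1 - (2 sum(p t) + eps) / (sum(p) + sum(t) + eps);
    ce   = mean(-t log p - (1-t) log(1-p)).
    """
    tensor_in = _is_tensor(probs)
    p = probs if tensor_in else Tensor(np.asarray(probs, dtype=np.float64))
    t = np.asarray(target_mask.data if _is_tensor(target_mask) else target_mask,
                   dtype=p.data.dtype)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs target {t.shape}")
    if np.any(p.data < 0) or np.any(p.data > 1):
        raise ValueError("probs must lie in [0, 1]")
    inter = ag.tsum(p * t)
    dice = 1.0 - (2.0 * inter + eps) / (ag.tsum(p) + float(t.sum()) + eps)
    clip = 1e-12
    pc = Tensor(np.clip(p.data, clip, 1.0 - clip))  # evaluation path only
    if tensor_in:
        # keep gradient flow: clamp via the graph (p is already in [0,1])
        pc = p * (1.0 - 2.0 * clip) + clip
    ce = -ag.tmean(Tensor(t) * ag.log(pc) + (1.0 - Tensor(t)) * ag.log(1.0 - pc)) \
        if tensor_in else \
        -float(np.mean(t * np.log(pc.data) + (1.0 - t) * np.log(1.0 - pc.data)))
    if tensor_in:
        return dice, ce
    return _maybe_item(dice), float(ce)


def segmentation_loss_from_logits(logits: Tensor, targets: np.ndarray,
                                  eps: float = DICE_EPS) -> tuple[Tensor, Tensor]:
    """Training-path Dice + CE computed from logits (numerically stable CE)."""
    t = np.asarray(targets, dtype=logits.data.dtype)
    if logits.shape != t.shape:
        raise ValueError(f"shape mismatch: logits {logits.shape} vs target {t.shape}")
    p = ag.sigmoid(logits)
    inter = ag.tsum(p * t)
    dice = 1.0 - (2.0 * inter + eps) / (ag.tsum(p) + float(t.sum()) + eps)
    ce = ag.bce_with_logits(logits, t)
    return dice, ce


def _rowwise_cosine(a, b):
    """Cosine similarity per paired row; numpy or tensor, broadcast-safe."""
    if _is_tensor(a) or _is_tensor(b):
        a = a if _is_tensor(a) else Tensor(np.asarray(a))
        b = b if _is_tensor(b) else Tensor(np.asarray(b))
        dot = ag.tsum(a * b, axis=-1)
        na = ag.sqrt(ag.tsum(a * a, axis=-1))
        nb = ag.sqrt(ag.tsum(b * b, axis=-1))
        return dot / (na * nb)
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    dot = (a * b).sum(axis=-1)
    return dot / (np.linalg.norm(a, axis=-1) * np.linalg.norm(b, axis=-1))


def _check_nonzero(z, name: str, exam_ids=None):
    data = z.data if _is_tensor(z) else np.asarray(z)
    norms = np.linalg.norm(np.atleast_2d(data), axis=-1)
    bad = np.nonzero(norms == 0)[0]
    if bad.size:
        which = (f" (exam {exam_ids[bad[0]]})" if exam_ids is not None
                 else f" (row {bad[0]})")
        raise ValueError(f"zero-norm latent vector in {name}{which}: "
                         "cosine distance undefined")


def cosine_alignment_loss(z_axial, z_other, exam_ids=None):
    """Mean cosine distance 1 - cos(z_axial_i, z_other_i) over paired rows.

    Range [0, 2]; 0 for perfectly aligned latents, 2 for antipodal ones.
    Symmetric in its arguments and invariant to positive per-row rescaling.
    """
    _check_nonzero(z_axial, "z_axial", exam_ids)
    _check_nonzero(z_other, "z_other", exam_ids)
    cos = _rowwise_cosine(z_axial, z_other)
    if _is_tensor(cos):
        return ag.tmean(1.0 - cos)
    return float(np.mean(1.0 - cos))


def infonce_alignment_loss(z_axial, z_other, temperature: float = 0.1):
    """Optional negatives-based alignment: other exams in the batch act as
    negatives under a temperature-scaled cosine-similarity softmax."""
    tensor_in = _is_tensor(z_axial) or _is_tensor(z_other)
    a = z_axial if _is_tensor(z_axial) else Tensor(np.atleast_2d(z_axial))
    b = z_other if _is_tensor(z_other) else Tensor(np.atleast_2d(z_other))
    _check_nonzero(a, "z_axial")
    _check_nonzero(b, "z_other")
    na = ag.sqrt(ag.tsum(a * a, axis=-1, keepdims=True))
    nb = ag.sqrt(ag.tsum(b * b, axis=-1, keepdims=True))
    an = a / na
    bn = b / nb
    sim = ag.matmul(an, _transpose(bn)) * (1.0 / temperature)
    n = sim.shape[0]
    # log-softmax over each row, positives on the diagonal
    m = np.max(sim.data, axis=1, keepdims=True)
    shifted = sim - Tensor(m)
    lse = ag.log(ag.tsum(ag.exp(shifted), axis=1))
    diag = ag.tsum(shifted * np.eye(n, dtype=sim.data.dtype), axis=1)
    loss = ag.tmean(lse - diag)
    return loss if tensor_in else loss.item()


def _transpose(t: Tensor) -> Tensor:
    out = Tensor(t.data.T, _parents=(t,))

    def bw(g):
        if t.requires_grad:
            t._accumulate(g.T)

    out._backward = bw
    return out


def kb_total_loss(seg_terms, con_ax_sag=None, con_ax_cor=None,
                  lam: float = DEFAULT_LAMBDA):
    """Combine segmentation and alignment terms into the knowledge-based loss.

    ``seg_terms`` is the (dice, ce) pair.  Missing contrastive terms are
    passed as None (absent views contribute nothing; ``lam`` is not
    rescaled).  Returns the total plus a :class:`LossBundle` of floats.
    """
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    dice, ce = seg_terms
    total = dice + ce
    present = [c for c in (con_ax_sag, con_ax_cor) if c is not None]
    if present and lam != 0:
        csum = present[0]
        for c in present[1:]:
            csum = csum + c
        total = total + lam * csum
    bundle = LossBundle(
        dice_term=_maybe_item(dice),
        ce_term=_maybe_item(ce),
        contrastive_ax_sag=None if con_ax_sag is None else _maybe_item(con_ax_sag),
        contrastive_ax_cor=None if con_ax_cor is None else _maybe_item(con_ax_cor),
        lam=float(lam),
        total=_maybe_item(total),
    )
    return total, bundle
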