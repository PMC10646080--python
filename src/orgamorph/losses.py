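"""Compound segmentation loss: soft dice + binary cross-entropy.

The training objective is the unweighted sum

    L_total = L_CE + L_Dice

where L_Dice = 1 - (2*sum(p*g) + eps) / (sum(p) + sum(g) + eps) with
smoothing eps = 1, and L_CE is the mean per-pixel binary cross-entropy with
probabilities clipped to (delta, 1 - delta), delta = 1e-7.  Each function
can also return the analytic gradient with respect to the probability map,
which the network's sigmoid backward consumes.

For batched inputs the dice term is computed per sample and averaged;
cross-entropy is the mean over all pixels of the batch.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dice_loss", "cross_entropy_loss", "compound_loss", "DICE_EPS", "CE_CLIP"]

DICE_EPS = 1.0
CE_CLIP = 1e-7


def _check(prob: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    prob = np.asarray(prob, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if prob.shape != gt.shape:
        raise ValueError(f"shape mismatch: {prob.shape} vs {gt.shape}")
    return prob, gt


def _per_sample(x: np.ndarray) -> np.ndarray:
    """View (N, ...) as (N, -1); a bare 2-D map becomes one sample."""
    if x.ndim <= 2:
        return x.reshape(1, -1)
    return x.reshape(x.shape[0], -1)


def dice_loss(prob, gt, return_grad: bool = False):
    """Soft dice loss in [0, 1]; 0 for a perfect (binary) prediction."""
    prob, gt = _check(prob, gt)
    p, g = _per_sample(prob), _per_sample(gt)
    inter = (p * g).sum(axis=1)
    sums = p.sum(axis=1) + g.sum(axis=1)
    dice = (2.0 * inter + DICE_EPS) / (sums + DICE_EPS)
    loss = float(np.mean(1.0 - dice))
    if not return_grad:
        return loss
    # d/dp_i of -(2*I+eps)/(S+eps): -(2*g_i*(S+eps) - (2*I+eps)) / (S+eps)^2
    denom = (sums + DICE_EPS)[:, None]
    grad = -(2.0 * g * denom - (2.0 * inter + DICE_EPS)[:, None]) / denom**2
    grad /= p.shape[0]
    return loss, grad.reshape(prob.shape)


def cross_entropy_loss(prob, gt, return_grad: bool = False):
    """Mean per-pixel binary cross-entropy with probability clipping."""
    prob, gt = _check(prob, gt)
    pc = np.clip(prob, CE_CLIP, 1.0 - CE_CLIP)
    loss = float(np.mean(-(gt * np.log(pc) + (1.0 - gt) * np.log1p(-pc))))
    if not return_grad:
        return loss
    grad = (-(gt / pc) + (1.0 - gt) / (1.0 - pc)) / prob.size
    # outside the clip range the loss is locally constant in prob
    grad[(prob < CE_CLIP) | (prob > 1.0 - CE_CLIP)] = 0.0
    return loss, grad


def compound_loss(prob, gt, return_grad: bool = False):
    """Dice + cross-entropy with unit weights; optionally the loss parts.

    Returns ``total`` or ``(total, grad)``; the parts are available via
    :func:`dice_loss` / :func:`cross_entropy_loss` on the same input.
    """
    if return_grad:
        ld, gd = dice_loss(prob, gt, return_grad=True)
        lc, gc = cross_entropy_loss(prob, gt, return_grad=True)
        return ld + lc, gd + gc
    return dice_loss(prob, gt) + cross_entropy_loss(prob, gt)
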