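"""Tversky, focal, and unweighted mixed segmentation losses.

With per-pixel foreground probabilities :math:`p_{0i}` (and
:math:`p_{1i} = 1 - p_{0i}`) and binary ground truth :math:`g_{0i}`
(:math:`g_{1i} = 1 - g_{0i}`):

.. math::

   T(\\beta) = \\frac{\\sum_i p_{0i} g_{0i}}
        {\\sum_i p_{0i} g_{0i} + \\beta \\sum_i p_{0i} g_{1i}
         + (1-\\beta) \\sum_i p_{1i} g_{0i}},
   \\qquad L_{Tversky} = 1 - T(\\beta)

   L_{Focal} = \\frac{1}{N} \\sum_i -(1 - p_{i,t})^\\gamma \\log p_{i,t},
   \\qquad p_{i,t} = \\begin{cases} p_{0i} & g_{0i} = 1 \\\\
                                    p_{1i} & g_{0i} = 0 \\end{cases}

   L_{mixed} = L_{Focal} + L_{Tversky}

Both sums run over all N pixels of the batch treated as one image.
``tversky_loss`` at beta=0.5 equals 1 - soft Dice; ``focal_loss`` at
gamma=0 equals mean binary cross-entropy. A small epsilon is added to the
Tversky numerator and denominator so the all-background batch is
well-defined.
"""

from __future__ import annotations

import numpy as np

from .config import LossParams
from .nn.tensor import Tensor

__all__ = ["tversky_loss", "focal_loss", "mixed_loss", "LossParams"]


def _validate(probs, truth) -> tuple[Tensor, np.ndarray, bool]:
    was_tensor = isinstance(probs, Tensor)
    p = probs if was_tensor else Tensor(probs)
    g = truth.data if isinstance(truth, Tensor) else np.asarray(truth, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs truth {g.shape}")
    if p.size == 0:
        raise ValueError("empty inputs")
    if np.any(p.data < 0) or np.any(p.data > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.isin(g, (0.0, 1.0)).all():
        raise ValueError("ground truth must be binary")
    return p, g, was_tensor


def _ret(loss: Tensor, as_tensor: bool):
    return loss if as_tensor else loss.item()


def tversky_loss(probs, truth, params: LossParams | None = None):
    """1 - Tversky index, aggregated over all pixels of the batch.

    Accepts plain arrays (returns a float) or autodiff Tensors (returns a
    differentiable scalar Tensor).
    """
    params = params or LossParams()
    p0, g0, as_tensor = _validate(probs, truth)
    g1 = 1.0 - g0
    tp = (p0 * g0).sum()
    fp = (p0 * g1).sum()
    fn = ((1.0 - p0) * g0).sum()
    eps = params.smooth
    t_index = (tp + eps) / (tp + params.beta * fp + (1.0 - params.beta) * fn + eps)
    return _ret(1.0 - t_index, as_tensor)


def focal_loss(probs, truth, params: LossParams | None = None):
    """Mean over pixels of -(1 - p_t)^gamma * log(p_t)."""
    params = params or LossParams()
    p0, g0, as_tensor = _validate(probs, truth)
    # p_t = p0 where positive, (1 - p0) where negative
    p_t = p0 * g0 + (1.0 - p0) * (1.0 - g0)
    p_t = p_t.clip(params.prob_clamp, 1.0 - params.prob_clamp)
    if params.gamma == 0:
        per_pixel = -p_t.log()
    else:
        per_pixel = -((1.0 - p_t) ** params.gamma) * p_t.log()
    return _ret(per_pixel.mean(), as_tensor)


def mixed_loss(probs, truth, params: LossParams | None = None):
    """Unweighted sum of the focal and Tversky losses."""
    params = params or LossParams()
    return focal_loss(probs, truth, params) + tversky_loss(probs, truth, params)
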