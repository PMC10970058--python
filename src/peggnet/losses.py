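"""Classification losses: cross-entropy, focal loss, and their 0.5/0.5 blend.

The five egg classes are imbalanced (the substandard and inferior categories
are rare in production), so plain cross-entropy is blended equally with a
focal term

    FL(p_t) = -alpha_t * (1 - p_t)**gamma * log(p_t)

which down-weights easy samples (the ``(1-p_t)**gamma`` modulator) and
re-weights classes (``alpha_t``, conventionally inverse-frequency).  The
blend is  Loss = 0.5 * L_CE + 0.5 * FL.

Two surfaces are provided: a numpy one operating on explicit probability
vectors (the reference semantics, validated and clamped), and a
graph-building one on logits for training (:func:`combined_loss_logits`).
Batch reduction is the mean throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag

__all__ = [
    "LossParams",
    "alpha_from_frequencies",
    "cross_entropy",
    "focal_loss",
    "combined_loss",
    "combined_loss_logits",
]

#: Floor for log arguments; keeps degenerate predictions finite.
LOG_EPS = 1e-12


@dataclass
class LossParams:
    """alpha_t per class, focusing exponent gamma, and the mixing weights."""

    alpha: np.ndarray = field(default_factory=lambda: np.ones(5))
    gamma: float = 2.0
    mix_ce: float = 0.5
    mix_fl: float = 0.5

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        if np.any(self.alpha < 0):
            raise ValueError("alpha entries must be nonnegative")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")


def alpha_from_frequencies(class_counts):
    """Inverse-frequency class weights, normalized to mean 1."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError("class counts must be positive")
    inv = 1.0 / counts
    return inv / inv.mean()


def _validate(pred, labels, num_classes=None):
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if pred.ndim == 1:
        pred = pred[None]
    if labels.ndim == 0:
        labels = labels[None]
    if pred.shape[0] != labels.shape[0]:
        raise ValueError("prediction/label count mismatch")
    if np.any(pred < 0) or np.any(pred > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if np.any(np.abs(pred.sum(axis=1) - 1.0) > 1e-5):
        raise ValueError("probability rows must sum to 1 (tolerance 1e-5)")
    k = num_classes or pred.shape[1]
    if np.any(labels < 0) or np.any(labels >= k):
        raise ValueError(f"labels must lie in 0..{k - 1}")
    return pred, labels


def cross_entropy(pred_dist, true_labels):
    """Mean over the batch of -log q(true class) (one-hot true distribution)."""
    pred, labels = _validate(pred_dist, true_labels)
    p_t = pred[np.arange(len(labels)), labels]
    return float(-np.log(np.maximum(p_t, LOG_EPS)).mean())


def focal_loss(pred_dist, true_labels, params: LossParams):
    """Mean over the batch of -alpha_t (1-p_t)^gamma log(p_t)."""
    pred, labels = _validate(pred_dist, true_labels, len(params.alpha))
    p_t = pred[np.arange(len(labels)), labels]
    a_t = params.alpha[labels]
    per_sample = -a_t * (1.0 - p_t) ** params.gamma * np.log(
        np.maximum(p_t, LOG_EPS)
    )
    return float(per_sample.mean())


def combined_loss(pred_dist, true_labels, params: LossParams):
    """mix_ce * cross-entropy + mix_fl * focal loss."""
    return params.mix_ce * cross_entropy(pred_dist, true_labels) + (
        params.mix_fl * focal_loss(pred_dist, true_labels, params)
    )


def combined_loss_logits(logits, true_labels, params: LossParams,
                         return_components=False):
    """Differentiable blend on raw logits (autograd tensor in, tensor out)."""
    labels = np.asarray(true_labels, dtype=int)
    logp = ag.log_softmax(ag.as_tensor(logits), axis=-1)
    logp_t = ag.take_class(logp, labels)
    ce = ag.mean(ag.mul(logp_t, -1.0))
    p_t = ag.exp(logp_t)
    modulator = ag.power(1.0 - p_t, params.gamma)
    a_t = params.alpha[labels].astype(logp.data.dtype)
    fl = ag.mean(ag.mul(ag.mul(modulator, logp_t), -a_t))
    total = ag.add(ag.mul(ce, params.mix_ce), ag.mul(fl, params.mix_fl))
    if return_components:
        return total, float(ce.data), float(fl.data)
    return total
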