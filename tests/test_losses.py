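"""Loss identities, hand-evaluated oracle values, the scalar-loop
cross-check, and gradient agreement."""

import math

import numpy as np
import pytest

from peggnet import autograd as ag
from peggnet.losses import (LossParams, alpha_from_frequencies, combined_loss,
                            combined_loss_logits, cross_entropy, focal_loss)


def random_probs(rng, n=8, k=5):
    p = rng.dirichlet(np.ones(k), size=n)
    y = rng.integers(0, k, size=n)
    return p, y


def scalar_loop_losses(pred, labels, params):
    """Independent per-sample implementation with explicit python loops."""
    ces, fls = [], []
    for i, lab in enumerate(labels):
        p_t = max(pred[i][lab], 1e-12)
        ces.append(-math.log(p_t))
        fls.append(-params.alpha[lab] * (1 - pred[i][lab]) ** params.gamma
                   * math.log(p_t))
    return sum(ces) / len(ces), sum(fls) / len(fls)


def test_certain_prediction_has_zero_loss():
    p = np.eye(5)[[2]]
    params = LossParams(alpha=np.full(5, 0.7), gamma=3.0)
    assert cross_entropy(p, [2]) == 0.0
    assert focal_loss(p, [2], params) == 0.0


def test_uniform_prediction_cross_entropy():
    p = np.full((3, 5), 0.2)
    assert cross_entropy(p, [0, 3, 4]) == pytest.approx(-math.log(0.2),
                                                        abs=1e-12)


def test_hand_evaluated_focal_value():
    """alpha=0.25, gamma=2, p_t=0.5 -> 0.25 * 0.25 * ln 2 ~= 0.043322."""
    params = LossParams(alpha=np.full(5, 0.25), gamma=2.0)
    p = np.array([[0.5, 0.2, 0.1, 0.1, 0.1]])
    assert focal_loss(p, [0], params) == pytest.approx(
        0.25 * 0.25 * math.log(2), abs=1e-9)
    assert focal_loss(p, [0], params) == pytest.approx(0.043322, abs=1e-6)


def test_combined_hand_value():
    params = LossParams(alpha=np.full(5, 0.25), gamma=2.0)
    p = np.array([[0.5, 0.2, 0.1, 0.1, 0.1]])
    want = 0.5 * math.log(2) + 0.5 * 0.25 * 0.25 * math.log(2)
    assert combined_loss(p, [0], params) == pytest.approx(want, abs=1e-9)
    assert combined_loss(p, [0], params) == pytest.approx(0.368235, abs=1e-6)


def test_focal_degenerates_to_cross_entropy(rng):
    """gamma=0, alpha=1: FL == CE, hence combined == CE."""
    params = LossParams(alpha=np.ones(5), gamma=0.0)
    p, y = random_probs(rng)
    assert focal_loss(p, y, params) == pytest.approx(cross_entropy(p, y),
                                                     abs=1e-12)
    assert combined_loss(p, y, params) == pytest.approx(cross_entropy(p, y),
                                                        abs=1e-12)


def test_batch_mean_reduction(rng):
    p, y = random_probs(rng, n=2)
    a = cross_entropy(p[:1], y[:1])
    b = cross_entropy(p[1:], y[1:])
    assert cross_entropy(p, y) == pytest.approx((a + b) / 2, abs=1e-12)


def test_vectorized_matches_scalar_loop(rng):
    params = LossParams(alpha=rng.uniform(0.1, 2.0, 5), gamma=1.7)
    for _ in range(5):
        p, y = random_probs(rng, n=12)
        ce_ref, fl_ref = scalar_loop_losses(p, y, params)
        assert cross_entropy(p, y) == pytest.approx(ce_ref, abs=1e-10)
        assert focal_loss(p, y, params) == pytest.approx(fl_ref, abs=1e-10)
        assert combined_loss(p, y, params) == pytest.approx(
            params.mix_ce * ce_ref + params.mix_fl * fl_ref, abs=1e-10)


def test_focal_monotone_decreasing_in_pt():
    params = LossParams(alpha=np.full(5, 0.5), gamma=2.0)
    grid = np.linspace(0.01, 0.99, 50)
    vals = []
    for pt in grid:
        p = np.zeros((1, 5))
        p[0, 0] = pt
        p[0, 1:] = (1 - pt) / 4
        vals.append(focal_loss(p, [0], params))
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_focal_bounded_by_weighted_cross_entropy(rng):
    """(1-p_t)^gamma <= 1, so FL <= alpha_t * CE per sample."""
    params = LossParams(alpha=rng.uniform(0.1, 2.0, 5), gamma=2.0)
    p, y = random_probs(rng, n=40)
    for i in range(len(y)):
        fl_i = focal_loss(p[i : i + 1], y[i : i + 1], params)
        ce_i = cross_entropy(p[i : i + 1], y[i : i + 1])
        assert fl_i <= params.alpha[y[i]] * ce_i + 1e-12


def test_invalid_probabilities_rejected(rng):
    params = LossParams()
    with pytest.raises(ValueError):
        cross_entropy(np.array([[0.5, 0.2, 0.1, 0.1, 0.2]]), [0])  # sums 1.1
    with pytest.raises(ValueError):
        cross_entropy(np.array([[1.2, -0.2, 0.0, 0.0, 0.0]]), [0])
    p, _ = random_probs(rng, n=2)
    with pytest.raises(ValueError):
        focal_loss(p, [0, 7], params)
    with pytest.raises(ValueError):
        cross_entropy(p, [0])  # length mismatch
    with pytest.raises(ValueError):
        LossParams(gamma=-1.0)
    with pytest.raises(ValueError):
        LossParams(alpha=[-1, 1, 1, 1, 1])


def test_alpha_from_frequencies_normalized():
    a = alpha_from_frequencies([484, 232, 366, 226, 179])
    assert a.mean() == pytest.approx(1.0, abs=1e-12)
    assert a[4] == a.max()  # rarest class weighted hardest
    with pytest.raises(ValueError):
        alpha_from_frequencies([10, 0, 5, 5, 5])


def test_logits_loss_matches_probability_surface(rng):
    params = LossParams(alpha=rng.uniform(0.5, 1.5, 5), gamma=2.0)
    z = rng.standard_normal((6, 5))
    y = rng.integers(0, 5, size=6)
    p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
    total, ce, fl = combined_loss_logits(ag.Tensor(z), y, params,
                                         return_components=True)
    assert ce == pytest.approx(cross_entropy(p, y), abs=1e-9)
    assert fl == pytest.approx(focal_loss(p, y, params), abs=1e-9)
    assert float(total.data) == pytest.approx(combined_loss(p, y, params),
                                              abs=1e-9)
    assert float(total.data) == pytest.approx(0.5 * ce + 0.5 * fl, abs=1e-12)


def test_logits_loss_gradient_matches_finite_difference(rng):
    params = LossParams(alpha=rng.uniform(0.5, 1.5, 5), gamma=2.0)
    z0 = rng.standard_normal((4, 5))
    y = rng.integers(0, 5, size=4)
    z = ag.Tensor(z0, requires_grad=True)
    combined_loss_logits(z, y, params).backward()
    eps = 1e-6
    num = np.zeros_like(z0)
    for i in range(4):
        for j in range(5):
            zp, zm = z0.copy(), z0.copy()
            zp[i, j] += eps
            zm[i, j] -= eps
            num[i, j] = (
                float(combined_loss_logits(ag.Tensor(zp), y, params).data)
                - float(combined_loss_logits(ag.Tensor(zm), y, params).data)
            ) / (2 * eps)
    np.testing.assert_allclose(z.grad, num, atol=1e-4)


def test_combined_nonnegative(rng):
    params = LossParams(alpha=rng.uniform(0, 2, 5), gamma=rng.uniform(0, 4))
    for _ in range(10):
        p, y = random_probs(rng)
        assert combined_loss(p, y, params) >= 0
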