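"""Hand-computed values, analytic identities and invariants of the
segmentation losses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hfsnet import losses, nn


def _probs_from_fg(fg):
    """(N, *spatial) foreground probabilities -> normalized 2-class map."""
    fg = np.asarray(fg, dtype=np.float64)
    return np.stack([1.0 - fg, fg], axis=1)


def _random_pair(rng, shape=(2, 6, 6)):
    fg = rng.uniform(0.02, 0.98, size=shape)
    target = (rng.uniform(size=shape) < 0.4).astype(np.int32)
    return _probs_from_fg(fg), target


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        t = np.array([[[0, 1], [1, 0]]], dtype=np.int32)
        p = _probs_from_fg(t.astype(float))
        assert losses.cross_entropy(p, t) == pytest.approx(0.0, abs=1e-5)

    def test_uniform_two_class_is_ln2(self):
        p = _probs_from_fg(np.full((1, 4, 4), 0.5))
        t = np.zeros((1, 4, 4), dtype=np.int32)
        assert losses.cross_entropy(p, t) == pytest.approx(np.log(2), abs=1e-9)

    def test_two_voxel_hand_value(self):
        # p(true class) = 0.5 and 0.25 -> -(ln 0.5 + ln 0.25)/2
        p = _probs_from_fg(np.array([[[0.5, 0.25]]]))
        t = np.ones((1, 1, 2), dtype=np.int32)
        assert losses.cross_entropy(p, t) == pytest.approx(1.0397207, abs=1e-6)


class TestDiceLoss:
    def test_perfect_and_disjoint(self):
        t = np.zeros((1, 16, 16), dtype=np.int32)
        t[0, 2:8, 2:8] = 1
        perfect = _probs_from_fg(t.astype(float))
        assert losses.dice_loss(perfect, t) == pytest.approx(0.0, abs=1e-2)
        disjoint = np.roll(t, 8, axis=2)
        assert losses.dice_loss(_probs_from_fg(disjoint.astype(float)),
                                t) == pytest.approx(1.0, abs=0.02)

    def test_constant_half_on_all_foreground(self):
        # closed form with smoothing s: 1 - (2*0.5*n + s)/(0.5*n + n + s)
        n = 64 * 64
        t = np.ones((1, 64, 64), dtype=np.int32)
        p = _probs_from_fg(np.full((1, 64, 64), 0.5))
        expected = 1 - (n + 1.0) / (1.5 * n + 1.0)
        assert losses.dice_loss(p, t) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1 / 3, abs=1e-3)

    def test_matches_set_arithmetic_on_hard_predictions(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pred = (rng.uniform(size=(1, 10, 10)) < 0.3)
            t = (rng.uniform(size=(1, 10, 10)) < 0.3).astype(np.int32)
            inter = np.logical_and(pred, t).sum()
            expected = 1 - (2 * inter + 1.0) / (pred.sum() + t.sum() + 1.0)
            got = losses.dice_loss(_probs_from_fg(pred.astype(float)), t)
            assert got == pytest.approx(expected, abs=1e-6)


class TestFocalLoss:
    def test_gamma_zero_equals_cross_entropy(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            p, t = _random_pair(rng)
            assert losses.focal_loss(p, t, gamma=0.0) == pytest.approx(
                losses.cross_entropy(p, t), abs=1e-6)

    def test_certain_prediction_is_zero(self):
        t = np.ones((1, 3, 3), dtype=np.int32)
        p = _probs_from_fg(np.ones((1, 3, 3)))
        assert losses.focal_loss(p, t, gamma=2.0) == pytest.approx(0.0,
                                                                   abs=1e-5)

    def test_single_voxel_hand_value(self):
        # p_t = 0.5, gamma = 2 -> 0.25 * ln 2
        p = _probs_from_fg(np.array([[[0.5]]]))
        t = np.ones((1, 1, 1), dtype=np.int32)
        assert losses.focal_loss(p, t, gamma=2.0) == pytest.approx(
            0.25 * np.log(2), abs=1e-9)

    def test_negative_gamma_rejected(self):
        p = _probs_from_fg(np.full((1, 2, 2), 0.5))
        with pytest.raises(ValueError):
            losses.focal_loss(p, np.zeros((1, 2, 2), dtype=np.int32),
                              gamma=-1.0)


class TestMfbWeights:
    @pytest.mark.parametrize("freqs,expected", [
        ((0.9, 0.1), (0.5 / 0.9, 5.0)),
        ((0.5, 0.5), (1.0, 1.0)),
        ((0.6, 0.3, 0.1), (0.5, 1.0, 3.0)),
    ])
    def test_hand_values(self, freqs, expected):
        np.testing.assert_allclose(losses.mfb_weights(freqs), expected,
                                   atol=1e-12)

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValueError):
            losses.mfb_weights((1.0, 0.0))
        with pytest.raises(ValueError):
            losses.mfb_weights((0.5, 0.4))  # does not sum to 1


class TestCombine:
    def test_single_term_equals_plain_loss(self):
        rng = np.random.default_rng(2)
        p, t = _random_pair(rng)
        fn = losses.combine(losses.LossSpec.parse("ce"))
        assert fn(p, t) == pytest.approx(losses.cross_entropy(p, t), abs=1e-12)

    def test_focal_gamma0_plus_dice_equals_ce_plus_dice(self):
        rng = np.random.default_rng(3)
        p, t = _random_pair(rng)
        a = losses.combine(losses.LossSpec.parse("focal+dice",
                                                 focal_gamma=0.0))(p, t)
        b = losses.combine(losses.LossSpec.parse("ce+dice"))(p, t)
        assert a == pytest.approx(b, abs=1e-9)

    def test_perfect_prediction_near_zero(self):
        t = np.zeros((1, 8, 8), dtype=np.int32)
        t[0, 1:5, 1:5] = 1
        p = _probs_from_fg(t.astype(float))
        fn = losses.combine(losses.LossSpec.parse("ce+dice"))
        assert fn(p, t) < 0.05

    def test_gradient_flows_through_every_term(self):
        rng = np.random.default_rng(4)
        fg = rng.uniform(0.1, 0.9, size=(1, 4, 4))
        logits = nn.Tensor(rng.normal(size=(1, 2, 4, 4)), requires_grad=True)
        probs = logits.softmax(axis=1)
        t = (rng.uniform(size=(1, 4, 4)) < 0.5).astype(np.int32)
        fn = losses.combine(losses.LossSpec.parse("focal+dice"))
        loss = fn(probs, t)
        loss.backward()
        assert logits.grad is not None and np.any(logits.grad != 0)

    def test_bad_specs_rejected(self):
        with pytest.raises(ValueError):
            losses.LossSpec(terms=())
        with pytest.raises(ValueError):
            losses.LossSpec.parse("ce+hausdorff")
        with pytest.raises(ValueError):
            losses.LossSpec(terms=("ce",), weights=(-1.0,))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.floats(0.0, 4.0))
def test_losses_nonnegative(seed, gamma):
    rng = np.random.default_rng(seed)
    p, t = _random_pair(rng, shape=(1, 5, 5))
    assert losses.cross_entropy(p, t) >= 0
    assert 0 <= losses.dice_loss(p, t) <= 1
    assert losses.focal_loss(p, t, gamma=gamma) >= 0
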