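"""Objective-function identities against hand-computed and brute-force
oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adverseg import losses
from adverseg.losses import (LossWeights, conventional_gan_value, dice_term,
                             dice_term_batch, discriminator_objective,
                             generator_objective, mae_term)
from adverseg.nn import Tensor


class TestDiceTerm:
    def test_empty_masks_hit_epsilon_limit(self):
        z = np.zeros((8, 8))
        for eps in (1.0, 0.5, 1e-6):
            assert dice_term(z, z, eps) == pytest.approx(-1.0)

    def test_perfect_match_is_minus_one(self):
        mask = np.zeros((16, 16))
        mask[:10, :10] = 1  # 100 foreground pixels
        assert dice_term(mask, mask, 1.0) == pytest.approx(-(201 / 201))

    def test_half_overlap(self):
        truth = np.zeros(200)
        truth[:100] = 1
        pred = np.zeros(200)
        pred[50:150] = 1  # 50 of 100 foreground pixels overlap
        val = dice_term(pred, truth, eps=1e-6)
        assert val == pytest.approx(-0.5, abs=1e-6)

    def test_bounded_and_decreasing_in_overlap(self, rng):
        truth = (rng.random((32, 32)) > 0.8).astype(float)
        vals = []
        for frac in (0.0, 0.5, 1.0):
            pred = truth * frac
            vals.append(dice_term(pred, truth, 1.0))
        assert all(-1 <= v <= 0 for v in vals)
        assert vals[0] > vals[1] > vals[2]  # more overlap, lower loss

    def test_pixel_permutation_invariance(self, rng):
        pred = rng.random(64)
        truth = (rng.random(64) > 0.5).astype(float)
        perm = rng.permutation(64)
        assert dice_term(pred, truth, 1.0) == pytest.approx(
            dice_term(pred[perm], truth[perm], 1.0))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            dice_term(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_batch_version_averages_items(self, rng):
        pred = rng.random((3, 1, 8, 8))
        truth = (rng.random((3, 1, 8, 8)) > 0.5).astype(float)
        per_item = [dice_term(pred[i], truth[i], 1.0) for i in range(3)]
        assert dice_term_batch(pred, truth, 1.0) == pytest.approx(
            np.mean(per_item), abs=1e-6)


class TestMaeTerm:
    def test_identical_pyramids_give_zero(self, rng):
        feats = [rng.random((1, 4, 8, 8)), rng.random((1, 8, 4, 4))]
        assert mae_term(feats, [f.copy() for f in feats]) == 0.0

    def test_constant_offset(self, rng):
        feats = [rng.random((1, 4, 8, 8)), rng.random((1, 8, 4, 4))]
        shifted = [f + 0.5 for f in feats]
        assert mae_term(feats, shifted) == pytest.approx(0.5, abs=1e-6)

    def test_matches_bruteforce_loop(self, rng):
        real = [rng.random((2, 3, 6, 6)), rng.random((2, 5, 3, 3))]
        fake = [rng.random((2, 3, 6, 6)), rng.random((2, 5, 3, 3))]
        expected = 0.0
        for r, f in zip(real, fake):
            acc, cnt = 0.0, 0
            for rv, fv in zip(r.ravel(), f.ravel()):
                acc += abs(rv - fv)
                cnt += 1
            expected += acc / cnt
        expected /= len(real)
        assert mae_term(real, fake) == pytest.approx(expected, rel=1e-9)

    def test_symmetry_and_nonnegativity(self, rng):
        a = [rng.random((1, 2, 4, 4))]
        b = [rng.random((1, 2, 4, 4))]
        assert mae_term(a, b) == pytest.approx(mae_term(b, a))
        assert mae_term(a, b) >= 0

    def test_level_count_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="levels"):
            mae_term([rng.random((1, 2, 4, 4))], [])


class TestObjectives:
    def test_lambda_zero_reduces_to_scaled_mae(self, rng):
        pred = rng.random((2, 1, 8, 8))
        truth = (rng.random((2, 1, 8, 8)) > 0.5).astype(float)
        real = [rng.random((2, 4, 4, 4))]
        fake = [rng.random((2, 4, 4, 4))]
        w = LossWeights(lam=0.0, delta=2.5)
        assert generator_objective(pred, truth, real, fake, w) == \
            pytest.approx(2.5 * mae_term(real, fake))

    def test_delta_zero_perfect_prediction_is_minus_lambda(self, rng):
        truth = (rng.random((2, 1, 8, 8)) > 0.5).astype(float)
        feats = [rng.random((2, 4, 4, 4))]
        w = LossWeights(lam=3.0, delta=0.0)
        assert generator_objective(truth, truth, feats, feats, w) == \
            pytest.approx(-3.0, abs=1e-5)

    def test_hand_computed_batch_value(self):
        # two items with known Dice terms plus a one-level pyramid offset
        pred = np.zeros((2, 1, 2, 2))
        truth = np.zeros((2, 1, 2, 2))
        pred[0] = 1.0
        truth[0] = 1.0          # item 0: dice = -(8+1)/(8+1) = -1
        truth[1, 0, 0, 0] = 1.0  # item 1: dice = -(0+1)/(1+1) = -0.5
        real = [np.zeros((2, 1, 2, 2))]
        fake = [np.full((2, 1, 2, 2), 0.25)]
        w = LossWeights(lam=1.0, delta=1.0, eps=1.0)
        expected = (-1.0 - 0.5) / 2 + 0.25
        assert generator_objective(pred, truth, real, fake, w) == \
            pytest.approx(expected, abs=1e-7)

    def test_discriminator_is_exact_negation_of_mae_component(self, rng):
        real = [rng.random((2, 3, 4, 4)), rng.random((2, 5, 2, 2))]
        fake = [rng.random((2, 3, 4, 4)), rng.random((2, 5, 2, 2))]
        w = LossWeights(lam=0.0, delta=1.7)
        pred = rng.random((2, 1, 8, 8))
        truth = (rng.random((2, 1, 8, 8)) > 0.5).astype(float)
        gen_obj = generator_objective(pred, truth, real, fake, w)
        assert discriminator_objective(real, fake, w) == \
            pytest.approx(-gen_obj, rel=1e-9)

    def test_identical_pyramids_give_zero_discriminator_loss(self, rng):
        feats = [rng.random((1, 2, 4, 4))]
        assert discriminator_objective(feats, feats) == 0.0

    def test_non_identical_pyramids_give_negative_loss(self, rng):
        real = [rng.random((1, 2, 4, 4))]
        fake = [rng.random((1, 2, 4, 4))]
        assert discriminator_objective(real, fake) < 0

    def test_gradients_flow_through_tensor_inputs(self, rng):
        pred = Tensor(rng.random((1, 1, 4, 4)).astype(np.float32),
                      requires_grad=True)
        truth = np.zeros((1, 1, 4, 4), dtype=np.float32)
        truth[0, 0, :2] = 1
        real = [Tensor(rng.random((1, 2, 2, 2)).astype(np.float32))]
        fake = [Tensor(rng.random((1, 2, 2, 2)).astype(np.float32),
                       requires_grad=True)]
        obj = generator_objective(pred, Tensor(truth), real, fake)
        obj.backward()
        assert pred.grad is not None and np.any(pred.grad != 0)
        assert fake[0].grad is not None


class TestInvalidWeights:
    @pytest.mark.parametrize("kw", [{"lam": -1}, {"delta": -0.5},
                                    {"eps": 0.0}])
    def test_rejected(self, kw):
        with pytest.raises(ValueError):
            LossWeights(**kw)


def test_conventional_gan_value_reference():
    # perfect discriminator on a non-trained reference objective
    assert conventional_gan_value([1.0], [1e-12]) == pytest.approx(0.0,
                                                                   abs=1e-9)
    # D(real)=D(fake)=0.5 gives 2*log(0.5)
    assert conventional_gan_value([0.5], [0.5]) == pytest.approx(
        2 * np.log(0.5))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=30),
       st.lists(st.booleans(), min_size=1, max_size=30),
       st.floats(1e-6, 10.0))
def test_dice_term_always_in_unit_interval(pred, truth, eps):
    n = min(len(pred), len(truth))
    p = np.array(pred[:n])
    t = np.array(truth[:n], dtype=float)
    val = dice_term(p, t, eps)
    assert -1.0 - 1e-9 <= val <= 0.0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_mae_triangle_inequality(seed):
    r = np.random.default_rng(seed)
    a = [r.random((1, 2, 3, 3))]
    b = [r.random((1, 2, 3, 3))]
    c = [r.random((1, 2, 3, 3))]
    assert mae_term(a, c) <= mae_term(a, b) + mae_term(b, c) + 1e-12
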