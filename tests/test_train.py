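"""Training-loop bookkeeping, reproducibility, prediction and evaluation."""

import dataclasses

import numpy as np
import pytest

from adverseg import losses as L
from adverseg import models
from adverseg import train as training


def _fresh_nets(seed=0):
    gen = models.build_generator(models.GeneratorConfig(seed=seed))
    disc = models.build_discriminator(models.DiscriminatorConfig(seed=seed + 1))
    return gen, disc


def _snapshot(net):
    return {k: v.copy() for k, v in net.state_dict().items()}


def test_one_epoch_bookkeeping(small_pairs):
    gen, disc = _fresh_nets()
    g0, d0 = _snapshot(gen), _snapshot(disc)
    cfg = training.TrainConfig(epochs=1, batch_size=2, seed=5)
    gen, disc, hist = training.train(gen, disc, small_pairs[:4],
                                     small_pairs[4:6], cfg)
    assert hist.epoch == [1]
    assert len(hist.gen_loss) == len(hist.val_dice) == 1
    changed_g = any(not np.array_equal(g0[k], v)
                    for k, v in gen.state_dict().items())
    changed_d = any(not np.array_equal(d0[k], v)
                    for k, v in disc.state_dict().items())
    assert changed_g and changed_d


def test_seeded_runs_are_bit_identical(small_pairs):
    histories = []
    for _ in range(2):
        gen, disc = _fresh_nets(seed=3)
        cfg = training.TrainConfig(epochs=2, batch_size=2, seed=9)
        *_, hist = training.train(gen, disc, small_pairs[:6],
                                  small_pairs[6:8], cfg)
        histories.append(dataclasses.asdict(hist))
    assert histories[0] == histories[1]


def test_dice_only_ablation_trains_without_discriminator(small_pairs):
    gen, disc = _fresh_nets(seed=1)
    d0 = _snapshot(disc)
    w = L.LossWeights(lam=1.0, delta=0.0)
    cfg = training.TrainConfig(epochs=1, batch_size=2, seed=2,
                               loss_weights=w)
    gen, disc, hist = training.train(gen, disc, small_pairs[:4],
                                     small_pairs[4:6], cfg)
    # discriminator untouched, logged discriminator loss identically zero
    assert all(np.array_equal(d0[k], v) for k, v in disc.state_dict().items())
    assert hist.disc_loss == [0.0]


def test_non_finite_input_aborts_with_diagnostic(small_pairs):
    gen, disc = _fresh_nets()
    bad = [(np.full((32, 32), np.nan, dtype=np.float32),
            small_pairs[0].mask)]
    cfg = training.TrainConfig(epochs=1, batch_size=1, seed=0)
    with pytest.raises(FloatingPointError, match="epoch 1"):
        training.train(gen, disc, bad, [], cfg)


def test_zero_sum_adversarial_contract(small_pairs, rng):
    """With lam=0 the generator objective and the discriminator objective
    are exact negations on the same feature pyramids."""
    gen, disc = _fresh_nets(seed=4)
    x = np.stack([p.image for p in small_pairs[:2]])[:, None]
    y = np.stack([p.mask for p in small_pairs[:2]])[:, None].astype(np.float32)
    pred = gen(x)
    feats_real, _ = disc(x, y)
    feats_fake, _ = disc(x, pred)
    w = L.LossWeights(lam=0.0, delta=1.0)
    g_obj = L.generator_objective(pred, y, feats_real, feats_fake, w)
    d_obj = L.discriminator_objective(feats_real, feats_fake, w)
    assert float(d_obj.data) == pytest.approx(-float(g_obj.data), rel=1e-6)


def test_predict_pads_and_crops_odd_sizes(trained_model, rng):
    gen = trained_model["gen"]
    img = rng.random((100, 100)).astype(np.float32)
    prob, mask = training.predict(gen, img)
    assert prob.shape == mask.shape == (100, 100)
    assert set(np.unique(mask)) <= {0, 1}


def test_predict_batch_preserves_order(trained_model, small_pairs):
    gen = trained_model["gen"]
    imgs = np.stack([p.image for p in small_pairs[:3]])
    probs, masks = training.predict(gen, imgs)
    assert probs.shape == masks.shape == imgs.shape
    for i in range(3):
        p_single, m_single = training.predict(gen, imgs[i])
        np.testing.assert_array_equal(m_single, masks[i])


class _TruthStub:
    """Generator stand-in that returns the probability map it is shown.

    Feeding it the ground-truth masks as images produces perfect
    predictions."""

    def eval(self):
        return self

    def __call__(self, x):
        from adverseg.nn import Tensor

        return Tensor(np.asarray(x, dtype=np.float32))


def test_evaluate_with_truth_stub_is_perfect(small_pairs):
    items = [(p.mask.astype(np.float32), p.mask) for p in small_pairs
             if p.mask.any()]
    report = training.evaluate(_TruthStub(), items)
    assert report.summary.loc["DSC", "mean"] == 1.0
    assert report.summary.loc["VOE", "mean"] == 0.0
    assert report.summary.loc["ASD", "mean"] == 0.0


class _BackgroundStub(_TruthStub):
    def __call__(self, x):
        from adverseg.nn import Tensor

        return Tensor(np.zeros_like(np.asarray(x, dtype=np.float32)))


def test_evaluate_with_background_stub_is_zero(small_pairs):
    items = [(p.image, p.mask) for p in small_pairs if p.mask.any()]
    report = training.evaluate(_BackgroundStub(), items)
    assert report.summary.loc["DSC", "mean"] == 0.0
    assert report.summary.loc["SEN", "mean"] == 0.0
    assert "ASD" in report.flags  # empty predictions: ASD undefined


def test_evaluate_empty_set_rejected(trained_model):
    with pytest.raises(ValueError, match="empty"):
        training.evaluate(trained_model["gen"], [])


def test_trained_model_learns_the_phantom_task(trained_model):
    """Session model (quick adaptive-optimizer training) reaches high Dice
    and its evaluation agrees with the final validation curve."""
    report = training.evaluate(trained_model["gen"], trained_model["val"])
    hard_dsc = report.summary.loc["DSC", "mean"]
    assert hard_dsc > 0.9
    assert hard_dsc == pytest.approx(trained_model["history"].val_dice[-1],
                                     abs=0.05)


def test_trained_model_excludes_hollow_interiors(trained_model):
    """The collecting-system analogue: interior cavities must not be
    labelled foreground."""
    from adverseg import phantom

    base = dict(image_size=32, region_axis_range=(5.0, 7.0),
                n_regions_choices=(1,), seed=321, noise_sd=0.02)
    hollow_cfg = phantom.PhantomConfig(hollow_prob=1.0, hollow_scale=0.5,
                                       **base)
    filled_cfg = phantom.PhantomConfig(hollow_prob=0.0, **base)
    excluded = total = 0
    for idx in range(10):
        hollow = phantom.generate_pair(hollow_cfg, idx)
        filled = phantom.generate_pair(filled_cfg, idx)
        hole = filled.mask.astype(bool) & ~hollow.mask.astype(bool)
        _, pred = training.predict(trained_model["gen"], hollow.image)
        excluded += int((pred[hole] == 0).sum())
        total += int(hole.sum())
    assert total > 0
    assert excluded / total >= 0.9


def test_checkpoint_roundtrip(tmp_path, trained_model, small_pairs):
    gen, disc = trained_model["gen"], trained_model["disc"]
    path = tmp_path / "ckpt.npz"
    training.save_checkpoint(path, gen, disc, trained_model["config"],
                             epoch=6)
    gen2, disc2, meta = training.load_checkpoint(path)
    assert meta["epoch"] == 6
    img = small_pairs[0].image
    p1, _ = training.predict(gen, img)
    p2, _ = training.predict(gen2, img)
    np.testing.assert_array_equal(p1, p2)


def test_split_dataset_fractions_and_determinism(small_pairs):
    tr1, va1, te1 = training.split_dataset(small_pairs, seed=3)
    tr2, va2, te2 = training.split_dataset(small_pairs, seed=3)
    assert len(tr1) + len(va1) + len(te1) == len(small_pairs)
    assert [id(p) for p in tr1] == [id(p) for p in tr2]
    with pytest.raises(ValueError):
        training.split_dataset(small_pairs, fractions=(0.5, 0.2, 0.1))


def test_history_csv_and_plot(tmp_path, trained_model):
    hist = trained_model["history"]
    hist.to_csv(tmp_path / "hist.csv")
    training.plot_history(hist, tmp_path / "curves.png")
    assert (tmp_path / "hist.csv").exists()
    assert (tmp_path / "curves.png").stat().st_size > 0
    df = hist.to_dataframe()
    assert list(df["epoch"]) == list(range(1, len(df) + 1))
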