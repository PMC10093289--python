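import numpy as np
import pytest

from adverseg import models, phantom
from adverseg import train as training


@pytest.fixture(scope="session")
def small_pairs():
    """A dozen 32x32 phantom pairs for fast structural tests."""
    cfg = phantom.PhantomConfig(image_size=32, region_axis_range=(4.0, 7.0),
                                seed=123)
    pairs, _ = phantom.generate_dataset(cfg, 12)
    return pairs


@pytest.fixture(scope="session")
def tiny_generator():
    return models.build_generator(models.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def tiny_discriminator():
    return models.build_discriminator(models.DiscriminatorConfig(seed=1))


@pytest.fixture(scope="session")
def trained_model():
    """A quickly trained (Adam, 32x32) model shared by prediction-quality
    tests; training cost is paid once per session."""
    cfg = phantom.PhantomConfig(image_size=32, region_axis_range=(4.0, 7.0),
                                seed=7)
    pairs, _ = phantom.generate_dataset(cfg, 60)
    gen = models.build_generator(models.GeneratorConfig(seed=2))
    disc = models.build_discriminator(models.DiscriminatorConfig(seed=3))
    tc = training.TrainConfig(epochs=6, batch_size=2, seed=4,
                              optimizer="adam", learning_rate=1e-3)
    gen, disc, history = training.train(gen, disc, pairs[:48], pairs[48:], tc)
    return {"gen": gen, "disc": disc, "history": history,
            "train": pairs[:48], "val": pairs[48:], "config": tc}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
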