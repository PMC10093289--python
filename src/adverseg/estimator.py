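"""Scikit-learn style front end for the adversarial segmenter.

:class:`AdversarialSegmenter` wraps network construction, adversarial
training and thresholded prediction behind the familiar
``fit`` / ``predict`` / ``predict_proba`` / ``score`` surface, so the model
composes with sklearn model selection. ``X`` is a stack of 2-D grayscale
slices ``(n_samples, height, width)`` with intensities in [0, 1]; ``y`` is
the matching stack of binary masks.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import losses, models, train as training


class AdversarialSegmenter(BaseEstimator):
    """Dense-block encoder-decoder generator trained against a multi-scale
    feature discriminator.

    Parameters
    ----------
    base_channels, growth, n_dense_layers:
        Generator widths: channels after the stem convolution, channels each
        dense layer adds, and layers per dense block.
    lam, delta, eps:
        Objective weights: Dice term weight, feature-MAE term weight, Dice
        smoothing constant. ``delta=0`` disables the adversarial term.
    learning_rate, weight_decay, momentum, optimizer, batch_size, epochs:
        Optimisation settings (momentum SGD by default).
    validation_fraction:
        Fraction of the fit data held out for the per-epoch validation
        curves (0 disables validation).
    threshold:
        Probability cut for ``predict``.
    random_state:
        Seed for initialisation and batch shuffling.

    Attributes
    ----------
    generator_, discriminator_:
        The trained networks.
    history_:
        Per-epoch :class:`~adverseg.train.TrainHistory`.
    n_params_:
        Trainable parameter count of the generator.
    """

    def __init__(self, base_channels: int = 8, growth: int = 4,
                 n_dense_layers: int = 4, lam: float = 1.0,
                 delta: float = 1.0, eps: float = 1.0,
                 learning_rate: float = 1e-4, weight_decay: float = 1e-4,
                 momentum: float = 0.9, optimizer: str = "sgd",
                 batch_size: int = 1, epochs: int = 14,
                 validation_fraction: float = 0.15, threshold: float = 0.5,
                 random_state: int = 0):
        self.base_channels = base_channels
        self.growth = growth
        self.n_dense_layers = n_dense_layers
        self.lam = lam
        self.delta = delta
        self.eps = eps
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.momentum = momentum
        self.optimizer = optimizer
        self.batch_size = batch_size
        self.epochs = epochs
        self.validation_fraction = validation_fraction
        self.threshold = threshold
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _validate_xy(self, X, y=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3:
            raise ValueError(
                f"X must have shape (n_samples, height, width), got {X.shape}")
        if X.shape[1] % 8 or X.shape[2] % 8:
            raise ValueError(
                "slice height and width must be divisible by 8 "
                f"(got {X.shape[1]}x{X.shape[2]})")
        if y is None:
            return X
        y = np.asarray(y)
        if y.shape != X.shape:
            raise ValueError(
                f"y shape {y.shape} does not match X shape {X.shape}")
        uniq = np.unique(y)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("y must be binary masks with values in {0, 1}")
        return X, y.astype(np.uint8)

    def fit(self, X, y):
        """Train generator and discriminator on slices ``X`` and masks
        ``y``."""
        X, y = self._validate_xy(X, y)
        seed = int(self.random_state)
        gen = models.build_generator(models.GeneratorConfig(
            base_channels=self.base_channels,
            dense=models.DenseBlockSpec(n_layers=self.n_dense_layers,
                                        growth=self.growth),
            seed=seed))
        disc = models.build_discriminator(
            models.DiscriminatorConfig(seed=seed + 1))
        config = training.TrainConfig(
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            momentum=self.momentum,
            optimizer=self.optimizer,
            batch_size=self.batch_size,
            epochs=self.epochs,
            loss_weights=losses.LossWeights(lam=self.lam, delta=self.delta,
                                            eps=self.eps),
            seed=seed)
        items = list(zip(X, y))
        if self.validation_fraction > 0 and len(items) >= 4:
            n_val = max(1, int(round(self.validation_fraction * len(items))))
            rng = np.random.default_rng(seed)
            order = rng.permutation(len(items))
            val_items = [items[i] for i in order[:n_val]]
            train_items = [items[i] for i in order[n_val:]]
        else:
            train_items, val_items = items, []
        gen, disc, history = training.train(gen, disc, train_items,
                                            val_items, config)
        self.generator_ = gen
        self.discriminator_ = disc
        self.history_ = history
        self.n_params_ = models.count_parameters(gen)
        self.image_shape_ = X.shape[1:]
        return self

    def _check_fitted(self):
        if not hasattr(self, "generator_"):
            raise RuntimeError("this AdversarialSegmenter is not fitted yet")

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel foreground probability maps, shape like ``X``."""
        self._check_fitted()
        X = self._validate_xy(X)
        prob, _ = training.predict(self.generator_, X, self.threshold)
        return prob

    def predict(self, X) -> np.ndarray:
        """Binary masks thresholded at ``threshold``."""
        self._check_fitted()
        X = self._validate_xy(X)
        _, masks = training.predict(self.generator_, X, self.threshold)
        return masks

    def score(self, X, y) -> float:
        """Mean Dice similarity coefficient over the given slices."""
        report = self.evaluate(X, y)
        return float(report.summary.loc["DSC", "mean"])

    def evaluate(self, X, y, spacing=(1.0, 1.0)):
        """Full per-slice metric report (DSC, VOE, ASD, ACC, SEN, SPE)."""
        self._check_fitted()
        X, y = self._validate_xy(X, y)
        return training.evaluate(self.generator_, list(zip(X, y)), spacing,
                                 self.threshold)
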