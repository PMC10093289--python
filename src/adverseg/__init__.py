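"""Adversarial dense-block segmentation of CT slices.

An encoder-decoder generator built from densely connected convolution blocks
produces per-pixel kidney probability maps; a six-layer multi-scale
discriminator judges (image, mask) pairs and supplies hierarchical features
for an L1 adversarial loss. The package also ships the standard overlap and
surface-distance evaluation metrics and a synthetic phantom generator for
fully self-contained experiments.
"""

__version__ = "0.1.0"


def __getattr__(name):
    if name == "AdversarialSegmenter":
        from .estimator import AdversarialSegmenter
        return AdversarialSegmenter
    raise AttributeError(name)


__all__ = ["AdversarialSegmenter", "__version__"]
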