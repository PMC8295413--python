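"""Per-slice condyle presence classification and run smoothing.

A small CNN decides for every axial slice whether a condyle head is visible:
two kernel-5 convolutions, two kernel-3 convolutions — each followed by ReLU
and a kernel-3 max pool — and one linear layer producing two logits.  The raw
per-slice decisions can oscillate on consecutive slices, so the binary vector
is post-processed with a uniform kernel: smoothed values exceeding a fixed
threshold are kept, which removes isolated flips and yields contiguous slice
runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .core import PresenceVector, ValidationError, Volume
from .nn import autograd as ag

MIN_INPUT_SIZE = 16  # four pooling stages of stride 2


@dataclass
class ClassifierConfig:
    """Architecture of the presence classifier.

    Kernel sizes are fixed by design to (5, 5, 3, 3) with a kernel-3 max pool
    after each convolution; channel widths are configurable (the model is
    deliberately small, with little effect on inference time).  The pool
    stride of 2 (padding 1) halves the feature map at every stage.
    """

    conv_channels: tuple[int, int, int, int] = (8, 16, 32, 32)
    kernel_sizes: tuple[int, int, int, int] = (5, 5, 3, 3)
    pool_kernel: int = 3
    pool_stride: int = 2
    input_shape: tuple[int, int] = (512, 512)
    n_classes: int = 2

    def validate(self) -> None:
        if tuple(self.kernel_sizes) != (5, 5, 3, 3):
            raise ValidationError("kernel_sizes: must be (5, 5, 3, 3)")
        if len(self.conv_channels) != 4 or any(c <= 0 for c in self.conv_channels):
            raise ValidationError("conv_channels: expected 4 positive widths")
        if min(self.input_shape) < MIN_INPUT_SIZE:
            raise ValidationError(
                f"input_shape: minimum side is {MIN_INPUT_SIZE} for the pooling cascade"
            )

    def feature_size(self) -> int:
        h, w = self.input_shape
        for _ in range(4):
            h = (h + 2 - self.pool_kernel) // self.pool_stride + 1
            w = (w + 2 - self.pool_kernel) // self.pool_stride + 1
        return self.conv_channels[-1] * h * w


class PresenceClassifier(nn.Module):
    def __init__(self, config: ClassifierConfig, rng: np.random.Generator):
        super().__init__()
        config.validate()
        self.config = config
        chans = [1, *config.conv_channels]
        self.convs = [
            nn.Conv2d(chans[i], chans[i + 1], config.kernel_sizes[i], rng) for i in range(4)
        ]
        self.pool = nn.MaxPool2d(config.pool_kernel, config.pool_stride, padding=1)
        self.head = nn.Linear(config.feature_size(), config.n_classes, rng)

    def layer_audit(self) -> list[str]:
        audit: list[str] = []
        for k in self.config.kernel_sizes:
            audit += [f"conv{k}", "relu", f"pool{self.config.pool_kernel}"]
        audit.append("linear")
        return audit

    def __call__(self, x):
        """x: (N, 1, H, W) -> logits (N, 2)."""
        h = x
        for conv in self.convs:
            h = self.pool(ag.relu(conv(h)))
        n = h.shape[0]
        return self.head(ag.reshape(h, (n, -1)))


def build_classifier(config: ClassifierConfig | None = None, seed: int = 0) -> PresenceClassifier:
    """Construct the presence classifier with seeded He initialization."""
    return PresenceClassifier(config or ClassifierConfig(), np.random.default_rng(seed))


def normalize_volume(volume: Volume) -> np.ndarray:
    """Per-volume z-score normalization applied before either network."""
    x = volume.intensities
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def predict_presence(
    model: PresenceClassifier, volume: Volume, batch_size: int = 16
) -> PresenceVector:
    """Score every slice and threshold by class argmax (deterministic)."""
    h, w = volume.shape[1:]
    if (h, w) != tuple(model.config.input_shape):
        raise ValidationError(
            f"volume slices {h}x{w} do not match classifier input {model.config.input_shape}"
        )
    model.eval()
    x = normalize_volume(volume)
    scores = np.empty(volume.n_slices)
    for lo in range(0, volume.n_slices, batch_size):
        batch = x[lo : lo + batch_size, None, :, :]
        logits = model(nn.Tensor(batch))
        p = ag.softmax(logits, axis=1).data
        scores[lo : lo + batch.shape[0]] = p[:, 1]
    bits = (scores >= 0.5).astype(np.uint8)
    return PresenceVector(bits, scores=scores)


def smooth_presence(
    v: PresenceVector | np.ndarray,
    kernel_width: int = 5,
    threshold: float = 0.5,
    max_iter: int | None = None,
) -> PresenceVector:
    """Uniform-kernel smoothing of the binary presence vector.

    The vector is convolved with a zero-padded uniform kernel of odd width and
    re-thresholded (``>= threshold``); the filter is iterated to its fixed
    point (for width 3 and threshold 0.5 this is an iterated majority filter),
    so the result carries no isolated single-slice flips.  ``max_iter=1``
    gives the plain single-pass filter.
    """
    if kernel_width % 2 == 0 or kernel_width < 1:
        raise ValidationError("kernel_width: must be an odd integer >= 1")
    if not (0 < threshold < 1):
        raise ValidationError("threshold: must lie in (0, 1)")
    values = v.values if isinstance(v, PresenceVector) else np.asarray(v)
    scores = v.scores if isinstance(v, PresenceVector) else None
    bits = values.astype(np.float64)
    kernel = np.full(kernel_width, 1.0 / kernel_width)
    limit = max_iter if max_iter is not None else max(len(bits), 1)
    for _ in range(limit):
        smoothed = np.convolve(bits, kernel, mode="same")
        new_bits = (smoothed >= threshold).astype(np.float64)
        if np.array_equal(new_bits, bits):
            break
        bits = new_bits
    else:
        bits = new_bits
    return PresenceVector(bits.astype(np.uint8), scores=scores)
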