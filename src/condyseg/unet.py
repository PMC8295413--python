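"""Modified U-Net for three-class axial slice segmentation.

The network follows the classic contracting/expansive layout with three
departures from the original design: every convolution uses same-padding (so
skip connections concatenate without cropping and the output matches the
input size), batch normalization is performed before every weighted layer,
and the head is a 1x1 convolution with a softmax over the three tissue
classes.  Downsampling is 2x2 max pooling; upsampling is a stride-2
transposed convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .classifier import normalize_volume
from .core import BACKGROUND, LabelVolume, PresenceVector, ValidationError, Volume
from .nn import autograd as ag


@dataclass
class UNetConfig:
    """Topology of the segmentation network.

    ``depth`` is the number of pooling (and upsampling) stages; channel width
    doubles at each stage from ``base_channels``.  ``bn_position`` is either
    ``"before"`` (batch norm before every weighted layer, the default) or
    ``"after"`` (the conventional conv -> BN -> ReLU ordering).  Input spatial
    dimensions must be divisible by ``2**depth``.
    """

    depth: int = 4
    base_channels: int = 64
    conv_kernel: int = 3
    pool_kernel: int = 2
    up_stride: int = 2
    bn_position: str = "before"
    padding: str = "same"
    n_classes: int = 3
    input_shape: tuple[int, int] = (512, 512)

    def validate(self) -> None:
        if self.depth < 1:
            raise ValidationError("depth: must be >= 1")
        if self.base_channels < 1:
            raise ValidationError("base_channels: must be >= 1")
        if self.bn_position not in ("before", "after"):
            raise ValidationError("bn_position: expected 'before' or 'after'")
        m = 2 ** self.depth
        if any(s % m for s in self.input_shape):
            raise ValidationError(
                f"input_shape: spatial dims must be divisible by {m} for depth {self.depth}"
            )


class _ConvBlock(nn.Module):
    """(BN -> conv -> ReLU) x 2, or (conv -> BN -> ReLU) x 2, per bn_position.

    ``first_of_network`` skips the normalization in front of the very first
    convolution (the raw input is already z-scored).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, bn_position: str,
                 rng: np.random.Generator, first_of_network: bool = False):
        super().__init__()
        self.bn_position = bn_position
        self.bn1 = None if (bn_position == "before" and first_of_network) else (
            nn.BatchNorm2d(c_in if bn_position == "before" else c_out)
        )
        self.conv1 = nn.Conv2d(c_in, c_out, kernel, rng)
        self.bn2 = nn.BatchNorm2d(c_out)
        self.conv2 = nn.Conv2d(c_out, c_out, kernel, rng)

    def __call__(self, x):
        if self.bn_position == "before":
            h = self.bn1(x) if self.bn1 is not None else x
            h = ag.relu(self.conv1(h))
            h = ag.relu(self.conv2(self.bn2(h)))
        else:
            h = ag.relu(self.bn1(self.conv1(x)))
            h = ag.relu(self.bn2(self.conv2(h)))
        return h


class UNet(nn.Module):
    def __init__(self, config: UNetConfig, rng: np.random.Generator):
        super().__init__()
        config.validate()
        self.config = config
        d, b, k = config.depth, config.base_channels, config.conv_kernel
        bp = config.bn_position

        self.enc = []
        c_in = 1
        for i in range(d):
            c_out = b * (2 ** i)
            self.enc.append(_ConvBlock(c_in, c_out, k, bp, rng, first_of_network=(i == 0)))
            c_in = c_out
        self.pool = nn.MaxPool2d(config.pool_kernel, config.pool_kernel)
        self.bottleneck = _ConvBlock(c_in, b * (2 ** d), k, bp, rng)

        self.up_bns = []
        self.ups = []
        self.dec = []
        c = b * (2 ** d)
        for i in reversed(range(d)):
            c_skip = b * (2 ** i)
            self.up_bns.append(nn.BatchNorm2d(c) if bp == "before" else None)
            self.ups.append(nn.ConvTranspose2d(c, c_skip, rng))
            self.dec.append(_ConvBlock(2 * c_skip, c_skip, k, bp, rng))
            c = c_skip
        self.head_bn = nn.BatchNorm2d(b) if bp == "before" else None
        self.head = nn.Conv2d(b, config.n_classes, 1, rng)

    def forward_logits(self, x):
        """x: (N, 1, H, W) -> pre-softmax logits (N, n_classes, H, W)."""
        skips = []
        h = x
        for block in self.enc:
            h = block(h)
            skips.append(h)
            h = self.pool(h)
        h = self.bottleneck(h)
        for up_bn, up, block, skip in zip(self.up_bns, self.ups, self.dec, reversed(skips)):
            h = up(up_bn(h) if up_bn is not None else h)
            h = block(ag.concat([skip, h], axis=1))
        h = self.head_bn(h) if self.head_bn is not None else h
        return self.head(h)

    def __call__(self, x):
        """Class probability maps (N, n_classes, H, W), summing to 1 per pixel."""
        return ag.softmax(self.forward_logits(x), axis=1)

    def log_probs(self, x):
        return ag.log_softmax(self.forward_logits(x), axis=1)


def build_unet(config: UNetConfig | None = None, seed: int = 0) -> UNet:
    """Construct the segmentation U-Net with seeded He initialization."""
    return UNet(config or UNetConfig(), np.random.default_rng(seed))


def segment_slices(
    model: UNet, volume: Volume, presence: PresenceVector, batch_size: int = 4
) -> "SegmentationResult":
    """Segment the presence-flagged slices; others are emitted all-background.

    ``presence`` is expected to be the smoothed vector so the selected slices
    form contiguous runs.  Argmax ties break toward the lowest class index.
    """
    if len(presence) != volume.n_slices:
        raise ValidationError("presence: length does not match the volume slice count")
    if tuple(volume.shape[1:]) != tuple(model.config.input_shape):
        raise ValidationError(
            f"volume slices {volume.shape[1:]} do not match U-Net input "
            f"{model.config.input_shape}"
        )
    model.eval()
    x = normalize_volume(volume)
    n_cls = model.config.n_classes
    prob_maps = np.zeros((volume.n_slices, n_cls) + volume.shape[1:])
    prob_maps[:, BACKGROUND] = 1.0
    selected = np.flatnonzero(presence.values)
    for lo in range(0, len(selected), batch_size):
        idx = selected[lo : lo + batch_size]
        probs = model(nn.Tensor(x[idx][:, None, :, :])).data
        prob_maps[idx] = probs
    label_slices = prob_maps.argmax(axis=1).astype(np.uint8)
    return SegmentationResult(prob_maps, label_slices, np.arange(volume.n_slices))


@dataclass
class SegmentationResult:
    """Per-slice class probability maps and their argmax labels."""

    prob_maps: np.ndarray  # (n_slices, n_classes, H, W)
    label_slices: np.ndarray  # (n_slices, H, W)
    slice_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.slice_indices = np.asarray(self.slice_indices, dtype=int)
        if len(self.slice_indices) != len(self.prob_maps):
            raise ValidationError("slice_indices: length mismatch with prob_maps")


def stack_to_labelvolume(result: SegmentationResult, volume: Volume) -> LabelVolume:
    """Stack per-slice labels into a 3D label volume in acquisition order."""
    order = np.argsort(result.slice_indices)
    idx = result.slice_indices[order]
    expected = np.arange(volume.n_slices)
    if not np.array_equal(idx, expected):
        missing = np.setdiff1d(expected, idx)
        raise ValidationError(f"slice_indices: missing slices {missing.tolist()}")
    return LabelVolume(result.label_slices[order], volume.voxel_spacing_mm)
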