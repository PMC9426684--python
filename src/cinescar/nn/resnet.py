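"""Canonical ResNet-50 topology as a structural description.

The classifier variant used here takes a 32-channel input (the cine frames
stacked as channels), keeps the standard bottleneck stages [3, 4, 6, 3] and
ends in global average pooling plus a single fully connected sigmoid unit.
``build_resnet50_classifier`` enumerates every layer and computes parameter
counts from the topology (convolutions carry biases; batch-normalisation
contributes scale/shift as trainable and moving mean/variance as
non-trainable parameters).  With 32 input channels the totals are the
full-scale 23.7M-parameter model; parameter accounting is the purpose of
this builder — phantom-scale training in this package uses the UNet and the
classical models.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class LayerCount:
    name: str
    trainable: int
    non_trainable: int = 0

    @property
    def total(self) -> int:
        return self.trainable + self.non_trainable


@dataclass
class ResNet50Spec:
    """Layer table and parameter totals of the classifier topology."""

    input_channels: int
    layers: list

    @property
    def total_params(self) -> int:
        return sum(l.total for l in self.layers)

    @property
    def trainable_params(self) -> int:
        return sum(l.trainable for l in self.layers)

    @property
    def non_trainable_params(self) -> int:
        return sum(l.non_trainable for l in self.layers)


_STAGES = ((64, 3), (128, 4), (256, 6), (512, 3))  # (bottleneck width, block count)


def _conv(name: str, cin: int, cout: int, k: int) -> LayerCount:
    return LayerCount(name, trainable=k * k * cin * cout + cout)


def _bn(name: str, channels: int) -> LayerCount:
    return LayerCount(name, trainable=2 * channels, non_trainable=2 * channels)


def build_resnet50_classifier(input_channels: int = 32) -> ResNet50Spec:
    """Enumerate the canonical 50-layer residual classifier and count parameters.

    The stem is a 7x7/64 convolution over ``input_channels`` planes; each
    stage stacks bottleneck blocks (1x1 -> 3x3 -> 1x1 with x4 expansion, a
    projection shortcut in the first block of each stage); the head is global
    average pooling into one fully connected output unit.
    """
    if input_channels < 1:
        raise ValueError("input_channels must be >= 1")
    layers: list = [
        _conv("stem.conv", input_channels, 64, 7),
        _bn("stem.bn", 64),
    ]
    cin = 64
    for stage_idx, (width, blocks) in enumerate(_STAGES):
        cout = width * 4
        for block in range(blocks):
            prefix = f"stage{stage_idx + 1}.block{block + 1}"
            if block == 0:
                layers.append(_conv(f"{prefix}.shortcut.conv", cin, cout, 1))
                layers.append(_bn(f"{prefix}.shortcut.bn", cout))
            layers.append(_conv(f"{prefix}.conv1", cin, width, 1))
            layers.append(_bn(f"{prefix}.bn1", width))
            layers.append(_conv(f"{prefix}.conv2", width, width, 3))
            layers.append(_bn(f"{prefix}.bn2", width))
            layers.append(_conv(f"{prefix}.conv3", width, cout, 1))
            layers.append(_bn(f"{prefix}.bn3", cout))
            cin = cout
    layers.append(LayerCount("head.fc", trainable=cin * 1 + 1))
    return ResNet50Spec(input_channels=input_channels, layers=layers)
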