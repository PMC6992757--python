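"""The Flat-net architecture: a pooling-free dilated heat-map generator.

The network keeps the full image resolution from input to output — no
pooling, no strided convolution, no upsampling, no fully connected layer.
Multi-scale context comes instead from a bank of parallel dilated
convolutions:

* **L1**: five parallel branches, each a 9x9 convolution at its own
  dilation rate (defaults 1, 2, 4, 8, 16), so the first layers see the
  image at five different resolutions;
* **L2**: a second consecutive 9x9 convolution per branch at the same
  rate;
* **L3**: channel concatenation of the five branch outputs;
* **L4**: a 5x5 convolution fusing the scales;
* **L5-L7**: three 1x1 convolutions, the last with ``outputs_per_network``
  channels.

All layers use rectifier activations except L7, which uses a hyperbolic
tangent; the training loss is the mean absolute error between predicted
and target heat-maps.  Because the concatenation at full resolution is
memory-hungry, the 21 landmarks are normally partitioned across several
networks of at most 5 output channels each (5 networks for the default
partition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..schema import LandmarkSchema
from .layers import Conv2D

__all__ = ["FlatNetConfig", "LandmarkPartition", "LayerInfo", "FlatNet",
           "build_flatnet", "count_parameters", "partition_landmarks"]


@dataclass(frozen=True)
class FlatNetConfig:
    """Hyper-parameters of one Flat-net sub-network.

    ``target_range`` selects the scale of the training targets fed to the
    tanh output layer: ``(0, 1)`` keeps the peak-1 Gaussian targets as
    encoded (the default; tanh covers [0, 1)), ``(-1, 1)`` rescales them
    to the full tanh range.
    """

    input_channels: int = 3
    branch_dilation_rates: tuple[int, ...] = (1, 2, 4, 8, 16)
    kernel_l1_l2: int = 9
    filters_l1: int = 32
    filters_l2: int = 64
    kernel_l4: int = 5
    filters_l4: int = 128
    filters_l5: int = 128
    filters_l6: int = 64
    outputs_per_network: int = 5
    target_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.branch_dilation_rates) != 5:
            raise ValueError("exactly 5 branch dilation rates are required")
        if any(int(d) != d or d < 1 for d in self.branch_dilation_rates):
            raise ValueError("dilation rates must be positive integers")
        for name in ("input_channels", "kernel_l1_l2", "filters_l1", "filters_l2",
                     "kernel_l4", "filters_l4", "filters_l5", "filters_l6",
                     "outputs_per_network"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.target_range not in ((0.0, 1.0), (-1.0, 1.0)):
            raise ValueError("target_range must be (0, 1) or (-1, 1)")


@dataclass(frozen=True)
class LandmarkPartition:
    """Disjoint ordered grouping of landmark abbreviations across networks."""

    groups: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        flat = [a for g in self.groups for a in g]
        if len(set(flat)) != len(flat):
            raise ValueError("partition groups must be disjoint")

    @property
    def flat(self) -> tuple[str, ...]:
        return tuple(a for g in self.groups for a in g)

    def __len__(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class LayerInfo:
    """Descriptor of one layer for architecture audits."""

    name: str
    kind: str            # "conv" or "concat"
    kernel: int | None
    dilation: int | None
    stride: int | None
    activation: str | None
    c_in: int | None
    c_out: int | None


def partition_landmarks(schema: LandmarkSchema,
                        max_per_network: int = 5) -> LandmarkPartition:
    """Greedy split of the schema into groups of at most ``max_per_network``.

    In schema order: 21 landmarks at <=5 per network give 5 groups of
    sizes [5, 5, 5, 5, 1]; at <=3 per network, 7 groups.
    """
    if max_per_network < 1:
        raise ValueError("max_per_network must be >= 1")
    abbrs = schema.abbreviations
    groups = tuple(tuple(abbrs[i:i + max_per_network])
                   for i in range(0, len(abbrs), max_per_network))
    return LandmarkPartition(groups=groups)


class FlatNet:
    """One Flat-net sub-network (see module docstring for the topology)."""

    def __init__(self, config: FlatNetConfig, rng_seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(rng_seed)
        c = config
        self.branches: list[tuple[Conv2D, Conv2D]] = []
        for d in c.branch_dilation_rates:
            l1 = Conv2D(c.kernel_l1_l2, c.input_channels, c.filters_l1,
                        dilation=int(d), activation="relu", rng=rng)
            l2 = Conv2D(c.kernel_l1_l2, c.filters_l1, c.filters_l2,
                        dilation=int(d), activation="relu", rng=rng)
            self.branches.append((l1, l2))
        n_branches = len(c.branch_dilation_rates)
        self.l4 = Conv2D(c.kernel_l4, n_branches * c.filters_l2, c.filters_l4,
                         activation="relu", rng=rng)
        self.l5 = Conv2D(1, c.filters_l4, c.filters_l5, activation="relu", rng=rng)
        self.l6 = Conv2D(1, c.filters_l5, c.filters_l6, activation="relu", rng=rng)
        self.l7 = Conv2D(1, c.filters_l6, c.outputs_per_network,
                         activation="tanh", rng=rng)

    # -- structure -------------------------------------------------------
    def conv_layers(self) -> list[Conv2D]:
        out = []
        for l1, l2 in self.branches:
            out += [l1, l2]
        out += [self.l4, self.l5, self.l6, self.l7]
        return out

    def layers(self) -> list[LayerInfo]:
        """Walkable layer descriptors, in forward order."""
        infos = []
        for i, (l1, l2) in enumerate(self.branches):
            for tag, lay in (("L1", l1), ("L2", l2)):
                infos.append(LayerInfo(f"{tag}.branch{i}", "conv", lay.kernel,
                                       lay.dilation, lay.stride, lay.activation,
                                       lay.c_in, lay.c_out))
        infos.append(LayerInfo("L3", "concat", None, None, None, None,
                               None, self.l4.c_in))
        for tag, lay in (("L4", self.l4), ("L5", self.l5),
                         ("L6", self.l6), ("L7", self.l7)):
            infos.append(LayerInfo(tag, "conv", lay.kernel, lay.dilation,
                                   lay.stride, lay.activation, lay.c_in, lay.c_out))
        return infos

    def parameters(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for i, (l1, l2) in enumerate(self.branches):
            out += [(f"L1.branch{i}.W", l1.W), (f"L1.branch{i}.b", l1.b),
                    (f"L2.branch{i}.W", l2.W), (f"L2.branch{i}.b", l2.b)]
        for tag, lay in (("L4", self.l4), ("L5", self.l5),
                         ("L6", self.l6), ("L7", self.l7)):
            out += [(f"{tag}.W", lay.W), (f"{tag}.b", lay.b)]
        return out

    # -- computation -----------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Run ``(B, rows, cols, input_channels)`` to ``(B, rows, cols, outputs)``."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[3] != self.config.input_channels:
            raise ValueError(
                f"expected (B, rows, cols, {self.config.input_channels}) input, "
                f"got {x.shape}")
        feats = [l2.forward(l1.forward(x, train), train) for l1, l2 in self.branches]
        cat = np.concatenate(feats, axis=3)
        h = self.l4.forward(cat, train)
        h = self.l5.forward(h, train)
        h = self.l6.forward(h, train)
        return self.l7.forward(h, train)

    def backward(self, dy: np.ndarray) -> None:
        """Backpropagate, leaving gradients on each layer's ``dW``/``db``."""
        d = self.l7.backward(dy)
        d = self.l6.backward(d)
        d = self.l5.backward(d)
        dcat = self.l4.backward(d)
        f2 = self.config.filters_l2
        for i, (l1, l2) in enumerate(self.branches):
            dbranch = dcat[..., i * f2:(i + 1) * f2]
            l1.backward(l2.backward(dbranch))


def build_flatnet(config: FlatNetConfig, rng_seed: int = 0) -> FlatNet:
    """Construct a Flat-net with seeded initial weights."""
    return FlatNet(config, rng_seed=rng_seed)


def count_parameters(net: FlatNet) -> int:
    """Total number of trainable scalars (weights + biases)."""
    return int(sum(p.size for _, p in net.parameters()))
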