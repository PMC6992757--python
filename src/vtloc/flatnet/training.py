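"""Training and inference for the partitioned heat-map localizer.

One Flat-net is trained per partition group on (3-channel image ->
Gaussian target heat-map stack) pairs with mean-absolute-error loss and
Adam.  5% of the training items are randomly set aside as a validation
split; training stops at ``max_epochs`` or when the validation loss stops
improving (plateau).  Inference runs every sub-network, concatenates the
predicted channels in partition order and decodes each channel by argmax
back to a full 21-point landmark set in schema order.

Input images are scaled to [0, 1]; targets are the peak-1 Gaussian
heat-maps (optionally rescaled to the full tanh range, see
``FlatNetConfig.target_range``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from ..augment import AugmentedCorpus
from ..heatmap import CodecConfig, HeatmapStack, encode_heatmaps, decode_heatmaps
from ..io import AnnotatedImage, to_three_channel
from ..schema import load_schema
from .layers import Adam, mae_loss
from .network import FlatNet, FlatNetConfig, LandmarkPartition, build_flatnet

__all__ = ["TrainConfig", "TrainedLocalizer", "train_localizer",
           "predict_landmarks", "predict_heatmaps"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation parameters shared by all sub-networks."""

    max_epochs: int = 30
    batch_size: int = 4
    validation_fraction: float = 0.05
    plateau_patience: int = 5
    plateau_min_delta: float = 1e-4
    optimizer_name: str = "adam"
    learning_rate: float = 1e-3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be >= 1")
        if self.optimizer_name != "adam":
            raise ValueError("only the 'adam' optimizer is implemented")


@dataclass
class TrainedLocalizer:
    """Per-group trained networks plus everything needed to run them."""

    networks: list[FlatNet]
    partition: LandmarkPartition
    codec: CodecConfig
    input_size: tuple[int, int]
    history: list[dict]          # per group: {"train_loss": [...], "val_loss": [...]}

    def save(self, model_dir) -> None:
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        cfg = self.networks[0].config
        manifest = {
            "partition": [list(g) for g in self.partition.groups],
            "codec": asdict(self.codec),
            "flatnet_config": {**asdict(cfg),
                               "branch_dilation_rates": list(cfg.branch_dilation_rates),
                               "target_range": list(cfg.target_range)},
            "input_size": list(self.input_size),
            "history": self.history,
        }
        (model_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        for g, net in enumerate(self.networks):
            arrays = {name: arr for name, arr in net.parameters()}
            np.savez(model_dir / f"group{g}.npz", **arrays)

    @classmethod
    def load(cls, model_dir) -> "TrainedLocalizer":
        model_dir = Path(model_dir)
        manifest = json.loads((model_dir / "manifest.json").read_text())
        fcfg = dict(manifest["flatnet_config"])
        fcfg["branch_dilation_rates"] = tuple(fcfg["branch_dilation_rates"])
        fcfg["target_range"] = tuple(fcfg["target_range"])
        partition = LandmarkPartition(tuple(tuple(g) for g in manifest["partition"]))
        networks = []
        for g, group in enumerate(partition.groups):
            net = build_flatnet(FlatNetConfig(**{**fcfg,
                                                 "outputs_per_network": len(group)}))
            stored = np.load(model_dir / f"group{g}.npz")
            for name, arr in net.parameters():
                arr[...] = stored[name]
            networks.append(net)
        return cls(networks=networks, partition=partition,
                   codec=CodecConfig(**manifest["codec"]),
                   input_size=tuple(manifest["input_size"]),
                   history=manifest["history"])


def _prepare_inputs(items: list[AnnotatedImage]) -> np.ndarray:
    x = np.stack([to_three_channel(it.image) for it in items]).astype(np.float32)
    return x / 255.0


def _prepare_targets(items: list[AnnotatedImage], group_idx: np.ndarray,
                     image_size: tuple[int, int], codec: CodecConfig,
                     target_range: tuple[float, float]) -> np.ndarray:
    stacks = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # augmented landmarks may leave the frame
        for it in items:
            st = encode_heatmaps(it.landmarks[group_idx], image_size, codec,
                                 skip_out_of_frame=True)
            stacks.append(st.values.astype(np.float32))
    t = np.stack(stacks)
    lo, hi = target_range
    if (lo, hi) != (0.0, 1.0):
        t = lo + (hi - lo) * t
    return t


def _epoch_loss(net: FlatNet, x: np.ndarray, t: np.ndarray, batch: int) -> float:
    total, n = 0.0, 0
    for i in range(0, len(x), batch):
        pred = net.forward(x[i:i + batch])
        total += float(np.abs(pred - t[i:i + batch]).sum())
        n += pred.size
    return total / n


def train_localizer(corpus, partition: LandmarkPartition,
                    flat_config: FlatNetConfig,
                    train_config: TrainConfig | None = None,
                    codec: CodecConfig | None = None,
                    verbose: bool = False) -> TrainedLocalizer:
    """Train one Flat-net per partition group.

    ``corpus`` is an :class:`AugmentedCorpus` or plain list of
    :class:`AnnotatedImage`; every item is a training sample.  Items must
    share a single image size.  Deterministic for a fixed
    ``train_config.rng_seed``.
    """
    train_config = train_config or TrainConfig()
    codec = codec or CodecConfig()
    items = corpus.items if isinstance(corpus, AugmentedCorpus) else list(corpus)
    if not items:
        raise ValueError("cannot train on an empty corpus")
    sizes = {it.shape for it in items}
    if len(sizes) != 1:
        raise ValueError(f"corpus mixes image sizes: {sorted(sizes)}")
    image_size = items[0].shape
    schema = load_schema()
    n_landmarks = len(items[0].landmarks)
    for abbr in partition.flat:
        if schema.index(abbr) >= n_landmarks:
            raise ValueError(f"landmark {abbr} missing from corpus annotations")

    x_all = _prepare_inputs(items)
    rng = np.random.default_rng(train_config.rng_seed)
    perm = rng.permutation(len(items))
    n_val = int(round(train_config.validation_fraction * len(items)))
    n_val = max(1, n_val) if len(items) >= 2 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    networks, history = [], []
    for g, group in enumerate(partition.groups):
        group_idx = np.array([schema.index(a) for a in group])
        cfg = FlatNetConfig(**{**_cfg_dict(flat_config),
                               "outputs_per_network": len(group)})
        net = build_flatnet(cfg, rng_seed=int(rng.integers(2 ** 31)))
        t_all = _prepare_targets(items, group_idx, image_size, codec,
                                 cfg.target_range)
        opt = Adam(net.conv_layers(), learning_rate=train_config.learning_rate)
        hist = {"train_loss": [], "val_loss": []}
        best_val, stale = np.inf, 0
        for epoch in range(train_config.max_epochs):
            order = rng.permutation(tr_idx)
            running, count = 0.0, 0
            for i in range(0, len(order), train_config.batch_size):
                idx = order[i:i + train_config.batch_size]
                pred = net.forward(x_all[idx], train=True)
                loss, grad = mae_loss(pred, t_all[idx])
                net.backward(grad)
                opt.step()
                running += loss * pred.size
                count += pred.size
            hist["train_loss"].append(running / max(count, 1))
            if n_val:
                vl = _epoch_loss(net, x_all[val_idx], t_all[val_idx],
                                 train_config.batch_size)
            else:
                vl = hist["train_loss"][-1]
            hist["val_loss"].append(vl)
            if verbose:
                print(f"group {g} epoch {epoch}: "
                      f"train {hist['train_loss'][-1]:.5f} val {vl:.5f}")
            if vl < best_val - train_config.plateau_min_delta:
                best_val, stale = vl, 0
            else:
                stale += 1
                if stale >= train_config.plateau_patience:
                    break
        networks.append(net)
        history.append(hist)
    return TrainedLocalizer(networks=networks, partition=partition, codec=codec,
                            input_size=image_size, history=history)


def _cfg_dict(cfg: FlatNetConfig) -> dict:
    return {f: getattr(cfg, f) for f in cfg.__dataclass_fields__}


def predict_heatmaps(localizer: TrainedLocalizer, image: np.ndarray) -> HeatmapStack:
    """Predicted heat-map stack for one grayscale image, in partition order."""
    if tuple(image.shape) != tuple(localizer.input_size):
        raise ValueError(f"image shape {image.shape} does not match the "
                         f"training size {localizer.input_size}")
    x = to_three_channel(np.asarray(image, dtype=np.float32) / 255.0)[None]
    channels = [net.forward(x)[0] for net in localizer.networks]
    values = np.concatenate(channels, axis=2)
    return HeatmapStack(values=values, channel_landmarks=localizer.partition.flat)


def predict_landmarks(localizer: TrainedLocalizer, image: np.ndarray) -> np.ndarray:
    """Predict the full landmark set for one image, in schema order.

    Returns an ``(L, 2)`` array of ``(x, y)`` pixel coordinates obtained by
    per-channel argmax decoding of the predicted heat-maps.
    """
    stack = predict_heatmaps(localizer, image)
    decoded = decode_heatmaps(stack)
    schema = load_schema()
    coords = np.full((len(schema), 2), np.nan)
    for ch, abbr in enumerate(stack.channel_landmarks):
        coords[schema.index(abbr)] = decoded.coords[ch]
    if np.any(np.isnan(coords)):
        missing = [a for a in schema.abbreviations
                   if a not in stack.channel_landmarks]
        raise ValueError(f"partition does not cover the schema; missing {missing}")
    return coords
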