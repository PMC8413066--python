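"""Hierarchical view-pooling network (HVPN) architectures and ablations.

The network has three parts.  (1) One view-specific CNN branch per input
view: two 3-wide convolutions with ``F`` filters, two locally connected
1x1 layers, and a fully connected layer, every layer followed by batch
normalization and ReLU, with dropout on the last LC and the FC layer; the
input itself is batch-normalized.  (2) Hierarchical view-pooling branches:
the first-level branch pools the raw view tensors, the second-level branch
pools the low-level (bottom-convolution) maps of all branches together
with the first-level pooled map.  Each pooling branch starts with a
feature-level view pooling (FLVP) layer — depth concatenation followed by
a 1x1 convolution with ``F`` filters — and continues with a conv/LC/FC
tail.  (3) A view aggregation network: the concatenated view-specific
features and each pooling branch's features feed separate classifier
streams (FC -> G-way FC -> softmax), and the final score is the
element-wise sum of the head softmax vectors.

Ablation variants: ``hvpn-maxpool`` / ``hvpn-avgpool`` swap the
second-level FLVP for an element-wise maximum / average over the (equally
shaped) depth-``F`` maps; ``vs-l1vp`` / ``vs-l2vp`` drop the second /
first pooling branch; ``vs-only`` keeps only the view-specific branches
and a single classifier.  The first-level FLVP is never replaced by an
element-wise pool because its inputs (the raw views) have different
depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import (BatchNorm, Conv1x1, Conv3, Dense, Dropout,
                 LocallyConnected1x1, Module, Tensor, add_n, concat, flatten,
                 maximum_n, mean_n, relu, softmax)

__all__ = [
    "HvpnConfig", "HvpnModel", "ModelOutput", "build_model", "forward",
    "predict", "low_level_taps", "flvp_forward", "elementwise_view_pool",
    "FlvpLayer", "ViewSpecificBranch", "VARIANTS", "n_parameters",
    "clone_model",
]

VARIANTS = ("hvpn", "hvpn-maxpool", "hvpn-avgpool",
            "vs-l1vp", "vs-l2vp", "vs-only")


@dataclass(frozen=True)
class HvpnConfig:
    """Architecture hyperparameters.

    ``view_dims`` are the per-view feature depths ``M_i``; ``channels`` the
    electrode count ``C``; ``num_classes`` the gesture count ``G``.  The
    paper-scale widths are 64 filters, FC 1024 and aggregation FC 512;
    they are configurable so that desk-scale experiments stay cheap.
    ``tap`` selects which bottom convolution provides the low-level maps
    for second-level pooling ("first" or "second"; both have depth ``F``
    so the shape algebra cannot distinguish them).
    """

    view_dims: tuple[int, ...]
    channels: int
    num_classes: int
    variant: str = "hvpn"
    dropout_rate: float = 0.65
    conv_filters: int = 64
    fc_units: int = 1024
    agg_units: int = 512
    tap: str = "first"
    flvp_bn_relu: bool = True
    input_bn: bool = True

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"choose from {VARIANTS}")
        if not 1 <= len(self.view_dims) <= 3:
            raise ValueError("between 1 and 3 views are supported")
        if self.variant != "vs-only" and len(self.view_dims) < 2:
            raise ValueError(f"variant {self.variant!r} pools across views "
                             "and needs at least 2 of them")
        if self.tap not in ("first", "second"):
            raise ValueError("tap must be 'first' or 'second'")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def has_l1(self) -> bool:
        return self.variant in ("hvpn", "hvpn-maxpool", "hvpn-avgpool",
                                "vs-l1vp")

    @property
    def has_l2(self) -> bool:
        return self.variant in ("hvpn", "hvpn-maxpool", "hvpn-avgpool",
                                "vs-l2vp")

    @property
    def n_heads(self) -> int:
        return 1 + int(self.has_l1) + int(self.has_l2)


class ViewSpecificBranch(Module):
    """One per-view CNN branch; exposes its low-level map as a tap."""

    def __init__(self, m: int, cfg: HvpnConfig, rng: np.random.Generator):
        super().__init__()
        F, C = cfg.conv_filters, cfg.channels
        self.cfg = cfg
        self.in_bn = BatchNorm(m, spatial=True) if cfg.input_bn else None
        self.conv1 = Conv3(m, F, rng)
        self.bn1 = BatchNorm(F, spatial=True)
        self.conv2 = Conv3(F, F, rng)
        self.bn2 = BatchNorm(F, spatial=True)
        self.lc1 = LocallyConnected1x1(F, F, C, rng)
        self.bn3 = BatchNorm(F, spatial=True)
        self.lc2 = LocallyConnected1x1(F, F, C, rng)
        self.bn4 = BatchNorm(F, spatial=True)
        self.drop_lc = Dropout(cfg.dropout_rate)
        self.fc = Dense(F * C, cfg.fc_units, rng)
        self.bn5 = BatchNorm(cfg.fc_units)
        self.drop_fc = Dropout(cfg.dropout_rate)

    def __call__(self, x: Tensor, rng=None) -> tuple[Tensor, Tensor]:
        if self.in_bn is not None:
            x = self.in_bn(x)
        h1 = relu(self.bn1(self.conv1(x)))
        h2 = relu(self.bn2(self.conv2(h1)))
        tap = h1 if self.cfg.tap == "first" else h2
        h = relu(self.bn3(self.lc1(h2)))
        h = self.drop_lc(relu(self.bn4(self.lc2(h))), rng)
        h = self.drop_fc(relu(self.bn5(self.fc(flatten(h)))), rng)
        return h, tap


class FlvpLayer(Module):
    """Feature-level view pooling: depth concat -> 1x1 conv to ``F`` filters."""

    def __init__(self, depth_in: int, cfg: HvpnConfig, rng: np.random.Generator):
        super().__init__()
        self.depth_in = depth_in
        self.conv = Conv1x1(depth_in, cfg.conv_filters, rng)
        self.bn = BatchNorm(cfg.conv_filters, spatial=True) \
            if cfg.flvp_bn_relu else None

    def __call__(self, maps: list[Tensor]) -> Tensor:
        cat = concat(maps, axis=1)
        if cat.data.shape[1] != self.depth_in:
            raise ValueError(f"concatenated depth {cat.data.shape[1]} does not "
                             f"match the layer's input depth {self.depth_in}")
        out = self.conv(cat)
        if self.bn is not None:
            out = relu(self.bn(out))
        return out


class PoolBranchTail(Module):
    """Conv/LC/FC tail shared by both view-pooling branches."""

    def __init__(self, cfg: HvpnConfig, rng: np.random.Generator):
        super().__init__()
        F, C = cfg.conv_filters, cfg.channels
        self.conv = Conv3(F, F, rng)
        self.bn1 = BatchNorm(F, spatial=True)
        self.lc1 = LocallyConnected1x1(F, F, C, rng)
        self.bn2 = BatchNorm(F, spatial=True)
        self.lc2 = LocallyConnected1x1(F, F, C, rng)
        self.bn3 = BatchNorm(F, spatial=True)
        self.drop_lc = Dropout(cfg.dropout_rate)
        self.fc = Dense(F * C, cfg.fc_units, rng)
        self.bn4 = BatchNorm(cfg.fc_units)
        self.drop_fc = Dropout(cfg.dropout_rate)

    def __call__(self, x: Tensor, rng=None) -> Tensor:
        h = relu(self.bn1(self.conv(x)))
        h = relu(self.bn2(self.lc1(h)))
        h = self.drop_lc(relu(self.bn3(self.lc2(h))), rng)
        return self.drop_fc(relu(self.bn4(self.fc(flatten(h)))), rng)


class ClassifierHead(Module):
    """FC -> BN/ReLU -> G-way FC; softmax applied by the aggregation step."""

    def __init__(self, d_in: int, cfg: HvpnConfig, rng: np.random.Generator):
        super().__init__()
        self.fc = Dense(d_in, cfg.agg_units, rng)
        self.bn = BatchNorm(cfg.agg_units)
        self.out = Dense(cfg.agg_units, cfg.num_classes, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.out(relu(self.bn(self.fc(x))))


@dataclass
class ModelOutput:
    """Forward-pass results: summed scores plus per-head distributions."""

    final_scores: Tensor
    head_probs: list[Tensor]
    head_logits: list[Tensor]
    head_names: tuple[str, ...]
    internals: dict = field(default_factory=dict)

    @property
    def scores(self) -> np.ndarray:
        return self.final_scores.data


class HvpnModel(Module):
    """The assembled computation graph for any variant."""

    def __init__(self, cfg: HvpnConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        F = cfg.conv_filters
        n_views = len(cfg.view_dims)
        self.branches = [ViewSpecificBranch(m, cfg, rng) for m in cfg.view_dims]

        self.l1_flvp = self.l1_tail = None
        if cfg.has_l1:
            self.l1_flvp = FlvpLayer(sum(cfg.view_dims), cfg, rng)
            self.l1_tail = PoolBranchTail(cfg, rng)

        self.l2_flvp = self.l2_tail = None
        self.l2_mode = None
        if cfg.has_l2:
            n_l2_inputs = n_views + int(cfg.has_l1)
            if cfg.variant == "hvpn-maxpool":
                self.l2_mode = "max"
            elif cfg.variant == "hvpn-avgpool":
                self.l2_mode = "avg"
            else:
                self.l2_mode = "flvp"
                self.l2_flvp = FlvpLayer(n_l2_inputs * F, cfg, rng)
            self.l2_tail = PoolBranchTail(cfg, rng)

        heads = [("vs", ClassifierHead(n_views * cfg.fc_units, cfg, rng))]
        if cfg.has_l1:
            heads.append(("l1", ClassifierHead(cfg.fc_units, cfg, rng)))
        if cfg.has_l2:
            heads.append(("l2", ClassifierHead(cfg.fc_units, cfg, rng)))
        self.head_names = tuple(name for name, _ in heads)
        self.heads = [head for _, head in heads]

    # ------------------------------------------------------------------
    def _check_views(self, views: list[np.ndarray]) -> list[Tensor]:
        if len(views) != len(self.cfg.view_dims):
            raise ValueError(f"model expects {len(self.cfg.view_dims)} views, "
                             f"got {len(views)}")
        out = []
        for v, m in zip(views, self.cfg.view_dims):
            arr = v.data if isinstance(v, Tensor) else np.asarray(v, float)
            if arr.ndim == 4 and arr.shape[-1] == 1:  # (N, M, C, 1) layout
                arr = arr[..., 0]
            if arr.ndim == 2:  # a single (M, C) map
                arr = arr[None]
            if arr.shape[1] != m:
                raise ValueError(f"view depth {arr.shape[1]} does not match "
                                 f"configured M_i={m}")
            out.append(Tensor(arr))
        return out

    def forward(self, views, rng: np.random.Generator | None = None,
                want_internals: bool = False) -> ModelOutput:
        xs = self._check_views(list(views))
        feats, taps = [], []
        for branch, x in zip(self.branches, xs):
            f, t = branch(x, rng)
            feats.append(f)
            taps.append(t)

        internals: dict = {}
        l1_map = None
        if self.cfg.has_l1:
            l1_map = self.l1_flvp(xs)
            l1_feat = self.l1_tail(l1_map, rng)
            internals["l1_concat_depth"] = sum(self.cfg.view_dims)

        l2_map = None
        if self.cfg.has_l2:
            l2_inputs = list(taps) + ([l1_map] if l1_map is not None else [])
            if self.l2_mode == "flvp":
                l2_map = self.l2_flvp(l2_inputs)
                internals["l2_concat_depth"] = self.l2_flvp.depth_in
            elif self.l2_mode == "max":
                l2_map = maximum_n(l2_inputs)
            else:
                l2_map = mean_n(l2_inputs)
            l2_feat = self.l2_tail(l2_map, rng)

        stream_inputs = {"vs": concat(feats, axis=1)}
        if self.cfg.has_l1:
            stream_inputs["l1"] = l1_feat
        if self.cfg.has_l2:
            stream_inputs["l2"] = l2_feat

        logits = [head(stream_inputs[name])
                  for name, head in zip(self.head_names, self.heads)]
        probs = [softmax(z) for z in logits]
        final = add_n(probs)
        if want_internals:
            internals["taps"] = [t.data for t in taps]
            if l1_map is not None:
                internals["l1_map"] = l1_map.data
            if l2_map is not None:
                internals["l2_map"] = l2_map.data
        return ModelOutput(final, probs, logits, self.head_names, internals)

    @property
    def n_heads(self) -> int:
        return len(self.heads)


def build_model(cfg: HvpnConfig, seed: int = 0) -> HvpnModel:
    """Instantiate a variant with seeded He-normal initialization."""
    return HvpnModel(cfg, np.random.default_rng(seed))


def clone_model(model: HvpnModel) -> HvpnModel:
    """Structural copy with identical weights and BN statistics."""
    twin = build_model(model.cfg, seed=0)
    twin.load_state_dict(model.state_dict())
    return twin


def forward(model: HvpnModel, views, **kw) -> ModelOutput:
    """Functional alias for :meth:`HvpnModel.forward` (inference mode)."""
    return model.forward(views, **kw)


def predict(model: HvpnModel, views, batch_size: int = 512) -> np.ndarray:
    """Argmax of the summed softmax scores; ties go to the lowest class."""
    xs = model._check_views(list(views))
    n = xs[0].data.shape[0]
    out = np.empty(n, dtype=np.int64)
    for lo in range(0, n, batch_size):
        hi = min(lo + batch_size, n)
        batch = [x.data[lo:hi] for x in xs]
        out[lo:hi] = model.forward(batch).scores.argmax(axis=1)
    return out


def low_level_taps(model: HvpnModel, views) -> list[np.ndarray]:
    """The per-view low-level maps feeding second-level pooling."""
    res = model.forward(views, want_internals=True)
    return res.internals["taps"]


def flvp_forward(maps, layer: FlvpLayer) -> np.ndarray:
    """Apply an FLVP layer to a list of ``(N, d_i, C)`` maps."""
    arrs = []
    shape = None
    for m in maps:
        a = m.data if isinstance(m, Tensor) else np.asarray(m, float)
        if a.ndim == 2:
            a = a[None]
        if shape is None:
            shape = (a.shape[0], a.shape[2])
        elif (a.shape[0], a.shape[2]) != shape:
            raise ValueError("FLVP inputs must share batch size and width")
        arrs.append(Tensor(a))
    return layer(arrs).data


def elementwise_view_pool(maps, mode: str) -> np.ndarray:
    """Element-wise max/avg pooling across equally shaped maps."""
    arrs = [np.asarray(m, dtype=np.float64) for m in maps]
    if len(arrs) < 2:
        raise ValueError("need at least 2 maps to pool")
    if any(a.shape != arrs[0].shape for a in arrs):
        raise ValueError("element-wise view pooling requires identical shapes")
    if mode == "max":
        return np.maximum.reduce(arrs)
    if mode == "avg":
        return np.mean(arrs, axis=0)
    raise ValueError("mode must be 'max' or 'avg'")


def n_parameters(model: HvpnModel) -> int:
    """Total learnable parameter count (BN gains/biases included)."""
    return int(sum(p.data.size for p in model.parameters()))


def save_checkpoint(model: HvpnModel, path) -> None:
    """Serialize architecture config, weights and BN statistics to ``.npz``."""
    import dataclasses
    import json
    cfg = dataclasses.asdict(model.cfg)
    cfg["view_dims"] = list(cfg["view_dims"])
    np.savez(path, __config__=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8), **model.state_dict())


def load_checkpoint(path) -> HvpnModel:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    import json
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        cfg_dict["view_dims"] = tuple(cfg_dict["view_dims"])
        state = {k: data[k] for k in data.files if k != "__config__"}
    model = build_model(HvpnConfig(**cfg_dict), seed=0)
    model.load_state_dict(state)
    return model
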