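"""Residual encoder-decoder segmentation network with deep supervision.

A U-shaped fully convolutional network for single-channel axial slices.
The encoder halves the spatial dimensions at each of ``depth`` levels while
doubling the channel count; the decoder mirrors it, concatenating the
encoder feature maps at the matching level.  Three residual block types
are used:

* **downsampling** — strided 3×3 convolutions in the convolutional path,
  2×2 max-pooling followed by a 1×1 convolution in the identity path;
* **flat** — spatial dimensions preserved, identity (or 1×1 convolution
  when the channel count changes) in the identity path;
* **upsampling** — 2×2 transposed convolutions in the convolutional path,
  nearest-neighbour interpolation plus a 1×1 convolution in the identity
  path.

With deep supervision enabled, each decoder level feeds a 1×1 convolution
with sigmoid activation whose output is upsampled to the input resolution;
the weighted Dice losses of these auxiliary heads (plus the main head)
stabilise gradient flow in the deep configuration.  SELU activations with
LeCun-normal initialisation give self-normalising behaviour without
normalisation layers; the ReLU ablation pairs with He-normal
initialisation.  At the reference configuration (1792×1280 input, depth 6)
the deepest feature maps measure 28×20 pixels and there are 7 supervised
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    Adam,  # noqa: F401  (re-exported convenience)
    Conv2d,
    ConvTranspose2x2,
    Module,
    Tensor,
    add,
    concat_channels,
    maxpool2d,
    relu,
    scale,
    selu,
    sigmoid,
    upsample_nearest,
)
from .objective import REFERENCE_SUPERVISION_WEIGHTS

__all__ = ["NetworkSpec", "SegmentationNetwork", "build_network", "summarize_network"]


def default_supervision_weights(depth: int) -> tuple[float, ...]:
    """Deepest-to-shallowest head weights; the depth-6 reference vector, or
    its renormalised tail for shallower configurations."""
    if depth == 6:
        return REFERENCE_SUPERVISION_WEIGHTS
    tail = REFERENCE_SUPERVISION_WEIGHTS[-(depth + 1):]
    s = sum(tail)
    return tuple(w / s for w in tail)


@dataclass
class NetworkSpec:
    input_height: int = 1792
    input_width: int = 1280
    depth: int = 6
    base_filters: int = 16
    filters_double_per_level: bool = True
    use_residual: bool = True
    use_deep_supervision: bool = True
    activation: str = "selu"           # "selu" or "relu"
    supervision_weights: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        d = 2 ** self.depth
        if self.input_height % d:
            raise ValueError(
                f"input_height {self.input_height} not divisible by 2^{self.depth}")
        if self.input_width % d:
            raise ValueError(
                f"input_width {self.input_width} not divisible by 2^{self.depth}")
        if self.activation not in ("selu", "relu"):
            raise ValueError(f"activation must be 'selu' or 'relu', got {self.activation!r}")
        if self.supervision_weights is None:
            self.supervision_weights = default_supervision_weights(self.depth)
        w = tuple(float(x) for x in self.supervision_weights)
        if len(w) != self.depth + 1:
            raise ValueError(
                f"supervision_weights needs {self.depth + 1} entries, got {len(w)}")
        if any(x <= 0 for x in w):
            raise ValueError("supervision weights must be positive")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"supervision weights must sum to 1, got {sum(w)}")
        self.supervision_weights = w

    def channels_at(self, level: int) -> int:
        if not self.filters_double_per_level:
            return self.base_filters
        return self.base_filters * (2 ** level)

    @property
    def init_scheme(self) -> str:
        return "lecun" if self.activation == "selu" else "he"

    def to_dict(self) -> dict:
        return {
            "input_height": self.input_height, "input_width": self.input_width,
            "depth": self.depth, "base_filters": self.base_filters,
            "filters_double_per_level": self.filters_double_per_level,
            "use_residual": self.use_residual,
            "use_deep_supervision": self.use_deep_supervision,
            "activation": self.activation,
            "supervision_weights": list(self.supervision_weights),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        if d.get("supervision_weights") is not None:
            d["supervision_weights"] = tuple(d["supervision_weights"])
        return cls(**d)


def _act(name: str):
    return selu if name == "selu" else relu


# Residual paths are merged as (identity + convolutional) / sqrt(2), which
# preserves variance for independent paths so the activations stay near the
# SELU self-normalizing fixed point even in the deep configuration.
_MERGE_SCALE = 1.0 / np.sqrt(2.0)


def _merge(shortcut: Tensor, convpath: Tensor) -> Tensor:
    return scale(add(shortcut, convpath), _MERGE_SCALE)


class _FlatBlock(Module):
    """Spatial-preserving block; residual identity path is the identity map
    (or a 1×1 convolution when the channel count changes)."""

    def __init__(self, cin, cout, spec: NetworkSpec, rng):
        init = spec.init_scheme
        self.residual = spec.use_residual
        self.act = _act(spec.activation)
        self.conv1 = Conv2d(cin, cout, 3, init=init, rng=rng)
        self.conv2 = Conv2d(cout, cout, 3, init=init, rng=rng)
        self.proj = (Conv2d(cin, cout, 1, init=init, rng=rng)
                     if (self.residual and cin != cout) else None)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv2(self.act(self.conv1(x)))
        if not self.residual:
            return self.act(h)
        shortcut = self.proj(x) if self.proj is not None else x
        return self.act(_merge(shortcut, h))


class _DownBlock(Module):
    """Halves H and W: strided convolution path, max-pool + 1×1 identity path."""

    def __init__(self, cin, cout, spec: NetworkSpec, rng):
        init = spec.init_scheme
        self.residual = spec.use_residual
        self.act = _act(spec.activation)
        self.conv1 = Conv2d(cin, cout, 3, stride=2, init=init, rng=rng)
        self.conv2 = Conv2d(cout, cout, 3, init=init, rng=rng)
        self.proj = Conv2d(cin, cout, 1, init=init, rng=rng) if self.residual else None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv2(self.act(self.conv1(x)))
        if not self.residual:
            return self.act(h)
        return self.act(_merge(self.proj(maxpool2d(x)), h))


class _UpBlock(Module):
    """Doubles H and W: transposed-convolution path, nearest-neighbour
    upsampling + 1×1 convolution identity path."""

    def __init__(self, cin, cout, spec: NetworkSpec, rng):
        init = spec.init_scheme
        self.residual = spec.use_residual
        self.act = _act(spec.activation)
        self.convt = ConvTranspose2x2(cin, cout, init=init, rng=rng)
        self.conv2 = Conv2d(cout, cout, 3, init=init, rng=rng)
        self.proj = Conv2d(cin, cout, 1, init=init, rng=rng) if self.residual else None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv2(self.act(self.convt(x)))
        if not self.residual:
            return self.act(h)
        return self.act(_merge(self.proj(upsample_nearest(x, 2)), h))


class SegmentationNetwork(Module):
    """The assembled encoder-decoder; ``forward`` returns all supervised heads."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        L = spec.depth
        ch = [spec.channels_at(l) for l in range(L + 1)]
        self.stem = _FlatBlock(1, ch[0], spec, rng)
        self.downs = [_DownBlock(ch[l - 1], ch[l], spec, rng) for l in range(1, L + 1)]
        self.enc_flats = [_FlatBlock(ch[l], ch[l], spec, rng) for l in range(1, L + 1)]
        self.ups = [_UpBlock(ch[l + 1], ch[l], spec, rng) for l in reversed(range(L))]
        self.dec_flats = [_FlatBlock(2 * ch[l], ch[l], spec, rng)
                          for l in reversed(range(L))]
        init = spec.init_scheme
        self.aux_heads = (
            [Conv2d(ch[l], 1, 1, init=init, rng=rng) for l in reversed(range(L))]
            if spec.use_deep_supervision else [])
        self.main_head = Conv2d(ch[0], 1, 1, init=init, rng=rng)

    def forward(self, x: Tensor) -> list[Tensor]:
        """Run one NCHW batch; returns supervised outputs deepest head first,
        main (full-resolution) head last.  All heads share the input's
        spatial dimensions."""
        spec = self.spec
        n, c, h, w = x.data.shape
        if c != 1:
            raise ValueError(f"expected single-channel input, got {c} channels")
        if h != spec.input_height or w != spec.input_width:
            raise ValueError(
                f"input {h}x{w} does not match network canvas "
                f"{spec.input_height}x{spec.input_width}")
        skips = [self.stem(x)]
        cur = skips[0]
        for down, flat in zip(self.downs, self.enc_flats):
            cur = flat(down(cur))
            skips.append(cur)
        heads: list[Tensor] = []
        for i, (up, flat) in enumerate(zip(self.ups, self.dec_flats)):
            level = spec.depth - 1 - i
            cur = flat(concat_channels([up(cur), skips[level]]))
            if spec.use_deep_supervision and level > 0:
                aux = sigmoid(self.aux_heads[i](cur))
                heads.append(upsample_nearest(aux, 2 ** level))
            elif spec.use_deep_supervision and level == 0:
                heads.append(sigmoid(self.aux_heads[i](cur)))
        heads.append(sigmoid(self.main_head(cur)))
        return heads

    def predict(self, batch: np.ndarray) -> np.ndarray:
        """Main-head probabilities for an (N, H, W) batch, without autodiff
        bookkeeping (graph-free forward)."""
        params = self.parameters()
        flags = [p.requires_grad for p in params]
        for p in params:
            p.requires_grad = False
        try:
            heads = self.forward(Tensor(np.asarray(batch)[:, None]))
            return heads[-1].data[:, 0]
        finally:
            for p, f in zip(params, flags):
                p.requires_grad = f


def build_network(spec: NetworkSpec, seed: int = 0) -> SegmentationNetwork:
    """Construct (and initialise) the network described by ``spec``."""
    return SegmentationNetwork(spec, seed=seed)


def save_checkpoint(net: SegmentationNetwork, path) -> None:
    """Persist weights plus the embedded spec (NumPy ``.npz`` container)."""
    import json

    arrays = {f"param_{i}": p.data for i, p in enumerate(net.parameters())}
    np.savez_compressed(path, spec_json=np.array(json.dumps(net.spec.to_dict())),
                        **arrays)


def load_checkpoint(path) -> SegmentationNetwork:
    """Rebuild a network from a checkpoint written by :func:`save_checkpoint`."""
    import json

    with np.load(path, allow_pickle=False) as data:
        spec = NetworkSpec.from_dict(json.loads(str(data["spec_json"])))
        net = SegmentationNetwork(spec, seed=0)
        state = [data[f"param_{i}"] for i in range(len(net.parameters()))]
    net.load_state_dict(state)
    return net


def summarize_network(net: SegmentationNetwork) -> dict:
    """Structure report: per-level spatial dims and channels, head count,
    trainable parameter total.  Deterministic given the spec."""
    spec = net.spec
    levels = []
    for l in range(spec.depth + 1):
        levels.append({
            "level": l,
            "height": spec.input_height // (2 ** l),
            "width": spec.input_width // (2 ** l),
            "channels": spec.channels_at(l),
        })
    n_heads = (spec.depth + 1) if spec.use_deep_supervision else 1
    blocks = [net.stem] + net.downs + net.enc_flats + net.ups + net.dec_flats
    return {
        "levels": levels,
        "deepest_height": levels[-1]["height"],
        "deepest_width": levels[-1]["width"],
        "num_supervised_outputs": n_heads,
        "supervision_weights": list(spec.supervision_weights),
        "total_parameters": net.parameter_count(),
        "identity_path_layers": sum(
            1 for b in blocks if getattr(b, "proj", None) is not None),
        "activation": spec.activation,
    }
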