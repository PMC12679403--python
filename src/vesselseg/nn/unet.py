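"""3D encoder-decoder segmentation network (U-Net family).

The architecture follows the volumetric U-Net convention: ``n`` encoder
blocks of two 3x3x3 convolutions (each followed by leaky-ReLU activation and
group normalization) with 2x max-pool downsampling between levels, and
``n - 1`` decoder blocks of a stride-2 transpose convolution, a skip merge
with the same-resolution encoder features, and two further convolutions.
Channels double per encoder level from ``base_filters``. The head is a
1x1x1 convolution to ``n_output_channels`` with a voxel-wise softmax, so the
output is a per-voxel class-probability map with the same spatial shape as
the input.

Skip merges come in two flavours:

``concat``
    plain channel concatenation of encoder and decoder features.

``attention``
    a multiplicative (Luong-style) cross-branch attention gate: encoder map
    ``q`` and upsampled decoder map ``k`` are each transformed by a
    trainable 3x3x3 convolution, combined by a channel-wise dot product,
    and squashed through a 1x1x1 convolution + sigmoid into a single-channel
    attention map in (0, 1) which rescales ``k`` element-wise before
    concatenation. With all gate weights zero the sigmoid yields 0.5
    everywhere, so the gated features are exactly ``0.5 * k``.

Everything is plain numpy with hand-written backprop; see ``layers.py``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .layers import (Conv3d, ConvTranspose3d, Dropout, GroupNorm, LeakyReLU,
                     MaxPool3d, Softmax, Sigmoid)

__all__ = ["NetworkConfig", "AttentionGate", "UNet3D", "build_network"]

CHECKPOINT_FORMAT_VERSION = "1"


@dataclass
class NetworkConfig:
    """Declarative description of the segmentation network.

    Defaults reproduce the full-size model: six encoder blocks, five decoder
    blocks, 32 base filters doubling per level, 3x3x3 kernels, leaky ReLU
    (alpha=0.2), group normalization, 30% dropout per block.
    """

    input_shape: tuple[int, int, int] = (64, 64, 64)
    in_channels: int = 1
    n_encoder_blocks: int = 6
    n_decoder_blocks: int = 5
    base_filters: int = 32
    kernel_size: int = 3
    activation: str = "leaky_relu"   # "relu" or "leaky_relu"
    leaky_alpha: float = 0.2
    norm_groups: int = 4
    dropout_rate: float = 0.30
    dropout_per_conv: bool = False
    skip_mode: str = "concat"        # "concat" or "attention"
    n_output_channels: int = 2
    init_seed: int = 0

    def __post_init__(self) -> None:
        self.input_shape = tuple(int(s) for s in self.input_shape)
        self.validate()

    def validate(self) -> None:
        if self.n_decoder_blocks != self.n_encoder_blocks - 1:
            raise ValueError(
                f"n_decoder_blocks must be n_encoder_blocks - 1, got "
                f"{self.n_decoder_blocks} vs {self.n_encoder_blocks}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if self.skip_mode not in ("concat", "attention"):
            raise ValueError(f"unknown skip_mode {self.skip_mode!r}")
        if self.activation not in ("relu", "leaky_relu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        factor = 2 ** (self.n_encoder_blocks - 1)
        for s in self.input_shape:
            if s % factor:
                raise ValueError(
                    f"input dims must be divisible by 2^(n_encoder_blocks-1)"
                    f"={factor}, got {self.input_shape}")

    @property
    def level_filters(self) -> list[int]:
        return [self.base_filters * 2 ** i for i in range(self.n_encoder_blocks)]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NetworkConfig":
        d = json.loads(text)
        d["input_shape"] = tuple(d["input_shape"])
        return cls(**d)

    def _activation(self) -> LeakyReLU:
        alpha = 0.0 if self.activation == "relu" else self.leaky_alpha
        return LeakyReLU(alpha)


class _ConvBlock:
    """Encoder block: [conv > act > norm > conv > act > norm > dropout]."""

    def __init__(self, cfg: NetworkConfig, c_in: int, c_out: int,
                 rng: np.random.Generator) -> None:
        k = cfg.kernel_size
        self.layers = [
            Conv3d(c_in, c_out, k, rng), cfg._activation(),
            GroupNorm(c_out, cfg.norm_groups),
        ]
        if cfg.dropout_per_conv:
            self.layers.append(Dropout(cfg.dropout_rate))
        self.layers += [
            Conv3d(c_out, c_out, k, rng), cfg._activation(),
            GroupNorm(c_out, cfg.norm_groups),
            Dropout(cfg.dropout_rate),
        ]

    def forward(self, x, train, rng):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class AttentionGate:
    """Multiplicative cross-branch attention between encoder and decoder maps.

    ``forward(q, k)`` returns ``attention_map * k`` where
    ``attention_map = sigmoid(conv_1x1x1(sum_c(Wq q * Wk k)))``.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 kernel_size: int = 3) -> None:
        self.wq = Conv3d(channels, channels, kernel_size, rng)
        self.wk = Conv3d(channels, channels, kernel_size, rng)
        self.psi = Conv3d(1, 1, 1, rng)
        self.sigmoid = Sigmoid()
        self.layers = [self.wq, self.wk, self.psi]
        self._cache = None

    def forward(self, q, k, train=False, rng=None):
        if q.shape != k.shape:
            raise ValueError(f"q/k shape mismatch: {q.shape} vs {k.shape}")
        tq = self.wq.forward(q, train=train, rng=rng)
        tk = self.wk.forward(k, train=train, rng=rng)
        combined = (tq * tk).sum(axis=-1, keepdims=True)
        attn = self.sigmoid.forward(self.psi.forward(combined))
        self._cache = (tq, tk, attn, k)
        return attn * k

    @property
    def attention_map(self) -> np.ndarray:
        """Attention map of the most recent forward pass, values in (0,1)."""
        return self._cache[2]

    def backward(self, dout):
        tq, tk, attn, k = self._cache
        dattn = (dout * k).sum(axis=-1, keepdims=True)
        dk = dout * attn
        dcombined = self.psi.backward(self.sigmoid.backward(dattn))
        dq = self.wq.backward(dcombined * tk)
        dk = dk + self.wk.backward(dcombined * tq)
        return dq, dk


class _DecoderBlock:
    """[transpose-conv 2x > skip merge > conv > act > conv > act > dropout]."""

    def __init__(self, cfg: NetworkConfig, c_in: int, c_out: int,
                 rng: np.random.Generator) -> None:
        k = cfg.kernel_size
        self.upconv = ConvTranspose3d(c_in, c_out, rng)
        self.gate = (AttentionGate(c_out, rng, k)
                     if cfg.skip_mode == "attention" else None)
        self.c_out = c_out
        self.layers = [
            Conv3d(2 * c_out, c_out, k, rng), cfg._activation(),
            Conv3d(c_out, c_out, k, rng), cfg._activation(),
            Dropout(cfg.dropout_rate),
        ]

    def forward(self, x, skip, train, rng):
        up = self.upconv.forward(x, train=train, rng=rng)
        if up.shape[1:4] != skip.shape[1:4]:
            raise ValueError(
                f"skip/decoder spatial mismatch: {skip.shape} vs {up.shape}")
        merged_half = (self.gate.forward(skip, up, train=train, rng=rng)
                       if self.gate is not None else up)
        x = np.concatenate([skip, merged_half], axis=-1)
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        dskip, dhalf = dy[..., :self.c_out], dy[..., self.c_out:]
        if self.gate is not None:
            dq, dup = self.gate.backward(dhalf)
            dskip = dskip + dq
        else:
            dup = dhalf
        dx = self.upconv.backward(dup)
        return dx, dskip


class UNet3D:
    """Executable network graph built from a :class:`NetworkConfig`."""

    def __init__(self, config: NetworkConfig,
                 rng: np.random.Generator | None = None) -> None:
        config.validate()
        self.config = config
        rng = rng or np.random.default_rng(config.init_seed)
        filters = config.level_filters
        n_enc = config.n_encoder_blocks

        self.encoder_blocks: list[_ConvBlock] = []
        c_in = config.in_channels
        for f in filters:
            self.encoder_blocks.append(_ConvBlock(config, c_in, f, rng))
            c_in = f
        self.pools = [MaxPool3d() for _ in range(n_enc - 1)]

        self.decoder_blocks: list[_DecoderBlock] = []
        c_cur = filters[-1]
        for level in range(n_enc - 2, -1, -1):
            self.decoder_blocks.append(
                _DecoderBlock(config, c_cur, filters[level], rng))
            c_cur = filters[level]

        self.head = Conv3d(c_cur, config.n_output_channels, 1, rng)
        self.softmax = Softmax()
        self._skips: list[np.ndarray] | None = None

    # -- execution ---------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Per-voxel class probabilities, shape ``x.shape[:-1] + (n_classes,)``.

        In inference mode (``train=False``) dropout is disabled and the
        output is deterministic.
        """
        x = np.asarray(x)
        if x.ndim == 4:  # (N, Z, Y, X) -> single channel
            x = x[..., None]
        if tuple(x.shape[1:4]) != self.config.input_shape:
            raise ValueError(
                f"batch spatial shape {x.shape[1:4]} != configured input "
                f"shape {self.config.input_shape}")
        skips = []
        for i, block in enumerate(self.encoder_blocks):
            x = block.forward(x, train, rng)
            if i < len(self.pools):
                skips.append(x)
                x = self.pools[i].forward(x)
        for dec, skip in zip(self.decoder_blocks, reversed(skips)):
            x = dec.forward(x, skip, train, rng)
        self._skips = skips
        return self.softmax.forward(self.head.forward(x))

    def backward(self, dprobs: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(probs); accumulates parameter gradients."""
        dy = self.head.backward(self.softmax.backward(dprobs))
        # decoder_blocks[0] consumed the deepest skip; walking them in reverse
        # yields skip gradients for levels 0, 1, ..., n_enc-2 in order.
        dskip_at_level = [None] * len(self.pools)
        for level, dec in enumerate(reversed(self.decoder_blocks)):
            dy, dskip_at_level[level] = dec.backward(dy)
        for i in range(len(self.encoder_blocks) - 1, -1, -1):
            if i < len(self.pools):
                dy = self.pools[i].backward(dy) + dskip_at_level[i]
            dy = self.encoder_blocks[i].backward(dy)
        return dy

    # -- parameter bookkeeping --------------------------------------------

    def _named_layers(self):
        for i, block in enumerate(self.encoder_blocks):
            for j, layer in enumerate(block.layers):
                yield f"enc{i}.{j}", layer
        for i, dec in enumerate(self.decoder_blocks):
            yield f"dec{i}.up", dec.upconv
            if dec.gate is not None:
                for name, layer in zip(("wq", "wk", "psi"), dec.gate.layers):
                    yield f"dec{i}.gate.{name}", layer
            for j, layer in enumerate(dec.layers):
                yield f"dec{i}.{j}", layer
        yield "head", self.head

    def parameters(self):
        for lname, layer in self._named_layers():
            for pname, value, grad in layer.parameters():
                yield f"{lname}.{pname}", value, grad

    def zero_grad(self) -> None:
        for _, layer in self._named_layers():
            layer.zero_grad()

    @property
    def n_params(self) -> int:
        return sum(v.size for _, v, _ in self.parameters())

    def astype(self, dtype) -> "UNet3D":
        """Cast all parameters/gradients in place (e.g. float64 for
        finite-difference verification)."""
        for _, layer in self._named_layers():
            for k in layer.params:
                layer.params[k] = layer.params[k].astype(dtype)
                layer.grads[k] = layer.grads[k].astype(dtype)
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: value.copy() for name, value, _ in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, value, _ in self.parameters():
            if name not in state:
                raise KeyError(f"checkpoint missing parameter {name}")
            if state[name].shape != value.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{state[name].shape} vs {value.shape}")
            value[...] = state[name]

    # -- description -------------------------------------------------------

    def summary(self) -> list[dict]:
        """Ordered layer descriptions: name, output shape, parameter count."""
        cfg = self.config
        shape = cfg.input_shape
        rows = []
        filters = cfg.level_filters
        for i, f in enumerate(filters):
            rows.append({"name": f"encoder_block_{i}",
                         "output_shape": (*shape, f),
                         "n_params": sum(l.n_params
                                         for l in self.encoder_blocks[i].layers)})
            if i < len(self.pools):
                shape = tuple(s // 2 for s in shape)
                rows.append({"name": f"maxpool_{i}",
                             "output_shape": (*shape, f), "n_params": 0})
        for i, dec in enumerate(self.decoder_blocks):
            shape = tuple(s * 2 for s in shape)
            f = dec.c_out
            n = dec.upconv.n_params + sum(l.n_params for l in dec.layers)
            if dec.gate is not None:
                n += sum(l.n_params for l in dec.gate.layers)
            rows.append({"name": f"decoder_block_{i}",
                         "output_shape": (*shape, f), "n_params": n})
        rows.append({"name": "head",
                     "output_shape": (*shape, cfg.n_output_channels),
                     "n_params": self.head.n_params})
        return rows


def build_network(config: NetworkConfig,
                  rng: np.random.Generator | None = None) -> UNet3D:
    """Construct the network described by ``config`` (validated)."""
    return UNet3D(config, rng)
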