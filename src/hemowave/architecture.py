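"""Declarative construction of multi-atrous U-Net autoencoder (MA-UDCAE) variants.

The network maps a 2-s single-lead ECG window to one or three pressure
waveforms of the same length.  Every level of the encoder applies a
*multi-atrous block* — parallel same-padding convolutions at several dilation
rates over the same input, concatenated along the channel axis — followed by
window-2 max pooling; the decoder mirrors it with x2 nearest upsampling, and
named U-Net skip concatenations bring encoder feature maps (and optionally
the raw input) back in at matching resolutions.  Skips are individually
removable, which is what the ablation harness exercises.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from ._exceptions import ConfigurationError


def receptive_field(kernel_size: int, dilation: int) -> int:
    """Temporal extent of one dilated convolution branch: 1 + (k-1) * d."""
    return 1 + (kernel_size - 1) * dilation


def available_skips(levels: int) -> tuple[str, ...]:
    """Skip names a ``levels``-deep model can wire.

    ``skip_Li`` carries the encoder's level-i pre-pool merge to the decoder
    stage of matching resolution; ``input_skip`` concatenates the raw input
    at full resolution before the head convolutions.
    """
    return tuple(f"skip_L{i}" for i in range(1, levels + 1)) + ("input_skip",)


@dataclass(frozen=True)
class ModelConfig:
    """Complete architectural description of an MA-UDCAE variant."""

    in_len: int = 256
    in_channels: int = 1
    out_channels: int = 3
    levels: int = 4
    base_filters: int = 16
    kernel_size: int = 3
    dilation_rates: tuple[int, ...] = (1, 2, 4)
    skip_connections: tuple[str, ...] | None = None  # None -> all available
    head_convs: int = 2
    activation: str = "relu"
    output_activation: str = "linear"
    filter_cap: int = 64

    def __post_init__(self) -> None:
        if self.skip_connections is None:
            object.__setattr__(self, "skip_connections", available_skips(self.levels))
        else:
            object.__setattr__(self, "skip_connections", tuple(self.skip_connections))
        object.__setattr__(self, "dilation_rates", tuple(self.dilation_rates))

    def filters_at(self, level: int) -> int:
        """Per-branch filter count at a 1-based level (doubling, capped)."""
        return min(self.base_filters * 2 ** (level - 1), self.filter_cap)


def cardio_config(**overrides) -> ModelConfig:
    """Cardiovascular preset: 3 output channels (ABP, CVP, PAP), 4 levels,
    all five removable merges present."""
    return ModelConfig(**{"in_len": 256, "out_channels": 3, "levels": 4, **overrides})


def cerebral_config(**overrides) -> ModelConfig:
    """Cerebral preset: single ICP output, 100-sample (2 s x 50 Hz) windows,
    2 levels, two encoder skip merges and no input skip."""
    defaults = dict(
        in_len=100, out_channels=1, levels=2, skip_connections=("skip_L1", "skip_L2")
    )
    return ModelConfig(**{**defaults, **overrides})


#: Cumulative ablation orders used by the ablation study, deepest merge first
#: for the cardiovascular model, deeper of the two first for the cerebral one.
CARDIO_ABLATION_SEQUENCE = ("skip_L4", "skip_L3", "skip_L2", "skip_L1", "input_skip")
CEREBRAL_ABLATION_SEQUENCE = ("skip_L2", "skip_L1")


def validate_config(config: ModelConfig) -> list[str]:
    """Return every violated invariant (empty list means buildable)."""
    v: list[str] = []
    if config.in_len % (2**config.levels) != 0:
        v.append(f"in_len not divisible by 2^levels ({config.in_len} / {2**config.levels})")
    if not config.dilation_rates:
        v.append("dilation_rates is empty")
    if any(d < 1 for d in config.dilation_rates):
        v.append("dilation rates must be >= 1")
    if config.out_channels not in (1, 3):
        v.append(f"out_channels must be 1 (ICP) or 3 (ABP/CVP/PAP), got {config.out_channels}")
    if config.levels < 1:
        v.append("levels must be >= 1")
    if config.base_filters < 1:
        v.append("base_filters must be >= 1")
    if config.head_convs < 0:
        v.append("head_convs must be >= 0")
    unknown = set(config.skip_connections) - set(available_skips(config.levels))
    if unknown:
        v.append(f"unknown skip connections {sorted(unknown)} for levels={config.levels}")
    if config.dilation_rates and config.levels >= 1:
        # the deepest convolutions run just above the bottleneck (pooling is
        # the last encoder step, upsampling the first decoder step)
        shortest = config.in_len // (2 ** max(config.levels - 1, 0))
        eff = receptive_field(config.kernel_size, max(config.dilation_rates))
        if eff > max(shortest, 1):
            v.append(f"kernel extent {eff} exceeds shortest layer length {shortest}")
    return v


def ablate(config: ModelConfig, connection_names: list[str] | tuple[str, ...]) -> ModelConfig:
    """Return a copy of ``config`` with the named merges removed."""
    names = tuple(connection_names)
    unknown = [n for n in names if n not in config.skip_connections]
    if unknown:
        raise ConfigurationError(
            f"connections {unknown} not present in config (has {config.skip_connections})"
        )
    remaining = tuple(s for s in config.skip_connections if s not in names)
    return replace(config, skip_connections=remaining)


@dataclass(frozen=True)
class LayerSpec:
    name: str
    kind: str       # conv | merge | pool | upsample | input | output
    length: int
    width: int
    note: str = ""


@dataclass
class NetworkSpec:
    """Ordered layer table of a built network (temporal length, width)."""

    layers: list[LayerSpec] = field(default_factory=list)

    def add(self, name, kind, length, width, note=""):
        self.layers.append(LayerSpec(name, kind, int(length), int(width), note))

    @property
    def final(self) -> LayerSpec:
        return self.layers[-1]

    @property
    def n_encoder_decoder_merges(self) -> int:
        return sum(1 for l in self.layers if l.kind == "merge" and "skip" in l.note)

    def to_rows(self) -> list[tuple]:
        return [(l.name, l.kind, l.length, l.width, l.note) for l in self.layers]

    def __str__(self) -> str:
        header = f"{'layer':<14}{'kind':<10}{'len':>6}{'width':>7}  note"
        rows = [f"{l.name:<14}{l.kind:<10}{l.length:>6}{l.width:>7}  {l.note}" for l in self.layers]
        return "\n".join([header] + rows)


class MultiAtrousBlock:
    """Parallel dilated convolutions over one input, channel-concatenated.

    Output width is ``filters * len(dilation_rates)``; temporal length is
    preserved by same-length padding.
    """

    def __init__(self, cin: int, filters: int, kernel_size: int,
                 dilation_rates: tuple[int, ...], rng: np.random.Generator,
                 activation: str = "relu"):
        if not dilation_rates:
            raise ConfigurationError("multi-atrous block needs at least one dilation rate")
        self.branches = [
            nn.Conv1dLayer(cin, filters, kernel_size, d, rng) for d in dilation_rates
        ]
        self.activation = activation
        self.out_channels = filters * len(dilation_rates)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        outs = [branch(x) for branch in self.branches]
        merged = nn.concat(outs) if len(outs) > 1 else outs[0]
        return nn.relu(merged) if self.activation == "relu" else merged

    @property
    def parameters(self) -> list[nn.Tensor]:
        return [p for br in self.branches for p in br.parameters]

    @property
    def n_params(self) -> int:
        return sum(br.n_params for br in self.branches)


class MAUDCAE:
    """A built multi-atrous U-Net autoencoder; call :func:`build` to create one."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.spec = NetworkSpec()
        c = config
        ndil = len(c.dilation_rates)
        self.spec.add("input", "input", c.in_len, c.in_channels)

        self.encoder: list[MultiAtrousBlock] = []
        length, width = c.in_len, c.in_channels
        enc_widths: dict[str, int] = {}
        for i in range(1, c.levels + 1):
            block = MultiAtrousBlock(width, c.filters_at(i), c.kernel_size,
                                     c.dilation_rates, rng, c.activation)
            self.encoder.append(block)
            width = block.out_channels
            self.spec.add(f"enc{i}_cv", "conv", length, width,
                          f"multi-atrous x{ndil}")
            self.spec.add(f"enc{i}_me", "merge", length, width, "dilation merge")
            enc_widths[f"skip_L{i}"] = width
            length //= 2
            self.spec.add(f"enc{i}_dp", "pool", length, width, "max pool /2")

        self.decoder: list[MultiAtrousBlock] = []
        self.decoder_skips: list[str | None] = []
        for i in range(c.levels, 0, -1):
            length *= 2
            self.spec.add(f"dec{i}_up", "upsample", length, width, "nearest x2")
            block = MultiAtrousBlock(width, c.filters_at(i), c.kernel_size,
                                     c.dilation_rates, rng, c.activation)
            self.decoder.append(block)
            width = block.out_channels
            self.spec.add(f"dec{i}_cv", "conv", length, width, f"multi-atrous x{ndil}")
            skip = f"skip_L{i}" if f"skip_L{i}" in c.skip_connections else None
            self.decoder_skips.append(skip)
            if skip is not None:
                width += enc_widths[skip]
                self.spec.add(f"dec{i}_me", "merge", length, width, f"skip {skip}")
        self.use_input_skip = "input_skip" in c.skip_connections
        if self.use_input_skip:
            width += c.in_channels
            self.spec.add("input_me", "merge", length, width, "skip input_skip")

        self.head: list[nn.Conv1dLayer] = []
        for j in range(c.head_convs):
            conv = nn.Conv1dLayer(width, c.base_filters, c.kernel_size, 1, rng)
            self.head.append(conv)
            width = c.base_filters
            self.spec.add(f"head{j + 1}", "conv", length, width)
        self.out_conv = nn.Conv1dLayer(width, c.out_channels, 1, 1, rng)
        self.spec.add("output", "output", length, c.out_channels,
                      c.output_activation)

    # -- forward ---------------------------------------------------------
    def forward(self, x: np.ndarray | nn.Tensor) -> nn.Tensor:
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(x)
        x0 = x
        skips: dict[str, nn.Tensor] = {}
        cur = x
        for i, block in enumerate(self.encoder, start=1):
            cur = block(cur)
            skips[f"skip_L{i}"] = cur
            cur = nn.maxpool2(cur)
        for block, skip in zip(self.decoder, self.decoder_skips):
            cur = nn.upsample2(cur)
            cur = block(cur)
            if skip is not None:
                cur = nn.concat([cur, skips[skip]])
        if self.use_input_skip:
            cur = nn.concat([cur, x0])
        for conv in self.head:
            cur = nn.relu(conv(cur))
        return self.out_conv(cur)  # linear output activation

    __call__ = forward

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Forward pass without gradient bookkeeping, in batches."""
        outs = [self.forward(x[i : i + batch_size]).data
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    # -- parameters ------------------------------------------------------
    @property
    def parameters(self) -> list[nn.Tensor]:
        params = [p for b in self.encoder + self.decoder for p in b.parameters]
        for conv in self.head:
            params += conv.parameters
        return params + self.out_conv.parameters

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters, weights):
            p.data = w.copy()


def parameter_count(network: MAUDCAE) -> int:
    """Total trainable parameter count of a built network."""
    return sum(p.data.size for p in network.parameters)


def build(config: ModelConfig, seed: int | np.random.Generator = 0) -> MAUDCAE:
    """Validate and build an MA-UDCAE; raises on an invalid configuration."""
    violations = validate_config(config)
    if violations:
        raise ConfigurationError("; ".join(violations))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return MAUDCAE(config, rng)
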