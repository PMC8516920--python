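"""Generator and discriminator architectures, and receptive-field analysis.

The generator is a 3D U-Net: encoder blocks of strided convolution ->
LeakyReLU -> instance normalization, and decoder blocks of nearest-neighbor
resize -> convolution -> ReLU -> instance normalization, with a skip
connection concatenating encoder block i onto decoder block n-i followed by a
ReLU, and a Tanh output so values stay in [-1, 1].  Resize-convolution is
used instead of transposed convolution to avoid checkerboard artifacts.

The discriminator is a 3D PatchGAN built from the same encoder-style blocks:
its output is a grid of logits, one per patch, and the default stack is sized
so each output unit sees a 70 x 70 in-plane by 4 through-plane patch of the
6-channel (condition + candidate) input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Adam,  # noqa: F401  (re-exported for training)
    Conv3d,
    InstanceNorm3d,
    LeakyReLU,
    NearestUpsample3d,
    ReLU,
    Sequential,
    Tanh,
)


@dataclass(frozen=True)
class LayerDescriptor:
    """One layer of a network, sufficient to re-instantiate it."""

    op: str  # 'conv' | 'upsample'
    filters: int
    kernel: tuple[int, int, int]
    stride: tuple[int, int, int]
    padding: tuple[int, int, int]
    norm: bool = False
    activation: str | None = None
    skip_from: int | None = None  # encoder block index concatenated after this layer


@dataclass
class NetworkSpec:
    """Ordered layer descriptors plus bookkeeping for one network."""

    layers: list[LayerDescriptor]
    input_shape: tuple[int, int, int]
    in_channels: int
    out_channels: int
    param_count: int = 0

    @property
    def conv_layers(self) -> list[LayerDescriptor]:
        return [d for d in self.layers if d.op == "conv"]


@dataclass(frozen=True)
class DiscLayer:
    filters: int
    kernel: tuple[int, int, int]
    stride: tuple[int, int, int]
    padding: tuple[int, int, int]
    norm: bool = True


def default_disc_layers() -> tuple[DiscLayer, ...]:
    """The canonical 70x70 PatchGAN stack, extended to 3D with a z footprint of 4.

    In-plane: three k=4/s=2 blocks, then two k=4/s=1 (the last is the 1-channel
    logit map).  Through-plane: kernel 2, stride 1 on the first three blocks
    and kernel 1 after, giving the 4-slice receptive field.
    """
    return (
        DiscLayer(64, (4, 4, 2), (2, 2, 1), (1, 1, 0), norm=True),
        DiscLayer(128, (4, 4, 2), (2, 2, 1), (1, 1, 0), norm=True),
        DiscLayer(256, (4, 4, 2), (2, 2, 1), (1, 1, 0), norm=True),
        DiscLayer(512, (4, 4, 1), (1, 1, 1), (1, 1, 0), norm=True),
        DiscLayer(1, (4, 4, 1), (1, 1, 1), (1, 1, 0), norm=False),
    )


def reduced_disc_layers() -> tuple[DiscLayer, ...]:
    """A small PatchGAN for desk-scale training (receptive field 22 x 22 x 3)."""
    return (
        DiscLayer(32, (4, 4, 2), (2, 2, 1), (1, 1, 0), norm=True),
        DiscLayer(64, (4, 4, 2), (2, 2, 1), (1, 1, 0), norm=True),
        DiscLayer(1, (4, 4, 1), (1, 1, 1), (1, 1, 0), norm=False),
    )


@dataclass
class ModelConfig:
    """Architecture hyperparameters for generator and discriminator.

    ``n_encoder_blocks`` is the total U-Net depth n of the skip rule; in-plane
    axes halve at every block, the slice axis halves only while its extent is
    even and > 1 (so a 16-slice input bottoms out at extent 1 after 4 blocks).
    """

    input_shape: tuple[int, int, int] = (512, 512, 16)
    in_channels: int = 3
    out_channels: int = 3
    n_encoder_blocks: int = 8
    base_filters: int = 64
    filter_growth: float = 2.0
    max_filters: int = 512
    leaky_slope: float = 0.2
    upsample_mode: str = "nearest"
    disc_layers: tuple[DiscLayer, ...] = field(default_factory=default_disc_layers)

    def __post_init__(self) -> None:
        if self.n_encoder_blocks < 2:
            raise ValueError("n_encoder_blocks must be >= 2")
        if self.upsample_mode != "nearest":
            raise ValueError("only nearest-neighbor upsampling is supported")
        self.input_shape = tuple(int(v) for v in self.input_shape)

    def encoder_filters(self) -> list[int]:
        return [
            int(min(self.base_filters * self.filter_growth**i, self.max_filters))
            for i in range(self.n_encoder_blocks)
        ]


def reduced_model_config(input_shape=(64, 64, 16)) -> ModelConfig:
    """Desk-scale configuration used by the bundled smoke study."""
    return ModelConfig(
        input_shape=input_shape,
        n_encoder_blocks=3,
        base_filters=16,
        max_filters=64,
        disc_layers=reduced_disc_layers(),
    )


def receptive_field(layers) -> tuple[int, int, int]:
    """Analytic receptive field of one output unit over a conv layer stack.

    Per axis the standard recursion r <- r + (k - 1) * jump, jump <- jump * s
    over the layers, starting from r = 1, jump = 1.  Accepts any iterable of
    objects with per-axis ``kernel`` and ``stride`` (or (kernel, stride)
    tuples); an empty stack has receptive field (1, 1, 1).
    """
    r = [1, 1, 1]
    jump = [1, 1, 1]
    ndim = 3
    for layer in layers:
        if hasattr(layer, "kernel"):
            k, s = layer.kernel, layer.stride
        else:
            k, s = layer
        k = (k,) * 3 if np.isscalar(k) else tuple(k)
        s = (s,) * 3 if np.isscalar(s) else tuple(s)
        ndim = min(ndim, len(k))
        for a in range(len(k)):
            r[a] += (k[a] - 1) * jump[a]
            jump[a] *= s[a]
    return tuple(r[:ndim])


def _plan_encoder(config: ModelConfig):
    """Per-block (stride, kernel, padding, out_shape); errors name the bad axis."""
    shape = list(config.input_shape)
    plan = []
    axis_names = "xyz"
    for b in range(config.n_encoder_blocks):
        stride, kernel, padding = [], [], []
        for a in range(3):
            ext = shape[a]
            halve = ext > 1 if a < 2 else (ext > 1 and ext % 2 == 0)
            if a < 2 and ext > 1 and ext % 2 != 0:
                raise ValueError(
                    f"input axis {axis_names[a]} (extent {ext} at block {b + 1}) is "
                    f"not divisible by the stride pyramid; use a power-of-two extent"
                )
            if halve:
                stride.append(2)
                kernel.append(4)
                padding.append(1)
            elif ext > 1:
                stride.append(1)
                kernel.append(3)
                padding.append(1)
            else:
                stride.append(1)
                kernel.append(1)
                padding.append(0)
        shape = [(shape[a] + 2 * padding[a] - kernel[a]) // stride[a] + 1 for a in range(3)]
        plan.append((tuple(stride), tuple(kernel), tuple(padding), tuple(shape)))
    return plan


class Generator:
    """U-Net generator; callable on a (in_channels, X, Y, Z) array."""

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.config = config
        n = config.n_encoder_blocks
        filters = config.encoder_filters()
        plan = _plan_encoder(config)
        descriptors: list[LayerDescriptor] = []

        self.encoders: list[Sequential] = []
        in_ch = config.in_channels
        for b, (stride, kernel, padding, out_shape) in enumerate(plan):
            layers: list = [Conv3d(in_ch, filters[b], kernel, stride, padding, rng=rng),
                            LeakyReLU(config.leaky_slope)]
            use_norm = int(np.prod(out_shape)) > 1
            if use_norm:
                layers.append(InstanceNorm3d(filters[b]))
            self.encoders.append(Sequential(layers))
            descriptors.append(LayerDescriptor(
                "conv", filters[b], kernel, stride, padding, norm=use_norm,
                activation="leaky_relu"))
            in_ch = filters[b]

        # Decoder block d mirrors encoder block n-d+1 and concatenates the
        # output of encoder block n-d (d = 1 .. n-1); block n emits the image.
        self.decoders: list[Sequential] = []
        self.post_relu: list[ReLU] = []
        dec_in = filters[n - 1]
        for d in range(1, n):
            mirror = plan[n - d]  # encoder block n-d+1 (1-based)
            up = mirror[0]
            tgt_shape = plan[n - d - 1][3]
            g = filters[n - d - 1]
            kernel = tuple(3 if tgt_shape[a] > 1 else 1 for a in range(3))
            padding = tuple(1 if tgt_shape[a] > 1 else 0 for a in range(3))
            use_norm = int(np.prod(tgt_shape)) > 1
            layers = [NearestUpsample3d(up),
                      Conv3d(dec_in, g, kernel, (1, 1, 1), padding, rng=rng),
                      ReLU()]
            if use_norm:
                layers.append(InstanceNorm3d(g))
            self.decoders.append(Sequential(layers))
            self.post_relu.append(ReLU())
            descriptors.append(LayerDescriptor(
                "upsample", g, kernel, up, padding, norm=use_norm,
                activation="relu", skip_from=n - d))
            dec_in = g + filters[n - d - 1]  # after skip concatenation

        up0 = plan[0][0]
        kernel = tuple(3 if config.input_shape[a] > 1 else 1 for a in range(3))
        padding = tuple(1 if config.input_shape[a] > 1 else 0 for a in range(3))
        self.final = Sequential([
            NearestUpsample3d(up0),
            Conv3d(dec_in, config.out_channels, kernel, (1, 1, 1), padding, rng=rng),
            Tanh(),
        ])
        descriptors.append(LayerDescriptor(
            "upsample", config.out_channels, kernel, up0, padding,
            norm=False, activation="tanh"))

        self.spec = NetworkSpec(
            layers=descriptors,
            input_shape=config.input_shape,
            in_channels=config.in_channels,
            out_channels=config.out_channels,
            param_count=sum(p.data.size for p in self.params()),
        )

    def params(self):
        out = []
        for enc in self.encoders:
            out.extend(enc.params())
        for dec in self.decoders:
            out.extend(dec.params())
        out.extend(self.final.params())
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        skips = []
        h = x
        for enc in self.encoders:
            h = enc.forward(h, train=train)
            skips.append(h)
        n = len(self.encoders)
        for d, dec in enumerate(self.decoders, start=1):
            h = dec.forward(h, train=train)
            h = np.concatenate([h, skips[n - d - 1]], axis=0)
            h = self.post_relu[d - 1].forward(h, train=train)
        self._skip_channels = [s.shape[0] for s in skips]
        return self.final.forward(h, train=train)

    __call__ = forward

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n = len(self.encoders)
        skip_grads: list = [None] * n
        g = self.final.backward(gy)
        for d in range(n - 1, 0, -1):
            g = self.post_relu[d - 1].backward(g)
            dec_ch = g.shape[0] - self._skip_channels[n - d - 1]
            g_dec, g_skip = g[:dec_ch], g[dec_ch:]
            if skip_grads[n - d - 1] is None:
                skip_grads[n - d - 1] = g_skip.copy()
            else:
                skip_grads[n - d - 1] += g_skip
            g = self.decoders[d - 1].backward(g_dec)
        for i in range(n - 1, -1, -1):
            g = self.encoders[i].backward(g)
            if i - 1 >= 0 and skip_grads[i - 1] is not None:
                g = g + skip_grads[i - 1]
        return g


class Discriminator:
    """Conditional PatchGAN; input is concat(condition, candidate) channels."""

    def __init__(self, config: ModelConfig, seed: int = 1) -> None:
        rng = np.random.default_rng(seed)
        self.config = config
        in_ch = config.in_channels + config.out_channels
        self.in_channels = in_ch
        layers: list = []
        descriptors: list[LayerDescriptor] = []
        specs = config.disc_layers
        for i, d in enumerate(specs):
            layers.append(Conv3d(in_ch, d.filters, d.kernel, d.stride, d.padding, rng=rng))
            last = i == len(specs) - 1
            if not last:
                layers.append(LeakyReLU(config.leaky_slope))
                if d.norm:
                    layers.append(InstanceNorm3d(d.filters))
            descriptors.append(LayerDescriptor(
                "conv", d.filters, d.kernel, d.stride, d.padding,
                norm=d.norm and not last,
                activation=None if last else "leaky_relu"))
            in_ch = d.filters
        self.net = Sequential(layers)
        self.spec = NetworkSpec(
            layers=descriptors,
            input_shape=config.input_shape,
            in_channels=self.in_channels,
            out_channels=1,
            param_count=sum(p.data.size for p in self.net.params()),
        )

    def params(self):
        return self.net.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.net.forward(np.asarray(x, dtype=np.float32), train=train)

    __call__ = forward

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return self.net.backward(gy)

    def receptive_field(self) -> tuple[int, int, int]:
        return receptive_field(self.spec.conv_layers)


def build_generator(config: ModelConfig, seed: int = 0) -> Generator:
    """Instantiate the U-Net generator; output shape always equals input shape."""
    return Generator(config, seed=seed)


def build_discriminator(config: ModelConfig, seed: int = 1) -> Discriminator:
    return Discriminator(config, seed=seed)


def _iter_norm_layers(model):
    seqs = []
    if isinstance(model, Discriminator):
        seqs = [model.net]
    elif isinstance(model, Generator):
        seqs = model.encoders + model.decoders + [model.final]
    elif isinstance(model, Sequential):
        seqs = [model]
    for seq in seqs:
        for layer in seq.layers:
            if isinstance(layer, InstanceNorm3d):
                yield layer


def gradient_receptive_field(
    model, input_shape: tuple[int, int, int], in_channels: int | None = None,
    seed: int = 0,
) -> tuple[int, int, int]:
    """Empirical receptive field: nonzero-gradient footprint of one output unit.

    Backpropagates from the central output unit on a random input and counts
    the per-axis extent of nonzero input gradient.  Normalization statistics
    are held fixed during the probe (the conventional effective-receptive-field
    definition: normalization couples all positions through its spatial mean,
    which is not part of the convolutional geometry being measured).
    """
    if in_channels is None:
        in_channels = getattr(model, "in_channels", 3)
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(in_channels, *input_shape)).astype(np.float32)
    norms = list(_iter_norm_layers(model))
    for layer in norms:
        layer.freeze = True
    try:
        out = model.forward(x, train=True)
        gy = np.zeros_like(out)
        center = tuple(s // 2 for s in out.shape[1:])
        gy[(0, *center)] = 1.0
        gx = model.backward(gy)
    finally:
        for layer in norms:
            layer.freeze = False
    support = np.abs(gx).max(axis=0) > 0
    extents = []
    for axis in range(3):
        proj = support.any(axis=tuple(a for a in range(3) if a != axis))
        idx = np.flatnonzero(proj)
        extents.append(int(idx[-1] - idx[0] + 1) if idx.size else 0)
    return tuple(extents)


def save_weights(model, path) -> None:
    np.savez(path, **{f"p{i}": p.data for i, p in enumerate(model.params())})


def load_weights(model, path) -> None:
    with np.load(path) as data:
        params = model.params()
        if len(data.files) != len(params):
            raise ValueError(
                f"checkpoint has {len(data.files)} arrays, model has {len(params)}")
        for i, p in enumerate(params):
            arr = data[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch: {arr.shape} vs {p.data.shape}")
            p.data[...] = arr


def describe(spec: NetworkSpec) -> str:
    """Human-readable layer table with the analytic receptive field."""
    lines = [f"{'#':>2} {'op':<9} {'filters':>7} {'kernel':<10} {'stride':<10} "
             f"{'pad':<10} {'norm':<5} {'act':<10} skip"]
    for i, d in enumerate(spec.layers):
        lines.append(
            f"{i:>2} {d.op:<9} {d.filters:>7} {str(d.kernel):<10} {str(d.stride):<10} "
            f"{str(d.padding):<10} {str(d.norm):<5} {str(d.activation):<10} "
            f"{d.skip_from if d.skip_from is not None else '-'}"
        )
    rf = receptive_field(spec.conv_layers)
    lines.append(f"parameters: {spec.param_count:,}")
    lines.append(f"analytic receptive field (conv stack): {rf}")
    return "\n".join(lines)
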