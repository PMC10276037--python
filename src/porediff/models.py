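"""CNN surrogate architectures for porous-media transport.

Three networks take a single-channel geometry image (solid = 1, fluid = 0)
as input:

* **C-Net** — a scalar predictor: five convolutional sections
  (10/20/40/80/100 kernels of sizes 5/4/3/3/2; each conv+ReLU followed by
  batch-norm, 2x2 max-pool and dropout), then fully-connected layers of 400
  (tanh) and 10 (linear) units and a linear 2-unit head for (phi, D).  At
  the canonical 128x128 input the flattened feature length is exactly 400.
* **U-Net** — a field reconstructor: an encoder of ``n_containers``
  downsampling containers (each ``blocks_per_container`` blocks of
  [conv 3x3 pad 1 + ReLU, dropout, batch-norm], then 2x2 max-pool) and a
  mirrored decoder (blocks, x2 nearest upsample, concatenation with the
  matching encoder output), closed by a final container and a 1x1 output
  convolution.  Output shape equals input shape.
* **U-Net-Half** — the U-Net encoder with the C-Net fully-connected head: a
  scalar predictor.

The **self-normalization (SN) module** optionally replaces the last hidden
layer of the scalar predictors: two parallel affine maps produce a raw
2-vector ``y_top`` and multiplicative correction factors
``y_bottom = 2*sigmoid(.) in (0, 2)``; the output is their elementwise
product and the loss gains the penalty ``sum_i (1 - y_bottom_i)^2`` pulling
the factors towards 1.

Predictive uncertainty comes from **Monte Carlo dropout**: ``M`` stochastic
forward passes with the dropout layers kept active (batch-norm stays in
inference mode); the element-wise mean is the prediction and the standard
deviation its 1-sigma band.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "ModelKind",
    "SurrogateSpec",
    "SNHead",
    "UncertaintyResult",
    "build_cnet",
    "build_unet",
    "build_unet_half",
    "build_model",
    "sn_transform",
    "mc_dropout_predict",
    "describe",
]

# C-Net convolutional sections: (kernels, kernel size)
CNET_SECTIONS = [(10, 5), (20, 4), (40, 3), (80, 3), (100, 2)]


class ModelKind(str, enum.Enum):
    CNET = "CNET"
    UNET_HALF = "UNET_HALF"
    UNET = "UNET"


@dataclass
class SurrogateSpec:
    """Declarative description of a surrogate architecture.

    ``n_containers``, ``blocks_per_container`` and ``channels`` apply to the
    U-Net family; the canonical architecture is 6 containers of 4 blocks
    with 64 kernels at ``input_side=128``, and a reduced desk-scale variant
    (e.g. 3 containers, 2 blocks, 32 kernels at 64) is expressed through the
    same fields.
    """

    kind: ModelKind
    input_side: int = 128
    dropout_p: float = 0.1
    sn_enabled: bool = False
    n_containers: int = 6
    blocks_per_container: int = 4
    channels: int = 64

    def __post_init__(self) -> None:
        self.kind = ModelKind(self.kind)
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.kind in (ModelKind.UNET, ModelKind.UNET_HALF):
            if self.input_side % (2**self.n_containers) != 0:
                raise ValueError(
                    f"input_side {self.input_side} not divisible by "
                    f"2^{self.n_containers} poolings"
                )


@dataclass
class UncertaintyResult:
    """MC-dropout mean prediction and per-element 1-sigma uncertainty."""

    mean: np.ndarray
    sigma: np.ndarray
    M: int


def sn_transform(y_top: np.ndarray, bottom_preact: np.ndarray):
    """Self-normalization output map and its unit-normalization penalty.

    ``y_bottom = 2*sigmoid(pre)``; output is ``y_top * y_bottom`` and the
    penalty ``sum_i (1 - y_bottom_i)^2`` is zero iff both factors equal 1
    (pre-activation 0 is the identity point: ``2*sigmoid(0) = 1``).
    """
    y_top = np.asarray(y_top, dtype=float)
    pre = np.asarray(bottom_preact, dtype=float)
    y_bottom = 2.0 / (1.0 + np.exp(-pre))
    output = y_top * y_bottom
    penalty = float(((1.0 - y_bottom) ** 2).sum())
    return output, penalty


class SNHead(nn.Layer):
    """Parallel top/bottom affine maps with multiplicative 2*sigmoid gate.

    Replaces the scalar networks' last hidden layer.  The backward pass
    injects the gradient of the per-sample penalty ``sum (1 - y_b)^2``
    (averaged over the batch) alongside the loss gradient.
    """

    def __init__(self, f_in: int, rng=None, dtype=np.float32):
        self.top = nn.Dense(f_in, 2, rng=rng, scale="xavier", dtype=dtype)
        self.bottom = nn.Dense(f_in, 2, rng=rng, scale="xavier", dtype=dtype)
        # identity initialisation of the normalization branch: factors start
        # at exactly 2*sigmoid(0) = 1 (zero penalty), so the module begins as
        # a transparent gate and learns a multiplicative correction
        self.bottom.w.value[...] = 0.0
        self.last_y_bottom: np.ndarray | None = None
        self.penalty_weight = 1.0  # set to 0 to train without the penalty

    def forward(self, x, training=False):
        yt = self.top.forward(x, training=training)
        pre = self.bottom.forward(x, training=training)
        yb = 2.0 / (1.0 + np.exp(-pre))
        self._yt, self._yb = yt, yb
        self.last_y_bottom = yb
        return yt * yb

    def backward(self, grad):
        yt, yb = self._yt, self._yb
        B = grad.shape[0]
        dyt = grad * yb
        dyb = grad * yt
        if self.penalty_weight:
            # d/dyb of mean_over_batch sum_i (1 - yb_i)^2
            dyb = dyb + self.penalty_weight * (-2.0 * (1.0 - yb)) / B
        dpre = dyb * yb * (1.0 - 0.5 * yb)  # d(2*sigmoid)/dpre
        dx = self.top.backward(dyt.astype(yt.dtype)) + self.bottom.backward(
            dpre.astype(yt.dtype)
        )
        self._yt = self._yb = None
        return dx

    def mean_penalty(self) -> float:
        """Batch-mean penalty of the most recent forward pass."""
        if self.last_y_bottom is None:
            return 0.0
        return float(((1.0 - self.last_y_bottom) ** 2).sum(axis=1).mean())

    def params(self):
        return self.top.params() + self.bottom.params()


def _fc_head(f_in: int, dropout_p: float, sn: bool, rng, dtype) -> list[nn.Layer]:
    """The shared scalar head: FC 400 (tanh), dropout, then either the
    [FC 10 linear -> FC 2] readout or the SN module."""
    layers: list[nn.Layer] = [
        nn.Dense(f_in, 400, rng=rng, scale="xavier", dtype=dtype),
        nn.Tanh(),
        nn.Dropout(dropout_p),
    ]
    if sn:
        layers.append(SNHead(400, rng=rng, dtype=dtype))
    else:
        layers += [
            nn.Dense(400, 10, rng=rng, scale="xavier", dtype=dtype),
            nn.Dense(10, 2, rng=rng, scale="xavier", dtype=dtype),
        ]
    return layers


class Model:
    """A surrogate network: spec + layer graph + convenience passes."""

    def __init__(self, spec: SurrogateSpec, net: nn.Layer):
        self.spec = spec
        self.net = net

    def forward(self, x, training=False):
        return self.net.forward(x, training=training)

    def backward(self, grad):
        return self.net.backward(grad)

    def predict(self, x):
        """Deterministic inference pass (dropout off, batch-norm running stats)."""
        return self.net.forward(np.asarray(x), training=False)

    def params(self):
        return self.net.params()

    def set_rng(self, rng):
        self.net.set_rng(rng)

    @property
    def sn_head(self) -> SNHead | None:
        found = None
        stack = [self.net]
        while stack:
            layer = stack.pop()
            if isinstance(layer, SNHead):
                found = layer
            if isinstance(layer, nn.Sequential):
                stack.extend(layer.layers)
            elif isinstance(layer, _UNetGraph):
                stack.extend(layer.all_layers())
        return found

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def dropout_layers(self):
        out = []
        stack = [self.net]
        while stack:
            layer = stack.pop()
            if isinstance(layer, nn.Dropout):
                out.append(layer)
            elif isinstance(layer, nn.Sequential):
                stack.extend(layer.layers)
            elif isinstance(layer, _UNetGraph):
                stack.extend(layer.all_layers())
        return out


def _conv_out(side: int, k: int) -> int:
    return side - k + 1


def build_cnet(spec: SurrogateSpec, rng: np.random.Generator | None = None,
               dtype=np.float32) -> Model:
    """C-Net scalar predictor (canonical input 128x128)."""
    if spec.kind is not ModelKind.CNET:
        raise ValueError("spec.kind must be CNET")
    rng = rng or np.random.default_rng(0)
    layers: list[nn.Layer] = []
    side = spec.input_side
    c_in = 1
    for c_out, k in CNET_SECTIONS:
        side = _conv_out(side, k)
        if side < 1:
            raise ValueError(
                f"input_side {spec.input_side} incompatible with the C-Net "
                "conv/pool chain"
            )
        layers += [
            nn.Conv2d(c_in, c_out, k, pad=0, rng=rng, dtype=dtype),
            nn.ReLU(),
            nn.BatchNorm(c_out, dtype=dtype),
            nn.MaxPool2(),
            nn.Dropout(spec.dropout_p),
        ]
        side //= 2
        if side < 1:
            raise ValueError("pooling chain exhausted the spatial extent")
        c_in = c_out
    flat = c_in * side * side
    layers.append(nn.Flatten())
    layers += _fc_head(flat, spec.dropout_p, spec.sn_enabled, rng, dtype)
    model = Model(spec, nn.Sequential(*layers))
    model.flatten_length = flat
    return model


def _unet_container(c_in: int, c_out: int, n_blocks: int, p: float, rng, dtype
                    ) -> nn.Sequential:
    """Blocks of [conv 3x3 pad 1 + ReLU, dropout, batch-norm]."""
    layers: list[nn.Layer] = []
    for b in range(n_blocks):
        layers += [
            nn.Conv2d(c_in if b == 0 else c_out, c_out, 3, pad=1, rng=rng, dtype=dtype),
            nn.ReLU(),
            nn.Dropout(p),
            nn.BatchNorm(c_out, dtype=dtype),
        ]
    return nn.Sequential(*layers)


class _UNetGraph(nn.Layer):
    """Encoder-decoder graph with skip concatenations."""

    def __init__(self, spec: SurrogateSpec, rng, dtype):
        ch = spec.channels
        p = spec.dropout_p
        nb = spec.blocks_per_container
        nc = spec.n_containers
        self.encoders = [
            _unet_container(1 if k == 0 else ch, ch, nb, p, rng, dtype)
            for k in range(nc)
        ]
        self.pools = [nn.MaxPool2() for _ in range(nc)]
        # decoder container k consumes the concat produced below container k+1
        self.decoders = [
            _unet_container(ch if k == nc - 1 else 2 * ch, ch, nb, p, rng, dtype)
            for k in range(nc)
        ]
        self.ups = [nn.UpsampleNearest2() for _ in range(nc)]
        self.final = _unet_container(2 * ch, ch, nb, p, rng, dtype)
        self.out_conv = nn.Conv2d(ch, 1, 1, pad=0, rng=rng, dtype=dtype)
        self.channels = ch

    def all_layers(self):
        return [*self.encoders, *self.pools, *self.decoders, *self.ups,
                self.final, self.out_conv]

    def forward(self, x, training=False):
        skips = []
        a = x
        for enc, pool in zip(self.encoders, self.pools):
            e = enc.forward(a, training=training)
            skips.append(e)
            a = pool.forward(e, training=training)
        d = a
        for k in range(len(self.decoders) - 1, -1, -1):
            d = self.decoders[k].forward(d, training=training)
            d = self.ups[k].forward(d, training=training)
            d = np.concatenate([d, skips[k]], axis=1)
        d = self.final.forward(d, training=training)
        return self.out_conv.forward(d, training=training)

    def backward(self, grad):
        ch = self.channels
        g = self.out_conv.backward(grad)
        g = self.final.backward(g)
        skip_grads: list[np.ndarray] = [None] * len(self.decoders)  # type: ignore
        for k in range(len(self.decoders)):
            g_up, skip_grads[k] = g[:, :ch], g[:, ch:]
            g = self.ups[k].backward(g_up)
            g = self.decoders[k].backward(g)
        for k in range(len(self.encoders) - 1, -1, -1):
            g = self.pools[k].backward(g)
            g = g + skip_grads[k]
            g = self.encoders[k].backward(g)
        return g

    def params(self):
        return [p for layer in self.all_layers() for p in layer.params()]

    def set_rng(self, rng):
        for layer in self.all_layers():
            layer.set_rng(rng)


def build_unet(spec: SurrogateSpec, rng: np.random.Generator | None = None,
               dtype=np.float32) -> Model:
    """U-Net field reconstructor: output shape equals input shape."""
    if spec.kind is not ModelKind.UNET:
        raise ValueError("spec.kind must be UNET")
    rng = rng or np.random.default_rng(0)
    return Model(spec, _UNetGraph(spec, rng, dtype))


def build_unet_half(spec: SurrogateSpec, rng: np.random.Generator | None = None,
                    dtype=np.float32) -> Model:
    """U-Net encoder followed by the C-Net fully-connected head."""
    if spec.kind is not ModelKind.UNET_HALF:
        raise ValueError("spec.kind must be UNET_HALF")
    rng = rng or np.random.default_rng(0)
    ch, p = spec.channels, spec.dropout_p
    layers: list[nn.Layer] = []
    c_in = 1
    for _ in range(spec.n_containers):
        layers.append(
            _unet_container(c_in, ch, spec.blocks_per_container, p, rng, dtype)
        )
        layers.append(nn.MaxPool2())
        c_in = ch
    bottleneck_side = spec.input_side // (2**spec.n_containers)
    flat = ch * bottleneck_side * bottleneck_side
    layers.append(nn.Flatten())
    layers += _fc_head(flat, p, spec.sn_enabled, rng, dtype)
    model = Model(spec, nn.Sequential(*layers))
    model.flatten_length = flat
    return model


_BUILDERS = {
    ModelKind.CNET: build_cnet,
    ModelKind.UNET: build_unet,
    ModelKind.UNET_HALF: build_unet_half,
}


def build_model(spec: SurrogateSpec, rng=None, dtype=np.float32) -> Model:
    return _BUILDERS[spec.kind](spec, rng=rng, dtype=dtype)


def mc_dropout_predict(model: Model, x: np.ndarray, M: int = 20,
                       seed: int | None = None) -> UncertaintyResult:
    """Monte Carlo dropout inference.

    ``M`` forward passes with dropout active (batch-norm in inference mode);
    returns the element-wise mean (the prediction) and standard deviation
    (the 1-sigma uncertainty).  With ``dropout_p = 0`` the spread is zero by
    construction (a warning-level fact, not an error).
    """
    if M < 2:
        raise ValueError("M must be >= 2")
    drops = model.dropout_layers()
    if not drops:
        raise ValueError("model has no dropout layer; MC dropout is undefined")
    rng = np.random.default_rng(seed)
    for d in drops:
        d.mc_active = True
        d.set_rng(rng)
    try:
        outs = np.stack([model.forward(x, training=False) for _ in range(M)])
    finally:
        for d in drops:
            d.mc_active = False
    return UncertaintyResult(
        mean=outs.mean(axis=0), sigma=outs.std(axis=0, ddof=0), M=M
    )


def describe(model: Model) -> str:
    """Structural walk: layers, output shapes and parameter count."""
    lines = [f"{model.spec.kind.value} (input {model.spec.input_side}x"
             f"{model.spec.input_side}, dropout p={model.spec.dropout_p}, "
             f"SN={'on' if model.spec.sn_enabled else 'off'})"]
    x = np.zeros((1, 1, model.spec.input_side, model.spec.input_side),
                 dtype=np.float32)

    def walk(layer, depth):
        nonlocal x
        name = type(layer).__name__
        if isinstance(layer, nn.Sequential):
            lines.append("  " * depth + name)
            for sub in layer.layers:
                walk(sub, depth + 1)
        elif isinstance(layer, _UNetGraph):
            lines.append("  " * depth + "UNetGraph")
            for sub in layer.all_layers():
                walk(sub, depth + 1)
        else:
            n_par = sum(p.value.size for p in layer.params())
            lines.append("  " * depth + f"{name} ({n_par} params)")

    walk(model.net, 1)
    lines.append(f"total parameters: {model.n_parameters()}")
    return "\n".join(lines)
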