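"""Feature-gain networks: convolutional blocks with cue-driven gains.

The network models selective listening as multiplicative, feature-based
attention.  A cue sound (an isolated sample of the target talker) is passed
through the same convolutional hierarchy as the cue+distractor mixture.  At
the cochleagram stage and after every convolutional block, the cue's
activation is averaged over time to form a "memory" m of the cue's features
(one value per channel x frequency), a sigmoidal function with learnable
bias/slope/threshold maps that memory to a gain map g(m), and the mixture's
activation at the same stage is multiplied by g (broadcast over time).
Features prominent in the cue are passed through; others are attenuated.

Each convolutional block is layer-normalization -> 2-D convolution (valid in
time, zero-padded 'same' in frequency, stride 1, no bias) -> ReLU ->
Hanning-weighted average pooling.  After the last block the mixture
representation is flattened and classified through a fully-connected layer,
ReLU, dropout (training only) and a softmax over the word vocabulary.

Three control variants are provided: a ``baseline`` network that receives
the cue and mixture concatenated as a 4-channel input with no gains, an
``early-only`` network that gates only the cochleagram, and a ``late-only``
network that gates only the final convolutional stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from ._tensor import (
    Tensor,
    conv2d,
    dropout as _dropout,
    hann_pool2d,
    softmax,
)
from .periphery import Cochleagram

__all__ = [
    "LayerNormParams",
    "ConvBlockParams",
    "GainParams",
    "StageState",
    "BlockSpec",
    "NetworkSpec",
    "GainNet",
    "init_network",
    "layer_normalize",
    "convolve_block",
    "pool_hanning",
    "time_average_memory",
    "compute_gains",
    "attended_forward",
    "variant_forward",
    "forward_with_activations",
    "save_network",
    "load_network",
    "toy_network_spec",
]

VARIANTS = ("feature-gain", "baseline", "early-only", "late-only")


# --------------------------------------------------------------------------
# Parameter containers
# --------------------------------------------------------------------------

@dataclass
class LayerNormParams:
    """Learnable scale/shift for layer normalization.

    ``gamma``/``beta`` must broadcast against a (C, F, T) activation; the
    default is per-channel (C, 1, 1).  Statistics are always computed over
    all feature dimensions (C, F, T) of each example.
    """

    gamma: np.ndarray
    beta: np.ndarray
    epsilon: float = 1e-5

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        self.gamma = np.asarray(self.gamma, dtype=np.float32)
        self.beta = np.asarray(self.beta, dtype=np.float32)


@dataclass
class ConvBlockParams:
    """One convolutional block: norm -> conv -> ReLU -> Hanning pool."""

    kernels: np.ndarray  # (C_out, C_in, n_f, n_t)
    pool_stride_freq: int
    pool_stride_time: int
    norm: LayerNormParams

    def __post_init__(self):
        self.kernels = np.asarray(self.kernels, dtype=np.float32)
        if self.kernels.ndim != 4:
            raise ValueError("kernels must be (C_out, C_in, n_f, n_t)")
        if min(self.kernels.shape[2:]) < 1:
            raise ValueError("kernel extents must be >= 1")
        if self.pool_stride_freq < 1 or self.pool_stride_time < 1:
            raise ValueError("pool strides must be >= 1")


@dataclass
class GainParams:
    """Sigmoidal gain function parameters: bias, slope, threshold.

    Two algebraic forms of the sigmoid are supported:

    - ``"saturating"`` (default): g = theta1 + (1 - theta1) * logistic(theta2*(m - theta3)),
      with limits {theta1, 1}; strongly cued features pass at unit gain.
    - ``"shifted"``: g = theta1 - (1 - theta1) * logistic(theta2*(m - theta3)),
      with limits {theta1, 2*theta1 - 1}.
    """

    theta1: float = 1.0
    theta2: float = 1.0
    theta3: float = 0.0
    parameterization: str = "saturating"

    def __post_init__(self):
        if self.parameterization not in ("saturating", "shifted"):
            raise ValueError(f"unknown gain parameterization {self.parameterization!r}")


@dataclass
class StageState:
    """Per-stage record: activation, cue memory, and applied gain map."""

    activation: np.ndarray  # (C, F, T)
    cue_memory: np.ndarray  # (C, F)
    gain_map: np.ndarray  # (C, F)


# --------------------------------------------------------------------------
# Architecture specification
# --------------------------------------------------------------------------

@dataclass
class BlockSpec:
    """Shape of one convolutional block (before weights exist)."""

    out_channels: int
    kernel_freq: int
    kernel_time: int
    pool_stride_freq: int = 1
    pool_stride_time: int = 1


@dataclass
class NetworkSpec:
    """Architecture description for a feature-gain network or control."""

    blocks: list[BlockSpec]
    fc_width: int
    n_classes: int
    dropout_p: float = 0.5
    variant: str = "feature-gain"
    gain_parameterization: str = "saturating"
    norm_param_shape: str = "channel"  # "channel" (C,1,1) or "full" (C,F,T)

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must be in [0, 1)")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")

    @property
    def in_channels(self) -> int:
        return 4 if self.variant == "baseline" else 2


def network_spec_from_yaml(path) -> NetworkSpec:
    """Load a :class:`NetworkSpec` from a YAML file.

    Expected layout::

        variant: feature-gain
        fc_width: 64
        n_classes: 8
        dropout_p: 0.5
        blocks:
          - {out_channels: 8, kernel_freq: 3, kernel_time: 5,
             pool_stride_freq: 2, pool_stride_time: 4}
    """
    import yaml

    with open(path) as f:
        cfg = yaml.safe_load(f)
    blocks = [BlockSpec(**b) for b in cfg.pop("blocks")]
    return NetworkSpec(blocks=blocks, **cfg)


def network_spec_to_yaml(spec: NetworkSpec, path) -> None:
    import yaml
    from dataclasses import asdict

    cfg = {
        "variant": spec.variant,
        "fc_width": spec.fc_width,
        "n_classes": spec.n_classes,
        "dropout_p": spec.dropout_p,
        "gain_parameterization": spec.gain_parameterization,
        "norm_param_shape": spec.norm_param_shape,
        "blocks": [asdict(b) for b in spec.blocks],
    }
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=False)


def toy_network_spec(n_classes: int = 8, variant: str = "feature-gain") -> NetworkSpec:
    """Small three-block architecture for desk-scale experiments."""
    return NetworkSpec(
        blocks=[
            BlockSpec(8, 3, 5, pool_stride_freq=2, pool_stride_time=4),
            BlockSpec(16, 3, 5, pool_stride_freq=2, pool_stride_time=4),
            BlockSpec(24, 2, 3, pool_stride_freq=2, pool_stride_time=2),
        ],
        fc_width=64,
        n_classes=n_classes,
        variant=variant,
    )


# --------------------------------------------------------------------------
# Instantiated network
# --------------------------------------------------------------------------

@dataclass
class GainNet:
    """A network with concrete weights.

    ``blocks`` holds the shared convolutional block parameters (identical
    storage is read for the cue and mixture passes), ``gains`` one
    :class:`GainParams` triple per gated stage (cochleagram stage first),
    and ``fc_*``/``out_*`` the classifier head.
    """

    spec: NetworkSpec
    blocks: list[ConvBlockParams]
    gains: list[GainParams]
    fc_w: np.ndarray
    fc_b: np.ndarray
    out_w: np.ndarray
    out_b: np.ndarray

    def n_gated_stages(self) -> int:
        return len(self.gains)

    def parameters(self) -> dict[str, np.ndarray]:
        """Flat name -> array view of every trainable parameter."""
        params: dict[str, np.ndarray] = {}
        for i, b in enumerate(self.blocks):
            params[f"block{i}.kernels"] = b.kernels
            params[f"block{i}.gamma"] = b.norm.gamma
            params[f"block{i}.beta"] = b.norm.beta
        params["fc.w"] = self.fc_w
        params["fc.b"] = self.fc_b
        params["out.w"] = self.out_w
        params["out.b"] = self.out_b
        return params


def _infer_shapes(spec: NetworkSpec, input_shape: tuple[int, int]) -> list[tuple[int, int, int]]:
    """Per-block input (C, F, T) shapes given the cochleagram (F, T)."""
    c, (f, t) = spec.in_channels, input_shape
    shapes = []
    for blk in spec.blocks:
        shapes.append((c, f, t))
        t = t - blk.kernel_time + 1
        if t < 1:
            raise ValueError("time axis exhausted: input too short for this architecture")
        f = f // blk.pool_stride_freq
        t = t // blk.pool_stride_time
        c = blk.out_channels
    shapes.append((c, f, t))  # final representation entering the classifier
    return shapes


def init_network(
    spec: NetworkSpec,
    input_shape: tuple[int, int],
    rng: np.random.Generator,
) -> GainNet:
    """He-initialize weights; gain functions start at identity (theta1=1).

    ``input_shape`` is the (n_freq, n_time) shape of the cochleagram.
    """
    shapes = _infer_shapes(spec, input_shape)
    blocks: list[ConvBlockParams] = []
    for blk, (c_in, f_in, t_in) in zip(spec.blocks, shapes[:-1]):
        fan_in = c_in * blk.kernel_freq * blk.kernel_time
        k = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(blk.out_channels, c_in, blk.kernel_freq, blk.kernel_time))
        if spec.norm_param_shape == "full":
            gshape = (c_in, f_in, t_in)
        else:
            gshape = (c_in, 1, 1)
        blocks.append(ConvBlockParams(
            kernels=k.astype(np.float32),
            pool_stride_freq=blk.pool_stride_freq,
            pool_stride_time=blk.pool_stride_time,
            norm=LayerNormParams(np.ones(gshape), np.zeros(gshape)),
        ))
    c_f, f_f, t_f = shapes[-1]
    flat = c_f * f_f * t_f
    fc_w = rng.normal(0.0, np.sqrt(2.0 / flat), size=(spec.fc_width, flat)).astype(np.float32)
    fc_b = np.zeros(spec.fc_width, dtype=np.float32)
    out_w = rng.normal(0.0, np.sqrt(1.0 / spec.fc_width),
                       size=(spec.n_classes, spec.fc_width)).astype(np.float32)
    out_b = np.zeros(spec.n_classes, dtype=np.float32)
    if spec.variant == "baseline":
        gains: list[GainParams] = []
    elif spec.variant in ("early-only", "late-only"):
        gains = [GainParams(parameterization=spec.gain_parameterization)]
    else:
        gains = [GainParams(parameterization=spec.gain_parameterization)
                 for _ in range(len(spec.blocks) + 1)]
    return GainNet(spec=spec, blocks=blocks, gains=gains,
                   fc_w=fc_w, fc_b=fc_b, out_w=out_w, out_b=out_b)


# --------------------------------------------------------------------------
# Operations (callable on plain arrays; autodiff-aware on Tensors)
# --------------------------------------------------------------------------

def _as4d(x) -> tuple[Tensor, bool]:
    """Promote (C,F,T) to (1,C,F,T); remember whether we added a batch axis."""
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
    if t.ndim == 3:
        return t.reshape(1, *t.shape), True
    if t.ndim != 4:
        raise ValueError(f"expected a 3-D or 4-D activation, got shape {t.shape}")
    return t, False


def _out(t: Tensor, squeeze: bool, want_tensor: bool):
    if squeeze:
        t = t.reshape(*t.shape[1:])
    return t if want_tensor else t.data


def layer_normalize(x, p: LayerNormParams):
    """(x - mean) / sqrt(var + eps) * gamma + beta, statistics over C,F,T."""
    t, squeezed = _as4d(x)
    want = isinstance(x, Tensor)
    feat_shape = t.shape[1:]
    try:
        np.broadcast_shapes(tuple(p.gamma.shape), tuple(feat_shape))
    except ValueError as e:
        raise ValueError(
            f"gamma shape {p.gamma.shape} does not broadcast to activation {feat_shape}"
        ) from e
    gamma = p.gamma if isinstance(p.gamma, Tensor) else Tensor(p.gamma)
    beta = p.beta if isinstance(p.beta, Tensor) else Tensor(p.beta)
    mu = t.mean(axis=(1, 2, 3), keepdims=True)
    centered = t - mu
    var = (centered * centered).mean(axis=(1, 2, 3), keepdims=True)
    y = centered / (var + p.epsilon).sqrt() * gamma + beta
    return _out(y, squeezed, want)


def pool_hanning(x, s_f: int, s_t: int):
    """Hanning-weighted average pooling (see :func:`_tensor.hann_pool2d`)."""
    if s_f == 1 and s_t == 1:
        return x
    t, squeezed = _as4d(x)
    return _out(hann_pool2d(t, s_f, s_t), squeezed, isinstance(x, Tensor))


def convolve_block(x, p: ConvBlockParams, _norm_params=None):
    """Full block: layer-normalize, convolve, rectify, pool."""
    t, squeezed = _as4d(x)
    want = isinstance(x, Tensor)
    y = layer_normalize(t, _norm_params if _norm_params is not None else p.norm)
    w = p.kernels if isinstance(p.kernels, Tensor) else Tensor(p.kernels)
    y = conv2d(y, w).relu()
    y = pool_hanning(y, p.pool_stride_freq, p.pool_stride_time)
    return _out(y, squeezed, want)


def time_average_memory(x):
    """Arithmetic mean over the trailing time axis: (...,C,F,T) -> (...,C,F)."""
    if isinstance(x, Tensor):
        if x.shape[-1] < 1:
            raise ValueError("empty time axis")
        return x.mean(axis=-1)
    arr = np.asarray(x, dtype=float)
    if arr.shape[-1] < 1:
        raise ValueError("empty time axis")
    return arr.mean(axis=-1)


def compute_gains(m, p: GainParams):
    """Elementwise sigmoidal gain of the cue memory."""
    if isinstance(m, Tensor):
        s = ((m - p.theta3) * p.theta2).sigmoid()
        if p.parameterization == "saturating":
            return p.theta1 + (1.0 - p.theta1) * s
        return p.theta1 - (1.0 - p.theta1) * s
    s = expit(p.theta2 * (np.asarray(m, dtype=float) - p.theta3))
    if p.parameterization == "saturating":
        return p.theta1 + (1.0 - p.theta1) * s
    return p.theta1 - (1.0 - p.theta1) * s


def _gain_tensor(m: Tensor, g: GainParams, params: list[Tensor] | None) -> Tensor:
    """Gain map from memory, optionally reading learnable theta Tensors."""
    if params is None:
        return compute_gains(m, g)
    t1, t2, t3 = params
    s = ((m - t3) * t2).sigmoid()
    if g.parameterization == "saturating":
        return t1 + (1.0 - t1) * s
    return t1 - (1.0 - t1) * s


def _apply_gain(x: Tensor, gmap: Tensor) -> Tensor:
    """Broadcast a (B,C,F) gain map over the time axis of (B,C,F,T)."""
    return x * gmap.reshape(*gmap.shape, 1)


# --------------------------------------------------------------------------
# Forward passes
# --------------------------------------------------------------------------

def _coerce_batch(cg) -> np.ndarray:
    """Accept Cochleagram, (C,F,T) array, or (B,C,F,T) array -> (B,C,F,T)."""
    if isinstance(cg, Cochleagram):
        arr = cg.values
    else:
        arr = np.asarray(cg)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4:
        raise ValueError(f"expected (C,F,T) or (B,C,F,T), got {arr.shape}")
    return arr.astype(np.float32, copy=False)


class _ForwardContext:
    """Holds Tensor views of the net parameters for one forward/backward."""

    def __init__(self, net: GainNet, trainable: bool):
        self.net = net
        self.trainable = trainable
        self.block_w = [Tensor(b.kernels, requires_grad=trainable) for b in net.blocks]
        self.block_gamma = [Tensor(b.norm.gamma, requires_grad=trainable) for b in net.blocks]
        self.block_beta = [Tensor(b.norm.beta, requires_grad=trainable) for b in net.blocks]
        self.gain_thetas = [
            [Tensor(np.asarray(v, dtype=np.float32), requires_grad=trainable)
             for v in (g.theta1, g.theta2, g.theta3)]
            for g in net.gains
        ]
        self.fc_w = Tensor(net.fc_w, requires_grad=trainable)
        self.fc_b = Tensor(net.fc_b, requires_grad=trainable)
        self.out_w = Tensor(net.out_w, requires_grad=trainable)
        self.out_b = Tensor(net.out_b, requires_grad=trainable)

    def block(self, i: int, x: Tensor) -> Tensor:
        b = self.net.blocks[i]
        norm = LayerNormParams.__new__(LayerNormParams)
        norm.gamma = self.block_gamma[i]
        norm.beta = self.block_beta[i]
        norm.epsilon = b.norm.epsilon
        y = layer_normalize(x, norm)
        y = conv2d(y, self.block_w[i]).relu()
        return pool_hanning(y, b.pool_stride_freq, b.pool_stride_time)

    def gain(self, stage: int, cue_act: Tensor) -> Tensor:
        m = time_average_memory(cue_act)
        return _gain_tensor(m, self.net.gains[stage], self.gain_thetas[stage])

    def head(self, x: Tensor, train_mode: bool, rng) -> Tensor:
        b = x.shape[0]
        flat = x.reshape(b, -1)
        h = (flat @ _transpose(self.fc_w) + self.fc_b).relu()
        if train_mode and self.net.spec.dropout_p > 0:
            if rng is None:
                raise ValueError("train_mode forward needs an rng for dropout")
            h = _dropout(h, self.net.spec.dropout_p, rng)
        return h @ _transpose(self.out_w) + self.out_b

    def grads(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i in range(len(self.net.blocks)):
            out[f"block{i}.kernels"] = self.block_w[i].grad
            out[f"block{i}.gamma"] = self.block_gamma[i].grad
            out[f"block{i}.beta"] = self.block_beta[i].grad
        for s, thetas in enumerate(self.gain_thetas):
            for j, t in enumerate(thetas, start=1):
                out[f"gain{s}.theta{j}"] = t.grad
        out["fc.w"] = self.fc_w.grad
        out["fc.b"] = self.fc_b.grad
        out["out.w"] = self.out_w.grad
        out["out.b"] = self.out_b.grad
        return out


def _transpose(t: Tensor) -> Tensor:
    out = Tensor(t.data.T, t.requires_grad, (t,))
    if out.requires_grad:
        out._backward = lambda g: t._accumulate(g.T)
    return out


def _forward_logits(
    ctx: _ForwardContext,
    cue: np.ndarray,
    mix: np.ndarray,
    train_mode: bool,
    rng,
    capture: list | None = None,
) -> Tensor:
    """Shared forward pass for all variants; optionally capture stage states."""
    net = ctx.net
    variant = net.spec.variant
    if variant == "baseline":
        x = Tensor(np.concatenate([cue, mix], axis=1))
        if capture is not None:
            capture.append(("cochleagram", x, None, None))
        for i in range(len(net.blocks)):
            x = ctx.block(i, x)
            if capture is not None:
                capture.append((f"block{i}", x, None, None))
        return ctx.head(x, train_mode, rng)

    if cue.shape != mix.shape:
        raise ValueError(f"cue shape {cue.shape} != mixture shape {mix.shape}")
    x_cue = Tensor(cue)
    x_mix = Tensor(mix)
    n_blocks = len(net.blocks)
    gate_cochlea = variant in ("feature-gain", "early-only")
    if gate_cochlea:
        g = ctx.gain(0, x_cue)
        x_mix = _apply_gain(x_mix, g)
        if capture is not None:
            capture.append(("cochleagram", x_mix, time_average_memory(x_cue), g))
    elif capture is not None:
        capture.append(("cochleagram", x_mix, None, None))
    for i in range(n_blocks):
        x_mix = ctx.block(i, x_mix)
        need_cue = variant == "feature-gain" or (variant == "late-only" and True)
        if need_cue:
            x_cue = ctx.block(i, x_cue)
        g = None
        if variant == "feature-gain":
            g = ctx.gain(i + 1, x_cue)
        elif variant == "late-only" and i == n_blocks - 1:
            g = ctx.gain(0, x_cue)
        if g is not None:
            x_mix = _apply_gain(x_mix, g)
        if capture is not None:
            mem = time_average_memory(x_cue) if g is not None else None
            capture.append((f"block{i}", x_mix, mem, g))
    return ctx.head(x_mix, train_mode, rng)


def attended_forward(cue, mix, net: GainNet, train_mode: bool = False,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Cue-conditioned forward pass of the feature-gain network.

    Returns class probabilities (sums to 1); batched inputs give (B, V).
    """
    if net.spec.variant != "feature-gain":
        raise ValueError("attended_forward requires a feature-gain network; "
                         "use variant_forward for controls")
    return _probs(cue, mix, net, train_mode, rng)


def variant_forward(cue, mix, net: GainNet) -> np.ndarray:
    """Forward pass for the baseline / early-only / late-only controls."""
    if net.spec.variant == "feature-gain":
        raise ValueError("variant_forward is for control variants; "
                         "use attended_forward for the feature-gain network")
    return _probs(cue, mix, net, train_mode=False, rng=None)


def _probs(cue, mix, net, train_mode, rng) -> np.ndarray:
    cue_a, mix_a = _coerce_batch(cue), _coerce_batch(mix)
    single = isinstance(mix, Cochleagram) or np.asarray(
        mix.values if isinstance(mix, Cochleagram) else mix).ndim == 3
    ctx = _ForwardContext(net, trainable=False)
    logits = _forward_logits(ctx, cue_a, mix_a, train_mode, rng)
    p = softmax(logits.data, axis=1)
    return p[0] if single else p


def forward_with_activations(cue, mix, net: GainNet) -> list[StageState]:
    """Evaluation-mode forward pass recording every stage's state.

    Returns one :class:`StageState` per stage (cochleagram first).  For
    ungated stages the memory/gain fields are unit/empty placeholders.
    """
    cue_a, mix_a = _coerce_batch(cue), _coerce_batch(mix)
    ctx = _ForwardContext(net, trainable=False)
    capture: list = []
    _forward_logits(ctx, cue_a, mix_a, train_mode=False, rng=None, capture=capture)
    states = []
    for name, act, mem, g in capture:
        a = act.data[0]
        mem_a = mem.data[0] if mem is not None else a.mean(axis=-1)
        g_a = g.data[0] if g is not None else np.ones(a.shape[:2], dtype=a.dtype)
        g_a = np.broadcast_to(g_a, a.shape[:2]).copy()
        states.append(StageState(activation=a, cue_memory=mem_a, gain_map=g_a))
    return states


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

def save_network(path, net: GainNet) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        s = net.spec
        f.attrs["variant"] = s.variant
        f.attrs["fc_width"] = s.fc_width
        f.attrs["n_classes"] = s.n_classes
        f.attrs["dropout_p"] = s.dropout_p
        f.attrs["gain_parameterization"] = s.gain_parameterization
        f.attrs["norm_param_shape"] = s.norm_param_shape
        for i, (bs, bp) in enumerate(zip(s.blocks, net.blocks)):
            grp = f.create_group(f"block{i}")
            grp.attrs["pool_stride_freq"] = bs.pool_stride_freq
            grp.attrs["pool_stride_time"] = bs.pool_stride_time
            grp.create_dataset("kernels", data=bp.kernels)
            grp.create_dataset("gamma", data=bp.norm.gamma)
            grp.create_dataset("beta", data=bp.norm.beta)
            grp.attrs["epsilon"] = bp.norm.epsilon
        for j, g in enumerate(net.gains):
            grp = f.create_group(f"gain{j}")
            grp.attrs["theta1"] = g.theta1
            grp.attrs["theta2"] = g.theta2
            grp.attrs["theta3"] = g.theta3
        f.create_dataset("fc_w", data=net.fc_w)
        f.create_dataset("fc_b", data=net.fc_b)
        f.create_dataset("out_w", data=net.out_w)
        f.create_dataset("out_b", data=net.out_b)


def load_network(path) -> GainNet:
    import h5py

    with h5py.File(path, "r") as f:
        blocks, specs = [], []
        i = 0
        while f"block{i}" in f:
            grp = f[f"block{i}"]
            k = np.asarray(grp["kernels"])
            blocks.append(ConvBlockParams(
                kernels=k,
                pool_stride_freq=int(grp.attrs["pool_stride_freq"]),
                pool_stride_time=int(grp.attrs["pool_stride_time"]),
                norm=LayerNormParams(np.asarray(grp["gamma"]), np.asarray(grp["beta"]),
                                     float(grp.attrs["epsilon"])),
            ))
            specs.append(BlockSpec(
                out_channels=k.shape[0], kernel_freq=k.shape[2], kernel_time=k.shape[3],
                pool_stride_freq=int(grp.attrs["pool_stride_freq"]),
                pool_stride_time=int(grp.attrs["pool_stride_time"]),
            ))
            i += 1
        gains = []
        j = 0
        while f"gain{j}" in f:
            grp = f[f"gain{j}"]
            gains.append(GainParams(
                theta1=float(grp.attrs["theta1"]),
                theta2=float(grp.attrs["theta2"]),
                theta3=float(grp.attrs["theta3"]),
                parameterization=str(f.attrs["gain_parameterization"]),
            ))
            j += 1
        spec = NetworkSpec(
            blocks=specs,
            fc_width=int(f.attrs["fc_width"]),
            n_classes=int(f.attrs["n_classes"]),
            dropout_p=float(f.attrs["dropout_p"]),
            variant=str(f.attrs["variant"]),
            gain_parameterization=str(f.attrs["gain_parameterization"]),
            norm_param_shape=str(f.attrs["norm_param_shape"]),
        )
        return GainNet(spec=spec, blocks=blocks, gains=gains,
                       fc_w=np.asarray(f["fc_w"]), fc_b=np.asarray(f["fc_b"]),
                       out_w=np.asarray(f["out_w"]), out_b=np.asarray(f["out_b"]))
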