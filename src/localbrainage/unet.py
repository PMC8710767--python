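"""3D regression U-Net for voxel-level brain-age prediction (NumPy/BLAS).

The network maps a two-channel 52^3 tissue-volume block to a 12^3 block of
voxel-level age predictions plus two scalar auxiliary (block-level) age
predictions.  All convolutions are "valid" (no padding) 3x3x3, stride 1,
followed by a leaky rectifier (slope 0.2) and a squeeze-and-excite channel
gate.  Channel width starts at ``base_channels`` and doubles at each of the
two encoder levels below the top.

Pooling geometry.  Average pooling uses a 2x2x2 kernel with *stride 1* and
the matching upsampling is a size-restoring nearest repeat; the network
therefore runs at full resolution throughout and every layer keeps an
effective stride of one.  This is the only geometry under which the two
published contracts hold simultaneously: the 52^3 -> 12^3 spatial contract
(a final centre crop takes the stride-1 output of 32^3 down to 12^3) and a
measured receptive field of exactly 23^3 voxels for each output voxel
(1 + 2 per conv x 10 convs + 1 per pooling x 2 poolings).  Conventional
stride-2 pooling would give a 44^3 receptive field instead.

Forward and backward passes are written out layer by layer; convolutions are
evaluated as an im2col gather (numba-jitted) followed by one GEMM so the
heavy lifting stays in BLAS.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass

import numpy as np
from numba import njit

__all__ = [
    "ArchitectureSpec",
    "LossConfig",
    "LocalBrainAgeUNet",
    "ConvChain",
    "build_network",
    "composite_loss",
    "loss_gradients",
    "measure_receptive_field",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Architecture hyperparameters; defaults are the full published model."""

    in_channels: int = 2
    base_channels: int = 64
    scales: int = 3
    convs_per_scale: int = 2
    conv_kernel: int = 3
    leaky_alpha: float = 0.2
    se_reduction: int = 16
    aux_heads: int = 2
    input_side: int = 52
    output_side: int = 12

    def __post_init__(self) -> None:
        if self.conv_kernel != 3:
            raise ValueError("only 3x3x3 convolution kernels are supported")
        if self.scales < 2:
            raise ValueError("need at least 2 scales")
        if self.aux_heads != self.scales - 1:
            raise ValueError(
                f"aux_heads must equal scales-1 (one per coarse scale); "
                f"got {self.aux_heads} with scales={self.scales}"
            )
        if self.se_reduction < 1:
            raise ValueError("se_reduction must be >= 1")
        n_convs = self.convs_per_scale * (2 * self.scales - 1)
        pre_crop = self.input_side - 2 * n_convs  # pools(-1 each) + ups(+1 each) cancel
        if pre_crop < self.output_side or (pre_crop - self.output_side) % 2:
            raise ValueError(
                f"spec violates the {self.input_side}->{self.output_side} spatial contract "
                f"(stride-1 network output would be {pre_crop}^3)"
            )

    @property
    def n_convs(self) -> int:
        return self.convs_per_scale * (2 * self.scales - 1)

    @property
    def receptive_field_side(self) -> int:
        """Analytic field of view: 1 + 2 per conv + 1 per pooling."""
        return 1 + 2 * self.n_convs + (self.scales - 1)


@dataclass(frozen=True)
class LossConfig:
    """Composite-loss weights: voxel MAE-sum plus decaying auxiliary terms.

    ``alpha_1``/``alpha_2`` weight the two block-level auxiliary MAE terms at
    iteration 0; both decay linearly to 0 at ``decay_iterations`` so that
    gradients flow exclusively from the voxel-level predictions afterwards.
    """

    alpha_1: float = 1.0
    alpha_2: float = 1.0
    decay_iterations: int = 50_000

    def __post_init__(self) -> None:
        if self.alpha_1 < 0 or self.alpha_2 < 0:
            raise ValueError("auxiliary loss weights must be >= 0")
        if self.decay_iterations < 1:
            raise ValueError("decay_iterations must be >= 1")

    def alphas(self, iteration: int) -> np.ndarray:
        scale = max(0.0, 1.0 - iteration / self.decay_iterations)
        return np.array([self.alpha_1, self.alpha_2], dtype=np.float64) * scale


# ---------------------------------------------------------------------------
# layers (each instance caches what its backward pass needs)

_OFFSETS = [(a, b, c) for a in range(3) for b in range(3) for c in range(3)]


@njit(fastmath=True)
def _im2col(x, col):  # pragma: no cover - exercised through _Conv3
    d_in, h_in, w_in, c_in = x.shape
    do, ho, wo = d_in - 2, h_in - 2, w_in - 2
    n = 0
    for d in range(do):
        for h in range(ho):
            for w in range(wo):
                k = 0
                for c in range(c_in):
                    for a in range(3):
                        for b in range(3):
                            for cc in range(3):
                                col[n, k] = x[d + a, h + b, w + cc, c]
                                k += 1
                n += 1


@njit(fastmath=True)
def _col2im(dcol, dx):  # pragma: no cover - exercised through _Conv3
    d_in, h_in, w_in, c_in = dx.shape
    do, ho, wo = d_in - 2, h_in - 2, w_in - 2
    n = 0
    for d in range(do):
        for h in range(ho):
            for w in range(wo):
                k = 0
                for c in range(c_in):
                    for a in range(3):
                        for b in range(3):
                            for cc in range(3):
                                dx[d + a, h + b, w + cc, c] += dcol[n, k]
                                k += 1
                n += 1


class _Conv3:
    """Valid 3x3x3 convolution via im2col + one GEMM.

    ``W`` has shape ``(c_in * 27, c_out)`` with rows ordered channel-major
    then kernel-offset.  The gather/scatter between the volume and the
    column matrix is numba-jitted (a strided NumPy copy is the bottleneck
    otherwise); outside training the column buffer is rebuilt in backward
    rather than cached, keeping peak memory to one buffer per live conv.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        init: str = "he",
        passthrough: tuple[int, int] | None = None,
    ):
        fan_in = 27 * c_in
        self.W = (rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        if init == "local":
            # identity-preserving start: damped variance-scaled noise plus a
            # unit centre tap copying an input channel, so local intensity
            # reaches the readout unmixed from iteration 0
            off, cnt = passthrough if passthrough is not None else (0, c_in)
            self.W *= np.float32(0.05)
            for c in range(c_out):
                src = off + (c % cnt)
                self.W[src * 27 + 13, c] += 1.0  # centre offset (1,1,1)
        elif init != "he":
            raise ValueError(f"unknown init {init!r}")
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None
        self._colbuf: np.ndarray | None = None
        #: keep the forward column buffer for backward; enabled by the
        #: training loop (saves a re-gather per conv) and off everywhere
        #: else - at full width the cached columns alone exceed 6 GB
        self.cache_col = False
        #: sensitivity probes need only the input gradient; skipping dW/db
        #: halves backward memory traffic at full width
        self.skip_param_grads = False

    params = property(lambda self: [self.W, self.b])
    grads = property(lambda self: [self.dW, self.db])

    @staticmethod
    def _col(x: np.ndarray) -> np.ndarray:
        do, ho, wo = (s - 2 for s in x.shape[:3])
        col = np.empty((do * ho * wo, 27 * x.shape[3]), dtype=np.float32)
        _im2col(x, col)
        return col

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        do, ho, wo = (s - 2 for s in x.shape[:3])
        col = self._col(x)
        self._colbuf = col if self.cache_col else None
        y = col @ self.W + self.b
        return y.reshape(do, ho, wo, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self._x = None
        do, ho, wo, c_out = dy.shape
        df = dy.reshape(-1, c_out)
        if not self.skip_param_grads:
            self.db += df.sum(axis=0)
            col = self._colbuf if self._colbuf is not None else self._col(x)
            self._colbuf = None
            self.dW += col.T @ df
            del col
        dcol = df @ self.W.T
        dx = np.zeros_like(x)
        _col2im(dcol, dx)
        return dx


class _LeakyReLU:
    def __init__(self, alpha: float):
        self.alpha = np.float32(alpha)
        self._pos: np.ndarray | None = None  # bool mask: 4x cheaper than slopes

    params = property(lambda self: [])
    grads = property(lambda self: [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._pos = x >= 0
        return np.where(self._pos, x, x * self.alpha)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._pos, dy, dy * self.alpha)


class _SqueezeExcite:
    """Channel attention: GAP -> dense/ReLU -> dense/sigmoid -> rescale."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator, init: str = "he"):
        hidden = max(1, channels // reduction)
        self.W1 = (rng.standard_normal((channels, hidden)) * np.sqrt(2.0 / channels)).astype(
            np.float32
        )
        self.b1 = np.zeros(hidden, dtype=np.float32)
        self.W2 = (rng.standard_normal((hidden, channels)) * np.sqrt(2.0 / hidden)).astype(
            np.float32
        )
        # gates start open (sigmoid(3) ~ 0.95): a closed-at-0.5 init would
        # attenuate activations by 0.5 per gated convolution - 1e-3 across
        # the ten-conv network - starving the readout of signal
        self.b2 = np.full(channels, 3.0, dtype=np.float32)
        if init == "local":
            # content-independent gates at start: an input-dependent gate
            # multiplies the passthrough by a per-block gain that compounds
            # across layers; zero weights (with a live hidden bias so the
            # gate stays trainable) keep the initial gain exactly constant
            self.W1[...] = 0.0
            self.W2[...] = 0.0
            self.b1[...] = 0.01
        self.dW1 = np.zeros_like(self.W1)
        self.db1 = np.zeros_like(self.b1)
        self.dW2 = np.zeros_like(self.W2)
        self.db2 = np.zeros_like(self.b2)
        self._cache = None
        #: when False, backward treats the channel gate as a constant
        #: (used by the receptive-field probe: the gate is a global scalar
        #: modulation, not part of the spatial convolutional pathway).
        self.gate_grad = True

    params = property(lambda self: [self.W1, self.b1, self.W2, self.b2])
    grads = property(lambda self: [self.dW1, self.db1, self.dW2, self.db2])

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = x.mean(axis=(0, 1, 2))
        u1 = s @ self.W1 + self.b1
        z = np.maximum(u1, 0.0)
        u2 = np.clip(z @ self.W2 + self.b2, -60.0, 60.0)  # saturate, don't overflow
        g = 1.0 / (1.0 + np.exp(-u2))
        self._cache = (x, s, u1, z, g)
        return x * g.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, s, u1, z, g = self._cache
        dx = dy * g.astype(np.float32)
        if not self.gate_grad:
            return dx
        dg = np.einsum("ijkc,ijkc->c", dy, x, optimize=True).astype(np.float64)
        du2 = dg * g * (1.0 - g)
        self.dW2 += np.outer(z, du2).astype(np.float32)
        self.db2 += du2.astype(np.float32)
        dz = du2 @ self.W2.T.astype(np.float64)
        du1 = dz * (u1 > 0)
        self.dW1 += np.outer(s, du1).astype(np.float32)
        self.db1 += du1.astype(np.float32)
        ds = (du1 @ self.W1.T.astype(np.float64)) / np.prod(x.shape[:3])
        dx = dx + ds.astype(np.float32)
        return dx


class _AvgPool2Stride1:
    """2x2x2 average pooling with stride 1: side n -> n-1, receptive field +1."""

    params = property(lambda self: [])
    grads = property(lambda self: [])

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        d, h, w = (s - 1 for s in x.shape[:3])
        y = np.zeros((d, h, w, x.shape[3]), dtype=np.float32)
        for a in (0, 1):
            for b in (0, 1):
                for c in (0, 1):
                    y += x[a : a + d, b : b + h, c : c + w, :]
        y *= np.float32(0.125)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape, dtype=np.float32)
        g = dy * np.float32(0.125)
        d, h, w = dy.shape[:3]
        for a in (0, 1):
            for b in (0, 1):
                for c in (0, 1):
                    dx[a : a + d, b : b + h, c : c + w, :] += g
        return dx


class _UpsampleRepeat:
    """Nearest repeat restoring the voxel removed by its stride-1 pooling.

    Duplicates existing information only (edge replication), so it adds no
    receptive field.
    """

    params = property(lambda self: [])
    grads = property(lambda self: [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.pad(x, ((0, 1), (0, 1), (0, 1), (0, 0)), mode="edge")

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = dy
        for ax in range(3):
            last = np.take(d, [-1], axis=ax)
            d = np.take(d, range(d.shape[ax] - 1), axis=ax)
            edge = [slice(None)] * 4
            edge[ax] = slice(-1, None)
            d[tuple(edge)] += last
        return np.ascontiguousarray(d)


class _ConcatCropSkip:
    """Concatenate upsampled features with a centre-cropped skip tensor."""

    params = property(lambda self: [])
    grads = property(lambda self: [])

    def __init__(self):
        self._split = None
        self._skip_shape = None
        self._off = None

    def forward(self, up: np.ndarray, skip: np.ndarray) -> np.ndarray:
        off = (skip.shape[0] - up.shape[0]) // 2
        s = up.shape[0]
        cropped = skip[off : off + s, off : off + s, off : off + s, :]
        self._split = up.shape[3]
        self._skip_shape = skip.shape
        self._off = (off, s)
        return np.concatenate([up, cropped], axis=3)

    def backward(self, dy: np.ndarray):
        off, s = self._off
        dup = np.ascontiguousarray(dy[..., : self._split])
        dskip = np.zeros(self._skip_shape, dtype=np.float32)
        dskip[off : off + s, off : off + s, off : off + s, :] = dy[..., self._split :]
        return dup, dskip


class _AuxHead:
    """Block-level age readout: global average pooling then one dense unit.

    ``scale`` is a fixed target-standardisation gain (years per unit of the
    pre-readout activation); with the published half-million-iteration budget
    it can stay 1, while short desk-scale schedules set it near the age SD
    so Adam's bounded per-parameter steps can span the age range.
    """

    def __init__(self, channels: int, rng: np.random.Generator, bias: float, scale: float = 1.0):
        # zero-init readout: predictions start at the bias (e.g. mean age)
        # and only grow along gradient-aligned feature directions
        self.w = np.zeros(channels, dtype=np.float32)
        self.b = np.array([bias], dtype=np.float32)
        self.scale = np.float32(scale)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None

    params = property(lambda self: [self.w, self.b])
    grads = property(lambda self: [self.dw, self.db])

    def forward(self, x: np.ndarray) -> float:
        s = x.mean(axis=(0, 1, 2))
        self._cache = (x.shape, s)
        return float(self.scale * (s @ self.w) + self.b[0])

    def backward(self, dy: float) -> np.ndarray:
        shape, s = self._cache
        self.dw += np.float32(dy) * self.scale * s
        self.db += np.float32(dy)
        v = np.prod(shape[:3])
        return np.broadcast_to(self.w * np.float32(dy * self.scale / v), shape).astype(
            np.float32
        )


class _Conv1:
    """1x1x1 readout convolution to a single output channel (see _AuxHead
    for the fixed ``scale`` gain)."""

    def __init__(self, c_in: int, rng: np.random.Generator, bias: float, scale: float = 1.0):
        self.w = np.zeros((c_in, 1), dtype=np.float32)  # zero-init readout
        self.b = np.array([bias], dtype=np.float32)
        self.scale = np.float32(scale)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    params = property(lambda self: [self.w, self.b])
    grads = property(lambda self: [self.dw, self.db])

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return (self.scale * (x.reshape(-1, x.shape[3]) @ self.w) + self.b).reshape(
            x.shape[:3]
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        df = dy.reshape(-1, 1)
        self.dw += self.scale * (x.reshape(-1, x.shape[3]).T @ df)
        self.db += df.sum(axis=0)
        return (df @ (self.scale * self.w).T).reshape(x.shape).astype(np.float32)


# ---------------------------------------------------------------------------
# networks


class LocalBrainAgeUNet:
    """The regression U-Net; see the module docstring for the geometry."""

    def __init__(
        self,
        spec: ArchitectureSpec,
        seed: int = 0,
        output_bias: float = 0.0,
        output_scale: float = 1.0,
        init: str = "he",
    ):
        self.spec = spec
        self.seed = seed
        self.output_bias = output_bias
        self.output_scale = output_scale
        self.init = init
        rng = np.random.default_rng(seed)
        c = spec.base_channels
        a = spec.leaky_alpha
        r = spec.se_reduction
        enc_levels = spec.scales - 1

        def conv_block(c_in, c_out, passthrough=None):
            return (
                _Conv3(c_in, c_out, rng, init=init, passthrough=passthrough),
                _LeakyReLU(a),
                _SqueezeExcite(c_out, r, rng, init=init),
            )

        self.enc: list[list] = []
        ch = spec.in_channels
        self.level_channels = []
        for lvl in range(enc_levels):
            out = c * 2**lvl
            blocks = [conv_block(ch, out)]
            for _ in range(spec.convs_per_scale - 1):
                blocks.append(conv_block(out, out))
            self.enc.append(blocks)
            self.level_channels.append(out)
            ch = out
        self.pools = [_AvgPool2Stride1() for _ in range(enc_levels)]

        bott = c * 2**enc_levels
        self.bottleneck = [conv_block(ch, bott)]
        for _ in range(spec.convs_per_scale - 1):
            self.bottleneck.append(conv_block(bott, bott))

        self.ups = [_UpsampleRepeat() for _ in range(enc_levels)]
        self.concats = [_ConcatCropSkip() for _ in range(enc_levels)]
        self.dec: list[list] = []
        ch = bott
        for lvl in reversed(range(enc_levels)):
            out = self.level_channels[lvl]
            blocks = [conv_block(ch + out, out, passthrough=(ch, out))]
            for _ in range(spec.convs_per_scale - 1):
                blocks.append(conv_block(out, out))
            self.dec.append(blocks)
            ch = out

        self.aux = [_AuxHead(bott, rng, output_bias, output_scale)]
        for i, blocks in enumerate(self.dec[:-1]):
            self.aux.append(_AuxHead(blocks[-1][0].W.shape[1], rng, output_bias, output_scale))
        self.final = _Conv1(ch, rng, output_bias, output_scale)

    # -- parameter plumbing -------------------------------------------------

    def _layers(self):
        for blocks in self.enc + [self.bottleneck] + self.dec:
            for trio in blocks:
                yield from trio
        yield from self.pools
        yield from self.ups
        yield from self.concats
        yield from self.aux
        yield self.final

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._layers() for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self._layers() for g in layer.grads]

    def zero_gradients(self) -> None:
        for g in self.gradients():
            g[...] = 0.0

    def output_side_for(self, input_side: int) -> int:
        return input_side - (self.spec.input_side - self.spec.output_side)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list[float]]:
        """Run one 2-channel block; returns (voxel ages, auxiliary ages).

        ``x`` is channels-last ``(n, n, n, in_channels)`` with ``n`` at least
        ``spec.input_side``; the voxel output has side ``n - 40`` for the
        default spec.
        """
        if x.ndim != 4 or x.shape[3] != self.spec.in_channels:
            raise ValueError(f"expected (n, n, n, {self.spec.in_channels}) input, got {x.shape}")
        h = np.ascontiguousarray(x, dtype=np.float32)
        skips = []
        for blocks, pool in zip(self.enc, self.pools):
            for conv, act, se in blocks:
                h = se.forward(act.forward(conv.forward(h)))
            skips.append(h)
            h = pool.forward(h)
        for conv, act, se in self.bottleneck:
            h = se.forward(act.forward(conv.forward(h)))
        aux_out = [self.aux[0].forward(h)]
        for i, (up, cat, blocks) in enumerate(zip(self.ups, self.concats, self.dec)):
            h = cat.forward(up.forward(h), skips[len(skips) - 1 - i])
            for conv, act, se in blocks:
                h = se.forward(act.forward(conv.forward(h)))
            if i < len(self.dec) - 1:
                aux_out.append(self.aux[i + 1].forward(h))
        h = self.final.forward(h)
        crop = (h.shape[0] - self.output_side_for(x.shape[0])) // 2
        self._crop = (crop, h.shape)
        if crop:
            h = h[crop:-crop, crop:-crop, crop:-crop]
        return h, aux_out

    def backward(self, dvoxel: np.ndarray, daux: list[float] | None = None) -> np.ndarray:
        """Accumulate parameter gradients; returns the input gradient."""
        crop, pre_shape = self._crop
        if daux is None:
            daux = [0.0] * len(self.aux)
        dh3 = np.zeros(pre_shape[:3], dtype=np.float32)
        if crop:
            dh3[crop:-crop, crop:-crop, crop:-crop] = dvoxel
        else:
            dh3[...] = dvoxel
        dh = self.final.backward(dh3)
        dskips: dict[int, np.ndarray] = {}
        for i in reversed(range(len(self.dec))):
            if i < len(self.dec) - 1 and daux[i + 1]:
                dh = dh + self.aux[i + 1].backward(daux[i + 1])
            for conv, act, se in reversed(self.dec[i]):
                dh = conv.backward(act.backward(se.backward(dh)))
            dup, dskip_i = self.concats[i].backward(dh)
            dh = self.ups[i].backward(dup)
            dskips[len(self.enc) - 1 - i] = dskip_i
        if daux[0]:
            dh = dh + self.aux[0].backward(daux[0])
        for conv, act, se in reversed(self.bottleneck):
            dh = conv.backward(act.backward(se.backward(dh)))
        for lvl in reversed(range(len(self.enc))):
            dh = self.pools[lvl].backward(dh)
            dh = dh + dskips[lvl]
            for conv, act, se in reversed(self.enc[lvl]):
                dh = conv.backward(act.backward(se.backward(dh)))
        return dh

    # -- utilities ----------------------------------------------------------

    def clone(self) -> "LocalBrainAgeUNet":
        return copy.deepcopy(self)

    @property
    def suggested_input_side(self) -> int:
        return self.spec.input_side


class ConvChain:
    """A bare stack of valid 3x3x3 convolutions (receptive-field baseline).

    Truncating the full architecture to its first convolution(s) gives the
    textbook 3 + 2(k-1) field of view; this class exists to measure that.
    """

    def __init__(self, n_convs: int, in_channels: int = 2, channels: int = 4, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = None
        self.layers = []
        c_in = in_channels
        for _ in range(n_convs):
            self.layers.append(_Conv3(c_in, channels, rng))
            self.layers.append(_LeakyReLU(0.2))
            c_in = channels
        self.in_channels = in_channels
        self.suggested_input_side = 2 * n_convs + 9

    def parameters(self):
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray):
        h = np.ascontiguousarray(x, dtype=np.float32)
        for layer in self.layers:
            h = layer.forward(h)
        return h.mean(axis=3), []

    def backward(self, dvoxel: np.ndarray, daux=None):
        c = self.layers[-2].W.shape[1] if len(self.layers) >= 2 else 1
        dh = np.repeat(dvoxel[..., None], c, axis=3) / np.float32(c)
        for layer in reversed(self.layers):
            dh = layer.backward(dh)
        return dh


def build_network(
    spec: ArchitectureSpec | None = None,
    seed: int = 0,
    output_bias: float = 0.0,
    output_scale: float = 1.0,
    init: str = "he",
) -> LocalBrainAgeUNet:
    """Instantiate the U-Net with variance-scaled fan-in initialisation.

    ``output_bias`` initialises the final readout and auxiliary-head biases
    (e.g. the training-cohort mean age), so the network starts from a
    sensible constant prediction instead of zero years.  ``output_scale``
    is the fixed target-standardisation gain of the readout heads (1 keeps
    the published parameterisation; desk-scale schedules set it near the
    training-age standard deviation).
    """
    return LocalBrainAgeUNet(
        spec or ArchitectureSpec(),
        seed=seed,
        output_bias=output_bias,
        output_scale=output_scale,
        init=init,
    )


# ---------------------------------------------------------------------------
# composite loss


def _as_batch(predictions):
    voxel, aux = predictions
    voxel = np.asarray(voxel, dtype=np.float64)
    if voxel.ndim == 3:
        voxel = voxel[None]
        aux = np.asarray(aux, dtype=np.float64)[None]
    else:
        aux = np.asarray(aux, dtype=np.float64)
    return voxel, aux


def composite_loss(predictions, target_age, config: LossConfig, iteration: int) -> float:
    """Mean-absolute-error sum over output voxels plus weighted auxiliary terms.

    ``predictions`` is ``(voxel_maps, aux_ages)`` for a single sample or a
    minibatch (leading batch axis); ``target_age`` is the chronological age
    (scalar or per-sample vector).  The voxel term sums |y - y_voxel| over
    all output voxels of every sample; each auxiliary scalar contributes
    ``alpha_b(iteration) * |y - y_b|``.  After ``config.decay_iterations``
    the loss is independent of the auxiliary predictions.
    """
    voxel, aux = _as_batch(predictions)
    y = np.broadcast_to(np.asarray(target_age, dtype=np.float64), voxel.shape[0])
    alphas = config.alphas(iteration)
    if aux.shape[1] != alphas.size:
        raise ValueError(f"expected {alphas.size} auxiliary predictions, got {aux.shape[1]}")
    loss = np.abs(voxel - y[:, None, None, None]).sum()
    loss += (alphas[None, :] * np.abs(aux - y[:, None])).sum()
    return float(loss)


def loss_gradients(predictions, target_age, config: LossConfig, iteration: int):
    """Subgradients of :func:`composite_loss` w.r.t. the predictions."""
    voxel, aux = _as_batch(predictions)
    y = np.broadcast_to(np.asarray(target_age, dtype=np.float64), voxel.shape[0])
    alphas = config.alphas(iteration)
    dvoxel = np.sign(voxel - y[:, None, None, None]).astype(np.float32)
    daux = (alphas[None, :] * np.sign(aux - y[:, None])).astype(np.float64)
    return dvoxel, daux


# ---------------------------------------------------------------------------
# receptive field


def measure_receptive_field(network, input_side: int | None = None) -> int:
    """Empirical side length of the input region influencing one output voxel.

    A clone of the network gets non-negative, sensitivity-preserving weights
    (absolute values; small positive biases), so no cancellation can hide a
    dependency.  The gradient of the central output voxel w.r.t. the input
    is then exactly supported on the dependency region; the result is the
    largest axis extent of its bounding box.
    """
    probe = copy.deepcopy(network)
    for p in probe.parameters():
        np.abs(p, out=p)
        if p.ndim == 1 or (p.size and float(p.max()) == 0.0):
            p += 0.1  # lift biases and zero-initialised readouts
    layers = probe._layers() if hasattr(probe, "_layers") else probe.layers
    for layer in layers:
        if isinstance(layer, _SqueezeExcite):
            layer.gate_grad = False
        if isinstance(layer, _Conv3):
            layer.skip_param_grads = True  # probes need only the input grad
    side = input_side or probe.suggested_input_side
    c_in = getattr(probe, "in_channels", None)
    if c_in is None:
        c_in = probe.spec.in_channels
    x = np.ones((side, side, side, c_in), dtype=np.float32)
    out, _ = probe.forward(x)
    centre = tuple(s // 2 for s in out.shape[:3])
    dvox = np.zeros(out.shape[:3], dtype=np.float32)
    dvox[centre] = 1.0
    dx = probe.backward(dvox)
    support = np.abs(dx).sum(axis=3) > 0
    extents = []
    for ax in range(3):
        idx = np.nonzero(support.any(axis=tuple(a for a in range(3) if a != ax)))[0]
        extents.append(int(idx.max() - idx.min() + 1))
    return max(extents)


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(network: LocalBrainAgeUNet, path) -> None:
    """Single-file checkpoint: all weights plus the embedded spec."""
    meta = {
        "spec": asdict(network.spec),
        "seed": network.seed,
        "output_bias": network.output_bias,
        "output_scale": getattr(network, "output_scale", 1.0),
        "init": getattr(network, "init", "he"),
    }
    arrays = {f"p{i:04d}": p for i, p in enumerate(network.parameters())}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> LocalBrainAgeUNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        net = LocalBrainAgeUNet(
            ArchitectureSpec(**meta["spec"]),
            seed=meta["seed"],
            output_bias=meta["output_bias"],
            output_scale=meta.get("output_scale", 1.0),
            init=meta.get("init", "he"),
        )
        for i, p in enumerate(net.parameters()):
            p[...] = data[f"p{i:04d}"]
    return net
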