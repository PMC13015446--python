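"""Minimal 3D convolutional network core (forward/backward/Adam) in numpy.

Everything here operates on channel-first single blocks (c, X, Y, Z) in
float32, since training always uses batch size 1.  Convolutions are 3x3x3,
stride 1, same-padding, computed as 27 shift-and-matmul accumulations so the
inner loop is BLAS.
"""

from __future__ import annotations

import numpy as np

_OFFSETS = [(a, b, c) for a in range(3) for b in range(3) for c in range(3)]


def _shifts(xpad: np.ndarray, shape: tuple[int, int, int]):
    X, Y, Z = shape
    cin = xpad.shape[0]
    for a, b, c in _OFFSETS:
        yield np.ascontiguousarray(
            xpad[:, a : a + X, b : b + Y, c : c + Z]
        ).reshape(cin, X * Y * Z)


class Conv3D:
    """3x3x3 same-padded convolution with optional ReLU."""

    def __init__(self, cin: int, cout: int, relu: bool, rng: np.random.Generator):
        self.cin, self.cout, self.relu = cin, cout, relu
        fan_in = cin * 27
        scale = np.sqrt(2.0 / fan_in)  # He init for the rectifier nonlinearity
        self.W = (rng.standard_normal((cout, cin, 3, 3, 3)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        X, Y, Z = x.shape[1:]
        xpad = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        n = X * Y * Z
        wf = self.W.reshape(self.cout, self.cin, 27)
        y = np.zeros((self.cout, n), dtype=np.float32)
        for k, sh in enumerate(_shifts(xpad, (X, Y, Z))):
            y += wf[:, :, k] @ sh
        y += self.b[:, None]
        y = y.reshape(self.cout, X, Y, Z)
        if self.relu:
            pre = y if training else None
            y = np.maximum(y, 0.0)
        else:
            pre = None
        if training:
            self._cache = (xpad, (X, Y, Z), pre)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xpad, (X, Y, Z), pre = self._cache
        self._cache = None
        if self.relu:
            dy = np.where(pre > 0, dy, 0.0).astype(np.float32)
        n = X * Y * Z
        dyf = np.ascontiguousarray(dy).reshape(self.cout, n)
        self.db += dyf.sum(axis=1)
        dwf = self.dW.reshape(self.cout, self.cin, 27)
        dxpad = np.zeros_like(xpad)
        wf = self.W.reshape(self.cout, self.cin, 27)
        for k, (a, b, c) in enumerate(_OFFSETS):
            sh = np.ascontiguousarray(
                xpad[:, a : a + X, b : b + Y, c : c + Z]
            ).reshape(self.cin, n)
            dwf[:, :, k] += dyf @ sh.T
            dxpad[:, a : a + X, b : b + Y, c : c + Z] += (
                wf[:, :, k].T @ dyf
            ).reshape(self.cin, X, Y, Z)
        return dxpad[:, 1:-1, 1:-1, 1:-1]


class BatchNorm3D:
    """Per-channel normalization over the spatial axes of a single block."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def parameters(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        c = x.shape[0]
        flat = x.reshape(c, -1)
        if training:
            mean = flat.mean(axis=1)
            var = flat.var(axis=1)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (flat - mean[:, None]) * ivar[:, None]
        y = self.gamma[:, None] * xhat + self.beta[:, None]
        if training:
            self._cache = (xhat, ivar, x.shape)
        return y.reshape(x.shape).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar, shape = self._cache
        self._cache = None
        c = shape[0]
        dyf = dy.reshape(c, -1)
        n = dyf.shape[1]
        self.dgamma += (dyf * xhat).sum(axis=1)
        self.dbeta += dyf.sum(axis=1)
        dxhat = dyf * self.gamma[:, None]
        dx = (
            dxhat
            - dxhat.mean(axis=1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=1, keepdims=True)
        ) * ivar[:, None]
        return dx.reshape(shape).astype(np.float32)


class MUNet:
    """Modified U-Net: a cascade of full-resolution 3x3x3 convolutions with
    matched-depth concatenation skips and no pooling/up-sampling.

    Layer j (0-based) of ``depth`` convolutions maps to ``channels`` features
    with ReLU, except the final layer which is a linear convolution to
    ``output_channels`` (the residual head).  Decoder-half layers
    j in [depth//2, depth-1) receive the concatenation of the previous output
    with the output of mirrored encoder layer ``depth-2-j``.  With
    ``use_batchnorm``, normalization precedes every convolution.
    """

    def __init__(self, depth: int, channels: int, input_channels: int,
                 output_channels: int, use_batchnorm: bool, seed: int = 0,
                 zero_init_head: bool = True):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        if channels < 1 or input_channels < 1 or output_channels < 1:
            raise ValueError("channel counts must be >= 1")
        self.depth, self.channels = depth, channels
        self.input_channels, self.output_channels = input_channels, output_channels
        self.use_batchnorm = use_batchnorm
        self.seed = seed
        rng = np.random.default_rng(seed)
        half = depth // 2
        self.skip_source = {
            j: depth - 2 - j
            for j in range(half, depth - 1)
            if 0 <= depth - 2 - j < half and depth - 2 - j != j
        }
        self.layers = []  # list of (bn_or_None, conv)
        for j in range(depth):
            cin = input_channels if j == 0 else channels
            if j in self.skip_source:
                cin += channels
            cout = output_channels if j == depth - 1 else channels
            bn = BatchNorm3D(cin) if use_batchnorm else None
            conv = Conv3D(cin, cout, relu=(j != depth - 1), rng=rng)
            if j == depth - 1 and zero_init_head:
                # zero residual head: the untrained denoiser is the identity,
                # avoiding a long shrink-to-zero phase at the start of training
                conv.W[...] = 0.0
                conv.b[...] = 0.0
            self.layers.append((bn, conv))
        self._fwd_cache = None

    # -- parameter plumbing -------------------------------------------------
    def parameters(self):
        out = []
        for bn, conv in self.layers:
            if bn is not None:
                out.extend(bn.parameters())
            out.extend(conv.parameters())
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.parameters())

    def zero_grad(self) -> None:
        for _, g in self.parameters():
            g[...] = 0.0

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """x: (c, X, Y, Z) float32 -> residual (output_channels, X, Y, Z)."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        needed = set(self.skip_source.values())
        outputs: dict[int, np.ndarray] = {}
        concat_split: dict[int, int] = {}
        h = x
        for j, (bn, conv) in enumerate(self.layers):
            if j in self.skip_source:
                skip = outputs[self.skip_source[j]]
                concat_split[j] = h.shape[0]
                h = np.concatenate([h, skip], axis=0)
            if bn is not None:
                h = bn.forward(h, training)
            h = conv.forward(h, training)
            if j in needed:
                outputs[j] = h
        if training:
            self._fwd_cache = concat_split
        return h

    def backward(self, dy: np.ndarray) -> None:
        concat_split = self._fwd_cache
        self._fwd_cache = None
        pending: dict[int, np.ndarray] = {}  # grads waiting at encoder outputs
        d = np.ascontiguousarray(dy, dtype=np.float32)
        for j in range(self.depth - 1, -1, -1):
            bn, conv = self.layers[j]
            if j in pending:
                d = d + pending.pop(j)
            d = conv.backward(d)
            if bn is not None:
                d = bn.backward(d)
            if j in concat_split:
                split = concat_split[j]
                src = self.skip_source[j]
                grad_skip = d[split:]
                pending[src] = pending.get(src, 0) + grad_skip
                d = d[:split]

    # -- (de)serialization ---------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for j, (bn, conv) in enumerate(self.layers):
            state[f"conv{j}_W"] = conv.W
            state[f"conv{j}_b"] = conv.b
            if bn is not None:
                state[f"bn{j}_gamma"] = bn.gamma
                state[f"bn{j}_beta"] = bn.beta
                state[f"bn{j}_rmean"] = bn.running_mean
                state[f"bn{j}_rvar"] = bn.running_var
        return state

    def load_state_arrays(self, state) -> None:
        for j, (bn, conv) in enumerate(self.layers):
            conv.W[...] = state[f"conv{j}_W"]
            conv.b[...] = state[f"conv{j}_b"]
            if bn is not None:
                bn.gamma[...] = state[f"bn{j}_gamma"]
                bn.beta[...] = state[f"bn{j}_beta"]
                bn.running_mean[...] = state[f"bn{j}_rmean"]
                bn.running_var[...] = state[f"bn{j}_rvar"]


class Adam:
    """Adam with the customary default moments (0.9, 0.999, eps 1e-8)."""

    def __init__(self, params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params  # list of (param, grad) arrays, updated in place
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
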