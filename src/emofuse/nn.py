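"""Multi-input deep 1-D convolutional network (MI-DCNN) in pure NumPy.

Each physiological channel (ECG, EDA, RSP) feeds its own convolutional branch:
three blocks of [conv -> ReLU -> batch-norm] x 2 -> max-pool, followed by a
global-average-pooling (GAP) layer.  Branch filters are NOT shared, so every
modality gets its own kernels and strides.  The per-branch GAP vectors are
concatenated (width 224 with the default parameterization: 128 + 32 + 64) and
classified by two fully connected layers (hidden ReLU + softmax over two
classes).  Training uses Adam and cross-entropy.

The single-input comparison variant runs one branch-shaped trunk over either a
single modality or all modalities resampled to a common grid and stacked as
channels of one input (so its first-layer kernels span all channels — the
shared-filter design the multi-input network avoids).

Tensors are ``(batch, length, channels)``.  "Same" padding follows the
``ceil(L / stride)`` output-length convention with the extra pad sample on the
right; max-pooling uses non-overlapping windows with floor semantics (tail
samples dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError, ShapeError

__all__ = [
    "ConvBlockSpec", "BranchConfig", "ArchitectureSpec", "default_architecture",
    "conv1d_forward", "relu", "max_pool", "global_average_pool",
    "BatchNormState", "batch_norm",
    "build_midcnn", "build_single_input_dcnn", "MIDCNN",
    "train", "trials_to_inputs", "stacked_input",
]


# ---------------------------------------------------------------------------
# Architecture specification
# ---------------------------------------------------------------------------

@dataclass
class ConvBlockSpec:
    """One convolutional block: two same-padded conv layers (ReLU + batch norm
    after each) followed by a max-pool."""

    filters: int
    kernel_size: int
    strides: tuple = (1, 1)  # per conv layer within the block
    n_conv_layers: int = 2
    pool_size: int = 2
    padding: str = "same"
    activation: str = "relu"

    def __post_init__(self) -> None:
        if min(self.filters, self.kernel_size, self.pool_size) < 1 or min(self.strides) < 1:
            raise InvalidParameterError("filters, kernel, strides and pool must all be >= 1")
        if len(self.strides) != self.n_conv_layers:
            raise InvalidParameterError("one stride per conv layer is required")


@dataclass
class BranchConfig:
    """One input branch: which channel it consumes, at what fixed length, and
    its three conv blocks.  ``window_s`` limits the branch to the first so many
    seconds of the trial (None = whole trial); fast channels like ECG need a
    short window so the resampled input keeps the QRS complexes."""

    input_name: str
    input_length: int
    blocks: list
    in_channels: int = 1
    window_s: float | None = None

    @property
    def gap_width(self) -> int:
        return self.blocks[-1].filters


@dataclass
class ArchitectureSpec:
    branches: list
    fc_hidden: int = 64
    n_classes: int = 2
    optimizer: str = "adam"
    loss: str = "cross-entropy"

    @property
    def concat_width(self) -> int:
        return sum(b.gap_width for b in self.branches)


def default_architecture(ecg_len: int = 2560, eda_len: int = 640,
                         rsp_len: int = 640) -> ArchitectureSpec:
    """The default three-branch parameterization.

    Branch 1 (ECG): blocks of 128 filters x kernel 32/32/16, GAP width 128;
    branch 2 (EDA): 64x16, 64x16, 32x4, GAP 32; branch 3 (RSP): 128x16,
    64x16, 64x8, GAP 64; concatenated width 224.  The slash-separated stride
    table reads per branch: branch 1 strides (2,2)/(2,1)/(1,1), branch 2
    (2,2)/(3,3)/(1,1), branch 3 (3,3)/(2,2)/(1,1).
    """
    b1 = BranchConfig("ecg", ecg_len, [
        ConvBlockSpec(128, 32, (2, 2)),
        ConvBlockSpec(128, 32, (2, 1)),
        ConvBlockSpec(128, 16, (1, 1)),
    ])
    b2 = BranchConfig("eda", eda_len, [
        ConvBlockSpec(64, 16, (2, 2)),
        ConvBlockSpec(64, 16, (3, 3)),
        ConvBlockSpec(32, 4, (1, 1)),
    ])
    b3 = BranchConfig("rsp", rsp_len, [
        ConvBlockSpec(128, 16, (3, 3)),
        ConvBlockSpec(64, 16, (2, 2)),
        ConvBlockSpec(64, 8, (1, 1)),
    ])
    return ArchitectureSpec([b1, b2, b3])


def small_architecture(ecg_len: int = 1024, eda_len: int = 128,
                       rsp_len: int = 128) -> ArchitectureSpec:
    """A reduced three-branch variant for desk-scale experiments (same shape
    algebra, far fewer filters)."""
    b1 = BranchConfig("ecg", ecg_len, [
        ConvBlockSpec(16, 16, (2, 2)),
        ConvBlockSpec(16, 16, (2, 1)),
        ConvBlockSpec(16, 8, (1, 1)),
    ], window_s=16.0)
    b2 = BranchConfig("eda", eda_len, [
        ConvBlockSpec(8, 8, (2, 2)),
        ConvBlockSpec(8, 8, (1, 1)),
        ConvBlockSpec(8, 4, (1, 1)),
    ])
    b3 = BranchConfig("rsp", rsp_len, [
        ConvBlockSpec(8, 8, (2, 2)),
        ConvBlockSpec(8, 8, (1, 1)),
        ConvBlockSpec(8, 4, (1, 1)),
    ])
    return ArchitectureSpec([b1, b2, b3], fc_hidden=32)


# ---------------------------------------------------------------------------
# Functional layer primitives
# ---------------------------------------------------------------------------

def _same_pad(L: int, k: int, stride: int) -> tuple[int, int, int]:
    out_len = -(-L // stride)  # ceil
    pad_total = max((out_len - 1) * stride + k - L, 0)
    left = pad_total // 2
    return out_len, left, pad_total - left


def _im2col(xp: np.ndarray, k: int, stride: int, out_len: int) -> np.ndarray:
    """(N, Lp, C) -> (N, out_len, k*C) patch matrix (a view, then reshaped)."""
    n, _lp, c = xp.shape
    s0, s1, s2 = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, shape=(n, out_len, k, c), strides=(s0, s1 * stride, s1, s2))
    return view.reshape(n, out_len, k * c)


def conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray,
                   stride: int = 1, padding: str = "same") -> np.ndarray:
    """Cross-correlation of a batch of 1-D multi-channel signals with a filter
    bank: ``out[n, j, f] = sum_{i in M_j} w[f, :, i] . x[n, ...] + b[f]``.

    ``x``: (N, L, C) (or (L,), (L, C) for a single signal); ``w``: (F, C, K);
    ``b``: (F,).  Same padding gives output length ``ceil(L / stride)``.
    """
    x = np.asarray(x, dtype=float)
    squeeze = False
    flat = False
    if x.ndim == 1:
        x = x[None, :, None]
        squeeze = flat = True
    elif x.ndim == 2:
        x = x[None]
        squeeze = True
    w = np.asarray(w, dtype=float)
    if w.ndim == 1:
        w = w[None, None, :]
    b = np.atleast_1d(np.asarray(b, dtype=float))
    n_f, c_w, k = w.shape
    n, L, c = x.shape
    if c != c_w:
        raise ShapeError(f"input has {c} channels but kernels expect {c_w}")
    if padding != "same":
        raise InvalidParameterError("only 'same' padding is supported")
    out_len, left, right = _same_pad(L, k, stride)
    if out_len < 1:
        raise ShapeError("input shorter than one stride step")
    xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
    patches = _im2col(xp, k, stride, out_len)
    w_mat = w.transpose(2, 1, 0).reshape(k * c, n_f)  # (k*C, F), matching patch order
    out = patches @ w_mat + b
    if flat and n_f == 1:
        return out[0, :, 0]
    return out[0] if squeeze else out


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(x, 0)."""
    return np.maximum(np.asarray(x), 0)


def max_pool(x: np.ndarray, pool_size: int = 2) -> np.ndarray:
    """Non-overlapping max-pooling along the temporal axis; floor semantics
    (a tail shorter than ``pool_size`` is dropped)."""
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim < 3
    flat = x.ndim == 1
    if x.ndim == 1:
        x = x[None, :, None]
    elif x.ndim == 2:
        x = x[None]
    n, L, c = x.shape
    if L < pool_size:
        raise ShapeError(f"length {L} shorter than pool size {pool_size}")
    L_out = L // pool_size
    out = x[:, :L_out * pool_size].reshape(n, L_out, pool_size, c).max(axis=2)
    if flat:
        return out[0, :, 0]
    return out[0] if squeeze else out


def global_average_pool(x: np.ndarray) -> np.ndarray:
    """Per-filter temporal mean: (N, L, C) -> (N, C) (or (L, C) -> (C,))."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        return x.mean(axis=0)
    return x.mean(axis=1)


@dataclass
class BatchNormState:
    """Trainable scale/shift plus running statistics for one feature axis."""

    gamma: np.ndarray
    beta: np.ndarray
    running_mean: np.ndarray
    running_var: np.ndarray
    eps: float = 1e-5
    momentum: float = 0.9

    @classmethod
    def create(cls, n_features: int, eps: float = 1e-5) -> "BatchNormState":
        return cls(np.ones(n_features), np.zeros(n_features),
                   np.zeros(n_features), np.ones(n_features), eps=eps)


def batch_norm(x_batch: np.ndarray, state: BatchNormState, training: bool = True) -> np.ndarray:
    """Normalize each feature to zero mean / unit variance over the batch,
    then scale and shift: ``y = gamma * (x - mu) / sqrt(var + eps) + beta``.

    For (N, F) inputs the statistics are over the batch axis; for (N, L, F)
    feature maps over batch and time.  Training mode updates the running
    statistics; inference mode uses them.  A training batch of one is an error.
    """
    x = np.asarray(x_batch, dtype=float)
    axes = tuple(range(x.ndim - 1))
    if training:
        if x.shape[0] < 2:
            raise InvalidParameterError("batch normalization needs batch size >= 2 in training")
        mu = x.mean(axis=axes)
        var = x.var(axis=axes)
        state.running_mean = state.momentum * state.running_mean + (1 - state.momentum) * mu
        state.running_var = state.momentum * state.running_var + (1 - state.momentum) * var
    else:
        mu, var = state.running_mean, state.running_var
    xhat = (x - mu) / np.sqrt(var + state.eps)
    return state.gamma * xhat + state.beta


# ---------------------------------------------------------------------------
# Trainable layers (forward + backward)
# ---------------------------------------------------------------------------

class _Layer:
    def params(self):
        return []

    def forward(self, x, training):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class _Conv1D(_Layer):
    def __init__(self, in_ch: int, filters: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (kernel * in_ch))  # He initialisation
        self.w = rng.normal(0.0, scale, (filters, in_ch, kernel))
        self.b = np.zeros(filters)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.stride = stride

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x, training):
        n_f, c, k = self.w.shape
        n, L, _ = x.shape
        out_len, left, right = _same_pad(L, k, self.stride)
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
        self._cache = (xp.shape, left, L, _im2col(xp, k, self.stride, out_len))
        w_mat = self.w.transpose(2, 1, 0).reshape(k * c, n_f)
        return self._cache[3] @ w_mat + self.b

    def backward(self, grad):
        n_f, c, k = self.w.shape
        xp_shape, left, L, patches = self._cache
        n, out_len, _ = grad.shape
        g2 = grad.reshape(-1, n_f)
        p2 = patches.reshape(-1, k * c)
        dw_mat = p2.T @ g2                      # (k*C, F)
        self.dw[:] = dw_mat.reshape(k, c, n_f).transpose(2, 1, 0)
        self.db[:] = g2.sum(axis=0)
        w_mat = self.w.transpose(2, 1, 0).reshape(k * c, n_f)
        dpatch = (g2 @ w_mat.T).reshape(n, out_len, k, c)
        dxp = np.zeros(xp_shape)
        base = np.arange(out_len) * self.stride
        for j in range(k):  # scatter-add each kernel offset (indices unique per j)
            dxp[:, base + j, :] += dpatch[:, :, j, :]
        return dxp[:, left:left + L, :]


class _ReLU(_Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class _BatchNorm(_Layer):
    def __init__(self, n_features: int, eps: float = 1e-5, momentum: float = 0.9):
        self.state = BatchNormState.create(n_features, eps=eps)
        self.state.momentum = momentum
        self.dgamma = np.zeros(n_features)
        self.dbeta = np.zeros(n_features)

    def params(self):
        return [(self.state.gamma, self.dgamma), (self.state.beta, self.dbeta)]

    def forward(self, x, training):
        st = self.state
        axes = tuple(range(x.ndim - 1))
        if training:
            if x.shape[0] < 2:
                raise InvalidParameterError("batch size must be >= 2 for batch norm training")
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            st.running_mean = st.momentum * st.running_mean + (1 - st.momentum) * mu
            st.running_var = st.momentum * st.running_var + (1 - st.momentum) * var
        else:
            mu, var = st.running_mean, st.running_var
        inv = 1.0 / np.sqrt(var + st.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, axes)
        return st.gamma * xhat + st.beta

    def backward(self, grad):
        xhat, inv, axes = self._cache
        m = np.prod([grad.shape[a] for a in axes])
        self.dgamma[:] = np.sum(grad * xhat, axis=axes)
        self.dbeta[:] = np.sum(grad, axis=axes)
        g = grad * self.state.gamma
        return inv * (g - g.mean(axis=axes, keepdims=True)
                      - xhat * np.mean(g * xhat, axis=axes, keepdims=True))


class _MaxPool(_Layer):
    def __init__(self, pool_size: int = 2):
        self.p = pool_size

    def forward(self, x, training):
        n, L, c = x.shape
        L_out = L // self.p
        if L_out < 1:
            raise ShapeError(f"feature map length {L} shorter than pool size {self.p}")
        xr = x[:, :L_out * self.p].reshape(n, L_out, self.p, c)
        self._arg = xr.argmax(axis=2)
        self._shape = x.shape
        return xr.max(axis=2)

    def backward(self, grad):
        n, L_out, c = grad.shape
        dx = np.zeros(self._shape)
        dxr = np.zeros((n, L_out, self.p, c))
        ni, li, ci = np.ogrid[:n, :L_out, :c]
        dxr[ni, li, self._arg, ci] = grad
        dx[:, :L_out * self.p] = dxr.reshape(n, L_out * self.p, c)
        return dx


class _GAP(_Layer):
    def forward(self, x, training):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad):
        return np.repeat(grad[:, None, :], self._L, axis=1) / self._L


class _Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x, training):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw[:] = self._x.T @ grad
        self.db[:] = grad.sum(axis=0)
        return grad @ self.w.T


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------

def _branch_layers(cfg: BranchConfig, rng: np.random.Generator) -> list:
    layers = []
    in_ch = cfg.in_channels
    for block in cfg.blocks:
        for li in range(block.n_conv_layers):
            layers.append(_Conv1D(in_ch, block.filters, block.kernel_size,
                                  block.strides[li], rng))
            layers.append(_ReLU())
            layers.append(_BatchNorm(block.filters))
            in_ch = block.filters
        layers.append(_MaxPool(block.pool_size))
    layers.append(_GAP())
    return layers


def _branch_output_length(cfg: BranchConfig) -> int:
    L = cfg.input_length
    for block in cfg.blocks:
        for s in block.strides:
            L = -(-L // s)
        L = L // block.pool_size
    return L


def _min_input_length(cfg: BranchConfig) -> int:
    for L in range(1, cfg.input_length + 1):
        probe = BranchConfig(cfg.input_name, L, cfg.blocks, cfg.in_channels)
        if _branch_output_length(probe) >= 1:
            return L
    return cfg.input_length


class MIDCNN:
    """Multi-branch 1-D CNN with concatenated GAP features and a two-layer
    fully connected head.  Built from an :class:`ArchitectureSpec`."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        if not spec.branches:
            raise InvalidParameterError("at least one branch is required")
        for b in spec.branches:
            if _branch_output_length(b) < 1:
                raise InvalidParameterError(
                    f"branch {b.input_name!r}: input length {b.input_length} is below "
                    f"the minimum {_min_input_length(b)} for its stride/pool schedule"
                )
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.branches = [_branch_layers(b, rng) for b in spec.branches]
        self.head = [
            _Dense(spec.concat_width, spec.fc_hidden, rng),
            _ReLU(),
            _Dense(spec.fc_hidden, spec.n_classes, rng),
        ]
        self._gap_widths = [b.gap_width for b in spec.branches]

    # -- plumbing ----------------------------------------------------------
    def parameters(self):
        out = []
        for layers in self.branches:
            for lay in layers:
                out.extend(lay.params())
        for lay in self.head:
            out.extend(lay.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _g in self.parameters()))

    def forward(self, inputs: list, training: bool = False) -> np.ndarray:
        if len(inputs) != len(self.branches):
            raise ShapeError(f"model expects {len(self.branches)} inputs, got {len(inputs)}")
        feats = []
        for x, layers in zip(inputs, self.branches):
            h = np.asarray(x, dtype=float)
            if h.ndim == 2:
                h = h[:, :, None]
            for lay in layers:
                h = lay.forward(h, training)
            feats.append(h)
        z = np.concatenate(feats, axis=1)
        for lay in self.head:
            z = lay.forward(z, training)
        return z

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for lay in reversed(self.head):
            g = lay.backward(g)
        start = 0
        for layers, width in zip(self.branches, self._gap_widths):
            gb = g[:, start:start + width]
            start += width
            for lay in reversed(layers):
                gb = lay.backward(gb)

    def predict_proba(self, inputs: list) -> np.ndarray:
        return _softmax(self.forward(inputs, training=False))

    def predict(self, inputs: list) -> np.ndarray:
        return self.predict_proba(inputs).argmax(axis=1)


def build_midcnn(spec: ArchitectureSpec | None = None, seed: int = 0) -> MIDCNN:
    """Build the multi-input network (default parameterization if no spec)."""
    return MIDCNN(spec or default_architecture(), seed=seed)


def build_single_input_dcnn(spec: ArchitectureSpec | None = None,
                            modalities=("ecg",), seed: int = 0) -> MIDCNN:
    """Single-input comparison network: one branch-1-shaped trunk whose input
    has one channel per requested modality (channels stacked, filters shared
    across them)."""
    spec = spec or default_architecture()
    base = spec.branches[0]
    trunk = BranchConfig("+".join(modalities), base.input_length, base.blocks,
                         in_channels=len(modalities))
    single = ArchitectureSpec([trunk], fc_hidden=spec.fc_hidden,
                              n_classes=spec.n_classes)
    return MIDCNN(single, seed=seed)


# ---------------------------------------------------------------------------
# Input preparation
# ---------------------------------------------------------------------------

def _resample(sig: np.ndarray, n_out: int) -> np.ndarray:
    t_in = np.linspace(0.0, 1.0, len(sig))
    t_out = np.linspace(0.0, 1.0, n_out)
    return np.interp(t_out, t_in, sig)


def _branch_signal(trial, channel: str, window_s: float | None) -> np.ndarray:
    sig = np.asarray(getattr(trial, channel), dtype=float)
    if window_s is not None:
        fs = getattr(trial, f"fs_{channel}")
        sig = sig[: max(int(window_s * fs), 2)]
    return sig


def trials_to_inputs(trials, spec: ArchitectureSpec) -> list:
    """Per-branch input tensors: each trial's channel (optionally limited to
    the branch's time window) linearly resampled to the branch input length.
    No per-trial standardization is applied, so absolute signal levels (e.g.
    tonic skin conductance) remain visible to the network.
    """
    inputs = []
    for b in spec.branches:
        arrs = [_resample(_branch_signal(tr, b.input_name, b.window_s), b.input_length)
                for tr in trials]
        inputs.append(np.stack(arrs)[:, :, None])
    return inputs


def stacked_input(trials, spec: ArchitectureSpec, modalities=("ecg", "eda", "rsp")) -> np.ndarray:
    """All modalities resampled to the first branch's single grid (length and
    time window) and stacked as channels of one input — the single-input
    scheme.  Raw scales are preserved, so modalities with very different
    amplitudes and rates share one set of filters and one grid; that forced
    compromise is exactly what the multi-input design avoids.
    """
    base = spec.branches[0]
    arrs = []
    for tr in trials:
        chans = [_resample(_branch_signal(tr, m, base.window_s), base.input_length)
                 for m in modalities]
        arrs.append(np.stack(chans, axis=1))
    return np.stack(arrs)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _g in params]
        self.v = [np.zeros_like(p) for p, _g in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(model: MIDCNN, inputs: list, y, epochs: int = 20, batch_size: int = 32,
          lr: float = 1e-3, seed: int = 0, val_inputs=None, val_y=None,
          patience: int | None = None, verbose: bool = False) -> dict:
    """Mini-batch Adam training with cross-entropy loss.

    Returns a history dict with per-epoch training loss/accuracy (and
    validation accuracy when validation data is given).  Optional early
    stopping monitors validation accuracy with the given patience.  A
    non-finite loss aborts with diagnostics.
    """
    y = np.asarray(y, dtype=int)
    n = len(y)
    if any(len(x) != n for x in inputs):
        raise ShapeError("all inputs must have one row per label")
    opt = _Adam(model.parameters(), lr=lr)
    rng = np.random.default_rng(seed)
    history = {"loss": [], "accuracy": [], "val_accuracy": []}
    best_val, best_epoch = -np.inf, 0
    onehot = np.eye(model.spec.n_classes)[y]

    for epoch in range(epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            if len(idx) < 2:
                continue  # batch norm needs >= 2 samples
            xb = [x[idx] for x in inputs]
            logits = model.forward(xb, training=True)
            probs = _softmax(logits)
            eps = 1e-12
            loss = -np.mean(np.sum(onehot[idx] * np.log(probs + eps), axis=1))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: logits range "
                    f"[{logits.min():.3g}, {logits.max():.3g}]"
                )
            losses.append(loss)
            correct += int(np.sum(probs.argmax(axis=1) == y[idx]))
            model.backward((probs - onehot[idx]) / len(idx))
            opt.step()
        history["loss"].append(float(np.mean(losses)) if losses else np.nan)
        history["accuracy"].append(correct / n)
        if val_inputs is not None:
            val_acc = float(np.mean(model.predict(val_inputs) == np.asarray(val_y)))
            history["val_accuracy"].append(val_acc)
            if patience is not None:
                if val_acc > best_val + 1e-12:
                    best_val, best_epoch = val_acc, epoch
                elif epoch - best_epoch >= patience:
                    break
        if verbose:
            print(f"epoch {epoch:3d}  loss {history['loss'][-1]:.4f}  "
                  f"acc {history['accuracy'][-1]:.3f}")
    return history
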