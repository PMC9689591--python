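"""The two feature-extraction branches of the fusion network.

MDIFEN treats the 300-d directed-information vector as a length-300 sequence
of scalars: each position is lifted to a small channel vector, passed through
a SAME-padded 1-D convolution, mean-pooled with stride 2, read by a
bidirectional LSTM, and pooled by soft attention against a learned context
vector.

MFFEN reads the 2048-bit Morgan fingerprint reshaped to a 32x64 binary image
through two [3x3 SAME conv -> 2x2 average pool] blocks (16 then 32 channels),
flattens row-major, and projects linearly to the branch dimension.

Dropout (rate 0.5) is applied to each branch output during training only;
evaluation is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat

DEFAULT_EMBED_DIM = 8
DEFAULT_CONV1D_CHANNELS = 16
DEFAULT_CONV1D_KERNEL = 5
DEFAULT_LSTM_HIDDEN = 64
DEFAULT_ATTENTION_DIM = 64
DEFAULT_MFFEN_CHANNELS = (16, 32)
DEFAULT_BRANCH_DIM = 128  # = 2 x lstm hidden; MFFEN projects to the same width
DEFAULT_DROPOUT = 0.5


class DimensionMismatch(ValueError):
    pass


class EmptySequence(ValueError):
    pass


class ShapeMismatch(ValueError):
    pass


@dataclass
class ExtractorConfig:
    """Hyperparameters of both branches (all overridable)."""

    embed_dim: int = DEFAULT_EMBED_DIM
    conv1d_channels: int = DEFAULT_CONV1D_CHANNELS
    conv1d_kernel: int = DEFAULT_CONV1D_KERNEL
    lstm_hidden: int = DEFAULT_LSTM_HIDDEN
    attention_dim: int = DEFAULT_ATTENTION_DIM
    mffen_channels: tuple[int, int] = DEFAULT_MFFEN_CHANNELS
    branch_dim: int = DEFAULT_BRANCH_DIM
    dropout: float = DEFAULT_DROPOUT
    use_bilstm: bool = True


def _uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


# --------------------------------------------------------------------------
# LSTM
# --------------------------------------------------------------------------

@dataclass
class LSTMParams:
    """Gate weights: ``W_*`` act on the previous hidden state, ``U_*`` on the
    input, ``b_*`` are biases; gates = (input i, candidate m~, output o,
    forget f)."""

    W_i: Tensor; U_i: Tensor; b_i: Tensor
    W_m: Tensor; U_m: Tensor; b_m: Tensor
    W_o: Tensor; U_o: Tensor; b_o: Tensor
    W_f: Tensor; U_f: Tensor; b_f: Tensor
    hidden_dim: int = DEFAULT_LSTM_HIDDEN

    def tensors(self) -> list[Tensor]:
        return [self.W_i, self.U_i, self.b_i, self.W_m, self.U_m, self.b_m,
                self.W_o, self.U_o, self.b_o, self.W_f, self.U_f, self.b_f]


def init_lstm_params(rng: np.random.Generator, input_dim: int, hidden_dim: int) -> LSTMParams:
    def W():
        return _uniform(rng, (hidden_dim, hidden_dim), hidden_dim)

    def U():
        return _uniform(rng, (hidden_dim, input_dim), input_dim)

    def b():
        return Tensor(np.zeros(hidden_dim), requires_grad=True)

    return LSTMParams(W(), U(), b(), W(), U(), b(), W(), U(), b(), W(), U(), b(),
                      hidden_dim=hidden_dim)


def lstm_step(x_t, state, params: LSTMParams):
    """One LSTM cell update.

    Gates are computed from the previous hidden state and the current input;
    the memory cell is ``m_t = f_t*m_{t-1} + i_t*m~_t`` and the hidden state
    ``c_t = o_t * tanh(m_t)``.  Accepts single vectors or (batch, dim) arrays.
    """
    m_prev, c_prev = state
    x_t, m_prev, c_prev = _as_tensor(x_t), _as_tensor(m_prev), _as_tensor(c_prev)
    single = x_t.ndim == 1
    if single:
        x_t = x_t.reshape(1, -1)
        m_prev = m_prev.reshape(1, -1)
        c_prev = c_prev.reshape(1, -1)
    if x_t.shape[1] != params.U_i.shape[1] or c_prev.shape[1] != params.W_i.shape[1]:
        raise DimensionMismatch(
            f"input dim {x_t.shape[1]} / hidden dim {c_prev.shape[1]} incompatible "
            f"with U {params.U_i.shape} / W {params.W_i.shape}"
        )
    i_t = (c_prev @ params.W_i.T + x_t @ params.U_i.T + params.b_i).sigmoid()
    m_tilde = (c_prev @ params.W_m.T + x_t @ params.U_m.T + params.b_m).tanh()
    o_t = (c_prev @ params.W_o.T + x_t @ params.U_o.T + params.b_o).sigmoid()
    f_t = (c_prev @ params.W_f.T + x_t @ params.U_f.T + params.b_f).sigmoid()
    m_t = f_t * m_prev + i_t * m_tilde
    c_t = o_t * m_t.tanh()
    if single:
        m_t = m_t.reshape(-1)
        c_t = c_t.reshape(-1)
    return m_t, c_t


def _combined_gates(params: LSTMParams) -> tuple[Tensor, Tensor, Tensor]:
    """Concatenate the four gates' weights once so each step is two matmuls."""
    Wc = concat([params.W_i, params.W_m, params.W_o, params.W_f], axis=0)
    Uc = concat([params.U_i, params.U_m, params.U_o, params.U_f], axis=0)
    bc = concat([params.b_i, params.b_m, params.b_o, params.b_f], axis=0)
    return Wc, Uc, bc


def _lstm_run(x_proj: Tensor, params: LSTMParams, reverse: bool = False) -> list[Tensor]:
    """Recurrence over precomputed input projections (B, T, 4H).

    The input-to-gate matmul is hoisted out of the time loop; each step is a
    single hidden-state matmul plus gate nonlinearities.  Returns hidden
    states c_t indexed in forward time order.
    """
    H = params.hidden_dim
    B, T, _ = x_proj.shape
    Wc, _, _ = _combined_gates(params)
    m = Tensor(np.zeros((B, H)))
    c = Tensor(np.zeros((B, H)))
    outs: list[Tensor | None] = [None] * T
    times = range(T - 1, -1, -1) if reverse else range(T)
    for t in times:
        z = c @ Wc.T + x_proj[:, t, :]
        i_t = z[:, 0:H].sigmoid()
        m_tilde = z[:, H:2 * H].tanh()
        o_t = z[:, 2 * H:3 * H].sigmoid()
        f_t = z[:, 3 * H:4 * H].sigmoid()
        m = f_t * m + i_t * m_tilde
        c = o_t * m.tanh()
        outs[t] = c
    return outs  # type: ignore[return-value]


def bilstm(sequence, params_fwd: LSTMParams, params_bwd: LSTMParams) -> Tensor:
    """Bidirectional LSTM; output at t is [forward c_t, backward c_t].

    ``sequence`` is (T, input_dim) or (B, T, input_dim); output has last
    dimension ``2 * hidden_dim``.
    """
    seq = _as_tensor(sequence)
    single = seq.ndim == 2
    if single:
        seq = seq.reshape((1,) + seq.shape)
    B, T, Cin = seq.shape
    if T == 0:
        raise EmptySequence("bilstm requires a non-empty sequence")
    flat = seq.reshape(B * T, Cin)
    runs = []
    for params, reverse in ((params_fwd, False), (params_bwd, True)):
        _, Uc, bc = _combined_gates(params)
        proj = (flat @ Uc.T + bc).reshape(B, T, 4 * params.hidden_dim)
        runs.append(_lstm_run(proj, params, reverse=reverse))
    fwd, bwd = runs
    steps = [concat([f, b], axis=1).reshape(B, 1, 2 * params_fwd.hidden_dim)
             for f, b in zip(fwd, bwd)]
    out = concat(steps, axis=1)
    return out.reshape(out.shape[1:]) if single else out


# --------------------------------------------------------------------------
# Attention pooling
# --------------------------------------------------------------------------

@dataclass
class AttentionParams:
    """Projection ``W_w``/``b_w`` and the learned context vector ``eta_w``."""

    W_w: Tensor
    b_w: Tensor
    eta_w: Tensor

    def tensors(self) -> list[Tensor]:
        return [self.W_w, self.b_w, self.eta_w]


def init_attention_params(rng: np.random.Generator, state_dim: int, attention_dim: int) -> AttentionParams:
    return AttentionParams(
        W_w=_uniform(rng, (attention_dim, state_dim), state_dim),
        b_w=Tensor(np.zeros(attention_dim), requires_grad=True),
        eta_w=_uniform(rng, (attention_dim,), attention_dim),
    )


def attention_weights(states, params: AttentionParams) -> Tensor:
    """Softmax weights over time from similarity to the context vector."""
    s = _as_tensor(states)
    single = s.ndim == 2
    if single:
        s = s.reshape((1,) + s.shape)
    B, T, D = s.shape
    if T == 0:
        raise EmptySequence("attention requires a non-empty state sequence")
    eta = (s.reshape(B * T, D) @ params.W_w.T + params.b_w).tanh()  # (B*T, A)
    scores = (eta @ params.eta_w).reshape(B, T)
    alpha = scores.softmax(axis=1)
    return alpha.reshape(T) if single else alpha


def attention_pool(states, params: AttentionParams) -> Tensor:
    """Attention-weighted sum of the states: s = sum_t alpha_t c_t."""
    s = _as_tensor(states)
    single = s.ndim == 2
    if single:
        s = s.reshape((1,) + s.shape)
    B, T, D = s.shape
    alpha = attention_weights(s, params)  # (B, T)
    pooled = (alpha.reshape(B, T, 1) * s).sum(axis=1)  # (B, D)
    return pooled.reshape(D) if single else pooled


# --------------------------------------------------------------------------
# SAME-padded convolutions and pooling
# --------------------------------------------------------------------------

def conv1d_same(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """1-D convolution with SAME padding; x (B, L, Cin), W (K, Cin, Cout).

    Fused im2col implementation: one BLAS matmul for the forward pass and a
    hand-written backward (small K-loop fold for the input gradient).
    """
    B, L, Cin = x.shape
    K, _, Cout = W.shape
    lo = (K - 1) // 2
    xp = np.pad(x.data, ((0, 0), (lo, K - 1 - lo), (0, 0)))
    # (B, L, Cin, K) windows -> (B*L, Cin*K) column matrix
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)
    col = win.reshape(B * L, Cin * K)
    Wm = W.data.transpose(1, 0, 2).reshape(Cin * K, Cout)
    y = (col @ Wm + b.data).reshape(B, L, Cout)
    out = Tensor(y, _parents=(x, W, b))

    def _backward(g):
        g2 = g.reshape(B * L, Cout)
        if b.requires_grad:
            b._accumulate(g2.sum(axis=0))
        if W.requires_grad:
            dWm = col.T @ g2
            W._accumulate(dWm.reshape(Cin, K, Cout).transpose(1, 0, 2))
        if x.requires_grad:
            dcol = (g2 @ Wm.T).reshape(B, L, Cin, K)
            dxp = np.zeros_like(xp)
            for k in range(K):
                dxp[:, k:k + L, :] += dcol[:, :, :, k]
            x._accumulate(dxp[:, lo:lo + L, :])

    out._backward = _backward
    return out


def mean_pool_1d(x: Tensor, stride: int = 2) -> Tensor:
    """Non-overlapping mean pooling along the length axis."""
    B, L, C = x.shape
    if L % stride:
        raise ShapeMismatch(f"length {L} not divisible by pooling stride {stride}")
    return x.reshape(B, L // stride, stride, C).mean(axis=2)


def conv2d_same(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """2-D convolution with SAME padding; x (B, H, W, Cin), W (kh, kw, Cin, Cout).

    Same fused im2col strategy as :func:`conv1d_same`.
    """
    B, H, Wd, Cin = x.shape
    kh, kw, _, Cout = W.shape
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    xp = np.pad(x.data, ((0, 0), (ph, kh - 1 - ph), (pw, kw - 1 - pw), (0, 0)))
    # windows (B, H, W, Cin, kh, kw) -> columns (B*H*W, Cin*kh*kw)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    col = win.reshape(B * H * Wd, Cin * kh * kw)
    Wm = W.data.transpose(2, 0, 1, 3).reshape(Cin * kh * kw, Cout)
    y = (col @ Wm + b.data).reshape(B, H, Wd, Cout)
    out = Tensor(y, _parents=(x, W, b))

    def _backward(g):
        g2 = g.reshape(B * H * Wd, Cout)
        if b.requires_grad:
            b._accumulate(g2.sum(axis=0))
        if W.requires_grad:
            dWm = col.T @ g2
            W._accumulate(dWm.reshape(Cin, kh, kw, Cout).transpose(1, 2, 0, 3))
        if x.requires_grad:
            dcol = (g2 @ Wm.T).reshape(B, H, Wd, Cin, kh, kw)
            dxp = np.zeros_like(xp)
            for di in range(kh):
                for dj in range(kw):
                    dxp[:, di:di + H, dj:dj + Wd, :] += dcol[:, :, :, :, di, dj]
            x._accumulate(dxp[:, ph:ph + H, pw:pw + Wd, :])

    out._backward = _backward
    return out


def avg_pool_2d(x: Tensor, size: int = 2) -> Tensor:
    B, H, W, C = x.shape
    if H % size or W % size:
        raise ShapeMismatch(f"spatial size {(H, W)} not divisible by pool size {size}")
    return x.reshape(B, H // size, size, W // size, size, C).mean(axis=2).mean(axis=3)


# --------------------------------------------------------------------------
# Branch parameter containers and forward passes
# --------------------------------------------------------------------------

@dataclass
class BranchFeature:
    values: np.ndarray
    branch: str


@dataclass
class MDIFENParams:
    embed_w: Tensor  # (embed_dim,) per-position scalar lift, shared weights
    embed_b: Tensor  # (embed_dim,)
    conv_W: Tensor   # (K, embed_dim, channels)
    conv_b: Tensor   # (channels,)
    lstm_fwd: LSTMParams
    lstm_bwd: LSTMParams
    attention: AttentionParams
    proj_W: Tensor   # (branch_dim, channels), used only without the bi-LSTM
    proj_b: Tensor   # (branch_dim,)
    config: ExtractorConfig = field(default_factory=ExtractorConfig)

    def tensors(self) -> list[Tensor]:
        return ([self.embed_w, self.embed_b, self.conv_W, self.conv_b]
                + self.lstm_fwd.tensors() + self.lstm_bwd.tensors()
                + self.attention.tensors() + [self.proj_W, self.proj_b])


@dataclass
class MFFENParams:
    conv1_W: Tensor
    conv1_b: Tensor
    conv2_W: Tensor
    conv2_b: Tensor
    proj_W: Tensor
    proj_b: Tensor
    config: ExtractorConfig = field(default_factory=ExtractorConfig)

    def tensors(self) -> list[Tensor]:
        return [self.conv1_W, self.conv1_b, self.conv2_W, self.conv2_b,
                self.proj_W, self.proj_b]


def init_mdifen_params(rng: np.random.Generator, config: ExtractorConfig | None = None) -> MDIFENParams:
    cfg = config or ExtractorConfig()
    K, E, C = cfg.conv1d_kernel, cfg.embed_dim, cfg.conv1d_channels
    return MDIFENParams(
        embed_w=_uniform(rng, (E,), 1),
        embed_b=Tensor(np.zeros(E), requires_grad=True),
        conv_W=_uniform(rng, (K, E, C), K * E),
        conv_b=Tensor(np.zeros(C), requires_grad=True),
        lstm_fwd=init_lstm_params(rng, C, cfg.lstm_hidden),
        lstm_bwd=init_lstm_params(rng, C, cfg.lstm_hidden),
        attention=init_attention_params(rng, 2 * cfg.lstm_hidden, cfg.attention_dim),
        proj_W=_uniform(rng, (cfg.branch_dim, C), C),
        proj_b=Tensor(np.zeros(cfg.branch_dim), requires_grad=True),
        config=cfg,
    )


def init_mffen_params(rng: np.random.Generator, config: ExtractorConfig | None = None) -> MFFENParams:
    cfg = config or ExtractorConfig()
    c1, c2 = cfg.mffen_channels
    flat = (32 // 4) * (64 // 4) * c2  # two 2x2 pools: 32x64 -> 8x16
    return MFFENParams(
        conv1_W=_uniform(rng, (3, 3, 1, c1), 9),
        conv1_b=Tensor(np.zeros(c1), requires_grad=True),
        conv2_W=_uniform(rng, (3, 3, c1, c2), 9 * c1),
        conv2_b=Tensor(np.zeros(c2), requires_grad=True),
        proj_W=_uniform(rng, (cfg.branch_dim, flat), flat),
        proj_b=Tensor(np.zeros(cfg.branch_dim), requires_grad=True),
        config=cfg,
    )


def mdifen_forward_batch(
    dpi: Tensor,
    params: MDIFENParams,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
) -> Tensor:
    """MDIFEN pipeline on a (B, L) batch of directed-information vectors."""
    cfg = params.config
    B, L = dpi.shape
    x = dpi.reshape(B, L, 1) * params.embed_w + params.embed_b  # (B, L, E)
    x = conv1d_same(x, params.conv_W, params.conv_b).relu()  # (B, L, C)
    x = mean_pool_1d(x, 2)  # (B, L/2, C)
    if cfg.use_bilstm:
        states = bilstm(x, params.lstm_fwd, params.lstm_bwd)  # (B, L/2, 2H)
        out = attention_pool(states, params.attention)  # (B, 2H)
    else:
        out = x.mean(axis=1) @ params.proj_W.T + params.proj_b  # (B, branch_dim)
    train = mode == "train"
    if train and rng is None:
        raise ValueError("train mode requires an rng for dropout")
    return out.dropout(cfg.dropout, rng, train)


def mffen_forward_batch(
    matrix: Tensor,
    params: MFFENParams,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
) -> Tensor:
    """MFFEN pipeline on a (B, 32, 64) batch of fingerprint matrices."""
    cfg = params.config
    if matrix.shape[1:] != (32, 64):
        raise ShapeMismatch(f"expected (B, 32, 64), got {matrix.shape}")
    B = matrix.shape[0]
    x = matrix.reshape(B, 32, 64, 1)
    x = avg_pool_2d(conv2d_same(x, params.conv1_W, params.conv1_b).relu())  # (B,16,32,c1)
    x = avg_pool_2d(conv2d_same(x, params.conv2_W, params.conv2_b).relu())  # (B,8,16,c2)
    flat = x.reshape(B, -1)  # row-major flatten
    out = flat @ params.proj_W.T + params.proj_b
    train = mode == "train"
    if train and rng is None:
        raise ValueError("train mode requires an rng for dropout")
    return out.dropout(cfg.dropout, rng, train)


def mdifen_forward(dpi, params: MDIFENParams, mode: str = "eval",
                   rng: np.random.Generator | None = None) -> BranchFeature:
    """Single-molecule MDIFEN feature (see :func:`mdifen_forward_batch`)."""
    v = np.asarray(dpi.values if hasattr(dpi, "values") else dpi, dtype=np.float64)
    out = mdifen_forward_batch(Tensor(v.reshape(1, -1)), params, mode, rng)
    return BranchFeature(values=out.data[0], branch="mdifen")


def mffen_forward(matrix, params: MFFENParams, mode: str = "eval",
                  rng: np.random.Generator | None = None) -> BranchFeature:
    """Single-molecule MFFEN feature (see :func:`mffen_forward_batch`)."""
    m = np.asarray(matrix, dtype=np.float64)
    if m.shape != (32, 64):
        raise ShapeMismatch(f"expected a 32x64 matrix, got {m.shape}")
    out = mffen_forward_batch(Tensor(m.reshape(1, 32, 64)), params, mode, rng)
    return BranchFeature(values=out.data[0], branch="mffen")
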