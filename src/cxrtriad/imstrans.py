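"""Improved Swin Transformer (IMSTrans) classifier.

Window-based self-attention on a token grid, alternating regular (W-MSA)
and shifted (SW-MSA) windows, with the token MLP replaced by a
DenseNet-style dense block. One block pair computes

    K̂r   = W-MSA(LN(Kr−1)) + Kr−1
    Kr   = D(LN(K̂r)) + K̂r
    K̂r+1 = SW-MSA(LN(K̂r)) + Kr
    Kr+1 = D(LN(K̂r+1)) + K̂r+1

where ``D`` is the dense-block MLP: L fully connected sub-layers, each
fed the concatenation of the block input and all previous sub-layer
outputs and emitting ``g`` (growth-rate) new features, followed by a
transition projection from width ``C + L·g`` back to ``C``. Sub-layers
use layer normalization + ReLU (batch-size-independent and deterministic
in token mode); the optional convolutional stem keeps batch norm.

Shifted windows are realized efficiently by a toroidal roll of
``⌊P/2⌋`` plus an additive attention mask that assigns −∞ to token pairs
originating from different pre-shift regions (and to padded tokens), so
their post-softmax weight is exactly zero. Token grids are zero-padded up
to a multiple of the window size ``P``; padded tokens are masked out of
attention and excluded from the global average pool. The classification
head is a fully connected layer emitting softmax class probabilities
(multi-class) or per-class sigmoids (multi-label).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .nn import (
    Adam,
    BatchNorm,
    LayerNorm,
    Linear,
    Module,
    Tensor,
    binary_cross_entropy_with_logits,
    concat,
    cross_entropy,
)

NEG_INF = -np.inf


@dataclass
class SwinConfig:
    input_side: int = 16
    patch_size: int = 2
    embed_dim: int = 16
    depths: tuple[int, ...] = (1,)  # block *pairs* (W-MSA + SW-MSA) per stage
    window_P: int = 4
    num_heads: int = 2
    dense_layers: int = 2  # L
    growth_rate: int = 8  # g
    n_classes: int = 3
    head_mode: str = "softmax"  # softmax | sigmoid
    positional_embedding: bool = True
    relative_position_bias: bool = False
    conv_stem: bool = False
    stem_channels: int = 4
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        self.depths = tuple(int(d) for d in self.depths)
        if self.head_mode not in ("softmax", "sigmoid"):
            raise ValueError("head_mode must be 'softmax' or 'sigmoid'")
        if self.embed_dim % self.num_heads:
            raise ValueError("embed_dim must be divisible by num_heads")
        if self.dense_layers < 1 or self.growth_rate < 1:
            raise ValueError("dense_layers and growth_rate must be >= 1")

    @property
    def shift(self) -> int:
        return self.window_P // 2


# ---------------------------------------------------------------------------
# structural primitives (numpy level)


def window_partition(grid: np.ndarray, P: int) -> np.ndarray:
    """Split an (H, W, C) token grid into (H/P·W/P, P, P, C) windows.

    Windows are ordered row-major over the window grid; requires H and W
    divisible by P (pad upstream).
    """
    grid = np.asarray(grid)
    H, W = grid.shape[:2]
    if H % P or W % P:
        raise ValueError(f"grid {H}x{W} not divisible by window size {P}")
    C = grid.shape[2] if grid.ndim == 3 else 1
    g = grid.reshape(H // P, P, W // P, P, -1)
    out = g.transpose(0, 2, 1, 3, 4).reshape(-1, P, P, C)
    return out if grid.ndim == 3 else out[..., 0]


def window_reverse(windows: np.ndarray, H: int, W: int) -> np.ndarray:
    """Exact inverse of :func:`window_partition`."""
    windows = np.asarray(windows)
    P = windows.shape[1]
    squeeze = windows.ndim == 3
    w = windows.reshape(H // P, W // P, P, P, -1)
    out = w.transpose(0, 2, 1, 3, 4).reshape(H, W, -1)
    return out[..., 0] if squeeze else out


def cyclic_shift(grid: np.ndarray, s: int) -> np.ndarray:
    """Toroidal roll by (−s, −s) over the two leading (spatial) axes."""
    if not (0 <= s < min(grid.shape[0], grid.shape[1])):
        raise ValueError("shift must satisfy 0 <= s < min(H, W)")
    return np.roll(grid, (-s, -s), axis=(0, 1))


def cyclic_unshift(grid: np.ndarray, s: int) -> np.ndarray:
    return np.roll(grid, (s, s), axis=(0, 1))


def conv2d(feature_map: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """2-D cross-correlation with zero padding, same spatial shape.

    ``O(m, n) = Σ_x Σ_y F(m+x, n+y) · K(x, y)`` over the odd-sided kernel
    support centered at the origin.
    """
    kernel = np.asarray(kernel, dtype=np.float64)
    if kernel.shape[0] % 2 == 0 or kernel.shape[1] % 2 == 0:
        raise ValueError("kernel sides must be odd (2l+1)")
    return ndimage.correlate(np.asarray(feature_map, dtype=np.float64), kernel,
                             mode="constant", cval=0.0)


def global_average_pool(feature_map: np.ndarray):
    """Spatial mean per channel: (H, W) -> scalar, (C, H, W) -> (C,)."""
    arr = np.asarray(feature_map, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty feature map")
    if arr.ndim == 2:
        return float(arr.mean())
    if arr.ndim == 3:
        return arr.mean(axis=(1, 2))
    raise ValueError("expected (H, W) or (C, H, W)")


# ---------------------------------------------------------------------------
# attention masks


def _region_map(Hp: int, Wp: int, P: int, s: int) -> np.ndarray:
    """Pre-shift region labels used to mask cross-region pairs after rolling."""
    bands = lambda n: [slice(0, n - P), slice(n - P, n - s), slice(n - s, n)]
    region = np.zeros((Hp, Wp), dtype=np.int64)
    cnt = 0
    for hs in bands(Hp):
        for ws in bands(Wp):
            region[hs, ws] = cnt
            cnt += 1
    return region


def build_attention_mask(Hp: int, Wp: int, P: int, s: int, valid: np.ndarray | None = None) -> np.ndarray | None:
    """Additive (nW, P², P²) mask: 0 where attention is allowed, −∞ otherwise.

    ``s = 0`` builds the plain-window mask (only padding is masked);
    ``s > 0`` additionally forbids pairs from different pre-shift regions.
    Returns None when nothing needs masking.
    """
    if valid is None:
        valid = np.ones((Hp, Wp), dtype=bool)
    if s > 0:
        # the band layout [0, H−P), [H−P, H−s), [H−s, H) labels each rolled
        # position with the contiguity class of its pre-shift origin, so the
        # canvas is partitioned as-is while the validity map rolls with the
        # actual content
        ids = _region_map(Hp, Wp, P, s)
        vmap = cyclic_shift(valid.astype(np.int64), s)
    else:
        ids = np.zeros((Hp, Wp), dtype=np.int64)
        vmap = valid.astype(np.int64)
    win_ids = window_partition(ids[..., None], P).reshape(-1, P * P)
    win_valid = window_partition(vmap[..., None], P).reshape(-1, P * P)
    blocked = win_ids[:, :, None] != win_ids[:, None, :]
    blocked |= win_valid[:, None, :] == 0  # padded keys
    # self-attention is always allowed so no softmax row is fully masked
    # (only reachable for padded query tokens, which GAP later ignores)
    blocked &= ~np.eye(P * P, dtype=bool)[None]
    if not blocked.any():
        return None
    mask = np.zeros(blocked.shape)
    mask[blocked] = NEG_INF
    return mask


# ---------------------------------------------------------------------------
# trainable pieces


class WindowAttention(Module):
    """Multi-head scaled dot-product attention within P×P windows."""

    def __init__(self, dim: int, window_P: int, num_heads: int, rng: np.random.Generator,
                 relative_position_bias: bool = False):
        self.dim = dim
        self.P = window_P
        self.num_heads = num_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.bias_table = None
        if relative_position_bias:
            n = 2 * window_P - 1
            self.bias_table = Tensor(np.zeros((num_heads, n * n)), requires_grad=True)
            coords = np.stack(np.meshgrid(np.arange(window_P), np.arange(window_P), indexing="ij"))
            flat = coords.reshape(2, -1)
            rel = flat[:, :, None] - flat[:, None, :] + window_P - 1
            self.bias_index = rel[0] * n + rel[1]  # (P², P²)

    def __call__(self, windows: Tensor, mask: np.ndarray | None = None) -> Tensor:
        nw, n, c = windows.shape
        h = self.num_heads
        hd = c // h
        qkv = self.qkv(windows).reshape(nw, n, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # each (nW, heads, N, hd)
        attn = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        if self.bias_table is not None:
            bias = self.bias_table.take_last(self.bias_index)  # (heads, N, N)
            attn = attn + bias.reshape(1, h, n, n)
        if mask is not None:
            attn = attn + Tensor(mask[:, None, :, :])
        weights = attn.softmax(axis=-1)
        out = (weights @ v).transpose(0, 2, 1, 3).reshape(nw, n, c)
        return self.proj(out)

    def forward_np(self, windows: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        return self(Tensor(np.asarray(windows, dtype=np.float64)), mask).data


def window_attention(windows: np.ndarray, weights: WindowAttention, mask: np.ndarray | None = None) -> np.ndarray:
    """Functional form of :class:`WindowAttention` on an (nW, P², C) array."""
    return weights.forward_np(windows, mask)


class DenseMLP(Module):
    """Token-wise dense block: concatenative FC sub-layers + transition.

    Sub-layer i maps width ``C + i·g`` to ``g`` (Linear → LayerNorm → ReLU)
    and its output joins the running concatenation; the transition layer
    projects the final ``C + L·g`` back to ``C``.
    """

    def __init__(self, dim: int, L: int, g: int, rng: np.random.Generator):
        self.dim = dim
        self.L = L
        self.g = g
        self.sublayers = [Linear(dim + i * g, g, rng) for i in range(L)]
        self.norms = [LayerNorm(g) for _ in range(L)]
        self.transition = Linear(dim + L * g, dim, rng)

    def pre_transition_width(self) -> int:
        return self.dim + self.L * self.g

    def __call__(self, x: Tensor) -> Tensor:
        feats = [x]
        for linear, norm in zip(self.sublayers, self.norms):
            h = concat(feats, axis=-1) if len(feats) > 1 else feats[0]
            feats.append(norm(linear(h)).relu())
        return self.transition(concat(feats, axis=-1))


def dense_mlp(tokens: np.ndarray, L: int, g: int, seed: int = 0) -> np.ndarray:
    """Run a freshly initialized dense block over (..., C) tokens."""
    tokens = np.asarray(tokens, dtype=np.float64)
    block = DenseMLP(tokens.shape[-1], L, g, np.random.default_rng(seed))
    return block(Tensor(tokens)).data


class _BlockPair(Module):
    """One W-MSA block followed by one SW-MSA block (Eqs-style residuals)."""

    def __init__(self, dim: int, cfg: SwinConfig, rng: np.random.Generator):
        self.ln1 = LayerNorm(dim)
        self.wmsa = WindowAttention(dim, cfg.window_P, cfg.num_heads, rng, cfg.relative_position_bias)
        self.ln2 = LayerNorm(dim)
        self.mlp1 = DenseMLP(dim, cfg.dense_layers, cfg.growth_rate, rng)
        self.ln3 = LayerNorm(dim)
        self.swmsa = WindowAttention(dim, cfg.window_P, cfg.num_heads, rng, cfg.relative_position_bias)
        self.ln4 = LayerNorm(dim)
        self.mlp2 = DenseMLP(dim, cfg.dense_layers, cfg.growth_rate, rng)

    def _windowed(self, attnmod: WindowAttention, x: Tensor, Hp: int, Wp: int,
                  shift: int, mask: np.ndarray | None) -> Tensor:
        b, n, c = x.shape
        P = attnmod.P
        grid = x.reshape(b, Hp, Wp, c)
        if shift:
            # toroidal roll of the token grid (axes 1, 2) via index gather
            grid = Tensor._lift(grid)[:, np.roll(np.arange(Hp), -shift), :, :][:, :, np.roll(np.arange(Wp), -shift), :]
        wins = (
            grid.reshape(b, Hp // P, P, Wp // P, P, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b * (Hp // P) * (Wp // P), P * P, c)
        )
        full_mask = None
        if mask is not None:
            full_mask = np.tile(mask, (b, 1, 1))
        out = attnmod(wins, full_mask)
        grid = (
            out.reshape(b, Hp // P, Wp // P, P, P, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, Hp, Wp, c)
        )
        if shift:
            grid = grid[:, np.roll(np.arange(Hp), shift), :, :][:, :, np.roll(np.arange(Wp), shift), :]
        return grid.reshape(b, n, c)

    def __call__(self, x: Tensor, Hp: int, Wp: int, masks: dict) -> Tensor:
        k_hat = self._windowed(self.wmsa, self.ln1(x), Hp, Wp, 0, masks["plain"]) + x
        k_r = self.mlp1(self.ln2(k_hat)) + k_hat
        k_hat1 = self._windowed(self.swmsa, self.ln3(k_hat), Hp, Wp, masks["shift"], masks["shifted"]) + k_r
        return self.mlp2(self.ln4(k_hat1)) + k_hat1


class ConvDenseStem(Module):
    """Optional convolutional dense block + transition + 2×2 mean pool.

    3×3 convolutions with dense channel concatenation, batch norm and ReLU,
    then a 1×1 transition convolution down to ``stem_channels`` followed by
    2×2 average pooling (halving the grid before patch embedding).
    """

    def __init__(self, side: int, L: int, g: int, out_channels: int, rng: np.random.Generator):
        self.side = side
        self.L = L
        self.g = g
        self.out_channels = out_channels
        self.convs = [
            Tensor(rng.normal(0, np.sqrt(2.0 / (9 * (1 + i * g))), size=(9 * (1 + i * g), g)), requires_grad=True)
            for i in range(L)
        ]
        self.conv_biases = [Tensor(np.zeros(g), requires_grad=True) for _ in range(L)]
        self.bns = [BatchNorm(g) for _ in range(L)]
        self.transition = Tensor(rng.normal(0, np.sqrt(2.0 / (1 + L * g)), size=(1 + L * g, out_channels)), requires_grad=True)
        self.transition_bias = Tensor(np.zeros(out_channels), requires_grad=True)
        # clamped im2col gather indices + zero-pad validity, 3x3 kernel
        k, s = 3, side
        off = np.arange(-1, 2)
        rows = np.arange(s)[:, None, None, None] + off[None, None, :, None]
        cols = np.arange(s)[None, :, None, None] + off[None, None, None, :]
        valid = (rows >= 0) & (rows < s) & (cols >= 0) & (cols < s)
        self.idx = (np.clip(rows, 0, s - 1) * s + np.clip(cols, 0, s - 1)).reshape(-1)
        self.valid = valid.reshape(-1).astype(np.float64)

    def _conv3x3(self, x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
        b, c, s = x.shape[0], x.shape[1], self.side
        patches = x.reshape(b, c, s * s).take_last(self.idx) * Tensor(self.valid)
        patches = patches.reshape(b, c, s * s, 9).transpose(0, 2, 1, 3).reshape(b, s * s, c * 9)
        out = patches @ weight + bias
        return out.reshape(b, s, s, -1).transpose(0, 3, 1, 2)

    def __call__(self, x: Tensor) -> Tensor:
        feats = [x]  # (B, 1, S, S)
        for w, bias, bn in zip(self.convs, self.conv_biases, self.bns):
            h = concat(feats, axis=1) if len(feats) > 1 else feats[0]
            feats.append(bn(self._conv3x3(h, w, bias)).relu())
        h = concat(feats, axis=1)
        b, c, s = h.shape[0], h.shape[1], self.side
        flat = h.transpose(0, 2, 3, 1).reshape(b, s * s, c)
        out = (flat @ self.transition + self.transition_bias).reshape(b, s, s, -1).transpose(0, 3, 1, 2)
        pooled = out.reshape(b, self.out_channels, s // 2, 2, s // 2, 2).mean(axis=(3, 5))
        return pooled


class SwinModel(Module):
    """Patch embedding → stacked block pairs → GAP → fully connected head."""

    def __init__(self, cfg: SwinConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        side = cfg.input_side
        self.stem = None
        in_channels = 1
        if cfg.conv_stem:
            if side % 2:
                raise ValueError("conv_stem needs an even input side")
            self.stem = ConvDenseStem(side, cfg.dense_layers, cfg.growth_rate, cfg.stem_channels, rng)
            side = side // 2
            in_channels = cfg.stem_channels
        if side % cfg.patch_size:
            raise ValueError(f"input side {side} not divisible by patch size {cfg.patch_size}")
        self.tokens_side = side // cfg.patch_size
        P = cfg.window_P
        self.pad_side = int(np.ceil(self.tokens_side / P) * P)
        self.valid = np.zeros((self.pad_side, self.pad_side), dtype=bool)
        self.valid[: self.tokens_side, : self.tokens_side] = True
        self.patch_embed = Linear(cfg.patch_size**2 * in_channels, cfg.embed_dim, rng)
        # learned absolute positional embedding, zero-initialized: a fresh
        # model carries no positional information; training may break the
        # token-permutation symmetry (essential when tokens are width-1
        # feature scalars whose identity is the signal)
        self.pos_embed = None
        if cfg.positional_embedding:
            self.pos_embed = Tensor(np.zeros((1, self.pad_side**2, cfg.embed_dim)), requires_grad=True)
        self.blocks = [
            _BlockPair(cfg.embed_dim, cfg, rng) for _ in range(sum(cfg.depths))
        ]
        self.final_norm = LayerNorm(cfg.embed_dim)
        self.head = Linear(cfg.embed_dim, cfg.n_classes, rng)
        self.masks = {
            "plain": build_attention_mask(self.pad_side, self.pad_side, P, 0, self.valid),
            "shifted": build_attention_mask(self.pad_side, self.pad_side, P, cfg.shift, self.valid),
            "shift": cfg.shift,
        }
        self.history: dict[str, list[float]] = {
            "epoch": [], "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []
        }
        self.trained_epochs = 0

    # -- forward -------------------------------------------------------------

    def _tokenize(self, x: np.ndarray) -> Tensor:
        """(B, S, S) grids -> (B, N, C) embedded tokens on the padded grid."""
        t = Tensor(x)
        if self.stem is not None:
            maps = self.stem(t.reshape(x.shape[0], 1, x.shape[1], x.shape[2]))
        else:
            maps = t.reshape(x.shape[0], 1, x.shape[1], x.shape[2])
        b, c, s = maps.shape[0], maps.shape[1], maps.shape[2]
        p = self.cfg.patch_size
        n_side = s // p
        patches = (
            maps.reshape(b, c, n_side, p, n_side, p)
            .transpose(0, 2, 4, 3, 5, 1)
            .reshape(b, n_side * n_side, p * p * c)
        )
        tokens = self.patch_embed(patches)  # (B, N, C)
        if self.pad_side != n_side:  # zero-pad token grid to window multiple
            grid = np.zeros((b, self.pad_side, self.pad_side, self.cfg.embed_dim))
            t_grid = tokens.reshape(b, n_side, n_side, self.cfg.embed_dim)
            pad_tail_r = np.zeros((b, self.pad_side - n_side, n_side, self.cfg.embed_dim))
            upper = concat([t_grid, Tensor(pad_tail_r)], axis=1)
            pad_tail_c = np.zeros((b, self.pad_side, self.pad_side - n_side, self.cfg.embed_dim))
            tokens = concat([upper, Tensor(pad_tail_c)], axis=2).reshape(b, self.pad_side**2, self.cfg.embed_dim)
        if self.pos_embed is not None:
            tokens = tokens + self.pos_embed
        return tokens

    def logits(self, x: np.ndarray) -> Tensor:
        tokens = self._tokenize(np.asarray(x, dtype=np.float64))
        b = tokens.shape[0]
        for block in self.blocks:
            tokens = block(tokens, self.pad_side, self.pad_side, self.masks)
        tokens = self.final_norm(tokens)
        vmask = self.valid.reshape(1, -1, 1).astype(np.float64)
        pooled = (tokens * Tensor(vmask)).sum(axis=1) * (1.0 / self.valid.sum())
        return self.head(pooled)


def imstrans_forward(model: SwinModel, inputs: np.ndarray) -> np.ndarray:
    """Class probabilities for (B, S, S) grids (or one (S, S) grid)."""
    inputs = np.asarray(inputs, dtype=np.float64)
    single = inputs.ndim == 2
    if single:
        inputs = inputs[None]
    z = model.logits(inputs)
    probs = z.softmax(axis=-1).data if model.cfg.head_mode == "softmax" else z.sigmoid().data
    return probs[0] if single else probs


def features_to_grids(features: np.ndarray) -> np.ndarray:
    """Zero-pad each feature row to the next perfect square, reshape to a grid."""
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    d = features.shape[1]
    side = int(np.ceil(np.sqrt(d)))
    padded = np.zeros((len(features), side * side))
    padded[:, :d] = features
    return padded.reshape(len(features), side, side)


def train_classifier(
    inputs: np.ndarray,
    labels: np.ndarray,
    cfg: SwinConfig | None = None,
    val_inputs: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
) -> SwinModel:
    """Adam training with cross-entropy (softmax) or per-label BCE (sigmoid).

    ``inputs``: (N, S, S) grids, or (N, d) feature rows which are reshaped
    to √d-side grids (set ``patch_size=1`` for that mode). ``labels``:
    integer classes or an (N, C) binary matrix. Per-epoch train (and
    optional validation) loss/accuracy land in ``model.history``.
    """
    cfg = cfg or SwinConfig()
    inputs = np.asarray(inputs, dtype=np.float64)
    if inputs.ndim == 2:
        inputs = features_to_grids(inputs)
        cfg = SwinConfig(**{**asdict(cfg), "input_side": inputs.shape[1], "patch_size": 1})
    labels = np.asarray(labels)
    if labels.ndim == 1:
        onehot = np.zeros((len(labels), cfg.n_classes))
        onehot[np.arange(len(labels)), labels.astype(int)] = 1.0
    else:
        onehot = labels.astype(np.float64)
    present = (onehot.sum(axis=0) > 0).sum()
    if present < 2:
        raise ValueError("training needs at least 2 classes present")

    model = SwinModel(cfg)
    loss_fn = cross_entropy if cfg.head_mode == "softmax" else binary_cross_entropy_with_logits
    opt = Adam(model.parameters(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 1)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(inputs))
        losses, correct = [], 0
        for start in range(0, len(inputs), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            z = model.logits(inputs[idx])
            loss = loss_fn(z, onehot[idx])
            if not np.isfinite(loss.item()):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item() * len(idx))
            if cfg.head_mode == "softmax":
                correct += int((z.data.argmax(axis=1) == onehot[idx].argmax(axis=1)).sum())
            else:
                correct += int(((z.data > 0) == (onehot[idx] > 0.5)).all(axis=1).sum())
        model.history["epoch"].append(epoch)
        model.history["train_loss"].append(float(np.sum(losses) / len(inputs)))
        model.history["train_acc"].append(correct / len(inputs))
        if val_inputs is not None:
            vz = model.logits(np.asarray(val_inputs, dtype=np.float64))
            v_onehot = np.asarray(val_labels)
            if v_onehot.ndim == 1:
                tmp = np.zeros((len(v_onehot), cfg.n_classes))
                tmp[np.arange(len(v_onehot)), v_onehot.astype(int)] = 1.0
                v_onehot = tmp
            model.history["val_loss"].append(loss_fn(vz, v_onehot).item())
            if cfg.head_mode == "softmax":
                v_correct = (vz.data.argmax(axis=1) == v_onehot.argmax(axis=1)).mean()
            else:
                v_correct = ((vz.data > 0) == (v_onehot > 0.5)).all(axis=1).mean()
            model.history["val_acc"].append(float(v_correct))
        model.trained_epochs = epoch + 1
    return model


# ---------------------------------------------------------------------------
# checkpointing


def save_swin(model: SwinModel, path: str | Path) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **{f"p{i}": p.data for i, p in enumerate(model.parameters())})
    path.with_suffix(".json").write_text(json.dumps({
        "config": asdict(model.cfg),
        "history": model.history,
        "trained_epochs": model.trained_epochs,
    }, indent=2))


def load_swin(path: str | Path) -> SwinModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_dict = sidecar["config"]
    cfg_dict["depths"] = tuple(cfg_dict["depths"])
    model = SwinModel(SwinConfig(**cfg_dict))
    with np.load(path.with_suffix(".npz")) as archive:
        for i, p in enumerate(model.parameters()):
            p.data = archive[f"p{i}"]
    model.history = sidecar["history"]
    model.trained_epochs = sidecar["trained_epochs"]
    return model
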