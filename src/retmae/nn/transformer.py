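"""Transformer blocks: global attention (ViT) and windowed attention
(Swin / SwinV2), plus the patch merging / expanding stages used by the
hierarchical encoders and decoders.

Swin blocks compute attention inside non-overlapping ``window × window``
token neighbourhoods, alternating between unshifted and half-window-shifted
partitions so information propagates across window boundaries.  The SwinV2
variant replaces dot-product attention with scaled cosine attention
(learnable per-head logit scale, capped at 100) and produces its relative
position bias from a small MLP over log-spaced relative coordinates; its
blocks are post-normalised (residual-then-norm) for training stability.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .layers import LayerNorm, Linear, Mlp, Module, Parameter, trunc_normal

__all__ = ["Attention", "ViTBlock", "SwinBlock", "PatchMerging",
           "PatchExpanding", "window_partition", "window_reverse"]


# --------------------------------------------------------------------- utils
def window_partition(x: Tensor, window: int) -> Tensor:
    """(B, H, W, C) → (B·nW, window², C)."""
    B, H, W, C = x.shape
    x = x.reshape(B, H // window, window, W // window, window, C)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(-1, window * window, C)


def window_reverse(x: Tensor, window: int, H: int, W: int) -> Tensor:
    """Inverse of :func:`window_partition`."""
    Bn = x.shape[0]
    B = Bn // ((H // window) * (W // window))
    x = x.reshape(B, H // window, W // window, window, window, -1)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(B, H, W, -1)


def _relative_index(window: int) -> np.ndarray:
    """Flat index into the (2w-1)² relative-position table for each token pair."""
    coords = np.stack(np.meshgrid(np.arange(window), np.arange(window),
                                  indexing="ij"))           # 2, w, w
    flat = coords.reshape(2, -1)                              # 2, w²
    rel = flat[:, :, None] - flat[:, None, :]                 # 2, w², w²
    rel = rel + (window - 1)
    return (rel[0] * (2 * window - 1) + rel[1]).astype(np.intp)  # w², w²


def _shift_attn_mask(H: int, W: int, window: int, shift: int) -> np.ndarray | None:
    """Additive mask (nW, w², w²) blocking attention across rolled regions."""
    if shift == 0:
        return None
    img = np.zeros((1, H, W, 1))
    slices = (slice(0, -window), slice(-window, -shift), slice(-shift, None))
    cnt = 0
    for hs in slices:
        for ws in slices:
            img[:, hs, ws, :] = cnt
            cnt += 1
    win = window_partition(Tensor(img), window).data.reshape(-1, window * window)
    diff = win[:, :, None] - win[:, None, :]
    return np.where(diff != 0, -100.0, 0.0)


def _sigmoid(x: Tensor) -> Tensor:
    return (x * 0.5).tanh() * 0.5 + 0.5


# ----------------------------------------------------------------- attention
class Attention(Module):
    """Standard multi-head self-attention over a full token sequence."""

    def __init__(self, rng, dim: int, heads: int):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.heads = heads
        self.dh = dim // heads
        self.qkv = Linear(rng, dim, 3 * dim)
        self.proj = Linear(rng, dim, dim)

    def forward(self, x: Tensor) -> Tensor:
        B, L, C = x.shape
        qkv = self.qkv(x).reshape(B, L, 3, self.heads, self.dh)
        qkv = qkv.transpose(2, 0, 3, 1, 4)                    # 3, B, h, L, dh
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = (q @ k.swapaxes(-1, -2)) * (self.dh ** -0.5)
        attn = attn.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, C)
        return self.proj(out)


class WindowAttention(Module):
    """Windowed multi-head attention with learned relative position bias.

    ``v2=True`` switches to SwinV2 conventions: cosine similarity scaled by
    a learnable per-head temperature and a continuous position bias produced
    by a 2-layer MLP on log-spaced relative coordinates.
    """

    def __init__(self, rng, dim: int, heads: int, window: int, v2: bool = False):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.heads = heads
        self.dh = dim // heads
        self.window = window
        self.v2 = v2
        self.qkv = Linear(rng, dim, 3 * dim)
        self.proj = Linear(rng, dim, dim)
        self._rel_index = _relative_index(window).ravel()
        if v2:
            self.logit_scale = Parameter(
                np.full((heads, 1, 1), np.log(10.0)))
            self.cpb_fc1 = Linear(rng, 2, 64)
            self.cpb_fc2 = Linear(rng, 64, heads, bias=False)
            self._log_coords = self._log_spaced_coords(window)
        else:
            n_rel = (2 * window - 1) ** 2
            self.rel_bias_table = Parameter(trunc_normal(rng, (n_rel, heads)))

    @staticmethod
    def _log_spaced_coords(window: int) -> np.ndarray:
        r = np.arange(-(window - 1), window)
        h, w = np.meshgrid(r, r, indexing="ij")
        coords = np.stack([h, w], axis=-1).reshape(-1, 2).astype(np.float64)
        coords *= 8.0 / max(window - 1, 1)
        return np.sign(coords) * np.log2(1.0 + np.abs(coords)) / np.log2(8.0)

    def _bias(self) -> Tensor:
        N = self.window * self.window
        if self.v2:
            table = _sigmoid(self.cpb_fc2(self.cpb_fc1(
                Tensor(self._log_coords)).relu())) * 16.0
        else:
            table = self.rel_bias_table
        bias = table.take(self._rel_index, axis=0)            # N², heads
        return bias.reshape(N, N, self.heads).transpose(2, 0, 1)

    def forward(self, x: Tensor, attn_mask: np.ndarray | None = None) -> Tensor:
        B_, N, C = x.shape
        qkv = self.qkv(x).reshape(B_, N, 3, self.heads, self.dh)
        qkv = qkv.transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]
        if self.v2:
            qn = q * ((q * q).sum(axis=-1, keepdims=True) + 1e-12) ** -0.5
            kn = k * ((k * k).sum(axis=-1, keepdims=True) + 1e-12) ** -0.5
            scale = self.logit_scale.clip(high=float(np.log(100.0))).exp()
            attn = (qn @ kn.swapaxes(-1, -2)) * scale
        else:
            attn = (q @ k.swapaxes(-1, -2)) * (self.dh ** -0.5)
        attn = attn + self._bias()
        if attn_mask is not None:
            nW = attn_mask.shape[0]
            attn = attn.reshape(B_ // nW, nW, self.heads, N, N)
            attn = attn + Tensor(attn_mask[None, :, None])
            attn = attn.reshape(B_, self.heads, N, N)
        attn = attn.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B_, N, C)
        return self.proj(out)


# -------------------------------------------------------------------- blocks
class ViTBlock(Module):
    """Pre-norm transformer block (global attention)."""

    def __init__(self, rng, dim: int, heads: int, mlp_ratio: float = 4.0):
        self.norm1 = LayerNorm(dim)
        self.attn = Attention(rng, dim, heads)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(rng, dim, int(dim * mlp_ratio))

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.mlp(self.norm2(x))


class SwinBlock(Module):
    """(Shifted-)window attention block on a (B, H, W, C) token grid.

    Swin uses pre-norm residuals; SwinV2 (``v2=True``) uses post-norm.
    ``shift`` is half the window for odd-indexed blocks, zero otherwise;
    when the grid is no larger than the window the shift is dropped and the
    window clipped to the grid.
    """

    def __init__(self, rng, dim: int, heads: int, input_size: tuple[int, int],
                 window: int, shift: bool, v2: bool = False,
                 mlp_ratio: float = 4.0):
        H, W = input_size
        self.input_size = (H, W)
        window = min(window, H, W)
        self.window = window
        self.shift = window // 2 if (shift and window < min(H, W)) else 0
        self.v2 = v2
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(rng, dim, heads, window, v2=v2)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(rng, dim, int(dim * mlp_ratio))
        self._mask = _shift_attn_mask(H, W, window, self.shift)

    def _attend(self, x: Tensor) -> Tensor:
        H, W = self.input_size
        if self.shift:
            x = x.roll((-self.shift, -self.shift), axis=(1, 2))
        windows = window_partition(x, self.window)
        windows = self.attn(windows, attn_mask=self._mask)
        x = window_reverse(windows, self.window, H, W)
        if self.shift:
            x = x.roll((self.shift, self.shift), axis=(1, 2))
        return x

    def forward(self, x: Tensor) -> Tensor:
        if self.v2:   # post-norm residuals
            x = x + self.norm1(self._attend(x))
            return x + self.norm2(self.mlp(x))
        x = x + self._attend(self.norm1(x))
        return x + self.mlp(self.norm2(x))


class PatchMerging(Module):
    """Downsample a (B, H, W, C) grid 2× and double the channels."""

    def __init__(self, rng, dim: int):
        self.reduction = Linear(rng, 4 * dim, 2 * dim, bias=False)
        self.norm = LayerNorm(4 * dim)

    def forward(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        x = x.reshape(B, H // 2, 2, W // 2, 2, C)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(B, H // 2, W // 2, 4 * C)
        return self.reduction(self.norm(x))


class PatchExpanding(Module):
    """Upsample a (B, H, W, C) grid 2× and halve the channels."""

    def __init__(self, rng, dim: int):
        self.expand = Linear(rng, dim, 2 * dim, bias=False)
        self.norm = LayerNorm(dim // 2)

    def forward(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        x = self.expand(x)                                    # B,H,W,2C
        x = x.reshape(B, H, W, 2, 2, C // 2)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(B, 2 * H, 2 * W, C // 2)
        return self.norm(x)
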