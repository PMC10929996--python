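"""Deformable transformer over flattened multi-scale feature tokens.

The fused pyramid's coarsest scales are flattened (scale-major, then H, W, D
raster order) into a token sequence.  Spatial structure is reintroduced by a
sinusoidal 3D positional encoding: each axis gets an independent sin/cos table
over a third of the channel budget, the three tables are concatenated per
token, and the result is combined element-wise (added) with the token content
when queries are formed inside each attention layer.

Each DeTrans layer applies deformable self-attention — every query predicts,
per head and scale, a small set of continuous sampling offsets around its own
reference location plus matching attention weights (softmax-normalized over
scales x points) — followed by a feed-forward network, with layer
normalization and skip connections in the pre-norm arrangement:
``x -> x + Attn(LN(x)) -> (.) + FFN(LN(.))``.  Cost is linear in sequence
length times sampling points, never quadratic in length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .config import DeTransConfig
from .encoder import FeaturePyramid
from .nn import LayerNorm, Linear, Module


@dataclass
class LevelInfo:
    """Bookkeeping for one pyramid scale inside the token sequence."""

    dims: tuple[int, int, int]
    start: int
    stop: int
    level: int
    scale: int
    stride: float


@dataclass
class TokenSequence:
    tokens: Tensor  # (N, C)
    encodings: np.ndarray  # (N, C), values in [-1, 1]
    positions: np.ndarray  # (N, 3) normalized voxel-center coordinates in [0, 1]
    levels: list[LevelInfo] = field(default_factory=list)

    def __post_init__(self):
        n = self.tokens.data.shape[0]
        if not (self.encodings.shape[0] == n and self.positions.shape[0] == n):
            raise ValueError("tokens/encodings/positions length mismatch")
        if np.abs(self.encodings).max(initial=0.0) > 1 + 1e-6:
            raise ValueError("positional encodings must lie in [-1, 1]")

    def __len__(self) -> int:
        return self.tokens.data.shape[0]


def positional_encoding(length: int, channels: int) -> np.ndarray:
    """Sinusoidal table for one axis: (length, channels), channels even.

    entry(pos, 2k)   = sin(pos * v_k)
    entry(pos, 2k+1) = cos(pos * v_k),   v_k = 1 / 10000^(2k / channels),
    so k = 0 gives v = 1 and entry(pos, 0) = sin(pos).
    """
    if channels % 2:
        raise ValueError("channels must be even (sin/cos pairs)")
    pos = np.arange(length, dtype=np.float64)[:, None]
    k = np.arange(channels // 2, dtype=np.float64)[None, :]
    v = 1.0 / 10000.0 ** (2.0 * k / channels)
    table = np.empty((length, channels), dtype=np.float32)
    table[:, 0::2] = np.sin(pos * v)
    table[:, 1::2] = np.cos(pos * v)
    return table


def encoding_3d(dims: tuple[int, int, int], channels: int) -> np.ndarray:
    """Concatenated per-axis encodings for a (H, W, D) grid -> (H*W*D, C).

    Each axis gets a table of width C/3 (rounded down to an even number);
    remainder channels are zero-padded.
    """
    w_axis = (channels // 3) // 2 * 2
    tables = [positional_encoding(n, w_axis) for n in dims]
    H, W, D = dims
    out = np.zeros((H * W * D, channels), dtype=np.float32)
    hh, ww, dd = np.meshgrid(np.arange(H), np.arange(W), np.arange(D), indexing="ij")
    idx = [hh.ravel(), ww.ravel(), dd.ravel()]
    for a in range(3):
        out[:, a * w_axis:(a + 1) * w_axis] = tables[a][idx[a]]
    return out


def flatten_with_pos(pyramid: FeaturePyramid, token_scales: int = 3) -> TokenSequence:
    """Flatten the ``token_scales`` coarsest shallow-branch scales of a fused
    pyramid into one token sequence with positional metadata.

    Raster order is scale-major (coarsest scale first), then H, W, D within a
    scale.  The positional encoding is *returned alongside* the tokens (the
    attention layers add it when forming queries, so flatten/reshape stays an
    exact inverse pair on the raw tokens).
    """
    if not pyramid.fused:
        raise ValueError("pyramid must be fused before flattening")
    maps = pyramid.level_maps(0)
    if not maps:
        raise ValueError("pyramid holds no shallow-branch maps")
    selected = sorted(maps, key=lambda m: -m.scale)[:token_scales]  # coarsest first
    C = selected[0].channels
    tok_parts, enc_parts, pos_parts, levels = [], [], [], []
    start = 0
    for m in selected:
        h, w, d = m.dims
        n = h * w * d
        tok_parts.append(ad.transpose(ad.reshape(m.tensor, (C, n))))
        enc_parts.append(encoding_3d(m.dims, C))
        hh, ww, dd = np.meshgrid(*[np.arange(x) for x in m.dims], indexing="ij")
        grid = np.stack([hh.ravel(), ww.ravel(), dd.ravel()], axis=1).astype(np.float32)
        pos_parts.append((grid + 0.5) / np.array(m.dims, dtype=np.float32))
        levels.append(LevelInfo(dims=m.dims, start=start, stop=start + n,
                                level=m.level, scale=m.scale, stride=m.stride))
        start += n
    return TokenSequence(tokens=ad.concat(tok_parts, axis=0),
                         encodings=np.concatenate(enc_parts, axis=0),
                         positions=np.concatenate(pos_parts, axis=0),
                         levels=levels)


class DeformableAttention(Module):
    """Multi-head deformable self-attention over a multi-scale sequence.

    Offset-predicting weights start at zero (all samples at the reference
    location) and attention-logit weights start at zero (uniform weights),
    the stable-start convention for deformable attention.
    """

    def __init__(self, channels: int, cfg: DeTransConfig, n_levels: int, *,
                 rng: np.random.Generator):
        if channels % cfg.n_heads:
            raise ValueError("channels must be divisible by n_heads")
        self.n_heads = cfg.n_heads
        self.n_points = cfg.n_sampling_points
        self.n_levels = n_levels
        self.head_dim = channels // cfg.n_heads
        hlp = cfg.n_heads * n_levels * cfg.n_sampling_points
        self.value_proj = Linear(channels, channels, rng=rng)
        self.out_proj = Linear(channels, channels, rng=rng)
        self.offset_net = Linear(channels, hlp * 3, rng=rng, zero_init=True)
        self.weight_net = Linear(channels, hlp, rng=rng, zero_init=True)

    def forward(self, x: Tensor, seq: TokenSequence, enc: Tensor | None = None) -> Tensor:
        N, C = x.data.shape
        L = min(self.n_levels, len(seq.levels))
        H, P, Dh = self.n_heads, self.n_points, self.head_dim
        v = self.value_proj(x)
        q = x if enc is None else x + enc
        offsets = ad.reshape(self.offset_net(q), (N, H, L, P, 3))
        logits = ad.reshape(self.weight_net(q), (N, H, L * P))
        weights = ad.reshape(ad.softmax(logits, axis=-1), (N, H, L, P))
        self.last_weights = weights.data  # (N, H, L, P), sums to 1 over (L, P)

        # per-level value grids: (C, h, w, d)
        grids = []
        refs = []
        for li in range(L):
            info = seq.levels[li]
            rows = v[info.start:info.stop, :]
            grids.append(ad.reshape(ad.transpose(rows), (C,) + info.dims))
            # reference = each query's own normalized position, in this level's voxel units
            refs.append(seq.positions * np.array(info.dims, dtype=np.float32) - 0.5)

        head_outputs = []
        for h in range(H):
            acc = None
            for li in range(L):
                grid_h = grids[li][h * Dh:(h + 1) * Dh, :, :, :]
                coords = ad.reshape(offsets[:, h, li, :, :], (N * P, 3)) + \
                    Tensor(np.repeat(refs[li], P, axis=0))
                sampled = ad.reshape(ad.grid_sample_trilinear(grid_h, coords), (N, P, Dh))
                w_hl = ad.reshape(weights[:, h, li, :], (N, P, 1))
                term = ad.tsum(ad.mul(sampled, w_hl), axis=1)
                acc = term if acc is None else acc + term
            head_outputs.append(acc)
        return self.out_proj(ad.concat(head_outputs, axis=1))


class DeTransLayer(Module):
    """Deformable self-attention + FFN with pre-norm skip connections."""

    def __init__(self, channels: int, cfg: DeTransConfig, n_levels: int, *,
                 rng: np.random.Generator):
        self.ln1 = LayerNorm(channels)
        self.attn = DeformableAttention(channels, cfg, n_levels, rng=rng)
        self.ln2 = LayerNorm(channels)
        self.ffn1 = Linear(channels, cfg.ffn_mult * channels, rng=rng)
        self.ffn2 = Linear(cfg.ffn_mult * channels, channels, rng=rng)

    def forward(self, x: Tensor, seq: TokenSequence, enc: Tensor | None = None) -> Tensor:
        x = x + self.attn(self.ln1(x), seq, enc)
        return x + self.ffn2(ad.relu(self.ffn1(self.ln2(x))))


class DeformableTransformer(Module):
    """A stack of DeTrans layers; positional encodings added at input only."""

    def __init__(self, channels: int, cfg: DeTransConfig, n_levels: int, *,
                 rng: np.random.Generator):
        if cfg.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        self.layers = [DeTransLayer(channels, cfg, n_levels, rng=rng)
                       for _ in range(cfg.n_layers)]

    def forward(self, seq: TokenSequence) -> TokenSequence:
        """The positional encoding enters through the attention query path
        (offset/weight prediction), the deformable-attention convention: the
        residual value stream stays encoding-free, so zeroing the residual
        branches makes the whole stack an exact identity."""
        x = seq.tokens
        enc = Tensor(seq.encodings)
        for layer in self.layers:
            x = layer(x, seq, enc)
        return TokenSequence(tokens=x, encodings=seq.encodings,
                             positions=seq.positions, levels=seq.levels)


def transformer_forward(seq: TokenSequence, model: DeformableTransformer) -> TokenSequence:
    return model(seq)
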