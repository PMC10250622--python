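"""The helix-region protein encoder.

Each embedded region (p_i x 100 word2vec matrix) is zero-padded at its
tail to the receptor's maximum region length p_max, passed through a
region-specific block of one length-preserving 1D convolution and a
gated linear unit (GLU), concatenated in anatomical order, given a
sinusoidal positional encoding over the concatenated axis, and run
through one self-attention block (multi-head attention + feedforward,
each with residual connection and layer normalisation). The result is
a (p_max x R) x 64 protein feature matrix with per-row region
provenance; padded rows are excluded as attention keys.

With R = 7 this encodes the seven transmembrane helices only; adding an
extracellular loop (e.g. ECL2 between TM4 and TM5) gives R = 8 with the
loop block inserted at its anatomical slot so residue order is
preserved in the positional encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .protein_features import EmbeddedRegion

MASK_NEG = -1e9  # additive logit bias that zeroes masked keys after softmax


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture knobs for the region encoder.

    The published hyperparameter listing is not available, so kernel
    size, head count and feedforward width are surfaced here with
    documented defaults.
    """
    embed_dim: int = 100        # word2vec width
    d_model: int = 64           # channel width after the GLU block
    kernel_size: int = 3
    heads: int = 8
    ff_width: int = 256
    pe_scale: float = 0.1        # amplitude of the sinusoidal table relative
                                 # to the sqrt(d)-scaled content features
    share_region_weights: bool = False
    include_ecls: tuple[str, ...] = ()
    whole_sequence: bool = False  # single-region whole-sequence baseline
    gnn_rounds: int = 3
    decoder_layers: int = 3


@dataclass(frozen=True)
class PaddedRegionStack:
    """R x p_max x dim region stack with a token-validity mask."""
    stack: np.ndarray          # (R, p_max, dim), padded cells exactly zero
    mask: np.ndarray           # (R, p_max) bool, True = real token
    region_order: tuple[str, ...]

    @property
    def p_max(self) -> int:
        return self.stack.shape[1]

    @property
    def n_regions(self) -> int:
        return self.stack.shape[0]


@dataclass(frozen=True)
class EncodedProtein:
    """(p_max x R) x d feature matrix with per-row provenance."""
    matrix: np.ndarray                      # (p_max*R, d)
    mask: np.ndarray                        # (p_max*R,) bool, True = real token
    provenance: tuple[tuple[str, int], ...]  # (region_id, within-region index) per row

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]


def pad_and_stack(regions: Sequence[EmbeddedRegion]) -> PaddedRegionStack:
    """Stack embedded regions to (R, p_max, dim), zero-padding each tail."""
    if not regions:
        raise ValueError("need at least one region")
    dims = {r.matrix.shape[1] for r in regions}
    if len(dims) != 1:
        raise ValueError(f"inconsistent embedding widths: {sorted(dims)}")
    dim = dims.pop()
    p_max = max(r.matrix.shape[0] for r in regions)
    R = len(regions)
    stack = np.zeros((R, p_max, dim), dtype=np.float32)
    mask = np.zeros((R, p_max), dtype=bool)
    for i, r in enumerate(regions):
        p = r.matrix.shape[0]
        stack[i, :p] = r.matrix
        mask[i, :p] = True
    return PaddedRegionStack(stack, mask, tuple(r.region_id for r in regions))


def sinusoidal_encoding(n_positions: int, d: int) -> np.ndarray:
    """Standard transformer sin/cos table; row 0 is (0, 1, 0, 1, ...)."""
    pos = np.arange(n_positions, dtype=np.float64)[:, None]
    i = np.arange(d // 2, dtype=np.float64)[None, :]
    angle = pos / np.power(10000.0, 2 * i / d)
    pe = np.zeros((n_positions, d), dtype=np.float32)
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def concat_positional(region_outputs: Sequence[np.ndarray],
                      region_order: Sequence[str],
                      mask: np.ndarray, d_model: int = 64,
                      pe_scale: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate per-region encoded blocks and add positional encoding.

    ``region_outputs`` are the R conv+GLU outputs (each p_max x d) in
    anatomical order; ``mask`` is the (R, p_max) token-validity mask.
    Returns the (R*p_max, d) matrix (content scaled by sqrt(d) before the
    scaled sinusoidal table is added) and the flat mask. This is the
    single-receptor form of what the batched encoder applies internally.
    """
    if len(region_outputs) != len(region_order):
        raise ValueError("one output block per region required")
    cat = np.concatenate(region_outputs, axis=0).astype(np.float32)
    if cat.shape[1] != d_model:
        raise ValueError(f"blocks must have width {d_model}")
    pe = pe_scale * sinusoidal_encoding(cat.shape[0], d_model)
    return cat * np.sqrt(d_model, dtype=np.float32) + pe, mask.reshape(-1)


class HelixEncoderParams:
    """All learned tensors of the encoder for a fixed region count R."""

    def __init__(self, rng: np.random.Generator, config: EncoderConfig, n_regions: int):
        c = config
        self.config = c
        self.n_regions = n_regions
        n_blocks = 1 if c.share_region_weights else n_regions
        self.convs = [nn.Conv1dSame(rng, c.embed_dim, 2 * c.d_model,
                                    c.kernel_size, f"enc.conv{r}")
                      for r in range(n_blocks)]
        d = c.d_model
        self.wq = nn.Linear(rng, d, d, "enc.wq")
        self.wk = nn.Linear(rng, d, d, "enc.wk")
        self.wv = nn.Linear(rng, d, d, "enc.wv")
        self.wo = nn.Linear(rng, d, d, "enc.wo")
        self.ln1 = nn.LayerNorm(d, "enc.ln1")
        self.ff1 = nn.Linear(rng, d, c.ff_width, "enc.ff1")
        self.ff2 = nn.Linear(rng, c.ff_width, d, "enc.ff2")
        self.ln2 = nn.LayerNorm(d, "enc.ln2")

    def conv_for_region(self, r: int) -> nn.Conv1dSame:
        return self.convs[0 if self.config.share_region_weights else r]

    def parameters(self):
        out = [p for conv in self.convs for p in conv.parameters()]
        for mod in (self.wq, self.wk, self.wv, self.wo, self.ln1,
                    self.ff1, self.ff2, self.ln2):
            out.extend(mod.parameters())
        return out


def conv_glu_block(x: nn.Tensor, conv: nn.Conv1dSame, d_model: int) -> nn.Tensor:
    """Length-preserving conv to 2*d channels, then GLU: A * sigmoid(B)."""
    y = conv(x)
    a = nn.narrow(y, y.ndim - 1, 0, d_model)
    b = nn.narrow(y, y.ndim - 1, d_model, d_model)
    return nn.mul(a, nn.sigmoid(b))


def multi_head_attention(q: nn.Tensor, k: nn.Tensor, v: nn.Tensor,
                         key_bias: np.ndarray, heads: int,
                         wo: nn.Linear) -> tuple[nn.Tensor, np.ndarray]:
    """Batched multi-head attention.

    q: (B, Nq, d); k, v: (B, Nk, d); key_bias: broadcastable to
    (B, heads, Nq, Nk) additive logit bias (MASK_NEG at padded keys).
    Returns the attended output (B, Nq, d) and the attention weights as
    a plain (B, heads, Nq, Nk) array.
    """
    B, Nq, d = q.shape
    Nk = k.shape[1]
    dh = d // heads

    def split(t: nn.Tensor, N: int) -> nn.Tensor:
        t = nn.reshape(t, (B, N, heads, dh))
        return nn.transpose(t, (0, 2, 1, 3))  # (B, H, N, dh)

    qh, kh, vh = split(q, Nq), split(k, Nk), split(v, Nk)
    # scale queries rather than the (much larger) score tensor
    qh = nn.scale(qh, 1.0 / np.sqrt(dh))
    scores = nn.matmul(qh, nn.transpose(kh, (0, 1, 3, 2)))
    attn = nn.softmax(scores, bias=key_bias)
    out = nn.matmul(attn, vh)                        # (B, H, Nq, dh)
    out = nn.reshape(nn.transpose(out, (0, 2, 1, 3)), (B, Nq, d))
    return wo(out), attn.data


def _key_bias(flat_mask: np.ndarray, heads: int) -> np.ndarray:
    """(B, N) bool -> (B, 1, 1, N) additive bias, MASK_NEG at padding."""
    return np.where(flat_mask[:, None, None, :], 0.0, MASK_NEG).astype(np.float32)


def self_attention_block(x: nn.Tensor, flat_mask: np.ndarray,
                         params: HelixEncoderParams) -> tuple[nn.Tensor, np.ndarray]:
    """Pre-softmax-masked MHA + FF, each with residual and layer norm."""
    c = params.config
    bias = _key_bias(flat_mask, c.heads)
    attended, weights = multi_head_attention(
        params.wq(x), params.wk(x), params.wv(x), bias, c.heads, params.wo)
    h = params.ln1(nn.add(x, attended))
    ff = params.ff2(nn.relu(params.ff1(h)))
    return params.ln2(nn.add(h, ff)), weights


def encode_batch(stacks: Sequence[PaddedRegionStack],
                 params: HelixEncoderParams) -> tuple[nn.Tensor, np.ndarray]:
    """Encode a batch of receptors into (B, R*P, d) + validity mask.

    P is the batch-wide maximum p_max; each receptor keeps its own
    positional-encoding positions r*p_max_i + t, so valid rows are
    numerically identical to an unbatched encoding of that receptor.
    """
    c = params.config
    R = params.n_regions
    if any(s.n_regions != R for s in stacks):
        raise ValueError("all stacks must have the encoder's region count")
    B = len(stacks)
    P = max(s.p_max for s in stacks)
    x = np.zeros((B, R, P, c.embed_dim), dtype=np.float32)
    mask = np.zeros((B, R, P), dtype=bool)
    pe = np.zeros((B, R * P, c.d_model), dtype=np.float32)
    for i, s in enumerate(stacks):
        x[i, :, :s.p_max] = s.stack
        mask[i, :, :s.p_max] = s.mask
        table = c.pe_scale * sinusoidal_encoding(R * s.p_max, c.d_model)
        for r in range(R):
            pe[i, r * P:r * P + s.p_max] = table[r * s.p_max:(r + 1) * s.p_max]
    xt = nn.constant(x)
    per_region = []
    for r in range(R):
        xr = nn.reshape(nn.narrow(xt, 1, r, 1), (B, P, c.embed_dim))
        per_region.append(conv_glu_block(xr, params.conv_for_region(r), c.d_model))
    cat = nn.concat(per_region, axis=1)              # (B, R*P, d)
    # scale features by sqrt(d) before adding the positional table, the
    # usual transformer convention, so positions do not drown content
    cat = nn.add(nn.scale(cat, np.sqrt(c.d_model)), nn.constant(pe))
    flat_mask = mask.reshape(B, R * P)
    out, _ = self_attention_block(cat, flat_mask, params)
    return out, flat_mask


def encode_protein(stack: PaddedRegionStack,
                   params: HelixEncoderParams) -> EncodedProtein:
    """Encode one receptor into its (p_max x R) x d matrix with provenance."""
    out, flat_mask = encode_batch([stack], params)
    provenance = tuple((rid, t) for rid in stack.region_order
                       for t in range(stack.p_max))
    return EncodedProtein(out.data[0], flat_mask[0], provenance)
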