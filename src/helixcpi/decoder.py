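"""TransformerCPI-style interaction decoder and the assembled CPI model.

Compound atom embeddings act as queries over the encoded protein
(keys/values) through a stack of cross-attention + feedforward layers
(residual + layer norm around each). Atom representations are then
pooled with a learned softmax attention over atoms and mapped through a
small affine head to a sigmoid interaction probability. Cross-attention
weights can be retained for the region-attribution analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .compound_features import (GNNParams, InvalidSmilesError, MolecularGraph,
                                gnn_forward, normalized_adjacency, smiles_to_graph)
from .corpus import InteractionRecord, ReceptorRecord
from .encoder import (MASK_NEG, EncodedProtein, EncoderConfig,
                      HelixEncoderParams, PaddedRegionStack, encode_batch,
                      multi_head_attention, pad_and_stack)
from .protein_features import (Word2VecVocab, embed_segments, region_order,
                               split_regions, whole_sequence_segments)

logger = logging.getLogger(__name__)


@dataclass
class PredictionResult:
    """One scored compound-protein pair.

    ``attention`` is a (layers, heads, a, p_max*R) array of decoder
    cross-attention weights over the protein rows of this receptor's
    encoding (padded rows carry ~0 mass); ``provenance`` names the
    (region, within-region index) of each protein row and ``mask``
    flags real (non-padding) rows.
    """
    accession: str
    smiles: str
    probability: float
    logit: float
    attention: np.ndarray | None = None
    provenance: tuple[tuple[str, int], ...] | None = None
    mask: np.ndarray | None = None
    label: str | None = None


class DecoderLayer:
    def __init__(self, rng: np.random.Generator, d: int, ff_width: int, name: str):
        self.wq = nn.Linear(rng, d, d, f"{name}.wq")
        self.wk = nn.Linear(rng, d, d, f"{name}.wk")
        self.wv = nn.Linear(rng, d, d, f"{name}.wv")
        self.wo = nn.Linear(rng, d, d, f"{name}.wo")
        self.ln1 = nn.LayerNorm(d, f"{name}.ln1")
        self.ff1 = nn.Linear(rng, d, ff_width, f"{name}.ff1")
        self.ff2 = nn.Linear(rng, ff_width, d, f"{name}.ff2")
        self.ln2 = nn.LayerNorm(d, f"{name}.ln2")

    def parameters(self):
        return [p for mod in (self.wq, self.wk, self.wv, self.wo, self.ln1,
                              self.ff1, self.ff2, self.ln2)
                for p in mod.parameters()]


class DecoderParams:
    def __init__(self, rng: np.random.Generator, config: EncoderConfig):
        d = config.d_model
        self.config = config
        self.layers = [DecoderLayer(rng, d, config.ff_width, f"dec{i}")
                       for i in range(config.decoder_layers)]
        self.pool = nn.Linear(rng, d, 1, "dec.pool")
        self.head1 = nn.Linear(rng, d, d, "dec.head1")
        self.head2 = nn.Linear(rng, d, 1, "dec.head2")

    def parameters(self):
        out = [p for layer in self.layers for p in layer.parameters()]
        for mod in (self.pool, self.head1, self.head2):
            out.extend(mod.parameters())
        return out


def decoder_forward(atoms: nn.Tensor, atom_mask: np.ndarray,
                    memory: nn.Tensor, memory_mask: np.ndarray,
                    params: DecoderParams, retain_attention: bool = False
                    ) -> tuple[nn.Tensor, list[np.ndarray]]:
    """Run the decoder stack on a batch.

    atoms: (B, A, d) atom embeddings; memory: (B, N, d) encoded
    proteins; masks flag real rows. Returns the (B,) logits tensor and
    (optionally) each layer's (B, H, A, N) cross-attention weights.
    """
    heads = params.config.heads
    key_bias = np.where(memory_mask[:, None, None, :], 0.0, MASK_NEG).astype(np.float32)
    h = atoms
    attn_layers: list[np.ndarray] = []
    for layer in params.layers:
        attended, weights = multi_head_attention(
            layer.wq(h), layer.wk(memory), layer.wv(memory), key_bias, heads, layer.wo)
        if retain_attention:
            attn_layers.append(weights)
        h = layer.ln1(nn.add(h, attended))
        ff = layer.ff2(nn.relu(layer.ff1(h)))
        h = layer.ln2(nn.add(h, ff))
    # learned softmax pooling over (real) atoms
    B, A, d = h.shape
    pool_bias = np.where(atom_mask, 0.0, MASK_NEG).astype(np.float32)
    w = nn.softmax(nn.reshape(params.pool(h), (B, A)), bias=pool_bias)
    pooled = nn.sum_axis(nn.mul(nn.reshape(w, (B, A, 1)), h), axis=1)
    logits = nn.reshape(params.head2(nn.relu(params.head1(pooled))), (B,))
    return logits, attn_layers


def decode(protein: EncodedProtein, compound: np.ndarray, params: DecoderParams,
           retain_attention: bool = True) -> PredictionResult:
    """Score one already-encoded pair (compound is an (a, d) atom embedding)."""
    if compound.ndim != 2 or compound.shape[1] != params.config.d_model:
        raise ValueError(f"compound embedding must be (a, {params.config.d_model})")
    atoms = nn.constant(compound[None])
    atom_mask = np.ones((1, compound.shape[0]), dtype=bool)
    memory = nn.constant(protein.matrix[None])
    logits, attn = decoder_forward(atoms, atom_mask, memory, protein.mask[None],
                                   params, retain_attention)
    z = float(logits.data[0])
    attention = np.stack([a[0] for a in attn]) if attn else None
    return PredictionResult("", "", probability=float(1 / (1 + np.exp(-z))),
                            logit=z, attention=attention,
                            provenance=protein.provenance, mask=protein.mask)


class CPIModel:
    """Compound GNN + region encoder + cross-attention decoder.

    Holds the word2vec vocabulary, receptor/compound featurisation
    caches, and every learned tensor. Deterministic for a fixed seed.
    """

    def __init__(self, config: EncoderConfig, vocab: Word2VecVocab, seed: int = 0):
        self.config = config
        self.vocab = vocab
        if config.whole_sequence:
            self.regions = ("FULL",)
        else:
            self.regions = region_order(config.include_ecls)
        rng = np.random.default_rng(seed)
        self.gnn = GNNParams(rng, d_out=config.d_model, rounds=config.gnn_rounds)
        self.encoder = HelixEncoderParams(rng, config, len(self.regions))
        self.decoder = DecoderParams(rng, config)
        self._stack_cache: dict[str, PaddedRegionStack] = {}
        self._graph_cache: dict[str, MolecularGraph] = {}

    # -- parameters ------------------------------------------------------
    def parameters(self) -> list[nn.Tensor]:
        return (self.gnn.parameters() + self.encoder.parameters()
                + self.decoder.parameters())

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, arr in zip(self.parameters(), state, strict=True):
            p.data = arr.copy()

    def save(self, path) -> None:
        np.savez(path, *[p.data for p in self.parameters()])

    def load(self, path) -> None:
        with np.load(path) as z:
            self.load_state([z[k] for k in z.files])

    # -- featurisation ---------------------------------------------------
    def featurize_receptor(self, receptor: ReceptorRecord) -> PaddedRegionStack:
        cached = self._stack_cache.get(receptor.accession)
        if cached is not None:
            return cached
        if self.config.whole_sequence:
            segments = whole_sequence_segments(receptor)
        else:
            segments = split_regions(receptor, self.config.include_ecls)
        stack = pad_and_stack(embed_segments(segments, self.vocab))
        self._stack_cache[receptor.accession] = stack
        return stack

    def featurize_compound(self, smiles: str) -> MolecularGraph:
        cached = self._graph_cache.get(smiles)
        if cached is not None:
            return cached
        graph = smiles_to_graph(smiles)
        self._graph_cache[smiles] = graph
        return graph

    # -- forward ---------------------------------------------------------
    def _compound_batch(self, graphs: list[MolecularGraph]):
        A = max(g.n_atoms for g in graphs)
        B = len(graphs)
        feats = np.zeros((B, A, graphs[0].atom_features.shape[1]), dtype=np.float32)
        nadj = np.zeros((B, A, A), dtype=np.float32)
        mask = np.zeros((B, A), dtype=bool)
        for i, g in enumerate(graphs):
            a = g.n_atoms
            feats[i, :a] = g.atom_features
            nadj[i, :a, :a] = normalized_adjacency(g.adjacency)
            mask[i, :a] = True
        return nn.constant(feats), nn.constant(nadj), mask

    def forward(self, stacks: list[PaddedRegionStack], protein_idx: np.ndarray,
                graphs: list[MolecularGraph], retain_attention: bool = False):
        """Score a batch of pairs.

        ``stacks`` holds the unique receptors of the batch and
        ``protein_idx[i]`` points each pair at its receptor, so every
        receptor is encoded once per step.
        Returns (logits tensor (B,), memory mask (B, N), attention list).
        """
        memory_u, mask_u = encode_batch(stacks, self.encoder)
        memory = nn.gather(memory_u, protein_idx)
        memory_mask = mask_u[protein_idx]
        feats, nadj, atom_mask = self._compound_batch(graphs)
        atoms = gnn_forward(feats, nadj, self.gnn)
        logits, attn = decoder_forward(atoms, atom_mask, memory, memory_mask,
                                       self.decoder, retain_attention)
        return logits, memory_mask, attn


def write_predictions(results: list[PredictionResult], path) -> None:
    """Prediction TSV: accession, smiles, score, label (blank if unknown)."""
    with open(path, "w") as fh:
        fh.write("accession\tsmiles\tscore\tlabel\n")
        for r in results:
            fh.write(f"{r.accession}\t{r.smiles}\t{r.probability:.6f}\t"
                     f"{r.label or ''}\n")


def write_attention_dump(results: list[PredictionResult], path) -> None:
    """Compressed array file of cross-attention tensors keyed by pair id."""
    arrays = {f"{r.accession}|{r.smiles}": r.attention
              for r in results if r.attention is not None}
    if not arrays:
        raise ValueError("no results carry attention; score with retain_attention=True")
    np.savez_compressed(path, **arrays)


def predict_batch(model: CPIModel, pairs, receptors: dict[str, ReceptorRecord],
                  batch_size: int = 64, retain_attention: bool = False
                  ) -> tuple[list[PredictionResult], list[tuple]]:
    """Score (accession, smiles[, label]) pairs or InteractionRecords.

    Order-preserving and batch-size invariant (same scores whether
    batched or one-by-one, within float tolerance). Unfeaturizable
    pairs are skipped and reported in the second return value.
    """
    norm: list[tuple[str, str, str | None]] = []
    for p in pairs:
        if isinstance(p, InteractionRecord):
            norm.append((p.accession, p.smiles, p.label))
        else:
            acc, smi = p[0], p[1]
            norm.append((acc, smi, p[2] if len(p) > 2 else None))

    results: list[PredictionResult] = []
    skipped: list[tuple] = []
    usable: list[tuple[int, str, str, str | None]] = []
    for i, (acc, smi, lab) in enumerate(norm):
        if acc not in receptors:
            skipped.append((acc, smi, "unknown accession"))
            continue
        try:
            model.featurize_compound(smi)
        except InvalidSmilesError as exc:
            logger.info("skipping pair (%s, %s): %s", acc, smi, exc)
            skipped.append((acc, smi, str(exc)))
            continue
        usable.append((i, acc, smi, lab))

    for s0 in range(0, len(usable), batch_size):
        chunk = usable[s0:s0 + batch_size]
        accs = [acc for _, acc, _, _ in chunk]
        uniq = sorted(set(accs))
        acc_to_u = {a: j for j, a in enumerate(uniq)}
        stacks = [model.featurize_receptor(receptors[a]) for a in uniq]
        idx = np.array([acc_to_u[a] for a in accs])
        graphs = [model.featurize_compound(smi) for _, _, smi, _ in chunk]
        logits, memory_mask, attn = model.forward(stacks, idx, graphs,
                                                  retain_attention)
        P = max(s.p_max for s in stacks)
        for row, (_, acc, smi, lab) in enumerate(chunk):
            st = stacks[acc_to_u[acc]]
            z = float(logits.data[row])
            res = PredictionResult(acc, smi, probability=float(1 / (1 + np.exp(-z))),
                                  logit=z, label=lab)
            if retain_attention:
                # crop batch padding back to this receptor's own p_max layout
                cols = np.concatenate([np.arange(r * P, r * P + st.p_max)
                                       for r in range(st.n_regions)])
                a = graphs[row].n_atoms
                res.attention = np.stack([layer[row][:, :a, :][:, :, cols]
                                          for layer in attn])
                res.provenance = tuple((rid, t) for rid in st.region_order
                                       for t in range(st.p_max))
                res.mask = st.mask.reshape(-1)
            results.append(res)
    return results, skipped
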