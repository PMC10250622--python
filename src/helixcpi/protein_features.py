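"""Region segmentation and word2vec embedding of receptor sequences.

A receptor is cut into its seven transmembrane helices (optionally with
extracellular loops interleaved at their anatomical slots), each segment
is tokenised into overlapping 3-mers, and every token is mapped to a
100-dimensional vector from a skip-gram word2vec model trained on the
training-split segment corpus. A segment of L residues therefore
becomes a (L - k + 1) x 100 matrix.

The skip-gram model (negative sampling) is implemented here directly in
numpy; it is deterministic for a fixed seed and persists as a plain
tab-separated vector table with a JSON sidecar.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import ECL_REGIONS, TM_REGIONS, ReceptorRecord

logger = logging.getLogger(__name__)

#: anatomical slot of each extracellular loop: ECLn sits after this helix
ECL_AFTER = {"ECL1": "TM2", "ECL2": "TM4", "ECL3": "TM6"}


@dataclass(frozen=True)
class RegionSegments:
    """Ordered (region_id, subsequence) pairs in anatomical order."""
    accession: str
    segments: tuple[tuple[str, str], ...]

    @property
    def order(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.segments)


@dataclass(frozen=True)
class EmbeddedRegion:
    region_id: str
    matrix: np.ndarray  # (p_i, dim)


def region_order(include_ecls: Iterable[str] = ()) -> tuple[str, ...]:
    """TM1..TM7 with requested ECLs interleaved at their anatomical slot
    (ECL1 between TM2/TM3, ECL2 between TM4/TM5, ECL3 between TM6/TM7)."""
    include = set(include_ecls)
    unknown = include - set(ECL_REGIONS)
    if unknown:
        raise ValueError(f"unknown extracellular loops: {sorted(unknown)}")
    order: list[str] = []
    for tm in TM_REGIONS:
        order.append(tm)
        for ecl, after in ECL_AFTER.items():
            if after == tm and ecl in include:
                order.append(ecl)
    return tuple(order)


def split_regions(receptor: ReceptorRecord,
                  include_ecls: Iterable[str] = ()) -> RegionSegments:
    """Slice the annotated helix (and requested loop) subsequences."""
    segments = []
    for rid in region_order(include_ecls):
        try:
            sub = receptor.region_sequence(rid)
        except KeyError:
            raise ValueError(f"{receptor.accession}: missing region {rid}") from None
        segments.append((rid, sub))
    return RegionSegments(receptor.accession, tuple(segments))


def whole_sequence_segments(receptor: ReceptorRecord) -> RegionSegments:
    """The entire sequence as a single pseudo-region (whole-sequence baseline)."""
    return RegionSegments(receptor.accession, (("FULL", receptor.sequence),))


def tokenize(sequence: str, k: int = 3, stride: int = 1) -> list[str]:
    """Overlapping k-mers; a sequence of L residues yields L-k+1 tokens."""
    if len(sequence) < k:
        return []
    return [sequence[i:i + k] for i in range(0, len(sequence) - k + 1, stride)]


@dataclass
class Word2VecVocab:
    """Token -> vector table with its training configuration.

    Out-of-vocabulary tokens map to the zero vector (mask-friendly).
    """
    index: dict[str, int]
    vectors: np.ndarray  # (V, dim) float32
    k: int
    stride: int
    seed: int
    corpus_digest: str

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, token: str) -> np.ndarray:
        i = self.index.get(token)
        if i is None:
            return np.zeros(self.dim, dtype=np.float32)
        return self.vectors[i]

    def embed_tokens(self, tokens: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(tokens), self.dim), dtype=np.float32)
        for j, t in enumerate(tokens):
            i = self.index.get(t)
            if i is not None:
                out[j] = self.vectors[i]
        return out

    def save(self, path: str | Path) -> None:
        path = Path(path)
        tokens = sorted(self.index, key=self.index.get)
        with open(path, "w") as fh:
            for t in tokens:
                row = "\t".join(f"{v:.6g}" for v in self.vectors[self.index[t]])
                fh.write(f"{t}\t{row}\n")
        sidecar = {"k": self.k, "stride": self.stride, "seed": self.seed,
                   "dim": self.dim, "corpus_digest": self.corpus_digest}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Word2VecVocab":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        index, rows = {}, []
        with open(path) as fh:
            for i, line in enumerate(fh):
                parts = line.rstrip("\n").split("\t")
                index[parts[0]] = i
                rows.append([float(v) for v in parts[1:]])
        return cls(index, np.asarray(rows, dtype=np.float32),
                   meta["k"], meta["stride"], meta["seed"], meta["corpus_digest"])


def _corpus_digest(sentences: Sequence[Sequence[str]]) -> str:
    h = hashlib.sha256()
    for s in sentences:
        h.update(" ".join(s).encode())
        h.update(b"\n")
    return h.hexdigest()[:16]


def train_word2vec(corpus: Sequence[str], seed: int = 0, *, k: int = 3,
                   stride: int = 1, dim: int = 100, window: int = 5,
                   negative: int = 5, epochs: int = 3,
                   lr: float = 0.025, normalize: bool = True) -> Word2VecVocab:
    """Train skip-gram word2vec with negative sampling on k-mer tokens.

    ``corpus`` is a list of amino-acid strings (region segments); each
    is tokenised into overlapping k-mers and treated as one sentence.
    Deterministic for a fixed seed (single worker by construction).

    With ``normalize`` (default) the trained vectors are L2-normalised,
    the usual convention when embeddings feed a downstream model: on a
    segment-sized corpus the raw SGNS vectors stay near their tiny
    initialisation scale, which would starve the encoder of protein
    signal.
    """
    if not corpus:
        raise ValueError("word2vec corpus is empty")
    sentences = [tokenize(s, k, stride) for s in corpus]
    sentences = [s for s in sentences if s]
    if not sentences:
        raise ValueError(f"every corpus sequence is shorter than k={k}")

    counts: dict[str, int] = {}
    for s in sentences:
        for t in s:
            counts[t] = counts.get(t, 0) + 1
    vocab_tokens = sorted(counts, key=lambda t: (-counts[t], t))
    index = {t: i for i, t in enumerate(vocab_tokens)}
    V = len(index)

    rng = np.random.default_rng(seed)
    vec_in = ((rng.random((V, dim)).astype(np.float32) - 0.5) / dim)
    vec_out = np.zeros((V, dim), dtype=np.float32)

    # negative-sampling table from the unigram^0.75 distribution
    freq = np.array([counts[t] for t in vocab_tokens], dtype=np.float64) ** 0.75
    neg_prob = freq / freq.sum()

    centers, contexts = [], []
    for s in sentences:
        ids = [index[t] for t in s]
        for i, c in enumerate(ids):
            lo, hi = max(0, i - window), min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(c)
                    contexts.append(ids[j])
    centers = np.asarray(centers, dtype=np.int64)
    contexts = np.asarray(contexts, dtype=np.int64)
    n_pairs = len(centers)

    batch = 1024
    for epoch in range(epochs):
        order = rng.permutation(n_pairs)
        alpha = lr * (1.0 - epoch / max(epochs, 1))
        for s0 in range(0, n_pairs, batch):
            sel = order[s0:s0 + batch]
            c, o = centers[sel], contexts[sel]
            neg = rng.choice(V, size=(len(sel), negative), p=neg_prob)
            vc = vec_in[c]                                   # (B, d)
            targets = np.concatenate([o[:, None], neg], axis=1)  # (B, 1+neg)
            vt = vec_out[targets]                            # (B, 1+neg, d)
            score = 1.0 / (1.0 + np.exp(-np.einsum("bd,bnd->bn", vc, vt)))
            y = np.zeros_like(score)
            y[:, 0] = 1.0
            err = (y - score).astype(np.float32)             # (B, 1+neg)
            grad_c = np.einsum("bn,bnd->bd", err, vt)
            grad_t = err[:, :, None] * vc[:, None, :]
            np.add.at(vec_in, c, alpha * grad_c)
            np.add.at(vec_out, targets.ravel(),
                      alpha * grad_t.reshape(-1, vec_in.shape[1]))

    if normalize:
        norms = np.linalg.norm(vec_in, axis=1, keepdims=True)
        vec_in = (vec_in / np.maximum(norms, 1e-12)).astype(np.float32)
    return Word2VecVocab(index, vec_in, k, stride, seed, _corpus_digest(sentences))


def embed_region(region_id: str, segment: str, vocab: Word2VecVocab) -> EmbeddedRegion:
    """Embed one segment as a (L-k+1) x dim matrix of k-mer vectors."""
    tokens = tokenize(segment, vocab.k, vocab.stride)
    if not tokens:
        raise ValueError(
            f"segment {region_id!r} of length {len(segment)} is shorter than k={vocab.k}")
    return EmbeddedRegion(region_id, vocab.embed_tokens(tokens))


def embed_segments(segments: RegionSegments, vocab: Word2VecVocab) -> list[EmbeddedRegion]:
    return [embed_region(rid, seg, vocab) for rid, seg in segments.segments]


def segment_corpus(receptors: Iterable[ReceptorRecord],
                   include_ecls: Iterable[str] = (),
                   whole_sequence: bool = False) -> list[str]:
    """Collect the segment strings used to train word2vec (train split only)."""
    out = []
    for rec in receptors:
        if whole_sequence:
            out.append(rec.sequence)
        else:
            out.extend(seg for _, seg in split_regions(rec, include_ecls).segments)
    return out
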