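"""Molecular-graph featurisation of compounds from SMILES.

Each heavy atom becomes a 34-dimensional feature vector and the
molecule an adjacency matrix with self-loops. A light graph neural
network (rounds of normalised-adjacency neighbour averaging with
learned linear maps) lifts the a x 34 atom features to the a x 64 atom
embedding consumed by the interaction decoder.

34-dimensional atom feature schema (fixed order):

====================  ====  =========================================
block                 dims  encoding
====================  ====  =========================================
element               15    one-hot over C N O S F Cl Br I P B Si Se
                            Na K + other
degree                6     one-hot over 0..5 heavy-atom neighbours
formal charge         1     signed integer value
radical electrons     1     integer value
hybridisation         5     one-hot over SP SP2 SP3 SP3D SP3D2
aromaticity           1     flag
total hydrogens       5     one-hot over 0..4 (implicit + explicit)
====================  ====  =========================================

Hydrogens are implicit and stereochemistry is ignored.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger

from . import nn

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")  # rdkit parse noise goes through our logger

ATOM_SYMBOLS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B",
                "Si", "Se", "Na", "K")  # + 1 "other" slot = 15
HYBRIDIZATIONS = (
    Chem.rdchem.HybridizationType.SP,
    Chem.rdchem.HybridizationType.SP2,
    Chem.rdchem.HybridizationType.SP3,
    Chem.rdchem.HybridizationType.SP3D,
    Chem.rdchem.HybridizationType.SP3D2,
)
N_ATOM_FEATURES = len(ATOM_SYMBOLS) + 1 + 6 + 1 + 1 + len(HYBRIDIZATIONS) + 1 + 5
assert N_ATOM_FEATURES == 34


class InvalidSmilesError(ValueError):
    pass


@dataclass(frozen=True)
class MolecularGraph:
    smiles: str
    atom_features: np.ndarray  # (a, 34) float32
    adjacency: np.ndarray      # (a, a) symmetric 0/1 with self-loops

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]


def _one_hot(value, choices) -> list[float]:
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def atom_features(atom: Chem.Atom) -> np.ndarray:
    feats = (
        _one_hot(atom.GetSymbol(), list(ATOM_SYMBOLS))
        + _one_hot(atom.GetDegree(), [0, 1, 2, 3, 4])[:6]
        + [float(atom.GetFormalCharge()), float(atom.GetNumRadicalElectrons())]
        + _one_hot(atom.GetHybridization(), list(HYBRIDIZATIONS))[:5]
        + [1.0 if atom.GetIsAromatic() else 0.0]
        + _one_hot(atom.GetTotalNumHs(), [0, 1, 2, 3])[:5]
    )
    vec = np.asarray(feats, dtype=np.float32)
    assert vec.shape == (N_ATOM_FEATURES,)
    return vec


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES into atom features + self-looped adjacency.

    Raises :class:`InvalidSmilesError` on unparseable input; callers in
    batch pipelines catch it and record a skip rather than crash.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"unparseable SMILES: {smiles!r}")
    a = mol.GetNumAtoms()
    if a == 0:
        raise InvalidSmilesError(f"SMILES has no heavy atoms: {smiles!r}")
    feats = np.stack([atom_features(at) for at in mol.GetAtoms()])
    adj = np.eye(a, dtype=np.float32)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[i, j] = adj[j, i] = 1.0
    return MolecularGraph(smiles, feats, adj)


def normalized_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Row-normalise so each atom averages over itself and its neighbours."""
    deg = adjacency.sum(axis=-1, keepdims=True)
    return adjacency / np.maximum(deg, 1.0)


class GNNParams:
    """Learned linear maps for the neighbour-averaging rounds (34 -> 64 -> ...)."""

    def __init__(self, rng: np.random.Generator, d_in: int = N_ATOM_FEATURES,
                 d_out: int = 64, rounds: int = 3):
        self.rounds = rounds
        # relu layers: sqrt(2) gain keeps activation scale through the rounds
        self.layers = [nn.Linear(rng, d_in if i == 0 else d_out, d_out,
                                 f"gnn{i}", gain=math.sqrt(2.0))
                       for i in range(rounds)]

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


def gnn_forward(feats: nn.Tensor, norm_adj: nn.Tensor, params: GNNParams) -> nn.Tensor:
    """One molecule or a padded batch: h <- relu(A_norm @ h @ W + b), ``rounds`` times.

    Permutation-equivariant by construction: relabeling atoms permutes
    the rows of both inputs and hence of the output identically.
    """
    h = feats
    for layer in params.layers:
        h = nn.relu(nn.matmul(norm_adj, layer(h)))
    return h


def gnn_embed(graph: MolecularGraph, params: GNNParams) -> np.ndarray:
    """Embed a single molecule as an (a, 64) array (inference helper)."""
    if graph.n_atoms == 0:
        raise ValueError("empty molecular graph")
    feats = nn.constant(graph.atom_features)
    na = nn.constant(normalized_adjacency(graph.adjacency))
    return gnn_forward(feats, na, params).data
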