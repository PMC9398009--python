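"""Molecular graphs and graph-convolutional neural fingerprints.

A SMILES string is parsed with RDKit into a heavy-atom graph (implicit
hydrogens). Each layer of the fingerprint network propagates atom states
through the degree-normalized adjacency with self-loops,

    H^{l+1} = act( D^{-1} (A + I) H^l W^l ),

where D is the diagonal degree matrix of (A + I). The default activation is
a row-wise softmax over the feature axis, which keeps every atom embedding
on the probability simplex; a conventional ReLU is available via
``activation="relu"``. The molecule-level fingerprint pools atom embeddings
(sum by default), and the per-atom embeddings are retained for the
drug-gene attention component downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from ._autodiff import Tensor

RDLogger.DisableLog("rdApp.*")  # rdkit parse warnings are surfaced as exceptions

# Featurization config: element one-hot (with catch-all), degree one-hot,
# aromatic flag, formal charge. Versioned so checkpoints can assert on it.
ATOM_VOCAB = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "other"]
MAX_DEGREE = 5
FEATURIZATION_VERSION = "element10-degree6-aromatic-charge-v1"
N_ATOM_FEATURES = len(ATOM_VOCAB) + (MAX_DEGREE + 1) + 2


@dataclass
class MolGraph:
    """Heavy-atom graph of one compound."""

    n_atoms: int
    atom_features: np.ndarray  # (n_atoms, F0)
    adjacency: np.ndarray      # (n_atoms, n_atoms), binary, zero diagonal
    bonds: list[tuple[int, int, str]]
    smiles: str = ""

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero (self-loops are added internally)")
        if self.atom_features.shape[0] != self.n_atoms:
            raise ValueError("atom_features row count must equal n_atoms")


@dataclass
class GCNParams:
    """Per-layer weight matrices of the fingerprint network."""

    weights: list  # list of Tensor, W^l of shape (d_l, d_{l+1})
    activation: str = "softmax"  # {"softmax", "relu"}

    def __post_init__(self):
        for wa, wb in zip(self.weights, self.weights[1:]):
            if wa.shape[1] != wb.shape[0]:
                raise ValueError(
                    f"layer dims do not chain: {wa.shape} -> {wb.shape}"
                )

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def out_dim(self) -> int:
        return self.weights[-1].shape[1] if self.weights else N_ATOM_FEATURES


@dataclass
class NeuralFingerprint:
    """Atom embeddings after the final layer plus a pooled molecule vector."""

    atom_embeddings: np.ndarray  # (n_atoms, d)
    pooled: np.ndarray           # (d,)


def smiles_to_graph(smiles: str) -> MolGraph:
    """Parse a SMILES string into a featurized heavy-atom graph."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    n = mol.GetNumAtoms()
    feats = np.zeros((n, N_ATOM_FEATURES))
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        sym = atom.GetSymbol()
        feats[i, ATOM_VOCAB.index(sym) if sym in ATOM_VOCAB else len(ATOM_VOCAB) - 1] = 1.0
        deg = min(atom.GetDegree(), MAX_DEGREE)
        feats[i, len(ATOM_VOCAB) + deg] = 1.0
        feats[i, len(ATOM_VOCAB) + MAX_DEGREE + 1] = float(atom.GetIsAromatic())
        feats[i, len(ATOM_VOCAB) + MAX_DEGREE + 2] = float(atom.GetFormalCharge())
    adj = np.zeros((n, n))
    bonds = []
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[a, b] = adj[b, a] = 1.0
        bonds.append((a, b, str(bond.GetBondType())))
    return MolGraph(n_atoms=n, atom_features=feats, adjacency=adj, bonds=bonds,
                    smiles=smiles)


def _propagate(h: Tensor, adj: np.ndarray, w: Tensor, activation: str) -> Tensor:
    n = adj.shape[0]
    if h.shape[0] != n:
        raise ValueError(f"H has {h.shape[0]} rows but adjacency is {n}x{n}")
    if h.shape[1] != w.shape[0]:
        raise ValueError(f"H columns {h.shape[1]} do not match W rows {w.shape[0]}")
    a_hat = adj + np.eye(n)
    norm = a_hat / a_hat.sum(axis=1, keepdims=True)  # D^{-1}(A+I)
    msg = Tensor(norm) @ h @ w
    if activation == "softmax":
        return msg.softmax(axis=-1)
    if activation == "relu":
        return msg.relu()
    raise ValueError(f"unknown activation {activation!r}")


def gcn_layer(h: np.ndarray, adj: np.ndarray, w: np.ndarray,
              activation: str = "softmax") -> np.ndarray:
    """One propagation step act(D^{-1}(A+I) H W); rows sum to 1 under softmax."""
    return _propagate(Tensor(np.atleast_2d(h)), np.asarray(adj, dtype=float),
                      Tensor(np.atleast_2d(w)), activation).data


def neural_fingerprint(g: MolGraph, p: GCNParams, pooling: str = "sum") -> NeuralFingerprint:
    """Stack the fingerprint layers and pool atoms into a molecule vector."""
    out = _fingerprint_tensors(g, p, pooling)
    return NeuralFingerprint(atom_embeddings=out[0].data, pooled=out[1].data)


def _fingerprint_tensors(g: MolGraph, p: GCNParams, pooling: str = "sum"
                         ) -> tuple[Tensor, Tensor]:
    """Differentiable path used by the training loop."""
    if g.n_atoms == 0:
        raise ValueError("empty molecule has no atoms to fingerprint")
    h = Tensor(g.atom_features)
    if p.weights and g.atom_features.shape[1] != p.weights[0].shape[0]:
        raise ValueError(
            f"atom feature dim {g.atom_features.shape[1]} does not match "
            f"first layer input dim {p.weights[0].shape[0]}"
        )
    for w in p.weights:
        h = _propagate(h, g.adjacency, Tensor.as_tensor(w), p.activation)
    if pooling == "sum":
        pooled = h.sum(axis=0)
    elif pooling == "mean":
        pooled = h.mean(axis=0)
    elif pooling == "max":
        pooled = h.max(axis=0)
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    return h, pooled


def init_gcn_params(rng: np.random.Generator, dims: list[int],
                    activation: str = "softmax") -> GCNParams:
    """Glorot-initialized layer weights for dims [F0, d1, ..., dL]."""
    weights = []
    for din, dout in zip(dims, dims[1:]):
        scale = np.sqrt(2.0 / (din + dout))
        weights.append(Tensor(rng.normal(0.0, scale, size=(din, dout)),
                              requires_grad=True))
    return GCNParams(weights=weights, activation=activation)
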