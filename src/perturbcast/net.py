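"""Assembly of the four input components and the task-specific heads.

One forward pass fuses:

1. the pooled graph-convolutional drug fingerprint,
2. a drug-gene attention map in which each panel gene's embedding queries
   the atom (substructure) embeddings of the drug,
3. the cell embedding produced by the expression-profile encoder, and
4. a categorical dosage embedding (doses form a finite vocabulary),

into a concatenated representation feeding fully connected task heads:
per-gene differential expression regression (dgx), binary up/down gene
regulation classification (logistic on the per-gene scores), and scalar
cell-viability regression.

The drug-gene attention supplies both a per-gene context matrix (fed to the
per-gene regression head) and its gene-average (part of the fused vector).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._autodiff import Tensor, concat
from . import chem_graph
from .chem_graph import GCNParams, MolGraph
from .cell_transformer import (
    CellDecoderParams,
    CellEncoderParams,
    encode_cell_tensor,
    init_decoder,
    init_encoder,
    _linear,
)

TASKS = ("dgx_regression", "dgx_binary", "viability")


# ---------------------------------------------------------------------------
# Inputs consumed as tables
# ---------------------------------------------------------------------------

@dataclass
class GeneEmbeddingTable:
    """Precomputed per-gene embedding vectors (one row per panel gene)."""

    gene_ids: list[str]
    vectors: np.ndarray  # (G, d_g)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape[0] != len(self.gene_ids):
            raise ValueError("one embedding row per panel gene required")
        if np.isnan(self.vectors).any():
            raise ValueError("gene embeddings contain NaN")

    @classmethod
    def load(cls, path) -> "GeneEmbeddingTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(gene_ids=[str(g) for g in df.index], vectors=df.to_numpy(float))

    def save(self, path) -> None:
        pd.DataFrame(self.vectors, index=self.gene_ids).to_csv(
            path, sep="\t", index_label="gene_id", float_format="%.17g")

    @classmethod
    def random(cls, gene_ids: list[str], d_g: int, rng: np.random.Generator
               ) -> "GeneEmbeddingTable":
        """Near-orthogonal random embeddings for synthetic runs (a pluggable
        random-walk embedding generator can be substituted at full scale)."""
        return cls(gene_ids=list(gene_ids),
                   vectors=rng.normal(0.0, 1.0 / np.sqrt(d_g), size=(len(gene_ids), d_g)))


@dataclass
class DosageVocab:
    """Ordered dose vocabulary with a learned embedding per dose."""

    doses: np.ndarray           # strictly increasing, positive (uM)
    embedding: Tensor = None    # (|vocab|, d_dose)

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        if np.any(self.doses <= 0):
            raise ValueError("doses must be positive")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")

    def index(self, dose: float, nearest_log: bool = False) -> int:
        if dose <= 0:
            raise ValueError("dose must be positive")
        hits = np.nonzero(np.isclose(self.doses, dose, rtol=1e-9, atol=0.0))[0]
        if hits.size:
            return int(hits[0])
        if not nearest_log:
            raise ValueError(
                f"dose {dose} not in vocabulary {self.doses.tolist()} "
                "(strict mode; pass nearest_log=True for grid sweeps)"
            )
        return int(np.argmin(np.abs(np.log(self.doses) - np.log(dose))))


def init_dosage_vocab(rng: np.random.Generator, doses, d_dose: int = 8) -> DosageVocab:
    v = DosageVocab(doses=np.asarray(doses, dtype=float))
    v.embedding = Tensor(rng.normal(0.0, 0.5, size=(len(v.doses), d_dose)),
                         requires_grad=True)
    return v


def embed_dosage(dose: float, v: DosageVocab, nearest_log: bool = False) -> np.ndarray:
    """One-hot dose lookup through the embedding matrix."""
    return v.embedding.data[v.index(dose, nearest_log=nearest_log)].copy()


# ---------------------------------------------------------------------------
# Binary labels
# ---------------------------------------------------------------------------

@dataclass
class BinaryLabeling:
    up_labels: np.ndarray
    down_labels: np.ndarray
    frac: float = 0.05

    def __post_init__(self):
        if np.any(self.up_labels * self.down_labels):
            raise ValueError("up and down positive sets overlap")


def label_binary(dgx: np.ndarray, frac: float = 0.05) -> BinaryLabeling:
    """Mark the floor(frac*G) most up- and most down-regulated genes.

    Ties are broken by gene-panel order (stable sort).
    """
    dgx = np.asarray(dgx, dtype=float)
    if not 0.0 < frac < 0.5:
        raise ValueError(f"frac must be in (0, 0.5), got {frac}")
    g = dgx.shape[0]
    n_pos = int(np.floor(frac * g))
    if n_pos == 0:
        raise ValueError(f"frac={frac} with G={g} selects zero genes")
    up_idx = np.argsort(-dgx, kind="stable")[:n_pos]
    down_idx = np.argsort(dgx, kind="stable")[:n_pos]
    up = np.zeros(g, dtype=int)
    down = np.zeros(g, dtype=int)
    up[up_idx] = 1
    down[down_idx] = 1
    return BinaryLabeling(up_labels=up, down_labels=down, frac=frac)


# ---------------------------------------------------------------------------
# Full parameter bundle
# ---------------------------------------------------------------------------

@dataclass
class PerturbNetParams:
    """All trainable parameters plus the fixed input tables."""

    gcn: GCNParams
    genes: GeneEmbeddingTable
    dose_vocab: DosageVocab
    encoder: CellEncoderParams
    decoder: CellDecoderParams
    attn: dict                      # wq, wk, wv (+ biases)
    fusion: list                    # [(w, b), ...] MLP on the fused vector
    heads: dict                     # task -> [(w, b), ...] per-gene or scalar stacks
    tasks: tuple = TASKS
    use_cell_context: bool = True   # ablation switch: zero the cell embedding
    fp_pooling: str = "sum"
    d_attn: int = 16

    # -- parameter groups (Procedure notation: E encoder, D decoder, S rest) --
    def encoder_parameters(self) -> list[Tensor]:
        return self.encoder.parameters()

    def decoder_parameters(self) -> list[Tensor]:
        return self.decoder.parameters()

    def supervised_parameters(self) -> list[Tensor]:
        ps = list(self.gcn.weights)
        ps.extend(t for t in self.attn.values())
        ps.append(self.dose_vocab.embedding)
        ps.extend(t for pair in self.fusion for t in pair)
        for head in self.heads.values():
            for key, val in head.items():
                if key == "stack":
                    ps.extend(t for pair in val for t in pair)
                else:
                    ps.append(val)
        return ps

    def all_parameters(self) -> list[Tensor]:
        return self.encoder_parameters() + self.decoder_parameters() + \
            self.supervised_parameters()

    def snapshot(self) -> dict[int, np.ndarray]:
        return {i: p.data.copy() for i, p in enumerate(self.all_parameters())}

    def restore(self, snap: dict[int, np.ndarray]) -> None:
        for i, p in enumerate(self.all_parameters()):
            p.data = snap[i].copy()


def init_params(rng: np.random.Generator, genes: GeneEmbeddingTable,
                doses, tasks=TASKS, gcn_dims=(32, 32), d_attn: int = 16,
                attn_heads: int = 1, d_dose: int = 8, d_model: int = 32,
                d_embed: int = 32, d_hidden: int = 64, encoder_layers: int = 1,
                noise_std: float = 0.1, dropout_rate: float = 0.1,
                gcn_activation: str = "softmax", use_cell_context: bool = True,
                input_loc: np.ndarray | None = None,
                input_scale: np.ndarray | None = None) -> PerturbNetParams:
    """Build a freshly initialized parameter bundle for a gene panel."""
    unknown = set(tasks) - set(TASKS)
    if unknown:
        raise ValueError(f"unknown tasks: {sorted(unknown)}")
    g = len(genes.gene_ids)
    d_g = genes.vectors.shape[1]
    gcn = chem_graph.init_gcn_params(
        rng, [chem_graph.N_ATOM_FEATURES, *gcn_dims], activation=gcn_activation)
    d_fp = gcn.out_dim
    attn = {}
    attn["wq"], attn["wq_b"] = _linear(rng, d_g, d_attn)
    attn["wk"], attn["wk_b"] = _linear(rng, d_fp, d_attn)
    attn["wv"], attn["wv_b"] = _linear(rng, d_fp, d_attn)
    encoder = init_encoder(rng, g, d_model=d_model, d_embed=d_embed,
                           n_layers=encoder_layers, noise_std=noise_std,
                           dropout_rate=dropout_rate, input_loc=input_loc,
                           input_scale=input_scale)
    decoder = init_decoder(rng, d_embed, g)
    vocab = init_dosage_vocab(rng, doses, d_dose=d_dose)
    # factorized bilinear drug-by-cell features make context interactions
    # directly trainable instead of relying on deep mixing
    d_bilin = 32
    attn["bilin_d"], attn["bilin_d_b"] = _linear(rng, d_fp + d_attn, d_bilin)
    attn["bilin_c"], attn["bilin_c_b"] = _linear(rng, d_embed, d_bilin)
    d_fused = d_fp + d_attn + d_embed + d_dose + d_bilin
    fusion = [_linear(rng, d_fused, d_hidden)]
    heads = {}
    for task in tasks:
        if task in ("dgx_regression", "dgx_binary"):
            # hidden -> G output layer (per-gene weights) plus a per-gene
            # contribution read off the drug-gene attention context
            w_out, b_out = _linear(rng, d_hidden, g)
            w_ctx = Tensor(rng.normal(0.0, np.sqrt(1.0 / d_attn), size=(d_attn,)),
                           requires_grad=True)
            heads[task] = {"w_out": w_out, "b_out": b_out, "w_ctx": w_ctx}
        elif task == "viability":
            heads[task] = {"stack": [_linear(rng, d_hidden, d_hidden // 2),
                                     _linear(rng, d_hidden // 2, 1)]}
    return PerturbNetParams(gcn=gcn, genes=genes, dose_vocab=vocab,
                            encoder=encoder, decoder=decoder, attn=attn,
                            fusion=fusion, heads=heads, tasks=tuple(tasks),
                            use_cell_context=use_cell_context, d_attn=d_attn)


# ---------------------------------------------------------------------------
# Forward passes
# ---------------------------------------------------------------------------

def drug_gene_attention(atom_embeddings, genes: GeneEmbeddingTable, p) -> np.ndarray:
    """Scaled dot-product attention: gene queries over atom keys/values."""
    ctx = _attention_tensor(Tensor.as_tensor(atom_embeddings), genes, p)
    return ctx.data


def _attention_tensor(atom_emb: Tensor, genes: GeneEmbeddingTable, p) -> Tensor:
    if atom_emb.shape[0] == 0:
        raise ValueError("empty molecule: no atom keys to attend over")
    q = Tensor(genes.vectors) @ p["wq"] + p["wq_b"]     # (G, d_a)
    k = atom_emb @ p["wk"] + p["wk_b"]                  # (n, d_a)
    v = atom_emb @ p["wv"] + p["wv_b"]                  # (n, d_a)
    d_a = q.shape[1]
    attn = ((q @ k.T) * (1.0 / np.sqrt(d_a))).softmax(axis=-1)
    return attn @ v                                     # (G, d_a)


def _forward_group(graph: MolGraph, basal_profile: np.ndarray, dose_idxs,
                   params: PerturbNetParams, task: str, train_mode: bool = False,
                   rng: np.random.Generator | None = None) -> list[Tensor]:
    """Shared assembly for all records of one (drug, cell) pair.

    Returns one output Tensor per dose index: shape (G,) for dgx tasks,
    scalar shape (1,) for viability.
    """
    if task not in params.heads:
        raise ValueError(f"task {task!r} not registered in this model "
                         f"(registered: {sorted(params.heads)})")
    atom_emb, pooled_fp = chem_graph._fingerprint_tensors(
        graph, params.gcn, pooling=params.fp_pooling)
    ctx = _attention_tensor(atom_emb, params.genes, params.attn)   # (G, d_a)
    ctx_mean = ctx.mean(axis=0)                                    # (d_a,)
    cell = encode_cell_tensor(basal_profile, params.encoder,
                              train_mode=train_mode, rng=rng)      # (d_embed,)
    if not params.use_cell_context:
        cell = cell * 0.0
    drug_vec = concat([pooled_fp, ctx_mean], axis=0)
    bilin = ((drug_vec @ params.attn["bilin_d"] + params.attn["bilin_d_b"]) *
             (cell @ params.attn["bilin_c"] + params.attn["bilin_c_b"]))
    outs = []
    for di in dose_idxs:
        dose_vec = params.dose_vocab.embedding[np.array([di])].reshape(-1)
        z = concat([pooled_fp, ctx_mean, cell, dose_vec, bilin], axis=0)
        h = z
        for w, b in params.fusion:
            h = (h @ w + b).tanh()  # bounded: large cell features cannot kill units
        if task == "viability":
            out = h
            stack = params.heads[task]["stack"]
            for i, (w, b) in enumerate(stack):
                out = out @ w + b
                if i < len(stack) - 1:
                    out = out.relu()
            outs.append(out)                                       # (1,)
        else:
            head = params.heads[task]
            pred = h @ head["w_out"] + head["b_out"] + ctx @ head["w_ctx"]
            outs.append(pred)                                      # (G,)
    return outs


def forward_dgx(smiles: str, basal_profile: np.ndarray, dose: float,
                params: PerturbNetParams, nearest_log: bool = False) -> np.ndarray:
    """Predict per-gene differential expression (inference mode, deterministic)."""
    graph = chem_graph.smiles_to_graph(smiles)
    di = params.dose_vocab.index(dose, nearest_log=nearest_log)
    return _forward_group(graph, basal_profile, [di], params, "dgx_regression")[0].data


def forward_binary(smiles: str, basal_profile: np.ndarray, dose: float,
                   params: PerturbNetParams, nearest_log: bool = False
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene up/down probabilities: logistic on the binary head's scores."""
    graph = chem_graph.smiles_to_graph(smiles)
    di = params.dose_vocab.index(dose, nearest_log=nearest_log)
    raw = _forward_group(graph, basal_profile, [di], params, "dgx_binary")[0]
    p_up = raw.sigmoid().data
    p_down = (-raw).sigmoid().data
    return p_up, p_down


def forward_viability(smiles: str, basal_profile: np.ndarray, dose: float,
                      params: PerturbNetParams, nearest_log: bool = False) -> float:
    """Predict scalar viability (fraction of control; unclamped)."""
    graph = chem_graph.smiles_to_graph(smiles)
    di = params.dose_vocab.index(dose, nearest_log=nearest_log)
    return float(_forward_group(graph, basal_profile, [di], params, "viability")[0].data[0])
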