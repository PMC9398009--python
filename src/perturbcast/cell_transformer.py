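"""Attention-based autoencoder over basal expression profiles.

The encoder turns a G-gene expression vector into a dense cell embedding:
each gene is one token whose embedding is the scalar expression value times
a learned per-gene identity vector (no positional encoding -- gene order is
arbitrary, identity vectors carry identity). During training, Gaussian
noise and dropout corrupt the input before the transformer; both are
skipped at inference, which makes the inference path a pure function of
(profile, parameters). Self-attention mixes the gene tokens (a learned
surrogate for gene-gene interaction structure), a max-pool over the gene
axis collapses the sequence, and a linear projection yields the embedding.
The decoder is a fully connected stack mapping the embedding back to the
G-gene profile; the autoencoder objective is mean squared error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, concat

_EPS = 1e-6


def _linear(rng: np.random.Generator, din: int, dout: int) -> tuple[Tensor, Tensor]:
    w = Tensor(rng.normal(0.0, np.sqrt(2.0 / (din + dout)), size=(din, dout)),
               requires_grad=True)
    b = Tensor(np.zeros(dout), requires_grad=True)
    return w, b


@dataclass
class CellEncoderParams:
    """Encoder parameters: corruption settings, transformer weights and the
    pooled-to-embedding projection."""

    n_genes: int
    d_model: int = 32
    n_heads: int = 4
    n_layers: int = 1
    d_ff: int = 64
    d_embed: int = 64
    noise_std: float = 0.1
    dropout_rate: float = 0.1
    input_loc: np.ndarray | None = None    # per-gene standardization (fixed)
    input_scale: np.ndarray | None = None
    gene_identity: Tensor = None  # (G, d_model)
    layers: list = field(default_factory=list)
    proj_w: Tensor = None
    proj_b: Tensor = None
    skip_w: Tensor = None  # (G, d_embed) linear path around the transformer

    def __post_init__(self):
        if self.d_embed < 1:
            raise ValueError("embedding dimension must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")

    def parameters(self) -> list[Tensor]:
        ps = [self.gene_identity]
        for layer in self.layers:
            ps.extend(layer.values())
        ps.extend([self.proj_w, self.proj_b, self.skip_w])
        return [p for p in ps if p is not None]


@dataclass
class CellDecoderParams:
    """Fully connected stack mapping an embedding back to G genes."""

    weights: list  # [(w, b), ...]

    def parameters(self) -> list[Tensor]:
        return [t for pair in self.weights for t in pair]

    @property
    def out_dim(self) -> int:
        return self.weights[-1][0].shape[1]


@dataclass
class CellEmbedding:
    vector: np.ndarray
    cell_id: str = ""

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=float)
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("cell embedding has non-finite entries")


def standardize_profile(profile: np.ndarray, p: CellEncoderParams) -> np.ndarray:
    """Apply the encoder's fixed per-gene standardization (identity if unset)."""
    if p.input_loc is not None:
        profile = (profile - p.input_loc) / p.input_scale
    return profile


def init_encoder(rng: np.random.Generator, n_genes: int, d_model: int = 32,
                 n_heads: int = 4, n_layers: int = 1, d_ff: int = 64,
                 d_embed: int = 64, noise_std: float = 0.1,
                 dropout_rate: float = 0.1,
                 input_loc: np.ndarray | None = None,
                 input_scale: np.ndarray | None = None) -> CellEncoderParams:
    p = CellEncoderParams(n_genes=n_genes, d_model=d_model, n_heads=n_heads,
                          n_layers=n_layers, d_ff=d_ff, d_embed=d_embed,
                          noise_std=noise_std, dropout_rate=dropout_rate,
                          input_loc=input_loc, input_scale=input_scale)
    p.gene_identity = Tensor(rng.normal(0.0, 1.0, size=(n_genes, d_model)),
                             requires_grad=True)
    for _ in range(n_layers):
        layer = {}
        for name in ("wq", "wk", "wv", "wo"):
            layer[name], layer[name + "_b"] = _linear(rng, d_model, d_model)
        layer["ff1"], layer["ff1_b"] = _linear(rng, d_model, d_ff)
        layer["ff2"], layer["ff2_b"] = _linear(rng, d_ff, d_model)
        p.layers.append(layer)
    p.proj_w, p.proj_b = _linear(rng, d_model, d_embed)
    p.skip_w = Tensor(rng.normal(0.0, 1.0 / np.sqrt(n_genes), size=(n_genes, d_embed)),
                      requires_grad=True)
    return p


def init_decoder(rng: np.random.Generator, d_embed: int, n_genes: int,
                 hidden: int = 128) -> CellDecoderParams:
    return CellDecoderParams(weights=[_linear(rng, d_embed, hidden),
                                      _linear(rng, hidden, n_genes)])


def _attention_block(x: Tensor, layer: dict, n_heads: int) -> Tensor:
    g, d = x.shape
    dh = d // n_heads
    q = x @ layer["wq"] + layer["wq_b"]
    k = x @ layer["wk"] + layer["wk_b"]
    v = x @ layer["wv"] + layer["wv_b"]
    heads = []
    for h in range(n_heads):
        sl = slice(h * dh, (h + 1) * dh)
        qh, kh, vh = q[:, sl], k[:, sl], v[:, sl]
        attn = ((qh @ kh.T) * (1.0 / np.sqrt(dh))).softmax(axis=-1)
        heads.append(attn @ vh)
    attended = concat(heads, axis=1) @ layer["wo"] + layer["wo_b"]
    x = x + attended  # residual; normalization-free at these desk-scale widths
    ff = ((x @ layer["ff1"] + layer["ff1_b"]).relu()) @ layer["ff2"] + layer["ff2_b"]
    return x + ff


def encode_cell_tensor(profile: np.ndarray, p: CellEncoderParams,
                       train_mode: bool = False,
                       rng: np.random.Generator | None = None) -> Tensor:
    """Differentiable encoder path; returns the embedding as a Tensor."""
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (p.n_genes,):
        raise ValueError(f"profile length {profile.shape} != ({p.n_genes},)")
    if not np.all(np.isfinite(profile)):
        raise ValueError("profile has non-finite values")
    profile = standardize_profile(profile, p)
    x_in = Tensor(profile.reshape(-1, 1))
    if train_mode and (p.noise_std > 0 or p.dropout_rate > 0):
        if rng is None:
            raise ValueError("train_mode corruption needs an rng")
        noisy = x_in + Tensor(rng.normal(0.0, p.noise_std, size=x_in.shape))
        x_in = noisy.dropout(p.dropout_rate, rng)
    tokens = x_in * p.gene_identity  # (G, d_model): scalar expression scales identity
    for layer in p.layers:
        tokens = _attention_block(tokens, layer, p.n_heads)
    pooled = tokens.max(axis=0)
    # attention path plus a linear skip from the (corrupted) profile; the
    # embedding is L2-normalized to sqrt(d_embed) so downstream fusion scales
    # stay stable while the encoder is co-trained, without the saturation a
    # squashing nonlinearity would introduce
    emb = pooled @ p.proj_w + p.proj_b + x_in.reshape(-1) @ p.skip_w
    norm = (emb.pow(2.0).sum() + 1e-12).pow(0.5)
    return emb * (np.sqrt(p.d_embed) / norm)


def encode_cell(profile: np.ndarray, p: CellEncoderParams, train_mode: bool = False,
                rng_seed: int | None = None, cell_id: str = "") -> CellEmbedding:
    rng = np.random.default_rng(rng_seed) if rng_seed is not None else None
    vec = encode_cell_tensor(profile, p, train_mode=train_mode, rng=rng)
    return CellEmbedding(vector=vec.data, cell_id=cell_id)


def decode_cell_tensor(embedding: Tensor, p: CellDecoderParams) -> Tensor:
    h = embedding
    for i, (w, b) in enumerate(p.weights):
        h = h @ w + b
        if i < len(p.weights) - 1:
            h = h.relu()
    return h


def decode_cell(e: CellEmbedding, p: CellDecoderParams) -> np.ndarray:
    if e.vector.shape[0] != p.weights[0][0].shape[0]:
        raise ValueError(
            f"embedding dim {e.vector.shape[0]} != decoder input "
            f"{p.weights[0][0].shape[0]}"
        )
    return decode_cell_tensor(Tensor(e.vector), p).data


def reconstruction_loss(profile: np.ndarray, reconstruction: np.ndarray) -> float:
    """Mean squared error between a profile and its reconstruction."""
    profile = np.asarray(profile, dtype=float)
    reconstruction = np.asarray(reconstruction, dtype=float)
    if profile.shape != reconstruction.shape:
        raise ValueError(f"shape mismatch {profile.shape} vs {reconstruction.shape}")
    return float(np.mean((profile - reconstruction) ** 2))
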