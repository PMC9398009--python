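"""Optimization procedures for the multi-task network.

Two schedules are provided, both sharing the expression encoder E between
the autoencoder (E, D) and the supervised components S:

- pretrain/fine-tune: ``epoch_max`` epochs of autoencoder training on basal
  profiles, then ``epoch_max`` epochs of supervised training that continues
  from the pretrained encoder;
- joint: every epoch runs one full autoencoder pass (updating E, D) followed
  by one full supervised pass (updating E, S).

On top of either schedule, a teacher-student loop augments the training set
with low-reliability perturbation records: the current model predicts each
low-quality record's profile, and records whose prediction correlates with
their experimental profile above a similarity threshold are added with the
*predicted* profile as a pseudo label (never the noisy experimental vector).
The student trained on the augmented set becomes the next teacher.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._autodiff import Adam, Tensor
from . import chem_graph
from .cell_transformer import decode_cell_tensor, encode_cell_tensor, standardize_profile
from .data_core import DoseResponsePoint, PerturbationRecord, ReplicateSet
from .net import PerturbNetParams, _forward_group, label_binary


@dataclass
class TrainConfig:
    epoch_max: int = 3
    lr: float = 1e-3
    ae_batch: int = 8
    rng_seed: int = 0
    tasks: tuple = ("dgx_regression",)
    similarity_threshold: float = 0.7
    n_augment_iters: int = 4
    early_stop: bool = False
    binary_frac: float = 0.05

    def __post_init__(self):
        if self.epoch_max < 1:
            raise ValueError("epoch_max must be >= 1")
        if self.n_augment_iters < 0:
            raise ValueError("n_augment_iters must be >= 0")


@dataclass
class SupervisedData:
    """Supervised samples plus the lookup tables the forward pass needs."""

    records: list[PerturbationRecord] = field(default_factory=list)
    basal: dict[str, np.ndarray] = field(default_factory=dict)
    viability: list[DoseResponsePoint] = field(default_factory=list)
    drug_smiles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for r in self.records:
            if r.cell_id not in self.basal:
                raise ValueError(f"no basal profile for cell {r.cell_id!r}")
        for p in self.viability:
            if p.cell_id not in self.basal:
                raise ValueError(f"no basal profile for cell {p.cell_id!r}")
            if p.drug_id not in self.drug_smiles:
                raise ValueError(f"no SMILES for drug {p.drug_id!r}")

    def is_empty(self) -> bool:
        return not self.records and not self.viability


@dataclass
class TrainedModel:
    params: PerturbNetParams
    history: list[dict]
    config: TrainConfig


# ---------------------------------------------------------------------------
# passes
# ---------------------------------------------------------------------------

def _autoencoder_pass(params: PerturbNetParams, profiles: np.ndarray,
                      opt: Adam, rng: np.random.Generator,
                      batch_size: int = 8) -> float:
    """One epoch over basal profiles; returns the mean reconstruction MSE."""
    order = rng.permutation(len(profiles))
    total, nb = 0.0, 0
    for start in range(0, len(order), batch_size):
        batch = [profiles[i] for i in order[start:start + batch_size]]
        loss = None
        for prof in batch:
            emb = encode_cell_tensor(prof, params.encoder, train_mode=True, rng=rng)
            rec = decode_cell_tensor(emb, params.decoder)
            # the decoder reconstructs in the encoder's standardized space
            target = standardize_profile(prof, params.encoder)
            term = (rec - Tensor(target)).pow(2.0).mean()
            loss = term if loss is None else loss + term
        loss = loss * (1.0 / len(batch))
        opt.zero_grad()
        loss.backward()
        opt.step()
        total += float(loss.data)
        nb += 1
    return total / max(nb, 1)


def _bce(raw: Tensor, labels: np.ndarray) -> Tensor:
    p = raw.sigmoid()
    y = Tensor(labels.astype(float))
    eps = 1e-7
    return -((y * (p + eps).log() + (1.0 - y) * (1.0 - p + eps).log()).mean())


def _supervised_pass(params: PerturbNetParams, data: SupervisedData, opt: Adam,
                     rng: np.random.Generator, tasks, binary_frac: float,
                     graph_cache: dict) -> dict[str, float]:
    """One epoch over supervised samples, grouped by (drug, cell).

    All doses of one (drug, cell) pair share a single fingerprint/attention/
    cell-embedding computation; one optimizer step per group.
    """
    losses = {t: [] for t in tasks}
    # dgx groups
    if "dgx_regression" in tasks or "dgx_binary" in tasks:
        groups: dict[tuple, list[PerturbationRecord]] = {}
        for r in data.records:
            groups.setdefault((r.drug_id, r.cell_id), []).append(r)
        keys = list(groups)
        for gi in rng.permutation(len(keys)):
            recs = groups[keys[gi]]
            graph = _graph_for(recs[0].smiles, graph_cache)
            dose_idxs = [params.dose_vocab.index(r.dose) for r in recs]
            loss = None
            if "dgx_regression" in tasks:
                outs = _forward_group(graph, data.basal[recs[0].cell_id], dose_idxs,
                                      params, "dgx_regression", train_mode=True, rng=rng)
                for out, r in zip(outs, recs):
                    term = (out - Tensor(r.dgx)).pow(2.0).mean()
                    loss = term if loss is None else loss + term
                losses["dgx_regression"].append(float(loss.data) / len(recs))
            if "dgx_binary" in tasks:
                outs = _forward_group(graph, data.basal[recs[0].cell_id], dose_idxs,
                                      params, "dgx_binary", train_mode=True, rng=rng)
                bl = None
                for out, r in zip(outs, recs):
                    lab = label_binary(r.dgx, frac=binary_frac)
                    term = _bce(out, lab.up_labels) + _bce(-out, lab.down_labels)
                    bl = term if bl is None else bl + term
                losses["dgx_binary"].append(float(bl.data) / len(recs))
                loss = bl if loss is None else loss + bl
            opt.zero_grad()
            loss.backward()
            opt.step()
    # viability groups
    if "viability" in tasks and data.viability:
        vgroups: dict[tuple, list[DoseResponsePoint]] = {}
        for p in data.viability:
            vgroups.setdefault((p.drug_id, p.cell_id), []).append(p)
        keys = list(vgroups)
        for gi in rng.permutation(len(keys)):
            pts = vgroups[keys[gi]]
            graph = _graph_for(data.drug_smiles[pts[0].drug_id], graph_cache)
            dose_idxs = [params.dose_vocab.index(p.dose) for p in pts]
            outs = _forward_group(graph, data.basal[pts[0].cell_id], dose_idxs,
                                  params, "viability", train_mode=True, rng=rng)
            loss = None
            for out, p in zip(outs, pts):
                term = (out.reshape(()) * 1.0 - p.viability).pow(2.0)
                loss = term if loss is None else loss + term
            loss = loss * (1.0 / len(pts))
            losses["viability"].append(float(loss.data))
            opt.zero_grad()
            loss.backward()
            opt.step()
    return {t: float(np.mean(v)) for t, v in losses.items() if v}


def _graph_for(smiles: str, cache: dict) -> chem_graph.MolGraph:
    if smiles not in cache:
        cache[smiles] = chem_graph.smiles_to_graph(smiles)
    return cache[smiles]


def predict_records(params: PerturbNetParams, records: list[PerturbationRecord],
                    basal: dict[str, np.ndarray], graph_cache: dict | None = None
                    ) -> np.ndarray:
    """Inference-mode dgx predictions, one row per record."""
    cache = graph_cache if graph_cache is not None else {}
    groups: dict[tuple, list[int]] = {}
    for i, r in enumerate(records):
        groups.setdefault((r.drug_id, r.cell_id), []).append(i)
    out = np.empty((len(records), len(params.genes.gene_ids)))
    for (drug, cell), idxs in groups.items():
        graph = _graph_for(records[idxs[0]].smiles, cache)
        dose_idxs = [params.dose_vocab.index(records[i].dose) for i in idxs]
        preds = _forward_group(graph, basal[cell], dose_idxs, params, "dgx_regression")
        for i, p in zip(idxs, preds):
            out[i] = p.data
    return out


def dev_pearson(params: PerturbNetParams, records: list[PerturbationRecord],
                basal: dict[str, np.ndarray], graph_cache: dict | None = None) -> float:
    """Mean per-record Pearson between predicted and observed dgx."""
    preds = predict_records(params, records, basal, graph_cache)
    rs = []
    for p, r in zip(preds, records):
        if np.std(p) == 0 or np.std(r.dgx) == 0:
            continue
        rs.append(stats.pearsonr(p, r.dgx)[0])
    return float(np.mean(rs)) if rs else float("nan")


# ---------------------------------------------------------------------------
# procedures
# ---------------------------------------------------------------------------

def train_pretrain_finetune(params: PerturbNetParams, ae_data: np.ndarray,
                            sup_data: SupervisedData, cfg: TrainConfig,
                            dev_data: SupervisedData | None = None) -> TrainedModel:
    """Autoencoder pretraining then supervised fine-tuning of the shared encoder."""
    if len(ae_data) == 0 or sup_data.is_empty():
        raise ValueError("both autoencoder and supervised datasets must be nonempty")
    rng = np.random.default_rng(cfg.rng_seed)
    history: list[dict] = []
    cache: dict = {}
    opt_ae = Adam(params.encoder_parameters() + params.decoder_parameters(), lr=cfg.lr)
    for epoch in range(cfg.epoch_max):
        recon = _autoencoder_pass(params, ae_data, opt_ae, rng, cfg.ae_batch)
        history.append({"phase": "pretrain", "epoch": epoch, "recon_loss": recon})
    opt_sup = Adam(params.encoder_parameters() + params.supervised_parameters(), lr=cfg.lr)
    best = None
    for epoch in range(cfg.epoch_max):
        losses = _supervised_pass(params, sup_data, opt_sup, rng, cfg.tasks,
                                  cfg.binary_frac, cache)
        entry = {"phase": "finetune", "epoch": epoch, **losses}
        if dev_data is not None and dev_data.records:
            entry["dev_pearson"] = dev_pearson(params, dev_data.records,
                                               dev_data.basal, cache)
            if cfg.early_stop and (best is None or entry["dev_pearson"] > best[0]):
                best = (entry["dev_pearson"], params.snapshot())
        history.append(entry)
    if cfg.early_stop and best is not None:
        params.restore(best[1])
    return TrainedModel(params=params, history=history, config=cfg)


def train_joint(params: PerturbNetParams, ae_data: np.ndarray,
                sup_data: SupervisedData, cfg: TrainConfig,
                dev_data: SupervisedData | None = None,
                ae_enabled: bool = True) -> TrainedModel:
    """Alternate a full autoencoder pass and a full supervised pass per epoch."""
    if len(ae_data) == 0 or sup_data.is_empty():
        raise ValueError("both autoencoder and supervised datasets must be nonempty")
    rng = np.random.default_rng(cfg.rng_seed)
    history: list[dict] = []
    cache: dict = {}
    opt_ae = Adam(params.encoder_parameters() + params.decoder_parameters(), lr=cfg.lr)
    opt_sup = Adam(params.encoder_parameters() + params.supervised_parameters(), lr=cfg.lr)
    best = None
    for epoch in range(cfg.epoch_max):
        entry: dict = {"phase": "joint", "epoch": epoch}
        if ae_enabled:
            entry["recon_loss"] = _autoencoder_pass(params, ae_data, opt_ae, rng, cfg.ae_batch)
        entry.update(_supervised_pass(params, sup_data, opt_sup, rng, cfg.tasks,
                                      cfg.binary_frac, cache))
        if dev_data is not None and dev_data.records:
            entry["dev_pearson"] = dev_pearson(params, dev_data.records,
                                               dev_data.basal, cache)
            if cfg.early_stop and (best is None or entry["dev_pearson"] > best[0]):
                best = (entry["dev_pearson"], params.snapshot())
        history.append(entry)
    if cfg.early_stop and best is not None:
        params.restore(best[1])
    return TrainedModel(params=params, history=history, config=cfg)


def teacher_student_augment(make_params, ae_data: np.ndarray,
                            high: SupervisedData, low: list[ReplicateSet],
                            cfg: TrainConfig,
                            dev_data: SupervisedData | None = None) -> TrainedModel:
    """Iterative pseudo-label augmentation from the low-quality pool.

    ``make_params(seed)`` builds a fresh parameter bundle; each iteration
    trains a fresh student on high + currently selected pseudo-labeled
    records. Pseudo labels are the model's predictions, keyed by
    (drug, cell, dose, time); re-selection replaces the previous pseudo
    label with the newer prediction.
    """
    if not -1.0 < cfg.similarity_threshold < 1.0:
        if cfg.similarity_threshold not in (-1.0, 1.0):
            raise ValueError("similarity_threshold must be within [-1, 1]")
    history: list[dict] = []
    cache: dict = {}
    low_records = [rs.to_record() for rs in low]  # experimental consensus labels
    pseudo: dict[tuple, PerturbationRecord] = {}
    model = None
    for it in range(cfg.n_augment_iters + 1):
        # every student starts from the same initialization and follows the
        # same schedule: iterations differ only by the pseudo-labeled data
        params = make_params(cfg.rng_seed)
        aug = SupervisedData(records=high.records + list(pseudo.values()),
                             basal=high.basal, viability=high.viability,
                             drug_smiles=high.drug_smiles)
        model = train_joint(params, ae_data, aug, cfg, dev_data=dev_data)
        entry = {"augment_iter": it, "n_pseudo": len(pseudo),
                 "n_train": len(aug.records)}
        if dev_data is not None and dev_data.records:
            entry["dev_pearson"] = dev_pearson(params, dev_data.records,
                                               dev_data.basal, cache)
        history.append(entry)
        if it == cfg.n_augment_iters:
            break
        # teacher labels the low-quality pool for the next student
        preds = predict_records(params, low_records, high.basal, cache)
        for rec, pred in zip(low_records, preds):
            if np.std(pred) == 0 or np.std(rec.dgx) == 0:
                continue
            r = stats.pearsonr(pred, rec.dgx)[0]
            if r > cfg.similarity_threshold:
                pseudo[rec.key] = PerturbationRecord(
                    rec.drug_id, rec.smiles, rec.cell_id, rec.dose, rec.time_h,
                    dgx=pred.copy())
    model.history = model.history + history
    return model
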