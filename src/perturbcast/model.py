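"""Model/Results surface for dose- and context-aware response prediction.

``DrugResponseModel`` bundles the data a fit needs — perturbation records
with dgx labels, basal expression profiles (also the autoencoder corpus),
optional viability points — with the architecture configuration.  ``fit``
runs one of the training procedures and returns a ``DrugResponseResults``
holding the trained parameters, the per-epoch history and prediction
methods. This mirrors the model-class/results-class split of mainstream
statistical packages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import net, training
from .data_core import ExpressionMatrix, PerturbationRecord
from .net import GeneEmbeddingTable, PerturbNetParams
from .training import SupervisedData, TrainConfig


class DrugResponseModel:
    """Multi-task predictor of drug-induced expression changes and viability.

    Parameters
    ----------
    sup_data : SupervisedData
        Labeled perturbation records (and optionally viability points) plus
        the basal profile of every referenced cell.
    ae_profiles : ndarray (n_profiles, G)
        Basal profiles for autoencoder training; typically a superset of the
        supervised cells.
    gene_embeddings : GeneEmbeddingTable, optional
        Precomputed per-gene vectors; random near-orthogonal vectors are
        drawn when omitted.
    doses : sequence of float, optional
        Dose vocabulary; inferred from the data when omitted.
    """

    def __init__(self, sup_data: SupervisedData, ae_profiles: np.ndarray,
                 gene_embeddings: GeneEmbeddingTable | None = None,
                 gene_ids: list[str] | None = None,
                 doses=None, tasks=("dgx_regression",),
                 use_cell_context: bool = True, init_seed: int = 0,
                 **arch_kwargs):
        self.sup_data = sup_data
        self.ae_profiles = np.asarray(ae_profiles, dtype=float)
        g = self.ae_profiles.shape[1]
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(g)]
        if gene_embeddings is None:
            gene_embeddings = GeneEmbeddingTable.random(
                gene_ids, d_g=16, rng=np.random.default_rng(init_seed + 7919))
        self.gene_embeddings = gene_embeddings
        if doses is None:
            doses = sorted({r.dose for r in sup_data.records} |
                           {p.dose for p in sup_data.viability})
        self.doses = list(doses)
        self.tasks = tuple(tasks)
        self.use_cell_context = use_cell_context
        self.init_seed = init_seed
        self.arch_kwargs = dict(arch_kwargs)

    @classmethod
    def from_dataframes(cls, perturbations: pd.DataFrame, basal: ExpressionMatrix,
                        **kwargs) -> "DrugResponseModel":
        """Build from a perturbation table (columns drug_id, smiles, cell_id,
        dose_uM, time_h, then one column per panel gene) and a basal matrix."""
        meta = ["drug_id", "smiles", "cell_id", "dose_uM", "time_h"]
        dgx_cols = [c for c in perturbations.columns if c not in meta]
        records = [
            PerturbationRecord(str(r.drug_id), str(r.smiles), str(r.cell_id),
                               float(r.dose_uM), float(r.time_h),
                               r[dgx_cols].to_numpy(float))
            for _, r in perturbations.iterrows()
        ]
        basal_map = {c: basal.values[:, j] for j, c in enumerate(basal.sample_ids)}
        sup = SupervisedData(records=records, basal=basal_map)
        return cls(sup, ae_profiles=basal.values.T,
                   gene_ids=list(basal.gene_ids), **kwargs)

    def make_params(self, seed: int) -> PerturbNetParams:
        loc = self.ae_profiles.mean(axis=0)
        scale = np.maximum(self.ae_profiles.std(axis=0), 1e-6)
        return net.init_params(np.random.default_rng(seed), self.gene_embeddings,
                               self.doses, tasks=self.tasks,
                               use_cell_context=self.use_cell_context,
                               input_loc=loc, input_scale=scale,
                               **self.arch_kwargs)

    def fit(self, method: str = "joint", cfg: TrainConfig | None = None,
            dev_data: SupervisedData | None = None) -> "DrugResponseResults":
        """Train with ``method`` in {"joint", "pretrain_finetune",
        "teacher_student"}; teacher_student needs ``cfg`` plus a low-quality
        pool passed via ``fit_teacher_student``."""
        cfg = cfg or TrainConfig()
        params = self.make_params(self.init_seed + cfg.rng_seed)
        if method == "joint":
            tm = training.train_joint(params, self.ae_profiles, self.sup_data,
                                      cfg, dev_data=dev_data)
        elif method == "pretrain_finetune":
            tm = training.train_pretrain_finetune(params, self.ae_profiles,
                                                  self.sup_data, cfg,
                                                  dev_data=dev_data)
        else:
            raise ValueError(f"unknown method {method!r}")
        return DrugResponseResults(self, tm)

    def fit_teacher_student(self, low, cfg: TrainConfig | None = None,
                            dev_data: SupervisedData | None = None
                            ) -> "DrugResponseResults":
        """Teacher-student augmentation using a low-quality replicate pool."""
        cfg = cfg or TrainConfig()
        tm = training.teacher_student_augment(
            lambda seed: self.make_params(self.init_seed + seed),
            self.ae_profiles, self.sup_data, low, cfg, dev_data=dev_data)
        return DrugResponseResults(self, tm)


@dataclass
class DrugResponseResults:
    """Trained parameters, history and prediction surface of one fit."""

    model: DrugResponseModel
    trained: training.TrainedModel

    @property
    def params(self) -> PerturbNetParams:
        return self.trained.params

    @property
    def history(self) -> list[dict]:
        return self.trained.history

    # -- prediction ---------------------------------------------------------
    def predict_dgx(self, smiles: str, basal_profile: np.ndarray, dose: float,
                    nearest_log: bool = False) -> np.ndarray:
        return net.forward_dgx(smiles, basal_profile, dose, self.params,
                               nearest_log=nearest_log)

    def predict_binary(self, smiles: str, basal_profile: np.ndarray, dose: float):
        return net.forward_binary(smiles, basal_profile, dose, self.params)

    def predict_viability(self, smiles: str, basal_profile: np.ndarray,
                          dose: float, nearest_log: bool = False) -> float:
        return net.forward_viability(smiles, basal_profile, dose, self.params,
                                     nearest_log=nearest_log)

    def predict_viability_curve(self, smiles: str, basal_profile: np.ndarray
                                ) -> pd.DataFrame:
        """Viability over the dose vocabulary for one (drug, cell)."""
        doses = self.params.dose_vocab.doses
        return pd.DataFrame({
            "dose_uM": doses,
            "viability": [self.predict_viability(smiles, basal_profile, d)
                          for d in doses],
        })

    def evaluate(self, records: list[PerturbationRecord],
                 basal: dict[str, np.ndarray]) -> dict:
        """Mean per-record Pearson/Spearman on held-out records."""
        from .evaluation import correlation_metrics
        preds = training.predict_records(self.params, records, basal)
        truth = np.stack([r.dgx for r in records])
        pear, spear = correlation_metrics(preds, truth, axis="pointwise")
        return {"pearson": pear, "spearman": spear, "n": len(records)}

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        cfg = self.trained.config
        lines = [
            "Drug response model fit",
            "=" * 47,
            f"genes: {len(self.params.genes.gene_ids)}  "
            f"doses: {len(self.params.dose_vocab.doses)}  "
            f"tasks: {', '.join(self.params.tasks)}",
            f"epochs: {cfg.epoch_max}  lr: {cfg.lr}  seed: {cfg.rng_seed}  "
            f"cell context: {'on' if self.params.use_cell_context else 'ablated'}",
            "-" * 47,
        ]
        for entry in self.history:
            bits = [f"{k}={v}" if isinstance(v, int) else f"{k}={v:.4f}"
                    for k, v in entry.items() if isinstance(v, (int, float))]
            phase = entry.get("phase", "augment")
            lines.append(f"[{phase}] " + "  ".join(bits))
        return "\n".join(lines)

    def save(self, path) -> None:
        """Self-contained checkpoint: parameter arrays plus architecture info."""
        import json
        p = self.params
        meta = {
            "gene_ids": p.genes.gene_ids,
            "doses": p.dose_vocab.doses.tolist(),
            "tasks": list(p.tasks),
            "use_cell_context": p.use_cell_context,
            "arch_kwargs": self.model.arch_kwargs,
        }
        arrays = {f"p{i}": t.data for i, t in enumerate(p.all_parameters())}
        arrays["gene_vectors"] = p.genes.vectors
        arrays["input_loc"] = p.encoder.input_loc if p.encoder.input_loc is not None else np.zeros(0)
        arrays["input_scale"] = p.encoder.input_scale if p.encoder.input_scale is not None else np.zeros(0)
        np.savez(path, meta=json.dumps(meta), **arrays)

    @staticmethod
    def load_params(path) -> PerturbNetParams:
        """Rebuild trained parameters from a checkpoint written by ``save``."""
        import json
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            genes = GeneEmbeddingTable(gene_ids=meta["gene_ids"],
                                       vectors=z["gene_vectors"])
            loc = z["input_loc"] if z["input_loc"].size else None
            scale = z["input_scale"] if z["input_scale"].size else None
            params = net.init_params(
                np.random.default_rng(0), genes, meta["doses"],
                tasks=tuple(meta["tasks"]),
                use_cell_context=meta["use_cell_context"],
                input_loc=loc, input_scale=scale, **meta["arch_kwargs"])
            for i, t in enumerate(params.all_parameters()):
                t.data = z[f"p{i}"].copy()
        return params

    def plot_history(self, ax=None):
        """Per-epoch training losses (and dev Pearson when tracked)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for key in ("recon_loss", "dgx_regression", "viability", "dev_pearson"):
            ys = [e[key] for e in self.history if key in e]
            if ys:
                ax.plot(ys, marker="o", label=key)
        ax.set_xlabel("epoch")
        ax.legend()
        return ax
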