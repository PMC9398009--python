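"""Cross-validation splitters and prediction metrics.

Generalization to unseen cellular contexts is measured with a
leave-new-cells-out design: cells are clustered on their basal expression
profiles (affinity propagation) and whole clusters are assigned to folds,
so every test cell is dissimilar from every training cell. The autoencoder
corpus is partitioned by the same plan, keeping each cell's role (train /
dev / test) identical in both tasks. Drug-centric tasks use an analogous
leave-group-of-drugs-out splitter.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import average_precision_score, roc_auc_score

from .data_core import ExpressionMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Clustering and fold plans
# ---------------------------------------------------------------------------

@dataclass
class CellClustering:
    assignments: dict[str, int]
    method: str = "affinity_propagation"

    @property
    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for cell, cl in self.assignments.items():
            out.setdefault(cl, []).append(cell)
        return out


@dataclass
class FoldPlan:
    """k disjoint folds of units (cells or drugs) with train/dev/test roles.

    ``folds[i]`` is the set of units whose test round is i; ``roles[i]`` maps
    every unit to its role when fold i is the test fold.
    """

    k: int
    folds: list[set]
    roles: list[dict[str, str]] = field(default_factory=list)

    def __post_init__(self):
        units = [u for f in self.folds for u in f]
        if len(units) != len(set(units)):
            raise ValueError("folds overlap")

    def test_units(self, i: int) -> set:
        return set(self.folds[i])

    def role_of(self, unit: str, i: int) -> str:
        return self.roles[i][unit]

    def to_json(self, path) -> None:
        payload = {
            "k": self.k,
            "folds": [sorted(f) for f in self.folds],
            "roles": self.roles,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def cluster_cells(basal: ExpressionMatrix, damping: float = 0.9,
                  random_state: int = 0) -> CellClustering:
    """Affinity propagation on standardized basal profiles.

    Similarity is the (negative squared Euclidean) default of the estimator;
    the preference defaults to the median similarity.
    """
    if basal.n_samples < 2:
        raise ValueError("need at least 2 cells to cluster")
    x = basal.values.T  # cells x genes
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = (x - x.mean(axis=0)) / sd
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            ap = AffinityPropagation(damping=damping, max_iter=1000,
                                     random_state=random_state).fit(x)
        except ConvergenceWarning as exc:
            raise RuntimeError(
                "affinity propagation did not converge; try a larger damping "
                "factor or an explicit preference") from exc
    labels = ap.labels_
    if np.any(labels < 0):
        raise RuntimeError("affinity propagation produced unassigned cells; "
                           "adjust damping or preference")
    return CellClustering(
        assignments={c: int(l) for c, l in zip(basal.sample_ids, labels)})


def _assign_clusters_to_folds(cluster_sizes: dict[int, int], k: int,
                              rng: np.random.Generator) -> dict[int, int]:
    """Greedy size balancing: largest cluster first into the smallest fold."""
    order = sorted(cluster_sizes, key=lambda c: (-cluster_sizes[c], c))
    fold_sizes = [0] * k
    fold_of = {}
    # random tie-break among equally loaded folds
    for cl in order:
        min_size = min(fold_sizes)
        cands = [i for i, s in enumerate(fold_sizes) if s == min_size]
        fi = int(rng.choice(cands))
        fold_of[cl] = fi
        fold_sizes[fi] += cluster_sizes[cl]
    return fold_of


def _build_roles(folds: list[set], k: int, rng: np.random.Generator,
                 unit_groups: dict[str, int] | None = None,
                 dev_fraction: float = 0.1) -> list[dict[str, str]]:
    """Per test round, mark ~``dev_fraction`` of the train-side groups as dev.

    ``unit_groups`` maps each unit to its group (cluster); units without a
    grouping are their own group. Dev selection is group-respecting.
    """
    if unit_groups is None:
        unit_groups = {u: i for i, u in enumerate(sorted(u for f in folds for u in f))}
    roles = []
    for i in range(k):
        role: dict[str, str] = {u: "test" for u in folds[i]}
        train_units = sorted(u for j in range(k) if j != i for u in folds[j])
        train_groups = sorted({unit_groups[u] for u in train_units})
        n_dev = max(1, int(round(dev_fraction * len(train_groups))))
        if n_dev >= len(train_groups):
            n_dev = len(train_groups) - 1  # keep at least one training group
        dev_groups = set(rng.choice(train_groups, size=n_dev, replace=False).tolist()) \
            if n_dev > 0 else set()
        for u in train_units:
            role[u] = "dev" if unit_groups[u] in dev_groups else "train"
        roles.append(role)
    return roles


def leave_new_cells_out_splits(clustering: CellClustering, k: int = 3,
                               rng_seed: int = 0) -> FoldPlan:
    """Assign whole cell clusters to k folds; zero cluster leakage.

    The returned plan governs both the supervised task and the autoencoder
    corpus: a cell's role is identical in both.
    """
    clusters = clustering.clusters
    if len(clusters) < k:
        raise ValueError(f"{len(clusters)} clusters cannot fill {k} folds")
    rng = np.random.default_rng(rng_seed)
    fold_of = _assign_clusters_to_folds(
        {cl: len(cells) for cl, cells in clusters.items()}, k, rng)
    folds = [set() for _ in range(k)]
    for cl, cells in clusters.items():
        folds[fold_of[cl]].update(cells)
    return FoldPlan(k=k, folds=folds,
                    roles=_build_roles(folds, k, rng,
                                       unit_groups=clustering.assignments))


def drug_grouped_splits(drug_ids, k: int, rng_seed: int = 0) -> FoldPlan:
    """Partition drugs into k folds; all samples of a drug travel together."""
    drugs = sorted(set(drug_ids))
    if len(drugs) < k:
        raise ValueError(f"{len(drugs)} drugs cannot fill {k} folds")
    rng = np.random.default_rng(rng_seed)
    order = list(rng.permutation(drugs))
    folds = [set(order[i::k]) for i in range(k)]
    return FoldPlan(k=k, folds=folds, roles=_build_roles(folds, k, rng))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def correlation_metrics(pred: np.ndarray, truth: np.ndarray,
                        axis: str = "pointwise",
                        groups: list | None = None) -> tuple[float, float]:
    """(Pearson, Spearman) between predictions and truth.

    ``pointwise`` on 2-D inputs correlates each row (sample) and averages;
    on 1-D inputs it correlates the flat vectors. ``per_drug``/``per_cell``
    require ``groups`` (one label per row/point): the metric is computed
    within each group, then averaged. Zero-variance groups are skipped with
    a warning.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")

    def _pair(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return None
        return stats.pearsonr(x, y)[0], stats.spearmanr(x, y)[0]

    if axis == "pointwise":
        if pred.ndim == 1:
            r = _pair(pred, truth)
            if r is None:
                raise ValueError("zero-variance input")
            return r
        pairs = [_pair(p, t) for p, t in zip(pred, truth)]
    elif axis in ("per_drug", "per_cell"):
        if groups is None:
            raise ValueError(f"axis={axis!r} requires group labels")
        groups = np.asarray(groups)
        pairs = []
        for g in np.unique(groups):
            mask = groups == g
            pairs.append(_pair(pred[mask].ravel(), truth[mask].ravel()))
    else:
        raise ValueError(f"unknown axis {axis!r}")
    kept = [p for p in pairs if p is not None]
    if len(kept) < len(pairs):
        logger.warning("skipped %d zero-variance groups", len(pairs) - len(kept))
    if not kept:
        raise ValueError("no group with nonzero variance")
    return (float(np.mean([p[0] for p in kept])),
            float(np.mean([p[1] for p in kept])))


def precision_at_k(pred: np.ndarray, truth: np.ndarray, k: int,
                   direction: str = "up") -> float:
    """|top-k(pred) ∩ top-k(truth)| / k, with stable gene-order tie-breaks."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if k > pred.shape[0]:
        raise ValueError(f"k={k} exceeds vector length {pred.shape[0]}")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    sign = -1.0 if direction == "up" else 1.0
    top_pred = set(np.argsort(sign * pred, kind="stable")[:k].tolist())
    top_truth = set(np.argsort(sign * truth, kind="stable")[:k].tolist())
    return len(top_pred & top_truth) / k


def auc_metrics(scores: np.ndarray, labels: np.ndarray,
                averaging: str = "macro") -> tuple[float, float]:
    """(ROC-AUC, PR-AUC) for multi-label scores.

    ``macro`` averages per-label AUCs, skipping single-class labels with a
    warning; ``micro`` pools all (score, label) pairs.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.atleast_2d(np.asarray(labels))
    if scores.shape != labels.shape:
        raise ValueError(f"shape mismatch {scores.shape} vs {labels.shape}")
    if averaging == "micro":
        y = labels.ravel()
        s = scores.ravel()
        if y.min() == y.max():
            raise ValueError("pooled labels are single-class")
        return float(roc_auc_score(y, s)), float(average_precision_score(y, s))
    if averaging != "macro":
        raise ValueError(f"unknown averaging {averaging!r}")
    rocs, prs = [], []
    for j in range(labels.shape[1]):
        y = labels[:, j]
        if y.min() == y.max():
            logger.warning("label column %d is single-class; skipped", j)
            continue
        rocs.append(roc_auc_score(y, scores[:, j]))
        prs.append(average_precision_score(y, scores[:, j]))
    if not rocs:
        raise ValueError("no label column with both classes")
    return float(np.mean(rocs)), float(np.mean(prs))
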