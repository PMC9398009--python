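"""Splitters (cluster and drug grouped) and prediction metrics."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from perturbcast.data_core import ExpressionMatrix
from perturbcast.evaluation import (
    auc_metrics,
    cluster_cells,
    correlation_metrics,
    drug_grouped_splits,
    leave_new_cells_out_splits,
    precision_at_k,
)


def _two_blob_matrix(rng, n_per=10, g=30, sep=8.0):
    a = rng.normal(0, 1, size=(n_per, g))
    b = rng.normal(sep, 1, size=(n_per, g))
    vals = np.vstack([a, b]).T
    cells = [f"c{i}" for i in range(2 * n_per)]
    return ExpressionMatrix([f"g{i}" for i in range(g)], cells, vals), \
        [0] * n_per + [1] * n_per


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def test_two_blobs_recovered(rng):
    m, truth = _two_blob_matrix(rng)
    clustering = cluster_cells(m)
    labels = [clustering.assignments[c] for c in m.sample_ids]
    assert adjusted_rand_score(truth, labels) == 1.0


def test_identical_profiles_single_cluster():
    vals = np.tile(np.arange(10.0)[:, None], (1, 5))
    m = ExpressionMatrix([f"g{i}" for i in range(10)],
                         [f"c{i}" for i in range(5)], vals)
    clustering = cluster_cells(m)
    assert len(set(clustering.assignments.values())) == 1


def test_clustering_invariant_to_cell_order(rng):
    m, _ = _two_blob_matrix(rng)
    perm = rng.permutation(m.n_samples)
    m2 = ExpressionMatrix(m.gene_ids, [m.sample_ids[i] for i in perm],
                          m.values[:, perm])
    c1 = cluster_cells(m)
    c2 = cluster_cells(m2)
    l1 = [c1.assignments[c] for c in m.sample_ids]
    l2 = [c2.assignments[c] for c in m.sample_ids]
    assert adjusted_rand_score(l1, l2) == 1.0


# ---------------------------------------------------------------------------
# fold plans
# ---------------------------------------------------------------------------

def _synthetic_clustering(rng, n_clusters=6, per=10):
    from perturbcast.evaluation import CellClustering
    assignments = {}
    for cl in range(n_clusters):
        for i in range(per):
            assignments[f"c{cl}_{i}"] = cl
    return CellClustering(assignments=assignments)


def test_leave_new_cells_out_no_cluster_leakage(rng):
    clustering = _synthetic_clustering(rng)
    plan = leave_new_cells_out_splits(clustering, k=3, rng_seed=0)
    all_cells = set(clustering.assignments)
    assert set().union(*plan.folds) == all_cells
    for i in range(3):
        test = plan.test_units(i)
        rest = all_cells - test
        test_clusters = {clustering.assignments[c] for c in test}
        rest_clusters = {clustering.assignments[c] for c in rest}
        assert test_clusters.isdisjoint(rest_clusters)


def test_roles_are_cluster_respecting_and_aligned(rng):
    clustering = _synthetic_clustering(rng)
    plan = leave_new_cells_out_splits(clustering, k=3, rng_seed=1)
    for i in range(3):
        roles = plan.roles[i]
        assert set(roles) == set(clustering.assignments)
        # every cluster is wholly one role
        by_cluster = {}
        for cell, role in roles.items():
            by_cluster.setdefault(clustering.assignments[cell], set()).add(role)
        assert all(len(r) == 1 for r in by_cluster.values())
        assert {"train", "dev", "test"} >= set(roles.values())


def test_fold_plan_seeded_determinism(rng):
    clustering = _synthetic_clustering(rng)
    p1 = leave_new_cells_out_splits(clustering, k=3, rng_seed=5)
    p2 = leave_new_cells_out_splits(clustering, k=3, rng_seed=5)
    assert p1.folds == p2.folds and p1.roles == p2.roles


def test_too_few_clusters_rejected(rng):
    clustering = _synthetic_clustering(rng, n_clusters=2)
    with pytest.raises(ValueError, match="clusters"):
        leave_new_cells_out_splits(clustering, k=3)


def test_drug_grouped_splits_properties():
    drugs = [f"d{i}" for i in range(17)]
    plan = drug_grouped_splits(drugs, k=5, rng_seed=2)
    assert set().union(*plan.folds) == set(drugs)
    assert sum(len(f) for f in plan.folds) == 17
    p2 = drug_grouped_splits(drugs, k=5, rng_seed=2)
    assert plan.folds == p2.folds
    with pytest.raises(ValueError):
        drug_grouped_splits(["a", "b"], k=3)


def test_fold_plan_json_roundtrip(tmp_path, rng):
    clustering = _synthetic_clustering(rng)
    plan = leave_new_cells_out_splits(clustering, k=3, rng_seed=0)
    path = tmp_path / "folds.json"
    plan.to_json(path)
    import json
    payload = json.loads(path.read_text())
    assert payload["k"] == 3
    assert sorted(sum(payload["folds"], [])) == sorted(clustering.assignments)


# ---------------------------------------------------------------------------
# correlation metrics
# ---------------------------------------------------------------------------

def test_identity_correlations(rng):
    x = rng.normal(size=(5, 20))
    assert correlation_metrics(x, x) == (1.0, 1.0)


def test_affine_invariance(rng):
    x = rng.normal(size=(4, 30))
    pear, spear = correlation_metrics(2 * x + 3, x)
    assert pear == pytest.approx(1.0)
    assert spear == pytest.approx(1.0)


def test_monotone_transform_keeps_spearman(rng):
    x = rng.normal(size=50)
    y = np.exp(x)  # rank preserving, nonlinear
    pear, spear = correlation_metrics(y, x)
    assert spear == pytest.approx(1.0)
    assert pear < 1.0


def test_group_averaging(rng):
    pred = rng.normal(size=40)
    truth = pred + rng.normal(0, 0.1, size=40)
    groups = ["a"] * 20 + ["b"] * 20
    pear, _ = correlation_metrics(pred, truth, axis="per_drug", groups=groups)
    pa = stats.pearsonr(pred[:20], truth[:20])[0]
    pb = stats.pearsonr(pred[20:], truth[20:])[0]
    assert pear == pytest.approx((pa + pb) / 2)


# ---------------------------------------------------------------------------
# precision at k
# ---------------------------------------------------------------------------

def test_precision_identity(rng):
    x = rng.normal(size=100)
    for k in (1, 5, 20):
        assert precision_at_k(x, x, k, "up") == 1.0
        assert precision_at_k(x, x, k, "down") == 1.0


def test_precision_hand_case():
    truth = np.array([5.0, 4.0, 1.0, 0.0])   # top-2 = {0, 1}
    pred = np.array([9.0, 0.0, 8.0, -1.0])   # top-2 = {0, 2}
    assert precision_at_k(pred, truth, 2, "up") == 0.5


def test_precision_matches_bruteforce(rng):
    for _ in range(200):
        g = int(rng.integers(10, 60))
        k = int(rng.integers(1, g))
        pred, truth = rng.normal(size=g), rng.normal(size=g)
        got = precision_at_k(pred, truth, k, "down")
        want = len(set(np.argsort(pred, kind="stable")[:k]) &
                   set(np.argsort(truth, kind="stable")[:k])) / k
        assert got == want


def test_precision_random_expectation(rng):
    """E[overlap] for independent rankings is k^2/G, so precision ~= k/G."""
    g, k, reps = 1000, 10, 400
    vals = np.mean([precision_at_k(rng.normal(size=g), rng.normal(size=g), k, "up")
                    for _ in range(reps)])
    assert abs(vals - k / g) < 0.005


def test_precision_k_bounds(rng):
    with pytest.raises(ValueError):
        precision_at_k(np.zeros(5), np.zeros(5), 6, "up")


# ---------------------------------------------------------------------------
# AUC metrics
# ---------------------------------------------------------------------------

def test_perfect_separation():
    roc, pr = auc_metrics(np.array([[0.9], [0.8], [0.2], [0.1]]),
                          np.array([[1], [1], [0], [0]]))
    assert roc == 1.0 and pr == 1.0


def test_hand_computed_roc():
    roc, _ = auc_metrics(np.array([0.9, 0.8, 0.7, 0.1])[:, None],
                         np.array([1, 0, 1, 0])[:, None])
    assert roc == pytest.approx(0.75)  # 3 of 4 pos/neg pairs ordered correctly


def test_null_roc_near_half(rng):
    scores = rng.normal(size=(4000, 1))
    labels = (rng.random((4000, 1)) < 0.3).astype(int)
    roc, _ = auc_metrics(scores, labels, averaging="micro")
    assert abs(roc - 0.5) < 0.03


def test_micro_equals_mannwhitney(rng):
    for _ in range(100):
        n = int(rng.integers(20, 60))
        scores = rng.normal(size=n)
        labels = (rng.random(n) < 0.4).astype(int)
        if labels.min() == labels.max():
            continue
        roc, _ = auc_metrics(scores[:, None], labels[:, None], averaging="micro")
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                               alternative="two-sided").statistic
        want = u / ((labels == 1).sum() * (labels == 0).sum())
        assert roc == pytest.approx(want)


def test_single_class_pooled_errors():
    with pytest.raises(ValueError):
        auc_metrics(np.array([[0.5], [0.4]]), np.array([[1], [1]]),
                    averaging="micro")
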