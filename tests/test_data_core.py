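"""Expression/perturbation I/O, log2 preprocessing and replicate quality."""

import math

import numpy as np
import pytest

from perturbcast.data_core import (
    ExpressionMatrix,
    ReplicateSet,
    average_replicate_correlation,
    group_replicates,
    load_expression_matrix,
    load_perturbation_table,
    log2_transform,
    partition_by_quality,
    write_expression_matrix,
    write_perturbation_table,
    PerturbationRecord,
)


@pytest.fixture()
def tiny_matrix():
    return ExpressionMatrix(
        gene_ids=["g1", "g2", "g3"], sample_ids=["s1", "s2"],
        values=np.array([[0.0, 1.0], [2.5, 3.25], [10.0, 0.125]]))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fmt", ["tsv", "csv", "gct"])
def test_expression_roundtrip_preserves_values_and_order(tiny_matrix, tmp_path, fmt):
    path = tmp_path / f"m.{fmt}"
    write_expression_matrix(tiny_matrix, path, fmt=fmt)
    back = load_expression_matrix(path, fmt=fmt)
    assert back.gene_ids == tiny_matrix.gene_ids
    assert back.sample_ids == tiny_matrix.sample_ids
    np.testing.assert_array_equal(back.values, tiny_matrix.values)


def test_tsv_fixture_shape(tmp_path):
    path = tmp_path / "m.tsv"
    path.write_text("gene_id\ts1\ts2\ng1\t1\t2\ng2\t3\t4\ng3\t5\t6\n")
    m = load_expression_matrix(path)
    assert m.values.shape == (3, 2)
    assert m.gene_ids == ["g1", "g2", "g3"]


def test_duplicate_gene_id_is_reported(tmp_path):
    path = tmp_path / "m.tsv"
    path.write_text("gene_id\ts1\ng1\t1\ng1\t2\n")
    with pytest.raises(ValueError, match="g1"):
        load_expression_matrix(path)


def test_perturbation_table_roundtrip(tmp_path):
    recs = [PerturbationRecord("d1", "CCO", "c1", 1.0, 24.0, np.array([0.5, -1.0])),
            PerturbationRecord("d2", "CC", "c2", 10.0, 6.0, np.array([2.0, 0.25]))]
    path = tmp_path / "p.tsv"
    write_perturbation_table(recs, path, gene_ids=["g1", "g2"])
    back = load_perturbation_table(path)
    assert [r.key for r in back] == [r.key for r in recs]
    np.testing.assert_array_equal(back[0].dgx, recs[0].dgx)


# ---------------------------------------------------------------------------
# log2 transform
# ---------------------------------------------------------------------------

def test_log2_closed_forms(tiny_matrix):
    out = log2_transform(tiny_matrix)
    assert out.space_tag == "log2"
    assert out.values[0, 0] == pytest.approx(math.log2(0.001))
    m = ExpressionMatrix(["g"], ["s"], np.array([[1.023]]))
    assert log2_transform(m).values[0, 0] == pytest.approx(math.log2(1.024))


def test_log2_rejects_second_application(tiny_matrix):
    once = log2_transform(tiny_matrix)
    with pytest.raises(ValueError, match="raw"):
        log2_transform(once)


def test_log2_reports_negative_coordinates():
    m = ExpressionMatrix(["gA", "gB"], ["sX"], np.array([[1.0], [-0.5]]))
    with pytest.raises(ValueError, match="gB.*sX"):
        log2_transform(m)


def test_log2_is_monotone(rng):
    vals = np.sort(rng.uniform(0, 50, size=20))
    m = ExpressionMatrix([f"g{i}" for i in range(20)], ["s"], vals[:, None])
    out = log2_transform(m).values[:, 0]
    assert np.all(np.diff(out) > 0)


# ---------------------------------------------------------------------------
# replicate quality
# ---------------------------------------------------------------------------

def _orthonormal_basis():
    e1 = np.array([1, 1, -1, -1]) / 2.0
    e2 = np.array([1, -1, 1, -1]) / 2.0
    e3 = np.array([1, -1, -1, 1]) / 2.0
    return e1, e2, e3


def test_identical_replicates_correlate_perfectly():
    v = np.array([1.0, 2.0, 5.0, 3.0])
    rs = ReplicateSet(key=("d", "c", 1.0, 24.0), replicates=[v, v.copy()])
    assert average_replicate_correlation(rs) == pytest.approx(1.0)


def test_antisymmetric_replicates_correlate_minus_one():
    v = np.array([1.0, -2.0, 3.0, 0.0])
    rs = ReplicateSet(key=("d", "c", 1.0, 24.0), replicates=[v, -v])
    assert average_replicate_correlation(rs) == pytest.approx(-1.0)


def test_three_replicates_average_known_pairwise():
    # constructed so the pairwise correlations are exactly (0.9, 0.6, 0.6)
    e1, e2, e3 = _orthonormal_basis()
    r1 = e1
    r2 = 0.9 * e1 + math.sqrt(1 - 0.81) * e2
    b = (0.6 - 0.9 * 0.6) / math.sqrt(0.19)
    r3 = 0.6 * e1 + b * e2 + math.sqrt(1 - 0.36 - b * b) * e3
    rs = ReplicateSet(key=("d", "c", 1.0, 24.0), replicates=[r1, r2, r3])
    assert average_replicate_correlation(rs) == pytest.approx(0.7, abs=1e-12)


def test_zero_variance_replicate_errors():
    rs = ReplicateSet(key=("d", "c", 1.0, 24.0),
                      replicates=[np.ones(4), np.array([1.0, 2, 3, 4])])
    with pytest.raises(ValueError, match="variance"):
        average_replicate_correlation(rs)


def _set_with_exact_correlation(which: str) -> ReplicateSet:
    # integer constructions whose centered sums are perfect squares, so the
    # Pearson value is exact in floating point (0.7 or 0.75)
    if which == "boundary":
        x = np.array([7.0, -7, 0, 0, 0, 0])
        y = np.array([12.0, -2, -4, -6, 0, 0])   # r = 98/140 = 0.7 exactly
    else:
        x = np.array([3.0, -3, 0, 0, 0, 0])
        y = np.array([4.0, -2, -3, 1, 1, -1])    # r = 18/24 = 0.75 exactly
    return ReplicateSet(key=("d", which, 1.0, 24.0), replicates=[x, y])


def test_partition_is_strict_at_the_boundary():
    at = _set_with_exact_correlation("boundary")
    above = _set_with_exact_correlation("above")
    assert average_replicate_correlation(at) == 0.7
    assert average_replicate_correlation(above) == 0.75
    high, low = partition_by_quality([at, above])
    assert [rs.key[1] for rs in high] == ["above"]
    assert [rs.key[1] for rs in low] == ["boundary"]


def test_single_replicate_goes_to_low():
    rs = ReplicateSet(key=("d", "c", 1.0, 24.0), replicates=[np.arange(4.0)])
    high, low = partition_by_quality([rs])
    assert high == [] and low == [rs]


def test_partition_is_a_partition(rng):
    sets = []
    for i in range(20):
        base = rng.normal(size=30)
        noise = rng.uniform(0.1, 3.0)
        sets.append(ReplicateSet(
            key=("d", f"c{i}", 1.0, 24.0),
            replicates=[base + rng.normal(0, noise, 30) for _ in range(3)]))
    high, low = partition_by_quality(sets)
    assert len(high) + len(low) == len(sets)
    assert {id(s) for s in high}.isdisjoint({id(s) for s in low})


def test_empty_input_partitions_to_empty():
    assert partition_by_quality([]) == ([], [])


def test_threshold_outside_open_interval_errors():
    with pytest.raises(ValueError):
        partition_by_quality([], threshold=1.0)


def test_group_replicates_merges_by_key():
    r1 = PerturbationRecord("d", "CC", "c", 1.0, 24.0, np.array([1.0, 2.0]))
    r2 = PerturbationRecord("d", "CC", "c", 1.0, 24.0, np.array([3.0, 4.0]))
    r3 = PerturbationRecord("d", "CC", "c", 10.0, 24.0, np.array([0.0, 0.0]))
    sets = group_replicates([r1, r2, r3])
    assert sorted(len(s.replicates) for s in sets) == [1, 2]
    merged = next(s for s in sets if len(s.replicates) == 2)
    np.testing.assert_array_equal(merged.consensus(), [2.0, 3.0])
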