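"""Enrichment statistic, permutation null, screening and patient clustering."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from perturbcast.dose_response import HillParams
from perturbcast.repurposing import (
    NullDistribution,
    PatientSignature,
    RankedProfile,
    build_null,
    cluster_patients,
    enrichment_score,
    hypergeom_enrich,
    p_value,
    reverse_similarity,
    screen_patient,
    smooth_null,
    N_BINS,
)


def brute_force_es(values: dict, query: set) -> float:
    """Literal evaluation of the running statistic, double loop."""
    m = len(values)
    n_q = len(query)
    ds = []
    for i in query:
        g_i = values[i]
        global_term = sum(1 for j in values if values[j] < g_i) / m
        local_term = sum(1 for j in query if values[j] < g_i) / n_q
        ds.append(global_term - local_term)
    sup, inf = max(ds), min(ds)
    return sup if abs(sup) >= abs(inf) else inf


def _profile(values):
    return RankedProfile(gene_ids=list(values), values=np.array(list(values.values())))


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def test_full_query_self_cancels():
    vals = {"a": 3.0, "b": 1.0, "c": 2.0, "d": -1.0}
    assert enrichment_score(_profile(vals), set(vals)) == 0.0


def test_single_gene_hand_value():
    vals = {"A": 4.0, "B": 3.0, "C": 2.0, "D": 1.0}
    assert enrichment_score(_profile(vals), {"A"}) == pytest.approx(0.75)


def test_matches_bruteforce_exactly(rng):
    for _ in range(1000):
        m = int(rng.integers(5, 51))
        vals = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=m))}
        n_q = int(rng.integers(1, m + 1))
        query = set(rng.choice(list(vals), size=n_q, replace=False))
        assert enrichment_score(_profile(vals), query) == brute_force_es(vals, query)


def test_ties_contribute_nothing():
    vals = {"a": 1.0, "b": 1.0, "c": 1.0}
    # all values tie: every indicator is 0, so every D is 0
    assert enrichment_score(_profile(vals), {"a", "b"}) == 0.0


def test_missing_query_genes_reported():
    vals = {"a": 1.0, "b": 2.0}
    with pytest.raises(ValueError, match="zz"):
        enrichment_score(_profile(vals), {"a", "zz"})


def test_es_bounded(rng):
    for _ in range(100):
        m = int(rng.integers(3, 40))
        vals = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=m))}
        q = set(rng.choice(list(vals), size=int(rng.integers(1, m + 1)),
                           replace=False))
        assert abs(enrichment_score(_profile(vals), q)) <= 1.0


# ---------------------------------------------------------------------------
# reverse similarity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("up,down,want", [
    (-0.5, 0.3, 0.2),
    (0.4, 0.2, 0.0),
    (0.5, -0.7, 0.2),
    (0.0, 0.5, 0.0),
    (-1.0, 1.0, 0.0),   # product is -1 < 0 -> -(0) = 0
])
def test_reverse_similarity_cases(up, down, want):
    assert reverse_similarity(up, down) == pytest.approx(want)


def test_reverse_similarity_piecewise_algebra(rng):
    pairs = rng.uniform(-1, 1, size=(10000, 2))
    for up, down in pairs:
        got = reverse_similarity(up, down)
        if up * down < 0:
            assert got == -(up + down)
        else:
            assert got == 0.0


def test_out_of_range_scores_rejected():
    with pytest.raises(ValueError):
        reverse_similarity(1.5, -0.2)


# ---------------------------------------------------------------------------
# permutation null and p-values
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def random_profile():
    rng = np.random.default_rng(11)
    m = 120
    return RankedProfile(gene_ids=[f"g{i}" for i in range(m)],
                         values=rng.normal(size=m))


def test_null_conservation_and_determinism(random_profile):
    nd1 = build_null(random_profile, 8, 8, n_perms=500, rng_seed=3)
    nd2 = build_null(random_profile, 8, 8, n_perms=500, rng_seed=3)
    assert nd1.counts.sum() == 500
    np.testing.assert_array_equal(nd1.counts, nd2.counts)
    np.testing.assert_array_equal(nd1.density, nd2.density)
    assert len(nd1.counts) == N_BINS


def test_null_infeasible_sizes(random_profile):
    with pytest.raises(ValueError):
        build_null(random_profile, 100, 100, n_perms=10)


def test_smooth_constant_counts_stay_constant():
    edges = np.linspace(-1, 1, N_BINS + 1)
    counts = np.full(N_BINS, 7.0)
    nd = NullDistribution(bin_edges=edges, counts=counts, n_perms=7 * N_BINS,
                          statistic="es")
    sm = smooth_null(nd)
    np.testing.assert_allclose(sm.density, sm.density[0])
    assert sm.density.sum() * sm.bin_width == pytest.approx(1.0)


def test_smooth_recovers_exponential_quadratic_family():
    edges = np.linspace(-1, 1, N_BINS + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.exp(1 + 2 * centers)
    nd = NullDistribution(bin_edges=edges, counts=counts,
                          n_perms=int(counts.sum()), statistic="es")
    # bypass the sum check: use exact float histogram
    nd.counts = counts
    sm = smooth_null(nd)
    want = counts / (counts.sum() * sm.bin_width)
    inner = slice(10, N_BINS - 10)
    np.testing.assert_allclose(sm.density[inner], want[inner], rtol=1e-6)


def test_smooth_window_narrower_than_bin_errors(random_profile):
    nd = build_null(random_profile, 8, 8, n_perms=200, rng_seed=0, smooth=False)
    with pytest.raises(ValueError):
        smooth_null(nd, window=1e-5)


def test_p_value_extremes_and_monotonicity(random_profile):
    nd = build_null(random_profile, 8, 8, n_perms=1000, rng_seed=1)
    assert p_value(-1.0, nd) == pytest.approx(1.0)
    assert p_value(1.0, nd) == pytest.approx(1.0 / 1001.0)
    xs = np.linspace(-1, 1, 101)
    ps = [p_value(float(x), nd) for x in xs]
    assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))
    with pytest.raises(ValueError):
        p_value(1.5, nd)


def test_unsmoothed_null_has_no_pvalue(random_profile):
    nd = build_null(random_profile, 8, 8, n_perms=100, rng_seed=0, smooth=False)
    with pytest.raises(ValueError, match="smooth"):
        p_value(0.0, nd)


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def _library(rng, n_drugs=8, m=80):
    gene_ids = [f"g{i}" for i in range(m)]
    return {f"d{i}": RankedProfile(gene_ids=gene_ids, values=rng.normal(size=m))
            for i in range(n_drugs)}


def test_screen_orders_by_p_then_score(rng):
    lib = _library(rng)
    sig = PatientSignature("p0", up_genes={f"g{i}" for i in range(6)},
                           down_genes={f"g{i}" for i in range(6, 12)})
    res = screen_patient(sig, lib, n_perms=300, rng_seed=0)
    keys = [(r.p_value, -r.score, r.drug_id) for r in res]
    assert keys == sorted(keys)
    assert {r.drug_id for r in res} == set(lib)


def test_screen_zero_score_never_beats_positive(rng):
    lib = _library(rng)
    sig = PatientSignature("p0", up_genes={f"g{i}" for i in range(6)},
                           down_genes={f"g{i}" for i in range(6, 12)})
    res = screen_patient(sig, lib, n_perms=300, rng_seed=0)
    by_drug = {r.drug_id: r for r in res}
    zeros = [r for r in res if r.score == 0.0]
    positives = [r for r in res if r.score > 0.0]
    for z in zeros:
        for p in positives:
            assert z.p_value >= p.p_value - 1e-12


def test_toxic_drug_kept_in_output_but_not_candidate(rng):
    lib = _library(rng, n_drugs=4)
    sig = PatientSignature("p0", up_genes={f"g{i}" for i in range(6)},
                           down_genes={f"g{i}" for i in range(6, 12)})
    viability = {d: HillParams(E0=1.0, Einf=0.95, EC50=5.0, H=1.0) for d in lib}
    viability["d2"] = HillParams(E0=1.0, Einf=0.3, EC50=1 / 6, H=1.0)  # 0.4 @ 1uM
    res = screen_patient(sig, lib, viability=viability, alpha=1.0,
                         n_perms=300, rng_seed=0)
    r2 = next(r for r in res if r.drug_id == "d2")
    assert not r2.safe and not r2.candidate
    assert any(r.candidate for r in res if r.drug_id != "d2")


def test_screen_invariant_to_drug_input_order(rng):
    lib = _library(rng)
    sig = PatientSignature("p0", up_genes={f"g{i}" for i in range(6)},
                           down_genes={f"g{i}" for i in range(6, 12)})
    res1 = screen_patient(sig, lib, n_perms=200, rng_seed=0)
    shuffled = dict(reversed(list(lib.items())))
    res2 = screen_patient(sig, shuffled, n_perms=200, rng_seed=0)
    assert [r.drug_id for r in res1] == [r.drug_id for r in res2]


def test_small_signature_skipped(rng):
    lib = _library(rng)
    sig = PatientSignature("p0", up_genes={"g0", "g1"}, down_genes={"g2"})
    assert screen_patient(sig, lib, n_perms=100, rng_seed=0) == []


# ---------------------------------------------------------------------------
# patient clustering
# ---------------------------------------------------------------------------

def test_identical_signatures_one_cluster():
    gene_ids = [f"g{i}" for i in range(30)]
    sigs = [PatientSignature(f"p{i}", {"g0", "g1"}, {"g2", "g3"})
            for i in range(4)]
    labels = cluster_patients(sigs, gene_ids)
    assert len(set(labels.values())) == 1
    assert set(labels) == {f"p{i}" for i in range(4)}


def test_two_planted_groups_recovered():
    gene_ids = [f"g{i}" for i in range(40)]
    group_a = [PatientSignature(f"a{i}", {f"g{j}" for j in range(6)},
                                {f"g{j}" for j in range(6, 12)})
               for i in range(5)]
    group_b = [PatientSignature(f"b{i}", {f"g{j}" for j in range(20, 26)},
                                {f"g{j}" for j in range(26, 32)})
               for i in range(5)]
    labels = cluster_patients(group_a + group_b, gene_ids)
    truth = [0] * 5 + [1] * 5
    got = [labels[s.patient_id] for s in group_a + group_b]
    assert adjusted_rand_score(truth, got) == 1.0


def test_cluster_needs_two_patients():
    with pytest.raises(ValueError):
        cluster_patients([PatientSignature("p", {"g0"}, set())], ["g0"])


# ---------------------------------------------------------------------------
# hypergeometric enrichment
# ---------------------------------------------------------------------------

def test_hypergeom_exact_example():
    universe = {f"d{i}" for i in range(10)}
    annotation = {f"d{i}": {"T"} for i in range(4)}   # K = 4 annotated
    candidates = {"d0", "d1", "d2", "d8", "d9"}       # n = 5, k = 3
    p = hypergeom_enrich(candidates, universe, annotation)["T"]
    assert p == pytest.approx(66 / 252)


def test_hypergeom_zero_hits_gives_one():
    universe = {f"d{i}" for i in range(10)}
    annotation = {f"d{i}": {"T"} for i in range(4)}
    p = hypergeom_enrich({"d8", "d9"}, universe, annotation)["T"]
    assert p == pytest.approx(1.0)


def test_hypergeom_candidates_equal_universe():
    universe = {f"d{i}" for i in range(6)}
    annotation = {"d0": {"T"}, "d1": {"T"}, "d2": {"U"}}
    ps = hypergeom_enrich(universe, universe, annotation)
    assert all(p == pytest.approx(1.0) for p in ps.values())


def test_hypergeom_requires_subset():
    with pytest.raises(ValueError):
        hypergeom_enrich({"x"}, {"y"}, {})
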