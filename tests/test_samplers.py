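"""Sampler behaviour: exact small-instance optima, constraints, determinism."""

import itertools
import math

import numpy as np
import pytest

from germcore import (
    CollectionDataset,
    SamplerConfig,
    allelic_coverage,
    compare_methods,
    dce_matrix,
    redundancy_minimum_size,
    sample_asls,
    sample_m_method,
    sample_mlst,
    sample_random,
    shannon_pooled,
    simple_matching_matrix,
)

from conftest import make_table, random_table


def _ds(table):
    return CollectionDataset(table)


# ---------------------------------------------------------------------------
# random baseline
# ---------------------------------------------------------------------------


def test_random_exhaustive_and_deterministic(small_collection):
    dataset, _ = small_collection
    whole = sample_random(dataset, dataset.n_accessions, seed=1)
    assert set(whole.ids) == set(dataset.accession_ids)
    assert sample_random(dataset, 10, seed=5).ids == sample_random(dataset, 10, seed=5).ids
    with pytest.raises(ValueError):
        sample_random(dataset, dataset.n_accessions + 1)


def test_random_is_uniform_over_pairs():
    table = make_table({f"g{i}": [("A", "B")] for i in range(4)})
    dataset = _ds(table)
    counts = {}
    for seed in range(1000):
        pair = tuple(sorted(sample_random(dataset, 2, seed=seed).ids))
        counts[pair] = counts.get(pair, 0) + 1
    # each of the 6 pairs should appear ~1/6 of the time (+-3 binomial SD)
    sd = math.sqrt(1000 * (1 / 6) * (5 / 6))
    for pair_count in counts.values():
        assert abs(pair_count - 1000 / 6) <= 3 * sd
    assert len(counts) == 6


# ---------------------------------------------------------------------------
# M-method
# ---------------------------------------------------------------------------


def _cover_toy():
    # accessions g1 and g4 jointly carry all eight alleles
    return make_table(
        {
            "g1": [("a", "b"), ("e", "f")],
            "g2": [("a", "a"), ("e", "e")],
            "g3": [("b", "b"), ("f", "f")],
            "g4": [("c", "d"), ("g", "h")],
            "g5": [("c", "c"), ("g", "g")],
            "g6": [("a", "c"), ("e", "g")],
        }
    )


def test_m_method_attains_exhaustive_cover_optimum():
    table = _cover_toy()
    dataset = _ds(table)
    # exhaustive search over all size-2 subsets
    best = max(
        allelic_coverage(table, list(pair))[0]
        for pair in itertools.combinations(table.accession_ids, 2)
    )
    assert best == 8
    core = sample_m_method(dataset, 2, replicates=5, seed=0)[0]
    assert allelic_coverage(table, core.ids)[0] == 8


def test_m_method_kernel_always_included(small_collection):
    dataset, _ = small_collection
    kernel = dataset.accession_ids[:5]
    for run in sample_m_method(dataset, 20, kernel=kernel, replicates=3, seed=1):
        assert set(kernel) <= set(run.ids)
        assert len(run.ids) == 20
    with pytest.raises(ValueError):
        sample_m_method(dataset, 3, kernel=kernel)


def test_m_method_replicates_ranked_by_categories_then_shannon(small_collection):
    dataset, _ = small_collection
    runs = sample_m_method(dataset, 15, replicates=6, seed=3)
    keys = [(r.provenance["categories_covered"], r.provenance["sh"]) for r in runs]
    assert keys == sorted(keys, reverse=True)


def test_m_method_deterministic(small_collection):
    dataset, _ = small_collection
    a = sample_m_method(dataset, 12, replicates=3, seed=9)[0]
    b = sample_m_method(dataset, 12, replicates=3, seed=9)[0]
    assert a.ids == b.ids


# ---------------------------------------------------------------------------
# redundancy curve / minimal size
# ---------------------------------------------------------------------------


def test_redundancy_private_alleles_force_full_collection():
    table = make_table({f"g{i}": [(f"p{i}", f"p{i}")] for i in range(5)})
    curve = redundancy_minimum_size(_ds(table), seed=0)
    assert curve.minimal_size == 5


def test_redundancy_single_carrier_covers_alone():
    table = make_table(
        {"all": [("a", "b"), ("c", "d")], "g1": [("a", "a"), ("c", "c")],
         "g2": [("b", "b"), ("d", "d")]}
    )
    curve = redundancy_minimum_size(_ds(table), seed=0)
    assert curve.minimal_size == 1
    # with a kernel, the minimum cannot undercut the kernel size
    curve_k = redundancy_minimum_size(_ds(table), kernel=("g1", "g2"), seed=0)
    assert curve_k.minimal_size == 2


def _exact_min_cover(table):
    ids = table.accession_ids
    total = table.n_alleles_total
    for k in range(1, len(ids) + 1):
        for combo in itertools.combinations(ids, k):
            if allelic_coverage(table, list(combo))[0] == total:
                return k
    return len(ids)


def test_redundancy_matches_exhaustive_min_cover():
    rng = np.random.default_rng(17)
    for trial in range(10):
        table = random_table(rng, 9, 3, 4)
        curve = redundancy_minimum_size(_ds(table), replicates=5, seed=trial)
        assert curve.minimal_size == _exact_min_cover(table)
        sizes = [s for s, _ in curve.points]
        covered = [c for _, c in curve.points]
        assert covered == sorted(covered)  # curve non-decreasing over probed sizes
        assert sizes == sorted(sizes)


# ---------------------------------------------------------------------------
# ASLS
# ---------------------------------------------------------------------------


def test_asls_shannon_strategy_avoids_clone_pair():
    table = make_table(
        {
            "c1": [("A", "A"), ("X", "X")],
            "c2": [("A", "A"), ("X", "X")],  # clone of c1
            "d1": [("B", "C"), ("Y", "Z")],
            "d2": [("D", "E"), ("W", "V")],
        }
    )
    dataset = _ds(table)
    best_pair = max(
        itertools.combinations(table.accession_ids, 2),
        key=lambda pair: shannon_pooled(table, list(pair)),
    )
    core = sample_asls(dataset, 2, {"Sh": 1}, replicas=4, steps=300, seed=2)
    assert set(core.ids) == set(best_pair)
    assert set(core.ids) != {"c1", "c2"}


def test_asls_coverage_strategy_attains_cover():
    dataset = _ds(_cover_toy())
    core = sample_asls(dataset, 2, {"Cv": 1}, replicas=4, steps=300, seed=1)
    assert allelic_coverage(dataset.genotypes, core.ids)[0] == 8


def test_asls_distance_strategy_picks_farthest_pair():
    table = make_table(
        {
            "g1": [("A", "A"), ("X", "X")],
            "g2": [("A", "B"), ("X", "Y")],
            "g3": [("C", "C"), ("Z", "Z")],
            "g4": [("A", "A"), ("X", "Z")],
        }
    )
    d = dce_matrix(table)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    expected = {table.accession_ids[i], table.accession_ids[j]}
    core = sample_asls(_ds(table), 2, {"Dce": 1}, replicas=4, steps=300, seed=0)
    assert set(core.ids) == expected


def test_asls_rejects_all_zero_weights(small_collection):
    dataset, _ = small_collection
    with pytest.raises(ValueError):
        sample_asls(dataset, 10, {"Sh": 0.0, "Cv": 0.0})
    with pytest.raises(ValueError):
        sample_asls(dataset, 10, {"bogus": 1.0})


def test_asls_deterministic(small_collection):
    dataset, _ = small_collection
    a = sample_asls(dataset, 12, {"Sh": 1}, replicas=2, steps=400, seed=4)
    b = sample_asls(dataset, 12, {"Sh": 1}, replicas=2, steps=400, seed=4)
    assert a.ids == b.ids


# ---------------------------------------------------------------------------
# MLST
# ---------------------------------------------------------------------------


def _nj4_external_edges(d):
    """Independent 4-taxon neighbor-joining external edge lengths for the
    cherry joined first (standard NJ formulas)."""
    n = 4
    r = d.sum(axis=1)
    q = (n - 2) * d - r[:, None] - r[None, :]
    np.fill_diagonal(q, np.inf)
    i, j = np.unravel_index(np.argmin(q), q.shape)
    ei = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (n - 2))
    ej = d[i, j] - ei
    return (i, ei), (j, ej)


def test_mlst_removes_shorter_edge_of_near_duplicate_pair():
    table = make_table(
        {
            "A": [("a", "a"), ("x", "x"), ("m", "m"), ("q", "q")],
            "B": [("a", "a"), ("x", "x"), ("m", "m"), ("q", "r")],  # near-dup of A
            "C": [("b", "b"), ("y", "y"), ("n", "n"), ("r", "s")],  # shares r with B
            "D": [("c", "c"), ("z", "z"), ("o", "o"), ("t", "t")],
        }
    )
    d = simple_matching_matrix(table)
    (i, ei), (j, ej) = _nj4_external_edges(d)
    cherry_ids = {table.accession_ids[i], table.accession_ids[j]}
    assert cherry_ids == {"A", "B"}
    expected_victim = table.accession_ids[i] if ei < ej else table.accession_ids[j]
    core = sample_mlst(_ds(table), 3)
    assert set(core.ids) == set(table.accession_ids) - {expected_victim}


def test_mlst_whole_collection_and_tie_determinism():
    # star configuration: all pairs equally dissimilar
    table = make_table(
        {
            "A": [("a", "a"), ("x", "x")],
            "B": [("b", "b"), ("y", "y")],
            "C": [("c", "c"), ("z", "z")],
            "D": [("d", "d"), ("w", "w")],
        }
    )
    dataset = _ds(table)
    assert set(sample_mlst(dataset, 4).ids) == set(table.accession_ids)
    first = sample_mlst(dataset, 3).ids
    assert first == sample_mlst(dataset, 3).ids  # stable under ties


# ---------------------------------------------------------------------------
# method comparison table
# ---------------------------------------------------------------------------


def test_compare_methods_self_comparison_trivial(small_collection):
    dataset, _ = small_collection
    n = dataset.n_accessions
    configs = [SamplerConfig("RANDOM"), SamplerConfig("M", replicates=1, iterations=1)]
    out = compare_methods(dataset, n, configs, seed=0)
    # a core equal to the whole collection differs from it in nothing
    assert (out["Cv_pct"] == 100.0).all()
    assert np.allclose(out["p_richness_mw"], 1.0)
    assert np.allclose(out["p_sh_paired_t"], 1.0)
    assert not out["richness_differs"].any()


def test_compare_methods_structured_contrast(small_collection):
    dataset, _ = small_collection
    size = round(0.16 * dataset.n_accessions)
    configs = [
        SamplerConfig("ASLS", weights={"Sh": 1}, replicates=4, steps=800, label="ASLS/Sh"),
        SamplerConfig("RANDOM"),
    ]
    out = compare_methods(dataset, size, configs, seed=2)
    assert out.loc["ASLS/Sh", "Sh"] > out.loc["RANDOM", "Sh"]
    assert out.loc["ASLS/Sh", "n_references"] <= 5
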