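"""Kinship, LD, ordination and certification-test machinery."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from germcore import (
    GenotypeTable,
    QMatrixInput,
    evanno_delta_k,
    generate_equilibrium_panel,
    kinship_histogram,
    ld_pairwise,
    ld_significance_classes,
    loiselle_kinship,
    mann_whitney_u,
    paired_t,
    pcoa,
)
from germcore.evaluation import KinshipMatrix

from conftest import make_table


# ---------------------------------------------------------------------------
# Loiselle kinship
# ---------------------------------------------------------------------------


def _loiselle_oracle(table: GenotypeTable):
    """Brute-force, loop-based evaluation of the Loiselle estimator
    (raw values, before negative truncation)."""
    n, L = table.n_accessions, table.n_loci
    # per-locus allele frequencies over the whole panel
    freqs = []
    copies = []
    for l in range(L):
        counts: dict[int, float] = {}
        total = 0
        for i in range(n):
            if table.observed[i, l]:
                for c in table.codes[i, l]:
                    counts[c] = counts.get(c, 0) + 1
                total += 2
        freqs.append({c: v / total for c, v in counts.items()})
        copies.append(total)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = 0.0
            den = 0.0
            for l in range(L):
                if not (table.observed[i, l] and table.observed[j, l]):
                    continue
                for allele, p in freqs[l].items():
                    xi = sum(0.5 for c in table.codes[i, l] if c == allele)
                    xj = sum(0.5 for c in table.codes[j, l] if c == allele)
                    num += (xi - p) * (xj - p) + p * (1 - p) / (copies[l] - 1)
                    den += p * (1 - p)
            out[i, j] = num / den
    return out


def test_loiselle_matches_bruteforce_oracle():
    table = make_table(
        {
            "g1": [("A", "A"), ("X", "Y"), ("M", "M")],
            "g2": [("A", "B"), ("X", "X"), ("M", "N")],
            "g3": [("B", "B"), ("Y", "Y"), None],
            "g4": [("A", "C"), ("X", "Z"), ("N", "N")],
            "g5": [("C", "C"), ("Z", "Z"), ("M", "N")],
            "g6": [("A", "A"), ("Y", "Z"), ("M", "M")],
        }
    )
    raw = _loiselle_oracle(table)
    k = loiselle_kinship(table)
    assert (raw < 0).any()  # fixture produces genuinely negative raw estimates
    expected = np.where(raw < 0, 0.0, raw)
    iu = np.triu_indices(6, k=1)
    assert np.allclose(k.values[iu], expected[iu], atol=1e-10)
    assert (k.values >= 0).all()


def test_clone_pair_has_highest_kinship():
    table = make_table(
        {
            "c1": [("A", "B"), ("X", "Y")],
            "c2": [("A", "B"), ("X", "Y")],  # clone of c1
            "g3": [("C", "C"), ("Z", "Z")],
            "g4": [("A", "C"), ("X", "Z")],
            "g5": [("B", "D"), ("Y", "W")],
            "g6": [("D", "D"), ("W", "W")],
        }
    )
    k = loiselle_kinship(table)
    clone_val = k.values[0, 1]
    others = [k.values[0, j] for j in range(2, 6)] + [k.values[1, j] for j in range(2, 6)]
    assert clone_val > max(others)


def test_kinship_invariant_under_relabeling():
    rng = np.random.default_rng(2)
    eq = generate_equilibrium_panel(12, 5, 4, seed=8)
    k = loiselle_kinship(eq)
    perm = rng.permutation(12)
    ids = [eq.accession_ids[i] for i in perm]
    k2 = loiselle_kinship(eq, subset=ids)
    assert np.allclose(k2.values, k.values[np.ix_(perm, perm)])


def test_kinship_histogram_binning():
    ids = tuple("abcd")
    zero = KinshipMatrix(ids, np.zeros((4, 4)))
    _, freq = kinship_histogram(zero)
    assert freq[0] == 1.0
    capped = KinshipMatrix(ids, np.full((4, 4), 0.47))
    _, freq_cap = kinship_histogram(capped)
    assert freq_cap[-1] == 1.0  # 0.47 lands in the open [0.45, inf) bin
    rng = np.random.default_rng(0)
    vals = np.abs(rng.normal(0.1, 0.2, size=(8, 8)))
    m = KinshipMatrix(tuple(f"g{i}" for i in range(8)), (vals + vals.T) / 2)
    _, f = kinship_histogram(m)
    assert f.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


def test_duplicated_locus_gives_perfect_r2():
    eq = generate_equilibrium_panel(80, 1, 2, seed=3)
    calls = [[eq.call(a, "SSR01")] * 2 for a in eq.accession_ids]
    dup = GenotypeTable.from_calls(eq.accession_ids, ["A", "B"], calls)
    res = ld_pairwise(dup, n_perm=99, seed=0)
    row = res.pairs.iloc[0]
    assert row["r2"] == pytest.approx(1.0, abs=1e-12)
    assert row["p_value"] == pytest.approx(1 / 100)  # minimum attainable


def test_ld_pair_count_and_filter():
    eq = generate_equilibrium_panel(100, 17, 8, seed=5)
    res = ld_pairwise(eq, min_allele_freq=0.0, n_perm=9, seed=1)
    assert len(res.pairs) == math.comb(17, 2) == 136
    # the frequency filter reduces retained allele counts, never below 2
    res_f = ld_pairwise(eq, min_allele_freq=0.05, n_perm=9, seed=1)
    assert all(v >= 2 for v in res_f.retained_alleles.values())


def test_ld_pvalues_not_subuniform_under_equilibrium():
    eq = generate_equilibrium_panel(150, 15, 6, seed=21)
    res = ld_pairwise(eq, n_perm=199, seed=4)
    p = res.pairs["p_value"].to_numpy()
    assert len(p) == 105
    # permutation p-values are stochastically >= uniform under the null
    ks = stats.kstest(p, "uniform", alternative="greater")
    assert ks.pvalue > 0.01
    assert p.mean() > 0.40


def test_ld_significance_classes_partition():
    eq = generate_equilibrium_panel(60, 6, 4, seed=2)
    res = ld_pairwise(eq, n_perm=49, seed=0)
    classes = ld_significance_classes(res)
    assert classes.sum() == len(res.pairs)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


def test_pcoa_equilateral_symmetry():
    d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
    res = pcoa(d, n_axes=2)
    assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])
    assert res.explained[0] == pytest.approx(res.explained[1]) == pytest.approx(0.5)


def test_pcoa_roundtrip_of_planar_points():
    rng = np.random.default_rng(9)
    pts = rng.normal(size=(7, 2))
    d = squareform(pdist(pts))
    res = pcoa(d, n_axes=2)
    recovered = squareform(pdist(res.coordinates))
    assert np.allclose(recovered, d, atol=1e-8)
    assert res.explained.sum() == pytest.approx(1.0, abs=1e-8)


def test_pcoa_rejects_asymmetric_input():
    with pytest.raises(ValueError):
        pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))


def test_pcoa_agrees_with_skbio():
    from skbio.stats.ordination import pcoa as skbio_pcoa

    rng = np.random.default_rng(4)
    pts = rng.normal(size=(10, 3))
    d = squareform(pdist(pts))
    ours = pcoa(d, n_axes=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        theirs = skbio_pcoa(d)
    assert np.allclose(
        np.abs(ours.coordinates), np.abs(theirs.samples.to_numpy()[:, :3]), atol=1e-8
    )


# ---------------------------------------------------------------------------
# Evanno ΔK and certification tests
# ---------------------------------------------------------------------------


def test_evanno_hand_computed_value():
    ll = {1: [-1000, -1000], 2: [-890, -910], 3: [-880, -880]}
    dk = evanno_delta_k(ll)
    sd2 = np.std([-890, -910], ddof=1)
    assert dk[2] == pytest.approx(abs(-880 - 2 * (-900) + (-1000)) / sd2)
    assert dk[2] == pytest.approx(8 * (10 / sd2))


def test_evanno_linear_means_and_zero_variance():
    linear = {2: [-900.0, -902.0], 3: [-800.0, -802.0], 4: [-700.0, -702.0]}
    assert evanno_delta_k(linear)[3] == pytest.approx(0.0)
    with pytest.warns(UserWarning, match="zero spread"):
        dk = evanno_delta_k({2: [-900.0, -900.0], 3: [-800.0, -800.0], 4: [-700.0, -700.0]})
    assert np.isnan(dk[3])
    with pytest.raises(ValueError):
        evanno_delta_k({2: [-900, -901], 4: [-700, -701], 5: [-600, -601]})


def test_mann_whitney_exact_enumeration():
    u, p = mann_whitney_u([1, 2], [3, 4])
    assert u == 0.0
    assert p == pytest.approx(2 / 6)
    _, p_same = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p_same == pytest.approx(1.0)


def test_mann_whitney_asymptotic_close_to_exact():
    rng = np.random.default_rng(7)
    for _ in range(10):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        _, p_asym = mann_whitney_u(x, y)
        p_exact = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert abs(p_asym - p_exact) < 0.02


def test_paired_t_zero_variance_warns():
    with pytest.warns(UserWarning, match="zero variance"):
        _, p = paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
    assert p == 1.0
    t, p2 = paired_t([1.0, 2.0, 3.5], [1.2, 1.8, 3.0])
    assert 0 < p2 <= 1


def test_qmatrix_validation_and_admixture_report():
    q = pd.DataFrame({"p1": [0.9, 0.5, 0.2], "p2": [0.1, 0.5, 0.8]},
                     index=["a", "b", "c"])
    qm = QMatrixInput(q)
    assert qm.admixed_ids(threshold=0.8) == ("b",)
    bad = q.copy()
    bad.iloc[0, 0] = 0.5
    with pytest.raises(ValueError):
        QMatrixInput(bad)
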