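import itertools

import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import random_matrix
from island_popgen.genotype_io import GenotypeMatrix, merge_populations
from island_popgen import popgen_stats as ps


def _single_pop(genotypes, name="p", locus="L1"):
    arr = np.array(genotypes, dtype=np.int64)[:, None, :]
    return GenotypeMatrix(
        [f"i{k}" for k in range(len(genotypes))], [locus], arr, [name] * len(genotypes)
    )


# ---------------------------------------------------------------- frequencies

def test_allele_frequencies_simple_counts():
    g = _single_pop([(100, 102), (100, 100)])
    f = ps.allele_frequencies(g)["p"][0]
    assert f == {100: 0.75, 102: 0.25}


def test_allele_frequencies_all_missing_flagged():
    g = _single_pop([(0, 0), (0, 0)])
    assert ps.allele_frequencies(g)["p"][0] is None


def test_merged_frequencies_are_count_weighted_average():
    # 6-individual fixture split 4/2: recounted by hand
    g = GenotypeMatrix(
        [f"i{k}" for k in range(6)],
        ["L1"],
        np.array([[[1, 1]], [[1, 2]], [[2, 2]], [[1, 2]],
                  [[2, 2]], [[2, 3]]]),
        ["a"] * 4 + ["b"] * 2,
    )
    merged = merge_populations(g, {"b": "a"})
    f = ps.allele_frequencies(merged)["a"][0]
    # hand count over 12 copies: allele1 x4, allele2 x7, allele3 x1
    assert f == {1: 4 / 12, 2: 7 / 12, 3: 1 / 12}


# ------------------------------------------------------------ allelic richness

def test_richness_full_sample_equals_allele_count():
    g = _single_pop([(10, 10), (12, 12)])
    out = ps.allelic_richness(g, rarefaction_size=4)
    assert out["A_R"].iloc[0] == pytest.approx(2.0)


def test_richness_pair_subsample_hand_value():
    # copies {10,10,10,12}, g=2: 3 of 6 pairs are monomorphic -> 1.5
    g = _single_pop([(10, 10), (10, 12)])
    out = ps.allelic_richness(g, rarefaction_size=2)
    assert out["A_R"].iloc[0] == pytest.approx(1.5)


def test_richness_matches_exhaustive_enumeration():
    rng = np.random.default_rng(7)
    for _ in range(20):
        n_cop = int(rng.integers(4, 9)) // 2 * 2
        copies = rng.integers(8, 12, size=n_cop).tolist()
        g = _single_pop([tuple(copies[i:i + 2]) for i in range(0, n_cop, 2)])
        for g_size in range(2, n_cop + 1):
            got = ps.allelic_richness(g, rarefaction_size=g_size)["A_R"].iloc[0]
            want = oracles.brute_allelic_richness(copies, g_size)
            assert got == pytest.approx(want, abs=1e-12)


def test_richness_auto_uses_min_copies_and_respects_bounds(three_pop_matrix):
    out = ps.allelic_richness(three_pop_matrix, "auto")
    # popA has a missing genotype at locB: min copies there is 2*2=4
    assert out["A_R"].dropna().between(1, 10).all()


def test_richness_size_below_two_errors(three_pop_matrix):
    with pytest.raises(ValueError):
        ps.allelic_richness(three_pop_matrix, rarefaction_size=1)


# ----------------------------------------------------------- heterozygosities

def test_monomorphic_locus_zero_heterozygosity():
    g = _single_pop([(7, 7), (7, 7)])
    row = ps.heterozygosities(g).iloc[0]
    assert row["H_O"] == 0.0 and row["H_E"] == 0.0


def test_unbiased_h_e_two_heterozygotes():
    g = _single_pop([(100, 102), (100, 102)])
    row = ps.heterozygosities(g).iloc[0]
    assert row["H_O"] == 1.0
    assert row["H_E"] == pytest.approx((4 / 3) * 0.5)


def test_single_typed_individual_flagged():
    g = _single_pop([(1, 2), (0, 0)])
    assert np.isnan(ps.heterozygosities(g)["H_E"].iloc[0])


def test_heterozygosities_match_bruteforce_on_random_fixtures():
    rng = np.random.default_rng(11)
    for _ in range(10):
        g = random_matrix(rng, n_pops=3, n_per_pop=6, n_loci=2)
        table = ps.heterozygosities(g).set_index(["population", "locus"])
        for pop in g.populations():
            idx = g.population_indices(pop)
            for j, locus in enumerate(g.locus_names):
                genos = [tuple(g.alleles[i, j]) for i in idx]
                assert table.loc[(pop, locus), "H_O"] == pytest.approx(
                    oracles.brute_h_o(genos), abs=1e-12)
                assert table.loc[(pop, locus), "H_E"] == pytest.approx(
                    oracles.brute_h_e(genos), abs=1e-12)


def test_duplicating_population_changes_h_e_only_by_small_n_factor():
    rng = np.random.default_rng(3)
    g = random_matrix(rng, n_pops=1, n_per_pop=10, n_loci=1)
    doubled = GenotypeMatrix(
        [f"d{k}" for k in range(20)], ["L0"],
        np.vstack([g.alleles, g.alleles]), ["pop0"] * 20,
    )
    he1 = ps.heterozygosities(g)["H_E"].iloc[0]
    he2 = ps.heterozygosities(doubled)["H_E"].iloc[0]
    n = 10
    # identical allele frequencies: only the 2n/(2n-1) factor differs
    assert he2 * (2 * 2 * n / (2 * 2 * n - 1)) ** -1 == pytest.approx(
        he1 * (2 * n / (2 * n - 1)) ** -1, abs=1e-12)


# ----------------------------------------------------------------------- F_IS

def test_fis_near_zero_under_hardy_weinberg_proportions():
    # n=500 with genotype counts at exact HW proportions for p=q=0.5
    genos = [(1, 1)] * 125 + [(1, 2)] * 250 + [(2, 2)] * 125
    g = _single_pop(genos)
    out = ps.fis(g, n_perm=50, seed=0)
    assert abs(out["F_IS"].iloc[0]) < 0.02


def test_fis_negative_for_universal_heterozygotes():
    g = _single_pop([(1, 2)] * 30)
    out = ps.fis(g, n_perm=200, seed=1)
    assert out["F_IS"].iloc[0] < 0
    assert out["F_IS_p"].iloc[0] < 0.05


def test_fis_monomorphic_flagged():
    g = _single_pop([(4, 4)] * 5)
    out = ps.fis(g, n_perm=10, seed=0)
    assert np.isnan(out["F_IS"].iloc[0]) and np.isnan(out["F_IS_p"].iloc[0])


def test_fis_null_pvalues_calibrated():
    """Null p-values are near-uniform (mildly conservative is acceptable
    for a discrete two-sided permutation test)."""
    rng = np.random.default_rng(5)
    pvals = []
    for _ in range(200):
        copies = rng.integers(1, 4, size=(12, 1, 2))
        g = GenotypeMatrix([f"i{k}" for k in range(12)], ["L1"],
                           copies, ["p"] * 12)
        out = ps.fis(g, n_perm=99, seed=int(rng.integers(1 << 30)))
        if not np.isnan(out["F_IS_p"].iloc[0]):
            pvals.append(out["F_IS_p"].iloc[0])
    p = np.asarray(pvals)
    assert 0.40 <= p.mean() <= 0.65
    assert (p <= 0.05).mean() <= 0.08
    assert 0.03 <= (p <= 0.10).mean() <= 0.18


# ------------------------------------------------------------------------ FST

def test_theta_one_for_fixed_different_alleles():
    g = GenotypeMatrix(
        [f"i{k}" for k in range(8)], ["L1"],
        np.array([[[1, 1]]] * 4 + [[[2, 2]]] * 4), ["a"] * 4 + ["b"] * 4,
    )
    assert ps.pairwise_fst(g).loc("a", "b") == pytest.approx(1.0)


def test_theta_near_zero_for_identical_compositions():
    # theta's small-sample bias is about -1/(2n-1), so use n=16 per pop
    block = ([[[1, 1]], [[1, 2]], [[2, 2]], [[1, 2]]]) * 4
    g = GenotypeMatrix(
        [f"i{k}" for k in range(32)], ["L1"],
        np.array(block + block), ["a"] * 16 + ["b"] * 16,
    )
    theta = ps.pairwise_fst(g).loc("a", "b")
    assert -0.06 < theta < 0.03


def test_theta_matches_bruteforce_on_random_fixtures():
    rng = np.random.default_rng(19)
    for _ in range(10):
        g = random_matrix(rng, n_pops=3, n_per_pop=7, n_loci=2,
                          missing_rate=0.1)
        fst = ps.pairwise_fst(g)
        for p1, p2 in itertools.combinations(g.populations(), 2):
            loci = []
            for j in range(g.n_loci):
                per_pop = []
                for pop in (p1, p2):
                    idx = g.population_indices(pop)
                    per_pop.append(
                        [tuple(g.alleles[i, j]) for i in idx
                         if g.alleles[i, j, 0] != 0]
                    )
                loci.append(per_pop)
            assert fst.loc(p1, p2) == pytest.approx(
                oracles.brute_theta(loci), abs=1e-12)


# ------------------------------------------------------------------------ D_A

def test_da_zero_for_identical_frequencies():
    block = [[[1, 1]], [[1, 2]]]
    g = GenotypeMatrix(["a1", "a2", "b1", "b2"], ["L1"],
                       np.array(block + block), ["a", "a", "b", "b"])
    assert ps.da_distance(g).loc("a", "b") == pytest.approx(0.0)


def test_da_one_for_disjoint_alleles():
    g = GenotypeMatrix(
        ["a1", "b1"], ["L1", "L2"],
        np.array([[[1, 1], [3, 3]], [[2, 2], [4, 4]]]), ["a", "b"],
    )
    assert ps.da_distance(g).loc("a", "b") == pytest.approx(1.0)


def test_da_hand_value_single_locus():
    # x=(1,0), y=(0.5,0.5) -> 1 - sqrt(0.5)
    g = GenotypeMatrix(
        ["a1", "a2", "b1", "b2"], ["L1"],
        np.array([[[1, 1]], [[1, 1]], [[1, 2]], [[2, 1]]]),
        ["a", "a", "b", "b"],
    )
    assert ps.da_distance(g).loc("a", "b") == pytest.approx(1 - np.sqrt(0.5))


def test_da_matches_bruteforce_on_random_fixtures():
    rng = np.random.default_rng(23)
    for _ in range(10):
        g = random_matrix(rng, n_pops=3, n_per_pop=6, n_loci=2)
        da = ps.da_distance(g)
        freqs = ps.allele_frequencies(g)
        for p1, p2 in itertools.combinations(g.populations(), 2):
            want = oracles.brute_da_multilocus(freqs[p1], freqs[p2])
            assert da.loc(p1, p2) == pytest.approx(want, abs=1e-12)


# ------------------------------------------------------- ABC summary vector

def test_summary_vector_m_ratio_and_allele_number():
    g = GenotypeMatrix(
        ["i1", "i2"], ["L1"],
        np.array([[[10, 11]], [[12, 10]]]), ["p", "p"],
    )
    vec, names = ps.abc_summary_vector(g, {"p": "G"})
    stats = dict(zip(names, vec))
    assert stats["G:mean_allele_number"] == 3
    assert stats["G:mean_M_ratio"] == pytest.approx(1.0)  # 3 / (2 + 1)


def test_summary_vector_size_variance_divisor_n():
    g = GenotypeMatrix(
        ["i1", "i2"], ["L1"],
        np.array([[[10, 10]], [[14, 10]]]), ["p", "p"],
    )
    vec, names = ps.abc_summary_vector(g, {"p": "G"})
    stats = dict(zip(names, vec))
    # copies {10,10,10,14}: population variance (divisor N) = 3
    assert stats["G:mean_size_variance"] == pytest.approx(np.var([10, 10, 10, 14]))


def test_summary_vector_identical_groups_zero_differentiation():
    block = [[[10, 11]], [[11, 12]], [[10, 12]]]
    g = GenotypeMatrix(
        [f"i{k}" for k in range(6)], ["L1"],
        np.array(block + block), ["a"] * 3 + ["b"] * 3,
    )
    vec, names = ps.abc_summary_vector(g, {"a": "A", "b": "B"})
    stats = dict(zip(names, vec))
    assert abs(stats["A-B:fst"]) < 0.15
    assert stats["A-B:mean_dmu2"] == pytest.approx(0.0)


def test_summary_vector_ordering_is_stable():
    names = ps.summary_stat_names(["YD", "B", "V"])
    assert names[0].startswith("B:") and names[-1] == "V-YD:mean_dmu2"
    assert len(names) == 18
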