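"""Estimator correctness against independently coded brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from alkscan.model import ALK, FW
from alkscan.popstats import (PopCounts, compare_diversity, pi_ratio_log2,
                              pop_counts, site_frequencies, site_pi,
                              site_stats, tajima_constants, tajimas_d,
                              wc_fst_components, wc_fst_ratio_of_sums,
                              wc_fst_site, window_pi)
from conftest import make_table


# ---------------------------------------------------------------------------
# independent oracles (scalar, loop-based transcriptions; kept deliberately
# separate from the vectorized implementation they check)


def oracle_wc_fst(geno1, geno2):
    """Weir & Cockerham (1984) theta-hat for two populations of diploids.

    geno1/geno2 are lists of per-individual alt-allele dosages (no missing).
    Returns (a, b, c, theta) computed with plain Python floats.
    """
    r = 2
    pops = [geno1, geno2]
    n = [len(g) for g in pops]
    p = [sum(g) / (2 * len(g)) for g in pops]
    h = [sum(1 for x in g if x == 1) / len(g) for g in pops]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (s2 - (1 / (nbar - 1))
                       * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                               - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    denom = a + b + c
    return a, b, c, (a / denom if denom != 0 else float("nan"))


def oracle_pairwise_pi(dosages):
    """Mean pairwise difference at one site by explicit haplotype enumeration."""
    haps = []
    for d in dosages:
        haps += {0: [0, 0], 1: [0, 1], 2: [1, 1]}[d]
    n = len(haps)
    diffs = sum(1 for i in range(n) for j in range(i + 1, n)
                if haps[i] != haps[j])
    return diffs / (n * (n - 1) / 2)


def oracle_tajimas_d(hap_matrix):
    """Tajima's D from a 0/1 haplotype matrix (sites x haplotypes), computed
    from explicit pairwise differences and textbook constants."""
    n = hap_matrix.shape[1]
    pi = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            pi += (hap_matrix[:, i] != hap_matrix[:, j]).sum()
    pi /= n * (n - 1) / 2
    s = int(((hap_matrix.sum(axis=1) > 0)
             & (hap_matrix.sum(axis=1) < n)).sum())
    if s == 0:
        return float("nan")
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


# ---------------------------------------------------------------------------


class TestSiteFrequencies:
    def test_simple_count(self):
        # 10 diploids per pop; ALK 5 het + 5 ref-hom -> p = 5/20
        table = make_table([[1] * 5 + [0] * 5 + [2] * 10])
        freqs = site_frequencies(table)
        assert freqs.loc[0, "p_alk"] == 0.25
        assert freqs.loc[0, "p_fw"] == 1.0
        assert freqs.loc[0, "n_alk"] == 20

    def test_all_missing_population_is_nan(self):
        table = make_table([[-1] * 3 + [1, 1, 2]], n_alk=3)
        freqs = site_frequencies(table)
        assert np.isnan(freqs.loc[0, "p_alk"])
        assert freqs.loc[0, "p_fw"] == pytest.approx(4 / 6)

    def test_matches_hand_count_on_random_sites(self):
        rng = np.random.default_rng(0)
        dosage = rng.integers(-1, 3, size=(50, 12))
        table = make_table(dosage, n_alk=6)
        freqs = site_frequencies(table)
        for i in range(50):
            alk = [d for d in dosage[i, :6] if d >= 0]
            expect = sum(alk) / (2 * len(alk)) if alk else np.nan
            got = freqs.loc[i, "p_alk"]
            assert (np.isnan(got) and np.isnan(expect)) or got == expect


class TestWcFst:
    def test_fixed_difference_is_one(self):
        table = make_table([[2] * 10 + [0] * 10])
        a, f = pop_counts(table, ALK), pop_counts(table, FW)
        ca, cb, cc = wc_fst_components(a, f)
        assert cb[0] == pytest.approx(0.0)
        assert cc[0] == pytest.approx(0.0)
        assert wc_fst_site(a, f)[0] == pytest.approx(1.0)

    def test_monomorphic_both_pops_is_nan(self):
        table = make_table([[0] * 20])
        assert np.isnan(wc_fst_site(pop_counts(table, ALK),
                                    pop_counts(table, FW))[0])

    def test_matches_oracle_on_random_small_tables(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(500):
            n1, n2 = rng.integers(2, 7, size=2)
            g1 = rng.integers(0, 3, size=n1)
            g2 = rng.integers(0, 3, size=n2)
            table = make_table([list(g1) + list(g2)], n_alk=n1)
            got = wc_fst_site(pop_counts(table, ALK), pop_counts(table, FW))[0]
            *_, expect = oracle_wc_fst(list(g1), list(g2))
            if np.isnan(expect):
                assert np.isnan(got)
            else:
                worst = max(worst, abs(got - expect))
        assert worst < 1e-12

    def test_window_equals_component_summation(self):
        rng = np.random.default_rng(3)
        dosage = rng.integers(0, 3, size=(40, 10))
        table = make_table(dosage, n_alk=5)
        a, f = pop_counts(table, ALK), pop_counts(table, FW)
        ca, cb, cc = wc_fst_components(a, f)
        got = wc_fst_ratio_of_sums(ca, cb, cc)
        num = den = 0.0
        for i in range(40):
            oa, ob, oc, _ = oracle_wc_fst(list(dosage[i, :5]), list(dosage[i, 5:]))
            num += oa
            den += oa + ob + oc
        assert got == pytest.approx(num / den, abs=1e-12)

    def test_single_site_window_degenerates_to_site_fst(self):
        table = make_table([[2, 1, 0, 0, 1, 2]], n_alk=3)
        a, f = pop_counts(table, ALK), pop_counts(table, FW)
        ca, cb, cc = wc_fst_components(a, f)
        assert wc_fst_ratio_of_sums(ca, cb, cc) == pytest.approx(
            wc_fst_site(a, f)[0])


class TestPi:
    def test_closed_form_single_snp(self):
        # p = 0.5, n = 10 chromosomes, span 10 kb
        table = make_table([[1] * 5 + [0] * 5], n_alk=5)
        counts = pop_counts(table, ALK)  # 5 diploids, all het: p = 0.5
        got = window_pi(counts, np.array([0]), 10_000)
        assert got == pytest.approx((2 * 0.25 * 10 / 9) / 10_000)
        assert got == pytest.approx(5.556e-5, rel=1e-3)

    def test_empty_window_is_zero(self):
        table = make_table(np.zeros((0, 6), dtype=np.int8))
        assert window_pi(pop_counts(table, ALK), np.array([], dtype=int),
                         1000) == 0.0

    def test_fixed_alt_contributes_zero(self):
        table = make_table([[2] * 6], n_alk=3)
        assert site_pi(pop_counts(table, ALK))[0] == 0.0

    def test_matches_pairwise_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            dosages = list(rng.integers(0, 3, size=5))
            table = make_table([dosages + [0] * 3], n_alk=5)
            got = site_pi(pop_counts(table, ALK))[0]
            assert got == pytest.approx(oracle_pairwise_pi(dosages), abs=1e-12)

    def test_additive_over_disjoint_subwindows_and_order_invariant(self):
        rng = np.random.default_rng(5)
        dosage = rng.integers(0, 3, size=(30, 8))
        table = make_table(dosage, n_alk=4)
        counts = pop_counts(table, ALK)
        idx = np.arange(30)
        whole = window_pi(counts, idx, 3000)
        left = window_pi(counts, idx[:11], 3000)
        right = window_pi(counts, idx[11:], 3000)
        assert whole == pytest.approx(left + right, abs=1e-15)
        shuffled = rng.permutation(idx)
        assert window_pi(counts, shuffled, 3000) == pytest.approx(whole)


class TestPiRatio:
    def test_equal_diversities(self):
        assert pi_ratio_log2(1e-3, 1e-3, 1e-9) == (0.0, False)

    def test_depleted_alk_hits_outlier_scale(self):
        ratio, flagged = pi_ratio_log2(1e-3, 4e-3, 1e-9)
        assert ratio == pytest.approx(-2.0)
        assert not flagged
        assert abs(ratio) > 1.875

    def test_zero_diversity_is_floored_and_flagged(self):
        ratio, flagged = pi_ratio_log2(0.0, 4e-3, 1e-6)
        assert flagged
        assert ratio == pytest.approx(np.log2(1e-6 / 4e-3))


class TestTajimasD:
    def test_no_segregating_sites_is_nan(self):
        table = make_table([[0] * 8, [2] * 8], n_alk=4)
        assert np.isnan(tajimas_d(pop_counts(table, ALK), np.array([0, 1])))

    def test_matches_haplotype_oracle(self):
        # 3 diploids = 6 haplotypes; dosages chosen so phase is irrelevant
        # (per-site D depends only on allele counts)
        rng = np.random.default_rng(11)
        for _ in range(25):
            haps = rng.integers(0, 2, size=(12, 6))
            dosage = haps[:, ::2] + haps[:, 1::2]
            table = make_table(np.hstack([dosage, np.zeros((12, 3), int)]),
                               n_alk=3)
            got = tajimas_d(pop_counts(table, ALK), np.arange(12))
            expect = oracle_tajimas_d(haps)
            if np.isnan(expect):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expect, abs=1e-12)

    def test_all_singletons_is_negative(self):
        # each variant appears once in one haplotype: excess of rare alleles
        dosage = np.zeros((10, 5), dtype=int)
        for i in range(10):
            dosage[i, i % 5] = 1
        table = make_table(np.hstack([dosage, np.zeros((10, 2), int)]), n_alk=5)
        assert tajimas_d(pop_counts(table, ALK), np.arange(10)) < 0

    def test_small_sample_is_nan(self):
        table = make_table([[1, 0, 1]], n_alk=1)
        assert np.isnan(tajimas_d(pop_counts(table, ALK), np.array([0])))

    def test_constants_match_published_n10_values(self):
        k = tajima_constants(10)
        assert k["a1"] == pytest.approx(sum(1 / i for i in range(1, 10)))
        assert k["b1"] == pytest.approx(11 / 27)


class TestSiteStats:
    def test_heterozygosity_and_delta_h(self):
        # ALK fixed ref (p = 0), FW at p = 0.5
        table = make_table([[0] * 6 + [1] * 6], n_alk=6)
        stats = site_stats(table)
        assert stats.loc[0, "h_alk"] == 0.0
        assert stats.loc[0, "h_fw"] == 0.5
        assert stats.loc[0, "delta_h"] == 0.5
        assert stats.loc[0, "maf_alk"] == 0.0

    def test_equal_frequencies_zero_delta(self):
        table = make_table([[1] * 12], n_alk=6)
        stats = site_stats(table)
        assert stats.loc[0, "delta_h"] == 0.0

    def test_matches_spreadsheet_recompute(self):
        rng = np.random.default_rng(21)
        dosage = rng.integers(0, 3, size=(20, 10))
        table = make_table(dosage, n_alk=5)
        stats = site_stats(table)
        for i in range(20):
            p = dosage[i, :5].sum() / 10
            assert stats.loc[i, "h_alk"] == pytest.approx(2 * p * (1 - p))
            assert stats.loc[i, "maf_alk"] == pytest.approx(min(p, 1 - p))


class TestCompareDiversity:
    def test_identical_vectors(self):
        out = compare_diversity(np.array([1.0, 2.0, 3.0]),
                                np.array([1.0, 2.0, 3.0]))
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_constant_nonzero_difference_is_degenerate(self):
        out = compare_diversity(np.array([1e-3, 2e-3, 3e-3]),
                                np.array([2e-3, 3e-3, 4e-3]))
        assert out["degenerate"] and np.isnan(out["p"])

    def test_matches_textbook_paired_t(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=25), rng.normal(size=25)
        out = compare_diversity(x, y)
        d = x - y
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert out["t"] == pytest.approx(t, abs=1e-12)


@given(st.lists(st.integers(0, 2), min_size=4, max_size=12),
       st.lists(st.integers(0, 2), min_size=4, max_size=12))
def test_fst_bounded_property(g1, g2):
    """Site Fst never exceeds 1 and matches the oracle on arbitrary tables."""
    n1 = len(g1)
    table = make_table([g1 + g2], n_alk=n1)
    got = wc_fst_site(pop_counts(table, ALK), pop_counts(table, FW))[0]
    *_, expect = oracle_wc_fst(g1, g2)
    if np.isnan(expect):
        assert np.isnan(got)
    else:
        assert got == pytest.approx(expect, abs=1e-12)
        assert got <= 1.0 + 1e-12
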