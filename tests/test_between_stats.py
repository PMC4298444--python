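import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelpop.between_stats import (
    compute_between,
    genotype_codes,
    gst_hedrick,
    gst_nei73,
    gst_nei_chesser,
    jost_d,
    multilocus_theta,
    shared_alleles,
    wc_theta,
)
from panelpop.core_model import (
    GenotypePanel,
    PopulationAssignment,
    build_allele_counts,
)

from conftest import make_random_panel, table_from_counts
from _naive import (
    gst73 as naive_gst73,
    hedrick as naive_hedrick,
    jost_d as naive_jost,
    nei_chesser as naive_nc,
    pair_share as naive_share,
    panel_to_genotypes,
    pop_tally,
    wc_components as naive_wc,
    wc_theta_locus as naive_theta,
    wc_theta_multilocus as naive_theta_multi,
)


def _two_pop_table(p1, p2, n_chrom, het1=None, het2=None):
    """Biallelic two-population table with exact integer counts."""
    c1 = round(p1 * n_chrom)
    c2 = round(p2 * n_chrom)
    het = None
    if het1 is not None:
        het = [[het1, het2]]
    return table_from_counts(
        [[[n_chrom - c1, c1, 0, 0], [n_chrom - c2, c2, 0, 0]]], het_obs=het
    )


class TestGst73:
    def test_hand_evaluated_closed_form(self):
        # p = 0.2 vs 0.8: Hs = 0.32, Ht = 0.5, Gst = 0.36
        t = _two_pop_table(0.2, 0.8, 10)
        r = compute_between(t)
        assert r["Hs"][0] == pytest.approx(0.32, abs=1e-12)
        assert r["Ht"][0] == pytest.approx(0.5, abs=1e-12)
        assert gst_nei73(t, 0) == pytest.approx(0.36, abs=1e-12)

    def test_identical_populations_exactly_zero(self):
        t = _two_pop_table(0.3, 0.3, 10)
        assert gst_nei73(t, 0) == 0.0

    def test_fixed_difference_is_one(self):
        t = _two_pop_table(1.0, 0.0, 10)
        r = compute_between(t)
        assert r["Hs"][0] == 0.0
        assert r["Ht"][0] == pytest.approx(0.5, abs=1e-15)
        assert gst_nei73(t, 0) == pytest.approx(1.0, abs=1e-15)


class TestNeiChesser:
    def test_limit_recovers_raw_hs(self):
        # HWE heterozygote count at p=0.2 with a million diploids per pop
        n = 10**6
        het = round(2 * 0.2 * 0.8 * n)
        t = _two_pop_table(0.2, 0.8, 2 * n, het1=het, het2=het)
        hs_hat, ht_hat, _ = gst_nei_chesser(t, 0)
        assert hs_hat == pytest.approx(0.32, abs=1e-5)
        assert ht_hat == pytest.approx(0.5, abs=1e-5)

    def test_matches_naive_small_sample(self):
        # two pops of 5 diploids, p = 0.2 / 0.8, HWE-ish het counts
        t = _two_pop_table(0.2, 0.8, 10, het1=2, het2=2)
        genotypes = [
            [(0, 1)], [(0, 1)], [(0, 0)], [(0, 0)], [(0, 0)],  # pop1: p=0.2
            [(0, 1)], [(0, 1)], [(1, 1)], [(1, 1)], [(1, 1)],  # pop2: p=0.8
        ]
        tallies = pop_tally(genotypes, [0] * 5 + [1] * 5, 2, 0)
        expect = naive_nc(tallies)
        got = gst_nei_chesser(t, 0)
        for g, e in zip(got, expect):
            assert g == pytest.approx(e, abs=1e-12)

    def test_identical_populations_near_zero_at_large_n(self):
        n = 10**6
        het = round(2 * 0.3 * 0.7 * n)
        t = _two_pop_table(0.3, 0.3, 2 * n, het1=het, het2=het)
        _, _, gst = gst_nei_chesser(t, 0)
        assert abs(gst) < 1e-5

    def test_small_sample_undefined_when_single_individual(self):
        t = table_from_counts([[[1, 1, 0, 0], [2, 0, 0, 0]]], het_obs=[[1, 0]])
        # harmonic mean of (1, 1) individuals = 1 -> undefined
        assert math.isnan(gst_nei_chesser(t, 0)[2])


class TestHedrick:
    def test_fixed_difference_is_one(self):
        # fixed difference with many individuals: Hs_hat = 0 so G'st = Gst_hat
        t = _two_pop_table(1.0, 0.0, 200)
        _, _, gst = gst_nei_chesser(t, 0)
        assert gst_hedrick(t, 0) == pytest.approx(gst, abs=1e-12)
        assert gst_hedrick(t, 0) == pytest.approx(1.0, abs=1e-2)

    def test_identical_populations_near_zero(self):
        n = 10**6
        het = round(2 * 0.4 * 0.6 * n)
        t = _two_pop_table(0.4, 0.4, 2 * n, het1=het, het2=het)
        assert abs(gst_hedrick(t, 0)) < 1e-4

    def test_random_locus_matches_naive(self):
        bundle = make_random_panel(17, max_pops=4)
        t = build_allele_counts(bundle.panel, bundle.assignment)
        genotypes = panel_to_genotypes(bundle.panel.matrix, 2)
        pop_of = bundle.assignment.pop_index.tolist()
        for j in range(t.n_loci):
            expect = naive_hedrick(pop_tally(genotypes, pop_of, t.n_populations, j))
            got = gst_hedrick(t, j)
            if expect is None:
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expect, abs=1e-12)


class TestJostD:
    def test_large_n_limit(self):
        # raw Hs = 0.32, Ht = 0.5 -> D -> 2 * 0.18 / 0.68 = 0.52941...
        n = 10**6
        het = round(2 * 0.2 * 0.8 * n)
        t = _two_pop_table(0.2, 0.8, 2 * n, het1=het, het2=het)
        assert jost_d(t, 0) == pytest.approx(2 * 0.18 / 0.68, abs=1e-4)

    def test_identical_populations_raw_exactly_zero(self):
        t = _two_pop_table(0.3, 0.3, 10, het1=2, het2=2)
        assert jost_d(t, 0, raw=True) == 0.0

    def test_fixed_difference_tends_to_one(self):
        t = _two_pop_table(1.0, 0.0, 2000)
        assert jost_d(t, 0) == pytest.approx(1.0, abs=2e-3)


class TestWeirCockerham:
    def test_fixed_difference_theta_one(self):
        t = _two_pop_table(1.0, 0.0, 10)
        a, b, c, theta, multi = wc_theta(t, 0)
        assert b[0] == pytest.approx(0.0, abs=1e-15)
        assert c[0] == 0.0
        assert theta[0] == pytest.approx(1.0, abs=1e-12)

    def test_identical_populations_nonpositive(self):
        t = _two_pop_table(0.5, 0.5, 10, het1=2, het2=2)
        a, b, c, theta, _ = wc_theta(t, 0)
        assert a[0] <= 0
        assert theta[0] <= 0  # reported as computed, not truncated

    def test_multilocus_is_ratio_of_sums(self):
        bundle = make_random_panel(23, max_loci=100)
        t = build_allele_counts(bundle.panel, bundle.assignment)
        genotypes = panel_to_genotypes(bundle.panel.matrix, 2)
        pop_of = bundle.assignment.pop_index.tolist()
        a, b, c, theta, multi = wc_theta(t)
        expect = naive_theta_multi(genotypes, pop_of, t.n_populations)
        assert multi == pytest.approx(expect, abs=1e-12)
        per_locus_mean = np.nanmean(theta)
        assert multi != pytest.approx(per_locus_mean, abs=1e-9)

    def test_clamping_flag(self):
        t = _two_pop_table(0.5, 0.5, 10, het1=2, het2=2)
        r = compute_between(t, clamp_negative=True)
        assert r["WC_theta"][0] == 0.0


class TestSharedAlleles:
    def _panel(self, rows, pops):
        return (
            GenotypePanel(
                matrix=np.asarray(rows, dtype=np.int8),
                ploidy=2,
                individual_ids=[f"i{k}" for k in range(len(rows) // 2)],
            ),
            PopulationAssignment.from_labels(pops),
        )

    def test_min_count_rule(self):
        panel, assign = self._panel([[0], [0], [0], [1]], ["a", "a"])
        m = shared_alleles(panel, assign)
        assert m.values[0, 1] == 0.5  # AA vs AG

    def test_order_free(self):
        panel, assign = self._panel([[0], [1], [1], [0]], ["a", "a"])
        m = shared_alleles(panel, assign)
        assert m.values[0, 1] == 1.0  # AG vs GA

    def test_disjoint_and_mean(self):
        # locus 1: AA vs AG (0.5); locus 2: AA vs AA (1.0) -> mean 0.75
        panel, assign = self._panel([[0, 0], [0, 0], [0, 0], [1, 0]], ["a", "a"])
        m = shared_alleles(panel, assign)
        assert m.values[0, 1] == 0.75
        panel2, assign2 = self._panel([[0], [0], [1], [1]], ["a", "a"])
        assert shared_alleles(panel2, assign2).values[0, 1] == 0.0

    def test_diagonal_and_symmetry(self):
        bundle = make_random_panel(31)
        m = shared_alleles(bundle.panel, bundle.assignment)
        np.testing.assert_array_equal(m.values, m.values.T)
        diag = np.diag(m.values)
        has_locus = np.diag(m.n_loci_used) > 0
        assert (diag[has_locus] == 1.0).all()

    @pytest.mark.parametrize("seed", [2, 12])
    def test_matches_naive_pairs(self, seed):
        bundle = make_random_panel(seed, max_ind=6, max_loci=20, missing=0.2)
        m = shared_alleles(bundle.panel, bundle.assignment)
        genotypes = panel_to_genotypes(bundle.panel.matrix, 2)
        n = len(genotypes)
        for i in range(n):
            for j in range(n):
                expect, used = naive_share(genotypes, i, j)
                assert m.n_loci_used[i, j] == used
                if expect is None:
                    assert math.isnan(m.values[i, j])
                else:
                    assert m.values[i, j] == pytest.approx(expect, abs=1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    def test_all_statistics_match_naive(self, seed):
        bundle = make_random_panel(seed + 100)
        t = build_allele_counts(bundle.panel, bundle.assignment)
        genotypes = panel_to_genotypes(bundle.panel.matrix, 2)
        pop_of = bundle.assignment.pop_index.tolist()
        r = compute_between(t)
        for j in range(t.n_loci):
            tallies = pop_tally(genotypes, pop_of, t.n_populations, j)
            checks = [
                ("Gst73", lambda: (naive_gst73(tallies) or (None,) * 3)[2]),
                ("GstNC", lambda: (naive_nc(tallies) or (None,) * 3)[2]),
                ("GstHedrick", lambda: naive_hedrick(tallies)),
                ("JostD", lambda: naive_jost(tallies)),
                ("WC_theta", lambda: naive_theta(tallies)),
            ]
            for name, fn in checks:
                expect = fn()
                got = r[name][j]
                if expect is None:
                    assert math.isnan(got), (name, j)
                else:
                    assert got == pytest.approx(expect, abs=1e-12), (name, j)
            comp = naive_wc(tallies)
            if comp is not None:
                assert r["WC_a"][j] == pytest.approx(comp[0], abs=1e-12)
                assert r["WC_b"][j] == pytest.approx(comp[1], abs=1e-12)
                assert r["WC_c"][j] == pytest.approx(comp[2], abs=1e-12)


class TestPermutationInvariance:
    @given(st.integers(0, 10**6))
    @settings(max_examples=20, deadline=None)
    def test_population_reordering(self, seed):
        rng = np.random.default_rng(seed)
        bundle = make_random_panel(int(rng.integers(1 << 30)), max_loci=8)
        t = build_allele_counts(bundle.panel, bundle.assignment)
        perm = rng.permutation(t.n_populations)
        t2 = build_allele_counts(
            bundle.panel,
            PopulationAssignment(
                populations=[bundle.assignment.populations[p] for p in perm],
                pop_index=np.argsort(perm)[bundle.assignment.pop_index],
            ),
        )
        r1, r2 = compute_between(t), compute_between(t2)
        for name in ("Gst73", "GstNC", "JostD", "WC_theta"):
            np.testing.assert_allclose(
                r1[name], r2[name], rtol=0, atol=1e-12, equal_nan=True
            )

    @given(st.integers(0, 10**6))
    @settings(max_examples=20, deadline=None)
    def test_allele_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        bundle = make_random_panel(int(rng.integers(1 << 30)), max_loci=8)
        t = build_allele_counts(bundle.panel, bundle.assignment)
        perm = rng.permutation(4).astype(np.int8)
        matrix = bundle.panel.matrix
        relabeled = np.where(matrix >= 0, perm[matrix], matrix).astype(np.int8)
        panel2 = GenotypePanel(
            matrix=relabeled, ploidy=2, individual_ids=bundle.panel.individual_ids
        )
        t2 = build_allele_counts(panel2, bundle.assignment)
        r1, r2 = compute_between(t), compute_between(t2)
        for name in ("Gst73", "GstNC", "GstHedrick", "JostD", "WC_theta"):
            np.testing.assert_allclose(
                r1[name], r2[name], rtol=0, atol=1e-12, equal_nan=True
            )
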