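import numpy as np
import pytest

from panelpop.core_model import (
    MISSING,
    GenotypePanel,
    LocusInfo,
    PanelError,
    PopulationAssignment,
    build_allele_counts,
    pool_counts,
    validate_panel,
)

from conftest import make_random_panel
from _naive import panel_to_genotypes, pop_tally


def _panel(matrix, ploidy=2, ids=None):
    matrix = np.asarray(matrix, dtype=np.int8)
    n_ind = matrix.shape[0] // ploidy
    return GenotypePanel(
        matrix=matrix,
        ploidy=ploidy,
        individual_ids=ids or [f"i{k}" for k in range(n_ind)],
    )


def _one_pop(n):
    return PopulationAssignment.from_labels(["p1"] * n)


class TestBuildAlleleCounts:
    def test_haploid_tally(self):
        panel = _panel([[0], [0], [0], [1]], ploidy=1)
        t = build_allele_counts(panel, _one_pop(4))
        assert t.counts[0, 0].tolist() == [3, 1, 0, 0]
        assert t.n_called[0, 0] == 4

    def test_one_heterozygote(self):
        # AA, AG, GG as diploid rows
        panel = _panel([[0], [0], [0], [1], [1], [1]])
        t = build_allele_counts(panel, _one_pop(3))
        assert t.het_obs[0, 0] == 1
        assert t.counts[0, 0].tolist() == [3, 3, 0, 0]
        assert t.het_obs_allele[0, 0].tolist() == [1, 1, 0, 0]

    def test_half_call_contributes_nothing(self):
        panel = _panel([[0], [MISSING]])
        t = build_allele_counts(panel, _one_pop(1))
        assert t.n_called[0, 0] == 0
        assert t.n_ind_called[0, 0] == 0
        assert t.counts[0, 0].sum() == 0

    def test_zero_individual_population_rejected(self):
        panel = _panel([[0], [1]])
        bad = PopulationAssignment(populations=["a", "b"], pop_index=np.array([0]))
        with pytest.raises(PanelError):
            build_allele_counts(panel, bad)

    def test_mismatched_individual_sets_rejected(self):
        panel = _panel([[0], [1], [0], [1]])  # 2 individuals
        with pytest.raises(PanelError):
            build_allele_counts(panel, _one_pop(3))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_double_loop(self, seed):
        bundle = make_random_panel(seed)
        t = build_allele_counts(bundle.panel, bundle.assignment)
        genotypes = panel_to_genotypes(bundle.panel.matrix, bundle.panel.ploidy)
        pop_of = bundle.assignment.pop_index.tolist()
        for j in range(bundle.panel.n_loci):
            tallies = pop_tally(genotypes, pop_of, t.n_populations, j)
            for k in range(t.n_populations):
                assert t.counts[j, k].tolist() == [
                    tallies[k]["counts"][a] for a in range(4)
                ]
                assert t.n_ind_called[j, k] == tallies[k]["n_ind"]
                assert t.het_obs[j, k] == tallies[k]["het"]
                assert t.het_obs_allele[j, k].tolist() == [
                    tallies[k]["het_by_allele"][a] for a in range(4)
                ]

    def test_permuting_individuals_leaves_counts_unchanged(self):
        bundle = make_random_panel(7)
        t = build_allele_counts(bundle.panel, bundle.assignment)
        rng = np.random.default_rng(0)
        perm = rng.permutation(bundle.panel.n_individuals)
        rows = np.empty_like(bundle.panel.matrix)
        rows[0::2] = bundle.panel.matrix[0::2][perm]
        rows[1::2] = bundle.panel.matrix[1::2][perm]
        panel2 = GenotypePanel(
            matrix=rows,
            ploidy=2,
            individual_ids=[bundle.panel.individual_ids[i] for i in perm],
        )
        assign2 = PopulationAssignment(
            populations=bundle.assignment.populations,
            pop_index=bundle.assignment.pop_index[perm],
        )
        t2 = build_allele_counts(panel2, assign2)
        assert (t.counts == t2.counts).all()
        assert (t.het_obs == t2.het_obs).all()


class TestPoolCounts:
    def test_pooled_is_sum(self, small_table):
        pooled = pool_counts(small_table)
        assert (pooled.counts[:, 0, :] == small_table.counts.sum(axis=1)).all()
        assert (pooled.n_called[:, 0] == small_table.n_called.sum(axis=1)).all()

    def test_two_pop_example(self):
        panel = _panel([[0], [0], [0], [1], [0], [1], [1], [1]])
        assign = PopulationAssignment.from_labels(["a", "a", "b", "b"])
        t = build_allele_counts(panel, assign)
        assert t.counts[0, 0, :2].tolist() == [3, 1]
        assert t.counts[0, 1, :2].tolist() == [1, 3]
        pooled = pool_counts(t)
        assert pooled.counts[0, 0, :2].tolist() == [4, 4]

    def test_single_population_identity(self):
        panel = _panel([[0], [1]])
        t = build_allele_counts(panel, _one_pop(1))
        pooled = pool_counts(t)
        assert (pooled.counts[:, 0] == t.counts[:, 0]).all()

    def test_pooled_counts_equal_pooled_panel(self):
        bundle = make_random_panel(11)
        t = build_allele_counts(bundle.panel, bundle.assignment)
        pooled = pool_counts(t)
        one = build_allele_counts(
            bundle.panel, _one_pop(bundle.panel.n_individuals)
        )
        assert (pooled.counts == one.counts).all()
        assert (pooled.het_obs == one.het_obs).all()


class TestValidatePanel:
    def _loci(self, m, labels=None):
        return [
            LocusInfo(f"L{j}", "1", j + 1, labels or ["A", "C", "G", "T"])
            for j in range(m)
        ]

    def test_all_missing_flagged(self):
        panel = _panel([[MISSING, 0], [MISSING, 1]])
        rep = validate_panel(panel, self._loci(2))
        assert rep.no_data == ["L0"]

    def test_monomorphic_flagged(self):
        panel = _panel([[0, 0], [0, 1]])
        rep = validate_panel(panel, self._loci(2))
        assert rep.monomorphic == ["L0"]

    def test_clean_panel_empty_report(self):
        panel = _panel([[0, 1], [1, 0]])
        rep = validate_panel(panel, self._loci(2))
        assert rep.clean

    def test_dimension_mismatch(self):
        panel = _panel([[0, 1], [1, 0]])
        with pytest.raises(PanelError):
            validate_panel(panel, self._loci(3))

    def test_removing_monomorphic_locus_preserves_other_counts(self):
        bundle = make_random_panel(13)
        t = build_allele_counts(bundle.panel, bundle.assignment)
        j = 1
        keep = [c for c in range(bundle.panel.n_loci) if c != j]
        panel2 = GenotypePanel(
            matrix=bundle.panel.matrix[:, keep],
            ploidy=2,
            individual_ids=bundle.panel.individual_ids,
        )
        t2 = build_allele_counts(panel2, bundle.assignment)
        assert (t2.counts == t.counts[keep]).all()


class TestInvariants:
    def test_out_of_range_allele_rejected(self):
        panel = _panel([[4], [0]])
        with pytest.raises(PanelError):
            panel.validate()

    def test_bad_ploidy_rejected(self):
        panel = GenotypePanel(
            matrix=np.zeros((3, 1), dtype=np.int8), ploidy=3, individual_ids=["a"]
        )
        with pytest.raises(PanelError):
            panel.validate()

    def test_count_table_consistency(self, small_table):
        small_table.validate()
        assert (small_table.n_called == 2 * small_table.n_ind_called).all()
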