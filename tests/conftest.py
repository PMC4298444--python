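import numpy as np
import pytest

from panelpop.core_model import (
    MISSING,
    GenotypePanel,
    LocusInfo,
    PanelBundle,
    PopulationAssignment,
    build_allele_counts,
)

ALLELE_NUMBER_WEIGHTS = (0.1, 0.6, 0.2, 0.1)  # P(locus has 1..4 alleles)


def make_random_panel(
    seed: int,
    max_pops: int = 5,
    max_ind: int = 10,
    max_loci: int = 50,
    missing: float = 0.1,
    ploidy: int = 2,
) -> PanelBundle:
    """Arbitrary messy panel: 1-4 alleles per locus, missing calls, half-calls."""
    rng = np.random.default_rng(seed)
    s = int(rng.integers(2, max_pops + 1))
    n_k = rng.integers(2, max_ind + 1, size=s)
    n_ind = int(n_k.sum())
    m = int(rng.integers(2, max_loci + 1))

    matrix = np.empty((n_ind * ploidy, m), dtype=np.int8)
    loci = []
    for j in range(m):
        n_alleles = int(rng.choice([1, 2, 3, 4], p=ALLELE_NUMBER_WEIGHTS))
        freq = rng.dirichlet(np.ones(n_alleles))
        matrix[:, j] = rng.choice(n_alleles, size=n_ind * ploidy, p=freq)
        loci.append(
            LocusInfo(
                locus_id=f"L{j + 1}",
                chrom="1",
                position=j + 1,
                allele_labels=list("ACGT")[:n_alleles],
            )
        )
    if missing > 0:
        mask = rng.random(matrix.shape) < missing
        matrix[mask] = MISSING

    labels = []
    for k in range(s):
        labels.extend([f"pop{k + 1}"] * int(n_k[k]))
    panel = GenotypePanel(
        matrix=matrix,
        ploidy=ploidy,
        individual_ids=[f"ind{i + 1}" for i in range(n_ind)],
    )
    return PanelBundle(
        panel=panel, loci=loci, assignment=PopulationAssignment.from_labels(labels)
    )


@pytest.fixture
def small_bundle() -> PanelBundle:
    return make_random_panel(seed=42)


@pytest.fixture
def small_table(small_bundle):
    return build_allele_counts(small_bundle.panel, small_bundle.assignment)


def table_from_counts(counts, het_obs=None, ploidy=2, het_obs_allele=None):
    """Hand-build an AlleleCountTable from nested count lists.

    ``counts``: [locus][pop][allele] chromosomes. For diploid tables without
    explicit het counts, zero heterozygotes are assumed. Used to construct
    exact closed-form scenarios (large-n limits etc.) without a panel.
    """
    from panelpop.core_model import AlleleCountTable

    counts = np.asarray(counts, dtype=np.int64)
    m, k, _ = counts.shape
    n_called = counts.sum(axis=2)
    if ploidy == 2:
        assert (n_called % 2 == 0).all()
        n_ind = n_called // 2
    else:
        n_ind = n_called
    het = (
        np.zeros((m, k), dtype=np.int64)
        if het_obs is None
        else np.asarray(het_obs, dtype=np.int64)
    )
    if het_obs_allele is None:
        # biallelic convenience: every heterozygote carries alleles 0 and 1
        het_al = np.zeros((m, k, 4), dtype=np.int64)
        het_al[:, :, 0] = het
        het_al[:, :, 1] = het
    else:
        het_al = np.asarray(het_obs_allele, dtype=np.int64)
    return AlleleCountTable(
        counts=counts,
        het_obs=het,
        het_obs_allele=het_al,
        n_called=n_called,
        n_ind_called=n_ind,
        ploidy=ploidy,
        populations=[f"pop{i + 1}" for i in range(k)],
        pop_n_individuals=n_ind.max(axis=0),
    )
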