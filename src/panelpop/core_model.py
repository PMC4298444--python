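"""Panel data model and allele-count tables.

The whole library works on a single in-memory currency: a haplotype-by-locus
matrix of small allele indices (:class:`GenotypePanel`) that is reduced once
into per-locus / per-population call counts (:class:`AlleleCountTable`).
Every downstream statistic is a function of that count table (plus, for the
individual-pair shared-allele matrix, the panel itself), so no statistic ever
needs information across loci and the locus axis can be partitioned freely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel for an uncalled allele in the panel matrix.
MISSING: int = -1

#: Maximum number of distinct alleles a locus may carry.
MAX_ALLELES: int = 4


class PanelError(ValueError):
    """Raised for structurally invalid panels, assignments or count tables."""


@dataclass
class LocusInfo:
    """Descriptor of one locus (column) of a panel.

    ``allele_labels`` is index-aligned with the allele indices stored in the
    panel matrix: label ``allele_labels[i]`` is the allele coded ``i``.
    """

    locus_id: str
    chrom: str
    position: int
    allele_labels: list[str]

    def validate(self) -> None:
        n = len(self.allele_labels)
        if not 1 <= n <= MAX_ALLELES:
            raise PanelError(
                f"locus {self.locus_id}: {n} allele labels (must be 1..{MAX_ALLELES})"
            )
        if len(set(self.allele_labels)) != n:
            raise PanelError(f"locus {self.locus_id}: duplicate allele labels")


@dataclass
class GenotypePanel:
    """Haplotype-by-locus matrix of allele indices.

    Parameters
    ----------
    matrix
        Integer array of shape (H, M) where ``H = n_individuals * ploidy``.
        Entries are allele indices 0..3 or :data:`MISSING`. Stored as int8.
    ploidy
        1 (haploid rows) or 2 (rows ``2i`` and ``2i+1`` belong to
        individual ``i``).
    individual_ids
        One identifier per individual.
    """

    matrix: np.ndarray
    ploidy: int
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise PanelError("panel matrix must be two-dimensional")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_loci(self) -> int:
        return self.matrix.shape[1]

    def haplotype_of(self, row: int) -> tuple[int, int]:
        """Map a haplotype row to (individual index, chromosome copy index)."""
        return divmod(row, self.ploidy)

    def validate(self) -> None:
        if self.ploidy not in (1, 2):
            raise PanelError(f"ploidy must be 1 or 2, got {self.ploidy}")
        if self.n_haplotypes != self.n_individuals * self.ploidy:
            raise PanelError(
                f"matrix has {self.n_haplotypes} rows but "
                f"{self.n_individuals} individuals x ploidy {self.ploidy}"
            )
        bad = (self.matrix != MISSING) & (
            (self.matrix < 0) | (self.matrix >= MAX_ALLELES)
        )
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise PanelError(
                f"allele index {self.matrix[r, c]} out of range at row {r}, locus {c}"
            )


@dataclass
class PopulationAssignment:
    """Maps each individual to exactly one population.

    ``pop_index`` is an int array of length n_individuals holding positions
    into the ordered ``populations`` list.
    """

    populations: list[str]
    pop_index: np.ndarray

    def __post_init__(self) -> None:
        self.pop_index = np.asarray(self.pop_index, dtype=np.int64)

    @classmethod
    def from_labels(cls, labels: list[str]) -> "PopulationAssignment":
        """Build from per-individual labels, population order = first appearance."""
        pops: list[str] = []
        seen: dict[str, int] = {}
        idx = np.empty(len(labels), dtype=np.int64)
        for i, lab in enumerate(labels):
            if lab not in seen:
                seen[lab] = len(pops)
                pops.append(lab)
            idx[i] = seen[lab]
        return cls(populations=pops, pop_index=idx)

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    def pop_of(self, individual: int) -> str:
        return self.populations[int(self.pop_index[individual])]

    def members(self, pop: int) -> np.ndarray:
        return np.flatnonzero(self.pop_index == pop)

    def validate(self, n_individuals: int) -> None:
        if len(self.pop_index) != n_individuals:
            raise PanelError(
                f"assignment covers {len(self.pop_index)} individuals, "
                f"panel has {n_individuals}"
            )
        if len(set(self.populations)) != len(self.populations):
            raise PanelError("duplicate population labels")
        if self.n_populations < 1:
            raise PanelError("at least one population required")
        counts = np.bincount(self.pop_index, minlength=self.n_populations)
        if (self.pop_index < 0).any() or (self.pop_index >= self.n_populations).any():
            raise PanelError("population index out of range")
        empty = np.flatnonzero(counts == 0)
        if empty.size:
            raise PanelError(
                f"population '{self.populations[empty[0]]}' has zero individuals"
            )


@dataclass
class AlleleCountTable:
    """Per-locus, per-population call counts — the hub of all statistics.

    Attributes
    ----------
    counts
        int64 array (M, K, 4): called chromosomes per allele.
    het_obs
        int64 array (M, K): heterozygous individuals (all zero for ploidy 1).
    het_obs_allele
        int64 array (M, K, 4): heterozygous individuals whose genotype
        carries each allele; needed per-allele by the variance-component
        Fst estimator.
    n_called
        int64 array (M, K): called chromosomes (sum of ``counts`` over alleles).
    n_ind_called
        int64 array (M, K): individuals with a complete genotype at the locus.
    """

    counts: np.ndarray
    het_obs: np.ndarray
    het_obs_allele: np.ndarray
    n_called: np.ndarray
    n_ind_called: np.ndarray
    ploidy: int
    populations: list[str]
    pop_n_individuals: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_loci(self) -> int:
        return self.counts.shape[0]

    @property
    def n_populations(self) -> int:
        return self.counts.shape[1]

    def loci_slice(self, sl: slice) -> "AlleleCountTable":
        """View of a contiguous block of loci (no copy)."""
        return AlleleCountTable(
            counts=self.counts[sl],
            het_obs=self.het_obs[sl],
            het_obs_allele=self.het_obs_allele[sl],
            n_called=self.n_called[sl],
            n_ind_called=self.n_ind_called[sl],
            ploidy=self.ploidy,
            populations=self.populations,
            pop_n_individuals=self.pop_n_individuals,
        )

    def validate(self) -> None:
        if not (self.counts.sum(axis=2) == self.n_called).all():
            raise PanelError("counts do not sum to n_called")
        if self.ploidy == 2 and not (self.n_called == 2 * self.n_ind_called).all():
            raise PanelError("n_called != 2 * n_ind_called under ploidy 2")
        if ((self.het_obs < 0) | (self.het_obs > self.n_ind_called)).any():
            raise PanelError("het_obs out of [0, n_ind_called]")


def build_allele_counts(
    panel: GenotypePanel, assignment: PopulationAssignment
) -> AlleleCountTable:
    """Tally called chromosomes and heterozygotes per locus and population.

    A diploid individual with any missing allele at a locus contributes
    nothing to that locus (complete-genotype rule), which keeps
    ``n_called == 2 * n_ind_called`` — the relation the heterozygosity
    estimators rely on.
    """
    panel.validate()
    assignment.validate(panel.n_individuals)

    m = panel.n_loci
    k = assignment.n_populations
    counts = np.zeros((m, k, MAX_ALLELES), dtype=np.int64)
    het = np.zeros((m, k), dtype=np.int64)
    het_allele = np.zeros((m, k, MAX_ALLELES), dtype=np.int64)
    n_ind = np.zeros((m, k), dtype=np.int64)

    if panel.ploidy == 2:
        a1 = panel.matrix[0::2]
        a2 = panel.matrix[1::2]
        called = (a1 != MISSING) & (a2 != MISSING)
        is_het = called & (a1 != a2)
        for p in range(k):
            rows = assignment.members(p)
            c1, c2 = a1[rows], a2[rows]
            ok = called[rows]
            hh = is_het[rows]
            n_ind[:, p] = ok.sum(axis=0)
            het[:, p] = hh.sum(axis=0)
            for al in range(MAX_ALLELES):
                counts[:, p, al] = ((c1 == al) & ok).sum(axis=0) + (
                    (c2 == al) & ok
                ).sum(axis=0)
                het_allele[:, p, al] = (hh & ((c1 == al) | (c2 == al))).sum(axis=0)
    else:
        a = panel.matrix
        ok = a != MISSING
        for p in range(k):
            rows = assignment.members(p)
            okp = ok[rows]
            ap = a[rows]
            n_ind[:, p] = okp.sum(axis=0)
            for al in range(MAX_ALLELES):
                counts[:, p, al] = ((ap == al) & okp).sum(axis=0)

    n_called = counts.sum(axis=2)
    return AlleleCountTable(
        counts=counts,
        het_obs=het,
        het_obs_allele=het_allele,
        n_called=n_called,
        n_ind_called=n_ind,
        ploidy=panel.ploidy,
        populations=list(assignment.populations),
        pop_n_individuals=np.bincount(
            assignment.pop_index, minlength=assignment.n_populations
        ),
    )


def pool_counts(table: AlleleCountTable) -> AlleleCountTable:
    """Collapse all populations into a single pooled population.

    Used where total counts over the whole panel (not mean frequencies)
    are needed, e.g. biallelic-locus screening for the frequency spectrum.
    """
    return AlleleCountTable(
        counts=table.counts.sum(axis=1, keepdims=True),
        het_obs=table.het_obs.sum(axis=1, keepdims=True),
        het_obs_allele=table.het_obs_allele.sum(axis=1, keepdims=True),
        n_called=table.n_called.sum(axis=1, keepdims=True),
        n_ind_called=table.n_ind_called.sum(axis=1, keepdims=True),
        ploidy=table.ploidy,
        populations=["pooled"],
        pop_n_individuals=np.array(
            [int(table.pop_n_individuals.sum())]
            if table.pop_n_individuals is not None
            else [0]
        ),
    )


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_panel` — purely informational."""

    no_data: list[str] = field(default_factory=list)
    monomorphic: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (self.no_data or self.monomorphic)


def validate_panel(panel: GenotypePanel, loci: list[LocusInfo]) -> ValidationReport:
    """Report all-missing and monomorphic loci; never mutates the input.

    Loci with more than four alleles cannot be represented and are rejected
    by the readers upstream, so they are not reported here.
    """
    panel.validate()
    if len(loci) != panel.n_loci:
        raise PanelError(
            f"panel has {panel.n_loci} loci but {len(loci)} locus records"
        )
    for info in loci:
        info.validate()
    report = ValidationReport()
    present = np.zeros((MAX_ALLELES, panel.n_loci), dtype=bool)
    for al in range(MAX_ALLELES):
        present[al] = (panel.matrix == al).any(axis=0)
    n_alleles = present.sum(axis=0)
    for j in np.flatnonzero(n_alleles == 0):
        report.no_data.append(loci[j].locus_id)
    for j in np.flatnonzero(n_alleles == 1):
        report.monomorphic.append(loci[j].locus_id)
    return report


@dataclass
class PanelBundle:
    """A panel together with its locus metadata and population assignment."""

    panel: GenotypePanel
    loci: list[LocusInfo]
    assignment: PopulationAssignment

    def validate(self) -> None:
        self.panel.validate()
        self.assignment.validate(self.panel.n_individuals)
        if len(self.loci) != self.panel.n_loci:
            raise PanelError(
                f"{len(self.loci)} locus records for {self.panel.n_loci} panel columns"
            )
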