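"""Single-population and joint allele frequency spectra.

Spectra require a uniform number of chromosomes per bin, so only loci with a
complete set of calls in every included population enter the spectrum; loci
with missing data (or more than two alleles) are excluded and counted. The
focal allele is either the reader-designated allele at index 1 (the first
ALT for VCF input) in unfolded mode, or the minor allele in folded mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_model import AlleleCountTable, PanelError

log = logging.getLogger(__name__)

#: Allele index standing in for the derived/ALT allele in unfolded spectra.
DESIGNATED_ALLELE = 1


@dataclass
class SpectrumResult:
    """An allele-frequency spectrum plus its bookkeeping.

    ``array`` has shape ``(n_1+1,)`` for a single-population spectrum or
    ``(n_1+1, ..., n_s+1)`` for the joint spectrum, where ``n_k`` is the
    number of chromosomes sampled in population ``k``.
    """

    array: np.ndarray
    populations: list[str]
    n_chrom: list[int]
    folded: bool
    n_loci_included: int
    n_excluded_missing: int
    n_excluded_multiallelic: int

    @property
    def kind(self) -> str:
        return "single" if self.array.ndim == 1 else "joint"


def _biallelic_mask(table: AlleleCountTable) -> np.ndarray:
    pooled = table.counts.sum(axis=1)
    return (pooled > 0).sum(axis=1) <= 2


def _complete_mask(table: AlleleCountTable, pop: int) -> np.ndarray:
    n_full = table.ploidy * int(table.pop_n_individuals[pop])
    return table.n_called[:, pop] == n_full


def single_sfs_bins(
    table: AlleleCountTable,
    pop: int,
    folded: bool = True,
    include_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, int, int]:
    """Per-locus spectrum bin of every included locus, plus exclusion counts.

    This is the chunk-friendly core: its output size is proportional to the
    number of loci in ``table``, so partial results from a locus partition
    can be concatenated and binned exactly once at merge time.
    """
    bi = _biallelic_mask(table)
    complete = _complete_mask(table, pop)
    include = bi & complete
    if include_mask is not None:
        include &= include_mask
    n = table.ploidy * int(table.pop_n_individuals[pop])
    c = table.counts[include, pop, DESIGNATED_ALLELE]
    if folded:
        c = np.minimum(c, n - c)
    return c, int((bi & ~complete).sum()), int((~bi).sum())


def single_sfs(
    table: AlleleCountTable,
    pop: int,
    folded: bool = True,
    include_mask: np.ndarray | None = None,
    warn_empty: bool = True,
) -> SpectrumResult:
    """Site frequency spectrum for one population.

    Parameters
    ----------
    include_mask
        Optional extra per-locus filter (used to build marginals on a shared
        locus set); combined by AND with the biallelic/complete-data filters.
    """
    bins, excl_missing, excl_multi = single_sfs_bins(
        table, pop, folded=folded, include_mask=include_mask
    )
    n = table.ploidy * int(table.pop_n_individuals[pop])
    length = n // 2 + 1 if folded else n + 1
    spectrum = np.bincount(bins, minlength=length).astype(np.int64)
    n_inc = int(bins.size)
    if n_inc == 0 and warn_empty:
        log.warning(
            "population %s: no biallelic loci with complete data; empty spectrum",
            table.populations[pop],
        )
    return SpectrumResult(
        array=spectrum,
        populations=[table.populations[pop]],
        n_chrom=[n],
        folded=folded,
        n_loci_included=n_inc,
        n_excluded_missing=excl_missing,
        n_excluded_multiallelic=excl_multi,
    )


def _canonical_fold(counts: np.ndarray, n_chrom: np.ndarray) -> np.ndarray:
    """Fold per-locus joint count vectors on the pooled minor allele.

    A locus whose pooled focal count exceeds half the pooled sample size is
    complemented; exact ties are resolved to the lexicographically smaller
    of the two equivalent cells so that folding is a well-defined projection.
    """
    total = counts.sum(axis=1)
    big_n = int(n_chrom.sum())
    flipped = n_chrom[None, :] - counts
    flip = 2 * total > big_n
    tie = 2 * total == big_n
    if tie.any():
        diff = counts - flipped
        nz = diff != 0
        any_nz = nz.any(axis=1)
        first = np.argmax(nz, axis=1)
        lead = np.take_along_axis(diff, first[:, None], axis=1)[:, 0]
        flip = flip | (tie & any_nz & (lead > 0))
    return np.where(flip[:, None], flipped, counts)


def joint_sfs_bins(
    table: AlleleCountTable,
    pops: list[int] | None = None,
    folded: bool = True,
    include_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, tuple[int, ...], int, int]:
    """Flattened joint-spectrum cell index per included locus.

    Returns ``(flat_indices, shape, n_excluded_missing,
    n_excluded_multiallelic)``; cells are row-major indices into an array of
    the returned shape.
    """
    if pops is None:
        pops = list(range(table.n_populations))
    if len(pops) < 2:
        raise PanelError("joint spectrum needs at least two populations")
    bi = _biallelic_mask(table)
    complete = np.ones(table.n_loci, dtype=bool)
    for p in pops:
        complete &= _complete_mask(table, p)
    include = bi & complete
    if include_mask is not None:
        include &= include_mask

    n_chrom = np.array(
        [table.ploidy * int(table.pop_n_individuals[p]) for p in pops], dtype=np.int64
    )
    counts = table.counts[np.ix_(np.flatnonzero(include), pops)][
        :, :, DESIGNATED_ALLELE
    ]
    if folded:
        counts = _canonical_fold(counts, n_chrom)
    shape = tuple(int(n) + 1 for n in n_chrom)
    if counts.shape[0]:
        idx = np.ravel_multi_index(tuple(counts[:, k] for k in range(len(pops))), shape)
    else:
        idx = np.zeros(0, dtype=np.int64)
    return idx, shape, int((bi & ~complete).sum()), int((~bi).sum())


def joint_sfs(
    table: AlleleCountTable,
    pops: list[int] | None = None,
    folded: bool = True,
    include_mask: np.ndarray | None = None,
) -> SpectrumResult:
    """Joint spectrum over an ordered list of populations (default: all).

    Loci enter only when every included population has complete data
    (intersection rule), so all marginals live on the same locus set.
    """
    if pops is None:
        pops = list(range(table.n_populations))
    idx, shape, excl_missing, excl_multi = joint_sfs_bins(
        table, pops, folded=folded, include_mask=include_mask
    )
    flat = np.bincount(idx, minlength=int(np.prod(shape))).astype(np.int64)
    return SpectrumResult(
        array=flat.reshape(shape),
        populations=[table.populations[p] for p in pops],
        n_chrom=[table.ploidy * int(table.pop_n_individuals[p]) for p in pops],
        folded=folded,
        n_loci_included=int(idx.size),
        n_excluded_missing=excl_missing,
        n_excluded_multiallelic=excl_multi,
    )


def fold_spectrum(result: SpectrumResult) -> SpectrumResult:
    """Fold an unfolded spectrum by summing each cell with its complement.

    Cells are mapped to the canonical (pooled-minor) representative used by
    the folded builders, so ``fold_spectrum(unfolded) == folded`` exactly.
    """
    if result.folded:
        return result
    n_chrom = np.asarray(result.n_chrom, dtype=np.int64)
    if result.array.ndim == 1:
        n = int(n_chrom[0])
        out = np.zeros(n // 2 + 1, dtype=result.array.dtype)
        for c in range(n + 1):
            out[min(c, n - c)] += result.array[c]
    else:
        out = np.zeros_like(result.array)
        for cell in np.argwhere(result.array != 0):
            canon = _canonical_fold(cell[None, :], n_chrom)[0]
            out[tuple(canon)] += result.array[tuple(cell)]
    return SpectrumResult(
        array=out,
        populations=result.populations,
        n_chrom=result.n_chrom,
        folded=True,
        n_loci_included=result.n_loci_included,
        n_excluded_missing=result.n_excluded_missing,
        n_excluded_multiallelic=result.n_excluded_multiallelic,
    )
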