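"""Within-population statistics: allele frequencies, Ho, He, summaries.

All heavy lifting is done by the vectorised ``*_table`` functions, which take
an :class:`~panelpop.core_model.AlleleCountTable` and return per-locus arrays
with ``NaN`` marking loci where a statistic is undefined. The scalar
single-locus functions are thin, readable wrappers over the same arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_model import MAX_ALLELES, AlleleCountTable


@dataclass
class LocusResult:
    """Per-locus record of requested statistics; NaN means "not defined"."""

    locus_id: str
    values: dict[str, float] = field(default_factory=dict)

    def defined(self, name: str) -> bool:
        v = self.values.get(name)
        return v is not None and not math.isnan(v)


@dataclass
class SummaryResult:
    """Across-locus mean/variance per statistic, over defined loci only."""

    stats: dict[str, tuple[float, float, int]] = field(default_factory=dict)

    def mean(self, name: str) -> float:
        return self.stats[name][0]

    def variance(self, name: str) -> float:
        return self.stats[name][1]

    def count(self, name: str) -> int:
        return self.stats[name][2]


# ---------------------------------------------------------------------------
# vectorised table-level computations


def frequency_table(table: AlleleCountTable) -> np.ndarray:
    """Allele frequencies, shape (M, K, 4); NaN where n_called == 0."""
    n = table.n_called[:, :, None].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, table.counts / n, np.nan)
    return freq


def ho_table(table: AlleleCountTable) -> np.ndarray:
    """Observed heterozygosity, shape (M, K); NaN where undefined.

    Undefined for haploid panels and for (locus, pop) cells with no
    complete genotypes.
    """
    m, k = table.het_obs.shape
    if table.ploidy != 2:
        return np.full((m, k), np.nan)
    n = table.n_ind_called.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, table.het_obs / n, np.nan)


def he_table(table: AlleleCountTable, unbiased: bool = True) -> np.ndarray:
    """Expected heterozygosity (gene diversity), shape (M, K).

    raw:       He = 1 - sum_i p_i^2
    unbiased:  He_raw * n / (n - 1) with n = called chromosomes.
    """
    freq = frequency_table(table)
    he = 1.0 - np.nansum(freq * freq, axis=2)
    he[table.n_called == 0] = np.nan
    if unbiased:
        n = table.n_called.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            he = np.where(n >= 2, he * n / (n - 1.0), np.nan)
    return he


# ---------------------------------------------------------------------------
# single-locus contract functions


def allele_frequencies(
    table: AlleleCountTable, locus: int, pop: int
) -> np.ndarray | None:
    """Frequency vector at one locus/population, trimmed to observed alleles.

    Returns None (undefined) when no chromosomes are called.
    """
    n = int(table.n_called[locus, pop])
    if n == 0:
        return None
    pooled = table.counts[locus].sum(axis=0)
    top = int(np.max(np.flatnonzero(pooled))) + 1 if pooled.any() else 1
    return table.counts[locus, pop, :top] / float(n)


def observed_heterozygosity(
    table: AlleleCountTable, locus: int, pop: int
) -> float | None:
    if table.ploidy != 2:
        return None
    n = int(table.n_ind_called[locus, pop])
    if n == 0:
        return None
    return int(table.het_obs[locus, pop]) / n


def expected_heterozygosity(
    table: AlleleCountTable, locus: int, pop: int, unbiased: bool = True
) -> float | None:
    n = int(table.n_called[locus, pop])
    if n == 0 or (unbiased and n < 2):
        return None
    p = table.counts[locus, pop] / float(n)
    he = 1.0 - float(np.sum(p * p))
    if unbiased:
        he *= n / (n - 1.0)
    return he


# ---------------------------------------------------------------------------
# across-locus summaries


def summarize(
    values: np.ndarray, sample_variance: bool = False
) -> tuple[float, float, int]:
    """Mean and variance of a per-locus vector over its defined entries.

    NaN entries are "undefined" and excluded. The variance denominator is
    ``count`` (population variance) by default, ``count - 1`` with
    ``sample_variance=True``. Exact (compensated) summation is used so the
    result does not depend on how the locus axis was chunked.

    Returns ``(nan, nan, 0)`` when no locus is defined.
    """
    values = np.asarray(values, dtype=float)
    defined = values[~np.isnan(values)]
    count = int(defined.size)
    if count == 0:
        return (math.nan, math.nan, 0)
    mean = math.fsum(defined.tolist()) / count
    dev = defined - mean
    ss = math.fsum((dev * dev).tolist())
    if sample_variance:
        var = ss / (count - 1) if count > 1 else math.nan
    else:
        var = ss / count
    return (mean, var, count)


def summarize_columns(
    columns: dict[str, np.ndarray], sample_variance: bool = False
) -> SummaryResult:
    """Apply :func:`summarize` to every named per-locus column."""
    out = SummaryResult()
    for name, vals in columns.items():
        out.stats[name] = summarize(vals, sample_variance=sample_variance)
    return out


def per_pop_column_names(populations: list[str], n_alleles: int = MAX_ALLELES):
    """Canonical output column names for the within-population block."""
    names = []
    for p in populations:
        names.extend(f"freq_{p}_{i}" for i in range(n_alleles))
    names.extend(f"Ho_{p}" for p in populations)
    names.extend(f"He_{p}" for p in populations)
    return names
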