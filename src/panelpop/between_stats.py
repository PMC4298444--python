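"""Between-population differentiation statistics.

Implements, per locus, the three gene-differentiation formulations
(the frequency-based Gst, its finite-sample corrected form, and the
standardised G'st), Jost's D, the variance-component Fst estimator
(with among-population ``a``, among-individual ``b`` and within-individual
``c`` components), and the individual-pair shared-allele matrix.

Everything except the shared-allele matrix is a pure function of the
:class:`~panelpop.core_model.AlleleCountTable`, computed with vectorised
per-locus arithmetic so results are bitwise independent of how the locus
axis is chunked. ``NaN`` marks loci where an estimator is undefined.

Conventions (see package docs):

* A population with zero called chromosomes at a locus is dropped from that
  locus; if fewer than two populations remain the locus is undefined for
  every between-population statistic.
* The plain Gst uses the *unweighted* mean of population frequencies for the
  total heterozygosity; sample-size weighting enters only through the
  corrected estimators.
* Negative estimates are reported as computed unless ``clamp_negative``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_model import MAX_ALLELES, MISSING, AlleleCountTable, GenotypePanel, PopulationAssignment

__all__ = [
    "DiffComponents",
    "PairShareMatrix",
    "compute_between",
    "diff_components",
    "gst_nei73",
    "gst_nei_chesser",
    "gst_hedrick",
    "jost_d",
    "wc_theta",
    "multilocus_theta",
    "shared_alleles",
    "genotype_codes",
    "shared_partial",
]


@dataclass
class DiffComponents:
    """Per-locus ingredients shared by the differentiation estimators."""

    hs: np.ndarray          # mean within-pop gene diversity (raw)
    ht: np.ndarray          # total gene diversity from unweighted mean freqs
    n_harm: np.ndarray      # harmonic mean sample size (individuals)
    s_eff: np.ndarray       # populations with data at the locus
    ho_bar: np.ndarray      # mean observed heterozygosity
    a: np.ndarray           # among-population variance component
    b: np.ndarray           # among-individual-within-population component
    c: np.ndarray           # within-individual component


def compute_between(
    table: AlleleCountTable, clamp_negative: bool = False
) -> dict[str, np.ndarray]:
    """All per-locus between-population statistics for a count table.

    Returns a dict of per-locus float arrays keyed by output column name:
    ``Hs``, ``Ht``, ``Gst73``, ``Hs_hat``, ``Ht_hat``, ``GstNC``,
    ``GstHedrick``, ``JostD``, ``JostD_raw``, ``WC_a``, ``WC_b``, ``WC_c``,
    ``WC_theta``, plus ``s_eff`` and ``n_harm``.
    """
    m, k, _ = table.counts.shape
    diploid = table.ploidy == 2

    valid = table.n_called > 0                       # (M, K)
    vf = valid.astype(float)
    s_eff = vf.sum(axis=1)                           # (M,)
    ok = s_eff >= 2                                  # locus usable at all

    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.where(valid, table.n_called, 1).astype(float)
        p = np.where(valid[:, :, None], table.counts / denom[:, :, None], 0.0)

        sumsq_k = (p * p).sum(axis=2)                # (M, K)
        h_k = np.where(valid, 1.0 - sumsq_k, 0.0)

        # --- plain Gst (unweighted mean frequencies) -----------------------
        hs = (vf * h_k).sum(axis=1) / s_eff
        pbar = (vf[:, :, None] * p).sum(axis=1) / s_eff[:, None]
        ht = 1.0 - (pbar * pbar).sum(axis=1)
        gst73 = np.where(ht > 0, (ht - hs) / ht, np.nan)

        # --- sample-size corrected estimators ------------------------------
        n_k = (table.n_ind_called if diploid else table.n_called).astype(float)
        n_safe = np.where(valid, n_k, 1.0)
        n_harm = s_eff / (vf / n_safe).sum(axis=1)
        mean_sumsq = (vf * sumsq_k).sum(axis=1) / s_eff
        if diploid:
            ho_bar = (vf * table.het_obs / n_safe).sum(axis=1) / s_eff
        else:
            ho_bar = np.zeros(m)

        nc_ok = ok & (n_harm > 1)
        hs_hat = (n_harm / (n_harm - 1.0)) * (
            1.0 - mean_sumsq - ho_bar / (2.0 * n_harm)
        )
        ht_hat = (
            ht
            + hs_hat / (n_harm * s_eff)
            - ho_bar / (2.0 * n_harm * s_eff)
        )
        gst_nc = np.where(ht_hat != 0, (ht_hat - hs_hat) / ht_hat, np.nan)
        hedrick = gst_nc * (s_eff - 1.0 + hs_hat) / ((s_eff - 1.0) * (1.0 - hs_hat))
        jost = (s_eff / (s_eff - 1.0)) * (ht_hat - hs_hat) / (1.0 - hs_hat)
        jost_raw = (s_eff / (s_eff - 1.0)) * (ht - hs) / (1.0 - hs)

        # --- variance components -------------------------------------------
        nbar = (vf * n_safe).sum(axis=1) / s_eff
        sum_n2 = (vf * n_safe * n_safe).sum(axis=1)
        n_c = (s_eff * nbar - sum_n2 / (s_eff * nbar)) / (s_eff - 1.0)
        pbar_w = (vf[:, :, None] * n_safe[:, :, None] * p).sum(axis=1) / (
            s_eff * nbar
        )[:, None]
        dev = np.where(valid[:, :, None], p - pbar_w[:, None, :], 0.0)
        s2 = (n_safe[:, :, None] * dev * dev).sum(axis=1) / (
            (s_eff - 1.0) * nbar
        )[:, None]
        if diploid:
            hbar = (vf[:, :, None] * table.het_obs_allele).sum(axis=1) / (
                s_eff * nbar
            )[:, None]
        else:
            hbar = np.zeros((m, MAX_ALLELES))

        pq = pbar_w * (1.0 - pbar_w)
        frac = ((s_eff - 1.0) / s_eff)[:, None]
        inner = pq - frac * s2 - hbar / 4.0
        a_i = (nbar / n_c)[:, None] * (s2 - inner / (nbar - 1.0)[:, None])
        b_i = (nbar / (nbar - 1.0))[:, None] * (
            pq - frac * s2 - ((2.0 * nbar - 1.0) / (4.0 * nbar))[:, None] * hbar
        )
        c_i = hbar / 2.0
        a = a_i.sum(axis=1)
        b = b_i.sum(axis=1)
        c = c_i.sum(axis=1)
        abc = a + b + c
        wc_ok = ok & (nbar > 1) & (n_c > 0) & (abc != 0)
        theta = np.where(abc != 0, a / abc, np.nan)

    def _mask(x: np.ndarray, m_: np.ndarray) -> np.ndarray:
        out = np.where(m_, x, np.nan)
        return out

    out = {
        "Hs": _mask(hs, ok),
        "Ht": _mask(ht, ok),
        "Gst73": _mask(gst73, ok),
        "Hs_hat": _mask(hs_hat, nc_ok),
        "Ht_hat": _mask(ht_hat, nc_ok),
        "GstNC": _mask(gst_nc, nc_ok),
        "GstHedrick": _mask(np.where(hs_hat != 1.0, hedrick, np.nan), nc_ok),
        "JostD": _mask(np.where(hs_hat != 1.0, jost, np.nan), nc_ok),
        "JostD_raw": _mask(np.where(hs != 1.0, jost_raw, np.nan), ok),
        "WC_a": _mask(a, ok & (nbar > 1) & (n_c > 0)),
        "WC_b": _mask(b, ok & (nbar > 1) & (n_c > 0)),
        "WC_c": _mask(c, ok & (nbar > 1) & (n_c > 0)),
        "WC_theta": _mask(theta, wc_ok),
        "s_eff": _mask(s_eff, ok),
        "n_harm": _mask(n_harm, ok),
        "Ho_bar": _mask(ho_bar, ok),
    }
    if clamp_negative:
        for key in ("Gst73", "GstNC", "GstHedrick", "JostD", "JostD_raw", "WC_theta"):
            out[key] = np.where(out[key] < 0, 0.0, out[key])
    return out


def diff_components(table: AlleleCountTable) -> DiffComponents:
    r = compute_between(table)
    return DiffComponents(
        hs=r["Hs"], ht=r["Ht"], n_harm=r["n_harm"], s_eff=r["s_eff"],
        ho_bar=r["Ho_bar"], a=r["WC_a"], b=r["WC_b"], c=r["WC_c"],
    )


# ---------------------------------------------------------------------------
# single-locus wrappers (contract surface; all share compute_between)


def _one(table: AlleleCountTable, locus: int, key: str) -> float:
    return float(compute_between(table.loci_slice(slice(locus, locus + 1)))[key][0])


def gst_nei73(table: AlleleCountTable, locus: int) -> float:
    """Plain Gst = (Ht - Hs) / Ht; NaN when undefined."""
    return _one(table, locus, "Gst73")


def gst_nei_chesser(table: AlleleCountTable, locus: int) -> tuple[float, float, float]:
    """Finite-sample corrected (Hs_hat, Ht_hat, Gst_hat) at one locus."""
    r = compute_between(table.loci_slice(slice(locus, locus + 1)))
    return float(r["Hs_hat"][0]), float(r["Ht_hat"][0]), float(r["GstNC"][0])


def gst_hedrick(table: AlleleCountTable, locus: int) -> float:
    """Standardised G'st = Gst_hat * (s-1+Hs_hat) / ((s-1)(1-Hs_hat))."""
    return _one(table, locus, "GstHedrick")


def jost_d(table: AlleleCountTable, locus: int, raw: bool = False) -> float:
    """Jost's D = (s/(s-1)) (Ht - Hs) / (1 - Hs), corrected estimators by default."""
    return _one(table, locus, "JostD_raw" if raw else "JostD")


def wc_theta(
    table: AlleleCountTable, locus: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    """Variance components and theta.

    With ``locus`` given, arrays are length 1. Returns
    ``(a, b, c, theta_per_locus, theta_multilocus)`` where the multilocus
    estimate is the ratio of summed components over defined loci.
    """
    sub = table if locus is None else table.loci_slice(slice(locus, locus + 1))
    r = compute_between(sub)
    a, b, c, theta = r["WC_a"], r["WC_b"], r["WC_c"], r["WC_theta"]
    return a, b, c, theta, multilocus_theta(a, a + b + c)


def multilocus_theta(a: np.ndarray, abc: np.ndarray) -> float:
    """Ratio-of-sums multilocus theta over loci where components are defined."""
    defined = ~(np.isnan(a) | np.isnan(abc))
    if not defined.any():
        return math.nan
    num = math.fsum(a[defined].tolist())
    den = math.fsum(abc[defined].tolist())
    return num / den if den != 0 else math.nan


# ---------------------------------------------------------------------------
# proportion of shared alleles between individuals

#: genotype codes: diploid -> 4*min+max in 0..15, haploid -> allele index;
#: _NOCALL marks an incomplete genotype.
_NOCALL = 16


def _share_lut(ploidy: int) -> np.ndarray:
    """(17, 17) table of 2x the shared-allele count between genotype codes."""
    lut = np.zeros((_NOCALL + 1, _NOCALL + 1), dtype=np.int64)
    if ploidy == 2:
        genos = [(i, j) for i in range(MAX_ALLELES) for j in range(i, MAX_ALLELES)]
        for a1, a2 in genos:
            for b1, b2 in genos:
                ca = np.bincount([a1, a2], minlength=MAX_ALLELES)
                cb = np.bincount([b1, b2], minlength=MAX_ALLELES)
                lut[4 * a1 + a2, 4 * b1 + b2] = int(np.minimum(ca, cb).sum())
    else:
        for a1 in range(MAX_ALLELES):
            for b1 in range(MAX_ALLELES):
                lut[a1, b1] = 2 if a1 == b1 else 0
    return lut


def genotype_codes(panel: GenotypePanel) -> np.ndarray:
    """Encode each individual x locus genotype as a small integer code."""
    if panel.ploidy == 2:
        a1 = panel.matrix[0::2].astype(np.int16)
        a2 = panel.matrix[1::2].astype(np.int16)
        lo = np.minimum(a1, a2)
        hi = np.maximum(a1, a2)
        codes = 4 * lo + hi
        codes[(a1 == MISSING) | (a2 == MISSING)] = _NOCALL
    else:
        codes = panel.matrix.astype(np.int16).copy()
        codes[codes == MISSING] = _NOCALL
    return codes.astype(np.uint8)


def shared_partial(
    codes: np.ndarray, ploidy: int, block: int = 2048
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate shared-allele numerators/denominators over a locus block.

    Returns ``(S, C)`` where ``S[i, j]`` is twice the summed shared-allele
    count over loci where both individuals are fully called and ``C[i, j]``
    is the number of such loci. Integer sums, so merging across chunks is
    exact and order-free.
    """
    lut = _share_lut(ploidy)
    n, m = codes.shape
    s_sum = np.zeros((n, n), dtype=np.int64)
    c_sum = np.zeros((n, n), dtype=np.int64)
    for start in range(0, m, block):
        g = codes[:, start : start + block]
        share = lut[g[:, None, :], g[None, :, :]]
        s_sum += share.sum(axis=2)
        v = g != _NOCALL
        both = v[:, None, :] & v[None, :, :]
        c_sum += both.sum(axis=2)
    return s_sum, c_sum


@dataclass
class PairShareMatrix:
    """Individual-by-individual mean proportion of shared alleles."""

    values: np.ndarray        # float (n, n), NaN where no usable locus
    n_loci_used: np.ndarray   # int (n, n)
    individual_ids: list[str]
    pop_labels: list[str]


def shared_alleles(
    panel: GenotypePanel, assignment: PopulationAssignment
) -> PairShareMatrix:
    """Mean per-locus shared-allele proportion for every pair of individuals.

    Per locus the share is ``sum_a min(copies of a in i, copies of a in j)``
    divided by the ploidy, i.e. in {0, 0.5, 1} for diploids; only loci where
    both genotypes are fully called contribute.
    """
    codes = genotype_codes(panel)
    s_sum, c_sum = shared_partial(codes, panel.ploidy)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(c_sum > 0, s_sum / (2.0 * c_sum), np.nan)
    return PairShareMatrix(
        values=values,
        n_loci_used=c_sum,
        individual_ids=list(panel.individual_ids),
        pop_labels=[assignment.pop_of(i) for i in range(panel.n_individuals)],
    )
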