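"""Independent naive reference implementations, written as plain double
loops directly from the estimator formulas. Used as the oracle for the
vectorised package code; deliberately shares no code with it.

Data model: ``genotypes[i][j]`` is a tuple of allele indices (length =
ploidy) for individual ``i`` at locus ``j``; ``None`` marks a missing
allele. ``pop_of[i]`` is the population index of individual ``i``.
"""

from __future__ import annotations

import math

ALLELES = (0, 1, 2, 3)


def pop_tally(genotypes, pop_of, n_pops, locus):
    """Per-population allele counts, called individuals, het counts."""
    out = []
    for k in range(n_pops):
        counts = {a: 0 for a in ALLELES}
        n_ind = 0
        het = 0
        het_by_allele = {a: 0 for a in ALLELES}
        for i, g in enumerate(genotypes):
            if pop_of[i] != k:
                continue
            alleles = g[locus]
            if any(a is None for a in alleles):
                continue
            n_ind += 1
            for a in alleles:
                counts[a] += 1
            if len(alleles) == 2 and alleles[0] != alleles[1]:
                het += 1
                for a in set(alleles):
                    het_by_allele[a] += 1
        out.append(
            {
                "counts": counts,
                "n_called": sum(counts.values()),
                "n_ind": n_ind,
                "het": het,
                "het_by_allele": het_by_allele,
            }
        )
    return out


def freqs(tally):
    n = tally["n_called"]
    if n == 0:
        return None
    return {a: tally["counts"][a] / n for a in ALLELES}


def ho(tally, ploidy):
    if ploidy != 2 or tally["n_ind"] == 0:
        return None
    return tally["het"] / tally["n_ind"]


def he(tally, unbiased=True):
    n = tally["n_called"]
    if n == 0 or (unbiased and n < 2):
        return None
    p = freqs(tally)
    raw = 1.0 - sum(p[a] ** 2 for a in ALLELES)
    return raw * n / (n - 1) if unbiased else raw


def gst73(tallies):
    """(Hs, Ht, Gst) with unweighted mean frequencies; None when undefined."""
    pops = [t for t in tallies if t["n_called"] > 0]
    s = len(pops)
    if s < 2:
        return None
    p_list = [freqs(t) for t in pops]
    hs = sum(1.0 - sum(p[a] ** 2 for a in ALLELES) for p in p_list) / s
    pbar = {a: sum(p[a] for p in p_list) / s for a in ALLELES}
    ht = 1.0 - sum(pbar[a] ** 2 for a in ALLELES)
    if ht == 0:
        return (hs, ht, None)
    return (hs, ht, (ht - hs) / ht)


def nei_chesser(tallies, ploidy=2):
    """(Hs_hat, Ht_hat, Gst_hat) with the harmonic-mean correction."""
    pops = [t for t in tallies if t["n_called"] > 0]
    s = len(pops)
    if s < 2:
        return None
    if ploidy == 2:
        n_k = [t["n_ind"] for t in pops]
        ho_bar = sum(t["het"] / t["n_ind"] for t in pops) / s
    else:
        n_k = [t["n_called"] for t in pops]
        ho_bar = 0.0
    n_tilde = s / sum(1.0 / n for n in n_k)
    if n_tilde <= 1:
        return None
    p_list = [freqs(t) for t in pops]
    mean_sumsq = sum(sum(p[a] ** 2 for a in ALLELES) for p in p_list) / s
    hs_hat = (n_tilde / (n_tilde - 1)) * (1 - mean_sumsq - ho_bar / (2 * n_tilde))
    pbar = {a: sum(p[a] for p in p_list) / s for a in ALLELES}
    ht_hat = (
        1
        - sum(pbar[a] ** 2 for a in ALLELES)
        + hs_hat / (n_tilde * s)
        - ho_bar / (2 * n_tilde * s)
    )
    gst = (ht_hat - hs_hat) / ht_hat if ht_hat != 0 else None
    return (hs_hat, ht_hat, gst)


def hedrick(tallies, ploidy=2):
    nc = nei_chesser(tallies, ploidy)
    if nc is None or nc[2] is None:
        return None
    hs_hat, _, gst = nc
    s = len([t for t in tallies if t["n_called"] > 0])
    if hs_hat == 1:
        return None
    return gst * (s - 1 + hs_hat) / ((s - 1) * (1 - hs_hat))


def jost_d(tallies, ploidy=2, raw=False):
    s = len([t for t in tallies if t["n_called"] > 0])
    if raw:
        g = gst73(tallies)
        if g is None:
            return None
        hs, ht = g[0], g[1]
    else:
        nc = nei_chesser(tallies, ploidy)
        if nc is None:
            return None
        hs, ht = nc[0], nc[1]
    if hs == 1:
        return None
    return (s / (s - 1)) * (ht - hs) / (1 - hs)


def wc_components(tallies, ploidy=2):
    """(a, b, c) variance components summed over alleles; None if undefined."""
    pops = [t for t in tallies if t["n_called"] > 0]
    s = len(pops)
    if s < 2:
        return None
    n_k = [t["n_ind"] if ploidy == 2 else t["n_called"] for t in pops]
    nbar = sum(n_k) / s
    if nbar <= 1:
        return None
    nc = (s * nbar - sum(n * n for n in n_k) / (s * nbar)) / (s - 1)
    if nc <= 0:
        return None
    p_list = [freqs(t) for t in pops]
    a_tot = b_tot = c_tot = 0.0
    for al in ALLELES:
        pbar = sum(n_k[k] * p_list[k][al] for k in range(s)) / (s * nbar)
        s2 = sum(n_k[k] * (p_list[k][al] - pbar) ** 2 for k in range(s)) / (
            (s - 1) * nbar
        )
        if ploidy == 2:
            hbar = sum(pops[k]["het_by_allele"][al] for k in range(s)) / (s * nbar)
        else:
            hbar = 0.0
        inner = pbar * (1 - pbar) - ((s - 1) / s) * s2 - hbar / 4
        a = (nbar / nc) * (s2 - inner / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((s - 1) / s) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
        a_tot += a
        b_tot += b
        c_tot += c
    return (a_tot, b_tot, c_tot)


def wc_theta_locus(tallies, ploidy=2):
    comp = wc_components(tallies, ploidy)
    if comp is None:
        return None
    a, b, c = comp
    if a + b + c == 0:
        return None
    return a / (a + b + c)


def wc_theta_multilocus(genotypes, pop_of, n_pops, ploidy=2):
    num = den = 0.0
    any_defined = False
    for j in range(len(genotypes[0])):
        comp = wc_components(pop_tally(genotypes, pop_of, n_pops, j), ploidy)
        if comp is None:
            continue
        any_defined = True
        num += comp[0]
        den += comp[0] + comp[1] + comp[2]
    if not any_defined or den == 0:
        return None
    return num / den


def pair_share(genotypes, i, j, ploidy=2):
    """(mean proportion of shared alleles, loci used) for one pair."""
    total = 0.0
    used = 0
    for locus in range(len(genotypes[i])):
        gi, gj = genotypes[i][locus], genotypes[j][locus]
        if any(a is None for a in gi) or any(a is None for a in gj):
            continue
        ci = {a: 0 for a in ALLELES}
        cj = {a: 0 for a in ALLELES}
        for a in gi:
            ci[a] += 1
        for a in gj:
            cj[a] += 1
        total += sum(min(ci[a], cj[a]) for a in ALLELES) / ploidy
        used += 1
    if used == 0:
        return (None, 0)
    return (total / used, used)


def _locus_alleles(genotypes, locus):
    # complete-genotype rule: half-called individuals contribute no alleles
    seen = set()
    for g in genotypes:
        alleles = g[locus]
        if any(a is None for a in alleles):
            continue
        seen.update(alleles)
    return seen


def single_sfs(genotypes, pop_of, n_pops, pop, ploidy=2, folded=True):
    """SFS vector by per-locus tally; returns (list, n_included)."""
    n_pop = sum(1 for p in pop_of if p == pop)
    n = n_pop * ploidy
    spectrum = [0] * (n // 2 + 1 if folded else n + 1)
    included = 0
    for j in range(len(genotypes[0])):
        if len(_locus_alleles(genotypes, j)) > 2:
            continue
        tally = pop_tally(genotypes, pop_of, n_pops, j)[pop]
        if tally["n_called"] != n:
            continue
        c = tally["counts"][1]
        if folded:
            c = min(c, n - c)
        spectrum[c] += 1
        included += 1
    return spectrum, included


def joint_sfs(genotypes, pop_of, n_pops, ploidy=2, folded=True):
    """Joint SFS as a dict cell-tuple -> count, plus included-locus count."""
    n_chrom = [sum(1 for p in pop_of if p == k) * ploidy for k in range(n_pops)]
    big_n = sum(n_chrom)
    cells: dict[tuple, int] = {}
    included = 0
    for j in range(len(genotypes[0])):
        if len(_locus_alleles(genotypes, j)) > 2:
            continue
        tallies = pop_tally(genotypes, pop_of, n_pops, j)
        if any(tallies[k]["n_called"] != n_chrom[k] for k in range(n_pops)):
            continue
        c = tuple(tallies[k]["counts"][1] for k in range(n_pops))
        if folded:
            comp = tuple(n_chrom[k] - c[k] for k in range(n_pops))
            if 2 * sum(c) > big_n or (2 * sum(c) == big_n and comp < c):
                c = comp
        cells[c] = cells.get(c, 0) + 1
        included += 1
    return cells, included


def panel_to_genotypes(matrix, ploidy):
    """Convert a haplotype-by-locus int matrix (-1 missing) to oracle form."""
    n_ind = matrix.shape[0] // ploidy
    genotypes = []
    for i in range(n_ind):
        row = []
        for j in range(matrix.shape[1]):
            alleles = tuple(
                None if matrix[ploidy * i + c, j] < 0 else int(matrix[ploidy * i + c, j])
                for c in range(ploidy)
            )
            row.append(alleles)
        genotypes.append(row)
    return genotypes
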