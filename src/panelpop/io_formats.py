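"""Readers for VCF / PLINK ped+map / Arlequin arp, and table writers.

All readers produce a :class:`~panelpop.core_model.PanelBundle`. Allele
indexing is per-locus and reader-defined: REF first then ALT order for VCF,
lexicographic label order for ped, order of first appearance for arp. Every
statistic downstream is invariant to this indexing.

Missing data follow the complete-genotype rule: a half-called diploid
genotype is stored as fully missing.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import (
    MAX_ALLELES,
    MISSING,
    GenotypePanel,
    LocusInfo,
    PanelBundle,
    PopulationAssignment,
)
from .within_stats import LocusResult, SummaryResult

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised for unparseable or inconsistent input files."""


@dataclass
class ParseStats:
    """Per-read bookkeeping surfaced in logs (never silently dropped data)."""

    n_sites_skipped_alleles: int = 0
    n_half_calls: int = 0
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# VCF


def read_popmap(path: str | Path) -> dict[str, str]:
    """Two-column (sample, population) whitespace-delimited file."""
    mapping: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{ln}: expected two columns, got {len(parts)}")
        mapping[parts[0]] = parts[1]
    if not mapping:
        raise FormatError(f"{path}: empty population map")
    return mapping


def read_vcf(
    path: str | Path,
    popmap: str | Path | None = None,
    snps_only: bool = False,
    stats: ParseStats | None = None,
) -> PanelBundle:
    """Load a VCF (v4.x, plain or gzipped) into a diploid panel.

    Sites with more than three ALT alleles are skipped with a logged count.
    ``./.`` and half-calls become missing genotypes. Without a popmap all
    samples form the single population ``pop1``.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # htslib raises plain exceptions on bad headers
        raise FormatError(f"{path}: cannot open VCF: {exc}") from None
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no sample columns")
    stats = stats if stats is not None else ParseStats()

    columns: list[np.ndarray] = []
    loci: list[LocusInfo] = []
    saw_gt = False
    for v in vcf:
        if "GT" not in (v.FORMAT or []):
            raise FormatError(f"{path}: record without GT at {v.CHROM}:{v.POS}")
        saw_gt = True
        alts = [a for a in v.ALT]
        if len(alts) > MAX_ALLELES - 1:
            stats.n_sites_skipped_alleles += 1
            continue
        labels = [v.REF] + alts
        if snps_only and any(len(a) != 1 for a in labels):
            continue
        gt = v.genotype.array()  # (n_samples, ploidy + 1)
        if gt.shape[1] < 3:
            raise FormatError(f"{path}: non-diploid GT at {v.CHROM}:{v.POS}")
        a1 = gt[:, 0].astype(np.int16)
        a2 = gt[:, 1].astype(np.int16)
        half = (a1 < 0) != (a2 < 0)
        if half.any():
            stats.n_half_calls += int(half.sum())
        bad = (a1 < 0) | (a2 < 0)
        a1 = np.where(bad, MISSING, a1)
        a2 = np.where(bad, MISSING, a2)
        col = np.empty(2 * len(samples), dtype=np.int8)
        col[0::2] = a1
        col[1::2] = a2
        columns.append(col)
        loci.append(
            LocusInfo(
                locus_id=v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}",
                chrom=v.CHROM,
                position=int(v.POS),
                allele_labels=labels,
            )
        )
    if not saw_gt:
        raise FormatError(f"{path}: no GT genotypes found")
    if stats.n_sites_skipped_alleles:
        log.warning(
            "%s: skipped %d sites with >%d ALT alleles",
            path, stats.n_sites_skipped_alleles, MAX_ALLELES - 1,
        )

    matrix = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((2 * len(samples), 0), dtype=np.int8)
    )
    panel = GenotypePanel(matrix=matrix, ploidy=2, individual_ids=samples)

    if popmap is not None:
        mapping = read_popmap(popmap)
        unknown = set(mapping) - set(samples)
        if unknown:
            raise FormatError(
                f"popmap names unknown sample(s): {sorted(unknown)[:5]}"
            )
        absent = [s for s in samples if s not in mapping]
        if absent:
            raise FormatError(f"popmap missing sample(s): {absent[:5]}")
        pops: list[str] = []
        for lab in mapping.values():  # insertion order = first appearance
            if lab not in pops:
                pops.append(lab)
        assignment = PopulationAssignment(
            populations=pops,
            pop_index=np.array([pops.index(mapping[s]) for s in samples]),
        )
    else:
        assignment = PopulationAssignment.from_labels(["pop1"] * len(samples))
    bundle = PanelBundle(panel=panel, loci=loci, assignment=assignment)
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# PLINK ped/map


def read_ped_map(ped: str | Path, map_: str | Path) -> PanelBundle:
    """Load a PLINK text ped/map pair; the FID column defines populations.

    Allele code ``"0"`` is missing; a half-called pair is stored fully
    missing. Per-locus allele indices follow lexicographic label order.
    """
    map_rows = []
    for ln, line in enumerate(Path(map_).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"{map_}:{ln}: expected >=4 columns")
        map_rows.append(parts)
    m = len(map_rows)

    fids: list[str] = []
    iids: list[str] = []
    rows: list[list[str]] = []
    for ln, line in enumerate(Path(ped).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 6:
            raise FormatError(f"{ped}:{ln}: fewer than 6 leading columns")
        n_allele_cols = len(parts) - 6
        if n_allele_cols % 2:
            raise FormatError(f"{ped}:{ln}: odd number of allele columns")
        if n_allele_cols // 2 != m:
            raise FormatError(
                f"{ped}:{ln}: {n_allele_cols // 2} loci in ped but {m} map rows"
            )
        fids.append(parts[0])
        iids.append(parts[1])
        rows.append(parts[6:])
    if not rows:
        raise FormatError(f"{ped}: no individuals")

    tokens = np.array(rows, dtype="U")          # (n_ind, 2M)
    a1 = tokens[:, 0::2]
    a2 = tokens[:, 1::2]
    half = (a1 == "0") != (a2 == "0")
    bad = (a1 == "0") | (a2 == "0")
    n_ind = len(rows)
    matrix = np.empty((2 * n_ind, m), dtype=np.int8)
    loci: list[LocusInfo] = []
    for j in range(m):
        col1, col2 = a1[:, j], a2[:, j]
        labels = sorted(set(col1[~bad[:, j]]) | set(col2[~bad[:, j]]))
        if len(labels) > MAX_ALLELES:
            raise FormatError(
                f"{ped}: locus {map_rows[j][1]} has {len(labels)} alleles (max 4)"
            )
        lab_arr = np.array(labels, dtype="U")
        i1 = np.searchsorted(lab_arr, col1)
        i2 = np.searchsorted(lab_arr, col2)
        i1 = np.where(bad[:, j], MISSING, i1).astype(np.int8)
        i2 = np.where(bad[:, j], MISSING, i2).astype(np.int8)
        matrix[0::2, j] = i1
        matrix[1::2, j] = i2
        chrom, lid, _cm, pos = map_rows[j][:4]
        loci.append(
            LocusInfo(
                locus_id=lid,
                chrom=chrom,
                position=int(pos),
                allele_labels=labels if labels else ["N"],
            )
        )
    if half.any():
        log.warning("%s: %d half-called genotypes set to missing", ped, int(half.sum()))

    panel = GenotypePanel(matrix=matrix, ploidy=2, individual_ids=iids)
    assignment = PopulationAssignment.from_labels(fids)
    bundle = PanelBundle(panel=panel, loci=loci, assignment=assignment)
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# Arlequin / fastsimcoal arp

_KEYVAL = re.compile(r"^\s*(\w+)\s*=\s*(.*?)\s*$")


def _arp_tokens(line: str) -> list[str]:
    """Split a SampleData row; a single run of symbols becomes one-per-locus."""
    toks = line.split()
    if len(toks) == 1 and len(toks[0]) > 1:
        return list(toks[0])
    return toks


def read_arp(path: str | Path) -> PanelBundle:
    """Load an Arlequin project file (as written by coalescent simulators).

    Each ``[[Samples]]`` block becomes one population. ``GenotypicData=0``
    gives a haploid panel (one row per haplotype, replicated by the row
    frequency); ``GenotypicData=1`` gives diploids from row pairs. Allele
    symbols map to per-locus indices by order of first appearance; ``?`` is
    missing.
    """
    text = Path(path).read_text()
    lines = text.splitlines()

    genotypic = 0
    missing_char = "?"
    nb_samples = None
    for line in lines:
        mm = _KEYVAL.match(line)
        if mm:
            key, val = mm.group(1), mm.group(2).strip().strip('"').strip("'")
            if key == "GenotypicData":
                genotypic = int(val)
            elif key == "MissingData":
                missing_char = val
            elif key == "NbSamples":
                nb_samples = int(val)

    # Collect (pop_name, declared_size, raw rows) per SampleData block.
    blocks: list[tuple[str, int, list[list[str]]]] = []
    i = 0
    cur_name, cur_size = None, None
    while i < len(lines):
        mm = _KEYVAL.match(lines[i])
        if mm and mm.group(1) == "SampleName":
            cur_name = mm.group(2).strip().strip('"').strip("'")
        elif mm and mm.group(1) == "SampleSize":
            cur_size = int(mm.group(2))
        elif mm and mm.group(1) == "SampleData":
            rows: list[list[str]] = []
            i += 1
            while i < len(lines) and "}" not in lines[i]:
                if lines[i].strip():
                    rows.append(lines[i].split())
                i += 1
            if cur_name is None or cur_size is None:
                raise FormatError(f"{path}: SampleData without SampleName/SampleSize")
            blocks.append((cur_name, cur_size, rows))
            cur_name, cur_size = None, None
        i += 1
    if not blocks:
        raise FormatError(f"{path}: no [[Samples]] blocks found")
    if nb_samples is not None and nb_samples != len(blocks):
        log.warning(
            "%s: NbSamples=%d but %d sample blocks found; trusting the blocks",
            path, nb_samples, len(blocks),
        )

    ploidy = 2 if genotypic == 1 else 1
    hap_rows: list[list[str]] = []
    ind_ids: list[str] = []
    pop_labels: list[str] = []

    for name, size, rows in blocks:
        if genotypic == 1:
            if len(rows) % 2:
                raise FormatError(f"{path}: block '{name}' has an odd row count")
            n_ind = 0
            for r1, r2 in zip(rows[0::2], rows[1::2]):
                ind_id = r1[0]
                hap1 = _arp_tokens(" ".join(r1[2:]))
                hap2 = _arp_tokens(" ".join(r2))
                if len(hap1) != len(hap2):
                    raise FormatError(
                        f"{path}: individual {ind_id}: haplotype length mismatch"
                    )
                hap_rows.append(hap1)
                hap_rows.append(hap2)
                ind_ids.append(ind_id)
                pop_labels.append(name)
                n_ind += 1
            if n_ind != size:
                raise FormatError(
                    f"{path}: block '{name}': SampleSize={size} but {n_ind} "
                    "individuals parsed"
                )
        else:
            n_hap = 0
            for r in rows:
                if len(r) < 3:
                    raise FormatError(
                        f"{path}: block '{name}': short haplotype row {r}"
                    )
                hap_id, freq_s = r[0], r[1]
                try:
                    freq = int(freq_s)
                except ValueError:
                    raise FormatError(
                        f"{path}: block '{name}': bad frequency '{freq_s}'"
                    ) from None
                hap = _arp_tokens(" ".join(r[2:]))
                for rep in range(freq):
                    hap_rows.append(hap)
                    ind_ids.append(hap_id if freq == 1 else f"{hap_id}.{rep + 1}")
                    pop_labels.append(name)
                    n_hap += 1
            if n_hap != size:
                raise FormatError(
                    f"{path}: block '{name}': SampleSize={size} but {n_hap} "
                    "haplotypes parsed"
                )

    lengths = {len(r) for r in hap_rows}
    if len(lengths) != 1:
        raise FormatError(f"{path}: rows disagree on locus count: {sorted(lengths)}")
    m = lengths.pop()

    # first-appearance allele indexing, scanning rows in file order
    symbol_maps: list[dict[str, int]] = [dict() for _ in range(m)]
    matrix = np.empty((len(hap_rows), m), dtype=np.int8)
    for ri, row in enumerate(hap_rows):
        for j, sym in enumerate(row):
            if sym == missing_char:
                matrix[ri, j] = MISSING
                continue
            smap = symbol_maps[j]
            if sym not in smap:
                if len(smap) >= MAX_ALLELES:
                    raise FormatError(
                        f"{path}: locus {j + 1} has more than {MAX_ALLELES} "
                        f"distinct symbols"
                    )
                smap[sym] = len(smap)
            matrix[ri, j] = smap[sym]

    loci = [
        LocusInfo(
            locus_id=f"L{j + 1}",
            chrom="1",
            position=j + 1,
            allele_labels=list(symbol_maps[j]) if symbol_maps[j] else ["N"],
        )
        for j in range(m)
    ]
    panel = GenotypePanel(matrix=matrix, ploidy=ploidy, individual_ids=ind_ids)
    assignment = PopulationAssignment.from_labels(pop_labels)
    bundle = PanelBundle(panel=panel, loci=loci, assignment=assignment)
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# writers


def _fmt(x: float) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return repr(float(x))


def write_per_locus(
    results: "pd.DataFrame | list[LocusResult]", path: str | Path
) -> None:
    """Tab-separated per-locus table, one row per locus, NA for undefined.

    Accepts either the engine's DataFrame or a list of
    :class:`~panelpop.within_stats.LocusResult`.
    """
    if isinstance(results, list):
        if results:
            records = [{"locus": r.locus_id, **r.values} for r in results]
            df = pd.DataFrame.from_records(records)
        else:
            df = pd.DataFrame(columns=["locus"])
    else:
        df = results
    # shortest round-trip formatting: re-parsing reproduces the exact
    # doubles, and cross-run byte comparison is meaningful
    df.to_csv(
        path, sep="\t", index=False, na_rep="NA",
        float_format=lambda v: repr(float(v)),
    )


def write_summary(summary: SummaryResult, path: str | Path) -> None:
    """Tab-separated summary: statistic, mean, variance, n_defined_loci."""
    with open(path, "w") as fh:
        fh.write("statistic\tmean\tvariance\tn_loci\n")
        for name, (mean, var, count) in summary.stats.items():
            fh.write(f"{name}\t{_fmt(mean)}\t{_fmt(var)}\t{count}\n")


def write_single_sfs(result, path: str | Path) -> None:
    """Two-column (bin, count) table for a single-population spectrum."""
    with open(path, "w") as fh:
        fh.write(f"# population={result.populations[0]} n_chrom={result.n_chrom[0]} "
                 f"folded={int(result.folded)} loci={result.n_loci_included} "
                 f"excluded_missing={result.n_excluded_missing} "
                 f"excluded_multiallelic={result.n_excluded_multiallelic}\n")
        fh.write("bin\tcount\n")
        for b, cnt in enumerate(result.array):
            fh.write(f"{b}\t{int(cnt)}\n")


def write_joint_sfs(result, path: str | Path) -> None:
    """Flattened text layout: a shape header line, then row-major counts."""
    dims = " ".join(str(d) for d in result.array.shape)
    with open(path, "w") as fh:
        fh.write(f"# populations={','.join(result.populations)} "
                 f"loci={result.n_loci_included} "
                 f"excluded_missing={result.n_excluded_missing} "
                 f"excluded_multiallelic={result.n_excluded_multiallelic}\n")
        fh.write(f"{dims} {'folded' if result.folded else 'unfolded'}\n")
        fh.write(" ".join(str(int(x)) for x in result.array.ravel()) + "\n")


def write_pairshare(matrix, path: str | Path) -> None:
    """Square tab-separated matrix with individual and population labels."""
    with open(path, "w") as fh:
        fh.write("individual\tpopulation\t" + "\t".join(matrix.individual_ids) + "\n")
        for i, (iid, pop) in enumerate(zip(matrix.individual_ids, matrix.pop_labels)):
            vals = "\t".join(_fmt(v) for v in matrix.values[i])
            fh.write(f"{iid}\t{pop}\t{vals}\n")
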