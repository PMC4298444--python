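"""Synthetic SNP panels with known population structure, in all formats.

Panels are generated under a frequency-level drift approximation: an
ancestral frequency per locus, then independent beta-distributed
present-day frequencies per population with variance governed by
``F = 1 - exp(-tau)`` (the Balding-Nichols parameterisation), then binomial
genotype sampling under Hardy-Weinberg. Two-population panels simulated
this way have an expected multilocus Fst close to F, which is what the
parameter-recovery tests lean on.

The writers emit files that the corresponding readers in
:mod:`panelpop.io_formats` parse back to an equivalent bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_model import (
    MISSING,
    GenotypePanel,
    LocusInfo,
    PanelBundle,
    PopulationAssignment,
)

_NUCS = np.array(list("ACGT"))
_F_MIN, _F_MAX = 1e-9, 1.0 - 1e-9


@dataclass
class SimConfig:
    """Two-or-more population divergence model parameters."""

    n_populations: int = 2
    n_individuals: tuple[int, ...] = (50, 50)   # diploids per population
    n_loci: int = 1000
    tau: tuple[float, ...] = (0.1, 0.1)         # divergence t / (2N) per pop
    ancestral_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.0
    ploidy: int = 2
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_individuals) != self.n_populations:
            raise ValueError("n_individuals length must match n_populations")
        if len(self.tau) != self.n_populations:
            raise ValueError("tau length must match n_populations")
        if any(t < 0 for t in self.tau):
            raise ValueError("tau must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must be in [0, 1)")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")


def simulate_panel(config: SimConfig) -> PanelBundle:
    """Draw a panel; identical seed gives an identical bundle."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_loci

    lo, hi = config.ancestral_range
    p0 = rng.uniform(lo, hi, size=m)

    pop_freqs = []
    for k in range(config.n_populations):
        f = min(max(1.0 - np.exp(-config.tau[k]), _F_MIN), _F_MAX)
        shape = (1.0 - f) / f
        pop_freqs.append(rng.beta(p0 * shape, (1.0 - p0) * shape))

    rows = []
    ids: list[str] = []
    labels: list[str] = []
    for k in range(config.n_populations):
        n_k = config.n_individuals[k]
        draws = (
            rng.random((n_k * config.ploidy, m)) < pop_freqs[k][None, :]
        ).astype(np.int8)
        if config.missing_rate > 0:
            miss = rng.random((n_k, m)) < config.missing_rate
            miss = np.repeat(miss, config.ploidy, axis=0)
            draws[miss] = MISSING
        rows.append(draws)
        ids.extend(f"pop{k + 1}_{i + 1}" for i in range(n_k))
        labels.extend([f"pop{k + 1}"] * n_k)

    # reference/alternate nucleotide labels per locus (derived allele = index 1)
    ref_idx = rng.integers(0, 4, size=m)
    alt_off = rng.integers(1, 4, size=m)
    alt_idx = (ref_idx + alt_off) % 4
    loci = [
        LocusInfo(
            locus_id=f"L{j + 1}",
            chrom="1",
            position=(j + 1) * 10,
            allele_labels=[str(_NUCS[ref_idx[j]]), str(_NUCS[alt_idx[j]])],
        )
        for j in range(m)
    ]

    panel = GenotypePanel(
        matrix=np.concatenate(rows, axis=0), ploidy=config.ploidy, individual_ids=ids
    )
    bundle = PanelBundle(
        panel=panel, loci=loci, assignment=PopulationAssignment.from_labels(labels)
    )
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# writers


def write_vcf(bundle: PanelBundle, path: str | Path) -> None:
    """Emit a minimal VCF v4.1 with GT-only genotypes."""
    panel, loci = bundle.panel, bundle.loci
    if panel.ploidy != 2:
        raise ValueError("VCF writer expects a diploid panel")
    chroms = []
    for li in loci:
        if li.chrom not in chroms:
            chroms.append(li.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.1\n")
        fh.write("##source=panelpop-synthetic\n")
        for ch in chroms:
            fh.write(f"##contig=<ID={ch}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.individual_ids)
            + "\n"
        )
        a1 = panel.matrix[0::2]
        a2 = panel.matrix[1::2]
        for j, li in enumerate(loci):
            ref = li.allele_labels[0]
            alt = ",".join(li.allele_labels[1:]) if len(li.allele_labels) > 1 else "."
            gts = [
                "./."
                if a1[i, j] == MISSING or a2[i, j] == MISSING
                else f"{a1[i, j]}/{a2[i, j]}"
                for i in range(panel.n_individuals)
            ]
            fh.write(
                f"{li.chrom}\t{li.position}\t{li.locus_id}\t{ref}\t{alt}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_ped_map(bundle: PanelBundle, prefix: str | Path) -> tuple[Path, Path]:
    """Emit ``<prefix>.ped`` and ``<prefix>.map``; FID = population label."""
    panel, loci = bundle.panel, bundle.loci
    if panel.ploidy != 2:
        raise ValueError("ped writer expects a diploid panel")
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for li in loci:
            fh.write(f"{li.chrom}\t{li.locus_id}\t0\t{li.position}\n")
    a1 = panel.matrix[0::2]
    a2 = panel.matrix[1::2]
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(panel.individual_ids):
            fid = bundle.assignment.pop_of(i)
            cells = []
            for j, li in enumerate(loci):
                x, y = a1[i, j], a2[i, j]
                if x == MISSING or y == MISSING:
                    cells.append("0 0")
                else:
                    cells.append(f"{li.allele_labels[x]} {li.allele_labels[y]}")
            fh.write(f"{fid} {iid} 0 0 0 -9 " + " ".join(cells) + "\n")
    return ped_path, map_path


def write_arp(bundle: PanelBundle, path: str | Path) -> None:
    """Emit an Arlequin project file.

    Diploid panels are written as genotypic data (two rows per individual)
    so that heterozygosity information survives the round trip; haploid
    panels as haplotypic blocks with unit frequencies.
    """
    panel, loci = bundle.panel, bundle.loci
    assignment = bundle.assignment
    genotypic = 1 if panel.ploidy == 2 else 0

    def symbols(row: int) -> str:
        out = []
        for j, li in enumerate(loci):
            a = panel.matrix[row, j]
            out.append("?" if a == MISSING else li.allele_labels[a])
        return " ".join(out)

    with open(path, "w") as fh:
        fh.write("[Profile]\n")
        fh.write('Title="panelpop synthetic panel"\n')
        fh.write(f"NbSamples={assignment.n_populations}\n")
        fh.write(f"GenotypicData={genotypic}\n")
        fh.write("DataType=STANDARD\n")
        fh.write("LocusSeparator=WHITESPACE\n")
        fh.write("MissingData='?'\n\n")
        fh.write("[Data]\n[[Samples]]\n")
        for k, pop in enumerate(assignment.populations):
            members = assignment.members(k)
            fh.write(f'SampleName="{pop}"\n')
            fh.write(f"SampleSize={len(members)}\n")
            fh.write("SampleData= {\n")
            for i in members:
                iid = panel.individual_ids[i]
                if genotypic:
                    fh.write(f"{iid} 1 {symbols(2 * i)}\n")
                    fh.write(f"\t{symbols(2 * i + 1)}\n")
                else:
                    fh.write(f"{iid} 1 {symbols(i)}\n")
            fh.write("}\n")


def write_panel(bundle: PanelBundle, fmt: str, path: str | Path):
    """Dispatch to one of the three format writers.

    For ``ped`` the path is a prefix; ``<path>.ped`` and ``<path>.map`` are
    written. Returns the path(s) written.
    """
    if fmt == "vcf":
        write_vcf(bundle, path)
        return Path(path)
    if fmt == "ped":
        return write_ped_map(bundle, path)
    if fmt == "arp":
        write_arp(bundle, path)
        return Path(path)
    raise ValueError(f"unknown format: {fmt}")
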