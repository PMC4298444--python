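"""Run orchestration: load, partition loci, compute, merge, write.

The parallel contract is locus partitioning: loci are cut into contiguous
chunks (boundaries depend only on the chunk size, never on the worker
count), each chunk is computed independently, and partial results are merged
in chunk-index order with exact (integer or compensated) summation. Output
files are therefore byte-identical for any worker count and chunk size.
"""

from __future__ import annotations

import logging
import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import between_stats, io_formats, sfs as sfs_mod, within_stats
from .core_model import (
    MAX_ALLELES,
    AlleleCountTable,
    PanelBundle,
    PanelError,
    build_allele_counts,
)
from .sfs import SpectrumResult

log = logging.getLogger(__name__)

ALL_STATS = ("freq", "het", "sfs", "jointsfs", "gst", "d", "wc", "shared")

_BETWEEN_COLUMNS = {
    "gst": ["Hs", "Ht", "Gst73", "GstNC", "GstHedrick"],
    "d": ["JostD"],
    "wc": ["WC_a", "WC_b", "WC_c", "WC_theta"],
}


@dataclass
class RunConfig:
    """Everything a run needs; mirrors the CLI surface."""

    fmt: str = "vcf"                       # vcf | ped | arp
    vcf: str | None = None
    ped: str | None = None
    map: str | None = None
    arp: str | None = None
    popmap: str | None = None
    stats: tuple[str, ...] = ALL_STATS
    workers: int = 1
    chunk_size: int = 10_000
    out_prefix: str = "panelpop_out"
    seed: int = 0
    folded: bool = True
    he_unbiased: bool = True
    sample_variance: bool = False
    clamp_negative: bool = False
    snps_only: bool = False
    log_file: str | None = None

    def validate(self) -> None:
        if self.workers < 1:
            raise PanelError("workers must be >= 1")
        if self.chunk_size < 1:
            raise PanelError("chunk size must be >= 1")
        if not self.stats:
            raise PanelError("no statistics selected")
        unknown = set(self.stats) - set(ALL_STATS)
        if unknown:
            raise PanelError(f"unknown statistics: {sorted(unknown)}")
        if self.fmt not in ("vcf", "ped", "arp"):
            raise PanelError(f"unknown input format: {self.fmt}")


@dataclass
class ChunkPartial:
    """Independent result for one contiguous block of loci."""

    index: int
    start: int
    stop: int
    per_locus: dict[str, np.ndarray] = field(default_factory=dict)
    # spectra are carried as per-locus bin indices (size ~ chunk loci), not
    # dense arrays, so tiny chunk sizes cannot blow up memory at merge time
    sfs_bins: list[np.ndarray] | None = None
    sfs_excl: list[tuple[int, int]] | None = None
    joint_bins: np.ndarray | None = None
    joint_shape: tuple[int, ...] | None = None
    joint_excl: tuple[int, int] = (0, 0)
    shared_s: np.ndarray | None = None
    shared_c: np.ndarray | None = None


@dataclass
class EngineResult:
    per_locus: pd.DataFrame
    summary: within_stats.SummaryResult
    spectra: list[SpectrumResult]
    joint_spectrum: SpectrumResult | None
    pairshare: between_stats.PairShareMatrix | None
    multilocus: dict[str, float]
    output_files: list[str]


# ---------------------------------------------------------------------------
# chunk computation (must stay a pure function of its slice)


def compute_chunk(
    table: AlleleCountTable,
    codes: np.ndarray | None,
    index: int,
    start: int,
    flags: dict,
) -> ChunkPartial:
    stats = flags["stats"]
    part = ChunkPartial(index=index, start=start, stop=start + table.n_loci)

    if "freq" in stats:
        freq = within_stats.frequency_table(table)
        for p, pop in enumerate(table.populations):
            for al in range(MAX_ALLELES):
                part.per_locus[f"freq_{pop}_{al}"] = freq[:, p, al]
    if "het" in stats:
        ho = within_stats.ho_table(table)
        he = within_stats.he_table(table, unbiased=flags["he_unbiased"])
        for p, pop in enumerate(table.populations):
            part.per_locus[f"Ho_{pop}"] = ho[:, p]
            part.per_locus[f"He_{pop}"] = he[:, p]
    if any(k in stats for k in _BETWEEN_COLUMNS):
        btw = between_stats.compute_between(
            table, clamp_negative=flags["clamp_negative"]
        )
        for key, cols in _BETWEEN_COLUMNS.items():
            if key in stats:
                for c in cols:
                    part.per_locus[c] = btw[c]
        if "wc" in stats:
            part.per_locus["_wc_abc"] = btw["WC_a"] + btw["WC_b"] + btw["WC_c"]
        if "gst" in stats or "d" in stats:
            for c in ("Hs_hat", "Ht_hat", "s_eff"):
                part.per_locus[f"_{c}"] = btw[c]
    if "sfs" in stats:
        part.sfs_bins = []
        part.sfs_excl = []
        for p in range(table.n_populations):
            bins, excl_miss, excl_multi = sfs_mod.single_sfs_bins(
                table, p, folded=flags["folded"]
            )
            part.sfs_bins.append(bins)
            part.sfs_excl.append((excl_miss, excl_multi))
    if "jointsfs" in stats and table.n_populations >= 2:
        idx, shape, excl_miss, excl_multi = sfs_mod.joint_sfs_bins(
            table, folded=flags["folded"]
        )
        part.joint_bins = idx
        part.joint_shape = shape
        part.joint_excl = (excl_miss, excl_multi)
    if "shared" in stats and codes is not None:
        part.shared_s, part.shared_c = between_stats.shared_partial(
            codes, flags["ploidy"]
        )
    return part


def _run_block(args):
    """Compute all chunks of one worker's contiguous block.

    Pair-share partials are integer matrices, so they are summed here and
    returned once per block (exact, order-free); everything per-locus stays
    per chunk.
    """
    table, codes, first_chunk, abs_start, chunk_size, flags = args
    out = []
    shared_s = shared_c = None
    m = table.n_loci
    for i, off in enumerate(range(0, m, chunk_size)):
        sl = slice(off, min(off + chunk_size, m))
        part = compute_chunk(
            table.loci_slice(sl),
            codes[:, sl] if codes is not None else None,
            first_chunk + i,
            abs_start + off,
            flags,
        )
        if part.shared_s is not None:
            if shared_s is None:
                shared_s, shared_c = part.shared_s, part.shared_c
            else:
                shared_s += part.shared_s
                shared_c += part.shared_c
            part.shared_s = part.shared_c = None
        out.append(part)
    return out, shared_s, shared_c


# ---------------------------------------------------------------------------
# merging


def merge_partials(
    partials: list[ChunkPartial],
    n_loci: int,
    table: AlleleCountTable,
    flags: dict,
) -> tuple[pd.DataFrame, within_stats.SummaryResult, list, object, dict]:
    """Combine chunk partials into final tables, order- and cut-invariant.

    Chunks must tile ``0..n_loci`` exactly once; anything else is an error.
    Per-locus columns are concatenated in chunk order; summaries are then
    recomputed from the merged vectors with compensated summation, so the
    result cannot depend on the chunking.
    """
    partials = sorted(partials, key=lambda p: p.index)
    pos = 0
    for p in partials:
        if p.start != pos:
            raise PanelError(f"chunks do not tile the locus axis at {pos}")
        pos = p.stop
    if pos != n_loci:
        raise PanelError(f"chunks cover {pos} of {n_loci} loci")

    columns: dict[str, np.ndarray] = {}
    if partials and partials[0].per_locus:
        for name in partials[0].per_locus:
            columns[name] = np.concatenate([p.per_locus[name] for p in partials])

    public = {k: v for k, v in columns.items() if not k.startswith("_")}
    per_locus = pd.DataFrame(public)

    summary = within_stats.summarize_columns(
        public, sample_variance=flags["sample_variance"]
    )

    multilocus: dict[str, float] = {}
    if "WC_a" in columns and "_wc_abc" in columns:
        multilocus["WC_theta_multilocus"] = between_stats.multilocus_theta(
            columns["WC_a"], columns["_wc_abc"]
        )
    if "_Hs_hat" in columns:
        hs, ht, s_eff = columns["_Hs_hat"], columns["_Ht_hat"], columns["_s_eff"]
        defined = ~(np.isnan(hs) | np.isnan(ht) | np.isnan(s_eff))
        if defined.any():
            n = int(defined.sum())
            hs_m = math.fsum(hs[defined].tolist()) / n
            ht_m = math.fsum(ht[defined].tolist()) / n
            s_m = math.fsum(s_eff[defined].tolist()) / n
            if ht_m != 0:
                multilocus["GstNC_global"] = (ht_m - hs_m) / ht_m
            if hs_m != 1 and s_m > 1:
                multilocus["JostD_global"] = (
                    (s_m / (s_m - 1.0)) * (ht_m - hs_m) / (1.0 - hs_m)
                )
                if ht_m != 0:
                    multilocus["GstHedrick_global"] = (
                        multilocus["GstNC_global"]
                        * (s_m - 1.0 + hs_m)
                        / ((s_m - 1.0) * (1.0 - hs_m))
                    )
    if "Hs" in columns and "Ht" in columns:
        hs, ht = columns["Hs"], columns["Ht"]
        defined = ~(np.isnan(hs) | np.isnan(ht))
        if defined.any():
            n = int(defined.sum())
            hs_m = math.fsum(hs[defined].tolist()) / n
            ht_m = math.fsum(ht[defined].tolist()) / n
            if ht_m != 0:
                multilocus["Gst73_global"] = (ht_m - hs_m) / ht_m

    spectra: list[SpectrumResult] = []
    joint: SpectrumResult | None = None
    with_sfs = [p for p in partials if p.sfs_bins is not None]
    if with_sfs:
        for k in range(table.n_populations):
            n = table.ploidy * int(table.pop_n_individuals[k])
            length = n // 2 + 1 if flags["folded"] else n + 1
            bins = np.concatenate([p.sfs_bins[k] for p in with_sfs])
            spectra.append(
                SpectrumResult(
                    array=np.bincount(bins, minlength=length).astype(np.int64),
                    populations=[table.populations[k]],
                    n_chrom=[n],
                    folded=flags["folded"],
                    n_loci_included=int(bins.size),
                    n_excluded_missing=sum(p.sfs_excl[k][0] for p in with_sfs),
                    n_excluded_multiallelic=sum(p.sfs_excl[k][1] for p in with_sfs),
                )
            )
            if int(spectra[-1].array.sum()) != spectra[-1].n_loci_included:
                raise PanelError("spectrum mass does not match included loci")
    with_joint = [p for p in partials if p.joint_bins is not None]
    if with_joint:
        shape = with_joint[0].joint_shape
        idx = np.concatenate([p.joint_bins for p in with_joint])
        joint = SpectrumResult(
            array=np.bincount(idx, minlength=int(np.prod(shape)))
            .astype(np.int64)
            .reshape(shape),
            populations=list(table.populations),
            n_chrom=[table.ploidy * int(n) for n in table.pop_n_individuals],
            folded=flags["folded"],
            n_loci_included=int(idx.size),
            n_excluded_missing=sum(p.joint_excl[0] for p in with_joint),
            n_excluded_multiallelic=sum(p.joint_excl[1] for p in with_joint),
        )
        if int(joint.array.sum()) != joint.n_loci_included:
            raise PanelError("joint spectrum mass does not match included loci")

    return per_locus, summary, spectra, joint, multilocus


# ---------------------------------------------------------------------------
# top-level run


def load_bundle(config: RunConfig) -> PanelBundle:
    if config.fmt == "vcf":
        if not config.vcf:
            raise PanelError("vcf path required")
        return io_formats.read_vcf(
            config.vcf, popmap=config.popmap, snps_only=config.snps_only
        )
    if config.fmt == "ped":
        if not (config.ped and config.map):
            raise PanelError("ped and map paths required")
        return io_formats.read_ped_map(config.ped, config.map)
    if config.fmt == "arp":
        if not config.arp:
            raise PanelError("arp path required")
        return io_formats.read_arp(config.arp)
    raise PanelError(f"unknown input format: {config.fmt}")


def run(config: RunConfig, bundle: PanelBundle | None = None) -> EngineResult:
    """Execute a full analysis; returns results and writes output files."""
    config.validate()
    if config.log_file:
        handler = logging.FileHandler(config.log_file)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logging.getLogger("panelpop").addHandler(handler)

    if bundle is None:
        bundle = load_bundle(config)
    bundle.validate()
    panel, loci = bundle.panel, bundle.loci
    table = build_allele_counts(panel, bundle.assignment)
    if "jointsfs" in config.stats and table.n_populations < 2:
        raise PanelError("joint spectrum requires at least two populations")

    codes = (
        between_stats.genotype_codes(panel) if "shared" in config.stats else None
    )
    flags = {
        "stats": tuple(config.stats),
        "he_unbiased": config.he_unbiased,
        "folded": config.folded,
        "clamp_negative": config.clamp_negative,
        "sample_variance": config.sample_variance,
        "ploidy": panel.ploidy,
    }

    m = panel.n_loci
    chunk = config.chunk_size
    n_chunks = max(1, -(-m // chunk))
    per_block = -(-n_chunks // config.workers)

    blocks = []
    for w in range(config.workers):
        c0, c1 = w * per_block, min((w + 1) * per_block, n_chunks)
        if c0 >= c1:
            continue
        lo, hi = c0 * chunk, min(c1 * chunk, m)
        blocks.append(
            (
                table.loci_slice(slice(lo, hi)),
                codes[:, lo:hi] if codes is not None else None,
                c0,
                lo,
                chunk,
                flags,
            )
        )

    if config.workers == 1 or len(blocks) <= 1:
        block_results = [_run_block(b) for b in blocks]
    else:
        with ProcessPoolExecutor(max_workers=config.workers) as pool:
            block_results = list(pool.map(_run_block, blocks))
    partials = [p for lst, _, _ in block_results for p in lst]
    shared_blocks = [(s, c) for _, s, c in block_results if s is not None]

    per_locus, summary, spectra, joint, multilocus = merge_partials(
        partials, m, table, flags
    )
    meta = pd.DataFrame(
        {
            "locus": [li.locus_id for li in loci],
            "chrom": [li.chrom for li in loci],
            "position": [li.position for li in loci],
        }
    )
    per_locus = pd.concat([meta, per_locus], axis=1)

    pairshare = None
    if "shared" in config.stats and shared_blocks:
        s_sum = sum(s for s, _ in shared_blocks)
        c_sum = sum(c for _, c in shared_blocks)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(c_sum > 0, s_sum / (2.0 * c_sum), np.nan)
        pairshare = between_stats.PairShareMatrix(
            values=values,
            n_loci_used=c_sum,
            individual_ids=list(panel.individual_ids),
            pop_labels=[bundle.assignment.pop_of(i) for i in range(panel.n_individuals)],
        )

    written: list[str] = []
    prefix = config.out_prefix
    if prefix:
        Path(prefix).parent.mkdir(parents=True, exist_ok=True)
        path = f"{prefix}_per_locus.tsv"
        io_formats.write_per_locus(per_locus, path)
        written.append(path)
        for name, value in multilocus.items():
            summary.stats[name] = (value, math.nan, int(per_locus.shape[0]))
        path = f"{prefix}_summary.tsv"
        io_formats.write_summary(summary, path)
        written.append(path)
        for spec in spectra:
            path = f"{prefix}_sfs_{spec.populations[0]}.tsv"
            io_formats.write_single_sfs(spec, path)
            written.append(path)
        if joint is not None:
            path = f"{prefix}_jointsfs.tsv"
            io_formats.write_joint_sfs(joint, path)
            written.append(path)
        if pairshare is not None:
            path = f"{prefix}_shared.tsv"
            io_formats.write_pairshare(pairshare, path)
            written.append(path)

    for spec in spectra:
        log.info(
            "sfs %s: %d loci included, %d excluded (missing), %d (multiallelic)",
            spec.populations[0], spec.n_loci_included,
            spec.n_excluded_missing, spec.n_excluded_multiallelic,
        )
    return EngineResult(
        per_locus=per_locus,
        summary=summary,
        spectra=spectra,
        joint_spectrum=joint,
        pairshare=pairshare,
        multilocus=multilocus,
        output_files=written,
    )
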