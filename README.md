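# panelpop

Fast per-locus and multilocus population-genetics statistics from large SNP
panels, with locus-partitioned (chunked) computation and deterministic
parallel merging.

The panel is held as a haplotype-by-locus matrix of small allele indices
(1–4 alleles per locus, missing sentinel) and reduced once into a
per-locus × per-population allele-count table; every statistic is a function
of that table (plus, for the pairwise shared-allele matrix, the panel
itself). No statistic uses information across loci, so the locus axis is cut
into contiguous chunks, each chunk is computed independently, and partials
are merged with exact summation — output files are byte-identical for any
worker count and chunk size.

## Statistics

Within populations:

- allele frequencies
- observed heterozygosity (Ho)
- expected heterozygosity (He), raw `1 − Σp²` or the unbiased
  `n/(n−1)` form (default)
- single-population and joint (multi-population) allele frequency spectra,
  folded (minor allele) or unfolded (reader-designated allele, e.g. the
  first VCF ALT), written in a dadi-style flattened text layout

Between populations:

- Gst in three formulations: the plain frequency form
  `(Ht − Hs)/Ht` with unweighted mean frequencies, the finite-sample
  corrected form using the harmonic mean sample size, and the standardised
  G′st
- Jost's D (corrected estimators by default; a raw variant is provided)
- the variance-component Fst estimator with per-locus `a`, `b`, `c`
  components and the ratio-of-sums multilocus theta
- the proportion of shared alleles between all pairs of individuals

Per-locus values and across-locus means/variances (over defined loci only,
`NA` elsewhere) are written as tab-separated tables.

## Input formats

- **VCF v4.1** (plain or gzipped), GT field, up to 3 ALT alleles; sites with
  more are skipped and counted. Populations come from an optional
  two-column `sample population` map file.
- **PLINK ped/map** (text); the FID column defines populations; allele
  code `0` is missing.
- **Arlequin arp** as emitted by coalescent simulators: haplotypic
  (`GenotypicData=0`) or genotypic (`GenotypicData=1`) `[[Samples]]`
  blocks; each block is one population; `?` is missing.

Missing data follow a complete-genotype rule: a diploid individual with any
missing allele at a locus contributes nothing to that locus in any
statistic. Loci with missing data in an included population are excluded
from the spectra (which need a uniform sample size) and counted.

## CLI

```sh
# analysis (one input format per run)
panelpop --vcf data.vcf.gz --popmap pops.txt \
    --stats het,freq,sfs,jointsfs,gst,d,wc,shared \
    --workers 4 --chunk-size 50000 --out run1

panelpop --ped data.ped --map data.map --stats het,gst --out run2
panelpop --arp sim.arp --unfolded --he raw --variance sample --out run3

# synthetic two-population divergence panels in any of the three formats
panelpop simulate --pops 2 --inds 50,50 --loci 5000 --tau 0.1,0.1 \
    --missing 0.02 --format arp --out panel.arp --seed 7
```

Outputs are written as `<prefix>_per_locus.tsv`, `<prefix>_summary.tsv`,
`<prefix>_sfs_<pop>.tsv`, `<prefix>_jointsfs.tsv` and
`<prefix>_shared.tsv`. Floats are printed with shortest round-trip
precision, so re-parsing reproduces the exact values and byte comparison
across runs is meaningful.

The simulator draws per-population present-day frequencies from a
Balding–Nichols beta around a uniform ancestral frequency, with
`F = 1 − exp(−tau)`; two-population panels therefore have a known expected
Fst, which the parameter-recovery tests exploit.

## Library use

```python
from panelpop import RunConfig, SimConfig, run, simulate_panel

bundle = simulate_panel(SimConfig(n_loci=10_000, seed=1))
result = run(RunConfig(stats=("het", "gst", "wc"), out_prefix="demo"),
             bundle=bundle)
result.per_locus          # pandas DataFrame, one row per locus
result.multilocus         # e.g. {"WC_theta_multilocus": ...}
```
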