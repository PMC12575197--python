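# sweepscan

Selection-signature scanning for a two-population contrast (an "object"
group scanned against a "reference" group), built around three
complementary statistics and their consensus:

* **FST / π windows** — sliding-window Weir–Cockerham FST (ratio-of-sums
  across SNPs) and per-group nucleotide diversity, Z-scored FST and
  log2 π-ratio transforms, and joint outlier calling by top-quantile or
  absolute thresholds.
* **XP-CLR-style composite likelihood scan** — grid-wise likelihood ratio
  of a hitchhiking sweep model against a truncated-normal neutral drift
  model of allele-frequency change, with r²-based down-weighting of
  correlated SNPs.
* **ROH islands** — PLINK-style per-individual runs of homozygosity,
  per-SNP occurrence percentages across the object group, and maximal
  above-threshold island segments.

Outlier regions from each method are mapped to genes, intersected into a
three-method consensus, and the consensus list is tested for term
over-representation with an exact hypergeometric (one-sided Fisher) test
plus Benjamini–Hochberg adjustment.

A forward Wright–Fisher haplotype simulator generates fully synthetic
two-population data (neutral drift genome-wide, hard sweeps conditioned on
fixation planted in the object group), so the entire pipeline is testable
without any external data.

## Command line

Every stage is a subcommand of `sweepscan`; run `sweepscan <cmd> --help`
for all options.

```bash
# synthetic data with one planted sweep
sweepscan simulate --out sim/ --seed 1 --sweep 1000000:0.1

# quality filters (QD/MQ/FS, call rate, MAF, mean depth)
sweepscan filter --vcf sim/sim.vcf --out filtered.vcf

# the three scans
sweepscan fstpi --vcf filtered.vcf --popmap sim/popmap.tsv \
    --obj fat --ref thin --window 50000 --step 25000 --out fstpi/
sweepscan xpclr --vcf filtered.vcf --popmap sim/popmap.tsv \
    --obj fat --ref thin --grid 2000 --top 0.01 --out xpclr/
sweepscan roh --vcf filtered.vcf --popmap sim/popmap.tsv \
    --group fat --preset plink --island-threshold 20 --out roh/

# consensus and enrichment
sweepscan consensus --fstpi fstpi/outlier_regions.bed \
    --xpclr xpclr/regions.bed --roh roh/islands.bed \
    --genes genes.bed --out consensus/
sweepscan enrich --candidates consensus/consensus_genes.txt \
    --annotation gene2term.tsv --out enrichment.tsv
```

Or run everything from one TOML configuration (see `examples/demo.toml`):

```bash
sweepscan run-all --config examples/demo.toml --out run/
```

`run-all` is resumable (stages with existing outputs are skipped), fully
seeded, and writes a `manifest.json` recording the config hash, seed and
per-stage row counts. Identical config + seed gives byte-identical
outputs.

## Conventions

* VCF input/output is 1-based; BED output is 0-based half-open; TSV
  outputs carry 1-based inclusive `start`/`end` columns.
* Genotypes are coded 0/1/2 alternate-allele counts, missing calls
  excluded per site from every statistic.
* Only biallelic SNPs are analysed; multi-allelic records and indels are
  skipped on read.

## Tests

```bash
python -m pytest tests/
```

The suite includes brute-force oracles for the FST, π and hypergeometric
computations, property tests for the scan invariants, and
`tests/test_acceptance.py`, which verifies planted-sweep recovery across
20 seeded desk-scale replicates (this is the slow part; the full suite
takes a few minutes).

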