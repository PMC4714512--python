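# tssenrich

Strand-aware quantification of histone-variant ChIP-seq signal around
transcription start sites (TSSs), for epigenomics analyses that ask whether
a chromatin mark or histone variant is deposited **independently of gene
expression** (as reported for testis-specific H3.5) or **coupled to
transcription** (as for H3.3).

The package implements the full analysis chain as a tested library plus a
CLI, and ships a synthetic-data generator with known ground truth so the
whole pipeline runs end-to-end without any external data.

## The signal model

1. **Binned coverage.** Mapped fragments are counted into fixed 1000-bp
   genomic bins; each fragment is assigned to the single bin containing its
   interval midpoint.
2. **RPKM normalization.** Per-bin counts `c` become
   `RPKM = c × 10⁹ / (bin_size × N)` with `N` the library size (for 1-kb
   bins: `c × 10⁶ / N`).
3. **ChIP − input subtraction.** The signal is the per-bin RPKM difference
   between ChIP and input-control libraries; negative values are kept.
4. **Expression deciles.** Genes with FPKM = 0 are excluded; the rest are
   ordered by FPKM and split into ten equal-membership groups
   (q0-10% … q90-100%).
5. **TSS metagene aggregation.** Per gene, the signal bins covering
   TSS ± 3 kb are extracted in transcription orientation (minus-strand
   profiles are reversed) and averaged per decile: mean ± SE versus signed
   distance from the TSS.
6. **Increment statistic.** Each gene is scalarized to its mean signal over
   the 2 kb downstream of the TSS; decile means are reported as increments
   relative to the grand mean, with SE across genes. A flat increment curve
   across deciles means expression-independent deposition; a monotone rise
   means expression-coupled deposition.
7. **Peak categories.** Peaks (called upstream, accepted as BED) are
   assigned one genomic category by midpoint with a fixed priority
   (promoter-TSS > TES > 5′UTR > 3′UTR > exon > intron > intergenic), and
   the category distribution plus the "around genes" percentage
   (100 − intergenic%) is tallied.

Two laboratory assay normalizations used alongside such analyses are also
provided: thermal-stability melt curves,
`F_norm(T) = [F(T) − F(26)] / [F(95) − F(26)]`, with a half-dissociation
temperature summary, and FRAP recovery curves (background-corrected
bleached/unbleached ratio normalized to the pre-bleach value).

## Worked example

Simulate an expression-independent (H3.5-like) dataset — 2000 genes on
4 × 4 Mb chromosomes, ~3 × 10⁵ ChIP reads with a Gaussian enrichment kernel
centred 500 bp downstream of each TSS — and analyse it:

```python
import tssenrich as te

genome, genes = te.generate_genome(n_chroms=4, chrom_length=4_000_000,
                                   n_genes=2000, seed=1)
expr = te.simulate_expression(genes, zero_fraction=0.15, seed=2)
spec = te.EnrichmentSpec(kernel_offset=500, kernel_width=500,
                         amplitude=30.0, coupling_mode="independent")
chip = te.simulate_reads(genome, genes, expr, spec, background_depth=15.0, seed=3)
inp  = te.simulate_reads(genome, genes, expr, None, background_depth=15.0, seed=4)

signal = te.subtract_control(
    te.rpkm_normalize(te.count_reads_in_bins(chip, genome)),
    te.rpkm_normalize(te.count_reads_in_bins(inp, genome)))
groups  = te.assign_deciles(expr)
profile = te.aggregate_profiles(signal, genes, groups, window_bp=3000)
print(profile.group("all").round(3).to_string(index=False))
```

```
group  offset_bp   mean    se    n
  all      -3000  0.433 0.688 1998
  all      -2000 -0.493 0.685 1998
  all      -1000 -0.771 0.600 1998
  all          0 34.441 0.648 1998
  all       1000 33.532 0.668 1998
  all       2000 -6.842 0.502 1998
  all       3000 -6.555 0.582 1998
```

The metagene peaks in the bins at offsets 0–1000 bp — the bins containing
the simulated +500 bp kernel — and is flat elsewhere. The per-decile
increment statistic confirms expression independence:

```python
curve = te.increment_by_decile(
    te.tss_signal_summary(signal, genes, window_bp=2000), groups)
print(curve.table.round(3).to_string(index=False))
```

```
 decile    label   n  raw_mean  increment    se
      0   q0-10% 170    32.887     -1.265 1.322
      1  q10-20% 170    33.968     -0.184 1.248
      ...
      9 q90-100% 170    34.936      0.784 1.358
```

Decile means differ by far less than three standard errors and Spearman
ρ(decile, mean) = 0.212: deposition does not track expression. Rerunning
with `coupling_mode="dependent"` yields ρ = 1.0 and a strictly increasing
increment curve — the expression-coupled (H3.3-like) signature.

The same analysis is available from the shell:

```bash
tssenrich run --profile independent --out-dir scratch/h35_like --seed 1
tssenrich run --config examples/h33_like.yaml
```

Each run writes reads/annotation/expression inputs, the signal bedGraph,
`aggregation.tsv`, `increment.tsv`, the peak category distribution, and a
`manifest.json` with SHA-256 checksums — reruns under the same seed are
byte-identical. Every stage is also its own subcommand
(`simulate`, `signal`, `groups`, `aggregate`, `increment`, `annotate`,
`melt`, `frap`).

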