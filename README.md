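# m5c — RNA bisulfite-sequencing methylome analysis

`m5c` is a tested, self-contained pipeline for transcriptome-wide analysis of
5-methylcytosine (m⁵C) in mRNA from RNA bisulfite sequencing (RNA-BisSeq).
Bisulfite treatment deaminates unmethylated cytosine to uracil (read as T),
while m⁵C resists conversion — so cytosines that survive in sequencing reads
mark methylated sites, and the fraction of reads showing C at a site estimates
its methylation stoichiometry.

The package is aimed at method developers and analysts who need a controlled
environment for RNA-BisSeq: every stage of the analysis is paired with a
synthetic-data generator that plants m⁵C sites with known stoichiometries, so
site-calling behavior can be measured against ground truth.

## What it does

* **Simulation** — a toy transcriptome (multi-exon genes on both strands, UTRs
  and CDS, optional ncRNA) with planted m⁵C sites, strand-specific 125-bp
  paired reads from ~200-nt fragments, near-complete bisulfite conversion
  (default 99.9% per cytosine), and a fully unmethylated *Dhfr* spike-in
  transcript as conversion control.
* **Three-letter alignment** — reads and reference are collapsed to a C→T
  alphabet for placement (methylation state cannot affect the locus), with
  exact 25-nt seeds, ≤2 extension mismatches, uniqueness-or-reject, and a
  concordant mate within 500 nt. Methylation evidence is recovered from the
  original read against the original reference.
* **Site calling** — reads with >30% unconverted cytosines are discarded;
  per-cytosine pileups count methylated (i, read C) vs converted (j, read T)
  observations; the level is i/(i+j); credible sites require coverage ≥ 30,
  level ≥ 0.1 and methylated depth ≥ 5. Global conversion measured on the
  spike-in must exceed 99.6% or calling refuses to proceed. Sites found in
  both replicates are intersected and projected through the exon chain to
  1-based genomic coordinates.
* **Annotation** — mRNA region (5′UTR/CDS/3′UTR/intron/ncRNA), CG/CHG/CHH
  sequence context with transcriptome-proportion normalization, 21-nt flank
  position-frequency matrices, metagene profiles over 100 percentile bins per
  region, and CDS positional histograms.
* **Comparative analysis** — RPKM expression gating (expressed = RPKM ≥ 1,
  union-mode counting), tissue-specific and stringent tissue-specific sites,
  dynamic sites between stages (|Δlevel| > 0.05), writer-knockdown-regulated
  sites, Pearson correlation clustering; RIP-peak intersection with
  Mann-Whitney comparison of bound vs input levels; EMSA and 2^(−ΔΔCt)
  calculators.

## Worked example

```sh
m5c simulate --out sim --seed 7
m5c align --ref sim/transcriptome.fa --fq1 sim/reads_1.fastq \
          --fq2 sim/reads_2.fastq --out aln.tsv
m5c call --aln aln.tsv --ref sim/transcriptome.fa \
         --annot sim/annotation.bed --genome sim/genome.fa --out sites.tsv
```

The `call` step prints its QC summary; with the default simulation
(20 transcripts, 50 planted sites, 50× depth, seed 7) it prints:

```
reads_in        7932
reads_removed   0
spikein_c_observations  8075
conversion_rate 0.999133
qc_passed       True
sites_called    33
```

All 7,932 pairs aligned uniquely and none tripped the >30% unconverted-C
filter (error-free simulation at 99.9% conversion rarely produces one); the
spike-in's 8,075 cytosine observations give a measured global conversion of
99.91% (gate: >99.6%), and 33 sites pass all three credibility gates —
planted sites whose stoichiometry and coverage clear the level ≥ 0.1,
coverage ≥ 30 and methylated depth ≥ 5 thresholds. `sites.tsv` lists each
site's genomic position, strand, level, CG/CHG/CHH context and mRNA region;
compare with `sim/truth.tsv` to check recovery.

Downstream, `m5c context`, `m5c metagene`, `m5c expression`, `m5c compare`
and `m5c rip-targets` operate on site tables; see `m5c --help`.

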