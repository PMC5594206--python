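# Methods

## The measurement model

RNA bisulfite sequencing reads the methylation state of each cytosine through
chemistry: bisulfite deaminates unmethylated C to U (sequenced as T) while
m⁵C resists conversion. At a site with true stoichiometry *s* (the fraction
of transcript molecules methylated) and per-cytosine conversion probability
*p* for unmethylated C, the probability that a read shows C is

    q = s + (1 − s)(1 − p)

Observed methylated counts at a site are therefore Binomial(n, q) over its
coverage n, and the level estimate i/(i + j) is the MLE of q. With the
default p = 0.999 the residual-failure term (1 − s)·0.001 is negligible
against the 0.1 level gate, which is why a hard level threshold plus a
methylated-depth threshold suffices to control false sites without a formal
test: a false site needs ≥ 5 independent conversion failures at one cytosine
*and* a level ≥ 0.1, with probability ≈ P(Binom(30, 0.001) ≥ 5) ≈ 3·10⁻¹⁰
per position at minimal coverage.

The unmethylated spike-in measures p directly: its pooled pileup gives
rate = Σj / Σ(i + j), and calling refuses to run when rate ≤ 0.996 (the QC
gate), since at lower conversion the failure term starts to compete with
low-stoichiometry sites.

## Pipeline stages and their parameters

**Simulation** (`SimulationConfig`). Defaults reflect the library protocol
being emulated: fragments Normal(200, 20) nt (RNA fragmented to ~200 nt),
125-bp paired reads, strand-specific sense-strand fragments only (a stranded
poly(A) protocol; antisense is a config toggle, default off), conversion
p = 0.999 for unmethylated C and 0 for methylated C, constant high base
qualities, no sequencing errors by default. Mean read1 fold-coverage `depth`
defaults to 50. The spike-in is a 600-nt single-exon transcript with typical
(~25%) C content, never planted. Planted stoichiometries default to
Beta(1.2, 4.0) — median ≈ 0.19, most mass below 0.4 — matching the reported
shape of mRNA m⁵C level distributions (median ≈ 20%); tests that need a
controlled range use Uniform(0.15, 0.9) or fixed values instead. RNA is
written in DNA alphabet (T, not U) because reads are DNA-space.

**Alignment.** Placement happens in three-letter space: both read and
reference have every C rewritten as T, making the locus invariant to
methylation state. An exact k-mer seed (25 nt, zero mismatches) anchors
candidates; the full read is verified in converted space with ≤ 2
mismatches; equally good loci are rejected as ambiguous rather than
tie-broken, and the mate must match sense-ward within a 500-nt fragment
span. Alignment is transcriptome-space only — reads are simulated from
mature transcripts, so a genome-plus-junction-library cascade would add
machinery without adding cases; genomic coordinates are recovered downstream
by exon-chain projection. Only read1 contributes methylation observations
(one observation per fragment molecule; overlapping mates would double-count
the same molecule). Indels and quality-aware scoring are out of scope.

**Calling.** The read-level filter (> 30% of covered reference Cs still C)
runs before any site is known, so it counts genuinely methylated cytosines
too — a heavily methylated read can be discarded; this is the faithful
pre-calling order, and with ≤ ~10 Cs per 125-nt read the filter only fires
on conversion failures or dense methylation. Reads covering zero reference
Cs pass (0/0 treated as 0). Non-C/T observations at a reference C (errors)
are excluded from both i and j. Gates are inclusive (≥), matching their
stated thresholds. Replicate intersection is keyed on (chrom, 1-based
position, strand); the merged level is the arithmetic mean of replicate
levels by default, with pooled counts (Σi / Σcoverage) as a config
alternative — the mean weights replicates equally, pooled weights by
coverage.

**Coordinates.** Internally 0-based half-open; all emitted tables 1-based
with explicit strand, the convention of published site lists. On the minus
strand transcript offset 0 maps to the *highest* genomic coordinate of its
exon block; projection and its inverse are exact bijections (tested by
round-trip).

**Annotation.** Sequence context (CG / CHG / CHH, H ∈ {A, C, T}) is read on
the spliced transcript sense strand from the two downstream bases; at a
transcript 3′ end the genomic downstream bases substitute when a genome is
available, otherwise the site is context-"NA" and excluded from context
summaries. Context normalization divides per-context site counts by the
transcriptome-wide proportion of cytosines in that context and renormalizes
to 1, so a uniform sampling of cytosines yields (⅓, ⅓, ⅓). Metagene
percentile bins use floor(offset / region_length × 100) clamped to bin 99;
the moving average (window 3 bins, centered) is mass-preserving — each bin
spreads its mass uniformly over its clipped window — so smoothed percentages
still sum to 100 exactly, which plain edge-truncated averaging does not
guarantee.

**Expression.** Gene counts use union-mode overlap resolution on the genomic
footprint of read1: a read overlapping the exon model of more than one gene
counts for none. A mapping-quality filter is moot here because the aligner
emits unique placements only. RPKM = count × 10⁹ / (exon-model length ×
total mapped); the exon model is the union of all transcript exons of the
gene; RPKM ≥ 1 defines "expressed".

**Comparative.** All classifications are pure set/threshold functions on
(chrom, pos, strand) keys. Delta thresholds are strict (> 0.05), so a change
of exactly 5 percentage points is "stable". A site absent from a knockdown
sample counts as level 0 only when the knockdown data could have detected it
(coverage at that position ≥ the calling threshold, when coverage is
supplied); otherwise it is not assessable and excluded. Clustering uses
pairwise-complete Pearson correlation, distance 1 − r, average linkage —
reasonable defaults where the choice was open; both are configurable through
the function arguments, and constant level vectors raise rather than emit
NaN correlations.

**RIP targets.** Peaks are BED-convention 0-based half-open; a 1-based site
position pos is inside a peak iff start ≤ pos − 1 < end. Peak calling itself
(and its P-value cutoff) happens upstream; this module consumes the
intervals. Bound-vs-input levels are compared with a two-sided Mann-Whitney
U test.

**Assay calculators.** EMSA binding ratio = bound / (bound + free), scale
invariant. The qPCR export ratio is 2^(−ΔΔCt) with ΔCt = Ct_target − Ct_ref
per compartment, Δ(C/N) = ΔCt_cyto − ΔCt_nuc per condition, and ΔΔCt =
Δ(C/N)_treatment − Δ(C/N)_control; positive ΔΔCt means reduced relative
export (fold < 1).

## What the simulator does and does not emulate

It reproduces the statistical structure that the caller's correctness
depends on: binomial methylation sampling per fragment molecule, independent
per-cytosine conversion failure, strand-specific paired reads with realistic
fragment/read lengths, an unmethylated spike-in, multi-exon gene structure
on both strands and a genome to project into. It deliberately omits:
hexamer-priming bias at fragment starts (uniform starts instead — the real
protocol's biased priming suppresses artifacts this simulator never
creates), RNA secondary-structure-dependent incomplete conversion (failures
are i.i.d. here, but cluster in structured regions in real data),
quality-score error models, intron-retaining pre-mRNA, adapter read-through
and hm⁵C. Passing tests therefore demonstrate correct *inference given the
conversion model*, not robustness to structure-correlated conversion
failure — on real data the >30% unconverted-read filter and the spike-in
gate carry that burden.

## Numerical and design notes

* Per-seed bit-reproducibility: all randomness flows from numpy Generators
  seeded from the config; replicate libraries use a separate `read_seed`
  stream so two libraries can share one transcriptome and truth set.
* Problem sizes in the test suite (tens of transcripts, 50–60× depth,
  200 planted sites) are chosen so every distributional check has enough
  observations for tight binomial/chi-square bounds while the whole suite
  runs in seconds.
* The stoichiometry-recovery test checks each called level against the 99%
  binomial interval around q and allows the number of out-of-interval sites
  that a 1% per-site miss rate predicts at the family level; demanding all
  200 sites fall inside a 99% interval simultaneously would reject correct
  implementations most of the time.
* Degenerate inputs fail loudly: empty references, duplicate sequence IDs,
  pileups beyond transcript ends, zero exon-model lengths, missing spike-in
  observations, non-C context queries and out-of-range projections all raise
  with specific messages.

## Known limitations

The aligner's k-mer index holds the full converted transcriptome in memory —
appropriate for transcriptome-scale references, not genomes. Uniqueness-or-
reject discards reads from repeated regions instead of rescuing them by
mapping quality. Replicate intersection matches on coordinate only, not
annotation. Context percentages of real methylomes depend on whether context
is read spliced or genomic at junctions; this implementation is spliced-first
with a genomic fallback at transcript ends, and junction-spanning context
differences are untested against external callers.
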