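"""Gene-level counting and RPKM to gate expressed mRNAs.

Counting follows union-mode overlap resolution: a read is assigned to a gene
only if its genomic footprint overlaps that gene's exon model and no other
gene's; reads overlapping two genes count for neither. RPKM = reads per
kilobase of exon model per million mapped reads; genes with RPKM >= 1 are
flagged as expressed.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .align import AlignmentRecord
from .model import TranscriptModel

RPKM_EXPRESSED = 1.0


@dataclass
class ExpressionRecord:
    gene_id: str
    count: int
    exon_model_length: int
    rpkm: float
    expressed: bool


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(ivals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def gene_exon_models(
    models: list[TranscriptModel],
) -> dict[str, tuple[str, list[tuple[int, int]]]]:
    """Per-gene union of all transcript exons: gene_id -> (chrom, merged intervals)."""
    raw: dict[str, tuple[str, list[tuple[int, int]]]] = {}
    for m in models:
        chrom, ivals = raw.setdefault(m.gene_id, (m.chrom, []))
        if chrom != m.chrom:
            raise ValueError(f"gene {m.gene_id} spans chromosomes")
        ivals.extend(m.exons)
    return {g: (chrom, _merge_intervals(iv)) for g, (chrom, iv) in raw.items()}


def _read_genomic_blocks(
    r: AlignmentRecord, model: TranscriptModel,
) -> list[tuple[int, int]]:
    """Genomic intervals (0-based half-open) covered by the read1 window."""
    blocks = []
    t0, t1 = r.tpos, r.tpos + r.length
    off = 0
    for s, e in model.exons:
        n = e - s
        lo, hi = max(t0, off), min(t1, off + n)
        if lo < hi:
            if model.strand == "+":
                blocks.append((s + (lo - off), s + (hi - off)))
            else:
                blocks.append((e - (hi - off), e - (lo - off)))
        off += n
    return blocks


def count_reads_per_gene(
    alignments: list[AlignmentRecord], models: list[TranscriptModel],
) -> dict[str, int]:
    """Union-mode gene counts: ambiguous (multi-gene) reads count for none."""
    by_id = {m.transcript_id: m for m in models}
    gene_models = gene_exon_models(models)
    by_chrom: dict[str, list[tuple[str, list[tuple[int, int]]]]] = defaultdict(list)
    for g, (chrom, ivals) in gene_models.items():
        by_chrom[chrom].append((g, ivals))

    counts: dict[str, int] = {g: 0 for g in gene_models}
    for r in alignments:
        model = by_id[r.transcript_id]
        blocks = _read_genomic_blocks(r, model)
        hit_genes = set()
        for g, ivals in by_chrom[model.chrom]:
            if any(s < be and bs < e for bs, be in blocks for s, e in ivals):
                hit_genes.add(g)
        if len(hit_genes) == 1:
            counts[hit_genes.pop()] += 1
    return counts


def compute_rpkm(
    counts: dict[str, int],
    models: list[TranscriptModel],
    total_mapped: int,
) -> pd.DataFrame:
    """RPKM per gene; ``expressed`` flags RPKM >= 1.

    rpkm = count * 1e9 / (exon_model_length * total_mapped)
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    gene_models = gene_exon_models(models)
    rows = []
    for g in sorted(gene_models):
        chrom, ivals = gene_models[g]
        length = sum(e - s for s, e in ivals)
        if length == 0:
            raise ValueError(f"gene {g} has zero exon model length")
        n = counts.get(g, 0)
        rpkm = n * 1e9 / (length * total_mapped)
        rows.append({
            "gene_id": g, "count": n, "exon_model_length": length,
            "rpkm": rpkm, "expressed": rpkm >= RPKM_EXPRESSED,
        })
    return pd.DataFrame(
        rows, columns=["gene_id", "count", "exon_model_length", "rpkm", "expressed"])


def expression_table(
    alignments: list[AlignmentRecord], models: list[TranscriptModel],
) -> pd.DataFrame:
    """Counting + RPKM in one step, using the number of unique alignments as
    the mapped-read total."""
    counts = count_reads_per_gene(alignments, models)
    return compute_rpkm(counts, models, total_mapped=len(alignments))
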