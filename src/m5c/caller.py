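"""m5C site calling from bisulfite alignments.

Order of operations mirrors the standard RNA-BisSeq workflow: discard reads
whose own conversion looks incomplete (> 30% of covered reference Cs still
read as C), pile up methylated (i, read C) vs converted (j, read T)
observations at every reference cytosine, check global conversion on the
unmethylated spike-in (> 99.6% gate), then call credible sites with
coverage >= 30, level i/(i+j) >= 0.1 and methylated depth >= 5, projecting
each to genome coordinates through the transcript's exon chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict

import pandas as pd

from . import annotation as annot_mod
from .align import AlignmentRecord
from .io import SITE_COLUMNS
from .model import TranscriptModel
from .simulate import SPIKEIN_ID


@dataclass
class CallerConfig:
    max_unconverted_read_frac: float = 0.30
    min_coverage: int = 30
    min_level: float = 0.10
    min_methylated_depth: int = 5
    min_conversion_rate: float = 0.996
    merge_levels: str = "mean"  # replicate merge: "mean" or "pooled"

    def validate(self) -> None:
        for name in ("max_unconverted_read_frac", "min_level", "min_conversion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class SitePileup:
    transcript_id: str
    tpos: int  # 0-based reference-C offset
    i: int  # methylated observations (read C)
    j: int  # unmethylated observations (read T)
    other: int  # non-C/T observations (errors); excluded from the level

    @property
    def coverage(self) -> int:
        return self.i + self.j

    @property
    def level(self) -> float:
        return self.i / (self.i + self.j) if self.i + self.j else float("nan")


@dataclass
class ConversionReport:
    total_spikein_c_observations: int
    converted: int
    rate: float
    passed: bool


class ConversionQCError(RuntimeError):
    """Raised when calling sites with a failed conversion QC and no --force."""


# ---------------------------------------------------------------- read filter

def filter_reads(
    alignments: list[AlignmentRecord], config: CallerConfig,
) -> tuple[list[AlignmentRecord], int]:
    """Drop reads with > max_unconverted_read_frac unconverted cytosines.

    The fraction counts ALL unconverted Cs in the read window, including
    genuinely methylated positions: the filter runs before any site is known.
    Reads covering zero reference Cs are kept (0/0 treated as 0).
    """
    kept = []
    for r in alignments:
        n_c = len(r.ref_c_positions)
        if n_c == 0 or r.n_unconverted / n_c <= config.max_unconverted_read_frac:
            kept.append(r)
    return kept, len(alignments) - len(kept)


# --------------------------------------------------------------------- pileup

def build_pileup(
    alignments: list[AlignmentRecord],
    reference: dict[str, str],
) -> list[SitePileup]:
    """Count methylated / converted / other observations per reference C.

    Only read1 of each fragment contributes (one observation per molecule).
    """
    counts: dict[tuple[str, int], list[int]] = defaultdict(lambda: [0, 0, 0])
    for r in alignments:
        ref = reference.get(r.transcript_id)
        if ref is None or r.tpos + r.length > len(ref):
            raise ValueError(
                f"alignment {r.read_id} extends beyond {r.transcript_id}")
        for tpos, base in zip(r.ref_c_positions, r.read_bases):
            row = counts[(r.transcript_id, tpos)]
            if base == "C":
                row[0] += 1
            elif base == "T":
                row[1] += 1
            else:
                row[2] += 1
    return [
        SitePileup(tid, tpos, i, j, other)
        for (tid, tpos), (i, j, other) in sorted(counts.items())
    ]


# -------------------------------------------------------------- conversion QC

def conversion_qc(
    pileups: list[SitePileup],
    config: CallerConfig,
    spikein_id: str = SPIKEIN_ID,
) -> ConversionReport:
    """Global C->T conversion rate over the unmethylated spike-in."""
    spike = [p for p in pileups if p.transcript_id == spikein_id]
    total = sum(p.i + p.j for p in spike)
    if total == 0:
        raise ValueError(f"no observations on spike-in {spikein_id!r}")
    converted = sum(p.j for p in spike)
    rate = converted / total
    return ConversionReport(
        total_spikein_c_observations=total, converted=converted, rate=rate,
        passed=rate > config.min_conversion_rate,
    )


# --------------------------------------------------------------- site calling

def call_sites(
    pileups: list[SitePileup],
    config: CallerConfig,
    models: list[TranscriptModel],
    conversion: ConversionReport | None = None,
    force: bool = False,
    genome: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Call credible m5C sites and return them as a site table.

    Gates (all inclusive): coverage i+j >= min_coverage, level i/(i+j) >=
    min_level, methylated depth i >= min_methylated_depth. ``other``
    observations count toward neither i nor j. Sites are projected to genome
    coordinates and annotated with sequence context and mRNA region. The
    spike-in is excluded from calling.
    """
    if conversion is not None and not conversion.passed and not force:
        raise ConversionQCError(
            f"global conversion rate {conversion.rate:.4f} fails the "
            f">{config.min_conversion_rate} gate; rerun with force to override")
    by_id = {m.transcript_id: m for m in models}
    rows = []
    for p in pileups:
        model = by_id.get(p.transcript_id)
        if model is None:
            raise KeyError(f"no transcript model for {p.transcript_id}")
        if model.is_spikein:
            continue
        cov = p.i + p.j
        if cov < config.min_coverage or p.i < config.min_methylated_depth:
            continue
        level = p.i / cov
        if level < config.min_level:
            continue
        chrom, gpos, strand = model.project(p.tpos)
        rows.append({
            "chrom": chrom, "pos": gpos, "strand": strand,
            "gene_id": model.gene_id, "transcript_id": model.transcript_id,
            "tpos": p.tpos, "coverage": cov, "methylated_depth": p.i,
            "level": level,
            "context": annot_mod.classify_context(model, p.tpos, genome),
            "region": annot_mod.classify_region(model, p.tpos),
        })
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return df.sort_values(["chrom", "pos", "strand"], kind="mergesort",
                          ignore_index=True)


# ------------------------------------------------------- replicate operations

def intersect_replicates(
    table_a: pd.DataFrame, table_b: pd.DataFrame,
    merge_levels: str = "mean",
) -> pd.DataFrame:
    """Keep sites present in both replicates, keyed by (chrom, pos, strand).

    Reported level is the arithmetic mean of the replicate levels ("mean",
    default) or the pooled-count estimate (i_a+i_b)/(cov_a+cov_b) ("pooled");
    per-replicate levels are retained as columns.
    """
    key = ["chrom", "pos", "strand"]
    merged = table_a.merge(table_b, on=key, suffixes=("_rep1", "_rep2"))
    if merged.empty:
        out = pd.DataFrame(columns=SITE_COLUMNS + ["level_rep1", "level_rep2"])
        return out
    if merge_levels == "mean":
        level = (merged["level_rep1"] + merged["level_rep2"]) / 2.0
    elif merge_levels == "pooled":
        i = merged["methylated_depth_rep1"] + merged["methylated_depth_rep2"]
        cov = merged["coverage_rep1"] + merged["coverage_rep2"]
        level = i / cov
    else:
        raise ValueError(f"unknown merge mode {merge_levels!r}")
    out = pd.DataFrame({
        "chrom": merged["chrom"], "pos": merged["pos"],
        "strand": merged["strand"],
        "gene_id": merged["gene_id_rep1"],
        "transcript_id": merged["transcript_id_rep1"],
        "tpos": merged["tpos_rep1"],
        "coverage": merged[["coverage_rep1", "coverage_rep2"]].min(axis=1),
        "methylated_depth": merged[
            ["methylated_depth_rep1", "methylated_depth_rep2"]].min(axis=1),
        "level": level,
        "context": merged["context_rep1"], "region": merged["region_rep1"],
        "level_rep1": merged["level_rep1"], "level_rep2": merged["level_rep2"],
    })
    return out.sort_values(["chrom", "pos", "strand"], kind="mergesort",
                           ignore_index=True)


def project_to_genome(model: TranscriptModel, tpos: int) -> tuple[str, int, str]:
    """Transcript offset -> (chrom, 1-based genomic position, strand)."""
    return model.project(tpos)


def project_from_genome(model: TranscriptModel, gpos: int) -> int:
    """Inverse of :func:`project_to_genome` (1-based genomic -> tpos)."""
    return model.unproject(gpos)
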