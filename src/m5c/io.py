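"""File formats used across the pipeline.

All genomic intervals on disk follow BED conventions (0-based, half-open);
site tables carry 1-based positions in their ``pos`` column, matching the
usual "chrN:12345" site-naming convention of methylome studies.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .model import TranscriptModel

SITE_COLUMNS = [
    "chrom", "pos", "strand", "gene_id", "transcript_id", "tpos",
    "coverage", "methylated_depth", "level", "context", "region",
]


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence dict (uppercased)."""
    with _open(path) as fh:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return seqs


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with _open(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq_pairs(fq1, fq2) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, read1_seq, read2_seq) from a pair of FASTQ files."""
    with _open(fq1) as f1, _open(fq2) as f2:
        it1 = SeqIO.parse(f1, "fastq")
        it2 = SeqIO.parse(f2, "fastq")
        for r1, r2 in zip(it1, it2, strict=True):
            name1 = r1.id.split("/")[0]
            name2 = r2.id.split("/")[0]
            if name1 != name2:
                raise ValueError(f"unpaired reads: {r1.id} vs {r2.id}")
            yield name1, str(r1.seq).upper(), str(r2.seq).upper()


def write_fastq(path, reads: Iterable[tuple[str, str]], quality_char: str = "I") -> None:
    with _open(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


# ------------------------------------------------------------- annotation BED

def write_annotation_bed(path, models: Iterable[TranscriptModel]) -> None:
    """Write transcript models as 12-column BED (one line per transcript).

    The name field packs ``transcript_id;gene_id[;spikein]`` so the models can
    be reconstructed without a separate gene table.
    """
    with _open(path, "wt") as fh:
        for m in models:
            genomic = sorted(m.exons)  # ascending, BED block order
            start = genomic[0][0]
            end = genomic[-1][1]
            if m.cds_start is not None:
                g1 = m.project(m.cds_start)[1] - 1
                g2 = m.project(m.cds_end - 1)[1] - 1
                thick_start, thick_end = min(g1, g2), max(g1, g2) + 1
            else:
                thick_start = thick_end = start
            sizes = ",".join(str(e - s) for s, e in genomic)
            offsets = ",".join(str(s - start) for s, e in genomic)
            name = f"{m.transcript_id};{m.gene_id}" + (";spikein" if m.is_spikein else "")
            fh.write("\t".join(map(str, [
                m.chrom, start, end, name, 0, m.strand,
                thick_start, thick_end, "0,0,0", len(genomic), sizes, offsets,
            ])) + "\n")


def read_annotation_bed(path, sequences: dict[str, str]) -> list[TranscriptModel]:
    """Rebuild TranscriptModels from a 12-column BED plus the transcriptome FASTA."""
    models = []
    with _open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, strand = f[0], int(f[1]), f[5]
            parts = f[3].split(";")
            tid, gid = parts[0], parts[1] if len(parts) > 1 else parts[0]
            spike = "spikein" in parts[2:]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            genomic = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
            exons = genomic if strand == "+" else genomic[::-1]
            seq = sequences[tid]
            model = TranscriptModel(
                transcript_id=tid, gene_id=gid, chrom=chrom, strand=strand,
                exons=exons, sequence=seq, is_spikein=spike,
            )
            thick_start, thick_end = int(f[6]), int(f[7])
            if thick_end > thick_start:
                t1 = model.unproject(thick_start + 1)
                t2 = model.unproject(thick_end)  # 1-based last CDS base
                model.cds_start, model.cds_end = min(t1, t2), max(t1, t2) + 1
            models.append(model)
    return models


# ------------------------------------------------------------------ TSV tables

def write_truth(path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sites(path, sites: pd.DataFrame) -> None:
    out = sites.copy()
    if "level" in out:
        out["level"] = out["level"].map(lambda x: f"{x:.6g}")
    out.to_csv(path, sep="\t", index=False)


def read_sites(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})


def write_sites_bed(path, sites: pd.DataFrame) -> None:
    """Export a site table as BED6; score = level * 1000, rounded."""
    with _open(path, "wt") as fh:
        for row in sites.itertuples():
            fh.write("\t".join(map(str, [
                row.chrom, row.pos - 1, row.pos,
                f"{row.gene_id}|{row.transcript_id}",
                int(round(row.level * 1000)), row.strand,
            ])) + "\n")


def read_peaks_bed(path) -> pd.DataFrame:
    """Read peak intervals from BED (3+ columns)."""
    rows = []
    with _open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append({
                "chrom": f[0], "start": int(f[1]), "end": int(f[2]),
                "name": f[3] if len(f) > 3 else ".",
                "score": float(f[4]) if len(f) > 4 else 0.0,
                "strand": f[5] if len(f) > 5 else ".",
            })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
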