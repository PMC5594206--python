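"""Transcript models and transcript<->genome coordinate projection.

A TranscriptModel is the coordinate backbone of the pipeline: an ordered exon
chain (genomic, 0-based half-open, listed 5'->3' in *transcript* orientation,
so descending genomic order on the minus strand), the spliced sense-strand
sequence written in DNA alphabet (T, not U -- sequencing reads are DNA space),
and CDS boundaries as transcript-space offsets when the transcript codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]  # genomic, 0-based half-open, transcript order
    sequence: str  # sense strand, A/C/G/T
    cds_start: int | None = None  # transcript-space, 0-based
    cds_end: int | None = None  # transcript-space, half-open
    is_spikein: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        total = sum(e - s for s, e in self.exons)
        if total != len(self.sequence):
            raise ValueError(
                f"{self.transcript_id}: exon lengths sum to {total}, "
                f"sequence is {len(self.sequence)} nt"
            )
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.cds_start is not None:
            if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
                raise ValueError(f"{self.transcript_id}: CDS out of bounds")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def gene_span(self) -> tuple[int, int]:
        genomic = sorted(self.exons)
        return genomic[0][0], genomic[-1][1]

    # ----------------------------------------------------------- projection

    def project(self, tpos: int) -> tuple[str, int, str]:
        """Map a transcript offset (0-based) to (chrom, gpos 1-based, strand).

        Walks the exon chain in transcript orientation; on the minus strand
        the genomic position is counted from the 3' end of each exon block.
        """
        if not 0 <= tpos < len(self.sequence):
            raise IndexError(f"tpos {tpos} outside {self.transcript_id}")
        off = tpos
        for s, e in self.exons:
            n = e - s
            if off < n:
                g0 = s + off if self.strand == "+" else e - 1 - off
                return self.chrom, g0 + 1, self.strand
            off -= n
        raise AssertionError("unreachable")

    def unproject(self, gpos: int) -> int:
        """Map a 1-based genomic position back to a transcript offset."""
        g0 = gpos - 1
        off = 0
        for s, e in self.exons:
            if s <= g0 < e:
                return off + (g0 - s if self.strand == "+" else e - 1 - g0)
            off += e - s
        raise ValueError(
            f"genomic position {gpos} not exonic in {self.transcript_id}"
        )
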