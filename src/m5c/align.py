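"""Three-letter (C->T) bisulfite alignment against the transcriptome.

Bisulfite conversion makes read C/T state uninformative for placement, so
both reads and reference are collapsed to a three-letter alphabet (every C
rewritten as T) before matching; methylation evidence is then recovered by
comparing the ORIGINAL read to the ORIGINAL reference at reference-C
positions. Alignment is seed-and-extend over an exact k-mer index of the
converted sense-strand transcriptome (the protocol is strand-specific, so
only the sense strand is indexed): zero mismatches in the seed, a small
mismatch allowance in the extension, uniqueness-or-reject across loci, and a
concordant mate within 500 nt.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .model import revcomp

DEFAULT_SEED_LEN = 25
DEFAULT_MAX_MISMATCH = 2
MAX_MATE_DIST = 500  # maximum fragment span, nt


def convert_c_to_t(seq: str) -> str:
    return seq.replace("C", "T")


@dataclass
class AlignmentRecord:
    """A uniquely placed read pair, with per-reference-C evidence from read1.

    ``ref_c_positions`` are transcript offsets of reference cytosines inside
    the read1 window; ``read_bases`` holds the original read1 base observed at
    each (C = unconverted/methylated, T = converted, anything else an error).
    """
    read_id: str
    transcript_id: str
    tpos: int  # 0-based start of read1 on the transcript
    length: int  # read1 aligned length
    ref_c_positions: list[int]
    read_bases: str
    n_mismatch_non_c: int
    strand: str = "+"

    @property
    def read_c_mask(self) -> list[bool]:
        return [b == "C" for b in self.read_bases]

    @property
    def n_unconverted(self) -> int:
        return self.read_bases.count("C")


@dataclass
class Rejection:
    read_id: str
    reason: str  # no_seed | ambiguous | too_many_mismatches | discordant_mate | too_short


class ConvertedIndex:
    """Exact k-mer index over C->T-converted reference sequences.

    Originals are retained for C-position lookup after placement.
    """

    def __init__(self, references, seed_len: int = DEFAULT_SEED_LEN):
        if not isinstance(references, dict):
            records = list(references)
            ids = [tid for tid, _ in records]
            if len(set(ids)) != len(ids):
                raise ValueError("duplicate sequence IDs")
            references = dict(records)
        if not references:
            raise ValueError("empty reference")
        self.seed_len = seed_len
        self.original = {tid: seq.upper() for tid, seq in references.items()}
        self.converted = {tid: convert_c_to_t(s) for tid, s in self.original.items()}
        self.kmers: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for tid, conv in self.converted.items():
            for i in range(len(conv) - seed_len + 1):
                self.kmers[conv[i:i + seed_len]].append((tid, i))
        self.kmers = dict(self.kmers)



def _hamming(a: str, b: str, limit: int) -> int:
    """Mismatch count between equal-length strings, early exit past limit."""
    if a == b:
        return 0
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def align_read_pair(
    pair: tuple[str, str, str],
    index: ConvertedIndex,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> AlignmentRecord | Rejection:
    """Place one read pair; unique best locus or rejection.

    read1 is C->T converted and seeded (exact, mirroring ``-N 0``) against the
    converted index; candidate loci are verified over the full read with at
    most ``max_mismatch`` mismatches in converted space. A tie between
    equally good loci is rejected as ambiguous. The mate (reverse complement
    of the fragment 3' end) must match concordantly downstream within
    ``MAX_MATE_DIST`` (``-X 500``).
    """
    read_id, seq1, seq2 = pair
    k = index.seed_len
    if len(seq1) < k:
        return Rejection(read_id, "too_short")
    conv1 = convert_c_to_t(seq1)
    candidates = index.kmers.get(conv1[:k], ())
    if not candidates:
        return Rejection(read_id, "no_seed")

    hits = []
    best = max_mismatch + 1
    for tid, pos in candidates:
        ref_conv = index.converted[tid]
        window = ref_conv[pos:pos + len(conv1)]
        if len(window) < len(conv1):
            continue
        mm = _hamming(conv1, window, max_mismatch)
        if mm <= max_mismatch:
            hits.append((mm, tid, pos))
            best = min(best, mm)
    if not hits:
        return Rejection(read_id, "too_many_mismatches")
    top = [h for h in hits if h[0] == best]
    if len(top) > 1:
        return Rejection(read_id, "ambiguous")
    _, tid, tpos = top[0]

    if seq2 and not _mate_concordant(seq2, index, tid, tpos, len(seq1), max_mismatch):
        return Rejection(read_id, "discordant_mate")

    ref = index.original[tid]
    window = ref[tpos:tpos + len(seq1)]
    ref_c = [tpos + i for i, b in enumerate(window) if b == "C"]
    read_bases = "".join(seq1[p - tpos] for p in ref_c)
    n_mm = sum(
        1 for i, b in enumerate(window) if b != "C" and seq1[i] != b
    )
    return AlignmentRecord(
        read_id=read_id, transcript_id=tid, tpos=tpos, length=len(seq1),
        ref_c_positions=ref_c, read_bases=read_bases, n_mismatch_non_c=n_mm,
    )


def _mate_concordant(
    seq2: str, index: ConvertedIndex, tid: str, tpos: int,
    len1: int, max_mismatch: int,
) -> bool:
    """Check read2 maps sense-ward downstream of read1 within the mate limit."""
    sense = convert_c_to_t(revcomp(seq2))
    ref_conv = index.converted[tid]
    lo = tpos  # fragment length >= read length: mate start not before read1
    hi = min(tpos + MAX_MATE_DIST - len(sense), len(ref_conv) - len(sense))
    if hi < lo:
        return False
    # fast path: exact occurrence
    found = ref_conv.find(sense, lo, hi + len(sense))
    if found != -1:
        return True
    if max_mismatch == 0:
        return False
    for p in range(lo, hi + 1):
        if _hamming(sense, ref_conv[p:p + len(sense)], max_mismatch) <= max_mismatch:
            return True
    return False


def align_pairs(
    pairs, index: ConvertedIndex, max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> tuple[list[AlignmentRecord], Counter]:
    """Align an iterable of (id, read1, read2); returns (records, rejection tally)."""
    records: list[AlignmentRecord] = []
    rejected: Counter = Counter()
    for pair in pairs:
        res = align_read_pair(pair, index, max_mismatch)
        if isinstance(res, AlignmentRecord):
            records.append(res)
        else:
            rejected[res.reason] += 1
    return records, rejected


# -------------------------------------------------------------------- TSV I/O

def write_alignments(path, records: list[AlignmentRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttranscript_id\ttpos\tlength\tc_total\tc_unconverted"
                 "\tref_c_positions\tread_bases\tn_mismatch_non_c\n")
        for r in records:
            fh.write("\t".join(map(str, [
                r.read_id, r.transcript_id, r.tpos, r.length,
                len(r.ref_c_positions), r.n_unconverted,
                ",".join(map(str, r.ref_c_positions)), r.read_bases or ".",
                r.n_mismatch_non_c,
            ])) + "\n")


def read_alignments(path) -> list[AlignmentRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError(f"not an alignment TSV: {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            ref_c = [int(x) for x in f[6].split(",")] if f[6] else []
            records.append(AlignmentRecord(
                read_id=f[0], transcript_id=f[1], tpos=int(f[2]),
                length=int(f[3]), ref_c_positions=ref_c,
                read_bases="" if f[7] == "." else f[7],
                n_mismatch_non_c=int(f[8]),
            ))
    return records
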