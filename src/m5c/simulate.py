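"""Synthetic RNA-BisSeq data with known ground truth.

Generates a toy transcriptome laid out on a synthetic genome, plants m5C
sites with chosen stoichiometries, and simulates strand-specific paired-end
bisulfite reads from ~200 nt mRNA fragments, plus a fully unmethylated Dhfr
spike-in transcript that serves as the bisulfite conversion control.

The conversion model, per fragment molecule: each planted cytosine is
methylated with probability equal to its stoichiometry; an unmethylated C is
deaminated to T with probability ``p_convert_unmethylated`` (default 0.999,
i.e. near-complete conversion); a methylated C is converted with probability
``p_convert_methylated`` (default 0, m5C resists bisulfite). Uniform
sequencing errors may then be layered on each read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .model import TranscriptModel, revcomp

SPIKEIN_ID = "Dhfr_spikein"

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    n_transcripts: int = 20
    utr5_range: tuple[int, int] = (60, 150)
    cds_range: tuple[int, int] = (300, 900)
    utr3_range: tuple[int, int] = (120, 400)
    ncrna_fraction: float = 0.1
    max_exons: int = 3
    intron_range: tuple[int, int] = (60, 200)
    spikein_length: int = 600
    n_planted_sites: int = 50
    # stoichiometry distribution: ("beta", a, b) | ("uniform", lo, hi) | ("fixed", v)
    stoichiometry: tuple = ("beta", 1.2, 4.0)
    depth: float = 50.0
    fragment_len_mean: int = 200
    fragment_len_sd: int = 20
    read_len: int = 125
    p_convert_unmethylated: float = 0.999
    p_convert_methylated: float = 0.0
    seq_error_rate: float = 0.0
    antisense: bool = False  # antisense fragments off: stranded poly(A) protocol
    seed: int = 0
    # separate stream for fragment sampling/conversion so replicate libraries
    # can be drawn from one transcriptome + truth set; None -> derived from seed
    read_seed: int | None = None

    def validate(self) -> None:
        for name in ("utr5_range", "cds_range", "utr3_range", "intron_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"invalid {name}: ({lo}, {hi})")
        for name in ("p_convert_unmethylated", "p_convert_methylated",
                     "seq_error_rate", "ncrna_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")
        if self.read_len < 1 or self.fragment_len_mean < self.read_len:
            raise ValueError("need read_len >= 1 and fragment_len_mean >= read_len")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def _draw_stoichiometry(rng: np.random.Generator, spec: tuple, n: int) -> np.ndarray:
    kind = spec[0]
    if kind == "beta":
        return rng.beta(spec[1], spec[2], size=n)
    if kind == "uniform":
        return rng.uniform(spec[1], spec[2], size=n)
    if kind == "fixed":
        v = float(spec[1])
        if not 0 < v <= 1:
            raise ValueError("fixed stoichiometry must be in (0,1]")
        return np.full(n, v)
    raise ValueError(f"unknown stoichiometry distribution {kind!r}")


# -------------------------------------------------------------- transcriptome

def generate_transcriptome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[TranscriptModel]]:
    """Build a synthetic genome and transcript set.

    Returns (genome chrom -> sequence, transcript models). Transcripts are
    laid out consecutively on "chr1" with random strands and 1..max_exons
    exons; the last model is the unmethylatable Dhfr-like spike-in on its own
    contig. A configurable fraction of transcripts are non-coding (no CDS).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom_parts: list[tuple[int, str]] = []
    cursor = 0
    models: list[TranscriptModel] = []

    for i in range(config.n_transcripts):
        utr5 = int(rng.integers(config.utr5_range[0], config.utr5_range[1] + 1))
        cds = int(rng.integers(config.cds_range[0], config.cds_range[1] + 1))
        utr3 = int(rng.integers(config.utr3_range[0], config.utr3_range[1] + 1))
        length = utr5 + cds + utr3
        coding = rng.random() >= config.ncrna_fraction
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, config.max_exons + 1))

        # split transcript length into exon blocks of >= 40 nt where possible
        if n_exons > 1 and length >= 40 * n_exons:
            cuts = np.sort(rng.choice(
                np.arange(40, length - 39), size=n_exons - 1, replace=False))
            bounds = [0, *cuts.tolist(), length]
            sizes = [bounds[k + 1] - bounds[k] for k in range(n_exons)]
            if min(sizes) < 25:  # re-merge degenerate blocks
                sizes = [length]
        else:
            sizes = [length]

        cursor += 100  # intergenic gap
        genomic = []
        for k, sz in enumerate(sizes):
            if k:
                cursor += int(rng.integers(config.intron_range[0],
                                           config.intron_range[1] + 1))
            genomic.append((cursor, cursor + sz))
            cursor += sz

        gene_seq_len = genomic[-1][1] - genomic[0][0]
        locus = _random_seq(rng, gene_seq_len)
        origin = genomic[0][0]
        spliced = "".join(locus[s - origin:e - origin] for s, e in genomic)
        chrom_parts.append((origin, locus))

        sense = spliced if strand == "+" else revcomp(spliced)
        exons = genomic if strand == "+" else genomic[::-1]
        models.append(TranscriptModel(
            transcript_id=f"tx{i:03d}", gene_id=f"gene{i:03d}", chrom="chr1",
            strand=strand, exons=exons, sequence=sense,
            cds_start=utr5 if coding else None,
            cds_end=utr5 + cds if coding else None,
        ))

    chr1 = []
    pos = 0
    for origin, locus in chrom_parts:
        chr1.append("A" * (origin - pos))
        chr1.append(locus)
        pos = origin + len(locus)
    genome = {"chr1": "".join(chr1)}

    spike_seq = _random_seq(rng, config.spikein_length)
    genome["chrSpike"] = "A" * 100 + spike_seq
    models.append(TranscriptModel(
        transcript_id=SPIKEIN_ID, gene_id=SPIKEIN_ID, chrom="chrSpike",
        strand="+", exons=[(100, 100 + config.spikein_length)],
        sequence=spike_seq, is_spikein=True,
    ))
    return genome, models


# ------------------------------------------------------------- site planting

def plant_m5c_sites(
    models: list[TranscriptModel],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Choose cytosines to methylate; returns the ground-truth table.

    Sites land only on C positions of non-spike-in transcripts; stoichiometry
    is drawn from the configured distribution. Columns: transcript_id, tpos
    (0-based), chrom, gpos (1-based), strand, stoichiometry.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    candidates = [
        (m, t) for m in models if not m.is_spikein
        for t, base in enumerate(m.sequence) if base == "C"
    ]
    if config.n_planted_sites > len(candidates):
        raise ValueError(
            f"requested {config.n_planted_sites} sites but only "
            f"{len(candidates)} cytosines available"
        )
    idx = rng.choice(len(candidates), size=config.n_planted_sites, replace=False)
    idx = np.sort(idx)
    stoich = _draw_stoichiometry(rng, config.stoichiometry, len(idx))
    rows = []
    for k, ci in enumerate(idx):
        m, t = candidates[ci]
        chrom, gpos, strand = m.project(t)
        rows.append({
            "transcript_id": m.transcript_id, "tpos": t, "chrom": chrom,
            "gpos": gpos, "strand": strand,
            "stoichiometry": round(float(stoich[k]), 6),
        })
    return pd.DataFrame(
        rows, columns=["transcript_id", "tpos", "chrom", "gpos", "strand",
                       "stoichiometry"])


# ------------------------------------------------------------ read simulation

def simulate_bisseq_reads(
    models: list[TranscriptModel],
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Simulate bisulfite-converted paired reads; returns (reads1, reads2).

    Fragments are drawn uniformly from the sense strand of each transcript
    (ACT-hexamer priming bias is not modeled); read1 reports the converted
    sense sequence, read2 its reverse complement. Read names encode
    ``transcript:start-end:serial`` for truth-based evaluation.
    """
    if config.depth <= 0:
        raise ValueError("depth must be > 0")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)

    planted: dict[str, dict[int, float]] = {}
    for row in truth.itertuples():
        planted.setdefault(row.transcript_id, {})[row.tpos] = row.stoichiometry

    reads1: list[tuple[str, str]] = []
    reads2: list[tuple[str, str]] = []
    serial = 0
    for m in models:
        L = len(m.sequence)
        if L < config.read_len:
            continue
        seq = np.frombuffer(m.sequence.encode(), dtype="S1")
        c_pos = np.flatnonzero(seq == b"C")
        tr_sites = planted.get(m.transcript_id, {})
        stoich = np.array([tr_sites.get(int(t), 0.0) for t in c_pos])
        is_planted = stoich > 0

        n_frag = max(1, round(config.depth * L / config.read_len))
        flens = np.rint(rng.normal(config.fragment_len_mean,
                                   config.fragment_len_sd, n_frag)).astype(int)
        flens = np.clip(flens, config.read_len, L)
        starts = (rng.random(n_frag) * (L - flens + 1)).astype(int)

        for fs, fl in zip(starts, flens):
            fe = fs + fl
            frag = seq[fs:fe].copy()
            lo, hi = np.searchsorted(c_pos, [fs, fe])
            if hi > lo:
                cs = c_pos[lo:hi]
                u = rng.random(hi - lo)
                meth = np.where(is_planted[lo:hi], u < stoich[lo:hi], False)
                conv = np.where(
                    meth,
                    rng.random(hi - lo) < config.p_convert_methylated,
                    rng.random(hi - lo) < config.p_convert_unmethylated,
                )
                frag[cs[conv] - fs] = b"T"
            fragment = frag.tobytes().decode()
            r1 = fragment[:config.read_len]
            r2 = revcomp(fragment[-config.read_len:])
            if config.seq_error_rate > 0:
                r1 = _apply_errors(r1, config.seq_error_rate, rng)
                r2 = _apply_errors(r2, config.seq_error_rate, rng)
            name = f"{m.transcript_id}:{fs}-{fe}:{serial}"
            reads1.append((name, r1))
            reads2.append((name, r2))
            serial += 1
    return reads1, reads2


def _apply_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(read.encode(), dtype="S1").copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for h in hit:
        choices = BASES[BASES != arr[h]]
        arr[h] = rng.choice(choices)
    return arr.tobytes().decode()


# ------------------------------------------------------------------- pipeline

def run_simulation(config: SimulationConfig, out_dir) -> dict[str, Path]:
    """Full simulation: writes FASTA, BED12 annotation, truth TSV and paired
    FASTQ into ``out_dir``; returns the paths. Bit-reproducible per seed."""
    out = io.ensure_dir(out_dir)
    genome, models = generate_transcriptome(config)
    truth = plant_m5c_sites(models, config, np.random.default_rng(config.seed + 1))
    read_seed = config.seed + 2 if config.read_seed is None else config.read_seed
    reads1, reads2 = simulate_bisseq_reads(
        models, truth, config, np.random.default_rng(read_seed))

    paths = {
        "transcriptome": out / "transcriptome.fa",
        "genome": out / "genome.fa",
        "annotation": out / "annotation.bed",
        "truth": out / "truth.tsv",
        "fq1": out / "reads_1.fastq",
        "fq2": out / "reads_2.fastq",
    }
    io.write_fasta(paths["transcriptome"],
                   [(m.transcript_id, m.sequence) for m in models])
    io.write_fasta(paths["genome"], sorted(genome.items()))
    io.write_annotation_bed(paths["annotation"], models)
    io.write_truth(paths["truth"], truth)
    io.write_fastq(paths["fq1"], reads1)
    io.write_fastq(paths["fq2"], reads2)
    return paths
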