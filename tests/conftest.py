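import numpy as np
import pandas as pd
import pytest

from m5c import (
    CallerConfig,
    ConvertedIndex,
    SimulationConfig,
    TranscriptModel,
    align_pairs,
    build_pileup,
    call_sites,
    conversion_qc,
    filter_reads,
    run_simulation,
)
from m5c import io
from m5c.io import SITE_COLUMNS


@pytest.fixture(scope="session")
def pipeline(tmp_path_factory):
    """One small simulate->align->call run shared across the suite."""
    cfg = SimulationConfig(n_transcripts=12, n_planted_sites=40, depth=50, seed=11)
    paths = run_simulation(cfg, tmp_path_factory.mktemp("sim"))
    seqs = io.read_fasta(paths["transcriptome"])
    models = io.read_annotation_bed(paths["annotation"], seqs)
    genome = io.read_fasta(paths["genome"])
    index = ConvertedIndex(seqs)
    records, rejected = align_pairs(
        io.read_fastq_pairs(paths["fq1"], paths["fq2"]), index)
    ccfg = CallerConfig()
    kept, n_removed = filter_reads(records, ccfg)
    pileups = build_pileup(kept, seqs)
    report = conversion_qc(pileups, ccfg)
    sites = call_sites(pileups, ccfg, models, report, genome=genome)
    return {
        "config": cfg, "paths": paths, "seqs": seqs, "models": models,
        "genome": genome, "index": index, "records": records,
        "rejected": rejected, "kept": kept, "n_removed": n_removed,
        "pileups": pileups, "report": report, "sites": sites,
        "truth": io.read_truth(paths["truth"]),
    }


def make_model(
    sequence,
    exons=None,
    strand="+",
    cds=None,
    transcript_id="tx",
    gene_id=None,
    chrom="chr1",
    spikein=False,
):
    """Single-transcript model helper for constructed fixtures."""
    if exons is None:
        exons = [(0, len(sequence))]
    return TranscriptModel(
        transcript_id=transcript_id, gene_id=gene_id or transcript_id,
        chrom=chrom, strand=strand, exons=exons, sequence=sequence,
        cds_start=cds[0] if cds else None, cds_end=cds[1] if cds else None,
        is_spikein=spikein,
    )


def make_site_table(rows):
    """Build a site table from dicts holding any subset of the site columns."""
    defaults = {
        "chrom": "chr1", "pos": 1, "strand": "+", "gene_id": "g",
        "transcript_id": "t", "tpos": 0, "coverage": 50,
        "methylated_depth": 10, "level": 0.2, "context": "CG", "region": "CDS",
    }
    filled = []
    for r in rows:
        d = dict(defaults)
        d.update(r)
        if "level" in r and "methylated_depth" not in r:
            d["methylated_depth"] = max(5, round(r["level"] * d["coverage"]))
        filled.append(d)
    return pd.DataFrame(filled, columns=SITE_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
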