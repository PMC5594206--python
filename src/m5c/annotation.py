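"""Site annotation and positional/context profiling.

Covers mRNA region assignment (5'UTR / CDS / 3'UTR / intron / ncRNA),
cytosine sequence context (CG / CHG / CHH, H = A, C or T in DNA space),
context-abundance normalization against the transcriptome background,
21-nt flank extraction as a position frequency matrix, and metagene
profiling with 100 percentile bins per mRNA region.

Context is read on the transcript sense strand from the two bases downstream
of the site (spliced context); at transcript ends the genomic downstream
bases are used when a genome is supplied, otherwise the site's context is
"NA" and it is excluded from context summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import TranscriptModel, revcomp

CONTEXTS = ("CG", "CHG", "CHH")
REGIONS = ("5UTR", "CDS", "3UTR")


# ----------------------------------------------------------------- region

def classify_region(
    model: TranscriptModel,
    tpos: int | None = None,
    gpos: int | None = None,
) -> str:
    """Assign a site to 5UTR / CDS / 3UTR / ncRNA / intron.

    Exonic positions (given as ``tpos``, or a ``gpos`` that projects into an
    exon) are split by the CDS offsets; a genomic position inside the gene
    span but outside every exon is intronic.
    """
    if tpos is None:
        if gpos is None:
            raise ValueError("need tpos or gpos")
        try:
            tpos = model.unproject(gpos)
        except ValueError:
            lo, hi = model.gene_span
            if lo < gpos <= hi:  # 1-based within span
                return "intron"
            raise ValueError(
                f"position {gpos} outside gene span of {model.transcript_id}")
    if not model.is_coding:
        return "ncRNA"
    if tpos < model.cds_start:
        return "5UTR"
    if tpos < model.cds_end:
        return "CDS"
    return "3UTR"


# ---------------------------------------------------------------- context

def _downstream_bases(
    model: TranscriptModel, tpos: int, genome: dict[str, str] | None,
) -> str:
    down = model.sequence[tpos + 1:tpos + 3]
    if len(down) == 2 or genome is None:
        return down
    chrom_seq = genome.get(model.chrom)
    if chrom_seq is None:
        return down
    # extend past the transcript 3' end with genomic bases, strand-aware
    lo, hi = model.gene_span
    need = 2 - len(down)
    if model.strand == "+":
        extra = chrom_seq[hi:hi + need]
    else:
        extra = revcomp(chrom_seq[max(0, lo - need):lo])
    return down + extra


def classify_context(
    model: TranscriptModel, tpos: int, genome: dict[str, str] | None = None,
) -> str:
    """CG if the next sense base is G, CHG if base+2 is G, else CHH."""
    if model.sequence[tpos] != "C":
        raise ValueError(f"base at {model.transcript_id}:{tpos} is not C")
    down = _downstream_bases(model, tpos, genome)
    if len(down) >= 1 and down[0] == "G":
        return "CG"
    if len(down) < 2:
        return "NA"
    return "CHG" if down[1] == "G" else "CHH"


def transcriptome_context_proportions(
    models: list[TranscriptModel], genome: dict[str, str] | None = None,
) -> dict[str, float]:
    """Fraction of transcriptome cytosines in each context (distinct transcripts)."""
    counts = dict.fromkeys(CONTEXTS, 0)
    seen = set()
    for m in models:
        if m.transcript_id in seen:
            continue
        seen.add(m.transcript_id)
        seq = m.sequence
        for t, base in enumerate(seq):
            if base != "C":
                continue
            ctx = classify_context(m, t, genome)
            if ctx != "NA":
                counts[ctx] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("transcriptome contains no classifiable cytosines")
    return {k: v / total for k, v in counts.items()}


@dataclass
class ContextSummary:
    raw_counts: dict[str, int]
    transcriptome_proportions: dict[str, float]
    normalized_fractions: dict[str, float]
    raw_fractions: dict[str, float] = field(default_factory=dict)


def normalize_context_counts(
    raw_counts: dict[str, int], proportions: dict[str, float],
) -> ContextSummary:
    """Normalize absolute per-context site counts to the transcriptome
    background: normalized_k = (n_k/p_k) / sum_m (n_m/p_m)."""
    ratios = {}
    for k in CONTEXTS:
        n, p = raw_counts.get(k, 0), proportions.get(k, 0.0)
        if n > 0 and p <= 0:
            raise ValueError(f"context {k} has sites but zero background proportion")
        ratios[k] = n / p if p > 0 else 0.0
    total_ratio = sum(ratios.values())
    total_n = sum(raw_counts.get(k, 0) for k in CONTEXTS)
    return ContextSummary(
        raw_counts={k: raw_counts.get(k, 0) for k in CONTEXTS},
        transcriptome_proportions=dict(proportions),
        normalized_fractions={
            k: (ratios[k] / total_ratio if total_ratio else 0.0) for k in CONTEXTS},
        raw_fractions={
            k: (raw_counts.get(k, 0) / total_n if total_n else 0.0)
            for k in CONTEXTS},
    )


def summarize_contexts(
    sites: pd.DataFrame, models: list[TranscriptModel],
    genome: dict[str, str] | None = None,
) -> ContextSummary:
    """Tally site contexts and normalize against transcriptome proportions."""
    counts = dict.fromkeys(CONTEXTS, 0)
    for ctx in sites["context"]:
        if ctx in counts:
            counts[ctx] += 1
    props = transcriptome_context_proportions(models, genome)
    return normalize_context_counts(counts, props)


# ------------------------------------------------------------------ flanks

def extract_flanks(
    sites: pd.DataFrame, models: list[TranscriptModel], halfwidth: int = 10,
) -> pd.DataFrame:
    """Position frequency matrix of the (2*halfwidth+1)-nt windows centered
    on each site; transcript ends pad with N, excluded from column counts.

    Returns a DataFrame with one row per window position and columns
    A/C/G/T holding base fractions (each row sums to 1 over non-N bases).
    """
    width = 2 * halfwidth + 1
    by_id = {m.transcript_id: m for m in models}
    counts = np.zeros((width, 4), dtype=float)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for row in sites.itertuples():
        m = by_id[row.transcript_id]
        t = row.tpos
        for k in range(width):
            p = t - halfwidth + k
            if 0 <= p < len(m.sequence):
                b = m.sequence[p]
                if b in base_idx:
                    counts[k, base_idx[b]] += 1
    col_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(col_tot > 0, counts / col_tot, 0.0)
    return pd.DataFrame(frac, columns=list("ACGT"),
                        index=pd.RangeIndex(width, name="position"))


# ---------------------------------------------------------------- metagene

@dataclass
class MetageneProfile:
    region_bins: dict[str, np.ndarray]  # raw counts per region, n_bins each
    percentages: dict[str, np.ndarray]  # percent of total profiled sites
    smoothed: dict[str, np.ndarray]  # mass-preserving moving average
    window: int
    n_sites: int
    n_skipped: int  # sites on transcripts missing the relevant region

    def concatenated(self, which: str = "percentages") -> np.ndarray:
        d = getattr(self, which if which != "raw" else "region_bins")
        return np.concatenate([d[r] for r in REGIONS])


def _smooth_mass_preserving(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average that conserves total mass: each bin spreads
    its mass uniformly over its window clipped to the array bounds."""
    if window <= 1:
        return x.astype(float).copy()
    n = len(x)
    half = window // 2
    out = np.zeros(n)
    for b in range(n):
        lo, hi = max(0, b - half), min(n, b + half + 1)
        out[lo:hi] += x[b] / (hi - lo)
    return out


def _region_offset(model: TranscriptModel, tpos: int) -> tuple[str, int, int]:
    region = classify_region(model, tpos)
    if region == "5UTR":
        return region, tpos, model.cds_start
    if region == "CDS":
        return region, tpos - model.cds_start, model.cds_end - model.cds_start
    if region == "3UTR":
        return region, tpos - model.cds_end, len(model.sequence) - model.cds_end
    raise ValueError("metagene profiling requires mRNA sites with a CDS")


def metagene_profile(
    sites: pd.DataFrame, models: list[TranscriptModel],
    n_bins: int = 100, smooth_window: int = 3,
) -> MetageneProfile:
    """Percentile-bin site positions within 5'UTR, CDS and 3'UTR.

    Each site's offset within its region is divided by the region length and
    multiplied by ``n_bins``; the bin is floor-ed and clamped to ``n_bins-1``.
    Sites on non-coding transcripts, or falling in a zero-length region, are
    skipped and tallied in ``n_skipped``.
    """
    by_id = {m.transcript_id: m for m in models}
    bins = {r: np.zeros(n_bins, dtype=int) for r in REGIONS}
    n_used = n_skipped = 0
    for row in sites.itertuples():
        m = by_id[row.transcript_id]
        if not m.is_coding:
            n_skipped += 1
            continue
        region, off, length = _region_offset(m, row.tpos)
        if length <= 0:
            n_skipped += 1
            continue
        b = min(int(off / length * n_bins), n_bins - 1)
        bins[region][b] += 1
        n_used += 1
    pct = {
        r: (bins[r] / n_used * 100.0 if n_used else bins[r].astype(float))
        for r in REGIONS
    }
    smoothed = {r: _smooth_mass_preserving(pct[r], smooth_window) for r in REGIONS}
    return MetageneProfile(
        region_bins=bins, percentages=pct, smoothed=smoothed,
        window=smooth_window, n_sites=n_used, n_skipped=n_skipped,
    )


def background_c_profile(
    models: list[TranscriptModel], n_bins: int = 100, smooth_window: int = 3,
) -> MetageneProfile:
    """Metagene profile of EVERY cytosine on CDS-bearing transcripts — the
    background against which site enrichment is judged."""
    rows = [
        {"transcript_id": m.transcript_id, "tpos": t}
        for m in models if m.is_coding
        for t, base in enumerate(m.sequence) if base == "C"
    ]
    sites = pd.DataFrame(rows, columns=["transcript_id", "tpos"])
    return metagene_profile(sites, models, n_bins, smooth_window)


def cds_positional_histogram(
    sites: pd.DataFrame, models: list[TranscriptModel], max_offset: int = 500,
) -> np.ndarray:
    """Histogram of CDS-site distances (nt, 0-based) from the translation
    start, over [0, max_offset]; sites farther downstream are not counted."""
    by_id = {m.transcript_id: m for m in models}
    hist = np.zeros(max_offset + 1, dtype=int)
    for row in sites.itertuples():
        m = by_id[row.transcript_id]
        if not m.is_coding:
            continue
        if m.cds_start <= row.tpos < m.cds_end:
            d = row.tpos - m.cds_start
            if d <= max_offset:
                hist[d] += 1
    return hist


def metagene_to_frame(profile: MetageneProfile) -> pd.DataFrame:
    """Flatten a MetageneProfile to a tidy table (region, bin, count, pct, smoothed)."""
    rows = []
    for r in REGIONS:
        for b in range(len(profile.region_bins[r])):
            rows.append({
                "region": r, "bin": b,
                "count": int(profile.region_bins[r][b]),
                "pct": profile.percentages[r][b],
                "smoothed": profile.smoothed[r][b],
            })
    return pd.DataFrame(rows)
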