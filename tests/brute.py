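"""Naive reference implementations used as independent oracles.

Everything here is deliberately written as plain nested loops over the raw
inputs, independent of the library's data paths, so tests can compare the
optimized implementations against first-principles recounts.
"""

from __future__ import annotations

from collections import defaultdict


def brute_site_calls(reads, reference, *, max_unconverted_frac=0.30,
                     min_coverage=30, min_level=0.10, min_depth=5):
    """First-principles site calling from placed reads.

    ``reads`` is a list of (transcript_id, tpos, read_seq) with known true
    placements. Returns {(tid, tpos): (i, j, level)} for credible sites.
    """
    # read filter: fraction of reference Cs in the window still read as C
    kept = []
    for tid, tpos, seq in reads:
        ref = reference[tid]
        c_idx = [k for k in range(len(seq)) if ref[tpos + k] == "C"]
        unconv = sum(1 for k in c_idx if seq[k] == "C")
        if not c_idx or unconv / len(c_idx) <= max_unconverted_frac:
            kept.append((tid, tpos, seq))

    counts = defaultdict(lambda: [0, 0])  # (tid, pos) -> [i, j]
    for tid, tpos, seq in kept:
        ref = reference[tid]
        for k, base in enumerate(seq):
            if ref[tpos + k] == "C":
                if base == "C":
                    counts[(tid, tpos + k)][0] += 1
                elif base == "T":
                    counts[(tid, tpos + k)][1] += 1

    sites = {}
    for key, (i, j) in counts.items():
        if i + j >= min_coverage and i >= min_depth and i / (i + j) >= min_level:
            sites[key] = (i, j, i / (i + j))
    return sites


def brute_specific(tables):
    """{sample: keys present in that sample and no other}; tables maps
    sample -> iterable of keys."""
    keysets = {name: set(keys) for name, keys in tables.items()}
    out = {}
    for name in keysets:
        exclusive = set()
        for key in keysets[name]:
            if all(key not in keysets[o] for o in keysets if o != name):
                exclusive.add(key)
        out[name] = exclusive
    return out


def brute_dynamic(levels_a, levels_b, delta=0.05):
    """{key: class} over common keys, strict thresholds."""
    out = {}
    for key in levels_a:
        if key not in levels_b:
            continue
        d = levels_b[key] - levels_a[key]
        out[key] = "increased" if d > delta else "decreased" if d < -delta else "stable"
    return out


def brute_kd_regulated(control_levels, kd_levels, delta=0.05):
    return {
        key for key, lv in control_levels.items()
        if lv - kd_levels.get(key, 0.0) > delta
    }


def brute_peak_hits(sites, peaks):
    """All-pairs interval scan. sites: [(chrom, pos1based, strand)],
    peaks: [(chrom, start, end)]. Returns indices of kept sites."""
    kept = []
    for idx, (chrom, pos, _strand) in enumerate(sites):
        for pchrom, start, end in peaks:
            if chrom == pchrom and start <= pos - 1 < end:
                kept.append(idx)
                break
    return kept


def brute_gene_counts(read_blocks, gene_models):
    """Union-mode counting oracle. read_blocks: list of (chrom, [(s,e),...])
    per read; gene_models: {gene: (chrom, [(s,e),...])}."""
    counts = {g: 0 for g in gene_models}
    for chrom, blocks in read_blocks:
        hits = set()
        for g, (gchrom, ivals) in gene_models.items():
            if gchrom != chrom:
                continue
            for bs, be in blocks:
                if any(bs < e and s < be for s, e in ivals):
                    hits.add(g)
                    break
        if len(hits) == 1:
            counts[hits.pop()] += 1
    return counts


def brute_context(seq, pos):
    """CG/CHG/CHH/NA from a sequence string and a C position."""
    down = seq[pos + 1:pos + 3]
    if len(down) >= 1 and down[0] == "G":
        return "CG"
    if len(down) < 2:
        return "NA"
    return "CHG" if down[1] == "G" else "CHH"
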