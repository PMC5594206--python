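"""Read filtering, pileups, conversion QC, credibility gates, replicates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from m5c import (
    AlignmentRecord,
    CallerConfig,
    ConversionQCError,
    SitePileup,
    build_pileup,
    call_sites,
    conversion_qc,
    filter_reads,
    intersect_replicates,
)
from m5c.simulate import SPIKEIN_ID
from conftest import make_model, make_site_table
import brute


def _read(read_id, tid, tpos, ref, read_seq):
    ref_c = [tpos + k for k, b in enumerate(ref[tpos:tpos + len(read_seq)])
             if b == "C"]
    bases = "".join(read_seq[p - tpos] for p in ref_c)
    return AlignmentRecord(
        read_id=read_id, transcript_id=tid, tpos=tpos, length=len(read_seq),
        ref_c_positions=ref_c, read_bases=bases, n_mismatch_non_c=0)


# ----------------------------------------------------------------- filtering

@pytest.mark.parametrize(
    "n_c,n_unconverted,kept",
    [
        (10, 4, False),  # 0.40 > 0.30 -> removed
        (10, 3, True),   # 0.30 is not > 0.30 -> kept (strict inequality)
        (0, 0, True),    # no reference Cs: 0/0 treated as 0
        (3, 3, False),
        (3, 0, True),
    ],
)
def test_unconverted_read_filter_boundary(n_c, n_unconverted, kept):
    ref = "C" * n_c + "A" * (20 - n_c)
    read = "C" * n_unconverted + "T" * (n_c - n_unconverted) + "A" * (20 - n_c)
    rec = _read("r", "t", 0, ref, read)
    kept_reads, n_removed = filter_reads([rec], CallerConfig())
    assert (len(kept_reads) == 1) is kept
    assert n_removed == (0 if kept else 1)


# -------------------------------------------------------------------- pileup

def test_pileup_counts_methylated_and_converted():
    ref = "ACTTTTTTTT"
    reads = [_read(f"c{k}", "t", 0, ref, "ACTTTTTTTT") for k in range(3)]
    reads += [_read(f"t{k}", "t", 0, ref, "ATTTTTTTTT") for k in range(7)]
    pileups = build_pileup(reads, {"t": ref})
    assert len(pileups) == 1
    p = pileups[0]
    assert (p.transcript_id, p.tpos, p.i, p.j, p.other) == ("t", 1, 3, 7, 0)
    assert p.level == pytest.approx(0.3)


def test_pileup_sequencing_errors_counted_as_other():
    ref = "ACAAAA"
    reads = [_read(f"g{k}", "t", 0, ref, "AGAAAA") for k in range(4)]
    p = build_pileup(reads, {"t": ref})[0]
    assert (p.i, p.j, p.other) == (0, 0, 4)


def test_pileup_conserves_observations(pipeline):
    pileups = pipeline["pileups"]
    total = sum(p.i + p.j + p.other for p in pileups)
    assert total == sum(len(r.ref_c_positions) for r in pipeline["kept"])


def test_pileup_rejects_out_of_bounds_alignment():
    rec = AlignmentRecord("r", "t", 5, 10, [], "", 0)
    with pytest.raises(ValueError, match="beyond"):
        build_pileup([rec], {"t": "ACGT"})


# ------------------------------------------------------------- conversion QC

def test_conversion_qc_rate_and_gate():
    cfg = CallerConfig()
    pile = [SitePileup(SPIKEIN_ID, 0, 30, 9970, 0)]
    rep = conversion_qc(pile, cfg)
    assert rep.rate == pytest.approx(0.9970)
    assert rep.passed
    pile = [SitePileup(SPIKEIN_ID, 0, 50, 9950, 0)]
    rep = conversion_qc(pile, cfg)
    assert rep.rate == pytest.approx(0.9950)
    assert not rep.passed
    with pytest.raises(ValueError, match="spike-in"):
        conversion_qc([SitePileup("tx0", 0, 1, 1, 0)], cfg)


def test_conversion_qc_from_simulation(pipeline):
    # depth 50x at p_convert 0.999: the measured global rate is tight
    rep = pipeline["report"]
    assert abs(rep.rate - 0.999) < 0.002
    assert rep.passed


def test_failed_qc_blocks_calling_unless_forced():
    cfg = CallerConfig()
    bad = conversion_qc([SitePileup(SPIKEIN_ID, 0, 60, 9940, 0)], cfg)
    model = make_model("C" * 60, transcript_id="t")
    pile = [SitePileup("t", 10, 10, 20, 0)]
    with pytest.raises(ConversionQCError):
        call_sites(pile, cfg, [model], bad)
    called = call_sites(pile, cfg, [model], bad, force=True)
    assert len(called) == 1


# --------------------------------------------------------------------- gates

@pytest.mark.parametrize(
    "i,j,called",
    [
        (5, 25, True),    # coverage 30, level 1/6, depth 5: all gates met
        (4, 26, False),   # methylated depth 4 < 5
        (10, 15, False),  # coverage 25 < 30
        (3, 27, False),   # level 0.1 but depth 3 < 5
        (2, 28, False),   # level 1/15 < 0.1
        (6, 54, True),    # level exactly 0.1 with depth and coverage met
    ],
)
def test_credibility_gates(i, j, called):
    model = make_model("C" * 60, transcript_id="t", cds=(10, 40))
    sites = call_sites([SitePileup("t", 20, i, j, 0)], CallerConfig(), [model])
    assert (len(sites) == 1) is called
    if called:
        assert sites.loc[0, "level"] == pytest.approx(i / (i + j))
        assert sites.loc[0, "coverage"] == i + j


def test_other_observations_excluded_from_level():
    model = make_model("C" * 60, transcript_id="t")
    sites = call_sites([SitePileup("t", 20, 5, 25, 40)], CallerConfig(), [model])
    assert sites.loc[0, "coverage"] == 30
    assert sites.loc[0, "level"] == pytest.approx(5 / 30)


def test_spikein_never_called():
    spike = make_model("C" * 60, transcript_id=SPIKEIN_ID, spikein=True)
    sites = call_sites([SitePileup(SPIKEIN_ID, 5, 30, 30, 0)],
                       CallerConfig(), [spike])
    assert sites.empty


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    pileups=st.lists(
        st.tuples(st.integers(0, 25), st.integers(0, 60), st.integers(0, 80)),
        min_size=1, max_size=30),
    bump=st.sampled_from(["min_coverage", "min_level", "min_methylated_depth"]),
    amount=st.floats(0.01, 0.5),
)
def test_raising_any_threshold_is_monotone(pileups, bump, amount):
    model = make_model("C" * 100, transcript_id="t")
    rows = [SitePileup("t", tpos, i, j, 0)
            for tpos, (i, j, _) in enumerate(pileups)]
    base = CallerConfig()
    raised = CallerConfig()
    if bump == "min_level":
        raised.min_level = base.min_level + amount
    else:
        setattr(raised, bump, getattr(base, bump) + max(1, int(amount * 20)))
    n_base = len(call_sites(rows, base, [model]))
    n_raised = len(call_sites(rows, raised, [model]))
    assert n_raised <= n_base


# ---------------------------------------------------------------- replicates

def test_replicate_intersection_is_set_intersection():
    a = make_site_table([
        {"pos": 10, "level": 0.20}, {"pos": 20, "level": 0.40},
        {"pos": 30, "level": 0.60}])
    b = make_site_table([
        {"pos": 20, "level": 0.30}, {"pos": 30, "level": 0.50},
        {"pos": 40, "level": 0.70}])
    merged = intersect_replicates(a, b)
    assert sorted(merged["pos"]) == [20, 30]
    row = merged.set_index("pos").loc[20]
    assert row["level"] == pytest.approx(0.35)  # mean of 0.40 and 0.30
    assert (row["level_rep1"], row["level_rep2"]) == (0.40, 0.30)


def test_replicate_intersection_idempotent():
    t = make_site_table([{"pos": 10, "level": 0.2}, {"pos": 20, "level": 0.5}])
    merged = intersect_replicates(t, t)
    assert list(merged["pos"]) == list(t["pos"])
    assert np.allclose(merged["level"], t["level"])
    assert list(merged["coverage"]) == list(t["coverage"])


def test_replicate_pooled_merge():
    a = make_site_table([{"pos": 10, "coverage": 40, "methylated_depth": 10,
                          "level": 0.25}])
    b = make_site_table([{"pos": 10, "coverage": 60, "methylated_depth": 30,
                          "level": 0.50}])
    merged = intersect_replicates(a, b, merge_levels="pooled")
    assert merged.loc[0, "level"] == pytest.approx(40 / 100)


# ------------------------------------------------- brute-force oracle checks

def test_caller_matches_bruteforce_on_random_instances(rng):
    """Full filter->pileup->call path vs a first-principles recount."""
    for _ in range(20):
        ref = "".join(rng.choice(list("ACGT"), size=120))
        reads = []
        for k in range(int(rng.integers(5, 50))):
            tpos = int(rng.integers(0, 60))
            ln = int(rng.integers(30, 60))
            window = ref[tpos:tpos + ln]
            # random conversion state per C
            seq = "".join(
                ("C" if rng.random() < 0.4 else "T") if b == "C" else b
                for b in window)
            reads.append(("t", tpos, seq))
        cfg = CallerConfig(min_coverage=5, min_methylated_depth=2)
        records = [_read(f"r{k}", t, p, ref, s)
                   for k, (t, p, s) in enumerate(reads)]
        kept, _ = filter_reads(records, cfg)
        pile = build_pileup(kept, {"t": ref})
        model = make_model(ref, transcript_id="t")
        called = call_sites(pile, cfg, [model])
        expected = brute.brute_site_calls(
            reads, {"t": ref}, min_coverage=5, min_depth=2)
        got = {("t", row.tpos): (row.methylated_depth,
                                 row.coverage - row.methylated_depth,
                                 row.level)
               for row in called.itertuples()}
        assert set(got) == set(expected)
        for key in got:
            assert got[key][:2] == expected[key][:2]
            assert got[key][2] == pytest.approx(expected[key][2])
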