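"""Reader-bound (RIP-target) site identification.

m5C sites are intersected with externally called RIP peaks (BED intervals,
0-based half-open); a site at 1-based position ``pos`` falls in a peak iff
``start <= pos - 1 < end``. Level distributions of bound vs input site sets
are compared with a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd
from scipy import stats


@dataclass
class PeakSet:
    """Sorted, queryable peak intervals grouped by chromosome (and strand
    when the BED carries one)."""
    intervals: pd.DataFrame  # chrom, start, end, name, score, strand
    stranded: bool = False

    def __post_init__(self):
        df = self.intervals
        if (df["start"] >= df["end"]).any():
            raise ValueError("peak with start >= end")
        if not df.sort_values(["chrom", "start", "end"]).reset_index(drop=True).equals(
                df.reset_index(drop=True)):
            # unsorted input is tolerated: sort internally
            self.intervals = df.sort_values(
                ["chrom", "start", "end"], ignore_index=True)
        self.stranded = bool((self.intervals["strand"].isin(["+", "-"])).all()) \
            if "strand" in self.intervals else False
        self._by_chrom: dict[str, tuple[list[int], list[int], list[str]]] = {}
        grouped = defaultdict(lambda: ([], [], []))
        for row in self.intervals.itertuples():
            starts, ends, strands = grouped[row.chrom]
            starts.append(row.start)
            ends.append(row.end)
            strands.append(getattr(row, "strand", "."))
        self._by_chrom = dict(grouped)

    def contains(self, chrom: str, pos: int, strand: str | None = None) -> bool:
        """Membership of a 1-based position; strand honored only for stranded peaks."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, ends, strands = entry
        g0 = pos - 1
        # peaks may nest; scan all with start <= g0
        hi = bisect_right(starts, g0)
        for k in range(hi):
            if g0 < ends[k]:
                if self.stranded and strand is not None and strands[k] != strand:
                    continue
                return True
        return False


def intersect_sites_with_peaks(sites: pd.DataFrame, peaks: PeakSet) -> pd.DataFrame:
    """Keep sites whose position falls inside at least one peak."""
    mask = [
        peaks.contains(row.chrom, row.pos, row.strand)
        for row in sites.itertuples()
    ]
    return sites.loc[mask].reset_index(drop=True)


def compare_level_distributions(
    bound: pd.DataFrame, input_table: pd.DataFrame,
) -> tuple[float, float, float, float]:
    """(median_bound, median_input, U, p) from a two-sided Mann-Whitney U test
    on the two level vectors."""
    x = bound["level"].to_numpy()
    y = input_table["level"].to_numpy()
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 sites in each group")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return (float(pd.Series(x).median()), float(pd.Series(y).median()),
            float(res.statistic), float(res.pvalue))
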