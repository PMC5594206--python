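"""Cross-sample m5C site classification and level clustering.

Site tables are compared by genomic key (chrom, pos, strand). Classifications
implemented: sample-specific sites (present in exactly one sample),
stringent-specific sites (same, restricted to genes expressed in every
sample), dynamic sites between two conditions (|delta level| > 0.05, strict),
writer-knockdown-regulated sites (control minus knockdown level > 0.05), and
average-linkage hierarchical clustering of pairwise Pearson correlations of
levels across samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

SiteKey = tuple[str, int, str]

DELTA_THRESHOLD = 0.05


def site_keys(table: pd.DataFrame) -> set[SiteKey]:
    return set(zip(table["chrom"], table["pos"], table["strand"]))


def _level_map(table: pd.DataFrame) -> dict[SiteKey, float]:
    return dict(zip(zip(table["chrom"], table["pos"], table["strand"]),
                    table["level"]))


# ------------------------------------------------------------ specificity

def find_specific_sites(tables: dict[str, pd.DataFrame]) -> dict[str, set[SiteKey]]:
    """Sites present in exactly one sample, per sample."""
    if len(tables) < 2:
        raise ValueError("need at least two samples")
    keysets = {name: site_keys(t) for name, t in tables.items()}
    specific: dict[str, set[SiteKey]] = {name: set() for name in tables}
    for name, keys in keysets.items():
        others = set().union(*(k for n, k in keysets.items() if n != name))
        specific[name] = keys - others
    return specific


def find_stringent_specific(
    tables: dict[str, pd.DataFrame],
    expression: dict[str, pd.DataFrame],
) -> dict[str, set[SiteKey]]:
    """Specific sites restricted to genes expressed (RPKM >= 1) in ALL samples."""
    missing = set(tables) - set(expression)
    if missing:
        raise ValueError(f"missing expression tables for: {sorted(missing)}")
    common_genes: set[str] | None = None
    for name in tables:
        e = expression[name]
        genes = set(e.loc[e["expressed"], "gene_id"])
        common_genes = genes if common_genes is None else common_genes & genes
    restricted = {
        name: t[t["gene_id"].isin(common_genes)] for name, t in tables.items()
    }
    return find_specific_sites(restricted)


# --------------------------------------------------------------- dynamics

@dataclass
class DeltaClassification:
    key: SiteKey
    level_a: float
    level_b: float
    delta: float
    klass: str  # increased | decreased | stable


def classify_dynamic(
    table_a: pd.DataFrame, table_b: pd.DataFrame,
    delta: float = DELTA_THRESHOLD,
) -> list[DeltaClassification]:
    """Classify common sites by level change b - a; strict |delta| > threshold."""
    la, lb = _level_map(table_a), _level_map(table_b)
    out = []
    for key in sorted(set(la) & set(lb)):
        d = lb[key] - la[key]
        if d > delta:
            klass = "increased"
        elif d < -delta:
            klass = "decreased"
        else:
            klass = "stable"
        out.append(DeltaClassification(key, la[key], lb[key], d, klass))
    return out


def knockdown_regulated(
    control: pd.DataFrame,
    kd_levels: pd.DataFrame | dict[SiteKey, float],
    delta: float = DELTA_THRESHOLD,
    kd_coverage: dict[SiteKey, int] | None = None,
    min_coverage: int = 30,
) -> set[SiteKey]:
    """Writer-dependent sites: control level minus knockdown level > delta.

    A site absent from the knockdown table is treated as level 0 — unless
    ``kd_coverage`` is supplied and shows coverage below ``min_coverage``
    there, in which case the site is not assessable and excluded.
    """
    kd = _level_map(kd_levels) if isinstance(kd_levels, pd.DataFrame) else dict(kd_levels)
    regulated = set()
    for key, level in _level_map(control).items():
        if key in kd:
            kd_level = kd[key]
        else:
            if kd_coverage is not None and kd_coverage.get(key, 0) < min_coverage:
                continue
            kd_level = 0.0
        if level - kd_level > delta:
            regulated.add(key)
    return regulated


# ------------------------------------------------------------- clustering

@dataclass
class ClusteringResult:
    correlation: pd.DataFrame  # samples x samples Pearson r
    linkage: np.ndarray  # scipy linkage matrix (average, 1 - r)
    order: list[str]  # dendrogram leaf order
    newick: str


def build_level_matrix(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Site-by-sample matrix of levels; NaN where a site is absent."""
    series = {
        name: pd.Series(_level_map(t)).rename(name)
        for name, t in tables.items()
    }
    mat = pd.DataFrame(series)
    mat.index.set_names(["chrom", "pos", "strand"], inplace=True)
    return mat.sort_index()


def correlation_clustering(matrix: pd.DataFrame, min_common: int = 3) -> ClusteringResult:
    """Pairwise-complete Pearson correlation + average-linkage clustering.

    Distance is 1 - r. A sample with constant levels over a pairwise-complete
    set has no defined correlation and raises, naming the sample.
    """
    samples = list(matrix.columns)
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    n = len(samples)
    corr = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            sub = matrix.iloc[:, [a, b]].dropna()
            if len(sub) < min_common:
                raise ValueError(
                    f"fewer than {min_common} common sites between "
                    f"{samples[a]} and {samples[b]}")
            x, y = sub.iloc[:, 0].to_numpy(), sub.iloc[:, 1].to_numpy()
            for v, name in ((x, samples[a]), (y, samples[b])):
                if np.ptp(v) == 0:
                    raise ValueError(f"constant levels for sample {name}")
            r = float(np.corrcoef(x, y)[0, 1])
            corr[a, b] = corr[b, a] = r
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [samples[i] for i in hierarchy.leaves_list(link)]
    newick = _to_newick(hierarchy.to_tree(link), samples)
    return ClusteringResult(
        correlation=pd.DataFrame(corr, index=samples, columns=samples),
        linkage=link, order=order, newick=newick,
    )


def _to_newick(node, labels: list[str]) -> str:
    def rec(nd, parent_dist):
        blen = max(parent_dist - nd.dist, 0.0)
        if nd.is_leaf():
            return f"{labels[nd.id]}:{blen:.6g}"
        left = rec(nd.left, nd.dist)
        right = rec(nd.right, nd.dist)
        return f"({left},{right}):{blen:.6g}"

    return rec(node, node.dist) + ";"
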