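"""Genomic and epigenomic characterization of region sets.

Per-region size, GC fraction, and coverage by feature tracks (origins,
genes, large genes, histone-mark intervals); a region-class x mark-track
mean-coverage matrix normalized per column to [0, 1] and ordered by
average-linkage clustering on correlation distance; and nonparametric
group comparisons (Kruskal-Wallis omnibus with Dunn's pairwise post-hoc
under a Holm or Bonferroni family-wise adjustment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .intervals import RegionSet, coverage_fraction

__all__ = [
    "region_gc",
    "region_stats_table",
    "large_gene_coverage",
    "CoverageMatrix",
    "mark_coverage_matrix",
    "GroupComparison",
    "compare_region_groups",
    "linkage_to_newick",
]


def region_gc(rs: RegionSet, genome_fasta: Mapping[str, object]) -> np.ndarray:
    """GC fraction per region: (G+C)/(A+C+G+T); N bases leave the denominator.

    ``genome_fasta`` is anything mapping chromosome name to a sliceable
    sequence (a pyfaidx.Fasta or a plain dict of strings). A region whose
    chromosome is missing or that runs past the sequence end is rejected.
    """
    out = np.empty(len(rs), dtype=float)
    for k, iv in enumerate(rs):
        if iv.chrom not in genome_fasta:
            raise ValueError(f"no sequence for chromosome {iv.chrom}")
        seq = str(genome_fasta[iv.chrom][iv.start : iv.end]).upper()
        if len(seq) < iv.length:
            raise ValueError(
                f"region {iv.chrom}:{iv.start}-{iv.end} extends beyond the sequence"
            )
        gc = seq.count("G") + seq.count("C")
        denom = gc + seq.count("A") + seq.count("T")
        out[k] = gc / denom if denom else np.nan
    return out


def region_stats_table(
    rs: RegionSet,
    genome_fasta: Mapping[str, object] | None = None,
    feature_tracks: Mapping[str, RegionSet] | None = None,
) -> pd.DataFrame:
    """Per-region table: coordinates, size, GC, and feature coverages."""
    df = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in rs],
            "start": [iv.start for iv in rs],
            "end": [iv.end for iv in rs],
            "size": [iv.length for iv in rs],
        }
    )
    if genome_fasta is not None:
        df["gc"] = region_gc(rs, genome_fasta)
    for name, track in (feature_tracks or {}).items():
        df[f"cov_{name}"] = coverage_fraction(rs, track)
    return df


def large_gene_coverage(rs: RegionSet, genes: RegionSet, min_len: int = 400_000) -> np.ndarray:
    """Per-region coverage by genes strictly longer than ``min_len`` bp.

    Large genes (>400 kb) are the classic companions of fragile sites;
    the strict inequality means a gene of exactly 400 kb is excluded.
    """
    big = RegionSet([iv for iv in genes if iv.length > min_len], label="large_genes")
    if len(big) == 0:
        return np.zeros(len(rs))
    return coverage_fraction(rs, big)


# ---------------------------------------------------------------------------
# coverage matrix


@dataclass
class CoverageMatrix:
    """Region-class x mark mean-coverage matrix, column-normalized to [0, 1].

    ``raw`` holds the un-normalized means. Row/column orders come from
    average-linkage clustering on (1 - Pearson correlation); a constant
    column normalizes to all zeros.
    """

    matrix: pd.DataFrame  # normalized, original row/col labels
    raw: pd.DataFrame
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None

    def ordered(self) -> pd.DataFrame:
        return self.matrix.loc[self.row_order, self.col_order]


def _corr_linkage(mat: np.ndarray) -> np.ndarray | None:
    """Average-linkage on 1 - Pearson rows; constant rows get distance 1."""
    if mat.shape[0] < 2:
        return None
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, None)
    return hierarchy.linkage(squareform(dist, checks=False), method="average")


def mark_coverage_matrix(
    groups: Mapping[str, RegionSet], marks: Mapping[str, RegionSet]
) -> CoverageMatrix:
    """Mean mark coverage per region class, normalized and clustered.

    Each cell is the unweighted mean over the class's regions of the
    fraction of the region covered by the mark (every region counts
    equally, not bp-weighted). Columns are min-max normalized so each
    mark spans [0, 1] across classes.
    """
    if len(groups) < 2 or len(marks) < 2:
        raise ValueError("need at least two groups and two marks")
    raw = pd.DataFrame(
        {
            mname: {g: float(np.mean(coverage_fraction(rs, mk))) for g, rs in groups.items()}
            for mname, mk in marks.items()
        }
    )
    norm = raw.copy()
    for col in norm.columns:
        lo, hi = norm[col].min(), norm[col].max()
        norm[col] = 0.0 if hi <= lo else (norm[col] - lo) / (hi - lo)
    row_link = _corr_linkage(norm.to_numpy())
    col_link = _corr_linkage(norm.to_numpy().T)
    row_order = (
        [norm.index[i] for i in hierarchy.leaves_list(row_link)] if row_link is not None else list(norm.index)
    )
    col_order = (
        [norm.columns[i] for i in hierarchy.leaves_list(col_link)] if col_link is not None else list(norm.columns)
    )
    return CoverageMatrix(norm, raw, row_order, col_order, row_link, col_link)


def linkage_to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(link)

    def rec(node) -> tuple[str, float]:
        if node.is_leaf():
            return labels[node.id], 0.0
        left, lh = rec(node.left)
        right, rh = rec(node.right)
        h = node.dist
        return f"({left}:{h - lh:.6g},{right}:{h - rh:.6g})", h

    text, _ = rec(tree)
    return text + ";"


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class GroupComparison:
    omnibus_statistic: float
    omnibus_p: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p_raw, p_adjusted


def _dunn_pairwise(values_by_group: Mapping[str, np.ndarray], adjust: str) -> pd.DataFrame:
    """Dunn's rank-based pairwise z tests with tie correction."""
    from statsmodels.stats.multitest import multipletests

    names = list(values_by_group)
    pooled = np.concatenate([np.asarray(values_by_group[g], dtype=float) for g in names])
    sizes = {g: len(values_by_group[g]) for g in names}
    ranks = stats.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    i = 0
    for g in names:
        mean_rank[g] = float(ranks[i : i + sizes[g]].mean())
        i += sizes[g]
    n = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n - 1))) if n > 1 else 0.0
    rows = []
    for a_i in range(len(names)):
        for b_i in range(a_i + 1, len(names)):
            a, b = names[a_i], names[b_i]
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = multipletests(df["p_raw"], method=adjust)[1]
    else:
        df["p_adjusted"] = []
    return df


def compare_region_groups(
    values_by_group: Mapping[str, Sequence[float]], adjust: str = "holm"
) -> GroupComparison:
    """Kruskal-Wallis omnibus plus Dunn's pairwise post-hoc tests.

    ``adjust`` is the family-wise correction applied to the pairwise
    p-values ("holm" default, "bonferroni" available). When every pooled
    value is tied the omnibus has no information: p = 1.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >=2 groups with >=2 values each")
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(*groups.values())
    pairwise = _dunn_pairwise(groups, adjust)
    return GroupComparison(float(stat), float(p), pairwise)
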