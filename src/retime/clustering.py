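"""Hierarchical clustering of cohorts by genome-wide RT similarity.

Cohorts (cell line x condition) are represented by their replicate-mean
smoothed RT values on the probe grid common to all cohorts. The pairwise
distance is 1 - Pearson correlation and agglomeration uses average
linkage, so the tree is invariant to positive rescaling of any column
and average linkage guarantees monotone merge heights. Edge support is
an ordinary probe-resampling bootstrap (fraction of resampled trees
containing the same leaf bipartition), labelled as such — it is not a
multiscale/AU p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .characterize import linkage_to_newick
from .differential import RTProfile, smooth_profile

__all__ = ["RTMatrix", "ClusterResult", "build_rt_matrix", "cluster_cohorts"]


@dataclass
class RTMatrix:
    """Probes x cohorts matrix of replicate-mean smoothed RT values."""

    values: pd.DataFrame  # index: "chrom:start", columns: cohort labels

    @property
    def n_cohorts(self) -> int:
        return self.values.shape[1]


def build_rt_matrix(
    profiles_by_cohort: dict[str, list[RTProfile]], span_bp: int = 500_000
) -> RTMatrix:
    """Replicate-mean smoothed values restricted to the shared probe set.

    Each cohort needs at least one replicate; probes are keyed by
    (chrom, start) and only probes present in every cohort are kept.
    """
    cols: dict[str, pd.Series] = {}
    for label, profiles in profiles_by_cohort.items():
        if not profiles:
            raise ValueError(f"cohort {label} has no profiles")
        sm = np.mean([smooth_profile(p, span_bp).values for p in profiles], axis=0)
        grid = profiles[0].grid
        keys = [f"{c}:{s}" for c, s in zip(grid.chroms, grid.starts)]
        cols[label] = pd.Series(sm, index=keys)
    df = pd.DataFrame(cols)
    df = df.dropna(axis=0, how="any")
    if df.empty:
        raise ValueError("probe grids share no common probes")
    return RTMatrix(df)


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: list[str]
    newick: str
    support: dict[frozenset, float] | None  # clade (leaf label set) -> bootstrap fraction

    def cut(self, k: int) -> dict[str, int]:
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, assign.tolist()))


def _clades(link: np.ndarray, labels: list[str]) -> set[frozenset]:
    """Leaf-label sets of every internal node (excluding root and leaves)."""
    n = len(labels)
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    out: set[frozenset] = set()
    for k, (a, b, _, _) in enumerate(link):
        merged = members[int(a)] | members[int(b)]
        members[n + k] = merged
        if len(merged) < n:
            out.add(merged)
    return out


def _corr_linkage(mat: np.ndarray, labels: list[str]) -> np.ndarray:
    sd = mat.std(axis=0)
    tiny = sd <= 1e-12 * np.maximum(np.abs(mat).max(axis=0), 1.0)
    if np.any(tiny):
        bad = labels[int(np.argmax(tiny))]
        raise ValueError(f"cohort {bad} has a constant profile; correlation undefined")
    corr = np.corrcoef(mat.T)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    return hierarchy.linkage(squareform(dist, checks=False), method="average")


def cluster_cohorts(
    m: RTMatrix, n_bootstrap: int = 100, seed: int = 0
) -> ClusterResult:
    """Correlation-distance, average-linkage dendrogram with edge support.

    Support of an internal edge is the fraction of ``n_bootstrap``
    probe-resampling replicates whose tree contains the same clade (as a
    leaf set). Pass ``n_bootstrap=0`` to skip the bootstrap.
    """
    labels = list(m.values.columns)
    if len(labels) < 2:
        raise ValueError("need at least two cohorts")
    mat = m.values.to_numpy()
    link = _corr_linkage(mat, labels)
    support: dict[frozenset, float] | None = None
    if n_bootstrap > 0 and len(labels) >= 3:
        ref = _clades(link, labels)
        counts = {cl: 0 for cl in ref}
        rng = np.random.default_rng(seed)
        n_probes = mat.shape[0]
        done = 0
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n_probes, size=n_probes)
            sub = mat[idx]
            try:
                blink = _corr_linkage(sub, labels)
            except ValueError:
                continue
            bcl = _clades(blink, labels)
            for cl in ref:
                if cl in bcl:
                    counts[cl] += 1
            done += 1
        support = {cl: (counts[cl] / done if done else float("nan")) for cl in ref}
    return ClusterResult(link, labels, linkage_to_newick(link, labels), support)
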