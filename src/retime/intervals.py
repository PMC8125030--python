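"""Genome model and interval algebra.

All coordinates are 0-based half-open (BED native) everywhere in the
package; 1-based dialects must be converted at the I/O boundary. Strand is
ignored: every region set handled here (timing domains, differential RT
regions, fragile sites, origins, peaks) is unstranded.

The operations in this module (merge, intersect, per-region coverage,
bp-level Jaccard) sit in the hot loop of the randomization statistic, so
they are implemented on sorted numpy arrays; each is checked against a
per-base bitmap oracle in the test suite.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "Interval",
    "RegionSet",
    "GenomeAssembly",
    "normalize_chrom",
    "merge_intervals",
    "intersect",
    "coverage_fraction",
    "jaccard",
]

_CHR_RE = re.compile(r"^chr", flags=re.IGNORECASE)


def normalize_chrom(name: str, strip_prefix: bool = True) -> str:
    """Normalize a chromosome name (default: strip a leading ``chr``).

    Input files in this field mix ``chr1``/``1`` dialects; a single
    normalization applied at every boundary keeps name matching exact.
    """
    name = name.strip()
    return _CHR_RE.sub("", name) if strip_prefix else name


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open, with optional name/score."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


class RegionSet:
    """An unstranded set of intervals with a label.

    The set is not merged on construction; :func:`merge_intervals` returns
    a sorted, disjoint equivalent. ``by_chrom()`` exposes the intervals as
    per-chromosome ``(n, 2)`` arrays sorted by start, which is the working
    representation for all bp arithmetic.
    """

    def __init__(self, intervals: Iterable[Interval], label: str = "") -> None:
        self.intervals: list[Interval] = list(intervals)
        self.label = label
        self._by_chrom: dict[str, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __repr__(self) -> str:  # pragma: no cover
        return f"RegionSet({self.label!r}, n={len(self)}, bp={self.total_bp})"

    def by_chrom(self) -> dict[str, np.ndarray]:
        if self._by_chrom is None:
            acc: dict[str, list[tuple[int, int]]] = {}
            for iv in self.intervals:
                acc.setdefault(iv.chrom, []).append((iv.start, iv.end))
            self._by_chrom = {
                c: np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
                for c, pairs in acc.items()
            }
        return self._by_chrom

    @property
    def total_bp(self) -> int:
        """Total covered bp (overlaps counted once)."""
        merged = _merge_by_chrom(self.by_chrom())
        return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in merged.values()))

    @classmethod
    def from_arrays(
        cls, by_chrom: Mapping[str, np.ndarray], label: str = ""
    ) -> "RegionSet":
        ivs = [
            Interval(c, int(s), int(e))
            for c, arr in by_chrom.items()
            for s, e in arr
        ]
        return cls(ivs, label=label)


@dataclass
class GenomeAssembly:
    """Chromosome names/lengths plus the mappable mask.

    The mappable set is where randomized interval placement is allowed
    (assembly gaps and blacklisted regions excluded); it is stored merged.
    """

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    mappable: RegionSet = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mappable is None:
            self.mappable = RegionSet(
                [Interval(c, 0, self.chrom_lengths[c]) for c in self.chrom_names],
                label="mappable",
            )
        self.mappable = merge_intervals(self.mappable)
        for iv in self.mappable:
            if iv.chrom not in self.chrom_lengths:
                raise ValueError(f"mappable interval on unknown chromosome {iv.chrom}")
            if iv.end > self.chrom_lengths[iv.chrom]:
                raise ValueError(
                    f"mappable interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {self.chrom_lengths[iv.chrom]}"
                )

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_lengths[c] for c in self.chrom_names)

    def validate_regions(self, rs: RegionSet) -> None:
        """Check every interval fits its chromosome (shared-assembly guard)."""
        for iv in rs:
            L = self.chrom_lengths.get(iv.chrom)
            if L is None:
                raise ValueError(f"{rs.label or 'region set'}: unknown chromosome {iv.chrom}")
            if iv.end > L:
                raise ValueError(
                    f"{rs.label or 'region set'}: {iv.chrom}:{iv.start}-{iv.end} "
                    f"exceeds chromosome length {L}"
                )


# ---------------------------------------------------------------------------
# array-level primitives


def _merge_arr(arr: np.ndarray) -> np.ndarray:
    """Merge a sorted-by-start (n,2) array; touching intervals fuse."""
    if len(arr) <= 1:
        return arr
    starts, ends = arr[:, 0], np.maximum.accumulate(arr[:, 1])
    # a new block starts where start > running max of previous ends
    new_block = np.empty(len(arr), dtype=bool)
    new_block[0] = True
    new_block[1:] = starts[1:] > ends[:-1]
    idx = np.flatnonzero(new_block)
    out = np.empty((len(idx), 2), dtype=np.int64)
    out[:, 0] = starts[idx]
    last = np.append(idx[1:] - 1, len(arr) - 1)
    out[:, 1] = ends[last]
    return out


def _merge_by_chrom(by_chrom: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {c: _merge_arr(arr) for c, arr in by_chrom.items() if len(arr)}


def _intersect_arrs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-base intersection of two merged (n,2) arrays (two-pointer sweep)."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def overlap_bp_arrays(
    a: Mapping[str, np.ndarray], b: Mapping[str, np.ndarray]
) -> int:
    """Intersection bp of two merged per-chrom dicts (no interval list built).

    Uses |A| + |B| - |A union B|, which costs one sort of the concatenation.
    """
    total = 0
    for c, arr_a in a.items():
        arr_b = b.get(c)
        if arr_b is None or not len(arr_a):
            continue
        bp_a = int((arr_a[:, 1] - arr_a[:, 0]).sum())
        bp_b = int((arr_b[:, 1] - arr_b[:, 0]).sum())
        both = np.concatenate([arr_a, arr_b])
        both = both[np.argsort(both[:, 0], kind="stable")]
        bp_u = int((lambda m: (m[:, 1] - m[:, 0]).sum())(_merge_arr(both)))
        total += bp_a + bp_b - bp_u
    return total


def jaccard_arrays(
    a: Mapping[str, np.ndarray], b: Mapping[str, np.ndarray]
) -> float:
    """bp-level Jaccard of two merged per-chrom dicts."""
    bp_a = int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in a.values()))
    bp_b = int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in b.values()))
    inter = overlap_bp_arrays(a, b)
    union = bp_a + bp_b - inter
    if union == 0:
        raise ValueError("Jaccard undefined: both interval sets are empty")
    return inter / union


# ---------------------------------------------------------------------------
# public operations


def merge_intervals(rs: RegionSet) -> RegionSet:
    """Sorted, disjoint equivalent of ``rs``; adjacent touching intervals fuse."""
    merged = _merge_by_chrom(rs.by_chrom())
    order = sorted(merged)
    out = RegionSet.from_arrays({c: merged[c] for c in order}, label=rs.label)
    return out


def intersect(a: RegionSet, b: RegionSet) -> RegionSet:
    """Per-base intersection as a merged RegionSet.

    Chromosomes present in only one set contribute nothing.
    """
    ma = _merge_by_chrom(a.by_chrom())
    mb = _merge_by_chrom(b.by_chrom())
    out: dict[str, np.ndarray] = {}
    for c in sorted(set(ma) & set(mb)):
        arr = _intersect_arrs(ma[c], mb[c])
        if len(arr):
            out[c] = arr
    return RegionSet.from_arrays(out, label=f"{a.label}&{b.label}")


def coverage_fraction(regions: RegionSet, features: RegionSet) -> np.ndarray:
    """Fraction of each region covered by the merged features, in [0, 1].

    Order follows ``regions.intervals``. Regions have positive length by
    invariant, so the fraction is always defined.
    """
    if len(regions) == 0:
        raise ValueError("coverage_fraction: empty region set")
    mf = _merge_by_chrom(features.by_chrom())
    fracs = np.zeros(len(regions), dtype=float)
    for k, iv in enumerate(regions):
        arr = mf.get(iv.chrom)
        if arr is None:
            continue
        # clip features against this region
        lo = np.clip(arr[:, 0], iv.start, iv.end)
        hi = np.clip(arr[:, 1], iv.start, iv.end)
        fracs[k] = (hi - lo).sum() / iv.length
    return fracs


def jaccard(a: RegionSet, b: RegionSet) -> float:
    """bp(intersection)/bp(union) after merging each set internally.

    Raises when both sets are empty (the index is undefined, not zero).
    """
    return jaccard_arrays(_merge_by_chrom(a.by_chrom()), _merge_by_chrom(b.by_chrom()))
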