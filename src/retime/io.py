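"""Readers and writers for the plain-text formats the pipeline consumes.

BED3/BED6 (tab-separated, no header), bedGraph (chrom start end value),
two-column chrom.sizes tables, and FASTA (written directly; read through
pyfaidx). All files are interpreted as 0-based half-open. Chromosome names
are normalized (``chr`` prefix stripped) by default so hg18/hg19-style
dialects can be mixed; pass ``normalize=False`` to keep names verbatim.

Float columns are written with a fixed ``%.6g`` format so that reruns of
the pipeline produce byte-identical artifacts.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import pandas as pd

from .intervals import GenomeAssembly, Interval, RegionSet, normalize_chrom

__all__ = [
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_chrom_sizes",
    "read_genome",
    "write_chrom_sizes",
    "write_fasta",
]

_FMT = "%.6g"


def read_bed(path: str | Path, label: str | None = None, normalize: bool = True) -> RegionSet:
    """Read BED3/BED6 into a RegionSet (name/score kept when present)."""
    path = Path(path)
    ivs: list[Interval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >=3 BED columns")
            chrom = normalize_chrom(parts[0], strip_prefix=normalize)
            start, end = int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            try:
                ivs.append(Interval(chrom, start, end, name=name, score=score))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
    return RegionSet(ivs, label=label if label is not None else path.stem)


def write_bed(rs: RegionSet, path: str | Path) -> Path:
    """Write BED3 (or BED6 when any interval carries a name or score)."""
    path = Path(path)
    six = any(iv.name is not None or iv.score is not None for iv in rs)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for iv in rs:
            if six:
                score = _FMT % iv.score if iv.score is not None else "."
                w.writerow([iv.chrom, iv.start, iv.end, iv.name or ".", score, "."])
            else:
                w.writerow([iv.chrom, iv.start, iv.end])
    return path


def read_bedgraph(path: str | Path, normalize: bool = True) -> pd.DataFrame:
    """Read bedGraph into a DataFrame with columns chrom/start/end/value."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )
    if normalize:
        df["chrom"] = [normalize_chrom(c) for c in df["chrom"]]
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise ValueError(f"{path}: record {bad} has start >= end")
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for chrom, start, end, value in df[["chrom", "start", "end", "value"]].itertuples(index=False):
            w.writerow([chrom, int(start), int(end), _FMT % value])
    return path


def read_chrom_sizes(path: str | Path, normalize: bool = True) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, length = line.split()[:2]
            sizes[normalize_chrom(name, strip_prefix=normalize)] = int(length)
    return sizes


def read_genome(
    sizes_path: str | Path,
    mappable_bed: str | Path | None = None,
    normalize: bool = True,
) -> GenomeAssembly:
    """Build a GenomeAssembly from chrom.sizes plus an optional mappable BED."""
    sizes = read_chrom_sizes(sizes_path, normalize=normalize)
    mappable = read_bed(mappable_bed, normalize=normalize) if mappable_bed else None
    return GenomeAssembly(list(sizes), sizes, mappable)


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")
    return path


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    items = seqs.items() if isinstance(seqs, dict) else seqs
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width])
                fh.write("\n")
    return path
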