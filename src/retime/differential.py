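"""Differential replication-timing analysis.

The replication-timing (RT) signal is the per-probe log2 ratio of
early-S to late-S nascent-DNA abundance: higher values replicate earlier.
This module takes replicate RT profiles for two conditions and

1. quantile-normalizes all replicates jointly onto a common scale,
2. Loess-smooths each profile (tricube-weighted local linear regression),
3. segments the smoothed landscape into Early/Mid/Late constant-timing
   regions and steep temporal transition regions (TTR),
4. calls regions whose timing differs significantly between conditions
   (RT-impacted loci: ADV = advanced, replicating earlier under
   treatment; DEL = delayed), and
5. assesses whether mother-generation calls persist in a daughter
   generation released from treatment.

The differential test is a windowed mean-difference ("mean method") test:
non-overlapping windows of probes are tested with a one-sample t-test of
the smoothed treated-minus-control deltas against zero, and windows must
additionally clear an amplitude floor, which controls genome-wide false
calls in the absence of an explicit multiple-testing correction
(Benjamini-Hochberg across windows is available as an option).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Interval, RegionSet

__all__ = [
    "ProbeGrid",
    "RTProfile",
    "SmoothedRT",
    "TimingDomains",
    "ARTILRegion",
    "ARTILSet",
    "TransmissionReport",
    "CallParams",
    "profile_from_bedgraph",
    "profile_to_bedgraph",
    "normalize_replicates",
    "smooth_profile",
    "segment_domains",
    "call_differential",
    "assess_transmission",
]


class ProbeGrid:
    """A fixed probe grid: sorted, non-overlapping probes grouped by chromosome."""

    def __init__(self, chroms: np.ndarray, starts: np.ndarray, ends: np.ndarray):
        order = np.lexsort((starts, chroms))
        self.chroms = np.asarray(chroms, dtype=object)[order]
        self.starts = np.asarray(starts, dtype=np.int64)[order]
        self.ends = np.asarray(ends, dtype=np.int64)[order]
        if np.any(self.starts >= self.ends):
            raise ValueError("probe with start >= end")
        self.chrom_names: list[str] = []
        self.slices: dict[str, slice] = {}
        i = 0
        while i < len(self.chroms):
            c = self.chroms[i]
            j = i
            while j < len(self.chroms) and self.chroms[j] == c:
                j += 1
            self.chrom_names.append(c)
            self.slices[c] = slice(i, j)
            if np.any(self.starts[i + 1 : j] < self.ends[i : j - 1]):
                raise ValueError(f"overlapping probes on {c}")
            i = j
        self.midpoints = 0.5 * (self.starts + self.ends)
        self._order = order

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def covered_bp(self) -> int:
        """Total probe-covered bp, counting inter-probe gaps inside a run as
        covered (the grid is treated as tiling its span per chromosome)."""
        total = 0
        for c in self.chrom_names:
            sl = self.slices[c]
            total += int(self.ends[sl][-1] - self.starts[sl][0])
        return total

    def same_as(self, other: "ProbeGrid") -> bool:
        return (
            len(self) == len(other)
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
            and np.array_equal(self.chroms, other.chroms)
        )


@dataclass
class RTProfile:
    """One replicate of one condition/generation on a fixed probe grid."""

    grid: ProbeGrid
    values: np.ndarray
    condition: str = ""
    generation: str = "t0"
    replicate: str = "r1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.grid):
            raise ValueError("values length does not match probe grid")

    @property
    def label(self) -> str:
        return f"{self.condition}.{self.generation}.{self.replicate}"


@dataclass
class SmoothedRT:
    """A smoothed profile on the same grid, remembering the span used."""

    grid: ProbeGrid
    values: np.ndarray
    span_bp: int
    source: str = ""


@dataclass
class TimingDomains:
    """Disjoint labeled domains (Early/Mid/Late/TTR) partitioning the probe span."""

    intervals: list[Interval]

    def to_region_set(self, label_filter: str | None = None) -> RegionSet:
        ivs = [
            iv for iv in self.intervals if label_filter is None or iv.name == label_filter
        ]
        return RegionSet(ivs, label=label_filter or "domains")

    def labels(self) -> list[str]:
        return sorted({iv.name for iv in self.intervals})


def profile_from_bedgraph(df: pd.DataFrame, condition: str = "", generation: str = "t0", replicate: str = "r1") -> RTProfile:
    grid = ProbeGrid(df["chrom"].to_numpy(dtype=object), df["start"].to_numpy(), df["end"].to_numpy())
    values = df["value"].to_numpy(dtype=float)[grid._order]
    return RTProfile(grid, values, condition, generation, replicate)


def profile_to_bedgraph(p: RTProfile | SmoothedRT) -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": p.grid.chroms, "start": p.grid.starts, "end": p.grid.ends, "value": p.values}
    )


# ---------------------------------------------------------------------------
# normalization


def normalize_replicates(profiles: list[RTProfile]) -> list[RTProfile]:
    """Joint quantile normalization, then rescale pooled P1/P99 to -2/+2.

    All replicates of both conditions are normalized together so that
    between-condition differences in distribution shape cannot masquerade
    as regional timing changes. Rank ties are broken by genomic order
    (stable argsort), which makes the transform deterministic.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to normalize jointly")
    grid = profiles[0].grid
    for p in profiles[1:]:
        if not grid.same_as(p.grid):
            raise ValueError(
                f"probe grids differ between {profiles[0].label} and {p.label}"
            )
    mat = np.column_stack([p.values for p in profiles])
    order = np.argsort(mat, axis=0, kind="stable")
    ref = np.take_along_axis(mat, order, axis=0).mean(axis=1)
    out = np.empty_like(mat)
    for j in range(mat.shape[1]):
        out[order[:, j], j] = ref
    pooled = out.ravel()
    q1, q99 = np.quantile(pooled, [0.01, 0.99])
    if q99 <= q1:
        warnings.warn("degenerate profile distribution; centering only")
        out = out - q1
    else:
        out = -2.0 + 4.0 * (out - q1) / (q99 - q1)
    return [replace(p, values=out[:, j].copy()) for j, p in enumerate(profiles)]


# ---------------------------------------------------------------------------
# smoothing


def _tricube(d: np.ndarray, half: float) -> np.ndarray:
    u = np.clip(np.abs(d) / half, 0.0, 1.0)
    return (1.0 - u**3) ** 3


def _local_linear_at_zero(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted linear fit y ~ a + b*x, returning the prediction at x=0."""
    sw = w.sum()
    swx = (w * x).sum()
    swx2 = (w * x * x).sum()
    swy = (w * y).sum()
    swxy = (w * x * y).sum()
    den = sw * swx2 - swx * swx
    if den <= 1e-12 * max(sw * swx2, 1e-300):
        return swy / sw
    return (swx2 * swy - swx * swxy) / den


def smooth_profile(p: RTProfile, span_bp: int = 500_000) -> SmoothedRT:
    """Loess smoothing: tricube-weighted local linear regression.

    The window is +-span_bp/2 in genomic distance around each probe,
    truncated at chromosome ends. For a uniform probe grid the interior
    reduces to a fixed-kernel convolution (the slope term vanishes by
    symmetry), which is what makes smoothing cheap enough to apply to
    every replicate of large simulated cohorts; edge probes fall back to
    the explicit truncated-window fit. Constant profiles are preserved
    exactly and linear ramps are reproduced exactly (local-linear
    exactness), which the tests assert.
    """
    half = span_bp / 2.0
    out = np.empty_like(p.values, dtype=float)
    for c in p.grid.chrom_names:
        sl = p.grid.slices[c]
        pos = p.grid.midpoints[sl]
        y = p.values[sl]
        n = len(y)
        if n < 5:
            warnings.warn(f"chromosome {c} has {n} probes (<5); passing through")
            out[sl] = y
            continue
        spacing = np.diff(pos)
        uniform = np.allclose(spacing, spacing[0])
        if uniform:
            step = spacing[0]
            k = int(half // step)
            if 2 * k + 1 < 5:
                raise ValueError(
                    f"span {span_bp} bp covers fewer than 5 probes at spacing {step:.0f}"
                )
            d = np.arange(-k, k + 1) * step
            w = _tricube(d, half)
            w = w / w.sum()
            if 2 * k + 1 <= n:
                out_c = np.convolve(y, w, mode="same")
                lo, hi = k, n - k
            else:
                # window wider than the chromosome: every probe is an edge
                out_c = np.empty(n)
                lo, hi = n, n
            for i in list(range(min(lo, n))) + list(range(max(hi, 0), n)):
                a, b = max(0, i - k), min(n, i + k + 1)
                x = pos[a:b] - pos[i]
                ww = _tricube(x, half)
                out_c[i] = _local_linear_at_zero(x, y[a:b], ww)
        else:
            out_c = np.empty(n)
            for i in range(n):
                m = np.abs(pos - pos[i]) <= half
                if m.sum() < 2:
                    out_c[i] = y[i]
                    continue
                x = pos[m] - pos[i]
                out_c[i] = _local_linear_at_zero(x, y[m], _tricube(x, half))
        out[sl] = out_c
    return SmoothedRT(p.grid, out, span_bp, source=p.label)


# ---------------------------------------------------------------------------
# segmentation


def segment_domains(
    s: SmoothedRT,
    early_thr: float = 0.25,
    late_thr: float = -0.25,
    slope_thr: float = 1.0,
    min_domain: int = 100_000,
) -> TimingDomains:
    """Partition the probe-covered genome into Early/Mid/Late/TTR domains.

    Probes whose local slope magnitude exceeds ``slope_thr`` (normalized
    units per Mb) become temporal transition regions; the remaining
    constant-timing probes are labeled by value against the two
    thresholds. Runs shorter than ``min_domain`` are absorbed into their
    longer neighbor so the segmentation does not fragment on probe noise.
    """
    if not late_thr < early_thr:
        raise ValueError("require late_thr < early_thr")
    intervals: list[Interval] = []
    for c in s.grid.chrom_names:
        sl = s.grid.slices[c]
        y = s.values[sl]
        pos = s.grid.midpoints[sl]
        starts = s.grid.starts[sl]
        ends = s.grid.ends[sl]
        slope = np.gradient(y, pos) * 1e6  # units per Mb
        lab = np.where(y >= early_thr, "Early", np.where(y <= late_thr, "Late", "Mid"))
        lab = np.where(np.abs(slope) > slope_thr, "TTR", lab)
        runs: list[list] = []  # [label, first_idx, last_idx]
        for i, L in enumerate(lab):
            if runs and runs[-1][0] == L:
                runs[-1][2] = i
            else:
                runs.append([L, i, i])

        def run_bp(r):
            return int(ends[r[2]] - starts[r[1]])

        changed = True
        while changed and len(runs) > 1:
            changed = False
            small = [r for r in runs if run_bp(r) < min_domain]
            if not small:
                break
            r = min(small, key=run_bp)
            k = runs.index(r)
            left = runs[k - 1] if k > 0 else None
            right = runs[k + 1] if k + 1 < len(runs) else None
            target = max((x for x in (left, right) if x is not None), key=run_bp)
            r[0] = target[0]
            # coalesce equal-label neighbors
            merged: list[list] = []
            for run in runs:
                if merged and merged[-1][0] == run[0]:
                    merged[-1][2] = run[2]
                else:
                    merged.append(run)
            runs = merged
            changed = True
        for L, i0, i1 in runs:
            intervals.append(Interval(c, int(starts[i0]), int(ends[i1]), name=L))
    return TimingDomains(intervals)


# ---------------------------------------------------------------------------
# differential calling


@dataclass
class CallParams:
    """Knobs of the windowed mean-difference caller.

    window_probes: probes per non-overlapping test window (10 probes at
        10 kb spacing = 100 kb, the scale of the smallest reportable call).
    p_thr: per-window t-test threshold.
    min_amp: amplitude floor in normalized RT units; with the signal
        rescaled to [-2, +2] a floor of 0.3 corresponds to a clearly
        visible timing shift and suppresses genome-wide false calls.
    min_region: minimum reported region size in bp.
    max_gap: retained same-sign windows separated by at most this many
        non-retained windows are merged into one region.
    span_bp: Loess span applied to every replicate before testing.
    fdr: apply Benjamini-Hochberg across windows instead of raw p.
    """

    window_probes: int = 10
    p_thr: float = 0.05
    min_amp: float = 0.3
    min_region: int = 100_000
    max_gap: int = 1
    span_bp: int = 500_000
    fdr: bool = False


@dataclass(frozen=True)
class ARTILRegion:
    chrom: str
    start: int
    end: int
    direction: str  # "ADV" or "DEL"
    amplitude: float  # mean smoothed treated-control delta over the region
    p_value: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ARTILSet:
    """Called RT-impacted regions plus cohort-level summaries."""

    regions: list[ARTILRegion]
    probe_bp: int  # probe-covered bp of the cohort grid

    def __post_init__(self) -> None:
        for r in self.regions:
            if r.direction == "ADV" and not r.amplitude > 0:
                raise ValueError(f"ADV region with non-positive amplitude: {r}")
            if r.direction == "DEL" and not r.amplitude < 0:
                raise ValueError(f"DEL region with non-negative amplitude: {r}")

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def n_adv(self) -> int:
        return sum(r.direction == "ADV" for r in self.regions)

    @property
    def n_del(self) -> int:
        return sum(r.direction == "DEL" for r in self.regions)

    @property
    def percent_genome_impacted(self) -> float:
        """Percent of probe-covered bp inside the union of called regions."""
        if not self.regions:
            return 0.0
        bp = self.to_region_set().total_bp
        return 100.0 * bp / self.probe_bp

    @property
    def proportions(self) -> dict[str, float]:
        """Share of calls by direction (count-based, as in stacked-bar reports)."""
        n = len(self.regions)
        if n == 0:
            return {"ADV": float("nan"), "DEL": float("nan")}
        return {"ADV": self.n_adv / n, "DEL": self.n_del / n}

    def to_region_set(self, direction: str | None = None) -> RegionSet:
        ivs = [
            Interval(
                r.chrom,
                r.start,
                r.end,
                name=r.direction,
                score=float(-np.log10(max(r.p_value, 1e-300))),
            )
            for r in self.regions
            if direction is None or r.direction == direction
        ]
        return RegionSet(ivs, label=direction or "aRTIL")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "direction": r.direction,
                    "amplitude": r.amplitude,
                    "p_value": r.p_value,
                    "length": r.length,
                }
                for r in self.regions
            ],
            columns=["chrom", "start", "end", "direction", "amplitude", "p_value", "length"],
        )


def _window_stats(delta: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Means, p-values and (first, last) probe indices of tiled windows."""
    n = len(delta)
    edges = list(range(0, n, w))
    bounds = [(a, min(a + w, n)) for a in edges]
    bounds = [(a, b) for a, b in bounds if b - a >= 2]  # need a variance
    means = np.empty(len(bounds))
    pvals = np.empty(len(bounds))
    for k, (a, b) in enumerate(bounds):
        d = delta[a:b]
        m = d.mean()
        sd = d.std(ddof=1)
        if sd == 0.0:
            # degenerate (noise-free) window: the t-test limit
            means[k], pvals[k] = m, (0.0 if m != 0.0 else 1.0)
        else:
            t = m / (sd / np.sqrt(len(d)))
            means[k] = m
            pvals[k] = 2.0 * stats.t.sf(abs(t), len(d) - 1)
    return means, pvals, np.array(bounds, dtype=int)


def call_differential(
    control: list[RTProfile],
    treated: list[RTProfile],
    params: CallParams | None = None,
) -> ARTILSet:
    """Call ADV/DEL RT-impacted regions between two conditions.

    Implements the windowed mean-difference test described in the module
    docstring. Requires at least two replicates per condition (the
    within-window variance of replicate-mean deltas is otherwise a pure
    smoothing artifact) and an identical probe grid everywhere.
    """
    params = params or CallParams()
    if len(control) < 2 or len(treated) < 2:
        raise ValueError("need >=2 replicates per condition")
    grid = control[0].grid
    for p in control + treated:
        if not grid.same_as(p.grid):
            raise ValueError(f"probe grid of {p.label} differs")
    sm_c = np.column_stack([smooth_profile(p, params.span_bp).values for p in control])
    sm_t = np.column_stack([smooth_profile(p, params.span_bp).values for p in treated])
    delta = sm_t.mean(axis=1) - sm_c.mean(axis=1)

    all_windows: list[tuple[str, int, int, float, float]] = []  # chrom, a, b, mean, p
    for c in grid.chrom_names:
        sl = grid.slices[c]
        means, pvals, bounds = _window_stats(delta[sl], params.window_probes)
        for k in range(len(means)):
            all_windows.append(
                (c, sl.start + bounds[k, 0], sl.start + bounds[k, 1], means[k], pvals[k])
            )
    pvals = np.array([w[4] for w in all_windows])
    if params.fdr and len(pvals):
        from statsmodels.stats.multitest import multipletests

        pvals = multipletests(pvals, method="fdr_bh")[1]

    regions: list[ARTILRegion] = []
    # group windows per chromosome, merge retained same-sign runs
    by_chrom: dict[str, list[tuple[int, int, int, float, float]]] = {}
    for idx, (c, a, b, m, _) in enumerate(all_windows):
        by_chrom.setdefault(c, []).append((idx, a, b, m, pvals[idx]))
    for c, wins in by_chrom.items():
        retained = [
            (k, a, b, m, p)
            for k, (idx, a, b, m, p) in enumerate(wins)
            if p < params.p_thr and abs(m) >= params.min_amp
        ]
        cur: list[tuple[int, int, int, float, float]] = []
        groups: list[list] = []
        for item in retained:
            if cur and np.sign(item[3]) == np.sign(cur[-1][3]) and item[0] - cur[-1][0] - 1 <= params.max_gap:
                cur.append(item)
            else:
                if cur:
                    groups.append(cur)
                cur = [item]
        if cur:
            groups.append(cur)
        for g in groups:
            a = g[0][1]
            b = g[-1][2]
            start = int(grid.starts[a])
            end = int(grid.ends[b - 1])
            if end - start < params.min_region:
                continue
            amp = float(delta[a:b].mean())
            pmin = float(min(item[4] for item in g))
            direction = "ADV" if amp > 0 else "DEL"
            regions.append(ARTILRegion(c, start, end, direction, amp, pmin))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return ARTILSet(regions, probe_bp=grid.covered_bp)


# ---------------------------------------------------------------------------
# transmission


@dataclass
class TransmissionReport:
    """Mother-to-daughter persistence of called regions."""

    records: pd.DataFrame  # one row per mother region
    n_transmitted: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_transmitted / self.n_total if self.n_total else float("nan")


def assess_transmission(
    mother: ARTILSet, daughter: ARTILSet, min_recip: float = 0.5
) -> TransmissionReport:
    """Flag each mother region transmitted when a same-direction daughter
    region covers at least ``min_recip`` of its bp; record the
    daughter/mother amplitude ratio for transmitted pairs."""
    rows = []
    n_trans = 0
    for m in mother.regions:
        best_bp = 0
        best: ARTILRegion | None = None
        for d in daughter.regions:
            if d.direction != m.direction or d.chrom != m.chrom:
                continue
            ov = min(m.end, d.end) - max(m.start, d.start)
            if ov > best_bp:
                best_bp, best = ov, d
        transmitted = best is not None and best_bp >= min_recip * m.length
        if transmitted:
            n_trans += 1
        rows.append(
            {
                "chrom": m.chrom,
                "start": m.start,
                "end": m.end,
                "direction": m.direction,
                "mother_amplitude": m.amplitude,
                "transmitted": transmitted,
                "overlap_bp": best_bp if best is not None else 0,
                "amplitude_ratio": (best.amplitude / m.amplitude) if transmitted else np.nan,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "direction", "mother_amplitude",
            "transmitted", "overlap_bp", "amplitude_ratio",
        ],
    )
    return TransmissionReport(df, n_trans, len(mother.regions))
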