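"""Synthetic replication-timing cohorts with ground truth.

Generates everything the pipeline consumes — genome sequence, mappable
mask, replicate RT profiles for two conditions and two generations,
origin/gene/fragile-site/histone-mark tracks and ATAC peak tables — from
a single seeded specification, together with the truth records needed to
score recovery.

The generative model is deliberately the simplest structure that shows
every phenomenon the analysis must detect:

* the base RT landscape is a stationary Gaussian field (white noise
  smoothed to a chosen correlation length, rescaled to [-2, +2]), so the
  genome alternates between early and late constant-timing plateaus
  joined by transition slopes;
* treatment effects are implanted as flat-top bumps with 100 kb cosine
  shoulders: advances (ADV, positive) are placed inside truth-late
  domains and delays (DEL, negative) inside truth-early domains,
  mirroring where such shifts are observed;
* replicate measurement noise is iid Gaussian per probe, added last;
* the daughter generation reuses the same base landscape with fresh
  noise; a seeded subset of the ADV implants persists at reduced
  amplitude (partial inheritance), DEL implants do not persist;
* GC content, origin density, gene placement, accessibility-peak density
  and histone-mark tracks all co-vary with the base RT field the way
  they do in real genomes (GC/origins/genes/accessibility higher in
  early-replicating chromatin).

Every random draw comes from a named child stream of the one spec seed,
so all outputs are byte-identical across runs for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .atac import PeakTrack
from .differential import ProbeGrid, RTProfile
from .intervals import GenomeAssembly, Interval, RegionSet, merge_intervals

__all__ = [
    "ImplantSpec",
    "SyntheticSpec",
    "TruthImplant",
    "SyntheticTruth",
    "ImplantPlacementError",
    "make_genome",
    "make_rt_profiles",
    "make_feature_tracks",
]

Direction = Literal["ADV", "DEL"]


class ImplantPlacementError(RuntimeError):
    pass


@dataclass(frozen=True)
class ImplantSpec:
    direction: Direction
    width: int  # bp, including shoulders
    amplitude: float  # log2-ratio units, > 0 (sign comes from direction)
    count: int

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("implant amplitude must be > 0")
        if self.direction not in ("ADV", "DEL"):
            raise ValueError("direction must be ADV or DEL")


@dataclass
class SyntheticSpec:
    """Study conditions of a simulated cohort.

    Defaults describe a CGH-array-like design: 2 chromosomes of 20 Mb
    probed every 10 kb (4,000 probes), biological duplicates per
    condition with probe noise of 0.25 normalized units, eight 1 Mb
    advances of amplitude +1.2 implanted in late domains and four 1 Mb
    delays of amplitude -1.2 in early domains. 57% of advances persist
    in the daughter generation at 0.6x amplitude, matching the observed
    28-of-49 transmission with lowered amplitude.
    """

    n_chroms: int = 2
    chrom_length: int = 20_000_000
    probe_spacing: int = 10_000
    rt_landscape_scale: int = 2_000_000  # correlation length of the base field
    noise_sd: float = 0.25
    n_replicates: int = 2
    implants: list[ImplantSpec] = field(
        default_factory=lambda: [
            ImplantSpec("ADV", 1_000_000, 1.2, 8),
            ImplantSpec("DEL", 1_000_000, 1.2, 4),
        ]
    )
    inherit_fraction: float = 0.57
    inherit_amplitude_factor: float = 0.6
    seed: int = 42
    # secondary structure
    shoulder_bp: int = 100_000
    implant_min_gap: int = 300_000
    truth_thr: float = 0.25  # |base| threshold defining truth early/late
    truth_slope_thr: float = 1.0  # units/Mb; steeper probes are truth transitions
    gap_fraction: float = 0.02  # masked assembly gaps, share of bp
    gaps_per_chrom: int = 2
    gc_mid: float = 0.42
    gc_slope: float = 0.02  # GC change per unit of base RT
    origin_rate_late: float = 1.0 / 120_000  # origins per bp, late
    origin_width: int = 2_000
    n_genes: int = 400
    gene_log_mean: float = 10.5  # log-normal gene lengths, median ~36 kb
    gene_log_sd: float = 1.1  # heavy tail: a few genes exceed 400 kb
    cfs_adv_fraction: float = 0.8  # fraction of ADV implants covered by a CFS
    n_cfs_decoy: int = 8
    atac_multiplier: float = 1.2  # treated peak value inside ADV implants
    atac_replicates: int = 3
    atac_value_noise: float = 0.1  # per-replicate lognormal sd
    atac_lib_sd: float = 0.2  # per-replicate library-depth lognormal sd
    atac_peak_width: int = 500

    def __post_init__(self) -> None:
        if self.chrom_length % self.probe_spacing != 0:
            raise ValueError("probe_spacing must divide chrom_length")
        if not 0.0 <= self.inherit_fraction <= 1.0:
            raise ValueError("inherit_fraction must be in [0, 1]")

    @property
    def chrom_names(self) -> list[str]:
        return [f"{i + 1}" for i in range(self.n_chroms)]

    @property
    def probes_per_chrom(self) -> int:
        return self.chrom_length // self.probe_spacing


@dataclass(frozen=True)
class TruthImplant:
    chrom: str
    start: int
    end: int
    direction: Direction
    amplitude: float  # signed
    inherited: bool

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, name=self.direction)


@dataclass
class SyntheticTruth:
    """Ground truth of one cohort: implants, domain truth, and the base field."""

    implants: list[TruthImplant]
    early: RegionSet
    late: RegionSet
    grid: ProbeGrid
    base_field: np.ndarray  # noise-free landscape on the grid
    cfs: RegionSet | None = None

    def implant_set(self, direction: Direction | None = None) -> RegionSet:
        return RegionSet(
            [t.interval for t in self.implants if direction is None or t.direction == direction],
            label=direction or "implants",
        )


# ---------------------------------------------------------------------------
# seeded streams


def _rng(spec: SyntheticSpec, *key: int) -> np.random.Generator:
    """Named child stream: a fixed purpose code per draw keeps every
    artifact independent of the order other artifacts are generated in."""
    return np.random.default_rng(np.random.SeedSequence((int(spec.seed), *key)))


# purpose codes for the seed tree
_BASE, _GAPS, _PLACE, _SEQ, _NOISE, _INHERIT, _ORIGINS, _GENES, _CFS, _MARKS, _ATAC = range(11)


# ---------------------------------------------------------------------------
# base landscape and truth domains


def _make_grid(spec: SyntheticSpec) -> ProbeGrid:
    n = spec.probes_per_chrom
    starts = np.arange(n) * spec.probe_spacing
    chroms = np.concatenate([[c] * n for c in spec.chrom_names]).astype(object)
    return ProbeGrid(
        chroms,
        np.tile(starts, spec.n_chroms),
        np.tile(starts + spec.probe_spacing, spec.n_chroms),
    )


def _base_field(spec: SyntheticSpec, grid: ProbeGrid) -> np.ndarray:
    """Plateau-like RT landscape on [-2, 2].

    Smoothed Gaussian noise alone yields a bell-shaped value
    distribution with few wide early/late plateaus; real RT profiles are
    dominated by constant-timing plateaus joined by short transitions.
    A saturating transform (tanh of the field over ~0.7 of its sd)
    reproduces that structure, after which the 1st/99th percentiles are
    mapped to -2/+2 and the tails clipped — the same scale convention
    the profile normalizer uses.
    """
    rng = _rng(spec, _BASE)
    sigma = (spec.rt_landscape_scale / 2.0) / spec.probe_spacing
    parts = []
    for _ in spec.chrom_names:
        white = rng.standard_normal(spec.probes_per_chrom)
        parts.append(gaussian_filter1d(white, sigma=sigma, mode="reflect"))
    base = np.concatenate(parts)
    base = np.tanh(base / (0.7 * base.std()))
    lo, hi = np.quantile(base, [0.01, 0.99])
    return np.clip(-2.0 + 4.0 * (base - lo) / (hi - lo), -2.0, 2.0)


def _truth_domains(spec: SyntheticSpec, grid: ProbeGrid, base: np.ndarray) -> tuple[RegionSet, RegionSet]:
    """Truth early/late plateaus: value beyond the threshold AND locally flat.

    Probes on steep stretches of the clean landscape are transitions,
    not early/late plateaus, so they belong to neither truth domain
    (the segmenter labels them TTR by the same slope criterion).
    """
    early_ivs, late_ivs = [], []
    for c in grid.chrom_names:
        sl = grid.slices[c]
        slope = np.gradient(base[sl], grid.midpoints[sl]) * 1e6  # units/Mb
        flat = np.abs(slope) <= spec.truth_slope_thr
        for mask, acc in (
            ((base[sl] >= spec.truth_thr) & flat, early_ivs),
            ((base[sl] <= -spec.truth_thr) & flat, late_ivs),
        ):
            idx = np.flatnonzero(mask)
            if not len(idx):
                continue
            breaks = np.flatnonzero(np.diff(idx) > 1)
            run_starts = np.concatenate([[0], breaks + 1])
            run_ends = np.concatenate([breaks, [len(idx) - 1]])
            for a, b in zip(run_starts, run_ends):
                acc.append(
                    Interval(c, int(grid.starts[sl][idx[a]]), int(grid.ends[sl][idx[b]]))
                )
    return RegionSet(early_ivs, "truth-early"), RegionSet(late_ivs, "truth-late")


# ---------------------------------------------------------------------------
# genome sequence


def make_genome(spec: SyntheticSpec) -> tuple[GenomeAssembly, dict[str, str]]:
    """Random genome whose windowed GC tracks the base RT field.

    GC probability per probe window is ``gc_mid + gc_slope * base``, so
    early-replicating truth regions are measurably GC-richer than late
    ones. A few random masked gaps (written as N runs) are excluded from
    the mappable set.
    """
    grid = _make_grid(spec)
    base = _base_field(spec, grid)
    rng_gap = _rng(spec, _GAPS)
    rng_seq = _rng(spec, _SEQ)
    gap_len = int(spec.gap_fraction * spec.chrom_length / spec.gaps_per_chrom)
    sizes = {c: spec.chrom_length for c in spec.chrom_names}
    seqs: dict[str, str] = {}
    mappable_ivs: list[Interval] = []
    bases = np.array(list("ACGT"))
    for c in spec.chrom_names:
        sl = grid.slices[c]
        p_gc = np.clip(spec.gc_mid + spec.gc_slope * base[sl], 0.25, 0.6)
        per_base_gc = np.repeat(p_gc, spec.probe_spacing)
        u = rng_seq.random(spec.chrom_length)
        strong = u < per_base_gc  # G or C
        pick = rng_seq.integers(0, 2, size=spec.chrom_length)
        # strong -> C(1)/G(2), weak -> A(0)/T(3)
        codes = np.where(strong, np.where(pick == 0, 1, 2), np.where(pick == 0, 0, 3))
        seq = bases[codes]
        # masked gaps
        gaps: list[tuple[int, int]] = []
        tries = 0
        while len(gaps) < spec.gaps_per_chrom and tries < 1000:
            s = int(rng_gap.integers(0, spec.chrom_length - gap_len))
            e = s + gap_len
            if all(e <= gs or s >= ge for gs, ge in gaps):
                gaps.append((s, e))
            tries += 1
        for s, e in gaps:
            seq[s:e] = "N"
        seqs[c] = "".join(seq)
        cuts = sorted(gaps)
        prev = 0
        for s, e in cuts:
            if s > prev:
                mappable_ivs.append(Interval(c, prev, s))
            prev = e
        if prev < spec.chrom_length:
            mappable_ivs.append(Interval(c, prev, spec.chrom_length))
    genome = GenomeAssembly(spec.chrom_names, sizes, RegionSet(mappable_ivs, "mappable"))
    return genome, seqs


# ---------------------------------------------------------------------------
# implants and profiles


def _place_implants(spec: SyntheticSpec, early: RegionSet, late: RegionSet) -> list[tuple[str, int, int, Direction, float]]:
    rng = _rng(spec, _PLACE)
    placed: list[tuple[str, int, int, Direction, float]] = []
    for imp in spec.implants:
        host = late if imp.direction == "ADV" else early
        segs = [iv for iv in host if iv.length >= imp.width]
        caps = [1 + (iv.length - imp.width) // (imp.width + spec.implant_min_gap) for iv in segs]
        if sum(caps) < imp.count:
            raise ImplantPlacementError(
                f"cannot place {imp.count} x {imp.direction} implants of "
                f"{imp.width} bp: eligible {'late' if imp.direction == 'ADV' else 'early'} "
                f"domains hold only {sum(caps)}"
            )
        # round-robin over segments in a seeded random order
        order = rng.permutation(len(segs))
        alloc = [0] * len(segs)
        remaining = imp.count
        while remaining > 0:
            progressed = False
            for k in order:
                if remaining == 0:
                    break
                if alloc[k] < caps[k]:
                    alloc[k] += 1
                    remaining -= 1
                    progressed = True
            if not progressed:  # pragma: no cover - guarded by capacity check
                raise ImplantPlacementError("allocation failed")
        sign = 1.0 if imp.direction == "ADV" else -1.0
        for k, m in enumerate(alloc):
            if m == 0:
                continue
            seg = segs[k]
            needed = m * imp.width + (m - 1) * spec.implant_min_gap
            slack = seg.length - needed
            cuts = np.sort(rng.integers(0, slack + 1, size=m))
            pos = seg.start
            prev_cut = 0
            for j in range(m):
                pos += int(cuts[j] - prev_cut)
                prev_cut = int(cuts[j])
                placed.append((seg.chrom, pos, pos + imp.width, imp.direction, sign * imp.amplitude))
                pos += imp.width + spec.implant_min_gap
    placed.sort(key=lambda t: (t[0], t[1]))
    return placed


def _bump_track(spec: SyntheticSpec, grid: ProbeGrid, implants: list[TruthImplant], factor: float = 1.0, inherited_only: bool = False) -> np.ndarray:
    track = np.zeros(len(grid))
    sh = spec.shoulder_bp
    for t in implants:
        if inherited_only and not t.inherited:
            continue
        sl = grid.slices[t.chrom]
        x = grid.midpoints[sl]
        b = np.zeros(len(x))
        core_lo, core_hi = t.start + sh, t.end - sh
        in_core = (x >= core_lo) & (x <= core_hi)
        b[in_core] = 1.0
        left = (x >= t.start) & (x < core_lo)
        b[left] = 0.5 * (1 - np.cos(np.pi * (x[left] - t.start) / sh))
        right = (x > core_hi) & (x <= t.end)
        b[right] = 0.5 * (1 - np.cos(np.pi * (t.end - x[right]) / sh))
        track[sl] += t.amplitude * factor * b
    return track


def make_rt_profiles(spec: SyntheticSpec) -> tuple[dict[tuple[str, str, str], RTProfile], SyntheticTruth]:
    """Replicate RT profiles for both conditions and generations, plus truth.

    Keys of the returned dict are (condition, generation, replicate) with
    condition in {control, treated} and generation in {t0, n1}. Daughter
    (n1) control profiles reuse the same base landscape with fresh noise;
    daughter treated profiles carry only the inherited ADV implants at
    ``inherit_amplitude_factor`` times the mother amplitude.
    """
    grid = _make_grid(spec)
    base = _base_field(spec, grid)
    early, late = _truth_domains(spec, grid, base)
    raw = _place_implants(spec, early, late)

    rng_inh = _rng(spec, _INHERIT)
    adv_idx = [i for i, r in enumerate(raw) if r[3] == "ADV"]
    n_inherit = int(round(spec.inherit_fraction * len(adv_idx)))
    chosen = set(rng_inh.choice(adv_idx, size=n_inherit, replace=False).tolist()) if n_inherit else set()
    implants = [
        TruthImplant(c, s, e, d, a, inherited=(i in chosen))
        for i, (c, s, e, d, a) in enumerate(raw)
    ]
    truth = SyntheticTruth(implants, early, late, grid, base)

    bumps_t0 = _bump_track(spec, grid, implants)
    bumps_n1 = _bump_track(spec, grid, implants, factor=spec.inherit_amplitude_factor, inherited_only=True)

    profiles: dict[tuple[str, str, str], RTProfile] = {}
    for gen, cond, signal in (
        ("t0", "control", base),
        ("t0", "treated", base + bumps_t0),
        ("n1", "control", base),
        ("n1", "treated", base + bumps_n1),
    ):
        for r in range(spec.n_replicates):
            rng_noise = _rng(spec, _NOISE, ("t0", "n1").index(gen), ("control", "treated").index(cond), r)
            noise = rng_noise.standard_normal(len(grid)) * spec.noise_sd if spec.noise_sd > 0 else 0.0
            profiles[(cond, gen, f"r{r + 1}")] = RTProfile(
                grid, signal + noise, condition=cond, generation=gen, replicate=f"r{r + 1}"
            )
    return profiles, truth


# ---------------------------------------------------------------------------
# feature tracks


def _probe_label(spec: SyntheticSpec, base: np.ndarray) -> np.ndarray:
    return np.where(base >= spec.truth_thr, 0, np.where(base <= -spec.truth_thr, 2, 1))


def make_feature_tracks(spec: SyntheticSpec, truth: SyntheticTruth) -> dict:
    """Origin/gene/CFS/mark/ATAC tracks statistically tied to the RT field.

    * origins: Poisson-placed, density 3:1 early:late (mid in between);
    * genes: log-normal lengths with a heavy tail (some exceed 400 kb),
      placed with a 3:2:1 early:mid:late probe-weight bias;
    * CFS: one fragile-site interval over ``cfs_adv_fraction`` of the ADV
      implants (seeded choice) plus decoy sites placed away from
      implants, so most fragile sites are not treatment-impacted;
    * marks: four histone-mark-like interval tracks thresholded from
      noisy transforms of the base field (two early-associated, one mid,
      one late-associated);
    * atac_peaks: shared peak locations, density highest in early
      chromatin; per replicate raw values carry lognormal measurement
      noise and a random library-depth factor, and the treated condition
      multiplies peaks inside ADV implants by ``atac_multiplier``.
    """
    grid, base = truth.grid, truth.base_field
    lab = _probe_label(spec, base)
    out: dict = {}

    # origins ---------------------------------------------------------------
    rng = _rng(spec, _ORIGINS)
    rate = spec.origin_rate_late * np.array([3.0, 2.0, 1.0])[lab]
    counts = rng.poisson(rate * spec.probe_spacing)
    origin_ivs: list[Interval] = []
    for i in np.flatnonzero(counts):
        c = grid.chroms[i]
        for _ in range(counts[i]):
            x = int(grid.starts[i] + rng.integers(0, spec.probe_spacing))
            end = min(x + spec.origin_width, spec.chrom_length)
            if end > x:
                origin_ivs.append(Interval(c, x, end))
    out["origins"] = RegionSet(origin_ivs, "origins")

    # genes -----------------------------------------------------------------
    rng = _rng(spec, _GENES)
    weights = np.array([3.0, 2.0, 1.0])[lab]
    weights = weights / weights.sum()
    gene_ivs: list[Interval] = []
    lengths = np.minimum(rng.lognormal(spec.gene_log_mean, spec.gene_log_sd, spec.n_genes), 2_000_000).astype(int)
    probe_idx = rng.choice(len(grid), size=spec.n_genes, p=weights)
    for g, (i, L) in enumerate(zip(probe_idx, lengths)):
        c = grid.chroms[i]
        s = int(grid.starts[i])
        e = min(s + max(int(L), 1_000), spec.chrom_length)
        gene_ivs.append(Interval(c, s, e, name=f"gene{g}"))
    out["genes"] = RegionSet(gene_ivs, "genes")
    out["large_genes"] = RegionSet([iv for iv in gene_ivs if iv.length > 400_000], "large_genes")

    # CFS -------------------------------------------------------------------
    rng = _rng(spec, _CFS)
    adv = [t for t in truth.implants if t.direction == "ADV"]
    n_cov = int(round(spec.cfs_adv_fraction * len(adv)))
    covered = rng.choice(len(adv), size=n_cov, replace=False) if n_cov else np.array([], dtype=int)
    cfs_ivs: list[Interval] = []
    for k in sorted(covered.tolist()):
        t = adv[k]
        width = int(rng.uniform(800_000, 1_600_000))
        center = int(0.5 * (t.start + t.end) + rng.integers(-200_000, 200_001))
        s = max(0, center - width // 2)
        e = min(spec.chrom_length, s + width)
        cfs_ivs.append(Interval(t.chrom, s, e, name=f"CFS_adv{k}"))
    implant_set = truth.implant_set()
    tries = 0
    while len(cfs_ivs) < n_cov + spec.n_cfs_decoy and tries < 10_000:
        tries += 1
        c = spec.chrom_names[int(rng.integers(0, spec.n_chroms))]
        width = int(rng.uniform(800_000, 1_600_000))
        s = int(rng.integers(0, spec.chrom_length - width))
        cand = Interval(c, s, s + width)
        if any(t.chrom == c and min(t.end, cand.end) > max(t.start, cand.start) for t in truth.implants):
            continue
        cfs_ivs.append(Interval(c, s, s + width, name=f"CFS_decoy{len(cfs_ivs)}"))
    out["cfs"] = RegionSet(cfs_ivs, "CFS")
    truth.cfs = out["cfs"]

    # histone-mark-like tracks ---------------------------------------------
    rng = _rng(spec, _MARKS)
    mark_defs = {
        "mark_early_a": (1, 0.3),   # active-promoter-like, early
        "mark_early_b": (1, 0.1),   # transcription-associated, broad early
        "mark_mid": (0, 0.45),      # facultative, mid (|base| small)
        "mark_late": (-1, 0.2),     # constitutive heterochromatin, late
    }
    marks: dict[str, RegionSet] = {}
    for name, (mode, thr) in mark_defs.items():
        noisy = base + rng.standard_normal(len(grid)) * 0.3
        if mode == 1:
            mask = noisy > thr
        elif mode == -1:
            mask = noisy < -thr
        else:
            mask = np.abs(noisy) < thr
        ivs: list[Interval] = []
        for c in grid.chrom_names:
            sl = grid.slices[c]
            idx = np.flatnonzero(mask[sl])
            if not len(idx):
                continue
            breaks = np.flatnonzero(np.diff(idx) > 1)
            run_s = np.concatenate([[0], breaks + 1])
            run_e = np.concatenate([breaks, [len(idx) - 1]])
            for a, b in zip(run_s, run_e):
                ivs.append(Interval(c, int(grid.starts[sl][idx[a]]), int(grid.ends[sl][idx[b]])))
        marks[name] = RegionSet(ivs, name)
    out["marks"] = marks

    # ATAC peaks ------------------------------------------------------------
    rng = _rng(spec, _ATAC)
    dens = np.array([1 / 30_000, 1 / 60_000, 1 / 150_000])[lab]
    counts = rng.poisson(dens * spec.probe_spacing)
    peak_chroms, peak_starts = [], []
    for i in np.flatnonzero(counts):
        for _ in range(counts[i]):
            x = int(grid.starts[i] + rng.integers(0, spec.probe_spacing))
            if x + spec.atac_peak_width <= spec.chrom_length:
                peak_chroms.append(grid.chroms[i])
                peak_starts.append(x)
    peak_starts = np.array(peak_starts, dtype=np.int64)
    order = np.lexsort((peak_starts, np.array(peak_chroms, dtype=object)))
    peak_chroms = np.array(peak_chroms, dtype=object)[order]
    peak_starts = peak_starts[order]
    peak_ends = peak_starts + spec.atac_peak_width
    base_vals = rng.lognormal(np.log(50.0), 0.5, size=len(peak_starts))
    mid = 0.5 * (peak_starts + peak_ends)
    in_adv = np.zeros(len(peak_starts), dtype=bool)
    for t in truth.implants:
        if t.direction != "ADV":
            continue
        in_adv |= (peak_chroms == t.chrom) & (mid >= t.start) & (mid <= t.end)
    tracks: dict[tuple[str, str], PeakTrack] = {}
    nominal_total = float(base_vals.sum())  # expected peak mass at depth 1
    for cond in ("control", "treated"):
        effect = np.where(in_adv & (cond == "treated"), spec.atac_multiplier, 1.0)
        for r in range(spec.atac_replicates):
            noise = rng.lognormal(0.0, spec.atac_value_noise, size=len(peak_starts))
            lib = rng.lognormal(0.0, spec.atac_lib_sd)
            values = base_vals * effect * noise * lib
            # sequencing depth is known per replicate; recording it lets
            # normalization divide by depth instead of the peak total
            tracks[(cond, f"r{r + 1}")] = PeakTrack(
                chroms=peak_chroms.copy(),
                starts=peak_starts.copy(),
                ends=peak_ends.copy(),
                values=values,
                condition=cond,
                replicate=f"r{r + 1}",
                library_size=lib * nominal_total,
            )
    out["atac_peaks"] = tracks
    out["atac_in_adv"] = in_adv
    return out
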