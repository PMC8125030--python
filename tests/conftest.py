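"""Shared fixtures and brute-force oracles.

The oracles work on explicit per-base boolean bitmaps, independent of
the interval-sweep implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from retime import (
    Interval,
    RegionSet,
    SyntheticSpec,
    call_differential,
    make_feature_tracks,
    make_genome,
    make_rt_profiles,
    normalize_replicates,
)

# ---------------------------------------------------------------------------
# per-base bitmap oracles


def bitmap(rs: RegionSet, chrom_lens: dict[str, int]) -> dict[str, np.ndarray]:
    out = {c: np.zeros(n, dtype=bool) for c, n in chrom_lens.items()}
    for iv in rs:
        out[iv.chrom][iv.start : iv.end] = True
    return out


def oracle_intersect_bp(a: RegionSet, b: RegionSet, chrom_lens) -> int:
    ba, bb = bitmap(a, chrom_lens), bitmap(b, chrom_lens)
    return int(sum((ba[c] & bb[c]).sum() for c in chrom_lens))


def oracle_jaccard(a: RegionSet, b: RegionSet, chrom_lens) -> float:
    ba, bb = bitmap(a, chrom_lens), bitmap(b, chrom_lens)
    inter = sum((ba[c] & bb[c]).sum() for c in chrom_lens)
    union = sum((ba[c] | bb[c]).sum() for c in chrom_lens)
    return inter / union


def oracle_coverage(regions: RegionSet, features: RegionSet, chrom_lens) -> np.ndarray:
    bf = bitmap(features, chrom_lens)
    return np.array([bf[iv.chrom][iv.start : iv.end].mean() for iv in regions])


def random_region_set(rng: np.random.Generator, chrom_lens, max_iv=12, label="") -> RegionSet:
    ivs = []
    n = rng.integers(1, max_iv + 1)
    chroms = list(chrom_lens)
    for _ in range(n):
        c = chroms[rng.integers(0, len(chroms))]
        L = chrom_lens[c]
        s = int(rng.integers(0, L - 1))
        e = int(rng.integers(s + 1, min(L, s + 1 + L // 4) + 1))
        ivs.append(Interval(c, s, e))
    return RegionSet(ivs, label=label)


# ---------------------------------------------------------------------------
# cohort fixtures (session-scoped: the default cohort is used by many tests)


@pytest.fixture(scope="session")
def default_cohort():
    """Seed-42 default study cohort: profiles, truth, called regions."""
    spec = SyntheticSpec()
    profiles, truth = make_rt_profiles(spec)
    ctrl = [profiles[("control", "t0", f"r{i + 1}")] for i in range(spec.n_replicates)]
    trt = [profiles[("treated", "t0", f"r{i + 1}")] for i in range(spec.n_replicates)]
    normed = normalize_replicates(ctrl + trt)
    artil = call_differential(normed[: len(ctrl)], normed[len(ctrl):])
    return {
        "spec": spec,
        "profiles": profiles,
        "truth": truth,
        "normed_control": normed[: len(ctrl)],
        "normed_treated": normed[len(ctrl):],
        "artil": artil,
    }


@pytest.fixture(scope="session")
def default_tracks(default_cohort):
    return make_feature_tracks(default_cohort["spec"], default_cohort["truth"])


@pytest.fixture(scope="session")
def small_genome():
    """A small genome (2 x 500 kb) with sequence, for GC and I/O tests."""
    spec = SyntheticSpec(
        n_chroms=2, chrom_length=500_000, probe_spacing=5_000,
        rt_landscape_scale=100_000, implants=[], seed=7,
    )
    genome, seqs = make_genome(spec)
    return {"spec": spec, "genome": genome, "seqs": seqs}
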