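"""The cohort generator: determinism, construction guarantees, truth records."""

import numpy as np
import pytest

from retime import (
    ImplantSpec,
    RegionSet,
    SyntheticSpec,
    coverage_fraction,
    intersect,
    make_feature_tracks,
    make_genome,
    make_rt_profiles,
)
from retime.synthetic import ImplantPlacementError


def small_spec(**kw):
    base = dict(
        n_chroms=2, chrom_length=4_000_000, probe_spacing=10_000,
        rt_landscape_scale=800_000, noise_sd=0.2,
        implants=[ImplantSpec("ADV", 400_000, 1.0, 2), ImplantSpec("DEL", 400_000, 1.0, 1)],
        implant_min_gap=200_000, seed=11,
    )
    base.update(kw)
    return SyntheticSpec(**base)


class TestDeterminism:
    def test_profiles_identical_across_runs(self):
        a, _ = make_rt_profiles(small_spec())
        b, _ = make_rt_profiles(small_spec())
        assert set(a) == set(b)
        for k in a:
            np.testing.assert_array_equal(a[k].values, b[k].values)

    def test_genome_sequence_identical_across_runs(self):
        _, seqs_a = make_genome(small_spec())
        _, seqs_b = make_genome(small_spec())
        assert seqs_a == seqs_b

    def test_feature_tracks_identical_across_runs(self):
        spec = small_spec()
        _, truth = make_rt_profiles(spec)
        ta = make_feature_tracks(spec, truth)
        tb = make_feature_tracks(spec, truth)
        assert [(iv.chrom, iv.start, iv.end) for iv in ta["origins"]] == [
            (iv.chrom, iv.start, iv.end) for iv in tb["origins"]
        ]
        for key in ta["atac_peaks"]:
            np.testing.assert_array_equal(
                ta["atac_peaks"][key].values, tb["atac_peaks"][key].values
            )


class TestGenome:
    def test_gc_tracks_rt(self, small_genome):
        """Early-replicating truth regions are GC-richer than late ones."""
        spec = small_genome["spec"]
        _, truth = make_rt_profiles(spec)
        seqs = small_genome["seqs"]

        def gc_of(rs):
            g = at = 0
            for iv in rs:
                s = seqs[iv.chrom][iv.start : iv.end]
                g += s.count("G") + s.count("C")
                at += s.count("A") + s.count("T")
            return g / (g + at)

        assert gc_of(truth.early) > gc_of(truth.late)

    def test_masked_gaps_excluded_from_mappable(self, small_genome):
        genome = small_genome["genome"]
        seqs = small_genome["seqs"]
        total = sum(genome.chrom_lengths.values())
        n_count = sum(s.count("N") for s in seqs.values())
        assert genome.mappable.total_bp == total - n_count
        for iv in genome.mappable:
            assert "N" not in seqs[iv.chrom][iv.start : iv.end]


class TestProfiles:
    def test_no_noise_no_implants_treated_equals_control(self):
        spec = small_spec(noise_sd=0.0, implants=[])
        profiles, _ = make_rt_profiles(spec)
        np.testing.assert_array_equal(
            profiles[("treated", "t0", "r1")].values,
            profiles[("control", "t0", "r1")].values,
        )

    def test_implant_core_mean_equals_amplitude(self):
        spec = small_spec(noise_sd=0.0)
        profiles, truth = make_rt_profiles(spec)
        delta = profiles[("treated", "t0", "r1")].values - profiles[("control", "t0", "r1")].values
        grid = truth.grid
        for t in truth.implants:
            sl = grid.slices[t.chrom]
            mid = grid.midpoints[sl]
            core = (mid >= t.start + spec.shoulder_bp) & (mid <= t.end - spec.shoulder_bp)
            np.testing.assert_allclose(delta[sl][core].mean(), t.amplitude, atol=1e-12)

    def test_amplitude_recovered_within_noise_bound(self):
        spec = small_spec(noise_sd=0.2)
        profiles, truth = make_rt_profiles(spec)
        delta = profiles[("treated", "t0", "r1")].values - profiles[("control", "t0", "r1")].values
        grid = truth.grid
        for t in truth.implants:
            sl = grid.slices[t.chrom]
            mid = grid.midpoints[sl]
            core = (mid >= t.start + spec.shoulder_bp) & (mid <= t.end - spec.shoulder_bp)
            n = core.sum()
            # replicate delta noise has sd sqrt(2)*noise_sd per probe
            bound = 3 * np.sqrt(2) * spec.noise_sd / np.sqrt(n)
            assert abs(delta[sl][core].mean() - t.amplitude) < bound

    def test_inherit_fraction_half_of_eight_gives_exactly_four(self):
        spec = SyntheticSpec(inherit_fraction=0.5, seed=42)  # default: 8 ADV implants
        _, truth = make_rt_profiles(spec)
        adv = [t for t in truth.implants if t.direction == "ADV"]
        assert len(adv) == 8
        assert sum(t.inherited for t in adv) == 4

    def test_implants_lie_in_truth_domains_and_are_disjoint(self):
        _, truth = make_rt_profiles(small_spec())
        for t in truth.implants:
            host = truth.late if t.direction == "ADV" else truth.early
            cov = coverage_fraction(RegionSet([t.interval]), host)
            assert cov[0] == 1.0
        ivs = sorted((t.chrom, t.start, t.end) for t in truth.implants)
        for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
            assert c1 != c2 or e1 <= s2

    def test_placement_failure_is_explicit(self):
        spec = small_spec(implants=[ImplantSpec("ADV", 3_900_000, 1.0, 2)])
        with pytest.raises(ImplantPlacementError, match="ADV"):
            make_rt_profiles(spec)


class TestFeatureTracks:
    def test_cfs_cover_stated_fraction_of_adv_implants(self, default_cohort, default_tracks):
        truth = default_cohort["truth"]
        spec = default_cohort["spec"]
        adv = [t for t in truth.implants if t.direction == "ADV"]
        covered = sum(
            1 for t in adv if len(intersect(RegionSet([t.interval]), default_tracks["cfs"]))
        )
        assert covered == round(spec.cfs_adv_fraction * len(adv))

    def test_origin_density_ratio_early_late(self, default_cohort, default_tracks):
        truth = default_cohort["truth"]
        origins = default_tracks["origins"]
        dens = {}
        for name, rs in (("early", truth.early), ("late", truth.late)):
            n = sum(len(intersect(RegionSet([iv]), origins)) for iv in rs)
            dens[name] = n / rs.total_bp
        ratio = dens["early"] / dens["late"]
        # 3:1 construction, binomial error at a few hundred origins
        assert 2.3 < ratio < 3.9

    def test_gene_lengths_have_heavy_tail(self, default_tracks):
        assert len(default_tracks["large_genes"]) >= 1
        assert all(iv.length > 400_000 for iv in default_tracks["large_genes"])

    def test_atac_multiplier_one_means_no_systematic_shift(self):
        spec = small_spec(atac_multiplier=1.0)
        _, truth = make_rt_profiles(spec)
        tracks = make_feature_tracks(spec, truth)
        c = tracks["atac_peaks"][("control", "r1")]
        t = tracks["atac_peaks"][("treated", "r1")]
        # same peaks, values differ only by replicate noise and depth
        np.testing.assert_array_equal(c.starts, t.starts)
        ratio = (t.values / t.library_size) / (c.values / c.library_size)
        assert abs(np.log(ratio).mean()) < 3 * spec.atac_value_noise
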