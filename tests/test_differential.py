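"""Normalization, smoothing, segmentation, calling, transmission."""

from dataclasses import replace

import numpy as np
import pytest

from retime import (
    Interval,
    RegionSet,
    SyntheticSpec,
    assess_transmission,
    call_differential,
    jaccard,
    make_rt_profiles,
    normalize_replicates,
    segment_domains,
    smooth_profile,
)
from retime.differential import ARTILRegion, ARTILSet, CallParams, ProbeGrid, RTProfile
from retime.synthetic import ImplantSpec


def grid_1chrom(n=200, spacing=10_000, chrom="1"):
    starts = np.arange(n) * spacing
    return ProbeGrid(np.array([chrom] * n, dtype=object), starts, starts + spacing)


def prof(values, grid=None, **kw):
    values = np.asarray(values, dtype=float)
    grid = grid or grid_1chrom(len(values))
    return RTProfile(grid, values, **kw)


class TestNormalize:
    def test_identical_profiles_stay_identical(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(200)
        out = normalize_replicates([prof(v), prof(v.copy())])
        np.testing.assert_array_equal(out[0].values, out[1].values)

    def test_pooled_percentiles_hit_plus_minus_two(self):
        rng = np.random.default_rng(1)
        out = normalize_replicates([prof(rng.standard_normal(500)) for _ in range(4)])
        pooled = np.concatenate([p.values for p in out])
        assert np.quantile(pooled, 0.01) == pytest.approx(-2.0)
        assert np.quantile(pooled, 0.99) == pytest.approx(2.0)

    def test_marginals_equalized(self):
        """After joint quantile normalization every replicate has the same
        sorted value vector (the defining property)."""
        rng = np.random.default_rng(2)
        out = normalize_replicates([prof(rng.standard_normal(300) * s) for s in (0.5, 1.0, 3.0)])
        for p in out[1:]:
            np.testing.assert_allclose(np.sort(p.values), np.sort(out[0].values))

    def test_shift_of_one_replicate_is_absorbed(self):
        """An additive offset on one replicate changes nothing: ranks are
        unchanged and the final percentile rescale removes the shift."""
        rng = np.random.default_rng(5)
        a, b = rng.standard_normal(300), rng.standard_normal(300)
        base = normalize_replicates([prof(a), prof(b)])
        shifted = normalize_replicates([prof(a + 7.5), prof(b)])
        np.testing.assert_allclose(base[0].values, shifted[0].values)
        np.testing.assert_allclose(base[1].values, shifted[1].values)

    def test_monotone_transform_preserves_output_ranks(self):
        """A monotone distortion of one replicate cannot reorder any
        replicate's normalized values (quantile normalization sees ranks
        only; the empirical reference may still shift values)."""
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(300), rng.standard_normal(300)
        base = normalize_replicates([prof(a), prof(b)])
        warped = normalize_replicates([prof(np.exp(a)), prof(b)])
        for i in range(2):
            np.testing.assert_array_equal(
                np.argsort(base[i].values, kind="stable"),
                np.argsort(warped[i].values, kind="stable"),
            )

    def test_grid_mismatch_rejected(self):
        g1, g2 = grid_1chrom(100), grid_1chrom(100, spacing=20_000)
        with pytest.raises(ValueError, match="grids differ"):
            normalize_replicates([prof(np.zeros(100), g1), prof(np.zeros(100), g2)])


class TestSmooth:
    def test_constant_preserved_exactly(self):
        out = smooth_profile(prof(np.full(100, 1.5)), 500_000)
        np.testing.assert_allclose(out.values, 1.5)

    def test_linear_ramp_preserved(self):
        """Local-linear smoothing reproduces linear signals exactly."""
        ramp = np.linspace(-1, 1, 200)
        out = smooth_profile(prof(ramp), 500_000)
        np.testing.assert_allclose(out.values, ramp, atol=1e-9)

    def test_noise_suppression_on_flat_profile(self):
        rng = np.random.default_rng(3)
        noisy = prof(rng.standard_normal(2000) * 0.3)
        out = smooth_profile(noisy, 500_000)
        assert out.values.std() < 0.1

    def test_short_chromosome_passes_through_with_warning(self):
        g = grid_1chrom(3)
        with pytest.warns(UserWarning, match="<5"):
            out = smooth_profile(prof([1.0, 2.0, 3.0], g), 500_000)
        np.testing.assert_array_equal(out.values, [1.0, 2.0, 3.0])


class TestSegment:
    def test_uniform_early_gives_one_domain_per_chromosome(self):
        n = 200
        starts = np.arange(2 * n) % n * 10_000
        chroms = np.array(["1"] * n + ["2"] * n, dtype=object)
        grid = ProbeGrid(chroms, starts, starts + 10_000)
        sm = smooth_profile(RTProfile(grid, np.full(2 * n, 1.0)), 500_000)
        dom = segment_domains(sm, 0.25, -0.25)
        assert [(iv.chrom, iv.name) for iv in dom.intervals] == [("1", "Early"), ("2", "Early")]

    def test_step_profile_late_ttr_early(self):
        v = np.where(np.arange(400) < 200, -1.0, 1.0)
        sm = smooth_profile(prof(v, grid_1chrom(400)), 500_000)
        dom = segment_domains(sm, 0.25, -0.25)
        labels = [iv.name for iv in dom.intervals]
        assert labels == ["Late", "TTR", "Early"]

    def test_labels_partition_probe_span(self):
        rng = np.random.default_rng(4)
        sm = smooth_profile(prof(rng.standard_normal(500)), 500_000)
        dom = segment_domains(sm)
        ivs = sorted(dom.intervals, key=lambda iv: iv.start)
        assert ivs[0].start == 0
        assert ivs[-1].end == 500 * 10_000
        for a, b in zip(ivs, ivs[1:]):
            assert a.end == b.start

    def test_truth_domains_recovered_from_noisy_cohort(self):
        """Early/Late plateaus recovered at bp-level Jaccard >= 0.9, noise 0.25."""
        spec = SyntheticSpec(implants=[], seed=42)
        profiles, truth = make_rt_profiles(spec)
        normed = normalize_replicates(
            [profiles[("control", "t0", "r1")], profiles[("control", "t0", "r2")],
             profiles[("treated", "t0", "r1")], profiles[("treated", "t0", "r2")]]
        )
        mean = replace(normed[0], values=np.mean([p.values for p in normed], axis=0))
        dom = segment_domains(smooth_profile(mean, 500_000))
        assert jaccard(dom.to_region_set("Early"), truth.early) >= 0.9
        assert jaccard(dom.to_region_set("Late"), truth.late) >= 0.9


class TestCall:
    def make_cohort(self, delta=None, n=400, noise=0.1, seed=0):
        rng = np.random.default_rng(seed)
        grid = grid_1chrom(n)
        base = np.zeros(n)
        ctrl = [RTProfile(grid, base + rng.standard_normal(n) * noise, "control", "t0", f"r{i}") for i in range(2)]
        shift = np.zeros(n) if delta is None else delta
        trt = [RTProfile(grid, base + shift + rng.standard_normal(n) * noise, "treated", "t0", f"r{i}") for i in range(2)]
        return ctrl, trt

    def test_identical_conditions_give_empty_call_set(self):
        grid = grid_1chrom(400)
        rng = np.random.default_rng(1)
        vals = [rng.standard_normal(400) * 0.2 for _ in range(2)]
        ctrl = [RTProfile(grid, v, "control") for v in vals]
        trt = [RTProfile(grid, v.copy(), "treated") for v in vals]
        artil = call_differential(ctrl, trt)
        assert len(artil) == 0
        assert artil.percent_genome_impacted == 0.0

    def test_sign_flip_swaps_directions(self, default_cohort):
        artil = default_cohort["artil"]
        flipped = call_differential(
            [replace(p, values=-p.values) for p in default_cohort["normed_control"]],
            [replace(p, values=-p.values) for p in default_cohort["normed_treated"]],
        )
        got = {(r.chrom, r.start, r.end, r.direction) for r in flipped.regions}
        want = {
            (r.chrom, r.start, r.end, {"ADV": "DEL", "DEL": "ADV"}[r.direction])
            for r in artil.regions
        }
        assert got == want

    def test_single_implant_detected_as_one_adv_region(self):
        shift = np.zeros(400)
        shift[150:250] = 1.2  # 1 Mb implant on 10 kb probes
        ctrl, trt = self.make_cohort(delta=shift, noise=0.25, seed=5)
        artil = call_differential(ctrl, trt)
        adv = [r for r in artil.regions if r.direction == "ADV"]
        assert len(adv) == 1
        r = adv[0]
        ov = min(r.end, 250 * 10_000) - max(r.start, 150 * 10_000)
        assert ov >= 0.5 * (r.end - r.start)
        assert ov >= 0.5 * 1_000_000

    def test_fewer_than_two_replicates_rejected(self):
        ctrl, trt = self.make_cohort()
        with pytest.raises(ValueError, match=">=2 replicates"):
            call_differential(ctrl[:1], trt)

    def test_percent_recomputable_from_region_set(self, default_cohort):
        artil = default_cohort["artil"]
        recomputed = 100.0 * artil.to_region_set().total_bp / artil.probe_bp
        assert artil.percent_genome_impacted == pytest.approx(recomputed)

    def test_adv_regions_later_than_del_in_control(self, default_cohort):
        """Advances arise from late-replicating chromatin, delays from early."""
        artil = default_cohort["artil"]
        mean_ctrl = np.mean([p.values for p in default_cohort["normed_control"]], axis=0)
        grid = default_cohort["normed_control"][0].grid

        def mean_rt(direction):
            vals = []
            for r in artil.regions:
                if r.direction != direction:
                    continue
                sl = grid.slices[r.chrom]
                sel = (grid.midpoints[sl] >= r.start) & (grid.midpoints[sl] < r.end)
                vals.append(mean_ctrl[sl][sel].mean())
            return np.mean(vals)

        assert mean_rt("ADV") < mean_rt("DEL")

    def test_direction_amplitude_consistency_enforced(self):
        with pytest.raises(ValueError, match="ADV region"):
            ARTILSet([ARTILRegion("1", 0, 100, "ADV", -0.5, 0.01)], probe_bp=1000)


class TestTransmission:
    def artil(self, regions):
        return ARTILSet(regions, probe_bp=10_000_000)

    def test_daughter_equals_mother_all_transmitted(self):
        regions = [
            ARTILRegion("1", 0, 1_000_000, "ADV", 1.0, 1e-5),
            ARTILRegion("1", 2_000_000, 3_000_000, "DEL", -0.8, 1e-4),
        ]
        rep = assess_transmission(self.artil(regions), self.artil(regions))
        assert rep.n_transmitted == rep.n_total == 2
        np.testing.assert_allclose(rep.records["amplitude_ratio"], 1.0)

    def test_empty_daughter_transmits_nothing(self):
        regions = [ARTILRegion("1", 0, 1_000_000, "ADV", 1.0, 1e-5)]
        rep = assess_transmission(self.artil(regions), self.artil([]))
        assert rep.n_transmitted == 0
        assert rep.fraction == 0.0

    def test_direction_must_match(self):
        mother = [ARTILRegion("1", 0, 1_000_000, "ADV", 1.0, 1e-5)]
        daughter = [ARTILRegion("1", 0, 1_000_000, "DEL", -1.0, 1e-5)]
        rep = assess_transmission(self.artil(mother), self.artil(daughter))
        assert rep.n_transmitted == 0

    def test_reciprocal_threshold_respected(self):
        mother = [ARTILRegion("1", 0, 1_000_000, "ADV", 1.0, 1e-5)]
        small = [ARTILRegion("1", 0, 400_000, "ADV", 0.6, 1e-4)]
        assert assess_transmission(self.artil(mother), self.artil(small), 0.5).n_transmitted == 0
        assert assess_transmission(self.artil(mother), self.artil(small), 0.3).n_transmitted == 1

    def test_truth_level_recovery_on_noise_free_cohort(self):
        """Inherited fraction 0.5 of ADV implants recovered exactly without noise."""
        spec = SyntheticSpec(
            noise_sd=0.0, inherit_fraction=0.5,
            implants=[ImplantSpec("ADV", 1_000_000, 1.2, 8)], seed=42,
        )
        profiles, truth = make_rt_profiles(spec)

        def cohort(gen):
            reps = [profiles[(c, gen, f"r{i + 1}")] for c in ("control", "treated") for i in range(2)]
            normed = normalize_replicates(reps)
            return call_differential(normed[:2], normed[2:])

        mother, daughter = cohort("t0"), cohort("n1")
        mother_adv = ARTILSet([r for r in mother.regions if r.direction == "ADV"], mother.probe_bp)
        rep = assess_transmission(mother_adv, daughter)
        assert rep.n_total == 8
        assert rep.fraction == pytest.approx(0.5)
        ratios = rep.records.loc[rep.records.transmitted, "amplitude_ratio"]
        assert ((ratios > 0.4) & (ratios < 1.0)).all()  # reduced daughter amplitude
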