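"""Particle statistics: thresholding, labelling, size distribution,
fractional coverage, signal-to-background and the visual quantifications."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from raftpuncta import particle_analysis as pa
from raftpuncta import synthetic_data as sd
from raftpuncta.containers import FluorescenceImage, Particle, ParticleSet, ROI


def _img(arr):
    return FluorescenceImage(data=np.asarray(arr, dtype=float))


class TestThreshold:
    def test_fixed_above_constant_empty(self):
        img = _img(np.full((20, 20), 5.0))
        assert not pa.threshold_image(img, method="fixed", level=10.0).any()

    def test_fixed_below_max_full(self):
        img = _img(np.full((20, 20), 50.0))
        assert pa.threshold_image(img, method="fixed", level=10.0).all()

    def test_adaptive_matches_brute_force_local_mean(self, rng):
        data = rng.uniform(0, 100, size=(31, 31))
        img = _img(data)
        mask = pa.threshold_image(img, method="adaptive_local", window=5, offset=2.0)
        local = ndimage.uniform_filter(data, size=5, mode="reflect")
        np.testing.assert_array_equal(mask, data > local - 2.0)

    def test_adaptive_covers_blob_only(self):
        data = np.zeros((41, 41))
        data[18:23, 18:23] = 100.0
        mask = pa.threshold_image(
            _img(data), method="adaptive_local", window=15, offset=-10.0
        )
        assert mask[20, 20]
        assert not mask[2, 2]

    @pytest.mark.parametrize("window", [2, 1, -3])
    def test_invalid_window(self, window):
        with pytest.raises(ValueError):
            pa.threshold_image(_img(np.zeros((5, 5))), method="adaptive_local", window=window)


class TestLabelParticles:
    def test_diagonal_connectivity_definition(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        eight = pa.label_particles(mask, connectivity=8)
        four = pa.label_particles(mask, connectivity=4)
        assert eight.n_total == 1 and eight.particles[0].area == 2
        assert four.n_total == 2 and all(p.area == 1 for p in four.particles)

    def test_empty_mask(self):
        ps = pa.label_particles(np.zeros((10, 10), dtype=bool))
        assert ps.n_total == 0 and ps.c_total == 0

    def test_idempotent_on_own_output_mask(self):
        rng = np.random.default_rng(5)
        mask = rng.random((64, 64)) > 0.7
        first = pa.label_particles(mask, connectivity=8)
        # rebuild a mask from the labelled components and relabel
        relabelled = pa.label_particles(mask.copy(), connectivity=8)
        assert first.n_total == relabelled.n_total
        assert first.c_total == relabelled.c_total

    def test_count_monotone_in_min_area(self):
        rng = np.random.default_rng(6)
        mask = rng.random((64, 64)) > 0.6
        counts = [
            pa.label_particles(mask, min_area=a).n_total for a in (1, 2, 4, 8)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_round_trip_with_synthetic_field(self):
        fs = sd.generate_particle_field(200, min_separation=12.0, seed=11)
        img = sd.render_image(fs, psf_sigma=0.8, background=100.0)
        det = pa.label_particles(
            pa.threshold_image(img, method="fixed", level=500.0), min_area=3
        )
        assert det.n_total == 200


class TestSizeDistribution:
    def test_worked_example_count_fractions(self, worked_example_set):
        dist = pa.size_distribution(worked_example_set)
        frac = dist.counts / dist.n_total
        rep = dist.rep_areas
        assert frac[np.isclose(rep, 10.0)][0] == pytest.approx(0.8)
        assert frac[np.isclose(rep, 60.0)][0] == pytest.approx(0.2)

    def test_percent_sums_to_100(self, worked_example_set):
        dist = pa.size_distribution(worked_example_set)
        assert dist.percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_identical_areas_single_bin(self):
        ps = ParticleSet(
            particles=[Particle(x=5 + i, y=5.0, area=7.0) for i in range(10)],
            shape=(50, 50),
        )
        dist = pa.size_distribution(ps)
        assert (dist.counts > 0).sum() == 1
        assert dist.percent.max() == pytest.approx(100.0)

    def test_counts_match_brute_force_tally(self, rng):
        areas = rng.integers(1, 30, size=200).astype(float)
        ps = ParticleSet(
            particles=[
                Particle(x=float(i % 40) * 5 + 2, y=float(i // 40) * 5 + 2, area=a)
                for i, a in enumerate(areas)
            ],
            shape=(300, 300),
        )
        dist = pa.size_distribution(ps)
        for rep, count in zip(dist.rep_areas, dist.counts):
            assert count == np.sum(np.isclose(areas, rep))

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            pa.size_distribution(ParticleSet(particles=[], shape=(10, 10)))


class TestFractionalCoverage:
    def test_worked_example_few_large(self, worked_example_set):
        cov = pa.fractional_coverage(worked_example_set)
        rep = cov.rep_areas
        assert cov.coverage[np.isclose(rep, 10.0)][0] == pytest.approx(0.4)
        assert cov.coverage[np.isclose(rep, 60.0)][0] == pytest.approx(0.6)

    def test_worked_example_many_small(self, many_small_set):
        dist = pa.size_distribution(many_small_set)
        frac = dist.counts / dist.n_total
        cov = pa.fractional_coverage(many_small_set)
        rep = dist.rep_areas
        small = np.isclose(rep, 1.0)
        large = np.isclose(rep, 10.0)
        assert frac[small][0] == pytest.approx(0.94, abs=0.005)
        assert frac[large][0] == pytest.approx(0.06, abs=0.005)
        assert cov.coverage[small][0] == pytest.approx(0.6)
        assert cov.coverage[large][0] == pytest.approx(0.4)

    def test_single_particle_full_coverage(self):
        ps = ParticleSet(particles=[Particle(x=5.0, y=5.0, area=12.0)], shape=(20, 20))
        cov = pa.fractional_coverage(ps)
        assert cov.coverage.sum() == pytest.approx(1.0)
        assert cov.coverage.max() == pytest.approx(1.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=60))
    def test_coverage_sums_to_one_property(self, areas):
        ps = ParticleSet(
            particles=[
                Particle(x=2.0 + (i % 30) * 3, y=2.0 + (i // 30) * 3, area=float(a))
                for i, a in enumerate(areas)
            ],
            shape=(200, 200),
        )
        cov = pa.fractional_coverage(ps)
        assert cov.coverage.sum() == pytest.approx(1.0, abs=1e-9)
        dist = pa.size_distribution(ps)
        assert dist.percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_binned_equals_per_particle_sum_at_unit_bins(self, rng):
        areas = rng.integers(1, 20, size=100).astype(float)
        ps = ParticleSet(
            particles=[
                Particle(x=2.0 + (i % 30) * 3, y=2.0 + (i // 30) * 3, area=a)
                for i, a in enumerate(areas)
            ],
            shape=(120, 120),
        )
        cov = pa.fractional_coverage(ps)
        ct = areas.sum()
        for rep, f in zip(cov.rep_areas, cov.coverage):
            brute = areas[np.isclose(areas, rep)].sum() / ct
            assert f == pytest.approx(brute, abs=1e-12)


class TestSignalToBackground:
    def test_equal_regions_give_zero(self):
        img = _img(np.full((20, 40), 7.0))
        on = ROI("on_cell", 0, 0, 20, 20)
        off = ROI("off_cell", 0, 20, 20, 40)
        res = pa.signal_to_background(img, on, off)
        assert res.sb_minus_1 == pytest.approx(0.0)

    def test_doubled_signal_gives_one(self):
        data = np.full((20, 40), 3.0)
        data[:, :20] = 6.0
        res = pa.signal_to_background(
            _img(data), ROI("on_cell", 0, 0, 20, 20), ROI("off_cell", 0, 20, 20, 40)
        )
        assert res.sb_minus_1 == pytest.approx(1.0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, factor):
        rng = np.random.default_rng(0)
        data = rng.uniform(1, 50, size=(30, 30))
        on = ROI("on_cell", 0, 0, 15, 30)
        off = ROI("off_cell", 15, 0, 30, 30)
        a = pa.signal_to_background(_img(data), on, off)
        b = pa.signal_to_background(_img(data * factor), on, off)
        assert b.sb == pytest.approx(a.sb, rel=1e-9)

    def test_zero_background_raises(self):
        data = np.zeros((10, 20))
        data[:, :10] = 5.0
        with pytest.raises(ZeroDivisionError):
            pa.signal_to_background(
                _img(data), ROI("on_cell", 0, 0, 10, 10), ROI("off_cell", 0, 10, 10, 20)
            )


class TestPercentOfControl:
    def test_printed_means_give_23_percent(self):
        """Group means 0.10 (treated) vs 0.44 (control) → 23% of control."""
        res = pa.percent_of_control(treated=[0.10], control=[0.44])
        assert res.percent == 23

    def test_identical_groups(self):
        res = pa.percent_of_control(treated=[1.0, 2.0, 3.0], control=[1.0, 2.0, 3.0])
        assert res.percent == 100
        assert res.comparison.pvalue == pytest.approx(1.0)

    def test_zero_treated(self):
        res = pa.percent_of_control(treated=[0.0, 0.0], control=[0.5, 0.7])
        assert res.percent == 0

    def test_zero_control_raises(self):
        with pytest.raises(ZeroDivisionError):
            pa.percent_of_control(treated=[1.0], control=[0.0])

    def test_simulated_cleavage_images(self):
        """Eight simulated treated / control images built to (S/B)−1 means
        0.10 and 0.44 reproduce the 23%-of-control readout."""
        rng = np.random.default_rng(12)
        on = ROI("on_cell", 0, 0, 32, 32)
        off = ROI("off_cell", 0, 32, 32, 64)
        vals = {}
        for name, sb1_mean, sem_target in (("control", 0.44, 0.066), ("treated", 0.10, 0.0217)):
            scatter = rng.normal(0, sem_target * np.sqrt(8), size=8)
            scatter -= scatter.mean()
            group = []
            for offset in scatter:
                bg = rng.uniform(80, 120)
                data = np.full((32, 64), bg)
                data[:, :32] = bg * (1 + sb1_mean + offset)
                res = pa.signal_to_background(_img(data), on, off)
                group.append(res.sb_minus_1)
            vals[name] = group
        res = pa.percent_of_control(vals["treated"], vals["control"])
        assert res.percent == 23
        assert res.comparison.pvalue < 0.001


class TestBoxScanContour:
    def test_constant_image_flat_profile(self):
        img = _img(np.full((20, 30), 4.0))
        profile = pa.box_scan(img, ROI("box", 5, 5, 15, 25), axis="x")
        np.testing.assert_allclose(profile, 4.0)
        assert profile.size == 20

    def test_vertical_stripe_top_hat(self):
        data = np.zeros((20, 30))
        data[:, 10:20] = 9.0
        profile = pa.box_scan(_img(data), ROI("box", 0, 0, 20, 30), axis="x")
        assert np.all(profile[10:20] == 9.0)
        assert np.all(profile[:10] == 0.0)

    def test_profile_equals_brute_force_column_mean(self, rng):
        data = rng.uniform(0, 50, size=(25, 25))
        box = ROI("box", 3, 4, 20, 22)
        profile = pa.box_scan(_img(data), box, axis="x")
        np.testing.assert_allclose(profile, data[3:20, 4:22].mean(axis=0))

    def test_contour_constant_single_band(self):
        bands = pa.contour_map(_img(np.full((10, 10), 3.0)), n_levels=4)
        assert set(np.unique(bands)) == {0}

    def test_contour_linear_ramp_equal_bands(self):
        data = np.tile(np.linspace(0, 255, 256), (4, 1))
        bands = pa.contour_map(_img(data), n_levels=4)
        assert set(np.unique(bands)) == {0, 1, 2, 3}
        counts = np.bincount(bands.ravel())
        assert counts.max() - counts.min() <= 4  # equal-width bands

    def test_contour_matches_brute_force_floor(self, rng):
        data = rng.uniform(0, 1000, size=(15, 15))
        n_levels = 6
        bands = pa.contour_map(_img(data), n_levels=n_levels)
        scaled = (data - data.min()) / (data.max() - data.min()) * 255.0
        brute = np.minimum(
            np.floor(scaled / (255.0 / n_levels)).astype(int), n_levels - 1
        )
        np.testing.assert_array_equal(bands, brute)

    def test_contour_monotone_in_intensity(self, rng):
        data = rng.uniform(0, 100, size=(12, 12))
        bands = pa.contour_map(_img(data), n_levels=5)
        flat_i = data.ravel()
        flat_b = bands.ravel()
        order = np.argsort(flat_i)
        assert np.all(np.diff(flat_b[order]) >= 0)
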