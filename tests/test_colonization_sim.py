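"""Synthetic colonization: cell sampling, placement, trajectories, rendering."""

import numpy as np
import pytest
from scipy import stats

from wrinklebio.colonization_sim import (
    STRAINS,
    CellPlacement,
    CellSpec,
    ColonizationModel,
    coverage_trajectory,
    local_groove_direction,
    place_cells,
    render_afm,
    sample_cell,
    simulate_coverage_dataset,
)
from wrinklebio.surface_synthesis import SurfaceSpec, synth_surface


class TestSampleCell:
    def test_zero_sd_returns_means(self):
        spec = CellSpec("x", "rod", 0.7, 0.0, 1.7, 0.0, "-", 0.7, 2.5)
        assert sample_cell(spec, np.random.default_rng(0)) == (0.7, 1.7)

    def test_rod_sample_means_match_morphometrics(self):
        spec = STRAINS["P. aeruginosa"]
        rng = np.random.default_rng(1)
        draws = np.array([sample_cell(spec, rng) for _ in range(10_000)])
        se_a = spec.a_sd / 100.0
        se_b = spec.b_sd / 100.0
        assert abs(draws[:, 0].mean() - 0.7) < 2.5 * se_a
        assert abs(draws[:, 1].mean() - 1.7) < 2.5 * se_b
        assert draws[:, 1].mean() / draws[:, 0].mean() == pytest.approx(2.4, abs=0.1)
        assert np.all(draws[:, 1] >= draws[:, 0])

    def test_strain_table_aspect_ratios(self):
        assert STRAINS["P. aeruginosa"].aspect_ratio == pytest.approx(2.4, abs=0.05)
        assert STRAINS["E. coli K12"].aspect_ratio == pytest.approx(3.2, abs=0.05)
        assert STRAINS["S. aureus"].aspect_ratio == pytest.approx(1.1, abs=0.05)
        assert STRAINS["C. albicans"].aspect_ratio == pytest.approx(1.1, abs=0.05)


class TestGrooveDirection:
    def test_ns_grooves_give_zero(self, map_1d):
        for pt in [(5.0, 5.0), (10.3, 12.1), (15.0, 4.4)]:
            assert local_groove_direction(map_1d, pt) == pytest.approx(0.0, abs=1.0)

    def test_rotation_equivariance(self):
        hmap = synth_surface(SurfaceSpec("1D", orientation=-45.0), 256, 256, 20 / 256)
        assert local_groove_direction(hmap, (10.0, 10.0)) == pytest.approx(45.0, abs=2.0)

    def test_flat_is_isotropic(self, map_flat):
        assert local_groove_direction(map_flat, (10.0, 10.0)) is None

    def test_point_outside_field_rejected(self, map_1d):
        with pytest.raises(ValueError):
            local_groove_direction(map_1d, (25.0, 10.0))


class TestPlaceCells:
    def test_zero_target_empty(self, map_1d):
        model = ColonizationModel()
        assert place_cells(map_1d, STRAINS["P. aeruginosa"], model, 0.0, np.random.default_rng(0)) == []

    def test_infinite_affinity_fills_valleys_only(self, map_1d):
        model = ColonizationModel(valley_affinity=np.inf)
        pl = place_cells(map_1d, STRAINS["P. aeruginosa"], model, 8.0, np.random.default_rng(3))
        assert len(pl) > 10
        assert all(p.in_valley for p in pl)

    def test_uniform_angles_without_guidance(self, map_flat):
        big = synth_surface(SurfaceSpec("F"), 512, 512, 50 / 512)
        model = ColonizationModel(valley_affinity=1.0, guidance_strength=0.0)
        pl = place_cells(big, STRAINS["P. aeruginosa"], model, 20.0, np.random.default_rng(4))
        angles = np.array([p.angle for p in pl])
        assert len(angles) >= 500
        counts, _ = np.histogram(angles, bins=np.linspace(-90, 90, 10))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_valley_occupancy_monotone_in_affinity(self):
        hmap = synth_surface(SurfaceSpec("1D"), 256, 256, 40 / 256)
        fracs = []
        for aff in (1.0, 3.0, 10.0):
            model = ColonizationModel(valley_affinity=aff, guidance_strength=0.0)
            pl = place_cells(hmap, STRAINS["P. aeruginosa"], model, 17.0, np.random.default_rng(9))
            assert len(pl) >= 250
            fracs.append(np.mean([p.in_valley for p in pl]))
        assert fracs[0] < fracs[1] < fracs[2]

    def test_angle_concentration_monotone_in_guidance(self, map_1d):
        cvars = []
        for kappa in (0.0, 2.0, 8.0):
            model = ColonizationModel(guidance_strength=kappa)
            pl = place_cells(map_1d, STRAINS["E. coli K12"], model, 10.0, np.random.default_rng(11))
            th = np.radians([2 * p.angle for p in pl])
            cvars.append(1.0 - abs(np.exp(1j * th).mean()))
        assert cvars[0] > cvars[1] > cvars[2]

    def test_area_conservation(self, map_1d):
        model = ColonizationModel()
        target = 15.0
        pl = place_cells(map_1d, STRAINS["P. aeruginosa"], model, target, np.random.default_rng(6))
        cov = 100.0 * sum(p.area for p in pl) / map_1d.footprint_area
        assert cov == pytest.approx(target, abs=1.0)

    def test_no_pairwise_overlap(self, map_1d):
        from wrinklebio.colonization_sim import _ellipses_overlap

        model = ColonizationModel()
        pl = place_cells(map_1d, STRAINS["P. aeruginosa"], model, 12.0, np.random.default_rng(8))
        for i, p in enumerate(pl):
            for q in pl[i + 1 :]:
                assert not _ellipses_overlap(p, q)

    def test_seeded_reproducibility(self, map_1d):
        model = ColonizationModel()
        a = place_cells(map_1d, STRAINS["P. aeruginosa"], model, 10.0, np.random.default_rng(5))
        b = place_cells(map_1d, STRAINS["P. aeruginosa"], model, 10.0, np.random.default_rng(5))
        assert [(p.center, p.angle, p.a_eff, p.b_eff) for p in a] == [
            (p.center, p.angle, p.a_eff, p.b_eff) for p in b
        ]


class TestCoverageTrajectory:
    def test_zero_before_lag(self):
        model = ColonizationModel(rate_per_SA=5.0)
        cov = coverage_trajectory(model, 0.5, "C", [0.0, 1.0, 2.0])
        assert np.all(cov == 0.0)

    def test_linear_on_flat(self):
        model = ColonizationModel(rate_per_SA=5.0)
        t = np.array([0.0, 2.0, 4.0, 6.0])
        cov = coverage_trajectory(model, 1.0, "F", t)
        assert np.allclose(cov, 5.0 * t)

    def test_ratio_equals_sa_ratio_at_equal_post_lag_time(self):
        model = ColonizationModel(rate_per_SA=5.0)
        c1 = coverage_trajectory(model, 1.0, "F", [4.0])[0]
        c2 = coverage_trajectory(model, 0.5, "C", [6.0])[0]  # t - lag = 4 h
        assert c2 / c1 == pytest.approx(0.5)

    def test_ceiling_caps_growth(self):
        model = ColonizationModel(rate_per_SA=20.0, jamming_ceiling=55.0)
        assert coverage_trajectory(model, 1.0, "F", [10.0])[0] == 55.0

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError, match="unknown pattern"):
            coverage_trajectory(ColonizationModel(), 0.5, "Z", [1.0])

    def test_simulated_dataset_shape_and_noise(self):
        model = ColonizationModel(rate_per_SA=5.0, seed=0)
        df = simulate_coverage_dataset(model, {"F": 1.0, "C": 0.5}, replicates=3)
        assert len(df) == 2 * 4 * 3
        six = df[(df.pattern == "F") & (df.time_h == 6.0)]["coverage_pct"]
        assert six.std() > 0
        assert six.mean() == pytest.approx(30.0, rel=0.05)


class TestRenderAfm:
    def test_no_cells_no_noise_identity(self, map_1d):
        out = render_afm(map_1d, [])
        assert np.array_equal(out.values, map_1d.values)

    def test_sphere_height_is_half_diameter(self, map_flat):
        out = render_afm(map_flat, [CellPlacement((10.0, 10.0), 0.0, 0.8, 0.8)])
        assert out.values.max() == pytest.approx(0.4, abs=0.01)

    def test_tip_dilation_broadens_but_preserves_height(self, map_flat):
        cell = [CellPlacement((10.0, 10.0), 0.0, 0.8, 0.8)]
        sharp = render_afm(map_flat, cell)
        dilated = render_afm(map_flat, cell, tip_radius=0.1)
        assert dilated.values.max() == pytest.approx(sharp.values.max(), abs=0.01)
        assert (dilated.values > 0.05).sum() > (sharp.values > 0.05).sum()

    def test_render_deterministic_under_seed(self, map_1d):
        cell = [CellPlacement((10.0, 10.0), 0.0, 0.7, 1.7)]
        a = render_afm(map_1d, cell, noise_rms=0.01, rng=np.random.default_rng(3))
        b = render_afm(map_1d, cell, noise_rms=0.01, rng=np.random.default_rng(3))
        assert np.array_equal(a.values, b.values)
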