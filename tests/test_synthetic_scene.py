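"""Generator correctness: scaffolds, cells, rendering, sizing, calipers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from implantquant import (
    CaliperSeriesConfig,
    SceneConfig,
    fold_change,
    generate_caliper_series,
    generate_cells,
    generate_scaffold,
    grid_particles,
    make_roi_mask,
    measure_particles,
    render_scene,
    sample_diameters,
)


SMALL_ROI = {"kind": "disk", "radius_um": 300.0}


class TestScaffold:
    def test_heparin_flag_count_is_exact(self):
        cfg = SceneConfig(seed=2, n_particles=100, heparin_fraction=0.10)
        particles = generate_scaffold(cfg)
        assert len(particles) == 100
        assert particles.heparin.sum() == 10

    def test_zero_heparin_fraction_flags_none(self):
        cfg = SceneConfig(seed=2, n_particles=25, heparin_fraction=0.0,
                          image_size_px=(384, 384), roi_shape=SMALL_ROI)
        assert generate_scaffold(cfg).heparin.sum() == 0

    def test_no_two_particles_overlap(self):
        cfg = SceneConfig(seed=3, n_particles=25, image_size_px=(384, 384),
                          roi_shape=SMALL_ROI)
        p = generate_scaffold(cfg)
        d = np.hypot(
            p.centers_um[:, None, 0] - p.centers_um[None, :, 0],
            p.centers_um[:, None, 1] - p.centers_um[None, :, 1],
        )
        radii = p.diameters_um / 2
        min_allowed = radii[:, None] + radii[None, :]
        off_diag = ~np.eye(len(p), dtype=bool)
        assert (d[off_diag] >= min_allowed[off_diag] - 1e-9).all()

    def test_particles_lie_inside_roi(self):
        cfg = SceneConfig(seed=3, n_particles=25, image_size_px=(384, 384),
                          roi_shape=SMALL_ROI)
        roi = make_roi_mask(cfg)
        p = generate_scaffold(cfg, roi)
        depth = roi.depth_map()
        px = roi.pixel_size_um
        cols = np.floor(p.centers_um[:, 0] / px).astype(int)
        rows = np.floor(p.centers_um[:, 1] / px).astype(int)
        assert (depth[rows, cols] >= p.diameters_um / 2 - px).all()

    def test_sampled_diameters_match_configured_mean(self):
        # law-of-large-numbers bound: |mean - mu| < 3 sd / sqrt(n)
        rng = np.random.default_rng(42)
        d = sample_diameters(500, 69.7, 2.25, rng)
        assert abs(d.mean() - 69.7) < 3 * 2.25 / np.sqrt(500)
        assert (d > 0).all()

    def test_packing_failure_reports_achieved_count(self):
        cfg = SceneConfig(seed=1, n_particles=500, image_size_px=(256, 256),
                          roi_shape={"kind": "disk", "radius_um": 200.0})
        with pytest.raises(RuntimeError, match=r"\d+/500"):
            generate_scaffold(cfg, max_attempts_per_particle=20)


class TestCells:
    def test_uniform_intensity_gives_poisson_count(self):
        # slope=0: expected count is density * area, observed within 4 sigma
        lam = 800.0
        cfg = SceneConfig(image_size_px=(500, 500), pixel_size_um=2.0,
                          roi_shape={"kind": "disk", "radius_um": 400.0},
                          cell_density_intercept=lam, cell_density_slope=0.0,
                          min_spacing_um=0.0, seed=4)
        roi = make_roi_mask(cfg)
        truth = generate_cells(cfg, roi)
        expected = lam * roi.area_mm2
        assert abs(len(truth) - expected) < 4 * np.sqrt(expected)

    def test_pure_class_gets_its_marker_always(self):
        cfg = SceneConfig(image_size_px=(384, 384), roi_shape=SMALL_ROI,
                          class_fractions={"macrophage": 1.0},
                          marker_probs={"CD68": {"macrophage": 1.0}}, seed=6)
        truth = generate_cells(cfg)
        assert len(truth) > 0
        assert truth.flags("CD68").all()

    def test_negative_slope_pulls_cells_toward_edge(self):
        # mean depth under a decreasing gradient < mean depth of uniform
        base = dict(image_size_px=(384, 384), roi_shape=SMALL_ROI,
                    min_spacing_um=0.0, seed=8)
        graded = generate_cells(SceneConfig(
            cell_density_intercept=1200, cell_density_slope=-3.0, **base))
        uniform = generate_cells(SceneConfig(
            cell_density_intercept=1200, cell_density_slope=0.0, **base))
        assert graded.table.depth_um.mean() < uniform.table.depth_um.mean()

    def test_negative_density_anywhere_is_an_error(self):
        cfg = SceneConfig(image_size_px=(384, 384), roi_shape=SMALL_ROI,
                          cell_density_intercept=100.0, cell_density_slope=-2.0)
        with pytest.raises(ValueError, match="negative"):
            generate_cells(cfg)

    def test_cells_inside_roi_with_consistent_depth(self):
        cfg = SceneConfig(image_size_px=(384, 384), roi_shape=SMALL_ROI, seed=9)
        roi = make_roi_mask(cfg)
        truth = generate_cells(cfg, roi)
        px = roi.pixel_size_um
        cols = np.floor(truth.table.x_um / px).astype(int)
        rows = np.floor(truth.table.y_um / px).astype(int)
        assert roi.mask[rows, cols].all()
        depth = roi.depth_map()
        assert np.allclose(truth.table.depth_um, depth[rows, cols], atol=px)

    def test_generator_is_reproducible(self):
        cfg = SceneConfig(image_size_px=(384, 384), roi_shape=SMALL_ROI, seed=12)
        a = generate_cells(cfg).table
        b = generate_cells(cfg).table
        pd.testing.assert_frame_equal(a, b)

    def test_marker_frequencies_match_probabilities(self):
        # chi-square goodness of fit on flags at n ~ 5000, fixed seed
        cfg = SceneConfig(
            image_size_px=(900, 900), pixel_size_um=2.0,
            roi_shape={"kind": "disk", "radius_um": 850.0},
            cell_density_intercept=2200.0, cell_density_slope=0.0,
            min_spacing_um=0.0, seed=13,
        )
        truth = generate_cells(cfg)
        assert len(truth) > 4000
        mac = truth.table.phenotype == "macrophage"
        n = int(mac.sum())
        for marker, p in [("CD68", 1.0), ("iNOS", 0.5), ("Arg1", 0.4)]:
            k = int(truth.flags(marker)[mac.to_numpy()].sum())
            if p == 1.0:
                assert k == n
            else:
                assert stats.binomtest(k, n, p).pvalue > 1e-4


class TestRender:
    def test_empty_truth_renders_background_stats(self):
        cfg = SceneConfig(image_size_px=(256, 256), roi_shape=SMALL_ROI,
                          cell_density_intercept=0.0, cell_density_slope=0.0,
                          roi_fill_level=0.0, seed=3)
        truth = generate_cells(cfg)
        assert len(truth) == 0
        img = render_scene(truth, cfg)
        dapi = img.channel("DAPI")
        assert abs(dapi.mean() - cfg.background_level) < 3 * cfg.noise_sd / 256
        assert abs(dapi.std() - cfg.noise_sd) < 0.1 * cfg.noise_sd

    def test_marker_peak_coincides_with_dapi_peak(self):
        cfg = SceneConfig(image_size_px=(128, 128), pixel_size_um=2.0,
                          roi_shape={"kind": "disk", "radius_um": 100.0},
                          marker_offset_sd_um=0.0, noise_sd=0.0, seed=1)
        roi = make_roi_mask(cfg)
        table = pd.DataFrame(
            {"x_um": [128.0], "y_um": [128.0], "depth_um": [50.0],
             "phenotype": ["macrophage"],
             **{f"flag_{m}": [m == "CD68"] for m in cfg.markers}}
        )
        from implantquant import GroundTruth

        img = render_scene(GroundTruth(table, roi), cfg)
        p_dapi = np.unravel_index(np.argmax(img.channel("DAPI")), img.shape)
        p_cd68 = np.unravel_index(np.argmax(img.channel("CD68")), img.shape)
        assert abs(p_dapi[0] - p_cd68[0]) <= 1 and abs(p_dapi[1] - p_cd68[1]) <= 1


class TestMeasureParticles:
    def test_single_disk_diameter_within_pixelation_bound(self):
        p = grid_particles(np.array([70.0]))
        out = measure_particles(p, 1.0)
        assert len(out) == 1
        assert abs(out.diameter_um.iloc[0] - 70.0) < 1.0

    def test_empty_set_gives_empty_table(self):
        p = grid_particles(np.empty(0))
        assert measure_particles(p, 1.0).empty

    def test_mean_recovered_diameter_matches_heparin_formulation(self):
        rng = np.random.default_rng(20)
        d = sample_diameters(500, *SceneConfig().particle_size_um["heparin"], rng)
        out = measure_particles(grid_particles(d), 1.0)
        assert abs(out.diameter_um.mean() - 69.7) < 0.5

    def test_touching_particles_raise_naming_pair(self):
        from implantquant import ParticleSet

        p = ParticleSet(np.array([[100.0, 100.0], [160.0, 100.0]]),
                        np.array([70.0, 70.0]), np.zeros(2, bool))
        with pytest.raises(ValueError, match="merged"):
            measure_particles(p, 1.0)


class TestCalipers:
    def test_zero_noise_fold_is_exact(self):
        cfg = CaliperSeriesConfig(noise_cv=0.0, seed=3)
        folds = fold_change(generate_caliper_series(cfg))
        at12 = folds[folds.timepoint == 12]
        assert np.allclose(at12.volume_fold, 0.45)
        assert np.allclose(at12.height_fold, 0.55)

    def test_default_decay_gives_55_percent_decrease(self):
        cfg = CaliperSeriesConfig(noise_cv=0.05, seed=3)
        folds = fold_change(generate_caliper_series(cfg))
        at12 = folds[folds.timepoint == 12]
        pct = 100 * (1 - at12.volume_fold.mean())
        assert abs(pct - 55.0) < 5.0

    def test_unit_height_fold_preserves_height(self):
        cfg = CaliperSeriesConfig(
            timepoints=(0, 1), noise_cv=0.0,
            volume_fold_by_time={0: 1.0, 1: 0.9},
            height_fold_by_time={0: 1.0, 1: 1.0}, seed=4,
        )
        folds = fold_change(generate_caliper_series(cfg))
        assert np.allclose(folds[folds.timepoint == 1].height_fold, 1.0)

    def test_missing_timepoint_zero_rejected(self):
        with pytest.raises(ValueError, match="timepoint 0"):
            CaliperSeriesConfig(timepoints=(1, 12))
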