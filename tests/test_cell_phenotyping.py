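"""Spot detection, deduplication, and the proximity-rule cascade."""

import numpy as np
import pytest

from implantquant import (
    BinaryStainMask,
    SpotSet,
    assign_by_proximity,
    assign_by_surface,
    deduplicate_spots,
    detect_spots,
    ki67_fraction,
    phenotype_image,
)
from implantquant.cell_phenotyping import nearest_marker_distance


def spots(coords, intensities=None, channel=""):
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    if intensities is None:
        intensities = np.ones(len(coords))
    return SpotSet(coords[:, 0], coords[:, 1], np.asarray(intensities, float), channel)


class TestDetectSpots:
    def test_blank_channel_yields_no_spots(self):
        img = np.full((100, 100), 0.1)
        assert len(detect_spots(img, 1.0, sigma_um=3.0, min_prominence=0.2)) == 0

    def test_two_separated_blobs_give_two_spots(self):
        yy, xx = np.mgrid[0:100, 0:100]
        img = (np.exp(-((xx - 30) ** 2 + (yy - 50) ** 2) / (2 * 9))
               + np.exp(-((xx - 50) ** 2 + (yy - 50) ** 2) / (2 * 9)))
        det = detect_spots(img, 1.0, sigma_um=3.0, min_prominence=0.3)
        assert len(det) == 2
        xs = np.sort(det.x)
        assert abs(xs[0] - 30.5) < 1.0 and abs(xs[1] - 50.5) < 1.0

    def test_recovers_true_cells_on_rendered_scene(self, small_scene):
        cfg, roi, truth, image = small_scene
        det = detect_spots(image.channel("DAPI"), cfg.pixel_size_um,
                           cfg.blob_sigma_um, min_prominence=0.3)
        pos = truth.positions()
        d = nearest_marker_distance(
            spots(pos), SpotSet(det.x, det.y, det.intensity))
        assert np.mean(d <= 3.0) >= 0.95
        # spurious detections: detections with no true cell within 3 um
        d_back = nearest_marker_distance(det, spots(pos))
        assert np.mean(d_back > 3.0) <= 0.05


class TestDeduplicate:
    def test_greedy_keeps_strongest_then_distant(self):
        s = spots([(0, 0), (5, 0), (20, 0)], [10, 8, 5])
        kept = deduplicate_spots(s, 8.0)
        assert sorted(zip(kept.x, kept.y)) == [(0.0, 0.0), (20.0, 0.0)]

    def test_well_separated_spots_all_kept(self):
        s = spots([(0, 0), (10, 0), (0, 10)], [3, 2, 1])
        assert len(deduplicate_spots(s, 8.0)) == 3

    def test_zero_separation_is_identity(self):
        s = spots([(0, 0), (0.1, 0)], [2, 1])
        assert len(deduplicate_spots(s, 0.0)) == 2

    def test_output_independent_of_input_order(self):
        rng = np.random.default_rng(7)
        xy = rng.uniform(0, 100, size=(60, 2))
        inten = rng.uniform(1, 10, size=60)  # distinct almost surely
        a = deduplicate_spots(SpotSet(xy[:, 0], xy[:, 1], inten), 8.0)
        perm = rng.permutation(60)
        b = deduplicate_spots(SpotSet(xy[perm, 0], xy[perm, 1], inten[perm]), 8.0)
        assert sorted(zip(a.x, a.y)) == sorted(zip(b.x, b.y))

    def test_kept_spots_respect_min_separation(self):
        rng = np.random.default_rng(8)
        xy = rng.uniform(0, 60, size=(150, 2))
        kept = deduplicate_spots(SpotSet(xy[:, 0], xy[:, 1],
                                         rng.uniform(size=150)), 8.0)
        d = np.hypot(kept.x[:, None] - kept.x[None, :],
                     kept.y[:, None] - kept.y[None, :])
        off = ~np.eye(len(kept), dtype=bool)
        assert (d[off] >= 8.0).all()

    def test_matches_brute_force_greedy_oracle(self):
        def oracle(xy, inten, sep):
            order = np.lexsort((xy[:, 1], xy[:, 0], -inten))
            kept = []
            for i in order:
                if all(np.hypot(*(xy[i] - xy[j])) >= sep for j in kept):
                    kept.append(i)
            return sorted(kept)

        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(5, 80))
            xy = rng.uniform(0, 50, size=(n, 2))
            inten = rng.uniform(1, 5, size=n)
            got = deduplicate_spots(SpotSet(xy[:, 0], xy[:, 1], inten), 6.0)
            want = oracle(xy, inten, 6.0)
            assert sorted(zip(got.x, got.y)) == sorted(map(tuple, xy[want]))


class TestProximityRules:
    def test_flags_only_cells_near_marker(self):
        cells = spots([(0, 0), (20, 0)])
        markers = spots([(21, 0)])
        flags = assign_by_proximity(cells, markers, 8.0)
        assert list(flags) == [False, True]

    def test_empty_marker_set_flags_nothing(self):
        cells = spots([(0, 0), (5, 5)])
        flags = assign_by_proximity(cells, spots(np.empty((0, 2))), 8.0)
        assert not flags.any()

    def test_marker_exactly_at_cutoff_not_flagged(self):
        cells = spots([(0, 0)])
        assert not assign_by_proximity(cells, spots([(8.0, 0)]), 8.0).any()
        assert assign_by_proximity(cells, spots([(7.999, 0)]), 8.0).all()

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(11)
        cells_xy = rng.uniform(0, 200, size=(300, 2))
        marks_xy = rng.uniform(0, 200, size=(150, 2))
        cells = spots(cells_xy)
        marks = spots(marks_xy)
        flags = assign_by_proximity(cells, marks, 10.0)
        d = np.hypot(cells_xy[:, None, 0] - marks_xy[None, :, 0],
                     cells_xy[:, None, 1] - marks_xy[None, :, 1])
        assert (flags == (d.min(axis=1) < 10.0)).all()

    def test_enlarging_distance_never_unflags(self):
        rng = np.random.default_rng(12)
        cells = spots(rng.uniform(0, 100, size=(100, 2)))
        marks = spots(rng.uniform(0, 100, size=(40, 2)))
        prev = np.zeros(100, dtype=bool)
        for dist in (2.0, 5.0, 10.0, 25.0):
            flags = assign_by_proximity(cells, marks, dist)
            assert (flags | ~prev).all() and flags.sum() >= prev.sum()
            prev = flags


class TestSurfaceRule:
    def _rect_mask(self):
        # positive pixels cover x in [10, 20) um, y in [10, 30) um at 1 um/px
        m = np.zeros((40, 40), dtype=bool)
        m[10:30, 10:20] = True
        return BinaryStainMask(m, "TE7", 1.0)

    def test_cell_near_edge_flagged_far_cell_not(self):
        mask = self._rect_mask()
        near = spots([(21.5, 20.0)])  # 1.5 um from the region's right edge
        far = spots([(25.0, 20.0)])
        assert assign_by_surface(near, mask, 2.0).all()
        assert not assign_by_surface(far, mask, 2.0).any()

    def test_cell_inside_surface_flagged(self):
        assert assign_by_surface(spots([(15.0, 15.0)]), self._rect_mask(), 2.0).all()

    def test_empty_surface_flags_nothing(self):
        empty = BinaryStainMask(np.zeros((40, 40), bool), "TE7", 1.0)
        assert not assign_by_surface(spots([(15.0, 15.0)]), empty, 2.0).any()


class TestKi67:
    def test_coincident_spots_give_fraction_one(self):
        cells = spots([(0, 0), (30, 30)])
        assert ki67_fraction(cells, cells, 4.0) == 1.0

    def test_no_ki67_spots_give_zero(self):
        cells = spots([(0, 0), (30, 30)])
        assert ki67_fraction(cells, spots(np.empty((0, 2))), 4.0) == 0.0

    def test_no_cells_is_an_error(self):
        with pytest.raises(ValueError):
            ki67_fraction(spots(np.empty((0, 2))), spots([(0, 0)]), 4.0)


class TestPhenotypeImage:
    def test_recovers_configured_class_fractions(self, default_scene):
        cfg, roi, truth, image = default_scene
        counts = phenotype_image(image, roi)
        fr = counts.fractions()
        assert abs(fr["macrophage"] - truth.class_fraction("macrophage")) <= 0.05
        assert abs(fr["tcell"] - truth.class_fraction("tcell")) <= 0.05
        assert abs(fr["fibroblast"] - truth.class_fraction("fibroblast")) <= 0.05
        assert abs(fr["ki67"] - 0.2) <= 0.05

    def test_subclass_counts_bounded_by_parents(self, default_scene):
        cfg, roi, truth, image = default_scene
        c = phenotype_image(image, roi)
        assert c.n_m1 <= c.n_macrophage <= c.n_cells
        assert c.n_m2 <= c.n_macrophage
        assert c.n_thelper <= c.n_tcell <= c.n_cells

    def test_missing_channel_error_names_it(self, small_scene):
        cfg, roi, truth, image = small_scene
        from implantquant import MultiplexImage

        partial = MultiplexImage(
            {k: v for k, v in image.channels.items() if k != "Arg1"},
            image.pixel_size_um, image.meta,
        )
        with pytest.raises(KeyError, match="Arg1"):
            phenotype_image(partial, roi)

    def test_pure_m2_macrophage_scene(self):
        from implantquant import SceneConfig, generate_cells, make_roi_mask, render_scene

        cfg = SceneConfig(
            image_size_px=(384, 384),
            roi_shape={"kind": "disk", "radius_um": 300.0},
            class_fractions={"macrophage": 1.0},
            marker_probs={
                "CD68": {"macrophage": 1.0}, "Arg1": {"macrophage": 1.0},
                "iNOS": {}, "CD3e": {}, "CD4": {}, "TE7": {}, "Ki67": {},
            },
            seed=21,
        )
        roi = make_roi_mask(cfg)
        truth = generate_cells(cfg, roi)
        image = render_scene(truth, cfg)
        c = phenotype_image(image, roi)
        assert c.n_cells > 0
        assert c.n_m2 / max(c.n_macrophage, 1) > 0.95
        assert c.n_m1 == 0
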