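import numpy as np
import pytest

import sbfquant as sq
from sbfquant.polarity import line_voxels

SP = sq.VoxelSpacing(150.0, 150.0, 300.0)


def axis_at(centroid_um, direction, lid=1, degenerate=False):
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return sq.PrincipalAxis(lid, tuple(centroid_um), tuple(d), (1.0, 0.5, 0.1),
                            degenerate=degenerate)


def brute_force_footprint(axis, params, dims, spacing):
    """Oracle: per-voxel point-line distance over the whole grid, loops only."""
    c = np.asarray(axis.centroid_um)
    a = np.asarray(axis.direction)
    out = np.zeros(dims, dtype=np.float64)
    sp = spacing.as_um
    for ix in range(dims[0]):
        for iy in range(dims[1]):
            for iz in range(dims[2]):
                p = (np.array([ix, iy, iz]) + 0.5) * sp
                rel = p - c
                d = np.linalg.norm(rel - np.dot(rel, a) * a)
                if d < params.radius_um:
                    out[ix, iy, iz] = 1.0 - d / params.radius_um
    return out


class TestRayFootprint:
    def test_voxel_centre_on_axis_has_intensity_one(self):
        # axis along x through the centre of voxel row iy=4, iz=2
        c = (np.array([10, 4, 2]) + 0.5) * SP.as_um
        fp = sq.ray_footprint(axis_at(c, (1, 0, 0)), sq.RayParams(radius_um=2.0),
                              (20, 9, 5), SP)
        np.testing.assert_allclose(fp[:, 4, 2], 1.0, atol=1e-6)

    def test_linear_falloff_at_half_radius_and_beyond(self):
        c = (np.array([10, 4, 2]) + 0.5) * SP.as_um
        radius = 2.0
        fp = sq.ray_footprint(axis_at(c, (1, 0, 0)), sq.RayParams(radius_um=radius),
                              (20, 40, 5), SP)
        # voxel displaced laterally by d = radius/2 along y (dy = 0.15 um)
        offset = int(round(radius / 2 / 0.15))
        d = offset * 0.15
        np.testing.assert_allclose(fp[:, 4 + offset, 2], 1.0 - d / radius, atol=1e-5)
        far = int(np.ceil(radius / 0.15))
        assert not fp[:, 4 + far:, 2].any()

    def test_matches_brute_force_and_point_symmetry(self):
        dims = (12, 10, 8)
        c = np.array(dims) * SP.as_um / 2  # centroid at grid centre
        params = sq.RayParams(radius_um=1.5)
        ax = axis_at(c, (1, 0, 0))
        fp = sq.ray_footprint(ax, params, dims, SP)
        oracle = brute_force_footprint(ax, params, dims, SP)
        np.testing.assert_allclose(fp, oracle, atol=1e-5)
        # point reflection through the centroid maps the footprint onto itself
        np.testing.assert_allclose(fp, fp[::-1, ::-1, ::-1], atol=1e-5)

    def test_degenerate_axis_skipped_with_warning(self):
        c = np.array([1.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="ambiguous"):
            fp = sq.ray_footprint(axis_at(c, (1, 0, 0), degenerate=True),
                                  sq.RayParams(radius_um=2.0), (8, 8, 8), SP)
        assert not fp.any()

    def test_line_voxels_traverse_grid(self):
        c = (np.array([10, 4, 2]) + 0.5) * SP.as_um
        vox = line_voxels(axis_at(c, (1, 0, 0)), (20, 9, 5), SP)
        assert vox.shape[0] == 20
        assert set(vox[:, 0]) == set(range(20))
        assert (vox[:, 1] == 4).all() and (vox[:, 2] == 2).all()


class TestAccumulation:
    def test_single_cell_map_equals_footprint(self):
        c = np.array([1.5, 0.7, 0.75])
        params = sq.RayParams(radius_um=1.0)
        fp = sq.ray_footprint(axis_at(c, (1, 0, 0)), params, (20, 9, 5), SP)
        acc = sq.accumulate_rays([fp])
        np.testing.assert_array_equal(acc, fp)
        assert acc.max() <= 1.0 + 1e-6

    def test_collinear_rays_add_to_two(self):
        params = sq.RayParams(radius_um=1.0)
        c1 = (np.array([5, 4, 2]) + 0.5) * SP.as_um
        c2 = (np.array([15, 4, 2]) + 0.5) * SP.as_um
        fps = [sq.ray_footprint(axis_at(c, (1, 0, 0), lid=i), params, (20, 9, 5), SP)
               for i, c in enumerate([c1, c2])]
        acc = sq.accumulate_rays(fps)
        np.testing.assert_allclose(acc[:, 4, 2], 2.0, atol=1e-5)

    def test_map_bounded_by_cell_count_and_order_invariant(self):
        rng = np.random.default_rng(0)
        params = sq.RayParams(radius_um=2.0)
        dims = (24, 24, 12)
        axes = [axis_at(rng.uniform(0, 3, 3), rng.standard_normal(3), lid=i)
                for i in range(5)]
        acc = sq.accumulation_map(axes, dims, SP, params)
        acc_rev = sq.accumulation_map(axes[::-1], dims, SP, params)
        assert acc.max() <= 5 + 1e-5
        np.testing.assert_allclose(acc, acc_rev, atol=1e-5)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="match"):
            sq.accumulate_rays([np.zeros((4, 4, 4)), np.zeros((4, 4, 5))])


class TestHotspot:
    def test_all_below_threshold_empty(self):
        assert not sq.extract_hotspot(np.zeros((5, 5, 5)), 3.5).any()

    def test_single_blob_returned(self):
        acc = np.zeros((10, 10, 5), dtype=np.float32)
        acc[2:5, 2:5, 1:3] = 4.0
        hs = sq.extract_hotspot(acc, 3.5)
        np.testing.assert_array_equal(hs, acc > 3.5)

    def test_largest_of_two_blobs_wins(self):
        acc = np.zeros((20, 10, 5), dtype=np.float32)
        acc[1:3, 1:3, 1:3] = 4.0   # 8 voxels
        acc[10:14, 1:3, 1:3] = 4.0  # 16 voxels
        hs = sq.extract_hotspot(acc, 3.5)
        assert hs[11, 1, 1] and not hs[1, 1, 1]
        assert hs.sum() == 16

    def test_threshold_strict(self):
        acc = np.full((4, 4, 4), 3.5, dtype=np.float32)
        assert not sq.extract_hotspot(acc, 3.5).any()


class TestClassifyPolarized:
    def test_empty_hotspot_no_cells(self):
        axes = [axis_at((1, 1, 1), (1, 0, 0))]
        out = sq.classify_polarized(axes, np.zeros((8, 8, 8), dtype=bool),
                                    sq.RayParams(radius_um=2.0), SP)
        assert out == set()

    def test_axis_through_hotspot_voxel_centre_is_polarized(self):
        hs = np.zeros((20, 9, 5), dtype=bool)
        hs[15, 4, 2] = True
        c = (np.array([2, 4, 2]) + 0.5) * SP.as_um
        out = sq.classify_polarized([axis_at(c, (1, 0, 0), lid=7)], hs,
                                    sq.RayParams(radius_um=2.0), SP)
        assert out == {7}

    def test_distant_cell_not_polarized(self):
        hs = np.zeros((20, 40, 5), dtype=bool)
        hs[15, 4, 2] = True
        c = (np.array([2, 30, 2]) + 0.5) * SP.as_um  # 26 px ~ 3.9 um away laterally
        out = sq.classify_polarized([axis_at(c, (1, 0, 0), lid=7)], hs,
                                    sq.RayParams(radius_um=2.0), SP)
        assert out == set()


class TestSceneRecovery:
    def test_hotspot_scene_precision_recall(self):
        """Aimed subset recovered from a convergent scene at tau=3.5."""
        H = (19.2, 19.2, 9.6)
        cfg = sq.SceneConfig(n_cells=40, seed=2, mito_per_cell=(0, 0),
                             orientation_model=sq.Hotspot(point_um=H, fraction=15 / 40,
                                                          sigma_deg=5))
        scene = sq.generate_scene(cfg)
        axes = sq.axes_from_labels(scene.labels, scene.segments, "cell")
        res = sq.run_polarity(axes, scene.labels.dims, scene.labels.spacing,
                              sq.RayParams(radius_um=2.5, threshold=3.5))
        truth = set(scene.truth.cells[scene.truth.cells.polarized].cell_id)
        tp = len(res.polarized_ids & truth)
        assert tp / max(len(res.polarized_ids), 1) >= 0.8
        assert tp / len(truth) >= 0.8
        centroid = (np.argwhere(res.hotspot_mask).mean(0) + 0.5) * scene.labels.spacing.as_um
        assert np.linalg.norm(centroid - np.array(H)) <= 2 * 2.5

    def test_isotropic_scene_rarely_exceeds_threshold(self):
        """Without convergence, the accumulation rarely reaches tau=3.5."""
        exceed = 0
        n_seeds = 5
        for seed in range(n_seeds):
            cfg = sq.SceneConfig(n_cells=20, seed=100 + seed, mito_per_cell=(0, 0))
            scene = sq.generate_scene(cfg)
            axes = sq.axes_from_labels(scene.labels, scene.segments, "cell")
            acc = sq.accumulation_map(axes, scene.labels.dims, scene.labels.spacing,
                                      sq.RayParams(radius_um=2.5))
            exceed += acc.max() > 3.5
        assert exceed <= 1  # <= 20% of seeds
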