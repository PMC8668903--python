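import numpy as np
import pytest
from scipy.ndimage import binary_dilation
from scipy.stats import spearmanr

import sbfquant as sq

SP = sq.VoxelSpacing(150.0, 150.0, 300.0)
SP15 = sq.VoxelSpacing(15.0, 15.0, 100.0)


def brute_force_dmap(capillary_mask, spacing):
    """O(N^2) oracle: min distance over all (query, capillary) voxel-centre pairs."""
    sp = spacing.as_um
    cap = np.argwhere(capillary_mask) * sp
    out = np.empty(capillary_mask.shape)
    for idx in np.ndindex(capillary_mask.shape):
        p = np.array(idx) * sp
        out[idx] = np.sqrt(((cap - p) ** 2).sum(1)).min()
    return out


class TestDistanceMap:
    def test_axis_aligned_wall_distance(self):
        mask = np.zeros((16, 4, 4), dtype=bool)
        mask[0, :, :] = True  # full x=0 wall
        dmap = sq.capillary_distance_map(mask, SP)
        assert dmap[10, 2, 2] == pytest.approx(10 * 0.15)

    def test_zero_on_capillary_voxels(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[3, 4, 5] = True
        dmap = sq.capillary_distance_map(mask, SP)
        assert dmap[3, 4, 5] == 0.0

    def test_matches_brute_force_on_random_grid(self):
        rng = np.random.default_rng(4)
        mask = rng.random((20, 20, 20)) < 0.02
        mask[0, 0, 0] = True  # ensure nonempty
        dmap = sq.capillary_distance_map(mask, SP)
        np.testing.assert_allclose(dmap, brute_force_dmap(mask, SP), atol=1e-6)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sq.capillary_distance_map(np.zeros((4, 4, 4), dtype=bool), SP)

    def test_translation_equivariance(self):
        mask = np.zeros((24, 16, 8), dtype=bool)
        mask[4:6, 4:6, 2:4] = True
        d1 = sq.capillary_distance_map(mask, SP)
        d2 = sq.capillary_distance_map(np.roll(mask, 5, axis=0), SP)
        np.testing.assert_allclose(d2[9:, :, :], d1[4:-5, :, :], atol=1e-9)

    def test_monotone_under_dilation(self):
        rng = np.random.default_rng(6)
        mask = rng.random((12, 12, 8)) < 0.05
        mask[5, 5, 3] = True
        d1 = sq.capillary_distance_map(mask, SP)
        d2 = sq.capillary_distance_map(binary_dilation(mask), SP)
        assert (d2 <= d1 + 1e-12).all()


class TestStructureDistance:
    def test_adjacent_structure_one_step(self):
        cap = np.zeros((16, 8, 8), dtype=bool)
        cap[0, :, :] = True
        dmap = sq.capillary_distance_map(cap, SP)
        mask = np.zeros_like(cap)
        mask[1:4, 2:5, 2:5] = True
        assert sq.structure_distance(mask, dmap) == pytest.approx(0.15)

    def test_overlap_warns_and_returns_zero(self):
        cap = np.zeros((8, 8, 8), dtype=bool)
        cap[0:2, :, :] = True
        dmap = sq.capillary_distance_map(cap, SP)
        mask = np.zeros_like(cap)
        mask[1:4, 2:4, 2:4] = True
        with pytest.warns(UserWarning, match="overlap"):
            assert sq.structure_distance(mask, dmap) == 0.0

    def test_cylinder_scene_distance_matches_geometry(self):
        """Surface distance ~ centre-to-axis distance minus radii (one diagonal tol)."""
        cfg = sq.SceneConfig(
            n_cells=6, seed=13, mito_per_cell=(0, 0),
            capillary=sq.CapillarySpec((-2.0, 19.2, 9.6), (41.0, 19.2, 9.6), 1.5),
        )
        scene = sq.generate_scene(cfg)
        cap_mask = scene.labels.labels == sq.synthetic.CAPILLARY_ID
        dmap = sq.capillary_distance_map(cap_mask, scene.labels.spacing)
        diag = float(np.linalg.norm(scene.labels.spacing.as_um))
        from sbfquant.morphometry import cell_body_mask

        for _, row in scene.truth.cells.iterrows():
            if not row["complete"]:
                continue
            mask = cell_body_mask(scene.labels, scene.segments, int(row.cell_id))
            measured = sq.structure_distance(mask, dmap)
            center = row[["cx_um", "cy_um", "cz_um"]].to_numpy(dtype=float)
            axis_d = np.hypot(center[1] - 19.2, center[2] - 9.6)  # distance to cylinder axis
            # analytic surface distance bounds: centre distance minus capillary
            # radius minus the cell's extent toward the capillary in [b, a]
            lo = axis_d - 1.5 - row.a_um - diag
            hi = axis_d - 1.5 - row.c_um + diag
            assert lo <= measured <= hi


class TestSpearman:
    def test_monotone_increasing_rho_one(self):
        r = sq.spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert r.rho == pytest.approx(1.0)
        assert r.p_value < 0.05 and r.significant

    def test_classic_closed_form_example(self):
        """No ties: rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 0.8 for this permutation."""
        r = sq.spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r.rho == pytest.approx(0.8)

    def test_antisymmetry(self):
        r = sq.spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert r.rho == pytest.approx(-1.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert sq.spearman(x, y).rho == pytest.approx(sq.spearman(y, x).rho)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=15), rng.normal(size=15)
        base = sq.spearman(x, y)
        trans = sq.spearman(np.exp(x), y**3)
        assert trans.rho == pytest.approx(base.rho)
        assert trans.p_value == pytest.approx(base.p_value)

    def test_matches_scipy_t_approximation(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=21), rng.normal(size=21)
        ours = sq.spearman(x, y)
        ref = spearmanr(x, y)
        assert ours.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_permutation_small_n(self):
        # n=4, all 24 permutations enumerable by hand: perfect ordering has p = 2/24
        r = sq.spearman([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.p_value == pytest.approx(2 / 24)

    def test_ties_use_midranks(self):
        x = [1, 2, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11]
        y = [1, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12]
        ours = sq.spearman(x, y)
        ref = spearmanr(x, y)
        assert ours.rho == pytest.approx(ref.statistic, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            sq.spearman([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            sq.spearman([1, 2], [3, 4])


@pytest.fixture(scope="module")
def capillary_scene():
    cfg = sq.SceneConfig(
        dims=(192, 192, 64), n_cells=26, seed=17, mito_per_cell=(10, 18),
        cell_radius_mean_um=3.0, size_distance_beta=0.6,
        capillary=sq.CapillarySpec((1.5, 14.4, 9.6), (27.3, 14.4, 9.6), 1.5),
    )
    return sq.generate_scene(cfg)


class TestReport:

    def test_report_counting_contract(self, capillary_scene):
        cells = sq.cell_table(capillary_scene.labels, capillary_scene.segments)
        corr = sq.build_report(cells)
        assert len(corr) == 6 + 5  # volumetric pairs + distance correlations
        assert (corr["n"] == len(cells)).all()

    def test_size_gradient_recovered_as_negative_rho(self, capillary_scene):
        cells = sq.cell_table(capillary_scene.labels, capillary_scene.segments)
        corr = sq.build_report(cells).set_index(["x", "y"])
        rho = corr.loc[("distance_to_capillary", "cell_volume"), "rho"]
        assert rho < 0

    def test_volume_correlations_positive(self, capillary_scene):
        """Bigger cells have bigger nuclei and cytoplasm by construction."""
        cells = sq.cell_table(capillary_scene.labels, capillary_scene.segments)
        corr = sq.build_report(cells).set_index(["x", "y"])
        assert corr.loc[("cell_volume", "nucleus_volume"), "rho"] > 0.9
        assert corr.loc[("cell_volume", "cytoplasm_volume"), "rho"] > 0.9

    def test_null_coupling_rarely_significant(self):
        """beta=0: distance-volume correlation is null; flag rarely fires."""
        hits = 0
        n_seeds = 6
        for seed in range(n_seeds):
            cfg = sq.SceneConfig(
                n_cells=21, seed=300 + seed, mito_per_cell=(0, 0),
                capillary=sq.CapillarySpec((1.5, 19.2, 4.8), (36.9, 19.2, 4.8), 1.5),
            )
            t = sq.generate_scene(cfg).truth.cells
            vol = t.a_um * t.b_um * t.c_um
            r = sq.spearman(t.distance_to_capillary_um, vol)
            hits += r.significant
        assert hits <= 1
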