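"""Morphometric indices, binarization, morphotype clustering and overlap tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial import cKDTree

from botmetrics import morpho
from botmetrics import synthgen as sg
from botmetrics._geometry import alpha_shape, auto_alpha
from tests.test_geometry import fibonacci_sphere


class TestBinarize:
    def make_volumes(self, seed=0):
        rng = np.random.default_rng(seed)
        z, y, x = np.mgrid[0:20, 0:40, 0:40]
        sphere = (x - 20) ** 2 + (y - 20) ** 2 + ((z - 10) * 2) ** 2 < 14**2
        body = 40.0 + 160.0 * sphere + rng.normal(0, 8.0, sphere.shape)
        cilia = 30.0 + 200.0 * sphere + rng.normal(0, 8.0, sphere.shape)
        return body, cilia, sphere

    def test_body_mask_recall_and_precision(self):
        body, cilia, truth = self.make_volumes()
        cloud = morpho.binarize_channels(body, cilia, voxel_spacing=(1, 1, 2))
        got = np.zeros_like(truth)
        idx = (cloud.body_points[:, ::-1] / np.array([2.0, 1.0, 1.0])).astype(int)
        got[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        tp = (got & truth).sum()
        assert tp / truth.sum() >= 0.95  # recall
        assert tp / got.sum() >= 0.95  # precision

    def test_renyi_threshold_separates_two_delta_peaks(self):
        # two exact intensity levels: any entropy threshold must cut the gap
        v = np.concatenate([np.full(4000, 10.0), np.full(1000, 200.0)])
        thr = morpho.renyi_entropy_threshold(v.reshape(50, 10, 10))
        assert 10 <= thr < 200
        mask = v > thr
        assert mask.sum() == 1000 and mask[4000:].all()

    def test_constant_volume_raises(self):
        with pytest.raises(ValueError, match="constant"):
            morpho.binarize_channels(np.zeros((5, 5, 5)), np.zeros((5, 5, 5)))


class TestSliceOutlines:
    def test_disc_slice_outline_area_matches_circle(self):
        from shapely import Polygon

        yy, xx = np.mgrid[-30:31, -30:31]
        disc = xx**2 + yy**2 <= 25**2
        pts = np.column_stack([xx[disc], yy[disc], np.zeros(disc.sum())])
        reduced, skipped = morpho.slice_outlines(pts, z_tol=0.5)
        poly = Polygon(reduced[:, :2])
        assert poly.area == pytest.approx(np.pi * 25**2, rel=0.05)
        assert skipped == 0

    def test_crescent_slice_is_smaller_than_convex_hull(self):
        from shapely import MultiPoint, Polygon

        yy, xx = np.mgrid[-30:31, -30:31]
        crescent = (xx**2 + yy**2 <= 28**2) & ((xx - 12) ** 2 + yy**2 > 18**2)
        pts = np.column_stack([xx[crescent], yy[crescent], np.zeros(crescent.sum())])
        reduced, _ = morpho.slice_outlines(pts, concave_ratio=0.1, z_tol=0.5)
        poly = Polygon(reduced[:, :2])
        hull = MultiPoint(pts[:, :2]).convex_hull
        assert poly.area < hull.area * 0.97

    def test_tiny_slices_skipped_and_counted(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [5, 5, 3.0]])
        with pytest.raises(ValueError):
            # the only valid slice is convex but has 4 points; the z=3 slice
            # is skipped; still produces an outline, so check count via valid z
            morpho.slice_outlines(pts[-1:], z_tol=0.5)
        reduced, skipped = morpho.slice_outlines(pts, z_tol=0.5)
        assert skipped == 1


class TestProjectionAndNoise:
    def test_projection_matches_brute_force(self):
        rng = np.random.default_rng(0)
        body = rng.normal(size=(80, 3))
        cilia = rng.normal(size=(40, 3)) * 1.2
        proj, count = morpho.project_cilia(cilia, body)
        d = np.linalg.norm(cilia[:, None, :] - body[None, :, :], axis=2)
        brute = body[d.argmin(axis=1)]
        assert np.array_equal(proj, brute)
        assert count == len(np.unique(d.argmin(axis=1)))

    def test_shared_nearest_body_point_counts_once(self):
        body = np.array([[0, 0, 0], [10, 0, 0.0]])
        cilia = np.array([[0.1, 0, 0], [-0.1, 0, 0.0]])
        _, count = morpho.project_cilia(cilia, np.vstack([body, np.zeros((48, 3)) + 100]))
        assert count == 1

    def test_noise_count_on_constructed_configuration(self):
        rng = np.random.default_rng(1)
        patch = rng.normal(0, 0.5, size=(30, 3))
        isolated = np.array(
            [[20, 0, 0], [-20, 0, 0], [0, 20, 0], [0, -20, 0], [0, 0, 20.0]]
        )
        pts = np.vstack([patch, isolated])
        assert morpho.count_noise_points(pts, eps=3.0, min_pts=4) == 5

    def test_noise_count_matches_naive_region_query_dbscan(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 10, size=(120, 3))
        eps, min_pts = 1.2, 4
        # naive DBSCAN: core points, then BFS over eps-neighborhoods
        tree = cKDTree(pts)
        neigh = tree.query_ball_point(pts, eps)
        core = np.array([len(nb) >= min_pts for nb in neigh])
        labels = np.full(len(pts), -1)
        cluster = 0
        for i in np.nonzero(core)[0]:
            if labels[i] != -1:
                continue
            stack = [i]
            labels[i] = cluster
            while stack:
                j = stack.pop()
                if not core[j]:
                    continue
                for k in neigh[j]:
                    if labels[k] == -1:
                        labels[k] = cluster
                        stack.append(k)
            cluster += 1
        assert morpho.count_noise_points(pts, eps=eps, min_pts=min_pts) == int(
            (labels == -1).sum()
        )


class TestPolarityAndHomogeneity:
    def test_single_pole_gives_one(self):
        cilia = np.tile([5.0, 0, 0], (10, 1))
        assert morpho.polarity(np.zeros(3), cilia) == pytest.approx(1.0)

    def test_antipodal_pair_cancels(self):
        cilia = np.array([[5.0, 0, 0], [-5.0, 0, 0]])
        assert morpho.polarity(np.zeros(3), cilia) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_cilia_have_low_polarity(self):
        pts = fibonacci_sphere(1000, r=10.0)
        assert morpho.polarity(np.zeros(3), pts) < 0.1

    def test_homogeneity_of_reference_against_itself_is_one(self):
        pts = fibonacci_sphere(600, r=10.0)
        surf = alpha_shape(pts, auto_alpha(pts))
        sample = surf.sample_surface(200, np.random.default_rng(0))
        from botmetrics._geometry import nn_distances

        d = nn_distances(sample)
        assert stats.ks_2samp(d, d).statistic == 0.0

    def test_clumped_cilia_score_below_uniform(self):
        pts = fibonacci_sphere(800, r=10.0)
        surf = alpha_shape(pts, auto_alpha(pts))
        rng = np.random.default_rng(3)
        # all cilia inside a tiny patch vs drawn uniformly
        pole = np.array([0, 0, 1.0])
        patch = pole + rng.normal(0, 0.02, (200, 3))
        patch = 10.0 * patch / np.linalg.norm(patch, axis=1, keepdims=True)
        h_patch = morpho.cilia_homogeneity(patch, surf, seed=0)
        uniform = surf.sample_surface(200, rng)
        h_unif = morpho.cilia_homogeneity(uniform, surf, seed=0)
        assert h_patch < 0.2
        assert h_unif > 0.7


class TestComputeIndices:
    def test_sphere_with_uniform_cilia(self):
        cloud = sg.generate_bot_cloud(
            sg.BotCloudSpec(bump_amplitude=0.0, cilia_mode="uniform", n_patches=150,
                            cluster_scatter_rad=0.5, seed=2)
        )
        idx = morpho.compute_morpho_indices(cloud)
        assert idx.aspect == pytest.approx(1.0, rel=0.05)
        assert 0.9 <= idx.shape_smoothness <= 1.0
        assert idx.polarity < 0.15

    def test_polarized_cloud_has_high_polarity(self):
        cloud = sg.generate_bot_cloud(
            sg.BotCloudSpec(cilia_mode="polarized", polar_concentration=20.0, seed=3)
        )
        idx = morpho.compute_morpho_indices(cloud)
        assert idx.polarity > 0.6

    def test_bumpy_cloud_less_smooth_than_paired_smooth(self):
        for seed in (0, 1, 2):
            smooth = morpho.compute_morpho_indices(
                sg.generate_bot_cloud(sg.BotCloudSpec(bump_amplitude=0.0, seed=seed))
            )
            bumpy = morpho.compute_morpho_indices(
                sg.generate_bot_cloud(sg.BotCloudSpec(bump_amplitude=0.3, seed=seed))
            )
            assert bumpy.shape_smoothness < smooth.shape_smoothness

    def test_rigid_motion_invariance_and_scaling_laws(self):
        from scipy.spatial.transform import Rotation

        spec = sg.BotCloudSpec(seed=5, bump_amplitude=0.1, noise_fraction=0.05)
        cloud = sg.generate_bot_cloud(spec)
        base = morpho.compute_morpho_indices(cloud, morpho.MorphoConfig(seed=0))
        R = Rotation.from_euler("xyz", [0.3, -1.0, 2.0]).as_matrix()
        shift = np.array([100.0, -50.0, 30.0])
        moved = sg.BotCloud(
            "moved",
            cloud.body_points @ R.T + shift,
            cloud.cilia_points @ R.T + shift,
        )
        got = morpho.compute_morpho_indices(moved, morpho.MorphoConfig(seed=0))
        assert got.cilia_points == base.cilia_points
        assert got.noise_points == base.noise_points
        assert got.max_radius == pytest.approx(base.max_radius, rel=1e-3)
        assert got.aspect == pytest.approx(base.aspect, rel=1e-3)
        assert got.shape_smoothness == pytest.approx(base.shape_smoothness, rel=1e-6)
        assert got.polarity == pytest.approx(base.polarity, rel=1e-6)
        # uniform scaling: max_radius ∝ s, cilia_per_area ∝ s⁻²
        s = 2.0
        scaled = sg.BotCloud("scaled", cloud.body_points * s, cloud.cilia_points * s)
        got_s = morpho.compute_morpho_indices(scaled, morpho.MorphoConfig(seed=0))
        assert got_s.max_radius == pytest.approx(base.max_radius * s, rel=1e-3)
        assert got_s.cilia_per_area == pytest.approx(base.cilia_per_area / s**2, rel=0.05)


POPULATIONS = {
    "small-smooth": dict(base_radius=40.0, bump_amplitude=0.03, n_cilia=80,
                         cilia_mode="uniform"),
    "large-dense": dict(base_radius=120.0, bump_amplitude=0.25, n_cilia=250,
                        cilia_mode="uniform"),
    "large-polarized": dict(base_radius=110.0, bump_amplitude=0.25, n_cilia=120,
                            cilia_mode="polarized", polar_concentration=20.0),
}


def three_population_table(n_each=8, seed=1):
    rng = np.random.default_rng(seed)
    records, truth = [], []
    for pop, kw in POPULATIONS.items():
        for i in range(n_each):
            cloud = sg.generate_bot_cloud(
                sg.BotCloudSpec(seed=int(rng.integers(2**31)), noise_fraction=0.05, **kw)
            )
            cloud.bot_id = f"{pop}-{i}"
            records.append(morpho.compute_morpho_indices(cloud))
            truth.append(pop)
    return morpho.MorphoIndices.table(records), truth


@pytest.fixture(scope="module")
def pop_table():
    return three_population_table(n_each=8, seed=1)


class TestMorphotypeClustering:
    def test_three_populations_recovered(self, pop_table):
        table, truth = pop_table
        result = morpho.cluster_morphotypes(table, k=3)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, result.labels.to_numpy()) >= 0.9

    def test_single_population_low_silhouette(self, pop_table):
        # a homogeneous table forced into k=3: silhouette must be weak
        # compared with the genuinely 3-population case (≈ 0.65 there)
        table, truth = pop_table
        one_pop = table[[t == "large-dense" for t in truth]]
        # pad with jittered copies to satisfy the k·5 row minimum
        pad = one_pop + one_pop.std() * 0.01
        pad.index = [f"{i}-pad" for i in one_pop.index]
        result = morpho.cluster_morphotypes(pd.concat([one_pop, pad]), k=3)
        assert result.silhouette < 0.5

    def test_duplicated_rows_share_labels(self, pop_table):
        table, _ = pop_table
        dup = pd.concat([table, table.iloc[:3].set_axis([f"dup-{i}" for i in range(3)])])
        result = morpho.cluster_morphotypes(dup, k=3)
        for i in range(3):
            assert result.labels[f"dup-{i}"] == result.labels[table.index[i]]

    def test_constant_column_raises_with_name(self, pop_table):
        table = pop_table[0].copy()
        table["aspect"] = 1.0
        with pytest.raises(ValueError, match="aspect"):
            morpho.cluster_morphotypes(table, k=3)


class TestBootstrapRanks:
    def test_dominant_variable_uniquely_rank_one(self):
        # the PCA runs on the z-scaled table, so dominance must come from
        # the correlation structure: one variable carries the latent factor
        # almost noiselessly, the others only weakly
        rng = np.random.default_rng(0)
        n = 300
        f = rng.normal(size=n)
        df = pd.DataFrame(
            {
                "dominant": f + 0.05 * rng.normal(size=n),
                "weak1": 0.4 * f + rng.normal(size=n),
                "weak2": 0.4 * f + rng.normal(size=n),
            }
        )
        ranks = morpho.bootstrap_loading_ranks(df, n_boot=10, subsample=200, seed=0)
        pc1 = ranks[ranks["component"] == "PC1"].set_index("variable")
        assert pc1.loc["dominant", "rank"] == 1
        assert (pc1.drop("dominant")["rank"] > 1).all()

    def test_two_correlated_variables_corank_one(self):
        rng = np.random.default_rng(1)
        n = 300
        shared = rng.normal(size=n)
        df = pd.DataFrame(
            {
                "a": shared + rng.normal(size=n) * 0.01,
                "b": shared + rng.normal(size=n) * 0.01,
                "c": rng.normal(size=n),
            }
        )
        ranks = morpho.bootstrap_loading_ranks(df, n_boot=10, subsample=200, seed=0)
        pc1 = ranks[ranks["component"] == "PC1"].set_index("variable")
        assert pc1.loc["a", "rank"] == 1 and pc1.loc["b", "rank"] == 1

    def test_deterministic_given_seed(self, pop_table):
        table, _ = pop_table
        r1 = morpho.bootstrap_loading_ranks(table, n_boot=5, subsample=10, seed=3)
        r2 = morpho.bootstrap_loading_ranks(table, n_boot=5, subsample=10, seed=3)
        pd.testing.assert_frame_equal(r1, r2)

    def test_n_boot_below_two_raises(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 3)))
        with pytest.raises(ValueError):
            morpho.bootstrap_loading_ranks(df, n_boot=1, subsample=10)


class TestOverlapFisher:
    def test_diagonal_table_matches_hypergeometric_enumeration(self):
        morph = pd.Series([1] * 10 + [2] * 10)
        behav = pd.Series(["nonmover"] * 10 + ["circular"] * 10)
        out = morpho.overlap_fisher(morph, behav)
        p = out["nonmover"][(1, 2)]["p"]
        # exact enumeration: P(table at least as extreme) under fixed margins
        expected = sum(
            stats.hypergeom.pmf(k, 20, 10, 10)
            for k in range(11)
            if stats.hypergeom.pmf(k, 20, 10, 10)
            <= stats.hypergeom.pmf(10, 20, 10, 10) * (1 + 1e-9)
        )
        assert p == pytest.approx(expected, rel=1e-9)
        assert p < 1e-4

    def test_balanced_table_gives_p_one(self):
        morph = pd.Series([1] * 10 + [2] * 10)
        behav = pd.Series((["nonmover"] * 5 + ["circular"] * 5) * 2)
        out = morpho.overlap_fisher(morph, behav)
        assert out["nonmover"][(1, 2)]["p"] == pytest.approx(1.0)

    def test_association_detected_at_cluster_size_20(self):
        rng = np.random.default_rng(0)
        # cluster 1 holds all non-movers, clusters 2/3 hold movers
        morph = pd.Series([1] * 20 + [2] * 20 + [3] * 20)
        behav = pd.Series(
            ["nonmover"] * 20
            + list(rng.choice(["circular", "linear"], 40))
        )
        out = morpho.overlap_fisher(morph, behav)
        assert out["nonmover"][(1, 2)]["p"] < 0.05
        assert out["nonmover"][(1, 3)]["p"] < 0.05

    def test_empty_margin_skipped_with_reason(self):
        morph = pd.Series([1] * 5 + [2] * 5)
        behav = pd.Series(["circular"] * 10)
        out = morpho.overlap_fisher(morph, behav)
        assert out["nonmover"][(1, 2)]["skipped"] == "empty margin"
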