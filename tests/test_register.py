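import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from limblab.core import (
    AffineTransform4,
    DegenerateInputError,
    LandmarkSet,
    ParameterError,
    SurfaceMesh,
    VoxelGrid,
)
from limblab.phantom import make_reference_set, perturb_with_known_transform
from limblab.register import (
    augment_pairs_closest,
    closest_points_on_mesh,
    distance_map,
    icp_refine,
    registry_build,
    similarity_from_landmarks,
    tps_fit,
    warp_grid,
)

from .conftest import icosphere


class TestRegistry:
    def test_full_stage_range_has_42_entries(self, tmp_path):
        registry = make_reference_set((249, 290), out_dir=tmp_path)
        assert len(registry) == 42
        rebuilt = registry_build((249, 290), tmp_path)
        assert rebuilt.entries == registry.entries

    def test_single_stage(self, tmp_path):
        registry = make_reference_set((250, 250), out_dir=tmp_path)
        assert len(registry) == 1

    def test_nearest_stage_rounds_half_up(self, tmp_path):
        registry = make_reference_set((260, 270), out_dir=tmp_path)
        assert registry.nearest_stage(267.4) == 267
        assert registry.nearest_stage(267.5) == 268
        assert registry.nearest_stage(300.0) == 270  # clamped

    def test_missing_stage_named(self, tmp_path):
        make_reference_set((249, 260), out_dir=tmp_path)
        (tmp_path / "stage_255.ply").unlink()
        with pytest.raises(ParameterError, match="255"):
            registry_build((249, 260), tmp_path)


class TestSimilarity:
    def test_identity_for_equal_sets(self, rng):
        pts = LandmarkSet(rng.uniform(0, 10, (20, 3)))
        t = similarity_from_landmarks(pts, pts)
        assert np.allclose(t.matrix, np.eye(4), atol=1e-12)

    def test_recovers_known_transform(self, rng):
        rot = Rotation.from_rotvec([0.3, -0.5, 0.2]).as_matrix()
        s, shift = 1.3, np.array([4.0, -2.0, 7.0])
        p = rng.uniform(0, 10, (50, 3))
        q = s * p @ rot.T + shift
        est = similarity_from_landmarks(LandmarkSet(p), LandmarkSet(q))
        assert np.abs(est.linear - s * rot).max() < 1e-9
        assert np.abs(est.offset - shift).max() < 1e-9

    def test_rigid_mode_keeps_unit_scale(self, rng):
        p = rng.uniform(0, 10, (30, 3))
        q = 2.0 * p
        est = similarity_from_landmarks(LandmarkSet(p), LandmarkSet(q), with_scale=False)
        g = est.linear.T @ est.linear
        assert np.allclose(g, np.eye(3), atol=1e-9)

    def test_reflection_still_gives_proper_rotation(self, rng):
        p = rng.uniform(0, 10, (40, 3))
        q = p * np.array([-1.0, 1.0, 1.0])  # mirror correspondence
        est = similarity_from_landmarks(LandmarkSet(p), LandmarkSet(q))
        assert np.linalg.det(est.linear) > 0
        resid = np.linalg.norm(est.apply(p) - q, axis=1)
        assert resid.max() > 0.1  # reflections cannot be fit exactly

    def test_invariant_under_joint_rigid_motion(self, rng):
        p = rng.uniform(0, 10, (25, 3))
        q = rng.uniform(0, 10, (25, 3))
        base = similarity_from_landmarks(LandmarkSet(p), LandmarkSet(q))
        resid0 = np.linalg.norm(base.apply(p) - q, axis=1)
        rot = Rotation.from_rotvec([1.0, 0.1, -0.3]).as_matrix()
        shift = np.array([5.0, 5.0, -2.0])
        moved = similarity_from_landmarks(
            LandmarkSet(p @ rot.T + shift), LandmarkSet(q @ rot.T + shift)
        )
        resid1 = np.linalg.norm(
            moved.apply(p @ rot.T + shift) - (q @ rot.T + shift), axis=1
        )
        assert np.abs(resid0 - resid1).max() < 1e-9

    def test_degenerate_configurations(self):
        line = LandmarkSet(np.outer(np.arange(4, dtype=float), [1, 0, 0]))
        with pytest.raises((DegenerateInputError, ParameterError)):
            similarity_from_landmarks(line, line)


class TestClosestPointsAndDistanceMap:
    def test_mesh_vs_itself_is_zero(self):
        mesh = icosphere(radius=10.0)
        dm = distance_map(mesh, mesh)
        assert dm.summary["max"] < 1e-12

    def test_concentric_spheres_mean_distance(self):
        inner = icosphere(radius=10.0, subdivisions=3)
        outer = icosphere(radius=12.0, subdivisions=3)
        dm = distance_map(inner, outer)
        assert abs(dm.summary["mean"] - 2.0) / 2.0 < 0.02
        assert dm.summary["rms"] >= dm.summary["mean"] - 1e-12

    def test_point_to_flat_patch_exact(self):
        # large flat target patch in z=0; query point directly above interior
        verts = np.array(
            [[-10.0, -10, 0], [10, -10, 0], [10, 10, 0], [-10, 10, 0]]
        )
        faces = [[0, 1, 2], [0, 2, 3]]
        target = SurfaceMesh(verts, faces)
        d = 3.7
        cp, dist = closest_points_on_mesh(np.array([[1.0, 2.0, d]]), target)
        assert abs(dist[0] - d) < 1e-9
        assert np.allclose(cp[0], [1.0, 2.0, 0.0], atol=1e-9)

    def test_summary_consistent_with_values(self):
        inner = icosphere(radius=5.0)
        outer = icosphere(radius=9.0)
        dm = distance_map(inner, outer)
        assert np.isclose(dm.summary["mean"], dm.distances.mean())
        assert np.isclose(dm.summary["max"], dm.distances.max())
        assert np.all(dm.distances >= 0)


class TestAugmentPairs:
    def seeds(self, mesh):
        pts = LandmarkSet(mesh.vertices[:4])
        return (pts, LandmarkSet(pts.points.copy()))

    def test_identical_meshes_all_zero_distance(self):
        mesh = icosphere(radius=10.0)
        src, tgt = augment_pairs_closest(mesh, mesh, self.seeds(mesh), n_extra=10)
        assert len(src) == len(tgt) == 14
        assert np.abs(src.points[4:] - tgt.points[4:]).max() < 1e-9

    def test_concentric_spheres_pair_distance(self):
        inner = icosphere(radius=10.0, subdivisions=3)
        outer = icosphere(radius=12.0, subdivisions=3)
        src, tgt = augment_pairs_closest(inner, outer, self.seeds(inner), n_extra=20)
        d = np.linalg.norm(src.points[4:] - tgt.points[4:], axis=1)
        assert np.abs(d - 2.0).max() < 0.1

    def test_zero_extra_returns_seeds(self):
        mesh = icosphere()
        seeds = self.seeds(mesh)
        src, tgt = augment_pairs_closest(mesh, mesh, seeds, n_extra=0)
        assert src is seeds[0] and tgt is seeds[1]

    def test_too_many_requested(self):
        mesh = icosphere(subdivisions=1)
        with pytest.raises(ParameterError):
            augment_pairs_closest(mesh, mesh, self.seeds(mesh), n_extra=10**6)


class TestICP:
    def test_identical_meshes_return_init(self):
        mesh = icosphere(radius=10.0)
        init = AffineTransform4.identity()
        out, hist = icp_refine(mesh, mesh, init=init, return_history=True)
        assert np.allclose(out.matrix, np.eye(4))
        assert len(hist) == 1 and hist[0] < 1e-12

    def test_recovers_small_rigid_perturbation(self, paddle_surface_coarse):
        res = perturb_with_known_transform(
            paddle_surface_coarse, "rigid", (5.0, 2.0), seed=3
        )
        est, hist = icp_refine(
            paddle_surface_coarse, res["perturbed"], max_iter=200, return_history=True
        )
        gt = res["transform"]
        d_rot = est.linear @ np.linalg.inv(gt.linear)
        angle = np.degrees(np.arccos(np.clip((np.trace(d_rot) - 1) / 2, -1, 1)))
        assert angle < 0.1
        assert np.linalg.norm(est.offset - gt.offset) < 0.05
        assert all(np.diff(hist) <= 1e-12)  # monotone non-increasing

    def test_empty_input_rejected(self):
        mesh = icosphere()
        empty = SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3)))
        with pytest.raises(DegenerateInputError):
            icp_refine(empty, mesh)


class TestTPS:
    def test_identity_and_zero_energy(self, rng):
        pts = LandmarkSet(rng.uniform(0, 10, (10, 3)))
        warp = tps_fit(pts, LandmarkSet(pts.points.copy()))
        assert warp.bending_energy < 1e-10
        probe = rng.uniform(0, 10, (50, 3))
        assert np.abs(warp.apply(probe) - probe).max() < 1e-8

    def test_affine_reproduction(self, rng):
        src = LandmarkSet(rng.uniform(0, 10, (12, 3)))
        A = np.eye(3) + rng.uniform(-0.2, 0.2, (3, 3))
        b = rng.uniform(-5, 5, 3)
        tgt = LandmarkSet(src.points @ A.T + b)
        warp = tps_fit(src, tgt)
        assert warp.bending_energy < 1e-8
        probe = rng.uniform(0, 10, (64, 3))
        assert np.abs(warp.apply(probe) - (probe @ A.T + b)).max() < 1e-6

    def test_landmark_interpolation(self, rng):
        src = LandmarkSet(rng.uniform(0, 10, (15, 3)))
        tgt = LandmarkSet(rng.uniform(0, 10, (15, 3)))
        warp = tps_fit(src, tgt)
        assert np.abs(warp.apply(src.points) - tgt.points).max() < 1e-6

    def test_coplanar_landmarks_suggest_regularization(self, rng):
        xy = rng.uniform(0, 10, (8, 2))
        src = LandmarkSet(np.column_stack([xy, np.zeros(8)]))
        tgt = LandmarkSet(rng.uniform(0, 10, (8, 3)))
        with pytest.raises(DegenerateInputError, match="regularization"):
            tps_fit(src, tgt)

    def test_too_few_pairs(self, rng):
        pts = LandmarkSet(rng.uniform(0, 1, (3, 3)))
        with pytest.raises(ParameterError):
            tps_fit(pts, pts)


class TestWarpGrid:
    def ramp_grid(self):
        n = 24
        x = np.arange(n, dtype=float)
        data = (
            x[:, None, None] + 2 * x[None, :, None] + 3 * x[None, None, :]
        )
        return VoxelGrid(data, (1.0, 1.0, 1.0))

    def test_identity_transform(self, rng):
        g = VoxelGrid(rng.uniform(0, 1, (12, 12, 12)))
        out = warp_grid(g, AffineTransform4.identity())
        assert np.abs(out.data - g.data).max() < 1e-9

    def test_integer_translation_shifts_exactly(self, rng):
        data = rng.uniform(0, 1, (16, 16, 16))
        g = VoxelGrid(data)
        t = AffineTransform4.translation([3.0, 0.0, 0.0])
        out = warp_grid(g, t)
        assert np.abs(out.data[3:, :, :] - data[:-3, :, :]).max() < 1e-12
        assert np.abs(out.data[:3]).max() == 0.0  # out-of-domain zeros

    def test_affine_roundtrip_within_interpolation_error(self):
        g = self.ramp_grid()
        rot = Rotation.from_rotvec([0, 0, 0.2]).as_matrix()
        t = AffineTransform4.from_rotation_translation(rot, [1.0, -2.0, 0.5])
        back = warp_grid(warp_grid(g, t), t.inverse())
        interior = back.data[6:-6, 6:-6, 6:-6]
        expected = g.data[6:-6, 6:-6, 6:-6]
        # trilinear is exact on affine fields away from the zero-padded rim
        assert np.abs(interior - expected).max() < 1e-6

    def test_noninvertible_affine_rejected(self, rng):
        g = VoxelGrid(rng.uniform(0, 1, (8, 8, 8)))
        with pytest.raises(ParameterError):
            AffineTransform4(np.diag([1.0, 1.0, 0.0, 1.0]))

    def test_end_to_end_morph_with_augmented_pairs(self, paddle_surface_coarse):
        # limb vs a reference deformed by a known smooth field: after TPS on
        # >= 20 augmented pairs the residual rms is small relative to size
        res = perturb_with_known_transform(paddle_surface_coarse, "tps", 2.5, seed=11)
        reference = res["perturbed"]
        src = paddle_surface_coarse
        seeds_src = LandmarkSet(src.vertices[:4])
        seeds_tgt = LandmarkSet(res["transform"].apply(src.vertices[:4]))
        pairs = augment_pairs_closest(src, reference, (seeds_src, seeds_tgt), 24)
        warp = tps_fit(*pairs)
        morphed = SurfaceMesh(warp.apply(src.vertices), src.faces)
        dm = distance_map(morphed, reference)
        bbox = src.vertices.max(axis=0) - src.vertices.min(axis=0)
        assert dm.summary["rms"] < 0.05 * np.linalg.norm(bbox)

    def test_tps_warp_keeps_gene_inside_morphed_surface(
        self, phantom_spec, phantom, paddle_surface_coarse
    ):
        # morph the surface by a smooth warp, then carry the gene channel
        # through the same warp: expression must stay inside the new surface
        from limblab.phantom import make_gene_domain
        from limblab.register import distance_map
        from limblab.surface import extract_isosurface

        res = perturb_with_known_transform(paddle_surface_coarse, "tps", 3.0, seed=9)
        warp = res["transform"]
        gene = make_gene_domain(phantom_spec, "bilobed")
        warped_gene = warp_grid(gene, warp)
        morphed_surface = res["perturbed"]
        iso = extract_isosurface(warped_gene, 50.0)
        # every point of the warped expression domain lies within the limb:
        # distances from gene isosurface to morphed limb stay below those
        # from the original relationship plus the warp magnitude
        dm = distance_map(iso, morphed_surface)
        orig_iso = extract_isosurface(gene, 50.0)
        dm0 = distance_map(orig_iso, paddle_surface_coarse)
        assert dm.summary["max"] < dm0.summary["max"] + 2 * 3.0
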