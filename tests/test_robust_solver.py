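import numpy as np
import pytest
from scipy import sparse

from pbnrr.core_io import DenseField, Image3D, MaterialTable, TetMesh
from pbnrr.fem_biomech import assemble_stiffness, build_interpolation
from pbnrr.feature_matching import BlockSpec
from pbnrr.phantom import PhantomSpec, make_phantom
from pbnrr.resection_adaptive import bcc_mesh
from pbnrr.robust_solver import (
    EmptySystemError,
    SolverConfig,
    block_error,
    compose_fields,
    nodal_to_dense,
    register,
    register_images,
    sample_field,
    solve_interpolation,
    warp_image,
)


def small_system(seed=0, n_pts=40, cell=10.0):
    """Small mesh + synthetic match system with a known smooth field."""
    ph = make_phantom(PhantomSpec(size=(32, 32, 32), seed=seed, deform_max=0.0))
    mesh = bcc_mesh(ph.labels, cell)
    rng = np.random.default_rng(seed)
    lo, hi = mesh.vertices.min(0), mesh.vertices.max(0)
    pts = rng.uniform(lo, hi, (n_pts, 3))
    interp, kept = build_interpolation(mesh, pts)
    H = interp.matrix
    n = len(kept)
    S = sparse.identity(3 * n, format="csr")
    K = assemble_stiffness(mesh, MaterialTable()).matrix
    return mesh, K, H, S, n


class TestSolveInterpolation:
    def test_homogeneous_system_returns_zero(self):
        mesh, K, H, S, n = small_system()
        U = solve_interpolation(K, H, S, np.zeros(3 * n))
        np.testing.assert_allclose(U, 0.0, atol=1e-12)

    def test_small_stiffness_limit_matches_normal_equations(self):
        """As the elastic term vanishes, the solution approaches the
        least-squares reproduction of the target field on matched dofs."""
        mesh, K, H, S, n = small_system(seed=1)
        rng = np.random.default_rng(1)
        U_star = rng.standard_normal(3 * mesh.n_vertices)
        D = np.asarray(H @ U_star)
        U = solve_interpolation(K * 1e-12, H, S, D)
        # compare the fitted values at the match points with the oracle
        # (pinv truncation in near-null directions limits the agreement)
        A = (H.T @ H).toarray()
        oracle = np.linalg.pinv(A) @ (H.T @ D)
        np.testing.assert_allclose(np.asarray(H @ U), np.asarray(H @ oracle),
                                   atol=1e-2)

    def test_exact_interpolation_fixed_point(self):
        """F = K U_prev with exactly interpolable D leaves U_prev fixed."""
        mesh, K, H, S, n = small_system(seed=2)
        rng = np.random.default_rng(2)
        U_prev = rng.standard_normal(3 * mesh.n_vertices)
        D = np.asarray(H @ U_prev)
        # [K + HtSH] U = HtS D + K U_prev has solution U = U_prev
        U = solve_interpolation(K, H, S, D, F=np.asarray(K @ U_prev))
        np.testing.assert_allclose(U, U_prev, atol=1e-6 * abs(U_prev).max())


class TestBlockError:
    def test_exact_interpolation_zero_error(self):
        mesh, K, H, S, n = small_system(seed=3)
        U = np.random.default_rng(3).standard_normal(3 * mesh.n_vertices)
        xi = block_error(U, H, S, np.asarray(H @ U))
        np.testing.assert_allclose(xi, 0.0, atol=1e-18)

    def test_single_corruption_has_highest_error(self):
        mesh, K, H, S, n = small_system(seed=4)
        U = np.random.default_rng(4).standard_normal(3 * mesh.n_vertices)
        D = np.asarray(H @ U)
        D[3 * 7] += 10.0
        xi = block_error(U, H, S, D)
        assert int(np.argmax(xi)) == 7

    def test_homogeneity_in_weights(self):
        mesh, K, H, S, n = small_system(seed=5)
        rng = np.random.default_rng(5)
        U = rng.standard_normal(3 * mesh.n_vertices)
        D = rng.standard_normal(3 * n)
        xi1 = block_error(U, H, S, D)
        xi2 = block_error(U, H, 4.0 * S, D)
        np.testing.assert_allclose(xi2, 4.0 * xi1, rtol=1e-12)


class TestRegister:
    def test_degenerate_config_equals_plain_solve(self):
        mesh, K, H, S, n = small_system(seed=6)
        D = np.random.default_rng(6).standard_normal(3 * n)
        cfg = SolverConfig(n_R=0, f_R=0.0, relax_max_iter=0,
                           stiffness_scale=1.0)
        U, log = register(K, H, S, D, cfg)
        expected = solve_interpolation(K, H, S, D)
        np.testing.assert_array_equal(U, expected)

    def test_relaxation_converges_to_approximation_minimizer(self):
        """Post-relaxation S-weighted residual within 1% of the direct
        normal-equations minimizer (pseudo-inverse oracle) on clean
        block-matching data over a small mesh."""
        from pbnrr.feature_matching import block_match, select_feature_points
        from pbnrr.robust_solver import build_match_system
        from pbnrr.fem_biomech import assemble_stiffness

        ph = make_phantom(PhantomSpec(size=(48, 48, 48), seed=4,
                                      deform_max=4.0))
        mesh = bcc_mesh(ph.labels, 10.0)
        assert mesh.n_vertices <= 500
        spec = BlockSpec()
        pts = select_feature_points(ph.preop, spec, fraction=0.05,
                                    mask=ph.labels, min_spacing=2.0,
                                    margin=(8, 8, 8))
        ms = block_match(ph.preop, ph.intraop, pts, spec)
        K = assemble_stiffness(mesh, MaterialTable())
        H, S, D, kept = build_match_system(mesh, ms, ph.preop)
        cfg = SolverConfig(n_R=0, f_R=0.0, relax_tol=1e-12,
                           relax_max_iter=300, target_trace_ratio=1.0)
        U, log = register(K, H, S, D, cfg)
        r = float(block_error(U, H, S, D).sum())
        A = (H.T @ S @ H).toarray()
        U_opt = np.linalg.pinv(A) @ (H.T @ (S @ D))
        r_opt = float(block_error(U_opt, H, S, D).sum())
        assert r <= 1.01 * r_opt

    def test_monotone_relaxation_residual(self):
        mesh, K, H, S, n = small_system(seed=8, n_pts=80)
        rng = np.random.default_rng(8)
        D = rng.standard_normal(3 * n)
        cfg = SolverConfig(n_R=0, f_R=0.0, relax_tol=1e-10, relax_max_iter=60)
        U, log = register(K, H, S, D, cfg)
        res = [r["residual"] for r in log["relaxation"]]
        res = np.asarray(res)
        assert np.all(np.diff(res) <= 1e-8 * np.maximum(res[:-1], 1e-30))

    def test_determinism_bitwise(self):
        mesh, K, H, S, n = small_system(seed=9)
        D = np.random.default_rng(9).standard_normal(3 * n)
        cfg = SolverConfig(n_R=3, f_R=0.3)
        conf = np.random.default_rng(10).uniform(0.5, 1.0, n)
        U1, log1 = register(K, H, S, D, cfg, confidences=conf)
        U2, log2 = register(K, H, S, D, cfg, confidences=conf)
        np.testing.assert_array_equal(U1, U2)
        assert log1["rejected_ids"] == log2["rejected_ids"]

    def test_rejection_respects_total_budget(self):
        mesh, K, H, S, n = small_system(seed=11)
        D = np.random.default_rng(11).standard_normal(3 * n)
        cfg = SolverConfig(n_R=4, f_R=0.37)
        U, log = register(K, H, S, D, cfg)
        assert len(log["rejected_ids"]) == int(np.floor(0.37 * n))

    def test_empty_match_system_is_an_error(self):
        mesh, K, H, S, n = small_system(seed=12)
        empty_H = sparse.csr_matrix((0, K.shape[0]))
        empty_S = sparse.csr_matrix((0, 0))
        with pytest.raises(EmptySystemError):
            register(K, empty_H, empty_S, np.zeros(0), SolverConfig())


class TestDenseFieldAndWarp:
    def test_zero_nodal_field_rasterizes_to_zero(self, phantom_small):
        mesh = bcc_mesh(phantom_small.labels, 8.0)
        ref = phantom_small.preop
        fld = nodal_to_dense(mesh, np.zeros((mesh.n_vertices, 3)), ref)
        np.testing.assert_array_equal(fld.data, 0.0)

    def test_constant_nodal_field_inside_hull(self, phantom_small):
        mesh = bcc_mesh(phantom_small.labels, 8.0)
        ref = phantom_small.preop
        c = np.array([1.5, -2.0, 0.5])
        fld = nodal_to_dense(mesh, np.tile(c, (mesh.n_vertices, 1)), ref)
        inside = np.linalg.norm(fld.data, axis=-1) > 0
        assert inside.any()
        np.testing.assert_allclose(fld.data[inside],
                                   np.tile(c, (int(inside.sum()), 1)),
                                   atol=1e-9)

    def test_vertex_coincident_voxels_take_nodal_values(self):
        verts = np.array([[2, 2, 2], [10, 2, 2], [2, 10, 2], [2, 2, 10.0]])
        mesh = TetMesh(vertices=verts, tets=[[0, 1, 2, 3]])
        rng = np.random.default_rng(0)
        U = rng.standard_normal((4, 3))
        ref = Image3D(data=np.zeros((14, 14, 14)))
        fld = nodal_to_dense(mesh, U, ref)
        for v, u in zip(verts.astype(int), U):
            np.testing.assert_allclose(fld.data[tuple(v)], u, atol=1e-9)

    def test_zero_field_warp_is_identity(self, phantom_small):
        img = phantom_small.preop
        fld = DenseField(np.zeros(img.shape + (3,)), img.spacing, img.origin)
        np.testing.assert_array_equal(warp_image(img, fld, 1).data, img.data)

    def test_constant_field_translates(self):
        rng = np.random.default_rng(1)
        from scipy.ndimage import gaussian_filter
        img = Image3D(gaussian_filter(rng.standard_normal((20, 20, 20)), 1.5))
        fld = DenseField(np.tile([1.0, 0, 0], (20, 20, 20, 1)))
        warped = warp_image(img, fld, 1)
        np.testing.assert_allclose(warped.data[3:, :, :], img.data[2:-1, :, :],
                                   atol=1e-9)

    def test_nearest_warp_preserves_label_values(self, phantom_small):
        labels = phantom_small.labels
        rng = np.random.default_rng(2)
        fld = DenseField(rng.uniform(-2, 2, labels.shape + (3,)))
        warped = warp_image(
            Image3D(labels.data, labels.spacing, labels.origin), fld, 0
        )
        assert set(np.unique(warped.data)) <= set(np.unique(labels.data))

    def test_compose_with_zero_is_identity(self, phantom_small):
        shape = phantom_small.preop.shape
        rng = np.random.default_rng(3)
        from scipy.ndimage import gaussian_filter
        data = np.stack([gaussian_filter(rng.standard_normal(shape), 3)
                         for _ in range(3)], axis=-1)
        fld = DenseField(data)
        zero = DenseField(np.zeros(shape + (3,)))
        np.testing.assert_array_equal(compose_fields(fld, zero).data, fld.data)
        np.testing.assert_allclose(compose_fields(zero, fld).data, fld.data,
                                   atol=1e-12)

    def test_sample_field_at_voxel_centers(self, phantom_small):
        rng = np.random.default_rng(4)
        fld = DenseField(rng.standard_normal(phantom_small.preop.shape + (3,)))
        pts_idx = np.array([[3, 4, 5], [10, 11, 12]])
        vals = sample_field(fld, pts_idx.astype(float))
        np.testing.assert_allclose(
            vals, fld.data[tuple(pts_idx.T)], atol=1e-12
        )
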