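"""Procrustes, thin-plate-spline and warp-decomposition behaviour."""

import numpy as np
import pytest

import pantherin as pt
from pantherin.geomorph import bending_energy_matrix, partial_warps
from _oracles import numeric_bending_energy


def _similarity(coords, theta, scale, shift):
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    return scale * coords @ rot.T + shift


class TestGeneralizedProcrustes:
    def test_identical_triangles_under_similarity(self):
        tri = np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 0.9]])
        configs = [
            pt.LandmarkConfiguration("a", tri),
            pt.LandmarkConfiguration("b", _similarity(tri, 1.1, 3.0, [4, -2])),
        ]
        fit = pt.generalized_procrustes(configs)
        np.testing.assert_allclose(fit.aligned[0], fit.aligned[1], atol=1e-9)
        np.testing.assert_allclose(fit.mean_shape, fit.aligned[0], atol=1e-9)

    def test_quarter_turn_copy_has_zero_procrustes_distance(self, rng):
        base = rng.normal(size=(6, 2))
        configs = [
            pt.LandmarkConfiguration("a", base),
            pt.LandmarkConfiguration("b", _similarity(base, np.pi / 2, 1.0, [0, 0])),
        ]
        fit = pt.generalized_procrustes(configs)
        assert fit.procrustes_distances().max() < 1e-9

    def test_unit_centroid_size_and_centering(self, rng):
        configs = [
            pt.LandmarkConfiguration(str(i), rng.normal(size=(8, 2)) * 10 + 50)
            for i in range(5)
        ]
        fit = pt.generalized_procrustes(configs)
        for x in fit.aligned:
            assert np.abs(x.mean(axis=0)).max() < 1e-9
            assert abs(np.sqrt((x**2).sum()) - 1.0) < 1e-9
        np.testing.assert_allclose(fit.mean_shape, fit.aligned.mean(axis=0), atol=1e-9)

    def test_mean_recovery_monte_carlo(self):
        # 30 specimens = mean + isotropic noise; recovered mean within 3 sd/sqrt(30)
        rng = np.random.default_rng(7)
        mean = np.array(
            [[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 1.6], [0.5, -0.6]], dtype=float
        )
        sd = 0.01
        configs = [
            pt.LandmarkConfiguration(str(i), mean + rng.normal(0, sd, mean.shape))
            for i in range(30)
        ]
        fit = pt.generalized_procrustes(configs)
        from pantherin.geomorph import _center_scale, _rotation_to

        target = _center_scale(mean)
        est = fit.mean_shape @ _rotation_to(target, fit.mean_shape)
        # compare in the common unit-size frame; noise shrinks by centroid size
        size = np.sqrt(((mean - mean.mean(axis=0)) ** 2).sum())
        assert np.abs(est - target).max() < 3 * (sd / size) / np.sqrt(30)

    def test_idempotence(self, rng):
        configs = [
            pt.LandmarkConfiguration(str(i), rng.normal(size=(7, 2)))
            for i in range(6)
        ]
        fit1 = pt.generalized_procrustes(configs)
        fit2 = pt.generalized_procrustes(fit1.aligned)
        np.testing.assert_allclose(fit1.aligned, fit2.aligned, atol=1e-8)

    def test_error_cases(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            pt.generalized_procrustes([pt.LandmarkConfiguration("a", rng.normal(size=(4, 2)))])
        degenerate = np.zeros((4, 2))
        with pytest.raises(ValueError, match="centroid size"):
            pt.generalized_procrustes(np.stack([degenerate, degenerate]))


class TestTps:
    def test_identity_map(self, rng):
        ref = rng.normal(size=(6, 2))
        sp = pt.tps_fit(ref, ref)
        assert np.abs(sp.weights).max() < 1e-10
        np.testing.assert_allclose(sp.affine, [[0, 0], [1, 0], [0, 1]], atol=1e-10)
        assert pt.bending_energy(sp) < 1e-10

    def test_affine_shear_has_zero_weights_and_energy(self, rng):
        ref = rng.normal(size=(8, 2))
        A = np.array([[1.0, 0.4], [0.0, 1.0]])  # shear
        sp = pt.tps_fit(ref, ref @ A.T + [2.0, -1.0])
        assert np.abs(sp.weights).max() < 1e-10
        assert pt.bending_energy(sp) < 1e-10

    def test_exact_interpolation_random_8_landmarks(self, rng):
        ref = rng.normal(size=(8, 2)) * 3
        tgt = ref + rng.normal(size=(8, 2))
        sp = pt.tps_fit(ref, tgt)
        assert np.abs(sp(ref) - tgt).max() < 1e-8

    def test_side_conditions(self, rng):
        ref = rng.normal(size=(7, 2))
        sp = pt.tps_fit(ref, ref + 0.5 * rng.normal(size=(7, 2)))
        assert np.abs(sp.weights.sum(axis=0)).max() < 1e-8
        assert np.abs(ref.T @ sp.weights).max() < 1e-8

    def test_energy_matches_numerical_integration(self):
        # fixed 5-landmark case; midpoint-rule integral agrees within 1%
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(5, 2))
        tgt = ref + 0.3 * rng.normal(size=(5, 2))
        sp = pt.tps_fit(ref, tgt)
        exact = pt.bending_energy(sp)
        numeric = numeric_bending_energy(sp)
        assert abs(numeric - exact) / exact < 0.01

    def test_collinear_reference_rejected(self):
        ref = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(ValueError, match="collinear"):
            pt.tps_fit(ref, ref + 1.0)

    def test_energy_zero_iff_affine(self, rng):
        ref = rng.normal(size=(6, 2))
        bent = ref.copy()
        bent[0] += [0.0, 0.5]  # a single displaced landmark cannot be affine
        assert pt.bending_energy(pt.tps_fit(ref, bent)) > 1e-6


class TestWarps:
    @pytest.fixture()
    def fit(self):
        rng = np.random.default_rng(11)
        mean = rng.normal(size=(8, 2))
        configs = [
            pt.LandmarkConfiguration(str(i), mean + rng.normal(0, 0.02, mean.shape))
            for i in range(12)
        ]
        return pt.generalized_procrustes(configs)

    def test_bending_energy_matrix_psd_with_3_zero_eigenvalues(self, fit):
        B = bending_energy_matrix(fit.mean_shape)
        evals = np.linalg.eigvalsh(B)
        assert (evals > -1e-9).all()
        assert (np.abs(evals) < 1e-8).sum() == 3

    def test_identical_specimens_give_zero_scores(self):
        rng = np.random.default_rng(2)
        mean = rng.normal(size=(6, 2))
        configs = [pt.LandmarkConfiguration(str(i), mean.copy()) for i in range(4)]
        decomp = partial_warps(pt.generalized_procrustes(configs))
        assert np.abs(decomp.scores).max() < 1e-9

    def test_single_principal_warp_deformation_loads_one_pair(self, fit):
        decomp = partial_warps(fit)
        warp = decomp.principal_warps[:, 1]
        deformed = fit.mean_shape + 0.01 * np.column_stack([warp, np.zeros_like(warp)])
        # project the constructed residual directly
        resid = deformed - fit.mean_shape
        px = resid[:, 0] @ decomp.principal_warps
        py = resid[:, 1] @ decomp.principal_warps
        on_target = abs(px[1])
        off = np.abs(np.concatenate([np.delete(px, 1), py])).max()
        assert on_target > 1e-3 and off < 1e-12

    def test_parseval_partial_plus_uniform(self, fit):
        # squared scores sum to the tangent-projected residual sum of squares
        decomp = partial_warps(fit)
        k = fit.k
        M = fit.mean_shape
        resid = fit.aligned - M
        resid_vec = np.hstack([resid[:, :, 0], resid[:, :, 1]])
        ones = np.ones(k)
        t_x = np.concatenate([ones, np.zeros(k)]) / np.sqrt(k)
        t_y = np.concatenate([np.zeros(k), ones]) / np.sqrt(k)
        s = np.concatenate([M[:, 0], M[:, 1]])
        s = s / np.linalg.norm(s)
        r = np.concatenate([-M[:, 1], M[:, 0]])
        r = r / np.linalg.norm(r)
        Q = np.column_stack([t_x, t_y, s, r])
        tangent = resid_vec - resid_vec @ Q @ Q.T
        assert abs((decomp.scores**2).sum() - (tangent**2).sum()) < 1e-9

    def test_triangle_has_no_bending_subspace(self):
        rng = np.random.default_rng(3)
        configs = [
            pt.LandmarkConfiguration(str(i), rng.normal(size=(3, 2))) for i in range(5)
        ]
        with pytest.raises(ValueError, match="triangle|bending"):
            partial_warps(pt.generalized_procrustes(configs))


class TestRelativeWarps:
    def test_alpha0_equals_direct_pca(self, rng):
        mean = rng.normal(size=(9, 2))
        configs = [
            pt.LandmarkConfiguration(str(i), mean + rng.normal(0, 0.03, mean.shape))
            for i in range(15)
        ]
        decomp = partial_warps(pt.generalized_procrustes(configs))
        rw = pt.relative_warps(decomp, alpha=0)
        S = decomp.scores
        Sc = S - S.mean(axis=0)
        cov = Sc.T @ Sc / (len(S) - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for j in range(evecs.shape[1]):
            nz = np.nonzero(np.abs(evecs[:, j]) > 1e-12)[0]
            if len(nz) and evecs[nz[0], j] < 0:
                evecs[:, j] *= -1
        np.testing.assert_allclose(rw.eigenvalues, np.clip(evals, 0, None), atol=1e-9)
        np.testing.assert_allclose(rw.relative_warp_scores, Sc @ evecs, atol=1e-9)

    def test_eigenvalue_sum_equals_trace(self, rng):
        mean = rng.normal(size=(7, 2))
        configs = [
            pt.LandmarkConfiguration(str(i), mean + rng.normal(0, 0.05, mean.shape))
            for i in range(10)
        ]
        rw = pt.RelativeWarpsModel(configs).fit()
        S = rw.decomposition.scores
        assert abs(rw.eigenvalues.sum() - np.trace(np.cov(S.T))) < 1e-9

    def test_group_separation_on_rw1(self):
        # two groups with mean-shape offset >> noise separate on RW1
        rng = np.random.default_rng(11)
        mean_a = rng.normal(size=(8, 2))
        offset = rng.normal(size=(8, 2))
        offset -= offset.mean(axis=0)
        mean_b = mean_a + 0.25 * offset / np.abs(offset).max()
        spec = pt.SimSpec(
            seed=11,
            groups=[
                pt.GroupSpec("A", 15, mean_shape=mean_a, noise_sd=0.005),
                pt.GroupSpec("B", 15, mean_shape=mean_b, noise_sd=0.005),
            ],
        )
        res = pt.RelativeWarpsModel(pt.simulate_landmarks(spec)).fit()
        df = res.scores
        a = df.loc[df.group == "A", "RW1"]
        b = df.loc[df.group == "B", "RW1"]
        within = max(a.std(), b.std())
        assert abs(a.mean() - b.mean()) > 5 * within

    def test_similarity_invariance_of_downstream_scores(self, rng):
        mean = rng.normal(size=(7, 2))
        coords = [mean + rng.normal(0, 0.02, mean.shape) for _ in range(8)]
        configs = [pt.LandmarkConfiguration(str(i), c) for i, c in enumerate(coords)]
        moved = [
            pt.LandmarkConfiguration(
                str(i), _similarity(c, 0.7 + 0.1 * i, 1.5, [3.0 * i, -1.0])
            )
            for i, c in enumerate(coords)
        ]
        rw1 = pt.RelativeWarpsModel(configs).fit()
        rw2 = pt.RelativeWarpsModel(moved).fit()
        np.testing.assert_allclose(
            np.abs(rw1.decomposition.relative_warp_scores),
            np.abs(rw2.decomposition.relative_warp_scores),
            atol=1e-8,
        )
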