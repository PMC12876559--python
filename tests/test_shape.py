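"""Statistical shape model: displacement fields, PCA, projection."""

import numpy as np
import pytest

import stenoshape as ss
from stenoshape.shape import vector_to_vertices


class TestAlignment:
    def test_idempotent_on_aligned_mesh(self, small_cohort, template):
        mesh = small_cohort[1][0]
        aligned = ss.align_to_template(mesh, template)
        assert np.allclose(aligned.vertices, mesh.vertices, atol=1e-12)

    def test_translation_undone(self, small_cohort, template):
        mesh = small_cohort[1][1]
        shifted = ss.TubeMesh(nz=mesh.nz, ntheta=mesh.ntheta,
                              vertices=mesh.vertices + np.array(
                                  [1e-3, 2e-3, 3e-3]),
                              source_id=mesh.source_id)
        aligned = ss.align_to_template(shifted, template)
        assert np.allclose(aligned.vertices, mesh.vertices, atol=1e-12)


class TestDisplacementField:
    def test_identity_is_zero(self, template):
        d = ss.displacement_field(template, template)
        assert np.all(d.values == 0)

    def test_radial_push_confined_to_ring(self, template):
        g = template.grid().copy()
        ring = 7
        r = np.hypot(g[ring, :, 0], g[ring, :, 1])
        scale = (r - 1e-4) / r
        g[ring, :, 0] *= scale
        g[ring, :, 1] *= scale
        target = ss.TubeMesh(nz=template.nz, ntheta=template.ntheta,
                             vertices=g.reshape(-1, 3))
        d = vector_to_vertices(ss.displacement_field(template, target).values)
        moved = np.linalg.norm(d, axis=1)
        nt = template.ntheta
        assert np.allclose(moved[ring * nt:(ring + 1) * nt], 1e-4)
        assert np.all(moved[:ring * nt] == 0)
        assert np.all(moved[(ring + 1) * nt:] == 0)
        assert np.all(d[:, 2] == 0)

    def test_additivity(self, template, small_cohort):
        a, b = small_cohort[1][0], small_cohort[1][1]
        d_ta = ss.displacement_field(template, a).values
        d_ab = a.vertices - b.vertices
        d_tb = ss.displacement_field(template, b).values
        assert np.allclose(
            d_ta - np.concatenate([d_ab[:, 0], d_ab[:, 1], d_ab[:, 2]]),
            d_tb, atol=1e-15)

    def test_topology_mismatch_rejected(self, template, consts):
        other = ss.straight_template(consts, ntheta=16)
        with pytest.raises(ValueError):
            ss.displacement_field(template, other)


class TestPCAFit:
    def test_two_shapes_have_one_mode(self, template, small_cohort):
        meshes = small_cohort[1][:2]
        disps = [ss.displacement_field(template, m) for m in meshes]
        model = ss.fit_shape_model(disps, n_modes=1, template=template)
        assert np.sum(model.variances > 1e-30) == 1

    def test_fewer_than_two_rejected(self, template):
        d = ss.displacement_field(template, template)
        with pytest.raises(ValueError):
            ss.fit_shape_model([d], template=template)

    def test_orthonormal_modes(self, shape_model):
        gram = shape_model.modes @ shape_model.modes.T
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_energy_conservation(self, shape_model, small_cohort, template):
        disps = np.stack([ss.displacement_field(template, m).values
                          for m in small_cohort[1]])
        total = np.sum((disps - disps.mean(0)) ** 2) / (len(disps) - 1)
        assert shape_model.variances.sum() == pytest.approx(total, rel=1e-8)

    def test_matches_brute_force_covariance_eig(self, template, small_cohort):
        """Independent oracle: eigendecomposition of the explicit covariance
        matrix of a 10-shape toy cohort."""
        meshes = small_cohort[1][:10]
        disps = [ss.displacement_field(template, m) for m in meshes]
        model = ss.fit_shape_model(disps, n_modes=2, template=template)
        X = np.stack([d.values for d in disps])
        Xc = X - X.mean(0)
        # brute force in sample space (dual trick keeps it exact and small)
        K = Xc @ Xc.T / (len(meshes) - 1)
        w, U = np.linalg.eigh(K)
        w, U = w[::-1], U[:, ::-1]
        k = min(int(np.sum(w > w.max() * 1e-10)), len(meshes) - 1)
        assert np.allclose(model.variances[:k], w[:k], rtol=1e-8)
        modes_bf = (Xc.T @ U[:, :k]) / np.sqrt(w[:k] * (len(meshes) - 1))
        for m in range(k):
            dot = abs(np.dot(modes_bf[:, m], model.modes[m]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_duplication_invariance(self, template, small_cohort):
        meshes = small_cohort[1][:6]
        disps = [ss.displacement_field(template, m) for m in meshes]
        m1 = ss.fit_shape_model(disps, n_modes=3, template=template)
        m2 = ss.fit_shape_model(disps + disps, n_modes=3, template=template)
        f1, _ = ss.explained_variance(m1)
        f2, _ = ss.explained_variance(m2)
        k = np.sum(m1.variances > m1.variances.max() * 1e-10)
        assert np.allclose(f1[:k], f2[:k], atol=1e-10)
        for m in range(k):
            assert abs(np.dot(m1.modes[m], m2.modes[m])) == \
                pytest.approx(1.0, abs=1e-8)


class TestProjection:
    def test_mean_projects_to_zero(self, shape_model):
        d = ss.DisplacementVector(values=shape_model.mean)
        alpha = ss.project(shape_model, d)
        assert np.allclose(alpha.alpha, 0, atol=1e-12)

    def test_mode_direction_recovers_coefficient(self, shape_model):
        d = ss.DisplacementVector(
            values=shape_model.mean + 2.0 * shape_model.modes[0])
        alpha = ss.project(shape_model, d, n_modes=3)
        assert np.allclose(alpha.alpha, [2.0, 0.0, 0.0], atol=1e-10)

    def test_cohort_alphas_centered(self, shape_model, small_cohort,
                                    template):
        alphas = np.stack([
            ss.project(shape_model,
                       ss.displacement_field(template, m)).alpha
            for m in small_cohort[1]])
        assert np.allclose(alphas.mean(0), 0, atol=1e-10)

    def test_projection_is_idempotent(self, shape_model, small_cohort,
                                      template):
        d = ss.displacement_field(template, small_cohort[1][2])
        a1 = ss.project(shape_model, d)
        mesh, _ = ss.reconstruct(shape_model, a1)
        a2 = ss.project(shape_model,
                        ss.displacement_field(template, mesh))
        assert np.allclose(a1.alpha, a2.alpha, atol=1e-10)


class TestReconstruction:
    def test_zero_alpha_gives_mean_shape(self, shape_model):
        mesh, _ = ss.reconstruct(shape_model, np.zeros(3))
        expected = shape_model.template.vertices + vector_to_vertices(
            shape_model.mean)
        assert np.allclose(mesh.vertices, expected, atol=1e-15)

    def test_full_basis_is_exact(self, shape_model, small_cohort, template):
        for mesh in small_cohort[1]:
            d = ss.displacement_field(template, mesh)
            alpha = ss.project(shape_model, d,
                               n_modes=shape_model.n_modes_total)
            _, err = ss.reconstruct(shape_model, alpha, target=mesh)
            assert err < 1e-8  # mm

    def test_error_monotone_in_mode_count(self, shape_model, small_cohort,
                                          template):
        """The aggregate (L2) reconstruction error of nested projections is
        non-increasing in the mode count."""
        mesh = small_cohort[1][5]
        d = ss.displacement_field(template, mesh)
        errs = []
        for k in range(1, shape_model.n_modes_total + 1):
            alpha = ss.project(shape_model, d, n_modes=k)
            recon, _ = ss.reconstruct(shape_model, alpha, target=mesh)
            errs.append(np.linalg.norm(recon.vertices - mesh.vertices))
        assert all(a >= b - 1e-15 for a, b in zip(errs, errs[1:]))


class TestExplainedVariance:
    def test_fractions_sum_to_one(self, shape_model):
        frac, cum = ss.explained_variance(shape_model)
        assert frac.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(cum) >= -1e-15)
        assert cum[-1] == pytest.approx(1.0, abs=1e-12)

    def test_single_mode_dataset(self, template):
        base = ss.DisplacementVector(
            values=np.zeros(template.vertices.size))
        direction = np.zeros(template.vertices.size)
        direction[0] = 1e-4
        shapes = [base,
                  ss.DisplacementVector(values=direction),
                  ss.DisplacementVector(values=2 * direction)]
        model = ss.fit_shape_model(shapes, n_modes=1, template=template)
        frac, _ = ss.explained_variance(model)
        assert frac[0] == pytest.approx(1.0, abs=1e-12)


def test_model_serialization_round_trip(shape_model, tmp_path):
    path = tmp_path / "model.ssm.npz"
    from stenoshape.shape import load_model, save_model
    save_model(shape_model, path)
    loaded = load_model(path)
    assert np.array_equal(loaded.mean, shape_model.mean)
    assert np.array_equal(loaded.modes, shape_model.modes)
    assert loaded.n_modes_kept == shape_model.n_modes_kept
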