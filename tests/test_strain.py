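"""Strain engine: tensor algebra, cylindrical projection, curves, polar map."""

import numpy as np
import pytest

from cinestrain.grids import DisplacementField, SegMask, VolumeGrid
from cinestrain.strain import (
    cylindrical_project,
    define_cardiac_cs,
    detect_es,
    displacement_gradient,
    extract_params,
    global_strain,
    green_lagrange,
    interpolate_and_rate,
    polar_map,
    strain_curves_from_fields,
)

GRID = VolumeGrid((24, 24, 6), (1.25, 1.25, 7.0))


def _field_from_phys(fn):
    """Displacement field (voxel units) from a physical-coordinates function."""
    xs = np.arange(GRID.shape[0]) * GRID.spacing[0]
    ys = np.arange(GRID.shape[1]) * GRID.spacing[1]
    zs = np.arange(GRID.shape[2]) * GRID.spacing[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    u_mm = fn(X, Y, Z)                       # (3, ...)
    dr = np.asarray(GRID.spacing).reshape(3, 1, 1, 1)
    return DisplacementField(GRID, u_mm / dr)


def _annulus_mask(r_in=5.0, r_out=10.0, rv=True):
    cx = (GRID.shape[0] - 1) / 2 * GRID.spacing[0]
    cy = (GRID.shape[1] - 1) / 2 * GRID.spacing[1]
    xs = np.arange(GRID.shape[0]) * GRID.spacing[0]
    ys = np.arange(GRID.shape[1]) * GRID.spacing[1]
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    r = np.hypot(X - cx, Y - cy)
    sl = np.zeros(GRID.shape[:2], dtype=int)
    sl[(r >= r_in) & (r <= r_out)] = 2
    sl[r < r_in] = 3
    if rv:
        sl[np.hypot(X - cx + 13.0, Y - cy) <= 3.0] = 1
    return SegMask(GRID, np.repeat(sl[:, :, None], GRID.shape[2], axis=2))


class TestGradient:
    def test_constant_field_has_zero_gradient(self):
        f = DisplacementField(GRID, np.full((3,) + GRID.shape, 2.0))
        assert np.abs(displacement_gradient(f)).max() == 0.0

    def test_linear_field_recovers_exact_matrix(self):
        A = np.array([[0.1, 0.02, 0.0], [-0.03, 0.2, 0.01], [0.0, 0.05, -0.1]])

        def fn(X, Y, Z):
            return np.stack([A[i, 0] * X + A[i, 1] * Y + A[i, 2] * Z
                             for i in range(3)])

        grad = displacement_gradient(_field_from_phys(fn))
        np.testing.assert_allclose(grad[5, 5, 3], A, atol=1e-12)

    def test_matches_dense_finite_difference_oracle(self):
        rng = np.random.default_rng(0)
        f = DisplacementField(GRID, rng.standard_normal((3,) + GRID.shape))
        grad = displacement_gradient(f)
        u_mm = f.to_mm()
        for i in range(3):
            for j, sp in enumerate(GRID.spacing):
                oracle = np.gradient(u_mm[i], sp, axis=j)
                np.testing.assert_allclose(grad[..., i, j], oracle, atol=1e-10)

    def test_too_small_grid_raises(self):
        g = VolumeGrid((2, 5, 5), (1, 1, 1))
        with pytest.raises(ValueError):
            displacement_gradient(DisplacementField(g, np.zeros((3, 2, 5, 5))))


class TestGreenLagrange:
    def test_zero_gradient_gives_zero_strain(self):
        assert np.abs(green_lagrange(np.zeros((4, 4, 3, 3)))).max() == 0.0

    def test_rigid_rotation_produces_no_strain(self):
        theta = np.deg2rad(30.0)
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])

        def fn(X, Y, Z):
            pts = np.stack([X, Y, Z])
            rot = np.einsum("ij,j...->i...", R, pts)
            return rot - pts

        grad = displacement_gradient(_field_from_phys(fn))
        E = green_lagrange(grad)
        interior = E[1:-1, 1:-1, 1:-1]
        assert np.abs(interior).max() < 1e-8

    def test_isotropic_scaling_closed_form(self):
        s = 1.2

        def fn(X, Y, Z):
            return np.stack([(s - 1) * X, (s - 1) * Y, (s - 1) * Z])

        E = green_lagrange(displacement_gradient(_field_from_phys(fn)))
        expected = (s**2 - 1) / 2 * np.eye(3)
        np.testing.assert_allclose(E[4, 4, 2], expected, atol=1e-10)


class TestCoordinateSystem:
    def test_centered_annulus_center_and_orthogonality(self):
        cs = define_cardiac_cs(_annulus_mask())
        mid = ((GRID.shape[0] - 1) / 2, (GRID.shape[1] - 1) / 2)
        np.testing.assert_allclose(cs.center_xy[0], mid, atol=1.0)
        dots = np.einsum("i...,i...->...", cs.radial, cs.circumferential)
        assert np.abs(dots).max() < 1e-12

    def test_septal_angle_points_to_rv(self):
        cs = define_cardiac_cs(_annulus_mask())
        # RV blob placed in -x direction from the centre
        assert abs(abs(cs.septal_angle[0]) - np.pi) < 0.15

    def test_missing_rv_leaves_orientation_undefined(self):
        cs = define_cardiac_cs(_annulus_mask(rv=False))
        assert cs.septal_angle is None

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            define_cardiac_cs(SegMask(GRID, np.zeros(GRID.shape, dtype=int)))


class TestProjection:
    def test_inplane_isotropic_field_has_equal_rr_cc(self):
        def fn(X, Y, Z):
            cx = (GRID.shape[0] - 1) / 2 * GRID.spacing[0]
            cy = (GRID.shape[1] - 1) / 2 * GRID.spacing[1]
            return np.stack([0.1 * (X - cx), 0.1 * (Y - cy), 0.0 * Z])

        E = green_lagrange(displacement_gradient(_field_from_phys(fn)))
        cyl = cylindrical_project(E, define_cardiac_cs(_annulus_mask()))
        sel = cyl.defined & (_annulus_mask().labels == 2)
        np.testing.assert_allclose(cyl.e_rr[sel], cyl.e_cc[sel], atol=1e-10)

    def test_z_shear_field_projects_onto_shear_components(self):
        alpha = 0.05

        def fn(X, Y, Z):
            return np.stack([alpha * Z, 0.0 * Y, 0.0 * Z])

        E = green_lagrange(displacement_gradient(_field_from_phys(fn)))
        cs = define_cardiac_cs(_annulus_mask())
        cyl = cylindrical_project(E, cs)
        # single-voxel hand computation: E has E_xz = alpha/2 (plus the
        # quadratic E_zz = alpha^2/2), so r^T E z = r_x * alpha/2 and
        # c^T E z = c_x * alpha/2, while E_rc vanishes (no in-plane terms).
        v = (18, 11, 3)
        r_x = cs.radial[0][v]
        c_x = cs.circumferential[0][v]
        assert cyl.e_rz[v] == pytest.approx(r_x * alpha / 2, rel=1e-6)
        assert cyl.e_cz[v] == pytest.approx(c_x * alpha / 2, rel=1e-6, abs=1e-12)
        assert abs(cyl.e_rc[v]) < 1e-10

    def test_phantom_truth_matches_analytic_wall_average(self, phantom_128):
        p, _, truth = phantom_128
        es = truth.es_index
        E = green_lagrange(displacement_gradient(truth.displacements[es]))
        cs = define_cardiac_cs(truth.masks[0])
        cyl = cylindrical_project(E, cs)
        lvm = truth.masks[0].labels == 2
        err = global_strain(cyl, lvm, "e_rr") / 100
        ecc = global_strain(cyl, lvm, "e_cc") / 100
        assert err == pytest.approx(truth.global_err[es], abs=0.01)
        assert ecc == pytest.approx(truth.global_ecc[es], abs=0.01)


class TestGlobalStrain:
    def test_uniform_field_reports_percent(self):
        mask = _annulus_mask()
        cyl = cylindrical_project(
            np.zeros(GRID.shape + (3, 3)), define_cardiac_cs(mask))
        cyl.e_cc[...] = 0.1
        assert global_strain(cyl, mask.labels == 2) == pytest.approx(10.0)

    def test_masked_mean_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        mask = _annulus_mask()
        cyl = cylindrical_project(
            rng.standard_normal(GRID.shape + (3, 3)), define_cardiac_cs(mask))
        sel = (mask.labels == 2) & cyl.defined
        oracle = np.mean([cyl.e_rr[i] for i in np.argwhere(sel)[:, 0:3].tolist()
                          for i in [tuple(i)]]) * 100
        assert global_strain(cyl, mask.labels == 2, "e_rr") == \
            pytest.approx(oracle, abs=1e-9)

    def test_empty_mask_raises(self):
        cyl = cylindrical_project(np.zeros(GRID.shape + (3, 3)),
                                  define_cardiac_cs(_annulus_mask()))
        with pytest.raises(ValueError):
            global_strain(cyl, np.zeros(GRID.shape, dtype=bool))


class TestCurves:
    def test_linear_ramp_gives_constant_rate(self):
        times = np.array([0.0, 50, 100, 150, 200])
        values = np.linspace(0.0, 0.2, 5)
        t, s, r = interpolate_and_rate(values, times)
        np.testing.assert_allclose(r[1:-1], 1.0, atol=1e-9)

    def test_constant_strain_zero_rate(self):
        t, s, r = interpolate_and_rate(np.full(5, 0.1), np.arange(5) * 100.0)
        np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_sinusoid_peak_rate_matches_calculus(self):
        T, A = 1000.0, 0.15
        times = np.arange(0, T + 1, 10.0)
        values = A * np.sin(2 * np.pi * times / T)
        _, _, r = interpolate_and_rate(values, times)
        assert np.abs(r).max() == pytest.approx(2 * np.pi * A / T * 1000,
                                                rel=0.01)

    def test_too_few_frames_raise(self):
        with pytest.raises(ValueError):
            interpolate_and_rate([0.0, 1.0], [0.0, 10.0])


class TestParams:
    def test_triangular_strain_extracts_ess_at_peak(self):
        t = np.arange(0.0, 401.0)
        s = np.where(t <= 200, -0.18 * t / 200, -0.18 * (400 - t) / 200)
        r = np.gradient(s, t) * 1000
        out = extract_params(t, s, r, es_time_ms=200.0)
        assert out["ESS_percent"] == pytest.approx(-18.0, abs=1e-9)
        assert abs(out["SRs_per_s"]) == pytest.approx(abs(out["SRe_per_s"]),
                                                      rel=1e-6)
        assert out["SRs_per_s"] < 0 < out["SRe_per_s"]

    def test_es_time_out_of_range_raises(self):
        t = np.arange(0.0, 100.0)
        with pytest.raises(ValueError):
            extract_params(t, t * 0, t * 0, es_time_ms=500.0)


class TestDetectES:
    def test_phantom_es_detected_from_cavity_minimum(self, desk_phantom):
        _, _, truth = desk_phantom
        assert detect_es(truth.masks) == truth.es_index

    def test_constant_cavity_ties_to_first_frame(self):
        mask = _annulus_mask()
        assert detect_es([mask, mask, mask]) == 0


class TestPolarMap:
    def test_homogeneous_field_has_sixteen_equal_segments(self):
        mask = _annulus_mask()
        cs = define_cardiac_cs(mask)
        cyl = cylindrical_project(np.zeros(GRID.shape + (3, 3)), cs)
        cyl.e_cc[...] = 0.07
        pm = polar_map(cyl, mask, cs)
        assert pm.values.shape == (16,)
        np.testing.assert_allclose(pm.values, 7.0, atol=1e-9)

    def test_segment_counts_partition_the_myocardium(self):
        mask = _annulus_mask()
        cs = define_cardiac_cs(mask)
        cyl = cylindrical_project(np.zeros(GRID.shape + (3, 3)), cs)
        pm = polar_map(cyl, mask, cs)
        lvm_defined = (mask.labels == 2) & cyl.defined
        assert pm.voxel_counts.sum() == lvm_defined.sum()

    def test_angular_field_matches_sector_average_oracle(self):
        mask = _annulus_mask()
        cs = define_cardiac_cs(mask)
        cyl = cylindrical_project(np.zeros(GRID.shape + (3, 3)), cs)
        # field = angle from septal direction
        xi = np.arange(GRID.shape[0])[:, None]
        yi = np.arange(GRID.shape[1])[None, :]
        for k in range(GRID.shape[2]):
            ang = np.arctan2(yi - cs.center_xy[k, 1], xi - cs.center_xy[k, 0])
            cyl.e_cc[:, :, k] = np.mod(ang - cs.septal_angle[k], 2 * np.pi)
        pm = polar_map(cyl, mask, cs)
        # oracle: direct masked average per sector on the basal ring
        ref = cs.septal_angle[0] + np.pi / 2
        lvm = (mask.labels == 2) & cyl.defined
        ang0 = np.mod(np.arctan2(yi - cs.center_xy[0, 1],
                                 xi - cs.center_xy[0, 0]) - ref, 2 * np.pi)
        sect0 = np.minimum((ang0 / (np.pi / 3)).astype(int), 5)
        k_basal = [0, 1]                      # 6 slices -> 2 per ring
        for s in range(6):
            vals = [cyl.e_cc[:, :, k][lvm[:, :, k] & (sect0 == s)]
                    for k in k_basal]
            oracle = np.concatenate(vals).mean() * 100
            assert pm.values[s] == pytest.approx(oracle, abs=1e-9)

    def test_missing_rv_raises(self):
        mask = _annulus_mask(rv=False)
        cs = define_cardiac_cs(mask)
        cyl = cylindrical_project(np.zeros(GRID.shape + (3, 3)), cs)
        with pytest.raises(ValueError):
            polar_map(cyl, mask, cs)


class TestCurvePipeline:
    def test_phantom_truth_fields_reproduce_analytic_curves(self, desk_phantom):
        p, seq, truth = desk_phantom
        curves = strain_curves_from_fields(
            truth.displacements, truth.masks[0], seq.frame_times,
            truth.es_index)
        ess_cc = curves.params["e_cc"]["ESS_percent"]
        assert ess_cc == pytest.approx(truth.global_ecc[truth.es_index] * 100,
                                       abs=1.0)
        # curves start at zero strain by construction
        assert curves.strain["e_cc"][0] == 0.0
        assert len(curves.strain_rate["e_cc"]) == len(curves.strain["e_cc"])
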