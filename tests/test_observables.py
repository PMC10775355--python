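"""Shape tensors, orientational order, and junction tension."""

import numpy as np
import pytest

import vertexclosure as vc
from vertexclosure.observables import cell_shape_tensor, observable_record

from conftest import P_HEX, build_brick_wall


class TestShapeTensor:
    def test_regular_hexagon_is_isotropic(self, hex44):
        alpha, theta = cell_shape_tensor(hex44)
        np.testing.assert_allclose(alpha, 1.0, atol=1e-9)
        assert np.isnan(theta).all()

    def test_wide_rectangle(self):
        state = build_brick_wall(2, 4, w=2.0, h=1.0)
        alpha, theta = cell_shape_tensor(state)
        np.testing.assert_allclose(alpha, 2.0, rtol=1e-12)
        np.testing.assert_allclose(theta, 0.0, atol=1e-12)

    def test_rotation_covariance(self):
        # the same 2:1 rectangle rotated 90 degrees: theta = pi/2
        state = build_brick_wall(2, 4, w=1.0, h=2.0)
        alpha, theta = cell_shape_tensor(state)
        np.testing.assert_allclose(alpha, 2.0, rtol=1e-12)
        np.testing.assert_allclose(np.abs(theta), np.pi / 2, atol=1e-12)

    def test_single_cell_access(self, hex44):
        a, t = cell_shape_tensor(hex44, cell_id=0)
        assert a == pytest.approx(1.0, abs=1e-9)
        assert np.isnan(t)


class TestOrderParameter:
    def test_perfect_ap_alignment(self):
        state = build_brick_wall(3, 4, w=2.0, h=1.0)
        assert vc.order_parameter(state) == pytest.approx(1.0, abs=1e-12)

    def test_perfect_transverse_alignment(self):
        state = build_brick_wall(3, 4, w=1.0, h=2.0)
        assert vc.order_parameter(state) == pytest.approx(-1.0, abs=1e-12)

    def test_disordered_tiling_is_near_zero(self, params):
        box = vc.Box(np.sqrt(128.0), np.sqrt(128.0))
        st = vc.build_voronoi_tissue(128, box, seed=21)
        st.p0[:] = 3.8
        relaxed, _ = vc.minimize(st, params, allow_t1=False)
        q = vc.order_parameter(relaxed)
        assert abs(q) < 3.0 / np.sqrt(128)

    def test_all_isotropic_warns_and_returns_zero(self, hex44):
        with pytest.warns(UserWarning):
            assert vc.order_parameter(hex44) == 0.0


class TestJunctionTension:
    def test_ground_state_tension_zero(self, hex44, params):
        hex44.p0[:] = P_HEX
        taus = vc.junction_tensions(hex44, params)
        np.testing.assert_allclose(taus, 0.0, atol=1e-12)

    def test_hexagon_closed_form(self, hex44, params):
        hex44.p0[:] = 3.5
        taus = vc.junction_tensions(hex44, params)
        expected = 2.0 * (P_HEX - 3.5)
        np.testing.assert_allclose(taus, expected, rtol=1e-12)
        assert expected == pytest.approx(0.4448, abs=1e-3)

    def test_single_junction_api(self, hex44, params):
        hex44.p0[:] = 3.5
        j = vc.junction_list(hex44)[5]
        tau = vc.junction_tension(hex44, params, j)
        assert tau == pytest.approx(2.0 * (P_HEX - 3.5), rel=1e-12)

    def test_dead_cell_junction_rejected(self, voronoi32, params):
        j = vc.junction_list(voronoi32)[0]
        removed, _ = vc.t2_remove_cell(voronoi32, j.cell_i)
        with pytest.raises(vc.GeometryError):
            vc.junction_tension(removed, params, j)

    def test_tension_is_energy_derivative_wrt_junction_length(
        self, voronoi32, params
    ):
        """Elongating one junction's contour by h (holding every other
        edge length fixed) changes the two adjacent cells' perimeters by
        h each, so dE/dh must equal the junction tension of the energy's
        perimeter springs."""
        st = voronoi32.copy()
        st.p0[:] = 3.7
        relaxed, _ = vc.minimize(st, params, allow_t1=False)
        areas, perims = vc.cell_geometry(relaxed)
        taus = vc.junction_tensions(relaxed, params)
        juncs = vc.junction_list(relaxed)
        h = 1e-6

        def energy_with_elongation(eps):
            e = 0.0
            for ci in range(len(relaxed.cells)):
                p = perims[ci]
                if ci in (j.cell_i, j.cell_j):
                    p = p + eps
                e += 0.5 * params.ka * (areas[ci] - params.a0) ** 2
                e += 0.5 * params.kp * (p - relaxed.p0[ci]) ** 2
            return e

        for k in (0, 7, 19):
            j = juncs[k]
            num = (energy_with_elongation(h) - energy_with_elongation(-h)) / (2 * h)
            assert abs(num - taus[k]) < 1e-4


class TestObservableRecord:
    def test_monodisperse_ground_state(self, hex44, params):
        hex44.p0[:] = P_HEX
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-isotropic order parameter
            rec = observable_record(hex44, params, dA=0.0)
        assert rec.q_mean == pytest.approx(P_HEX, rel=1e-12)
        assert rec.q_sd == pytest.approx(0.0, abs=1e-12)
        assert rec.tension_mean == pytest.approx(0.0, abs=1e-12)
        assert rec.fr == 0.0

    def test_relabeling_invariance(self, voronoi32, params):
        st = voronoi32.copy()
        st.p0[:] = 3.75
        relaxed, _ = vc.minimize(st, params, allow_t1=False)
        rec = observable_record(relaxed, params, dA=0.1)
        perm = np.random.default_rng(0).permutation(len(relaxed.cells))
        shuffled = vc.TissueState(
            vertices=relaxed.vertices.copy(),
            cells=[relaxed.cells[i] for i in perm],
            p0=relaxed.p0[perm],
            a0=relaxed.a0,
            box=relaxed.box,
            alive=relaxed.alive[perm],
        )
        rec2 = observable_record(shuffled, params, dA=0.1)
        for f in ("q_mean", "q_sd", "ar_mean", "ar_sd", "Q_order",
                  "tension_mean", "fr"):
            assert getattr(rec2, f) == pytest.approx(getattr(rec, f), rel=1e-9)

    def test_compression_raises_orientational_order(self, params):
        from vertexclosure.protocol import ClosureSchedule, apply_deformation_step

        box = vc.Box(np.sqrt(128.0), np.sqrt(128.0))
        st = vc.build_voronoi_tissue(64, vc.Box(np.sqrt(128.0), np.sqrt(32.0)), seed=6)
        st.p0[:] = 3.8
        relaxed, _ = vc.minimize(st, params, allow_t1=False)
        q_before = vc.order_parameter(relaxed)
        schedule = ClosureSchedule(delta=0.01, dA_max=0.4)
        box0 = relaxed.box
        stc = relaxed.copy()
        for _ in range(40):
            stc = apply_deformation_step(stc, schedule, box0, inplace=True)
        stc, _ = vc.minimize(stc, params, allow_t1=False, inplace=True)
        assert vc.order_parameter(stc) > q_before
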