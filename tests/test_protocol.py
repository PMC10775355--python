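"""The quasistatic dorsal-closure protocol."""

import numpy as np
import pytest

import vertexclosure as vc
from vertexclosure.protocol import (
    ClosureSchedule,
    ClosureStage,
    RunConfig,
    apply_deformation_step,
    initialize_polydisperse,
    ingress_cells,
    run_closure,
    update_preferred_perimeters,
)


@pytest.fixture(scope="module")
def smoke_traj():
    """One small closure run shared by the smoke-level assertions."""
    cfg = RunConfig(
        n_cells=48, seed=3, dA_max=0.12, record_stride=0.02,
        snapshot_stride=0.06, tol=1e-6,
    )
    return cfg, run_closure(cfg)


class TestInitialization:
    def test_preferred_index_distribution(self, params):
        box = vc.Box(np.sqrt(800.0), np.sqrt(200.0))
        state = vc.build_voronoi_tissue(400, box, seed=2)
        dist = vc.InitialShapeDistribution(q0_mean=4.2, q0_sd=0.45)
        st = initialize_polydisperse(state, dist, seed=5, relax=False)
        q0 = st.p0 / np.sqrt(params.a0)
        assert q0.std(ddof=1) == pytest.approx(0.45, abs=0.05)
        assert q0.mean() == pytest.approx(4.2, abs=0.08)
        assert (st.p0 > 0).all()

    def test_degenerate_distribution(self):
        box = vc.Box(6.0, 6.0)
        state = vc.build_voronoi_tissue(36, box, seed=0)
        dist = vc.InitialShapeDistribution(q0_mean=3.9, q0_sd=0.0)
        st = initialize_polydisperse(state, dist, seed=1, relax=False)
        assert np.unique(st.p0).size == 1

    def test_same_seed_same_assignment(self):
        box = vc.Box(6.0, 6.0)
        state = vc.build_voronoi_tissue(36, box, seed=0)
        dist = vc.InitialShapeDistribution()
        a = initialize_polydisperse(state, dist, seed=7, relax=False)
        b = initialize_polydisperse(state, dist, seed=7, relax=False)
        np.testing.assert_array_equal(a.p0, b.p0)

    def test_misconfigured_width_rejected(self):
        with pytest.raises(ValueError):
            vc.InitialShapeDistribution(q0_mean=0.5, q0_sd=0.45)


class TestDeformation:
    def test_uniaxial_step_area_algebra(self, voronoi32):
        schedule = ClosureSchedule(delta=0.00125)
        box0 = voronoi32.box
        st = voronoi32.copy()
        for k in range(1, 9):
            st = apply_deformation_step(st, schedule, box0)
            dA = 1.0 - st.box.area / box0.area
            assert dA == pytest.approx(k * schedule.delta, rel=1e-12)
            assert st.box.lx == box0.lx  # width held fixed

    def test_isotropic_step_matches_area_decrement(self, voronoi32):
        box0 = voronoi32.box
        uni = apply_deformation_step(
            voronoi32, ClosureSchedule(mode="uniaxial"), box0
        )
        iso = apply_deformation_step(
            voronoi32, ClosureSchedule(mode="isotropic"), box0
        )
        assert iso.box.area == pytest.approx(uni.box.area, rel=1e-12)
        assert iso.box.lx / iso.box.ly == pytest.approx(
            box0.lx / box0.ly, rel=1e-12
        )

    def test_360_steps_reach_45_percent_closure(self):
        schedule = ClosureSchedule(delta=0.00125, dA_max=0.45)
        assert schedule.n_steps == 360
        assert 360 * 0.00125 == pytest.approx(0.45)

    def test_collapse_guard(self, voronoi32):
        schedule = ClosureSchedule(delta=0.09, dA_max=0.9 - 1e-9)
        st = voronoi32.copy()
        box0 = st.box
        with pytest.raises(ValueError):
            for _ in range(12):
                st = apply_deformation_step(st, schedule, box0, inplace=True)


class TestPreferredPerimeterSchedule:
    def test_no_shrink_control(self, voronoi32):
        p0 = voronoi32.p0.copy()
        schedule = ClosureSchedule(shrink_slope=0.0)
        st = update_preferred_perimeters(
            voronoi32, ClosureStage(0.7, 100.0), schedule, p0
        )
        np.testing.assert_array_equal(st.p0, p0)

    def test_linear_shrink_arithmetic(self, voronoi32):
        p0 = voronoi32.p0.copy()
        schedule = ClosureSchedule(shrink_slope=0.5)
        st = update_preferred_perimeters(
            voronoi32, ClosureStage(0.4, 100.0), schedule, p0
        )
        np.testing.assert_allclose(st.p0, 0.8 * p0, rtol=1e-12)

    def test_mean_ratio_linear_in_dA(self, voronoi32):
        p0 = voronoi32.p0.copy()
        schedule = ClosureSchedule(shrink_slope=0.65)
        ratios = []
        for dA in (0.1, 0.2, 0.3):
            st = update_preferred_perimeters(
                voronoi32, ClosureStage(dA, 100.0), schedule, p0
            )
            ratios.append(np.mean(st.p0 / p0))
        np.testing.assert_allclose(np.diff(ratios), -0.65 * 0.1, rtol=1e-9)

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            ClosureSchedule(shrink_slope=-0.1)


class TestIngression:
    def test_zero_fraction_is_noop(self, voronoi32):
        schedule = ClosureSchedule(ingression_fraction=0.0)
        rng = np.random.default_rng(0)
        st, events = ingress_cells(voronoi32, schedule, rng, 32, relax=False)
        assert events == []
        assert st.n_cells_alive == 32

    def test_removal_rate_matches_schedule(self, voronoi32):
        # expected removals over a full schedule: f_I * N0, binomial spread
        schedule = ClosureSchedule(ingression_fraction=0.1, dA_max=0.1)
        rng = np.random.default_rng(12)
        st = voronoi32.copy()
        n_removed = 0
        for _ in range(schedule.n_steps):
            st, events = ingress_cells(st, schedule, rng, 32, relax=False)
            n_removed += len(events)
        mean = 0.1 * 32
        assert abs(n_removed - mean) <= 5 * np.sqrt(mean)

    def test_same_seed_same_removals(self, voronoi32):
        schedule = ClosureSchedule(ingression_fraction=0.5, dA_max=0.1)
        seqs = []
        for _ in range(2):
            rng = np.random.default_rng(3)
            st = voronoi32.copy()
            removed = []
            for _ in range(20):
                st, events = ingress_cells(st, schedule, rng, 32, relax=False)
                removed += [e["cell"] for e in events]
            seqs.append(removed)
        assert seqs[0] == seqs[1]


class TestRunClosure:
    def test_smoke_run_records(self, smoke_traj):
        cfg, traj = smoke_traj
        assert traj.valid
        df = traj.to_frame()
        assert len(df) == 7  # dA = 0.00, 0.02, ..., 0.12
        assert (np.diff(df["dA"]) > 0).all()
        assert (df["fr"] >= 0).all() and (df["fr"] <= 1).all()

    def test_quasistatic_snapshots_force_balanced(self, smoke_traj, params):
        cfg, traj = smoke_traj
        assert traj.snapshots
        for dA, snap in traj.snapshots:
            assert vc.force_residual(snap, params) < cfg.tol * 1.01

    def test_box_and_cell_area_bookkeeping_agree(self, smoke_traj):
        cfg, traj = smoke_traj
        for dA, snap in traj.snapshots:
            areas, _ = vc.cell_geometry(snap)
            assert np.nansum(areas) == pytest.approx(snap.box.area, rel=1e-9)

    def test_trajectory_is_pure_function_of_config(self, smoke_traj):
        cfg, traj = smoke_traj
        again = run_closure(cfg)
        assert traj.to_frame().equals(again.to_frame())

    def test_fluidization_control_stops_on_first_t1(self):
        cfg = RunConfig(
            n_cells=48, seed=3, shrink_slope=0.0, dA_max=0.3,
            stop_on_t1=True, tol=1e-6,
        )
        traj = run_closure(cfg)
        assert traj.valid
        assert traj.n_t1 >= 1
        assert "stopped after first T1" in traj.message
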