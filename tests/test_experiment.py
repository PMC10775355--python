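"""Tracked-cell staging/filtering, recoil fitting, and the S-vr crossover."""

import numpy as np
import pandas as pd
import pytest

import vertexclosure as vc
from vertexclosure.experiment import (
    AblationTrace,
    FitError,
    StagingError,
    central_region_filter,
    closure_stage,
    crossover_fit,
    fit_recoil,
    junction_straightness,
    stage_binned_stats,
)


def frames_df(areas, embryo="e1"):
    n = len(areas)
    return pd.DataFrame(
        {
            "embryo": embryo, "frame": range(n), "time_s": 15.0 * np.arange(n),
            "as_area_um2": areas,
            "ell_cx": 0.0, "ell_cy": 0.0, "ell_a": 60.0, "ell_b": 30.0,
            "ell_theta": 0.0,
        }
    )


class TestClosureStage:
    def test_definition_arithmetic(self):
        staged = closure_stage(frames_df([11_000.0, 4_950.0]), A0=11_000.0)
        assert staged["dA"].iloc[0] == pytest.approx(0.0)
        assert staged["dA"].iloc[1] == pytest.approx(0.55)

    def test_pre_crossing_frames_dropped(self):
        staged = closure_stage(frames_df([14_000.0, 12_000.0, 10_000.0, 8_000.0]))
        assert len(staged) == 2
        assert staged["frame"].tolist() == [2, 3]

    def test_linear_area_gives_linear_stage(self):
        areas = 11_000.0 - 50.0 * np.arange(20)
        staged = closure_stage(frames_df(areas))
        slopes = np.diff(staged["dA"]) / np.diff(staged["time_s"])
        np.testing.assert_allclose(slopes, slopes[0], rtol=1e-12)

    def test_unreached_reference_errors(self):
        with pytest.raises(StagingError):
            closure_stage(frames_df([20_000.0, 18_000.0]))


class TestCentralRegionFilter:
    def make_table(self, points):
        cells = pd.DataFrame(
            {
                "embryo": "e1", "frame": 0, "time_s": 0.0,
                "cell": range(len(points)),
                "x_um": [p[0] for p in points],
                "y_um": [p[1] for p in points],
                "area_um2": 30.0, "perim_um": 25.0,
                "aspect_ratio": 1.5, "theta_rad": 0.0,
            }
        )
        return vc.TrackedCellTable(
            cells=cells, frames=frames_df([11_000.0]),
            junctions=pd.DataFrame(columns=[
                "embryo", "frame", "junction", "contour_um", "endtoend_um",
            ]),
        )

    def test_gate_boundaries(self):
        # ellipse a=60, b=30: keep within 0.75a on the major axis and
        # 0.90b on the minor axis
        table = self.make_table(
            [(0.0, 0.0), (0.80 * 60.0, 0.0), (0.0, 0.85 * 30.0)]
        )
        kept = central_region_filter(table, "e1", 0)
        assert kept["cell"].tolist() == [0, 2]

    def test_missing_ellipse_errors(self):
        table = self.make_table([(0.0, 0.0)])
        table.frames.loc[0, "ell_a"] = np.nan
        with pytest.raises(ValueError):
            central_region_filter(table, "e1", 0)


class TestStraightness:
    @pytest.mark.parametrize(
        "dv,L,expected",
        [
            (5.0, 5.0, 1.0),
            (4.65, 5.0, 0.93),
            (2.0, np.pi, 2.0 / np.pi),  # semicircular arc of radius 1
        ],
    )
    def test_values(self, dv, L, expected):
        assert junction_straightness(dv, L) == pytest.approx(expected, rel=1e-12)

    def test_segmentation_artifact_rejected(self):
        with pytest.raises(ValueError):
            junction_straightness(5.1, 5.0)
        with pytest.raises(ValueError):
            junction_straightness(1.0, 0.0)


class TestRecoilFit:
    def make_trace(self, a1, b0, a2, d0, c, noise=0.0, n=300, seed=0):
        t = np.arange(n) / 5.0
        rng = np.random.default_rng(seed)
        d = a1 * np.exp(b0 * t) + a2 * np.exp(d0 * t) + c
        d = d + noise * rng.normal(size=n)
        return AblationTrace(time_s=t, d_um=d)

    def test_noiseless_recovery(self):
        trace = self.make_trace(-0.35, -0.8, -1.5, -0.04, 2.5)
        fit = fit_recoil(trace)
        expected = (-0.35) * (-0.8) + (-1.5) * (-0.04)
        assert fit.vr == pytest.approx(expected, rel=1e-3)
        assert fit.ssr < 1e-12

    def test_single_exponential_limit(self):
        trace = self.make_trace(-0.5, -0.6, 0.0, -0.05, 2.0)
        fit = fit_recoil(trace)
        assert fit.vr == pytest.approx(0.3, rel=1e-3)

    def test_constant_trace_gives_zero_velocity(self):
        trace = AblationTrace(time_s=np.arange(20) / 5.0, d_um=np.full(20, 1.3))
        fit = fit_recoil(trace)
        assert fit.vr == pytest.approx(0.0, abs=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_recoil(AblationTrace(time_s=np.arange(5.0), d_um=np.ones(5)))

    def test_noisy_recovery_within_five_percent(self):
        """v_r recovered within 5% at 2% noise for >= 95% of replicates."""
        traces, truth = vc.generate_ablation_traces(
            n=100, noise=0.02, seed=42, n_frames=300
        )
        ok = 0
        for trace, info in zip(traces, truth):
            fit = fit_recoil(trace)
            if abs(fit.vr - info["vr"]) <= 0.05 * info["vr"]:
                ok += 1
        assert ok >= 95


class TestCrossoverFit:
    def make_pairs(self, n=97, knot=0.93, flat=0.2, slope=2.5, noise=0.01, seed=1):
        rng = np.random.default_rng(seed)
        s = rng.uniform(0.80, 1.0, size=n)
        v = flat + slope * np.maximum(s - knot, 0.0) + noise * rng.normal(size=n)
        return s, v

    def test_planted_breakpoint_recovered(self):
        s, v = self.make_pairs()
        fit = crossover_fit(s, v)
        assert fit.breakpoint == pytest.approx(0.93, abs=0.02)
        assert fit.identifiable
        assert fit.flat_level == pytest.approx(0.2, abs=0.03)

    def test_flat_data_flagged_unidentifiable(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(0.8, 1.0, size=50)
        v = 0.3 + 0.005 * rng.normal(size=50)
        fit = crossover_fit(s, v, n_boot=20)
        assert not fit.identifiable
        assert abs(fit.slope) < 0.5

    def test_pure_linear_data_pushes_knot_to_lower_edge(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(0.8, 1.0, size=60)
        v = 2.0 * s + 0.002 * rng.normal(size=60)
        fit = crossover_fit(s, v, n_boot=20)
        assert fit.breakpoint < 0.84

    def test_insufficient_pairs_rejected(self):
        with pytest.raises(ValueError):
            crossover_fit([0.9] * 5, [0.1] * 5)


class TestStageBinnedStats:
    def test_single_occupied_bin(self):
        out = stage_binned_stats([1.0, 2.0, 3.0], [0.1, 0.2, 0.3])
        assert out["n"].tolist() == [3, 0, 0]
        assert np.isnan(out["median"].iloc[1])
        assert out["median"].iloc[0] == 2.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        v = rng.uniform(size=40)
        d = rng.uniform(0, 1, size=40)
        a = stage_binned_stats(v, d)
        perm = rng.permutation(40)
        b = stage_binned_stats(v[perm], d[perm])
        pd.testing.assert_frame_equal(a, b)

    def test_hump_peaks_in_middle_bin(self):
        _, truth = vc.generate_ablation_traces(n=120, noise=0.0, seed=9, n_frames=20)
        vr = np.array([t["vr"] for t in truth])
        dA = np.array([t["dA"] for t in truth])
        out = stage_binned_stats(vr, dA)
        medians = out["median"].to_numpy()
        assert medians[1] > medians[0]
        assert medians[1] > medians[2]

    def test_bin_edges_as_configured(self):
        out = stage_binned_stats([1.0], [0.5], edges=(0.4, 0.7))
        assert out["bin"].tolist() == ["dA<0.4", "0.4<=dA<0.7", "dA>=0.7"]
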