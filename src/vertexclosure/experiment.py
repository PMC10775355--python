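"""Analysis of tracked-cell tables and laser-ablation recoil traces.

These are the computations applied to segmented live-imaging data (or to
synthetic stand-ins with the same statistical structure): staging closure
progress by fractional area change, restricting to the central tissue
region, junction straightness S = dv / L, double-exponential recoil fits
yielding the initial recoil velocity v_r, the flat-then-linear crossover
of v_r against S, and stage-binned summaries.  Times are seconds and
lengths micrometres throughout; model units never appear in these tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

#: reference area (um^2) at which per-embryo analysis starts
DEFAULT_A0_UM2 = 11_000.0

#: central-region gate: fractions of the fitted AS ellipse semi-axes
MAJOR_AXIS_FRACTION = 0.75
MINOR_AXIS_FRACTION = 0.90

CELL_COLUMNS = [
    "embryo", "frame", "time_s", "cell", "x_um", "y_um",
    "area_um2", "perim_um", "aspect_ratio", "theta_rad",
]
FRAME_COLUMNS = [
    "embryo", "frame", "time_s", "as_area_um2",
    "ell_cx", "ell_cy", "ell_a", "ell_b", "ell_theta",
]
JUNCTION_COLUMNS = [
    "embryo", "frame", "time_s", "junction", "contour_um", "endtoend_um",
]


class StagingError(ValueError):
    """Raised when a tracked area series cannot be staged."""


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails from every starting point."""


@dataclass
class TrackedCellTable:
    """Per-frame cell, tissue and junction measurements of one cohort."""

    cells: pd.DataFrame
    frames: pd.DataFrame
    junctions: pd.DataFrame

    def validate(self, strict: bool = False) -> None:
        for df, cols, name in (
            (self.cells, CELL_COLUMNS, "cells"),
            (self.frames, FRAME_COLUMNS, "frames"),
            (self.junctions, JUNCTION_COLUMNS, "junctions"),
        ):
            missing = set(cols) - set(df.columns)
            if missing:
                raise ValueError(f"{name} table missing columns {sorted(missing)}")
            if strict:
                unknown = set(df.columns) - set(cols)
                if unknown:
                    raise ValueError(
                        f"{name} table has unknown column(s) {sorted(unknown)}"
                    )
        if (self.cells["area_um2"] <= 0).any() or (self.cells["perim_um"] <= 0).any():
            raise ValueError("cell areas and perimeters must be positive")
        if (self.junctions["contour_um"] <= 0).any():
            raise ValueError("junction contour lengths must be positive")
        if (
            self.junctions["endtoend_um"] > self.junctions["contour_um"] * (1 + 1e-9)
        ).any():
            raise ValueError("end-to-end distance exceeds contour length")

    def write_csv(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(d / "cells.csv", index=False)
        self.frames.to_csv(d / "frames.csv", index=False)
        self.junctions.to_csv(d / "junctions.csv", index=False)

    @classmethod
    def read_csv(cls, directory, strict: bool = False) -> "TrackedCellTable":
        d = Path(directory)
        table = cls(
            cells=pd.read_csv(d / "cells.csv"),
            frames=pd.read_csv(d / "frames.csv"),
            junctions=pd.read_csv(d / "junctions.csv"),
        )
        table.validate(strict=strict)
        return table


@dataclass(frozen=True)
class AblationTrace:
    """Inter-vertex distance d(t) after severing one junction."""

    time_s: np.ndarray
    d_um: np.ndarray
    straightness: float = np.nan
    dA: float = np.nan

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        d = np.asarray(self.d_um, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "d_um", d)
        if t.size != d.size:
            raise ValueError("time and distance series must have equal length")
        if t.size and d[0] < 0:
            raise ValueError("initial vertex separation must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class RecoilFit:
    """d(t) = amp1 exp(rate1 t) + amp2 exp(rate2 t) + offset."""

    amp1: float
    amp2: float
    offset: float
    rate1: float
    rate2: float
    ssr: float
    n_points: int

    @property
    def vr(self) -> float:
        """Initial recoil velocity: the fit's slope at t = 0 (um/s)."""
        return self.amp1 * self.rate1 + self.amp2 * self.rate2

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (
            self.amp1 * np.exp(self.rate1 * t)
            + self.amp2 * np.exp(self.rate2 * t)
            + self.offset
        )


# ---------------------------------------------------------------------------
# staging and filtering
# ---------------------------------------------------------------------------

def closure_stage(
    frames: pd.DataFrame, A0: float = DEFAULT_A0_UM2
) -> pd.DataFrame:
    """Per-frame dA = (A0 - A) / A0, started at the A0 crossing.

    Frames before the tissue area first drops to A0 are dropped so that
    embryos with different absolute timing can be pooled on a common
    stage axis.  Raises :class:`StagingError` for an embryo whose area
    series never reaches A0.
    """
    if A0 <= 0:
        raise ValueError("reference area must be positive")
    out = []
    for embryo, grp in frames.groupby("embryo", sort=False):
        grp = grp.sort_values("frame")
        area = grp["as_area_um2"].to_numpy(dtype=float)
        hits = np.flatnonzero(area <= A0)
        if hits.size == 0:
            raise StagingError(
                f"embryo {embryo!r}: AS area never reaches A0={A0:g} um^2"
            )
        grp = grp.iloc[hits[0]:].copy()
        grp["dA"] = (A0 - grp["as_area_um2"]) / A0
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def central_region_filter(
    table: TrackedCellTable, embryo, frame
) -> pd.DataFrame:
    """Cells of one frame inside the central-region ellipse gate.

    A cell is kept when its centroid, in the frame's fitted-ellipse
    coordinates, satisfies (x'/(0.75 a))^2 + (y'/(0.90 b))^2 <= 1 --
    i.e. within 75% of the semi-major and 90% of the semi-minor axis,
    excluding the tissue border and canthi regions.
    """
    fr = table.frames
    sel = fr[(fr["embryo"] == embryo) & (fr["frame"] == frame)]
    if len(sel) != 1 or sel[["ell_a", "ell_b"]].isna().any().any():
        raise ValueError(f"no ellipse fit for embryo {embryo!r} frame {frame!r}")
    row = sel.iloc[0]
    cells = table.cells
    sub = cells[(cells["embryo"] == embryo) & (cells["frame"] == frame)].copy()
    dx = sub["x_um"].to_numpy() - row["ell_cx"]
    dy = sub["y_um"].to_numpy() - row["ell_cy"]
    ct, st = np.cos(row["ell_theta"]), np.sin(row["ell_theta"])
    xp = dx * ct + dy * st
    yp = -dx * st + dy * ct
    r2 = (xp / (MAJOR_AXIS_FRACTION * row["ell_a"])) ** 2 + (
        yp / (MINOR_AXIS_FRACTION * row["ell_b"])
    ) ** 2
    return sub[r2 <= 1.0]


def junction_straightness(dv, L):
    """S = dv / L in (0, 1]: end-to-end distance over contour length."""
    dv = np.asarray(dv, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise ValueError("contour length must be positive")
    if np.any(dv > L * (1 + 1e-9)):
        raise ValueError(
            "end-to-end distance exceeds contour length (segmentation artifact)"
        )
    return dv / L


# ---------------------------------------------------------------------------
# recoil fitting
# ---------------------------------------------------------------------------

def _double_exp(t, a1, b0, a2, d0, c):
    return a1 * np.exp(b0 * t) + a2 * np.exp(d0 * t) + c


def _varpro_amplitudes(t, d, b0, d0):
    """Linear least squares for amplitudes/offset at fixed rates."""
    design = np.column_stack([np.exp(b0 * t), np.exp(d0 * t), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(design, d, rcond=None)
    resid = d - design @ coef
    return coef, float(resid @ resid)


def fit_recoil(trace: AblationTrace, min_points: int = 10) -> RecoilFit:
    """Double-exponential fit of a post-cut recoil trace.

    Rates are multi-started on a grid spanning fast and slow relaxation
    relative to the trace duration, with amplitudes initialized by linear
    least squares at fixed rates, then all five parameters refined by
    nonlinear least squares.  The best fit by residual sum of squares is
    returned; if no start converges (and no rate pair already explains
    the data to near machine precision) a :class:`FitError` carries the
    diagnostics rather than a silent best-effort value.
    """
    t = trace.time_s - trace.time_s[0]
    d = trace.d_um
    if t.size < min_points:
        raise ValueError(f"need at least {min_points} post-cut samples, got {t.size}")
    T = t[-1] if t[-1] > 0 else 1.0
    scale = float(np.mean(d * d)) * t.size
    rate_starts = [
        (-20.0 / T, -2.0 / T),
        (-5.0 / T, -0.5 / T),
        (-2.0 / T, -0.2 / T),
        (-1.0 / T, -0.05 / T),
    ]
    best: RecoilFit | None = None
    diagnostics = []
    for b0, d0 in rate_starts:
        (a1, a2, c), ssr0 = _varpro_amplitudes(t, d, b0, d0)
        candidate = None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(
                    _double_exp, t, d, p0=[a1, b0, a2, d0, c], maxfev=20_000
                )
            pred = _double_exp(t, *popt)
            ssr = float(np.sum((d - pred) ** 2))
            candidate = RecoilFit(
                amp1=popt[0], rate1=popt[1], amp2=popt[2], rate2=popt[3],
                offset=popt[4], ssr=ssr, n_points=t.size,
            )
        except RuntimeError as exc:
            diagnostics.append(f"start ({b0:.3g},{d0:.3g}): {exc}")
            if ssr0 <= 1e-20 * max(scale, 1.0):
                # rates explain the data exactly (e.g. a constant trace)
                candidate = RecoilFit(
                    amp1=a1, rate1=b0, amp2=a2, rate2=d0,
                    offset=c, ssr=ssr0, n_points=t.size,
                )
        if candidate is not None and (best is None or candidate.ssr < best.ssr):
            best = candidate
    if best is None:
        raise FitError(
            "recoil fit failed from all starting points: " + "; ".join(diagnostics)
        )
    return best


# ---------------------------------------------------------------------------
# straightness-recoil crossover
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossoverFit:
    """Continuous flat-then-linear (hinge) fit of v_r against S."""

    breakpoint: float
    flat_level: float
    slope: float
    ssr: float
    ci_low: float
    ci_high: float
    identifiable: bool
    note: str = ""

    def __call__(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return self.flat_level + self.slope * np.maximum(s - self.breakpoint, 0.0)


def _hinge_lsq(s, v, knot):
    design = np.column_stack([np.ones_like(s), np.maximum(s - knot, 0.0)])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    resid = v - design @ coef
    return coef, float(resid @ resid)


def crossover_fit(
    s,
    vr,
    candidates: np.ndarray | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> CrossoverFit:
    """Locate the straightness above which recoil velocity rises linearly.

    Profiles the breakpoint over a candidate grid, solving the two linear
    coefficients exactly at each knot, and returns the knot minimizing
    the residual sum of squares with a bootstrap percentile interval.
    Data that are flat to within noise are flagged unidentifiable; purely
    linear data drive the knot to the lower edge of the S range.
    """
    s = np.asarray(s, dtype=float)
    vr = np.asarray(vr, dtype=float)
    if s.size != vr.size:
        raise ValueError("S and vr must have equal length")
    if s.size < 10:
        raise ValueError("need at least 10 (S, vr) pairs")
    if candidates is None:
        lo, hi = s.min(), s.max()
        candidates = np.linspace(lo, hi, 201)[:-1]
    candidates = np.asarray(candidates, dtype=float)
    valid = np.array([(s > c).sum() >= 2 for c in candidates])
    if not valid.any():
        raise ValueError("every candidate breakpoint leaves all S on one side")
    candidates = candidates[valid]

    def best_knot(ss, vv):
        ssrs = []
        for c in candidates:
            _, r = _hinge_lsq(ss, vv, c)
            ssrs.append(r)
        k = int(np.argmin(ssrs))
        coef, r = _hinge_lsq(ss, vv, candidates[k])
        return candidates[k], coef, r

    knot, (flat, slope), ssr = best_knot(s, vr)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, s.size, size=s.size)
        try:
            bk, _, _ = best_knot(s[idx], vr[idx])
            boots.append(bk)
        except (ValueError, np.linalg.LinAlgError):
            continue
    ci_low, ci_high = (
        (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
        if boots
        else (np.nan, np.nan)
    )
    # the breakpoint is meaningful only if the hinge explains a sizable
    # fraction of the variance a constant fit leaves unexplained
    ssr_flat = float(np.sum((vr - vr.mean()) ** 2))
    identifiable = bool(ssr_flat > 0 and (ssr_flat - ssr) > 0.2 * ssr_flat)
    note = "" if identifiable else "slope indistinguishable from flat"
    return CrossoverFit(
        breakpoint=float(knot),
        flat_level=float(flat),
        slope=float(slope),
        ssr=ssr,
        ci_low=ci_low,
        ci_high=ci_high,
        identifiable=identifiable,
        note=note,
    )


# ---------------------------------------------------------------------------
# stage-binned summaries
# ---------------------------------------------------------------------------

def stage_binned_stats(
    values,
    dA,
    edges: tuple[float, float] = (0.4, 0.7),
) -> pd.DataFrame:
    """Median / IQR / 5-95% summaries across closure-stage intervals.

    Default bins are dA < 0.4, 0.4 <= dA < 0.7 and dA >= 0.7.  Empty
    bins are reported with n = 0 and NaN summaries, never dropped.
    """
    values = np.asarray(values, dtype=float)
    dA = np.asarray(dA, dtype=float)
    if values.size != dA.size:
        raise ValueError("values and dA stamps must have equal length")
    if values.size == 0:
        raise ValueError("no values to bin")
    lo_edge, hi_edge = edges
    bins = [(-np.inf, lo_edge), (lo_edge, hi_edge), (hi_edge, np.inf)]
    rows = []
    for lo, hi in bins:
        mask = (dA >= lo) & (dA < hi)
        sub = values[mask]
        label = (
            f"dA<{lo_edge:g}" if np.isinf(lo)
            else f"dA>={hi_edge:g}" if np.isinf(hi)
            else f"{lo_edge:g}<=dA<{hi_edge:g}"
        )
        if sub.size:
            rows.append(
                {
                    "bin": label, "lo": lo, "hi": hi, "n": int(sub.size),
                    "median": float(np.median(sub)),
                    "q25": float(np.percentile(sub, 25)),
                    "q75": float(np.percentile(sub, 75)),
                    "p5": float(np.percentile(sub, 5)),
                    "p95": float(np.percentile(sub, 95)),
                }
            )
        else:
            rows.append(
                {
                    "bin": label, "lo": lo, "hi": hi, "n": 0,
                    "median": np.nan, "q25": np.nan, "q75": np.nan,
                    "p5": np.nan, "p95": np.nan,
                }
            )
    return pd.DataFrame(rows)
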