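"""Synthetic cohorts, ablation traces and percolation fixtures.

Every input the analysis pipeline consumes can be generated here with
known ground truth: tracked-cell tables with the statistical structure of
segmented dorsal-closure recordings (linear tissue-area decrease, normal
shape-index distribution of width 0.45, progressive elongation and
alignment, ~10% ingression, near-straight junctions), double-exponential
recoil traces whose initial velocity follows a hump over closure stage,
and small tilings with prescribed rigid-edge sets for wrapping tests.
All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .experiment import AblationTrace, TrackedCellTable
from .tissue import Box, TissueState, build_hexagonal_tissue, build_voronoi_tissue


@dataclass(frozen=True)
class QDriftCurve:
    """Piecewise-linear mean shape-index drift with an interior minimum.

    An explicit modeling input for synthetic cohorts (never fitted
    silently from anything): q falls from ``q_start`` to ``q_min`` at
    ``dA_min`` and rises to ``q_end`` at ``dA_end``.
    """

    q_start: float = 3.95
    q_min: float = 3.85
    q_end: float = 4.35
    dA_min: float = 0.55
    dA_end: float = 0.8

    def __call__(self, dA) -> np.ndarray:
        dA = np.asarray(dA, dtype=float)
        down = self.q_start + (self.q_min - self.q_start) * dA / self.dA_min
        up = self.q_min + (self.q_end - self.q_min) * (dA - self.dA_min) / (
            self.dA_end - self.dA_min
        )
        return np.where(dA <= self.dA_min, down, up)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study-condition parameters of a synthetic tracked-cell cohort.

    Defaults emulate the imaging cohorts this pipeline targets: a dozen
    embryos of ~200 tracked amnioserosa cells each, analysis starting at
    a tissue area of 11,000 um^2, area decreasing linearly in time,
    pooled shape-index standard deviation 0.45, and a tenth of the cells
    ingressing over the run.  ``embryo_scale`` scales all embryo-to-embryo
    variability; zero makes every embryo identical.
    """

    n_embryos: int = 12
    cells_per_embryo: int = 200
    A0_um2: float = 11_000.0
    area_slope_um2_per_s: float = 1.25
    dA_end: float = 0.8
    n_frames: int = 41
    q_sd: float = 0.45
    q_drift: QDriftCurve = QDriftCurve()
    ingression_fraction: float = 0.1
    embryo_scale: float = 1.0
    junctions_per_frame: int = 60
    mean_junction_um: float = 5.0

    def __post_init__(self) -> None:
        if self.area_slope_um2_per_s <= 0 or self.A0_um2 <= 0:
            raise ValueError("area parameters must be positive")
        if not (0 < self.dA_end < 1):
            raise ValueError("dA_end must lie in (0, 1)")
        if self.q_sd < 0 or not (0 <= self.ingression_fraction < 1):
            raise ValueError("inconsistent cohort rates")
        if self.q_drift.q_min - 3 * self.q_sd <= 0:
            raise ValueError("shape-index noise would produce non-positive indices")


def generate_tracked_cohort(
    spec: SyntheticCohortSpec, seed: int = 0
) -> tuple[TrackedCellTable, dict]:
    """Emulated segmentation-and-tracking output with ground truth.

    Per embryo: a linear AS-area time series (embryo-varied slope), an
    AP-elongating fitted ellipse, per-cell areas and perimeters consistent
    with a normal shape-index distribution drifting along ``q_drift``,
    orientations aligning with closure, random ingression events, and
    junction (contour, end-to-end) pairs with straightness near 1.
    Returns the table and a ground-truth parameter dictionary.
    """
    sd_embryo = 0.2 * spec.q_sd * spec.embryo_scale
    sd_cell = float(np.sqrt(max(spec.q_sd**2 - sd_embryo**2, 1e-12)))
    cells_rows, frame_rows, junction_rows = [], [], []
    t_end = spec.dA_end * spec.A0_um2 / spec.area_slope_um2_per_s
    times0 = np.linspace(0.0, t_end, spec.n_frames)
    for e in range(spec.n_embryos):
        emb = f"embryo{e:02d}"
        # per-embryo substream; with variability off every embryo reuses
        # the same stream and is therefore bit-identical
        rng = np.random.default_rng(
            [seed, e if spec.embryo_scale > 0 else 0]
        )
        slope = spec.area_slope_um2_per_s * (
            1.0 + 0.1 * spec.embryo_scale * rng.normal()
        )
        q_emb = sd_embryo * rng.normal() if spec.embryo_scale > 0 else 0.0
        q_cell = sd_cell * rng.normal(size=spec.cells_per_embryo)
        n_ingress = int(round(spec.ingression_fraction * spec.cells_per_embryo))
        ingressors = rng.choice(spec.cells_per_embryo, size=n_ingress, replace=False)
        gone_after = np.full(spec.cells_per_embryo, spec.n_frames + 1)
        lo = max(1, int(0.1 * spec.n_frames))
        hi = max(lo + 1, int(0.9 * spec.n_frames))
        gone_after[ingressors] = rng.integers(lo, hi, size=n_ingress)
        for k, t in enumerate(times0):
            area_total = spec.A0_um2 - slope * t
            dA = (spec.A0_um2 - area_total) / spec.A0_um2
            ratio = 2.0 / max(1.0 - dA, 0.2)  # AS ellipse elongates with closure
            ell_a = np.sqrt(area_total * ratio / np.pi)
            ell_b = np.sqrt(area_total / (ratio * np.pi))
            frame_rows.append(
                {
                    "embryo": emb, "frame": k, "time_s": t,
                    "as_area_um2": area_total,
                    "ell_cx": 0.0, "ell_cy": 0.0,
                    "ell_a": ell_a, "ell_b": ell_b, "ell_theta": 0.0,
                }
            )
            present = np.flatnonzero(gone_after > k)
            mean_area = area_total / present.size
            areas = mean_area * np.clip(
                1.0 + 0.25 * rng.normal(size=present.size), 0.3, None
            )
            q = (
                spec.q_drift(dA)
                + q_emb
                + q_cell[present]
                + 0.02 * rng.normal(size=present.size)
            )
            sigma_theta = 1.2 * (1.0 - 0.8 * dA)
            theta = rng.normal(0.0, sigma_theta, size=present.size)
            theta = np.mod(theta + np.pi / 2, np.pi) - np.pi / 2
            aspect = 1.0 + (0.5 + 2.0 * dA) * np.clip(
                1.0 + 0.3 * rng.normal(size=present.size), 0.2, None
            )
            # centroids uniform in the fitted ellipse
            u = rng.uniform(size=present.size)
            phi = rng.uniform(0, 2 * np.pi, size=present.size)
            cells_rows.append(
                pd.DataFrame(
                    {
                        "embryo": emb, "frame": k, "time_s": t,
                        "cell": present,
                        "x_um": ell_a * np.sqrt(u) * np.cos(phi),
                        "y_um": ell_b * np.sqrt(u) * np.sin(phi),
                        "area_um2": areas,
                        "perim_um": q * np.sqrt(areas),
                        "aspect_ratio": aspect,
                        "theta_rad": theta,
                    }
                )
            )
            contour = spec.mean_junction_um * np.clip(
                1.0 + 0.3 * rng.normal(size=spec.junctions_per_frame), 0.2, None
            )
            straightness = np.clip(
                1.0 - np.abs(rng.normal(0.0, 0.03, size=spec.junctions_per_frame)),
                0.5, 1.0,
            )
            junction_rows.append(
                pd.DataFrame(
                    {
                        "embryo": emb, "frame": k, "time_s": t,
                        "junction": np.arange(spec.junctions_per_frame),
                        "contour_um": contour,
                        "endtoend_um": straightness * contour,
                    }
                )
            )
    table = TrackedCellTable(
        cells=pd.concat(cells_rows, ignore_index=True),
        frames=pd.DataFrame(frame_rows),
        junctions=pd.concat(junction_rows, ignore_index=True),
    )
    table.validate()
    truth = {
        "spec": {**asdict(spec), "q_drift": asdict(spec.q_drift)},
        "seed": seed,
        "sd_cell": sd_cell,
        "sd_embryo": sd_embryo,
    }
    return table, truth


# ---------------------------------------------------------------------------
# ablation traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoilHump:
    """Mean initial recoil velocity as a hump-shaped function of dA."""

    v_base: float = 0.15
    v_amp: float = 0.35
    dA_peak: float = 0.55
    width: float = 0.15

    def __call__(self, dA) -> np.ndarray:
        dA = np.asarray(dA, dtype=float)
        return self.v_base + self.v_amp * np.exp(
            -((dA - self.dA_peak) ** 2) / (2.0 * self.width**2)
        )


def generate_ablation_traces(
    n: int,
    noise: float = 0.02,
    seed: int = 0,
    hump: RecoilHump = RecoilHump(),
    frame_rate_hz: float = 5.0,
    n_frames: int = 576,
    rate_fast: float = -0.15,
    rate_slow: float = -0.015,
    d_initial_um: float = 0.5,
) -> tuple[list[AblationTrace], list[dict]]:
    """Double-exponential recoil traces with known parameters.

    Each trace samples d(t) = C - |A1| e^{b0 t} - |A2| e^{d0 t} at the
    acquisition frame rate, with the ground-truth initial velocity
    v_r = A1 b0 + A2 d0 drawn from a hump over closure stage peaking at
    ``hump.dA_peak``; 80% of the velocity is carried by the fast mode
    (relaxation times of roughly 7 s and 70 s within the ~2 min
    recording).  Gaussian noise is ``noise`` times the pre-cut vertex
    separation — the tracking error of the kymograph measurement, which
    does not scale with the recoil amplitude.  Returns the traces and
    per-trace ground truth.
    """
    if n < 1:
        raise ValueError("need at least one trace")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / frame_rate_hz
    traces, truth = [], []
    for i in range(n):
        dA = rng.uniform(0.0, 0.85)
        vr = float(hump(dA) * (1.0 + 0.05 * rng.normal()))
        a1 = -0.8 * vr / abs(rate_fast)
        a2 = -0.2 * vr / abs(rate_slow)
        c = d_initial_um - a1 - a2
        clean = a1 * np.exp(rate_fast * t) + a2 * np.exp(rate_slow * t) + c
        d = clean + noise * d_initial_um * rng.normal(size=t.size)
        s = float(np.clip(1.0 - np.abs(rng.normal(0, 0.03)), 0.5, 1.0))
        traces.append(AblationTrace(time_s=t, d_um=d, straightness=s, dA=dA))
        truth.append(
            {
                "amp1": a1, "rate1": rate_fast,
                "amp2": a2, "rate2": rate_slow,
                "offset": c, "vr": vr, "dA": dA, "straightness": s,
            }
        )
    return traces, truth


def straightness_proxy(tensions, scale: float) -> np.ndarray:
    """Straightness trajectory proportional to junction tension.

    Taut junctions are straight, so synthetic straightness is a single
    positive multiple of tension; ``scale`` must keep all values <= 1.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    s = scale * np.asarray(tensions, dtype=float)
    if np.any(s > 1.0):
        raise ValueError("scale maps some tensions above straightness 1")
    return s


# ---------------------------------------------------------------------------
# percolation fixtures
# ---------------------------------------------------------------------------

def generate_percolation_fixture(
    kind: str, size: int = 8, seed: int = 0, f: float = 0.9
) -> tuple[TissueState, np.ndarray]:
    """Deterministic (state, rigid-junction mask) pairs with known verdicts.

    ``chain``: honeycomb with a single zigzag of rigid bonds winding the
    box in x only.  ``full`` / ``empty``: all or no bonds rigid.
    ``voronoi``: random periodic Voronoi tiling with bonds marked rigid
    independently with probability ``f``.
    """
    if kind in ("chain", "full", "empty"):
        ny = 4
        state = build_hexagonal_tissue(max(size, 2), ny)
        topo = state.topology()
        m = topo.n_junctions
        if kind == "full":
            return state, np.ones(m, dtype=bool)
        if kind == "empty":
            return state, np.zeros(m, dtype=bool)
        # bottom zigzag of the first hexagon row: alternating corners
        # (X-1,-1)-(X,-2)-(X+1,-1) for each column, all integer-lattice keys
        s = np.sqrt(2.0 / (3.0 * np.sqrt(3.0)))
        ux, uy = np.sqrt(3.0) * s / 2.0, s / 2.0
        IX, IY = 2 * max(size, 2), 3 * ny
        coords = {
            (int(round(x / ux)) % IX, int(round(y / uy)) % IY): v
            for v, (x, y) in enumerate(state.vertices)
        }
        wanted = set()
        for col in range(max(size, 2)):
            X = 2 * col
            a = coords[((X - 1) % IX, (IY - 1))]
            b = coords[(X % IX, (IY - 2))]
            c = coords[((X + 1) % IX, (IY - 1))]
            wanted.add(frozenset((a, b)))
            wanted.add(frozenset((b, c)))
        va = topo.corner_vertex[topo.junction_corner_a]
        vb = topo.corner_vertex[topo.corner_next[topo.junction_corner_a]]
        mask = np.array(
            [frozenset((int(x), int(y))) in wanted for x, y in zip(va, vb)]
        )
        return state, mask
    if kind == "voronoi":
        side = float(np.sqrt(size))
        state = build_voronoi_tissue(size, Box(side, side), seed=seed)
        rng = np.random.default_rng(seed + 1)
        mask = rng.uniform(size=state.topology().n_junctions) < f
        return state, mask
    raise ValueError(f"unknown fixture kind {kind!r}")
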