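"""Tension-network rigidity percolation.

A confluent tissue is mechanically solid when its tension-bearing
junctions form a cluster that wraps the periodic box in both directions.
This module measures the rigid-junction fraction f_r (junctions with
tension above a small numerical floor), detects wrapping clusters with a
union-find that tracks periodic image displacements (a cluster wraps in x
when some cycle of rigid junctions has non-zero winding number in x), and
calibrates the bond-percolation threshold f_c of random periodic Voronoi
tilings, which for square boxes is close to 0.66.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mechanics import EnergyParams
from .observables import junction_tensions
from .tissue import Box, TissueState, build_voronoi_tissue, minimum_image

#: numerical floor below which a junction tension counts as zero
#: (units kp * sqrt(a0)); config-exposed everywhere it is used
DEFAULT_EPS_TAU = 1e-4

#: bond-percolation threshold of random periodic Voronoi tilings
DEFAULT_FC = 0.66


@dataclass(frozen=True)
class PercolationResult:
    fr: float
    wraps_x: bool
    wraps_y: bool
    classification: str
    eps_tau: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fr <= 1.0):
            raise ValueError("fr must lie in [0, 1]")
        solid = self.wraps_x and self.wraps_y
        if (self.classification == "solid") != solid:
            raise ValueError("classification must follow the wrapping verdict")


class _WindingUnionFind:
    """Union-find over vertices with per-node periodic image offsets.

    Each constraint ``offset[b] = offset[a] + shift`` comes from one
    junction; a redundant constraint whose mismatch is non-zero exposes a
    wrapping cycle in the corresponding direction(s).
    """

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n
        self.off = [(0, 0)] * n
        self.wrap_x = [False] * n  # valid at roots
        self.wrap_y = [False] * n

    def find(self, v: int) -> tuple[int, tuple[int, int]]:
        path = []
        while self.parent[v] != v:
            path.append(v)
            v = self.parent[v]
        ox, oy = 0, 0
        for u in reversed(path):
            dx, dy = self.off[u]
            ox, oy = ox + dx, oy + dy
            self.off[u] = (ox, oy)
            self.parent[u] = v
        # after compression every path node hangs off the root directly
        return v, (0, 0)

    def _offset_to_root(self, v: int) -> tuple[int, int]:
        self.find(v)
        return self.off[v] if self.parent[v] != v else (0, 0)

    def union(self, a: int, b: int, shift: tuple[int, int]) -> None:
        ra, _ = self.find(a)
        rb, _ = self.find(b)
        oa = (0, 0) if a == ra else self.off[a]
        ob = (0, 0) if b == rb else self.off[b]
        if ra == rb:
            wx = oa[0] + shift[0] - ob[0]
            wy = oa[1] + shift[1] - ob[1]
            if wx != 0:
                self.wrap_x[ra] = True
            if wy != 0:
                self.wrap_y[ra] = True
            return
        # offset[b] must equal offset[a] + shift; attach smaller tree
        if self.rank[ra] < self.rank[rb]:
            # root ra goes under rb: offset of ra relative to rb
            orx = ob[0] - shift[0] - oa[0]
            ory = ob[1] - shift[1] - oa[1]
            self.parent[ra] = rb
            self.off[ra] = (orx, ory)
            self.wrap_x[rb] |= self.wrap_x[ra]
            self.wrap_y[rb] |= self.wrap_y[ra]
        else:
            orx = oa[0] + shift[0] - ob[0]
            ory = oa[1] + shift[1] - ob[1]
            self.parent[rb] = ra
            self.off[rb] = (orx, ory)
            self.wrap_x[ra] |= self.wrap_x[rb]
            self.wrap_y[ra] |= self.wrap_y[rb]
            if self.rank[ra] == self.rank[rb]:
                self.rank[ra] += 1

    def wraps(self) -> tuple[bool, bool]:
        return any(self.wrap_x), any(self.wrap_y)


def _junction_graph(state: TissueState):
    """(v_a, v_b, integer image shifts) for every junction."""
    topo = state.topology()
    va = topo.corner_vertex[topo.junction_corner_a]
    vb = topo.corner_vertex[topo.corner_next[topo.junction_corner_a]]
    ra = state.vertices[va]
    rb = state.vertices[vb]
    m = minimum_image(rb - ra, state.box)
    shifts = np.round((ra + m - rb) / state.box.lengths).astype(int)
    return va, vb, shifts


def wrapping_percolation(
    state: TissueState, rigid_mask: np.ndarray
) -> tuple[bool, bool]:
    """Whether the sub-network of masked junctions wraps in x and in y.

    ``rigid_mask`` is boolean over junctions in topology order.  Wrapping
    is detected from the winding numbers of cycles in the sub-network, so
    the verdict is exact on the torus (a chain that merely spans the box
    once without closing periodically does not wrap).
    """
    va, vb, shifts = _junction_graph(state)
    rigid_mask = np.asarray(rigid_mask, dtype=bool)
    if rigid_mask.shape != va.shape:
        raise ValueError("rigid_mask must have one entry per junction")
    nv = state.vertices.shape[0]
    uf = _WindingUnionFind(nv)
    for k in np.flatnonzero(rigid_mask):
        uf.union(int(va[k]), int(vb[k]), (int(shifts[k, 0]), int(shifts[k, 1])))
    return uf.wraps()


def rigid_fraction(
    state: TissueState, params: EnergyParams, eps_tau: float = DEFAULT_EPS_TAU
) -> float:
    """Fraction of junctions carrying tension above the floor ``eps_tau``."""
    taus = junction_tensions(state, params)
    return float((taus > eps_tau).mean())


def rigid_junction_analysis(
    state: TissueState,
    params: EnergyParams,
    eps_tau: float = DEFAULT_EPS_TAU,
) -> PercolationResult:
    """Full verdict: rigid fraction, wrapping flags, solid/fluid class.

    Solidity requires wrapping in both periodic directions (stricter than
    the f_r > f_c summary statistic, which is reported alongside).
    """
    taus = junction_tensions(state, params)
    mask = taus > eps_tau
    wx, wy = wrapping_percolation(state, mask)
    return PercolationResult(
        fr=float(mask.mean()),
        wraps_x=wx,
        wraps_y=wy,
        classification="solid" if (wx and wy) else "fluid",
        eps_tau=eps_tau,
    )


# ---------------------------------------------------------------------------
# percolation threshold calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FcEstimate:
    mean: float
    stderr: float
    thresholds: tuple

    @property
    def n_trials(self) -> int:
        return len(self.thresholds)


def percolation_threshold(state: TissueState, rng: np.random.Generator) -> float:
    """Two-direction wrapping threshold of one tiling under random marking.

    Each junction j receives an independent uniform mark ``u_j``; at
    occupation probability f exactly the junctions with ``u_j < f`` are
    rigid, so sweeping f is equivalent to adding junctions in increasing
    mark order and recording the mark at which wrapping in both directions
    first appears.  (This coupled sweep gives the same threshold a
    bisection on f would, in one pass.)
    """
    va, vb, shifts = _junction_graph(state)
    m = va.size
    u = rng.uniform(size=m)
    order = np.argsort(u)
    uf = _WindingUnionFind(state.vertices.shape[0])
    for k in order:
        uf.union(int(va[k]), int(vb[k]), (int(shifts[k, 0]), int(shifts[k, 1])))
        wx, wy = uf.wraps()
        if wx and wy:
            return float(u[k])
    raise RuntimeError("full junction set does not wrap; tiling invalid")


def calibrate_fc_voronoi(
    n_cells: int,
    n_trials: int,
    seed: int,
    box: Box | None = None,
    states: list[TissueState] | None = None,
) -> FcEstimate:
    """Monte-Carlo estimate of the wrapping threshold f_c.

    Builds ``n_trials`` random periodic Voronoi tilings of ``n_cells``
    cells (square box by default), marks junctions at random, and returns
    the mean and standard error of the per-trial thresholds.  Pre-built
    ``states`` (e.g. uniaxially deformed tissues) may be supplied instead.
    """
    if states is None:
        if n_cells < 64 or n_trials < 20:
            raise ValueError("calibration needs >= 64 cells and >= 20 trials")
        if box is None:
            side = float(np.sqrt(n_cells))
            box = Box(side, side)
    rng = np.random.default_rng(seed)
    thresholds = []
    for t in range(n_trials):
        if states is not None:
            state = states[t % len(states)]
        else:
            sub = int(rng.integers(0, 2**31 - 1))
            state = build_voronoi_tissue(n_cells, box, seed=sub)
        thresholds.append(percolation_threshold(state, rng))
    arr = np.array(thresholds)
    return FcEstimate(
        mean=float(arr.mean()),
        stderr=float(arr.std(ddof=1) / np.sqrt(arr.size)),
        thresholds=tuple(arr.tolist()),
    )


# ---------------------------------------------------------------------------
# standard-model rigidity point
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionSweep:
    """Result of a monodisperse preferred-shape-index sweep."""

    onset_mean: float
    onset_per_seed: tuple
    p0_grid: tuple
    fr_curves: tuple  # one fr(p0) tuple per seed


def rigidity_transition_sweep(
    n_cells: int = 128,
    seeds=(0, 1, 2, 3, 4),
    p0_min: float = 3.70,
    p0_max: float = 3.95,
    step: float = 0.01,
    fc: float = DEFAULT_FC,
    eps_tau: float = DEFAULT_EPS_TAU,
    params: EnergyParams | None = None,
    settings=None,
) -> TransitionSweep:
    """Locate the solid-fluid onset of the standard (monodisperse,
    undeformed, non-shrinking) model.

    For each seed, a random periodic Voronoi tiling in a square box is
    relaxed at the lowest preferred shape index, then the uniform p0 is
    raised quasistatically (warm starts, T1 moves enabled); the onset is
    the first grid value at which the rigid-junction fraction drops below
    the percolation threshold (residual tensions no longer percolate).
    """
    from .mechanics import EnergyParams as EP, MinimizerSettings, minimize

    params = params or EP()
    settings = settings or MinimizerSettings()
    grid = np.arange(p0_min, p0_max + step / 2, step)
    onsets = []
    curves = []
    for seed in seeds:
        side = float(np.sqrt(n_cells * params.a0))
        state = build_voronoi_tissue(n_cells, Box(side, side), seed=int(seed))
        state.p0[:] = grid[0] * np.sqrt(params.a0)
        state, rep = minimize(state, params, settings, inplace=True)
        onset = np.nan
        frs = []
        for p0 in grid:
            state.p0[:] = p0 * np.sqrt(params.a0)
            state, rep = minimize(state, params, settings, inplace=True)
            if not rep.converged:
                raise RuntimeError(
                    f"sweep minimization failed at p0={p0:.3f}: {rep.message}"
                )
            fr = rigid_fraction(state, params, eps_tau)
            frs.append(fr)
            if np.isnan(onset) and fr < fc:
                onset = float(p0)
        curves.append(tuple(frs))
        onsets.append(onset)
    return TransitionSweep(
        onset_mean=float(np.nanmean(onsets)),
        onset_per_seed=tuple(onsets),
        p0_grid=tuple(float(x) for x in grid),
        fr_curves=tuple(curves),
    )


# ---------------------------------------------------------------------------
# phase diagram
# ---------------------------------------------------------------------------

@dataclass
class PhaseDiagram:
    """Grid of (q_mean, dA) states with rigid fractions and classification."""

    table: pd.DataFrame
    boundary: pd.DataFrame
    fc: float
    trajectory: pd.DataFrame | None = None
    failures: list = field(default_factory=list)


def build_phase_diagram(
    q0_grid,
    dA_grid,
    n_cells: int = 128,
    seed: int = 0,
    fc: float = DEFAULT_FC,
    eps_tau: float = DEFAULT_EPS_TAU,
    include_default_trajectory: bool = False,
    **run_overrides,
) -> PhaseDiagram:
    """Solid/fluid map in (q_mean, dA) space.

    Each grid column is prepared by the uniaxial closure protocol started
    from the given initial mean preferred shape index (states along a
    deformation trajectory, not independent fresh tilings), evaluating
    f_r and the wrapping verdict at each requested dA.  Minimization
    failures mark grid points invalid rather than silently skipping them.
    """
    from .protocol import RunConfig, run_closure

    q0_grid = np.atleast_1d(np.asarray(q0_grid, dtype=float))
    dA_grid = np.atleast_1d(np.asarray(dA_grid, dtype=float))
    if q0_grid.size == 0 or dA_grid.size == 0:
        raise ValueError("phase-diagram grids must be nonempty")
    rows = []
    failures = []
    dA_max = float(dA_grid.max())
    for q0 in q0_grid:
        cfg = RunConfig(
            n_cells=n_cells,
            seed=seed,
            q0_mean=float(q0),
            dA_max=max(dA_max, 0.00125),
            record_dA=sorted(set(float(d) for d in dA_grid)),
            **run_overrides,
        )
        traj = run_closure(cfg)
        if not traj.valid:
            failures.append({"q0": float(q0), "reason": traj.message})
        for rec in traj.records:
            if not np.isclose(dA_grid, rec.dA, atol=1e-9).any():
                continue
            rows.append(
                {
                    "q0": float(q0),
                    "q_mean": rec.q_mean,
                    "dA": rec.dA,
                    "fr": rec.fr,
                    "wraps_x": rec.wraps_x,
                    "wraps_y": rec.wraps_y,
                    "classification": "solid"
                    if (rec.wraps_x and rec.wraps_y)
                    else "fluid",
                }
            )
    table = pd.DataFrame(rows)
    boundary_rows = []
    for q0, grp in table.groupby("q0"):
        grp = grp.sort_values("dA")
        f = grp["fr"].to_numpy()
        d = grp["dA"].to_numpy()
        qm = grp["q_mean"].to_numpy()
        cross = np.flatnonzero(np.diff(np.sign(f - fc)))
        for k in cross:
            w = (fc - f[k]) / (f[k + 1] - f[k]) if f[k + 1] != f[k] else 0.5
            boundary_rows.append(
                {
                    "q_mean": qm[k] + w * (qm[k + 1] - qm[k]),
                    "dA": d[k] + w * (d[k + 1] - d[k]),
                }
            )
    trajectory = None
    if include_default_trajectory:
        cfg = RunConfig(n_cells=n_cells, seed=seed, dA_max=dA_max, **run_overrides)
        traj = run_closure(cfg)
        trajectory = traj.to_frame()[["q_mean", "dA", "fr"]]
    return PhaseDiagram(
        table=table,
        boundary=pd.DataFrame(boundary_rows),
        fc=fc,
        trajectory=trajectory,
        failures=failures,
    )
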