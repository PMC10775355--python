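"""Vertex-model energy, analytic forces, and quasistatic minimization.

The tissue energy is

    E = sum_i  1/2 ka (a_i - a0)^2  +  1/2 kp (p_i - p0_i)^2

over alive cells, with per-cell preferred perimeters ``p0_i`` and a shared
preferred area ``a0``.  Quantities are nondimensionalized by a0 = 1 and
kp = 1.  Force balance is enforced with an energy-monotone FIRE descent;
during descent, edges shorter than a threshold length optionally trigger
T1 neighbor exchanges, each of which is logged so that their complete
absence in a run is an observed outcome rather than an assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .tissue import TissueState, TopologyError, t1_flip


@dataclass(frozen=True)
class EnergyParams:
    """Moduli and preferred area; defaults set the model's unit system."""

    ka: float = 1.0
    kp: float = 1.0
    a0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.ka > 0 and self.kp > 0 and self.a0 > 0):
            raise ValueError("ka, kp, a0 must all be positive")


@dataclass(frozen=True)
class MinimizerSettings:
    """FIRE parameters and T1 handling during descent.

    ``tol`` is the convergence threshold on the largest force component
    (units kp * sqrt(a0)).  ``t1_threshold`` is the edge length (units
    sqrt(a0)) below which a neighbor exchange fires when enabled; the new
    edge is placed perpendicular with length ``t1_post_factor`` times the
    threshold.  Short edges are checked every ``t1_check_every`` accepted
    iterations, at most one flip per edge per check.
    """

    tol: float = 1e-7
    max_iter: int = 500_000
    dt0: float = 0.05
    dt_max: float = 0.2
    f_inc: float = 1.1
    f_dec: float = 0.5
    alpha0: float = 0.1
    f_alpha: float = 0.99
    n_min: int = 5
    t1_threshold: float = 0.02
    t1_post_factor: float = 1.5
    t1_check_every: int = 10
    max_t1_per_minimize: int = 20_000
    max_flips_per_edge: int = 4
    #: edges shorter than this (units sqrt(a0)) count as merged rosette
    #: vertices in the force-balance criterion; far below t1_threshold
    pin_threshold: float = 1e-4
    #: collapsed edges whose junction tension is above -pin_tension_floor
    #: (units kp*sqrt(a0)) are merged; only meaningfully compressed pairs
    #: (tension below the floor) are free to re-extend.  The floor must
    #: sit well above ``tol`` or weakly compressed pairs re-open at creep
    #: speed and the descent never terminates
    pin_tension_floor: float = 1e-3
    #: a candidate T1 is tested between minima: the state is first
    #: converged with the short edge intact (collapsed edges pinned),
    #: then flipped and re-relaxed for at most this many iterations; the
    #: flip is kept only if it lowers the relaxed energy by more than the
    #: relative margin below (athermal quasistatic dynamics cannot cross
    #: barriers, and an exchange that releases no energy is a marginal
    #: rosette rearrangement, not a plastic event).  Rejected flips are
    #: reverted and the edge forms a stable rosette vertex.
    t1_gate_iters: int = 5_000
    t1_gate_margin: float = 1e-8
    #: after this many FIRE iterations without convergence, a quasi-Newton
    #: polish on rosette-merged coordinates resolves glassy soft-mode
    #: tails that first-order descent crawls on
    polish_after: int = 100_000

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("force tolerance must be positive")


@dataclass
class MinimizeReport:
    converged: bool
    energy: float
    residual: float
    iterations: int
    t1_events: list = field(default_factory=list)
    message: str = ""

    @property
    def n_t1(self) -> int:
        return len(self.t1_events)


def tissue_energy(state: TissueState, params: EnergyParams) -> float:
    """Total mechanical energy over alive cells."""
    topo = state.topology()
    p0c = state.p0[topo.cell_ids]
    _, energy, _ = _kernels.forces_energy(
        state, topo, p0c, params.ka, params.kp, params.a0
    )
    return energy


def vertex_forces(state: TissueState, params: EnergyParams) -> np.ndarray:
    """Analytic force -dE/dr on every vertex row (zeros on retired rows)."""
    topo = state.topology()
    p0c = state.p0[topo.cell_ids]
    force, _, _ = _kernels.forces_energy(
        state, topo, p0c, params.ka, params.kp, params.a0
    )
    return force


def force_residual(
    state: TissueState,
    params: EnergyParams,
    pin_threshold: float = 1e-4,
    pin_tension_floor: float = 1e-4,
) -> float:
    """Largest force component, with collapsed rosette pairs merged.

    This is the residual the minimizer converges on: vertex pairs joined
    by a (numerically) zero-length contractile junction balance forces
    jointly, as a single higher-order vertex.
    """
    topo = state.topology()
    p0c = state.p0[topo.cell_ids]
    return float(
        _kernels.pinned_residual(
            state, topo, p0c, params.ka, params.kp, params.a0,
            pin_threshold * np.sqrt(params.a0),
            pin_tension_floor * params.kp * np.sqrt(params.a0),
        )
    )


def _pin_groups(state: TissueState, params: EnergyParams,
                settings: "MinimizerSettings") -> np.ndarray:
    """Vertex -> group id, merging pairs joined by pinned collapsed edges."""
    topo = state.topology()
    _, perims, edge_vec = _kernels.geometry_arrays(state, topo)
    lengths = np.hypot(edge_vec[:, 0], edge_vec[:, 1])
    pin = settings.pin_threshold * np.sqrt(params.a0)
    floor = settings.pin_tension_floor * params.kp * np.sqrt(params.a0)
    nv = state.vertices.shape[0]
    parent = np.arange(nv)

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    va = topo.corner_vertex
    vb = topo.corner_vertex[topo.corner_next]
    cc = topo.corner_cell
    p0c = state.p0[topo.cell_ids]
    for k in np.flatnonzero(lengths < pin):
        a, b = int(va[k]), int(vb[k])
        if a >= b:
            continue
        # junction tension from both adjacent cells (partner half-edge)
        tension = params.kp * (perims[cc[k]] - p0c[cc[k]])
        partner = np.flatnonzero((va == b) & (vb == a) & (lengths < pin))
        if partner.size:
            j = int(partner[0])
            tension += params.kp * (perims[cc[j]] - p0c[cc[j]])
        if tension <= -floor:
            continue
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    roots = np.array([find(v) for v in range(nv)])
    _, groups = np.unique(roots, return_inverse=True)
    return groups


def _quasi_newton_polish(
    st: TissueState,
    params: EnergyParams,
    settings: "MinimizerSettings",
    maxiter: int = 5_000,
) -> tuple[float, float]:
    """L-BFGS finish for glassy soft-mode tails.

    Operates on reduced coordinates in which every pinned rosette group
    moves as one vertex; the energy is smooth there, so quasi-Newton
    steps resolve the nearly-flat directions that stall first-order
    descent.  Returns (energy, merged-residual) of the polished state.
    """
    from scipy.optimize import minimize as scipy_minimize

    groups = _pin_groups(st, params, settings)
    n_groups = int(groups.max()) + 1
    x0 = st.vertices.copy()

    def fun(u):
        disp = u.reshape(-1, 2)
        st.vertices = x0 + disp[groups]
        energy = tissue_energy(st, params)
        f = vertex_forces(st, params)
        grad = np.zeros((n_groups, 2))
        np.add.at(grad, groups, -f)
        return energy, grad.ravel()

    res = scipy_minimize(
        fun, np.zeros(2 * n_groups), jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "maxls": 100, "ftol": 1e-18,
                 "gtol": 0.2 * settings.tol},
    )
    st.vertices = x0 + res.x.reshape(-1, 2)[groups]
    st.wrap()
    residual = force_residual(
        st, params, settings.pin_threshold, settings.pin_tension_floor
    )
    return float(res.fun), residual


def minimize(
    state: TissueState,
    params: EnergyParams,
    settings: MinimizerSettings = MinimizerSettings(),
    allow_t1: bool = True,
    inplace: bool = False,
    event_context: dict | None = None,
) -> tuple[TissueState, MinimizeReport]:
    """Relax the tissue to force balance.

    Returns the relaxed state and a report with the final energy, residual,
    iteration count and any T1 events (time-stamped with ``event_context``,
    e.g. the closure stage).  A run that exhausts ``max_iter`` returns
    ``converged=False`` explicitly; callers must not treat such a state as
    quasistatic.
    """
    st = state if inplace else state.copy()
    vel = np.zeros_like(st.vertices)
    t1_events: list[dict] = []
    lt1 = settings.t1_threshold * np.sqrt(params.a0) if allow_t1 else 0.0
    pin = settings.pin_threshold * np.sqrt(params.a0)
    total_iter = 0
    # vertex pairs excluded from further flip attempts: topologically
    # impossible or energetically rejected at the current minimum
    # (re-tested after any accepted flip changes the topology), or already
    # at their per-call flip quota (permanent for this call; caps
    # flip-flop oscillations of zero-tension edges in the floppy regime)
    rejected: set[tuple[int, int]] = set()
    flip_counts: dict[tuple[int, int], int] = {}

    def fire(budget: int) -> tuple[bool, int, float, float]:
        nonlocal vel
        topo = st.topology()
        p0c = st.p0[topo.cell_ids]
        if vel.shape != st.vertices.shape:
            vel = np.zeros_like(st.vertices)
        status, it, energy, residual, _ = _kernels._fire(
            st.vertices, vel,
            st.box.lx, st.box.ly,
            topo.cell_start, topo.corner_vertex, topo.corner_cell, p0c,
            params.ka, params.kp, params.a0,
            settings.tol, budget,
            settings.dt0, settings.dt_max, settings.f_inc, settings.f_dec,
            settings.alpha0, settings.f_alpha, settings.n_min,
            0.0, settings.t1_check_every,
            np.zeros(topo.n_corners, dtype=np.bool_),
            pin, settings.pin_tension_floor * params.kp * np.sqrt(params.a0),
        )
        return status == _kernels.CONVERGED, it, energy, residual

    # T1 gate tests are accounted separately from the descent budget so a
    # state with many stable short edges cannot starve the minimization
    gate_iter = 0
    while True:
        remaining = settings.max_iter - total_iter
        converged, it, energy, residual = fire(
            min(max(remaining, 0), settings.polish_after)
        )
        total_iter += it
        if not converged:
            if it < settings.polish_after:
                # total iteration budget exhausted mid-round
                st.wrap()
                return st, MinimizeReport(
                    False, energy, residual, total_iter, t1_events,
                    message=f"FIRE did not reach tol={settings.tol} within "
                            f"{settings.max_iter} iterations "
                            f"(residual {residual:.3e})",
                )
            energy, residual = _quasi_newton_polish(st, params, settings)
            vel = np.zeros_like(st.vertices)
            if residual >= settings.tol:
                continue  # another FIRE round from the polished state
        if not allow_t1:
            st.wrap()
            return st, MinimizeReport(True, energy, residual, total_iter, t1_events)
        # at the minimum, look for a short edge eligible for a T1 test
        topo = st.topology()
        _, _, edge_vec = _kernels.geometry_arrays(st, topo)
        lengths = np.hypot(edge_vec[:, 0], edge_vec[:, 1])
        va_all = topo.corner_vertex
        vb_all = topo.corner_vertex[topo.corner_next]
        candidate = None
        for k in np.argsort(lengths):
            if lengths[k] >= lt1:
                break
            pair = (
                min(int(va_all[k]), int(vb_all[k])),
                max(int(va_all[k]), int(vb_all[k])),
            )
            if pair in rejected:
                continue
            candidate = (int(va_all[k]), int(vb_all[k]), pair)
            break
        if candidate is None:
            st.wrap()
            return st, MinimizeReport(True, energy, residual, total_iter, t1_events)
        if len(t1_events) >= settings.max_t1_per_minimize:
            st.wrap()
            return st, MinimizeReport(
                False, energy, residual, total_iter, t1_events,
                message="T1 limit exceeded (flip storm)",
            )
        v_a, v_b, pair = candidate
        saved_vertices = st.vertices.copy()
        saved_cells = [list(c) for c in st.cells]
        try:
            t1_flip(st, v_a, v_b, settings.t1_post_factor * lt1, inplace=True)
        except TopologyError:
            rejected.add(pair)
            continue
        # athermal gate: compare the converged pre-flip minimum with the
        # re-relaxed flipped state
        vel = np.zeros_like(st.vertices)
        _, git, e_new, _ = fire(settings.t1_gate_iters)
        gate_iter += git
        if e_new < energy - settings.t1_gate_margin * (1.0 + abs(energy)):
            event = {"v_a": v_a, "v_b": v_b, "iteration": total_iter}
            if event_context:
                event.update(event_context)
            t1_events.append(event)
            flip_counts[pair] = flip_counts.get(pair, 0) + 1
            rejected = {
                p for p, c in flip_counts.items()
                if c >= settings.max_flips_per_edge
            }
        else:
            st.vertices = saved_vertices
            st.cells = saved_cells
            st.invalidate_topology()
            rejected.add(pair)
        vel = np.zeros_like(st.vertices)
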