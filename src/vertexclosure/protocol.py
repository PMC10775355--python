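"""The dorsal-closure simulation protocol.

A rectangular periodic tissue (long axis = anterior-posterior) is
initialized with normally distributed preferred shape indices, then driven
quasistatically: at every step the box height shrinks by a fixed fraction
of its *initial* height (width fixed; an isotropic variant removes the
same area per step by scaling both axes), each cell's preferred perimeter
decreases linearly with the fractional area change dA, a small random
subset of cells ingresses (T2 removal), and the energy is re-minimized
with T1 moves enabled so that any neighbor exchange is an observed event.

Closure progress is measured by dA = (A0 - A) / A0 with A0 the initial
box area; with per-step decrement ``delta`` of the initial height the
uniaxial schedule gives dA = k * delta after k steps exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .mechanics import EnergyParams, MinimizerSettings, minimize
from .observables import ObservableRecord, observable_record
from .rigidity import DEFAULT_EPS_TAU
from .tissue import Box, TissueState, TopologyError, build_voronoi_tissue, t2_remove_cell

#: default initial mean preferred shape index and linear shrink slope
#: (fraction of the initial preferred perimeter lost per unit dA); see
#: docs/methods.md for the calibration of both against the study
#: conditions (initial shape-index distribution, linear mean-perimeter
#: decrease, tension non-monotonicity)
DEFAULT_Q0_MEAN = 4.2
DEFAULT_SHRINK_SLOPE = 0.65
DEFAULT_Q0_SD = 0.45


@dataclass(frozen=True)
class InitialShapeDistribution:
    """Normal distribution of preferred shape indices q0_i = p0_i / sqrt(a0)."""

    q0_mean: float = DEFAULT_Q0_MEAN
    q0_sd: float = DEFAULT_Q0_SD

    def __post_init__(self) -> None:
        if self.q0_sd < 0:
            raise ValueError("q0_sd must be non-negative")
        if self.q0_sd > 0 and norm.cdf(0.0, self.q0_mean, self.q0_sd) > 0.01:
            raise ValueError(
                "more than 1% of preferred-shape draws would be non-positive; "
                "distribution misconfigured"
            )


@dataclass(frozen=True)
class ClosureSchedule:
    """Deformation, shrinkage and ingression schedule of one run."""

    delta: float = 0.00125
    dA_max: float = 0.8
    shrink_slope: float = DEFAULT_SHRINK_SLOPE
    ingression_fraction: float = 0.1
    mode: str = "uniaxial"

    def __post_init__(self) -> None:
        if not (0 < self.delta < 0.1):
            raise ValueError("per-step height decrement must satisfy 0 < delta << 1")
        if not (0 < self.dA_max < 1):
            raise ValueError("dA_max must lie in (0, 1)")
        if self.shrink_slope < 0:
            raise ValueError("preferred-perimeter shrink slope must be >= 0")
        if not (0 <= self.ingression_fraction < 1):
            raise ValueError("ingression fraction must lie in [0, 1)")
        if self.mode not in ("uniaxial", "isotropic"):
            raise ValueError("deformation mode must be 'uniaxial' or 'isotropic'")

    @property
    def n_steps(self) -> int:
        return int(round(self.dA_max / self.delta))


@dataclass(frozen=True)
class ClosureStage:
    """Fractional area change relative to the reference area A0."""

    dA: float
    A0: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.dA < 1.0):
            raise ValueError("dA must lie in [0, 1)")
        if self.A0 <= 0:
            raise ValueError("reference area must be positive")


@dataclass
class ClosureTrajectory:
    """Recorded observables, event log and optional snapshots of one run."""

    records: list[ObservableRecord] = field(default_factory=list)
    t1_events: list[dict] = field(default_factory=list)
    ingressions: list[dict] = field(default_factory=list)
    snapshots: list[tuple[float, TissueState]] = field(default_factory=list)
    valid: bool = True
    message: str = ""
    config: dict = field(default_factory=dict)

    @property
    def n_t1(self) -> int:
        return len(self.t1_events)

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "dA", "q_mean", "q_sd", "ar_mean", "ar_sd", "Q_order",
            "tension_mean", "fr", "wraps_x", "wraps_y", "n_cells",
            "n_t1", "energy",
        ]
        return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in self.records])


@dataclass(frozen=True)
class RunConfig:
    """Complete, seedable description of one closure simulation."""

    n_cells: int = 400
    aspect: float = 2.0
    seed: int = 0
    q0_mean: float = DEFAULT_Q0_MEAN
    q0_sd: float = DEFAULT_Q0_SD
    delta: float = 0.00125
    dA_max: float = 0.8
    shrink_slope: float = DEFAULT_SHRINK_SLOPE
    ingression_fraction: float = 0.1
    mode: str = "uniaxial"
    ka: float = 1.0
    kp: float = 1.0
    a0: float = 1.0
    tol: float = 1e-5
    max_iter: int = 1_000_000
    t1_threshold: float = 0.02
    allow_t1: bool = True
    #: neighbor exchanges during the *preparation* quench of the initial
    #: tiling; off by default so the initial state keeps the Voronoi
    #: topology and its frustration, and T1 activity is an observable of
    #: the driven protocol only
    t1_in_preparation: bool = False
    eps_tau: float = DEFAULT_EPS_TAU
    record_stride: float = 0.01
    record_dA: tuple | None = None
    snapshot_stride: float | None = None
    #: end the run as soon as one spontaneous neighbor exchange has been
    #: logged (used by the fluidization control, where the first T1 is
    #: the observable of interest)
    stop_on_t1: bool = False

    def __post_init__(self) -> None:
        if self.record_dA is not None and not isinstance(self.record_dA, tuple):
            object.__setattr__(self, "record_dA", tuple(self.record_dA))

    @property
    def schedule(self) -> ClosureSchedule:
        return ClosureSchedule(
            delta=self.delta,
            dA_max=self.dA_max,
            shrink_slope=self.shrink_slope,
            ingression_fraction=self.ingression_fraction,
            mode=self.mode,
        )

    @property
    def distribution(self) -> InitialShapeDistribution:
        return InitialShapeDistribution(self.q0_mean, self.q0_sd)

    @property
    def params(self) -> EnergyParams:
        return EnergyParams(self.ka, self.kp, self.a0)

    @property
    def minimizer(self) -> MinimizerSettings:
        return MinimizerSettings(
            tol=self.tol, max_iter=self.max_iter, t1_threshold=self.t1_threshold
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["record_dA"] is not None:
            d["record_dA"] = list(d["record_dA"])
        return d


# ---------------------------------------------------------------------------
# protocol operations
# ---------------------------------------------------------------------------

def initialize_polydisperse(
    state: TissueState,
    dist: InitialShapeDistribution,
    seed: int,
    params: EnergyParams = EnergyParams(),
    settings: MinimizerSettings = MinimizerSettings(),
    allow_t1: bool = True,
    relax: bool = True,
) -> TissueState:
    """Assign p0_i = q0_i sqrt(a0) with q0_i ~ N(q0_mean, q0_sd), then relax.

    Non-positive draws are resampled (the distribution validator already
    rejects parameterizations where that happens for more than 1% of
    draws).  The same seed reproduces the same assignment exactly.
    """
    st = state.copy()
    rng = np.random.default_rng(seed)
    n = len(st.cells)
    q0 = rng.normal(dist.q0_mean, dist.q0_sd, size=n)
    bad = q0 <= 0
    while bad.any():
        q0[bad] = rng.normal(dist.q0_mean, dist.q0_sd, size=int(bad.sum()))
        bad = q0 <= 0
    st.p0 = q0 * np.sqrt(params.a0)
    st.a0 = params.a0
    if relax:
        st, report = minimize(st, params, settings, allow_t1=allow_t1, inplace=True)
        if not report.converged:
            raise RuntimeError(f"initial relaxation failed: {report.message}")
    return st


def apply_deformation_step(
    state: TissueState,
    schedule: ClosureSchedule,
    box0: Box,
    inplace: bool = False,
) -> TissueState:
    """One quasistatic box deformation with affine vertex remap.

    Uniaxial: the height drops by ``delta`` of the *initial* height with
    the width fixed, so after k steps dA = k * delta exactly.  Isotropic:
    both box lengths shrink by a common factor chosen to remove the same
    area per step.  The state must be re-minimized afterwards.
    """
    st = state if inplace else state.copy()
    box = st.box
    dA_step = schedule.delta * box0.area
    if schedule.mode == "uniaxial":
        new_ly = box.ly - schedule.delta * box0.ly
        if new_ly <= 0:
            raise ValueError("deformation step would make the box height non-positive")
        st.vertices[:, 1] *= new_ly / box.ly
        st.box = Box(box.lx, new_ly)
    else:
        new_area = box.area - dA_step
        if new_area <= 0:
            raise ValueError("deformation step would make the box area non-positive")
        f = np.sqrt(new_area / box.area)
        st.vertices *= f
        st.box = Box(box.lx * f, box.ly * f)
    st.invalidate_topology()
    return st


def update_preferred_perimeters(
    state: TissueState,
    stage: ClosureStage,
    schedule: ClosureSchedule,
    p0_initial: np.ndarray,
    inplace: bool = False,
) -> TissueState:
    """Linear active shrinkage p0_i(dA) = p0_i(0) (1 - c dA), floored at 0.

    The preferred area a0 is deliberately left unchanged; only the
    perimeter spring rest length is actively remodeled.
    """
    st = state if inplace else state.copy()
    factor = max(1.0 - schedule.shrink_slope * stage.dA, 0.0)
    st.p0 = np.asarray(p0_initial, dtype=float) * factor
    return st


def ingress_cells(
    state: TissueState,
    schedule: ClosureSchedule,
    rng: np.random.Generator,
    n_initial_cells: int,
    params: EnergyParams = EnergyParams(),
    settings: MinimizerSettings = MinimizerSettings(),
    inplace: bool = False,
    relax: bool = True,
) -> tuple[TissueState, list[dict]]:
    """Random cell ingression at the per-step experimental rate.

    With probability ``f_I * N(0) / n_steps`` one uniformly chosen alive
    cell is removed (T2 collapse) and the tissue re-minimized, so that
    roughly a fraction f_I of the initial cells disappears over a full
    run.  Cells whose removal would break trivalence are skipped in favor
    of another draw; if nothing is removable the step is a silent no-op.
    """
    st = state if inplace else state.copy()
    events: list[dict] = []
    p_step = schedule.ingression_fraction * n_initial_cells / schedule.n_steps
    if rng.uniform() >= p_step:
        return st, events
    alive = np.flatnonzero(st.alive)
    if alive.size <= 3:
        return st, events
    order = rng.permutation(alive)
    for cell_id in order[: min(10, alive.size)]:
        try:
            _, info = t2_remove_cell(st, int(cell_id), inplace=True)
        except TopologyError:
            continue
        if relax:
            st, report = minimize(st, params, settings, allow_t1=True, inplace=True)
            info["relaxed"] = report.converged
        events.append(info)
        break
    return st, events


def run_closure(config: RunConfig) -> ClosureTrajectory:
    """Full quasistatic dorsal-closure run; a pure function of the config.

    Loops deformation -> preferred-perimeter update -> optional ingression
    -> T1-enabled minimization until dA_max, recording observables every
    ``record_stride`` in dA (or exactly at the dA values in ``record_dA``).
    A minimization failure aborts with the partial trajectory flagged
    invalid.
    """
    schedule = config.schedule
    params = config.params
    settings = config.minimizer
    traj = ClosureTrajectory(config=config.to_dict())

    lx = float(np.sqrt(config.aspect * config.n_cells * params.a0))
    box0 = Box(lx, lx / config.aspect)
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    build_seed = int(seeds[0].generate_state(1)[0] % (2**31 - 1))
    init_seed = int(seeds[1].generate_state(1)[0] % (2**31 - 1))
    rng_ingress = np.random.default_rng(seeds[2])

    state = build_voronoi_tissue(config.n_cells, box0, seed=build_seed)
    state = initialize_polydisperse(
        state, config.distribution, init_seed, params, settings,
        allow_t1=config.t1_in_preparation,
    )
    p0_initial = state.p0.copy()
    n0 = config.n_cells
    A0 = box0.area

    n_steps = schedule.n_steps
    if config.record_dA is not None:
        record_steps = {
            int(round(d / schedule.delta)) for d in config.record_dA
        }
    else:
        every = max(int(round(config.record_stride / schedule.delta)), 1)
        record_steps = set(range(0, n_steps + 1, every))
        record_steps.add(n_steps)
    snap_steps: set[int] = set()
    if config.snapshot_stride is not None:
        snap_every = max(int(round(config.snapshot_stride / schedule.delta)), 1)
        snap_steps = set(range(0, n_steps + 1, snap_every))

    def record(k: int) -> None:
        dA = k * schedule.delta
        rec = observable_record(
            state, params, dA, eps_tau=config.eps_tau, n_t1=traj.n_t1
        )
        traj.records.append(rec)
        if k in snap_steps:
            traj.snapshots.append((dA, state.copy()))

    if 0 in record_steps:
        record(0)
    for k in range(1, n_steps + 1):
        dA = k * schedule.delta
        stage = ClosureStage(dA=dA, A0=A0)
        apply_deformation_step(state, schedule, box0, inplace=True)
        update_preferred_perimeters(state, stage, schedule, p0_initial, inplace=True)
        if schedule.ingression_fraction > 0:
            state, events = ingress_cells(
                state, schedule, rng_ingress, n0, params, settings,
                inplace=True, relax=False,
            )
            for ev in events:
                ev["dA"] = dA
                traj.ingressions.append(ev)
        state, report = minimize(
            state, params, settings,
            allow_t1=config.allow_t1, inplace=True,
            event_context={"dA": dA},
        )
        traj.t1_events.extend(report.t1_events)
        if not report.converged:
            traj.valid = False
            traj.message = f"minimization failed at dA={dA:.4f}: {report.message}"
            return traj
        if k in record_steps:
            record(k)
        if config.stop_on_t1 and traj.n_t1 > 0:
            traj.message = f"stopped after first T1 at dA={dA:.4f}"
            return traj
    return traj
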