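"""Cell- and tissue-level measurements: shape index statistics, aspect
ratio and orientation from the area-weighted second-moment tensor of each
cell polygon, the nematic order parameter Q = <cos 2 theta> along the
anterior-posterior axis, and junction tension

    tau_J = kp (p_i - p0_i) + kp (p_j - p0_j)

summed over the two cells sharing a junction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .mechanics import EnergyParams
from .tissue import GeometryError, Junction, TissueState, _unwrap_cycle

#: cells closer to circular than this in aspect ratio have no defined
#: orientation and are excluded from the order parameter (the polygon
#: second moments of a regular polygon are equal only to within float
#: round-off, so the cut sits just above that noise floor)
ISOTROPY_ATOL = 1e-7


@dataclass(frozen=True)
class ObservableRecord:
    """One row of the closure observables table."""

    dA: float
    q_mean: float
    q_sd: float
    ar_mean: float
    ar_sd: float
    Q_order: float
    tension_mean: float
    fr: float
    wraps_x: bool
    wraps_y: bool
    n_cells: int
    n_t1: int
    energy: float

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.Q_order <= 1.0 + 1e-12):
            raise ValueError("order parameter must lie in [-1, 1]")
        if not (0.0 <= self.fr <= 1.0):
            raise ValueError("rigid fraction must lie in [0, 1]")


def _polygon_moments(poly: np.ndarray) -> tuple[float, float, float, float]:
    """(area, Mxx, Mxy, Myy): area-normalized central second moments."""
    r = poly - poly[0]
    x, y = r[:, 0], r[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    if area <= 0:
        raise GeometryError("zero or negative polygon area")
    cx = (x + xn) @ cross / (6.0 * area)
    cy = (y + yn) @ cross / (6.0 * area)
    mxx = (x * x + x * xn + xn * xn) @ cross / (12.0 * area) - cx * cx
    myy = (y * y + y * yn + yn * yn) @ cross / (12.0 * area) - cy * cy
    mxy = (x * yn + 2 * x * y + 2 * xn * yn + xn * y) @ cross / (24.0 * area) - cx * cy
    return area, mxx, mxy, myy


def cell_shape_tensor(
    state: TissueState, cell_id: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Aspect ratio and orientation of each alive cell.

    The shape tensor is the second-moment (covariance) tensor of the cell
    polygon's area, taken about its area centroid with minimum-image
    unwrapping.  The aspect ratio is sqrt(lambda_max / lambda_min) and the
    orientation is the angle of the major axis to the x (anterior-
    posterior) axis, folded to [-pi/2, pi/2].  Isotropic cells get
    ``theta = nan``.  Dead cells get NaN in both outputs.

    With ``cell_id`` given, returns the scalar pair for that cell.
    """
    ids = (
        [cell_id]
        if cell_id is not None
        else [ci for ci in range(len(state.cells)) if state.alive[ci]]
    )
    alpha = np.full(len(state.cells), np.nan)
    theta = np.full(len(state.cells), np.nan)
    for ci in ids:
        if not state.alive[ci]:
            raise GeometryError(f"cell {ci} is not alive")
        poly = _unwrap_cycle(state.vertices[state.cells[ci]], state.box)
        _, mxx, mxy, myy = _polygon_moments(poly)
        tr = mxx + myy
        det = mxx * myy - mxy * mxy
        disc = max(tr * tr / 4.0 - det, 0.0)
        root = np.sqrt(disc)
        lmax = tr / 2.0 + root
        lmin = tr / 2.0 - root
        if lmin <= 0:
            raise GeometryError(f"cell {ci} has a degenerate shape tensor")
        a = np.sqrt(lmax / lmin)
        alpha[ci] = a
        if a >= 1.0 + ISOTROPY_ATOL:
            ang = 0.5 * np.arctan2(2.0 * mxy, mxx - myy)
            if ang > np.pi / 2:
                ang -= np.pi
            elif ang <= -np.pi / 2:
                ang += np.pi
            theta[ci] = ang
    if cell_id is not None:
        return alpha[cell_id], theta[cell_id]
    return alpha, theta


def order_parameter(state: TissueState) -> float:
    """Mean cos(2 theta) over alive, anisotropic cells.

    1 for perfect alignment with the AP axis, 0 for random orientations,
    -1 for alignment with the transverse axis.  An all-isotropic state
    has no defined orientations and returns 0 with a warning.
    """
    _, theta = cell_shape_tensor(state)
    ok = np.isfinite(theta)
    if not ok.any():
        warnings.warn("all cells isotropic; order parameter defined as 0")
        return 0.0
    return float(np.mean(np.cos(2.0 * theta[ok])))


def junction_tensions(state: TissueState, params: EnergyParams) -> np.ndarray:
    """Tension of every junction, in topology junction order."""
    topo = state.topology()
    _, perims, _ = _kernels.geometry_arrays(state, topo)
    p0c = state.p0[topo.cell_ids]
    t = params.kp * (perims - p0c)
    ci = topo.corner_cell[topo.junction_corner_a]
    cj = topo.corner_cell[topo.junction_corner_b]
    return t[ci] + t[cj]


def junction_tension(
    state: TissueState, params: EnergyParams, junction: Junction
) -> float:
    """Tension of one junction from the two adjacent cells' perimeter springs."""
    for ci in (junction.cell_i, junction.cell_j):
        if not state.alive[ci]:
            raise GeometryError(f"junction cell {ci} is not alive")
    topo = state.topology()
    _, perims, _ = _kernels.geometry_arrays(state, topo)
    p0c = state.p0[topo.cell_ids]
    t = params.kp * (perims - p0c)
    pos = {int(c): k for k, c in enumerate(topo.cell_ids)}
    return float(t[pos[junction.cell_i]] + t[pos[junction.cell_j]])


def observable_record(
    state: TissueState,
    params: EnergyParams,
    dA: float,
    eps_tau: float = 1e-4,
    n_t1: int = 0,
) -> ObservableRecord:
    """Assemble the full measurement row for a minimized state.

    Means and standard deviations are unweighted over alive cells; the
    mean tension runs over all junctions; the rigid fraction and wrapping
    verdict come from the rigidity analysis at tension floor ``eps_tau``.
    """
    from .mechanics import tissue_energy
    from .rigidity import rigid_junction_analysis

    topo = state.topology()
    areas, perims, _ = _kernels.geometry_arrays(state, topo)
    q = perims / np.sqrt(areas)
    alpha, _ = cell_shape_tensor(state)
    alpha = alpha[np.isfinite(alpha)]
    taus = junction_tensions(state, params)
    perc = rigid_junction_analysis(state, params, eps_tau)
    return ObservableRecord(
        dA=float(dA),
        q_mean=float(q.mean()),
        q_sd=float(q.std(ddof=0)),
        ar_mean=float(alpha.mean()),
        ar_sd=float(alpha.std(ddof=0)),
        Q_order=order_parameter(state),
        tension_mean=float(taus.mean()),
        fr=perc.fr,
        wraps_x=perc.wraps_x,
        wraps_y=perc.wraps_y,
        n_cells=state.n_cells_alive,
        n_t1=n_t1,
        energy=tissue_energy(state, params),
    )
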