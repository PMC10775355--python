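"""Geometry and topology of a confluent periodic 2D cell tiling.

A tissue is a trivalent polygonal tiling of a periodic rectangle: every
vertex has exactly three edges, every edge is shared by exactly two cells,
and the cell polygons partition the box, so on the torus ``V - E + F = 0``
(hence ``E = 3V/2`` and ``F = V/2``).  All geometry is computed with the
minimum-image convention so that cells straddling the periodic boundary
behave exactly like cells in the bulk.

The module provides construction (periodic Voronoi tilings, regular
honeycombs), measurement (areas, perimeters, shape index), the two
elementary topological moves of vertex models (T1 neighbor exchange and
T2 cell removal), and lossless JSON snapshots.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi, cKDTree

SNAPSHOT_SCHEMA = "vertexclosure-tissue-1"


class TopologyError(RuntimeError):
    """Raised when an operation would break tiling invariants."""


class GeometryError(RuntimeError):
    """Raised for degenerate or non-simple cell geometry."""


@dataclass(frozen=True)
class Box:
    """Periodic rectangular domain; ``lx`` is the anterior-posterior axis."""

    lx: float
    ly: float

    def __post_init__(self) -> None:
        if not (self.lx > 0 and self.ly > 0):
            raise ValueError(f"box lengths must be positive, got {self.lx}, {self.ly}")

    @property
    def area(self) -> float:
        return self.lx * self.ly

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly])


@dataclass(frozen=True)
class Junction:
    """An edge of the tiling: a vertex pair shared by two distinct cells."""

    v_a: int
    v_b: int
    cell_i: int
    cell_j: int
    length: float

    def __post_init__(self) -> None:
        if self.cell_i == self.cell_j:
            raise TopologyError("junction must separate two distinct cells")
        if self.length < 0:
            raise GeometryError("junction length must be non-negative")


def minimum_image(disp: np.ndarray, box: Box) -> np.ndarray:
    """Wrap displacement vectors into the nearest periodic image."""
    d = np.asarray(disp, dtype=float).copy()
    d[..., 0] -= box.lx * np.round(d[..., 0] / box.lx)
    d[..., 1] -= box.ly * np.round(d[..., 1] / box.ly)
    return d


class _FlatTopology:
    """Flat corner/junction arrays for vectorized kernels.

    Corners are the (cell, vertex) incidences of alive cells, grouped by
    cell in cycle order.  Junctions are matched half-edge pairs.
    """

    def __init__(self, state: "TissueState") -> None:
        cells = [
            (ci, cyc)
            for ci, cyc in enumerate(state.cells)
            if state.alive[ci] and len(cyc) > 0
        ]
        self.cell_ids = np.array([ci for ci, _ in cells], dtype=np.int64)
        sizes = np.array([len(cyc) for _, cyc in cells], dtype=np.int64)
        self.cell_start = np.concatenate([[0], np.cumsum(sizes)])
        self.corner_vertex = np.array(
            [v for _, cyc in cells for v in cyc], dtype=np.int64
        )
        ncell = len(cells)
        self.corner_cell = np.repeat(np.arange(ncell, dtype=np.int64), sizes)
        # next corner within each cycle
        nxt = np.arange(self.corner_vertex.size, dtype=np.int64) + 1
        for c in range(ncell):
            nxt[self.cell_start[c + 1] - 1] = self.cell_start[c]
        self.corner_next = nxt
        self._match_half_edges()

    def _match_half_edges(self) -> None:
        va = self.corner_vertex
        vb = self.corner_vertex[self.corner_next]
        key: dict[tuple[int, int], list[int]] = {}
        for k in range(va.size):
            a, b = int(va[k]), int(vb[k])
            key.setdefault((min(a, b), max(a, b)), []).append(k)
        ca, cb = [], []
        for (a, b), corners in key.items():
            if len(corners) % 2 != 0:
                raise TopologyError(
                    f"edge ({a},{b}) appears {len(corners)} times; tiling invalid"
                )
            # generically exactly two half-edges; tiny tori can have parallel
            # edges with identical endpoints, paired here in discovery order
            fwd = [k for k in corners if int(va[k]) == a]
            bwd = [k for k in corners if int(va[k]) == b]
            if len(fwd) != len(bwd):
                raise TopologyError(f"edge ({a},{b}) traversed inconsistently")
            for kf, kb in zip(fwd, bwd):
                ca.append(kf)
                cb.append(kb)
        self.junction_corner_a = np.array(ca, dtype=np.int64)
        self.junction_corner_b = np.array(cb, dtype=np.int64)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_corners(self) -> int:
        return self.corner_vertex.size

    @property
    def n_junctions(self) -> int:
        return self.junction_corner_a.size

    def active_vertices(self) -> np.ndarray:
        return np.unique(self.corner_vertex)


@dataclass
class TissueState:
    """Confluent periodic tiling with per-cell preferred geometry.

    ``cells`` holds counter-clockwise vertex cycles; dead (ingressed) cells
    keep an empty cycle and ``alive=False`` so that cell ids remain stable
    over a simulation.  ``vertices`` may contain retired rows that no alive
    cell references.
    """

    vertices: np.ndarray
    cells: list[list[int]]
    p0: np.ndarray
    a0: float
    box: Box
    alive: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.p0 = np.asarray(self.p0, dtype=float)
        if self.alive is None:
            self.alive = np.ones(len(self.cells), dtype=bool)
        self.alive = np.asarray(self.alive, dtype=bool)
        if len(self.cells) != self.p0.size or len(self.cells) != self.alive.size:
            raise ValueError("cells, p0 and alive must have matching lengths")
        self._topo: _FlatTopology | None = None

    # -- caching ---------------------------------------------------------
    def topology(self) -> _FlatTopology:
        if self._topo is None:
            self._topo = _FlatTopology(self)
        return self._topo

    def invalidate_topology(self) -> None:
        self._topo = None

    # -- bookkeeping -----------------------------------------------------
    @property
    def n_cells_alive(self) -> int:
        return int(self.alive.sum())

    @property
    def n_vertices(self) -> int:
        return self.topology().active_vertices().size

    @property
    def n_junctions(self) -> int:
        return self.topology().n_junctions

    def copy(self) -> "TissueState":
        return TissueState(
            vertices=self.vertices.copy(),
            cells=[list(c) for c in self.cells],
            p0=self.p0.copy(),
            a0=self.a0,
            box=self.box,
            alive=self.alive.copy(),
        )

    def wrap(self) -> None:
        """Fold vertex positions back into the fundamental domain."""
        self.vertices[:, 0] %= self.box.lx
        self.vertices[:, 1] %= self.box.ly

    def cell_centroid(self, cell_id: int) -> np.ndarray:
        """Arithmetic centroid of a cell's (minimum-image unwrapped) cycle."""
        cyc = self.cells[cell_id]
        pos = _unwrap_cycle(self.vertices[cyc], self.box)
        return pos.mean(axis=0)

    # -- snapshots -------------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "schema": SNAPSHOT_SCHEMA,
            "box": {"lx": self.box.lx, "ly": self.box.ly},
            "vertices": self.vertices.tolist(),
            "cells": [list(map(int, c)) for c in self.cells],
            "p0": self.p0.tolist(),
            "a0": self.a0,
            "alive": [bool(a) for a in self.alive],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "TissueState":
        doc = json.loads(text)
        if doc.get("schema") != SNAPSHOT_SCHEMA:
            raise ValueError(f"unknown snapshot schema {doc.get('schema')!r}")
        return cls(
            vertices=np.array(doc["vertices"], dtype=float),
            cells=[list(c) for c in doc["cells"]],
            p0=np.array(doc["p0"], dtype=float),
            a0=float(doc["a0"]),
            box=Box(doc["box"]["lx"], doc["box"]["ly"]),
            alive=np.array(doc["alive"], dtype=bool),
        )


def _unwrap_cycle(pos: np.ndarray, box: Box) -> np.ndarray:
    """Unwrap a vertex cycle into a contiguous polygon around its first vertex."""
    steps = minimum_image(np.diff(pos, axis=0), box)
    out = np.empty_like(pos)
    out[0] = pos[0]
    out[1:] = pos[0] + np.cumsum(steps, axis=0)
    return out


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def cell_geometry(state: TissueState) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (area, perimeter); NaN for dead cells.

    Areas use the shoelace formula on minimum-image unwrapped cycles,
    perimeters sum minimum-image edge lengths.  Raises
    :class:`GeometryError` naming the first cell whose polygon has
    non-positive signed area (orientation is an invariant, so this flags a
    collapsed or inverted cell).
    """
    from ._kernels import geometry_arrays

    topo = state.topology()
    areas_c, perims_c, _ = geometry_arrays(state, topo)
    bad = np.flatnonzero(areas_c <= 0)
    if bad.size:
        raise GeometryError(
            f"cell {int(topo.cell_ids[bad[0]])} has non-positive area "
            f"{areas_c[bad[0]]:.3e}"
        )
    areas = np.full(len(state.cells), np.nan)
    perims = np.full(len(state.cells), np.nan)
    areas[topo.cell_ids] = areas_c
    perims[topo.cell_ids] = perims_c
    return areas, perims


def shape_index(area, perimeter):
    """Dimensionless cell shape index q = p / sqrt(a)."""
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0):
        raise GeometryError("shape index requires positive area")
    return np.asarray(perimeter, dtype=float) / np.sqrt(area)


def junction_list(state: TissueState) -> list[Junction]:
    """All edges of the tiling as :class:`Junction` records."""
    topo = state.topology()
    va = topo.corner_vertex[topo.junction_corner_a]
    vb = topo.corner_vertex[topo.corner_next[topo.junction_corner_a]]
    ci = topo.cell_ids[topo.corner_cell[topo.junction_corner_a]]
    cj = topo.cell_ids[topo.corner_cell[topo.junction_corner_b]]
    d = minimum_image(state.vertices[vb] - state.vertices[va], state.box)
    lengths = np.hypot(d[:, 0], d[:, 1])
    return [
        Junction(int(a), int(b), int(i), int(j), float(l))
        for a, b, i, j, l in zip(va, vb, ci, cj, lengths)
    ]


def validate_state(state: TissueState, check_simple: bool = False) -> None:
    """Check the full set of tiling invariants; raise on the first violation.

    Verifies trivalence, the Euler relation, double-counted edges, positive
    CCW areas, and confluence (cell areas tile the box).  With
    ``check_simple`` each polygon is additionally tested for
    self-intersection (O(m^2) per cell, test-path only).
    """
    topo = state.topology()
    counts: dict[int, int] = {}
    for v in topo.corner_vertex:
        counts[int(v)] = counts.get(int(v), 0) + 1
    bad = [v for v, c in counts.items() if c != 3]
    if bad:
        raise TopologyError(f"vertices {bad[:5]} do not have degree 3")
    V = len(counts)
    E = topo.n_junctions
    F = topo.n_cells
    if V - E + F != 0:
        raise TopologyError(f"Euler relation violated: V={V} E={E} F={F}")
    if 2 * E != topo.n_corners:
        raise TopologyError("edges are not each shared by exactly two cells")
    areas, _ = cell_geometry(state)
    total = np.nansum(areas)
    if not np.isclose(total, state.box.area, rtol=1e-9, atol=0):
        raise GeometryError(
            f"cell areas sum to {total!r}, box area is {state.box.area!r}"
        )
    if check_simple:
        for ci in np.flatnonzero(state.alive):
            poly = _unwrap_cycle(state.vertices[state.cells[ci]], state.box)
            if not _is_simple(poly):
                raise GeometryError(f"cell {int(ci)} polygon is self-intersecting")


def _is_simple(poly: np.ndarray) -> bool:
    m = len(poly)
    segs = [(poly[i], poly[(i + 1) % m]) for i in range(m)]

    def intersects(p, q, r, s):
        def orient(a, b, c):
            u, v = b - a, c - a
            return np.sign(u[0] * v[1] - u[1] * v[0])

        return (
            orient(p, q, r) * orient(p, q, s) < 0
            and orient(r, s, p) * orient(r, s, q) < 0
        )

    for i in range(m):
        for j in range(i + 2, m):
            if i == 0 and j == m - 1:
                continue  # adjacent around the cycle
            if intersects(*segs[i], *segs[j]):
                return False
    return True


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_voronoi_tissue(
    n_cells: int,
    box: Box,
    seed: int,
    max_attempts: int = 10,
) -> TissueState:
    """Trivalent periodic tiling from a Voronoi diagram of uniform seeds.

    Degenerate (cocircular) seed sets are jittered by ``1e-8 * sqrt(a0)``
    and retried rather than returned.  Identical seeds give identical
    vertex coordinates.
    """
    if n_cells < 3:
        raise ValueError("need at least 3 cells for a periodic trivalent tiling")
    rng = np.random.default_rng(seed)
    pts = rng.uniform(size=(n_cells, 2)) * box.lengths
    scale = np.sqrt(box.area / n_cells)
    for attempt in range(max_attempts):
        try:
            state = _voronoi_tiling(pts, box)
            validate_state(state)
            return state
        except (TopologyError, GeometryError):
            jitter = 1e-8 * scale * 10.0**attempt
            pts = (pts + rng.normal(scale=jitter, size=pts.shape)) % box.lengths
    raise TopologyError(
        f"could not build a valid Voronoi tiling after {max_attempts} attempts"
    )


def _voronoi_tiling(points: np.ndarray, box: Box) -> TissueState:
    n = len(points)
    offsets = [
        (ix, iy) for iy in (-1, 0, 1) for ix in (-1, 0, 1) if (ix, iy) != (0, 0)
    ]
    tiles = [points] + [points + np.array(o) * box.lengths for o in offsets]
    vor = Voronoi(np.vstack(tiles))

    raw_cycles = []
    raw_coords = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise TopologyError("open Voronoi region for an interior seed")
        verts = vor.vertices[region]
        ang = np.arctan2(verts[:, 1] - points[i, 1], verts[:, 0] - points[i, 0])
        order = np.argsort(ang)  # CCW
        raw_cycles.append([len(raw_coords) + k for k in range(len(order))])
        raw_coords.extend(verts[order])
    raw_coords = np.asarray(raw_coords)
    wrapped = raw_coords % box.lengths
    # vertices appear once per incident cell; merge coincident copies
    # (periodic KD-tree handles copies that wrapped to opposite box edges)
    tol = 1e-7 * np.sqrt(box.area / n)
    eps = 1e-12 * max(box.lx, box.ly)
    boxed = np.minimum(wrapped, box.lengths - eps)
    tree = cKDTree(boxed, boxsize=box.lengths)
    pairs = tree.query_pairs(r=tol)
    parent = list(range(len(wrapped)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    labels = {}
    rep = []
    for k in range(len(wrapped)):
        r = find(k)
        if r not in labels:
            labels[r] = len(rep)
            rep.append(wrapped[r])
    cells = []
    for cyc in raw_cycles:
        ids = [labels[find(k)] for k in cyc]
        dedup = [v for i, v in enumerate(ids) if v != ids[i - 1]]
        if len(set(dedup)) != len(dedup) or len(dedup) < 3:
            raise TopologyError("degenerate Voronoi cell after vertex merging")
        cells.append(dedup)
    return TissueState(
        vertices=np.asarray(rep),
        cells=cells,
        p0=np.full(n, 3.8),
        a0=box.area / n,
        box=box,
    )


def build_hexagonal_tissue(nx: int, ny: int, a0: float = 1.0) -> TissueState:
    """Regular honeycomb of ``nx * ny`` unit-area hexagons (``ny`` even).

    A stationary reference state: by symmetry every vertex force vanishes
    for any uniform preferred perimeter.
    """
    if ny % 2 != 0:
        raise ValueError("ny must be even for a periodic honeycomb")
    if nx < 2 or ny < 2:
        raise ValueError("need at least a 2x2 honeycomb")
    s = np.sqrt(2.0 * a0 / (3.0 * np.sqrt(3.0)))  # hexagon side
    ux, uy = np.sqrt(3.0) * s / 2.0, s / 2.0
    IX, IY = 2 * nx, 3 * ny  # integer periods: lx = IX*ux, ly = IY*uy
    box = Box(IX * ux, IY * uy)
    # pointy-top hexagon corners on the integer lattice (X, Y) in units (ux, uy)
    corner_offsets = [(1, -1), (1, 1), (0, 2), (-1, 1), (-1, -1), (0, -2)]
    ids: dict[tuple[int, int], int] = {}
    coords: list[tuple[float, float]] = []
    cells = []
    for row in range(ny):
        for col in range(nx):
            X = 2 * col + (row % 2)
            Y = 3 * row
            cyc = []
            for dx, dy in corner_offsets:
                key = ((X + dx) % IX, (Y + dy) % IY)
                if key not in ids:
                    ids[key] = len(coords)
                    coords.append((key[0] * ux, key[1] * uy))
                cyc.append(ids[key])
            cells.append(cyc)
    n = nx * ny
    return TissueState(
        vertices=np.asarray(coords, dtype=float),
        cells=cells,
        p0=np.full(n, 3.8),
        a0=a0,
        box=box,
    )


# ---------------------------------------------------------------------------
# elementary moves
# ---------------------------------------------------------------------------

def _cells_with_directed_edge(state: TissueState, a: int, b: int):
    hits = []
    for ci, cyc in enumerate(state.cells):
        if not state.alive[ci]:
            continue
        for k, v in enumerate(cyc):
            if v == a and cyc[(k + 1) % len(cyc)] == b:
                hits.append((ci, k))
    return hits

def _cells_with_vertex(state: TissueState, v: int):
    return [
        ci
        for ci, cyc in enumerate(state.cells)
        if state.alive[ci] and v in cyc
    ]


def t1_flip(
    state: TissueState,
    v_a: int,
    v_b: int,
    post_length: float,
    inplace: bool = False,
) -> TissueState:
    """T1 neighbor exchange on edge (v_a, v_b).

    The edge is rotated 90 degrees about its midpoint and reconnected so
    that the two cells previously sharing it separate and the two cells
    previously meeting it only at its endpoints become neighbors.  Cycles
    stay CCW and trivalent.  Raises :class:`TopologyError` if the flip
    would create a two-sided cell or the four surrounding cells are not
    distinct.
    """
    st = state if inplace else state.copy()
    fwd = _cells_with_directed_edge(st, v_a, v_b)
    bwd = _cells_with_directed_edge(st, v_b, v_a)
    if len(fwd) != 1 or len(bwd) != 1:
        raise TopologyError(f"edge ({v_a},{v_b}) is not a unique tiling edge")
    c1, _ = fwd[0]  # traverses a -> b, keeps b
    c2, _ = bwd[0]  # traverses b -> a, keeps a
    if c1 == c2:
        raise TopologyError("edge bounds a single cell; cannot flip")
    third_a = [c for c in _cells_with_vertex(st, v_a) if c not in (c1, c2)]
    third_b = [c for c in _cells_with_vertex(st, v_b) if c not in (c1, c2)]
    if len(third_a) != 1 or len(third_b) != 1:
        raise TopologyError("edge endpoints are not trivalent")
    ck, cl = third_a[0], third_b[0]
    if ck == cl:
        raise TopologyError("flip would create a two-sided cell")
    if len(st.cells[c1]) <= 3 or len(st.cells[c2]) <= 3:
        raise TopologyError("flip would reduce a triangle to a two-sided cell")

    ra, rb = st.vertices[v_a], st.vertices[v_b]
    e = minimum_image(rb - ra, st.box)
    mid = ra + 0.5 * e
    u = np.array([-e[1], e[0]])
    norm = np.linalg.norm(u)
    if norm < 1e-300:
        u = np.array([1.0, 0.0])
    else:
        u = u / norm
    # vertex a stays with cell c2: point it toward c2's centroid
    toward = minimum_image(st.cell_centroid(c2) - mid, st.box)
    if np.dot(u, toward) < 0:
        u = -u

    cyc1 = st.cells[c1]
    cyc2 = st.cells[c2]
    cyc1.remove(v_a)
    cyc2.remove(v_b)
    cyck = st.cells[ck]
    cycl = st.cells[cl]
    cyck.insert(cyck.index(v_a) + 1, v_b)
    cycl.insert(cycl.index(v_b) + 1, v_a)

    st.vertices[v_a] = (mid + 0.5 * post_length * u) % st.box.lengths
    st.vertices[v_b] = (mid - 0.5 * post_length * u) % st.box.lengths
    st.invalidate_topology()
    return st


def t2_remove_cell(
    state: TissueState,
    cell_id: int,
    inplace: bool = False,
    edge_post_length: float = 0.03,
) -> tuple[TissueState, dict]:
    """Remove (ingress) a cell, collapsing it to a single trivalent vertex.

    Cells with more than three sides are first retracted by collapsing
    their shortest edges through neighbor exchanges (these junction losses
    are part of the ingression event, reported in the returned info dict,
    and are distinct from spontaneous T1 events during energy descent).
    The final triangle is replaced by one vertex at its centroid, which
    inherits the three outgoing edges, so trivalence and confluence are
    restored exactly.
    """
    st = state if inplace else state.copy()
    if cell_id < 0 or cell_id >= len(st.cells) or not st.alive[cell_id]:
        raise TopologyError(f"cell {cell_id} does not exist or is already dead")
    if len(st.cells[cell_id]) < 3:
        raise TopologyError(f"cell {cell_id} has fewer than 3 vertices")
    if st.n_cells_alive <= 3:
        raise TopologyError("cannot remove a cell from a <=3-cell tiling")

    collapse_flips = 0
    while len(st.cells[cell_id]) > 3:
        cyc = st.cells[cell_id]
        m = len(cyc)
        lengths = []
        for k in range(m):
            a, b = cyc[k], cyc[(k + 1) % m]
            d = minimum_image(st.vertices[b] - st.vertices[a], st.box)
            lengths.append((float(np.hypot(*d)), a, b))
        lengths.sort()
        flipped = False
        for _, a, b in lengths:
            try:
                t1_flip(st, a, b, edge_post_length, inplace=True)
                collapse_flips += 1
                flipped = True
                break
            except TopologyError:
                continue
        if not flipped:
            raise TopologyError(
                f"cell {cell_id} cannot be retracted without breaking trivalence"
            )

    v1, v2, v3 = st.cells[cell_id]
    centroid = st.cell_centroid(cell_id) % st.box.lengths
    neighbors = []
    for a, b in ((v1, v2), (v2, v3), (v3, v1)):
        hit = _cells_with_directed_edge(st, b, a)  # neighbor traverses b -> a
        if len(hit) != 1:
            raise TopologyError("triangle edge not shared with a unique neighbor")
        neighbors.append(hit[0][0])
    if len(set(neighbors)) != 3:
        raise TopologyError("triangle collapse would create a two-sided cell")
    if any(len(st.cells[c]) <= 3 for c in neighbors):
        raise TopologyError("triangle collapse would reduce a neighbor to a digon")

    new_v = len(st.vertices)
    st.vertices = np.vstack([st.vertices, centroid])
    tri = {v1, v2, v3}
    for c in neighbors:
        cyc = st.cells[c]
        kept = []
        inserted = False
        for v in cyc:
            if v in tri:
                if not inserted:
                    kept.append(new_v)
                    inserted = True
            else:
                kept.append(v)
        st.cells[c] = kept
    st.cells[cell_id] = []
    st.alive[cell_id] = False
    st.invalidate_topology()
    info = {"cell": int(cell_id), "collapse_flips": collapse_flips, "vertex": new_v}
    return st, info
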