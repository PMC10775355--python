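"""Geometry, topology, and the T1/T2 elementary moves."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import vertexclosure as vc
from vertexclosure.tissue import _unwrap_cycle

from conftest import P_HEX, build_brick_wall


class TestConstruction:
    def test_voronoi_euler_counts(self):
        box = vc.Box(np.sqrt(800.0), np.sqrt(200.0))  # 2:1 aspect
        state = vc.build_voronoi_tissue(400, box, seed=7)
        assert state.n_cells_alive == 400
        assert state.n_vertices == 800  # F = V/2 on the trivalent torus
        assert state.n_junctions == 1200  # E = 3V/2
        vc.validate_state(state)

    def test_voronoi_deterministic(self):
        box = vc.Box(6.0, 6.0)
        a = vc.build_voronoi_tissue(36, box, seed=5)
        b = vc.build_voronoi_tissue(36, box, seed=5)
        np.testing.assert_array_equal(a.vertices, b.vertices)
        assert a.cells == b.cells

    def test_minimum_cell_count_enforced(self):
        with pytest.raises(ValueError):
            vc.build_voronoi_tissue(1, vc.Box(1.0, 1.0), seed=0)
        with pytest.raises(ValueError):
            vc.build_voronoi_tissue(2, vc.Box(1.0, 1.0), seed=0)

    def test_hexagonal_lattice_geometry(self, hex44):
        areas, perims = vc.cell_geometry(hex44)
        np.testing.assert_allclose(areas, 1.0, rtol=1e-12)
        np.testing.assert_allclose(perims, P_HEX, rtol=1e-12)
        assert P_HEX == pytest.approx(3.7224, abs=1e-4)


class TestGeometry:
    def test_unit_square_cells(self):
        state = build_brick_wall(2, 4, w=1.0, h=1.0)
        vc.validate_state(state, check_simple=True)
        areas, perims = vc.cell_geometry(state)
        np.testing.assert_allclose(areas, 1.0, atol=1e-12)
        np.testing.assert_allclose(perims, 4.0, atol=1e-12)

    def test_translation_invariance(self, voronoi32):
        st = voronoi32.copy()
        a0, p0 = vc.cell_geometry(st)
        st.vertices = (st.vertices + [0.37 * st.box.lx, 0.71 * st.box.ly]) % [
            st.box.lx, st.box.ly,
        ]
        st.invalidate_topology()
        a1, p1 = vc.cell_geometry(st)
        np.testing.assert_allclose(a1, a0, rtol=1e-9)
        np.testing.assert_allclose(p1, p0, rtol=1e-9)

    def test_area_sums_to_box(self, voronoi32):
        areas, _ = vc.cell_geometry(voronoi32)
        assert np.nansum(areas) == pytest.approx(voronoi32.box.area, rel=1e-12)

    @pytest.mark.parametrize(
        "area,perim,expected",
        [(1.0, 4.0, 4.0), (1.0, P_HEX, P_HEX), (4.0, 8.0, 4.0)],
    )
    def test_shape_index_values(self, area, perim, expected):
        assert vc.shape_index(area, perim) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(0.1, 10.0), st.floats(0.5, 20.0), st.floats(0.1, 5.0))
    def test_shape_index_scale_invariant(self, area, perim, scale):
        q0 = vc.shape_index(area, perim)
        q1 = vc.shape_index(area * scale**2, perim * scale)
        assert q1 == pytest.approx(q0, rel=1e-9)

    def test_shape_index_rejects_nonpositive_area(self):
        with pytest.raises(vc.GeometryError):
            vc.shape_index(0.0, 1.0)


class TestSnapshots:
    def test_json_roundtrip_lossless(self, voronoi32):
        text = voronoi32.to_json()
        back = vc.TissueState.from_json(text)
        np.testing.assert_array_equal(back.vertices, voronoi32.vertices)
        assert back.cells == voronoi32.cells
        np.testing.assert_array_equal(back.p0, voronoi32.p0)
        assert back.a0 == voronoi32.a0
        assert back.box == voronoi32.box

    def test_unknown_schema_rejected(self):
        with pytest.raises(ValueError):
            vc.TissueState.from_json('{"schema": "bogus"}')


def _neighbor_sets(state):
    """cell -> set of edge-adjacent cells."""
    out = {ci: set() for ci in range(len(state.cells)) if state.alive[ci]}
    for j in vc.junction_list(state):
        out[j.cell_i].add(j.cell_j)
        out[j.cell_j].add(j.cell_i)
    return out


class TestT1:
    def _pick_edge(self, state):
        for j in vc.junction_list(state):
            thirds = set()
            for ci, cyc in enumerate(state.cells):
                if state.alive[ci] and (j.v_a in cyc) != (j.v_b in cyc):
                    thirds.add(ci)
            if (
                len(thirds) == 2
                and len(state.cells[j.cell_i]) > 3
                and len(state.cells[j.cell_j]) > 3
            ):
                return j
        raise AssertionError("no flippable edge found")

    def test_flip_exchanges_neighbors(self, voronoi32):
        j = self._pick_edge(voronoi32)
        before = _neighbor_sets(voronoi32)
        flipped = vc.t1_flip(voronoi32, j.v_a, j.v_b, post_length=0.05)
        vc.validate_state(flipped)
        after = _neighbor_sets(flipped)
        assert j.cell_j in before[j.cell_i]
        assert j.cell_j not in after[j.cell_i]

    def test_flip_is_adjacency_involution(self, voronoi32):
        j = self._pick_edge(voronoi32)
        before = _neighbor_sets(voronoi32)
        once = vc.t1_flip(voronoi32, j.v_a, j.v_b, post_length=0.05)
        twice = vc.t1_flip(once, j.v_a, j.v_b, post_length=0.05)
        vc.validate_state(twice)
        assert _neighbor_sets(twice) == before

    def test_flip_conserves_area_and_euler(self, voronoi32):
        j = self._pick_edge(voronoi32)
        flipped = vc.t1_flip(voronoi32, j.v_a, j.v_b, post_length=0.05)
        areas, _ = vc.cell_geometry(flipped)
        assert np.nansum(areas) == pytest.approx(flipped.box.area, rel=1e-9)
        vc.validate_state(flipped)  # includes V - E + F = 0 and degree 3

    def test_flip_rejects_two_sided_cell(self):
        # on a 2x2 honeycomb torus the two off-edge cells coincide
        state = vc.build_hexagonal_tissue(2, 2)
        j = vc.junction_list(state)[0]
        with pytest.raises(vc.TopologyError):
            vc.t1_flip(state, j.v_a, j.v_b, post_length=0.05)

    def test_flip_rejects_nonexistent_edge(self, voronoi32):
        with pytest.raises(vc.TopologyError):
            vc.t1_flip(voronoi32, 0, 0, post_length=0.05)


class TestT2:
    def test_removal_updates_counts(self, voronoi32):
        v_before = voronoi32.n_vertices
        removed, info = vc.t2_remove_cell(voronoi32, 4)
        vc.validate_state(removed)
        assert removed.n_cells_alive == voronoi32.n_cells_alive - 1
        # V = 2F on the trivalent torus, for the active vertex set
        assert removed.n_vertices == 2 * removed.n_cells_alive
        assert removed.n_vertices < v_before
        assert info["cell"] == 4

    def test_removal_conserves_area(self, voronoi32):
        removed, _ = vc.t2_remove_cell(voronoi32, 7)
        areas, _ = vc.cell_geometry(removed)
        assert np.nansum(areas) == pytest.approx(removed.box.area, rel=1e-9)

    def test_removing_dead_cell_errors(self, voronoi32):
        removed, _ = vc.t2_remove_cell(voronoi32, 3)
        with pytest.raises(vc.TopologyError):
            vc.t2_remove_cell(removed, 3)

    def test_tiny_tiling_removal_errors(self):
        state = vc.build_hexagonal_tissue(2, 2)  # placeholder small torus
        state.alive[:] = [True, True, True, False]
        state.cells[3] = []
        state.invalidate_topology()
        with pytest.raises(vc.TopologyError):
            vc.t2_remove_cell(state, 0)


def test_unwrap_cycle_handles_boundary_cells(voronoi32):
    # every cell, wrapped or not, unwraps into a closed polygon
    for ci in range(len(voronoi32.cells)):
        poly = _unwrap_cycle(voronoi32.vertices[voronoi32.cells[ci]], voronoi32.box)
        gap = poly[0] - (
            poly[-1]
            + vc.tissue.minimum_image(
                voronoi32.vertices[voronoi32.cells[ci][0]]
                - voronoi32.vertices[voronoi32.cells[ci][-1]],
                voronoi32.box,
            )
        )
        assert np.abs(gap).max() < 1e-9
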