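"""Shared fixtures: small reference tilings and energy parameters."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vertexclosure as vc

settings.register_profile(
    "package",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")

#: perimeter of the unit-area regular hexagon, q_hex = 2 sqrt(6) / 3^(3/4)
P_HEX = 6.0 * np.sqrt(2.0 / (3.0 * np.sqrt(3.0)))


@pytest.fixture(scope="session")
def params():
    return vc.EnergyParams()


@pytest.fixture()
def hex44():
    return vc.build_hexagonal_tissue(4, 4)


@pytest.fixture(scope="session")
def voronoi32():
    box = vc.Box(np.sqrt(32.0), np.sqrt(32.0))
    return vc.build_voronoi_tissue(32, box, seed=11)


def build_brick_wall(nx: int, ny: int, w: float = 1.0, h: float = 1.0):
    """Periodic running-bond brick tiling: rectangular cells, trivalent.

    Row j is offset by w/2 relative to row j-1, so every brick has six
    boundary vertices (four corners plus one T-junction on the top and
    bottom edges).  Requires even ny.
    """
    assert ny % 2 == 0
    lx, ly = nx * w, ny * h
    ids: dict[tuple[int, int], int] = {}
    coords: list[tuple[float, float]] = []

    def vid(ix: int, j: int) -> int:
        key = (ix % (2 * nx), j % ny)
        if key not in ids:
            ids[key] = len(coords)
            coords.append((key[0] * w / 2.0, key[1] * h))
        return ids[key]

    cells = []
    for j in range(ny):
        for i in range(nx):
            x0 = 2 * i + (j % 2)  # in units of w/2
            cells.append(
                [
                    vid(x0, j), vid(x0 + 1, j), vid(x0 + 2, j),
                    vid(x0 + 2, j + 1), vid(x0 + 1, j + 1), vid(x0, j + 1),
                ]
            )
    return vc.TissueState(
        vertices=np.asarray(coords, dtype=float),
        cells=cells,
        p0=np.full(nx * ny, 2.0 * (w + h)),
        a0=w * h,
        box=vc.Box(lx, ly),
    )


@pytest.fixture()
def brick_wall():
    return build_brick_wall
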