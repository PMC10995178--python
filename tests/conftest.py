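"""Shared fixtures: hand-built micro-tissues and cached simulation series."""

from __future__ import annotations

import numpy as np
import pytest

from organgrowth.core_model import CellPolygon, LineageMap, TissueSnapshot
from organgrowth.synthetic_tissue import scenario

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


def square_cell(label, x0, y0, size=1.0, **kw):
    verts = np.array(
        [[x0, y0], [x0 + size, y0], [x0 + size, y0 + size], [x0, y0 + size]]
    )
    return CellPolygon(label=label, vertices=verts, **kw)


@pytest.fixture
def grid_snapshot():
    """2x2 grid of unit-square cells (labels 1..4) with shared vertex ids."""
    # vertex ids on the 3x3 lattice: id = 3*j + i for (i, j)
    def vid(i, j):
        return 3 * j + i

    cells = {}
    for lab, (i, j) in enumerate([(0, 0), (1, 0), (0, 1), (1, 1)], start=1):
        verts = np.array(
            [[i, j], [i + 1, j], [i + 1, j + 1], [i, j + 1]], dtype=float
        )
        ids = (vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1))
        cells[lab] = CellPolygon(label=lab, vertices=verts, vertex_ids=ids)
    adjacency = {(1, 2), (1, 3), (2, 4), (3, 4)}
    return TissueSnapshot(time_dai=0.0, cells=cells, adjacency=adjacency)


@pytest.fixture
def chain_snapshot():
    """Five 10x10 µm cells in a row; centroids 10 µm apart."""
    cells = {
        k + 1: square_cell(k + 1, 10.0 * k, 0.0, size=10.0) for k in range(5)
    }
    adjacency = {(k, k + 1) for k in range(1, 5)}
    return TissueSnapshot(time_dai=0.0, cells=cells, adjacency=adjacency)


@pytest.fixture(scope="session")
def gyn_series():
    """Full gynoecium preset at acceptance scale (shared across the session;
    takes about a minute to simulate)."""
    return scenario("gynoecium", overrides={"n_cells": 500}, seed=1)


@pytest.fixture(scope="session")
def mini_series():
    """Small, fast gynoecium series for structural tests."""
    return scenario(
        "gynoecium", overrides={"n_cells": 60, "t_end": 8.0}, seed=3
    )


@pytest.fixture(scope="session")
def sepal_series():
    return scenario("sepal", seed=2)
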