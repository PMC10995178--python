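"""Forward model: advect the shared-vertex tessellation through the
prescribed growth field, divide, differentiate, and place stomata.

Every step returns, besides the new snapshot and lineage map, a ground-truth
table with the imposed per-parent area factor, principal stretches and
direction, obtained by integrating the velocity gradient along each cell's
centroid trajectory with the same sub-stepping as the vertex update.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from organgrowth.core_model import LineageMap, TissueSnapshot, shoelace_area
from organgrowth.synthetic_tissue.fields import GrowthFieldSpec
from organgrowth.synthetic_tissue.tessellation import Tissue

__all__ = ["step", "GROUND_TRUTH_COLUMNS"]

GROUND_TRUTH_COLUMNS = [
    "parent_label",
    "t0",
    "t1",
    "area_factor",
    "lambda_max",
    "lambda_min",
    "anisotropy",
    "direction_x",
    "direction_y",
    "n_daughters",
]

_FD_H = 1e-4  # µm, finite-difference step for the velocity gradient


def _advect(
    tissue: Tissue, spec: GrowthFieldSpec, dt: float, n_sub: int
) -> Tuple[Dict[int, np.ndarray], Dict[int, np.ndarray]]:
    """Integrate vertices and per-cell deformation gradients over ``dt``.

    The ground-truth deformation gradient of a cell integrates the
    *area-averaged* velocity gradient over the cell (area-weighted centroid
    quadrature on the triangle fan around the cell centroid, gradients by
    central differences of the velocity field), following the deforming
    cell. This is independent of the polygon update arithmetic while
    representing the imposed field at the scale of the whole cell.

    Returns (new vertex coordinates, per-cell 2x2 deformation gradient F).
    """
    vids = sorted(tissue.verts)
    pos = np.array([tissue.verts[v] for v in vids])
    vindex = {v: i for i, v in enumerate(vids)}
    labels = sorted(tissue.cells)
    cell_vidx = [np.array([vindex[v] for v in tissue.cells[lab]]) for lab in labels]
    cent = np.array([tissue.cell_centroid(lab) for lab in labels])
    F = np.tile(np.eye(2), (len(labels), 1, 1))

    h = _FD_H
    dt_s = dt / n_sub
    offsets = np.array([[h, 0.0], [-h, 0.0], [0.0, h], [0.0, -h]])

    # flat triangle-fan layout: per cell, triangles (centroid, v_i, v_i+1)
    tri_cell = np.concatenate(
        [np.full(len(vidx), i) for i, vidx in enumerate(cell_vidx)]
    )
    tri_a = np.concatenate(cell_vidx)
    tri_b = np.concatenate([np.roll(vidx, -1) for vidx in cell_vidx])

    def grad_at(points: np.ndarray, t: float) -> np.ndarray:
        m = len(points)
        probes = np.concatenate([points + off for off in offsets])
        vp = spec.velocity(probes, t)
        dvdx = (vp[:m] - vp[m : 2 * m]) / (2 * h)
        dvdy = (vp[2 * m : 3 * m] - vp[3 * m :]) / (2 * h)
        return np.stack([dvdx, dvdy], axis=2)  # [:, i, j] = dV_i/dx_j

    n = len(labels)
    for k in range(n_sub):
        t = tissue.time_dai + k * dt_s
        pa, pb, pc = pos[tri_a], pos[tri_b], cent[tri_cell]
        tri_centroids = (pa + pb + pc) / 3.0
        tri_areas = 0.5 * np.abs(
            (pa[:, 0] - pc[:, 0]) * (pb[:, 1] - pc[:, 1])
            - (pb[:, 0] - pc[:, 0]) * (pa[:, 1] - pc[:, 1])
        )
        L_tri = grad_at(tri_centroids, t)
        wsum = np.zeros(n)
        L_cell = np.zeros((n, 2, 2))
        np.add.at(wsum, tri_cell, tri_areas)
        np.add.at(L_cell, tri_cell, tri_areas[:, None, None] * L_tri)
        L_cell /= wsum[:, None, None]
        F = (np.tile(np.eye(2), (n, 1, 1)) + dt_s * L_cell) @ F
        cent = cent + dt_s * spec.velocity(cent, t)
        pos = pos + dt_s * spec.velocity(pos, t)

    new_verts = {v: pos[i] for i, v in enumerate(vids)}
    gt = {lab: F[i] for i, lab in enumerate(labels)}
    return new_verts, gt


def _polygon_moments(coords: np.ndarray) -> np.ndarray:
    """Central second-moment (covariance) matrix of a polygon's area."""
    x, y = coords[:, 0], coords[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    cx = ((x + xn) * cross).sum() / (6 * a)
    cy = ((y + yn) * cross).sum() / (6 * a)
    mxx = (cross * (x * x + x * xn + xn * xn)).sum() / 12.0
    myy = (cross * (y * y + y * yn + yn * yn)).sum() / 12.0
    mxy = (cross * (x * yn + 2 * x * y + 2 * xn * yn + xn * y)).sum() / 24.0
    return np.array([[mxx / a - cx * cx, mxy / a - cx * cy], [mxy / a - cx * cy, myy / a - cy * cy]])


def _division_direction(coords: np.ndarray) -> np.ndarray:
    """Wall direction: perpendicular to the longest principal axis.

    Near-isotropic cells (tie) get a wall along the x-axis.
    """
    cov = _polygon_moments(coords)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] - evals[0] < 1e-9 * max(evals[1], 1e-12):
        return np.array([1.0, 0.0])
    longest = evecs[:, 1]
    wall = np.array([-longest[1], longest[0]])
    if wall[0] < 0 or (wall[0] == 0 and wall[1] < 0):
        wall = -wall
    return wall


def _insert_on_edge(
    tissue: Tissue, aid: int, bid: int, vid: int, edge_cells: Dict[Tuple[int, int], List[int]]
) -> None:
    """Insert ``vid`` between ``aid`` and ``bid`` in every cell using that edge."""
    for lab in edge_cells.get(tuple(sorted((aid, bid))), []):
        cyc = tissue.cells[lab]
        n = len(cyc)
        for i in range(n):
            u, w = cyc[i], cyc[(i + 1) % n]
            if {u, w} == {aid, bid}:
                tissue.cells[lab] = cyc[: i + 1] + [vid] + cyc[i + 1 :]
                break


def split_cell(tissue: Tissue, label: int) -> Optional[Tuple[int, int]]:
    """Split a cell by the shortest wall through its centroid perpendicular
    to its longest axis. Returns the two fresh daughter labels, or ``None``
    when no valid chord exists (degenerate geometry)."""
    coords = tissue.cell_coords(label)
    centroid = tissue.cell_centroid(label)
    wall = _division_direction(coords)

    cyc = tissue.cells[label]
    n = len(cyc)
    hits: List[Tuple[float, int, float]] = []  # (t along wall, edge index, s on edge)
    for i in range(n):
        a = tissue.verts[cyc[i]]
        b = tissue.verts[cyc[(i + 1) % n]]
        e = b - a
        denom = wall[0] * (-e[1]) - wall[1] * (-e[0])
        if abs(denom) < 1e-14:
            continue
        rhs = a - centroid
        t = (rhs[0] * (-e[1]) - rhs[1] * (-e[0])) / denom
        s = (wall[0] * rhs[1] - wall[1] * rhs[0]) / denom
        if -1e-12 <= s < 1.0 - 1e-12:
            hits.append((t, i, s))
    neg = [h for h in hits if h[0] < 0]
    pos = [h for h in hits if h[0] >= 0]
    if not neg or not pos:
        return None
    h1 = max(neg, key=lambda h: h[0])
    h2 = min(pos, key=lambda h: h[0])

    edge_cells = tissue.edge_map()
    cut_vids: List[int] = []
    # insert the later-indexed hit first so edge indices stay valid
    for t, i, s in sorted([h1, h2], key=lambda h: -h[1]):
        cyc = tissue.cells[label]
        n = len(cyc)
        aid, bid = cyc[i], cyc[(i + 1) % n]
        a, b = tissue.verts[aid], tissue.verts[bid]
        if s < 1e-9:
            cut_vids.append(aid)
            continue
        p = a + s * (b - a)
        vid = tissue.next_vid
        tissue.next_vid += 1
        tissue.verts[vid] = p
        _insert_on_edge(tissue, aid, bid, vid, edge_cells)
        cut_vids.append(vid)

    v1, v2 = cut_vids[-1], cut_vids[0]  # order back to (h1, h2)
    cyc = tissue.cells[label]
    i1, i2 = cyc.index(v1), cyc.index(v2)
    if i1 == i2:
        return None
    if i1 < i2:
        cyc_a = cyc[i1 : i2 + 1]
        cyc_b = cyc[i2:] + cyc[: i1 + 1]
    else:
        cyc_a = cyc[i1:] + cyc[: i2 + 1]
        cyc_b = cyc[i2 : i1 + 1]
    if len(cyc_a) < 3 or len(cyc_b) < 3:
        return None
    area_a = shoelace_area(np.array([tissue.verts[v] for v in cyc_a]))
    area_b = shoelace_area(np.array([tissue.verts[v] for v in cyc_b]))
    if area_a <= 0 or area_b <= 0:
        return None

    la, lb = tissue.next_label, tissue.next_label + 1
    tissue.next_label += 2
    region = tissue.regions.pop(label, "none")
    state = tissue.states.pop(label, "proliferative")
    del tissue.cells[label]
    for lab, c in ((la, cyc_a), (lb, cyc_b)):
        tissue.cells[lab] = c
        tissue.regions[lab] = region
        tissue.states[lab] = state
    return la, lb


def step(
    snapshot: TissueSnapshot,
    spec: GrowthFieldSpec,
    dt: float,
    seed: int,
) -> Tuple[TissueSnapshot, LineageMap, pd.DataFrame]:
    """Advance the tissue by ``dt`` days.

    Growth displaces shared vertices through the integrated field; cells
    above the division threshold (and still proliferative) are split; cells
    whose local differentiation-onset time has passed switch state; stomata
    appear stochastically among differentiated cells with one-cell spacing.

    Returns ``(snapshot_t1, lineage, ground_truth)`` where ``ground_truth``
    has one row per t0 cell (see :data:`GROUND_TRUTH_COLUMNS`).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t0, t1 = snapshot.time_dai, snapshot.time_dai + dt
    rng = np.random.default_rng(seed)

    n_sub = spec.n_substeps
    for attempt in range(3):
        tissue = Tissue.from_snapshot(snapshot)
        # keep edges at or below ~one cell diameter so straight polygon
        # edges track the (curved) integrated deformation faithfully
        areas = [tissue.cell_area(lab) for lab in sorted(tissue.cells)]
        tissue.refine_edges(1.2 * float(np.sqrt(np.median(areas))))
        new_verts, gt_F = _advect(tissue, spec, dt, n_sub * (2**attempt))
        tissue.verts = new_verts
        bad = [
            lab
            for lab in sorted(tissue.cells)
            if not Polygon(tissue.cell_coords(lab)).is_valid
        ]
        if not bad:
            break
    else:
        raise RuntimeError(
            f"vertex displacement produced self-intersecting polygons {bad} "
            f"even with {n_sub * 4} sub-steps"
        )
    tissue.time_dai = t1

    # differentiation: positional onset time, evaluated at current centroids
    if spec.differentiation_onset is not None:
        labels = sorted(tissue.cells)
        cents = np.array([tissue.cell_centroid(lab) for lab in labels])
        tau = np.asarray(spec.differentiation_onset(cents), dtype=float)
        if np.any(tau < 0):
            raise ValueError("differentiation onset times must be >= 0")
        for lab, tv in zip(labels, tau):
            if t1 >= tv and tissue.states[lab] == "proliferative":
                tissue.states[lab] = "differentiated"

    # division
    parent_links: Dict[int, int] = {}  # child -> parent at t0
    queue = sorted(tissue.cells)
    while queue:
        lab = queue.pop(0)
        if tissue.states.get(lab) != "proliferative":
            continue
        if tissue.cell_area(lab) <= spec.division_area_threshold:
            continue
        result = split_cell(tissue, lab)
        if result is None:
            continue
        la, lb = result
        origin = parent_links.pop(lab, lab)
        parent_links[la] = origin
        parent_links[lb] = origin
        queue.extend([la, lb])

    # stomata among differentiated cells, minimum spacing one cell
    if spec.stomata_rate > 0:
        adj = tissue.adjacency()
        neigh: Dict[int, set] = {lab: set() for lab in tissue.cells}
        for a, b in adj:
            neigh[a].add(b)
            neigh[b].add(a)
        p = min(1.0, spec.stomata_rate * dt)
        for lab in sorted(tissue.cells):
            if tissue.states[lab] != "differentiated":
                continue
            if any(tissue.states[m] == "stoma" for m in neigh[lab]):
                continue
            if rng.random() < p:
                tissue.states[lab] = "stoma"

    out = tissue.to_snapshot()
    parent_of = {lab: parent_links.get(lab, lab) for lab in sorted(tissue.cells)}
    lineage = LineageMap(t0=t0, t1=t1, parent_of=parent_of)

    rows = []
    daughters_per_parent: Dict[int, int] = {}
    for child, par in parent_of.items():
        daughters_per_parent[par] = daughters_per_parent.get(par, 0) + 1
    for lab in sorted(snapshot.cells):
        F = gt_F[lab]
        U, S, Vt = np.linalg.svd(F)
        d = U[:, 0]
        if d[0] < 0 or (d[0] == 0 and d[1] < 0):
            d = -d
        rows.append(
            {
                "parent_label": lab,
                "t0": t0,
                "t1": t1,
                "area_factor": float(np.linalg.det(F)),
                "lambda_max": float(S[0]),
                "lambda_min": float(S[1]),
                "anisotropy": float(S[0] / S[1]),
                "direction_x": float(d[0]),
                "direction_y": float(d[1]),
                "n_daughters": daughters_per_parent.get(lab, 0),
            }
        )
    ground_truth = pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)
    return out, lineage, ground_truth
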