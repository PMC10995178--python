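"""Initial cell tessellations and the shared-vertex tissue representation.

Cells are stored as counterclockwise cycles of vertex ids into a common
vertex pool, so that neighbouring cells reference *identical* vertices.
Growth displaces vertices (never individual cell copies), which keeps the
tessellation gap-free and provides exact junction correspondence through
time for downstream growth-tensor estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import voronoi_diagram

from organgrowth.core_model import CellPolygon, TissueSnapshot, shoelace_area

__all__ = ["Tissue", "make_initial_tissue", "lloyd_tessellation"]

# vertex dedup grid (µm); well below any cell edge length we generate
_SNAP = 1e-7


def _key(p: np.ndarray) -> Tuple[int, int]:
    return (int(round(p[0] / _SNAP)), int(round(p[1] / _SNAP)))


@dataclass
class Tissue:
    """Mutable shared-vertex tessellation used by the simulator.

    ``cells`` maps label → counterclockwise list of vertex ids;
    ``verts`` maps vertex id → (2,) coordinate array (µm).
    """

    time_dai: float
    verts: Dict[int, np.ndarray]
    cells: Dict[int, List[int]]
    regions: Dict[int, str]
    states: Dict[int, str]
    next_vid: int = 0
    next_label: int = 0

    def __post_init__(self) -> None:
        if self.next_vid == 0 and self.verts:
            self.next_vid = max(self.verts) + 1
        if self.next_label == 0 and self.cells:
            self.next_label = max(self.cells) + 1

    # -- geometry -----------------------------------------------------------

    def cell_coords(self, label: int) -> np.ndarray:
        return np.array([self.verts[v] for v in self.cells[label]])

    def cell_area(self, label: int) -> float:
        return shoelace_area(self.cell_coords(label))

    def cell_centroid(self, label: int) -> np.ndarray:
        v = self.cell_coords(label)
        x, y = v[:, 0], v[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = 0.5 * cross.sum()
        return np.array(
            [((x + xn) * cross).sum() / (6 * a), ((y + yn) * cross).sum() / (6 * a)]
        )

    def total_area(self) -> float:
        return sum(self.cell_area(lab) for lab in self.cells)

    # -- topology -----------------------------------------------------------

    def edge_map(self) -> Dict[Tuple[int, int], List[int]]:
        """Map of undirected vertex-id edge → labels of cells using it."""
        edges: Dict[Tuple[int, int], List[int]] = {}
        for lab in sorted(self.cells):
            cyc = self.cells[lab]
            for i in range(len(cyc)):
                e = tuple(sorted((cyc[i], cyc[(i + 1) % len(cyc)])))
                edges.setdefault(e, []).append(lab)
        return edges

    def adjacency(self) -> Set[Tuple[int, int]]:
        adj: Set[Tuple[int, int]] = set()
        for labs in self.edge_map().values():
            if len(labs) == 2:
                adj.add(tuple(sorted(labs)))
        return adj

    def neighbors(self, label: int) -> Set[int]:
        out: Set[int] = set()
        for a, b in self.adjacency():
            if a == label:
                out.add(b)
            elif b == label:
                out.add(a)
        return out

    def refine_edges(self, max_length: float) -> int:
        """Insert midpoint vertices on every edge longer than ``max_length``.

        Keeps the polygonal boundary fine enough to follow spatially curved
        deformation; inserted vertices are shared by both incident cells.
        Returns the number of vertices added.
        """
        added = 0
        changed = True
        while changed:
            changed = False
            for edge, labs in sorted(self.edge_map().items()):
                a, b = edge
                pa, pb = self.verts[a], self.verts[b]
                if float(np.hypot(*(pb - pa))) <= max_length:
                    continue
                mid = 0.5 * (pa + pb)
                vid = self.next_vid
                self.next_vid += 1
                self.verts[vid] = mid
                for lab in labs:
                    cyc = self.cells[lab]
                    n = len(cyc)
                    for i in range(n):
                        if {cyc[i], cyc[(i + 1) % n]} == {a, b}:
                            self.cells[lab] = cyc[: i + 1] + [vid] + cyc[i + 1 :]
                            break
                added += 1
                changed = True
        return added

    # -- conversion ---------------------------------------------------------

    def to_snapshot(self) -> TissueSnapshot:
        cells = {
            lab: CellPolygon(
                label=lab,
                vertices=self.cell_coords(lab),
                region=self.regions.get(lab, "none"),
                state=self.states.get(lab, "proliferative"),
                vertex_ids=tuple(self.cells[lab]),
            )
            for lab in sorted(self.cells)
        }
        return TissueSnapshot(time_dai=self.time_dai, cells=cells, adjacency=self.adjacency())

    @classmethod
    def from_snapshot(cls, snapshot: TissueSnapshot) -> "Tissue":
        """Rebuild the shared-vertex representation from a snapshot.

        Uses ``vertex_ids`` when present; otherwise vertices are deduplicated
        by coordinate snapping.
        """
        verts: Dict[int, np.ndarray] = {}
        cells: Dict[int, List[int]] = {}
        if all(c.vertex_ids is not None for c in snapshot.cells.values()):
            for lab in sorted(snapshot.cells):
                c = snapshot.cells[lab]
                cells[lab] = list(c.vertex_ids)  # type: ignore[arg-type]
                for vid, xy in zip(c.vertex_ids, c.vertices):  # type: ignore[arg-type]
                    verts[vid] = np.asarray(xy, dtype=float)
        else:
            lookup: Dict[Tuple[int, int], int] = {}
            nxt = 0
            for lab in sorted(snapshot.cells):
                c = snapshot.cells[lab]
                cyc = []
                for xy in c.vertices:
                    k = _key(xy)
                    if k not in lookup:
                        lookup[k] = nxt
                        verts[nxt] = np.asarray(xy, dtype=float)
                        nxt += 1
                    cyc.append(lookup[k])
                cells[lab] = cyc
        return cls(
            time_dai=snapshot.time_dai,
            verts=verts,
            cells=cells,
            regions={lab: c.region for lab, c in snapshot.cells.items()},
            states={lab: c.state for lab, c in snapshot.cells.items()},
        )


def _as_polygon(domain) -> Polygon:
    if isinstance(domain, Polygon):
        poly = domain
    else:
        poly = Polygon(np.asarray(domain, dtype=float))
    if (not poly.is_valid) or poly.area <= 0:
        raise ValueError("domain must be a simple polygon with positive area")
    return poly


def lloyd_tessellation(
    n_cells: int, domain: Polygon, rng: np.random.Generator, n_iter: int = 40
) -> List[Polygon]:
    """Centroidally relaxed Voronoi tessellation clipped to ``domain``.

    Returns one shapely polygon per generator point, in generator order.
    """
    minx, miny, maxx, maxy = domain.bounds
    pts: List[np.ndarray] = []
    while len(pts) < n_cells:
        p = rng.uniform([minx, miny], [maxx, maxy])
        if domain.contains(MultiPoint([p]).geoms[0]):
            pts.append(p)
    points = np.array(pts)

    cells: List[Polygon] = []
    for _ in range(n_iter):
        cells = _clipped_voronoi(points, domain)
        points = np.array([np.asarray(c.centroid.coords[0]) for c in cells])
    return _clipped_voronoi(points, domain)


def _clipped_voronoi(points: np.ndarray, domain: Polygon) -> List[Polygon]:
    vd = voronoi_diagram(MultiPoint(points), envelope=domain.buffer(1.0))
    regions = list(vd.geoms)
    # match regions back to their generating points
    out: List[Optional[Polygon]] = [None] * len(points)
    from shapely.geometry import Point

    for reg in regions:
        for i, p in enumerate(points):
            if out[i] is None and reg.contains(Point(p)):
                out[i] = reg
                break
    for i, reg in enumerate(out):
        if reg is None:  # point on a region boundary; nearest region fallback
            p = Point(points[i])
            out[i] = min(regions, key=lambda r: r.distance(p))
        clipped = out[i].intersection(domain)  # type: ignore[union-attr]
        if clipped.geom_type == "MultiPolygon":
            clipped = max(clipped.geoms, key=lambda g: g.area)
        out[i] = clipped
    return out  # type: ignore[return-value]


def make_initial_tissue(
    n_cells: int,
    domain,
    seed: int,
    region_map=None,
    time_dai: float = 0.0,
) -> TissueSnapshot:
    """Generate an initial tissue as a relaxed Voronoi tessellation.

    Parameters
    ----------
    n_cells
        Number of cells (≥ 4).
    domain
        Organ outline: a shapely polygon or an ``(n, 2)`` coordinate array.
    seed
        Seed for the generator-point sampling; identical seeds give
        byte-identical snapshots.
    region_map
        Optional callable ``(x, y) -> region tag`` evaluated at each cell
        centroid.
    """
    if n_cells < 4:
        raise ValueError(f"n_cells must be >= 4, got {n_cells}")
    poly = _as_polygon(domain)
    rng = np.random.default_rng(seed)
    cell_polys = lloyd_tessellation(n_cells, poly, rng)

    verts: Dict[int, np.ndarray] = {}
    lookup: Dict[Tuple[int, int], int] = {}
    cells: Dict[int, List[int]] = {}
    nxt = 0
    for i, cp in enumerate(cell_polys):
        coords = np.array(cp.exterior.coords[:-1])
        if shoelace_area(coords) < 0:
            coords = coords[::-1]
        cyc: List[int] = []
        for xy in coords:
            k = _key(xy)
            if k not in lookup:
                lookup[k] = nxt
                verts[nxt] = np.asarray(xy, dtype=float)
                nxt += 1
            if not cyc or cyc[-1] != lookup[k]:
                cyc.append(lookup[k])
        if cyc[0] == cyc[-1]:
            cyc.pop()
        cells[i + 1] = cyc

    # T-junction repair: insert vertices lying on a neighbour's edge interior
    _insert_collinear_vertices(verts, cells)

    tissue = Tissue(
        time_dai=time_dai,
        verts=verts,
        cells=cells,
        regions={},
        states={lab: "proliferative" for lab in cells},
    )
    for lab in sorted(cells):
        cx, cy = tissue.cell_centroid(lab)
        tissue.regions[lab] = region_map(cx, cy) if region_map is not None else "none"
    return tissue.to_snapshot()


def _insert_collinear_vertices(
    verts: Dict[int, np.ndarray], cells: Dict[int, List[int]], tol: float = 1e-9
) -> None:
    """Ensure every vertex lying on a cell edge appears in that cell's cycle.

    Clipping can leave a vertex of one cell in the interior of a neighbour's
    edge; downstream edge-pair adjacency requires both cells to list it.
    """
    vids = sorted(verts)
    coords = np.array([verts[v] for v in vids])
    for lab in sorted(cells):
        changed = True
        while changed:
            changed = False
            cyc = cells[lab]
            n = len(cyc)
            for i in range(n):
                a, b = verts[cyc[i]], verts[cyc[(i + 1) % n]]
                ab = b - a
                L2 = float(ab @ ab)
                if L2 == 0:
                    continue
                t = ((coords - a) @ ab) / L2
                d = np.linalg.norm(coords - (a + np.clip(t, 0, 1)[:, None] * ab), axis=1)
                on = (d < tol) & (t > 1e-9) & (t < 1 - 1e-9)
                hit = [
                    (t[j], vids[j])
                    for j in np.nonzero(on)[0]
                    if vids[j] not in cyc
                ]
                if hit:
                    hit.sort()
                    cells[lab] = cyc[: i + 1] + [v for _, v in hit] + cyc[i + 1 :]
                    changed = True
                    break
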