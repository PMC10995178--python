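"""Core domain types for tissue time-series analysis.

The pipeline operates on 2D planar-projected cell outlines of one epidermal
surface. Units are fixed throughout: coordinates in micrometres (µm), areas
in µm², time in days; percentages are on the 0–100 scale.

The central objects are

* :class:`CellPolygon` — one labeled cell footprint with region/state tags,
* :class:`TissueSnapshot` — all cells at one time point plus cell adjacency,
* :class:`LineageMap` — the child→parent relation between two time points,
* :class:`GrowthRecord` — per-lineage interval growth quantities,
* :class:`DistanceField` / :class:`GradientProfile` — derived read-outs.

Validation of a whole series (snapshots + lineage maps) is performed by
:func:`validate_series`, which produces a :class:`ValidationReport` rather
than raising, so that quality-control issues (e.g. cells leaving the imaged
region) can be surfaced without aborting an analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "REGIONS",
    "STATES",
    "CellPolygon",
    "TissueSnapshot",
    "LineageMap",
    "GrowthRecord",
    "DistanceField",
    "GradientProfile",
    "ValidationIssue",
    "ValidationReport",
    "validate_series",
    "shoelace_area",
]

REGIONS = frozenset({"style", "valve", "replum", "medial", "base", "none"})
STATES = frozenset({"proliferative", "differentiated", "stoma"})


def shoelace_area(vertices: np.ndarray) -> float:
    """Signed polygon area (positive for counterclockwise vertex order)."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass(frozen=True)
class CellPolygon:
    """One labeled epidermal cell footprint.

    Parameters
    ----------
    label
        Positive integer cell label, unique within a snapshot.
    vertices
        ``(n, 2)`` array of outline coordinates in µm, counterclockwise,
        forming a simple polygon with at least 3 vertices.
    region
        One of ``{"style", "valve", "replum", "medial", "base", "none"}``.
    state
        One of ``{"proliferative", "differentiated", "stoma"}``.
    vertex_ids
        Optional persistent junction identifiers, one per vertex. When both
        snapshots of an interval carry them, they provide the junction
        correspondence used for growth-tensor estimation.
    """

    label: int
    vertices: np.ndarray
    region: str = "none"
    state: str = "proliferative"
    vertex_ids: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise ValueError(
                f"cell {self.label}: vertices must be an (n>=3, 2) array, "
                f"got shape {verts.shape}"
            )
        if int(self.label) <= 0:
            raise ValueError(f"cell label must be positive, got {self.label}")
        if self.region not in REGIONS:
            raise ValueError(f"cell {self.label}: unknown region {self.region!r}")
        if self.state not in STATES:
            raise ValueError(f"cell {self.label}: unknown state {self.state!r}")
        if shoelace_area(verts) <= 0:
            raise ValueError(
                f"cell {self.label}: vertices must be counterclockwise with "
                "positive area"
            )
        if self.vertex_ids is not None and len(self.vertex_ids) != len(verts):
            raise ValueError(
                f"cell {self.label}: vertex_ids length {len(self.vertex_ids)} "
                f"!= vertex count {len(verts)}"
            )
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "label", int(self.label))
        if self.vertex_ids is not None:
            object.__setattr__(self, "vertex_ids", tuple(int(i) for i in self.vertex_ids))

    @property
    def area(self) -> float:
        """Polygon area in µm² (shoelace formula)."""
        return shoelace_area(self.vertices)

    @property
    def centroid(self) -> np.ndarray:
        """Area centroid in µm."""
        v = self.vertices
        x, y = v[:, 0], v[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = 0.5 * cross.sum()
        cx = ((x + xn) * cross).sum() / (6.0 * a)
        cy = ((y + yn) * cross).sum() / (6.0 * a)
        return np.array([cx, cy])

    def to_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    def is_simple(self) -> bool:
        return self.to_shapely().is_valid


@dataclass
class TissueSnapshot:
    """All cells of one imaged surface at one time point.

    ``adjacency`` holds unordered label pairs of cells sharing a boundary
    segment; it is stored as a set of sorted 2-tuples.
    """

    time_dai: float
    cells: Dict[int, CellPolygon]
    adjacency: Set[Tuple[int, int]] = field(default_factory=set)
    warnings: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cells = {int(lab): c for lab, c in self.cells.items()}
        for lab, c in self.cells.items():
            if lab != c.label:
                raise ValueError(f"cell dict key {lab} != cell label {c.label}")
        self.adjacency = {tuple(sorted((int(a), int(b)))) for a, b in self.adjacency}
        for a, b in self.adjacency:
            if a not in self.cells or b not in self.cells:
                raise ValueError(f"adjacency pair ({a}, {b}) references unknown label")
            if a == b:
                raise ValueError(f"self-adjacency for label {a}")

    @property
    def labels(self) -> List[int]:
        return sorted(self.cells)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def total_area(self) -> float:
        return sum(c.area for c in self.cells.values())

    def graph(self) -> nx.Graph:
        """Cell adjacency graph with centroid positions as node attributes."""
        g = nx.Graph()
        for lab, c in sorted(self.cells.items()):
            g.add_node(lab, centroid=c.centroid, region=c.region, state=c.state)
        for a, b in sorted(self.adjacency):
            ca = self.cells[a].centroid
            cb = self.cells[b].centroid
            g.add_edge(a, b, weight=float(np.hypot(*(ca - cb))))
        return g

    def region_labels(self, region: str) -> List[int]:
        return sorted(lab for lab, c in self.cells.items() if c.region == region)

    def check_region_connectivity(self) -> List[str]:
        """Record a warning for every present region tag whose induced
        adjacency subgraph is disconnected."""
        g = self.graph()
        notes: List[str] = []
        for region in sorted({c.region for c in self.cells.values()}):
            labs = self.region_labels(region)
            if len(labs) < 2:
                continue
            sub = g.subgraph(labs)
            if not nx.is_connected(sub):
                msg = (
                    f"region {region!r} adjacency subgraph is disconnected "
                    f"({nx.number_connected_components(sub)} components) "
                    f"at t={self.time_dai}"
                )
                notes.append(msg)
        self.warnings.extend(notes)
        return notes


@dataclass
class LineageMap:
    """Child→parent relation between the snapshots at ``t0`` and ``t1``."""

    t0: float
    t1: float
    parent_of: Dict[int, int]

    def __post_init__(self) -> None:
        if not self.t1 > self.t0:
            raise ValueError(f"require t1 > t0, got t0={self.t0}, t1={self.t1}")
        self.parent_of = {int(c): int(p) for c, p in self.parent_of.items()}

    @property
    def parents(self) -> Set[int]:
        return set(self.parent_of.values())

    @property
    def children(self) -> Set[int]:
        return set(self.parent_of)

    def children_of(self, parent: int) -> List[int]:
        return sorted(c for c, p in self.parent_of.items() if p == parent)


@dataclass(frozen=True)
class GrowthRecord:
    """Growth quantities of one lineage over one interval.

    ``lambda_max``/``lambda_min`` are the principal stretches of the best-fit
    linear deformation of the cell over the interval; ``anisotropy`` is their
    ratio. ``principal_direction`` is a unit vector in the snapshot plane, or
    ``None`` when the deformation is isotropic to within tolerance.
    """

    parent_label: int
    interval: Tuple[float, float]
    area_expansion_pct: float
    lambda_max: float
    lambda_min: float
    anisotropy: float
    principal_direction: Optional[Tuple[float, float]]
    n_daughters: int
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if not (self.lambda_max >= self.lambda_min > 0):
            raise ValueError(
                f"require lambda_max >= lambda_min > 0, got "
                f"({self.lambda_max}, {self.lambda_min})"
            )
        if self.anisotropy < 1.0 - 1e-12:
            raise ValueError(f"anisotropy must be >= 1, got {self.anisotropy}")
        if self.area_expansion_pct < -100.0:
            raise ValueError("area expansion cannot be below -100%")
        if self.n_daughters < 1:
            raise ValueError("n_daughters must be >= 1")


@dataclass
class DistanceField:
    """Per-cell shortest-path distance from a source label set.

    ``distance`` maps label → µm (0 exactly on sources, ``inf`` for
    unreachable cells); ``normalized`` maps label → [0, 1] after
    :func:`organgrowth.axes_distance.normalize_distance` has been applied
    over a stated domain.
    """

    source_labels: Set[int]
    distance: Dict[int, float]
    normalized: Dict[int, float] = field(default_factory=dict)
    domain_labels: Set[int] = field(default_factory=set)
    unreachable: Set[int] = field(default_factory=set)


@dataclass
class GradientProfile:
    """Binned statistic versus normalized distance along a named axis."""

    axis: str
    interval: Tuple[float, float]
    bin_edges: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    singleton_bins: List[int] = field(default_factory=list)
    n_excluded: int = 0

    @property
    def n_total(self) -> int:
        return int(self.n.sum())

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


# ---------------------------------------------------------------------------
# Series validation


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "fatal" | "warning"
    code: str
    message: str


@dataclass
class ValidationReport:
    issues: List[ValidationIssue] = field(default_factory=list)

    @property
    def fatal(self) -> List[ValidationIssue]:
        return [i for i in self.issues if i.severity == "fatal"]

    @property
    def warnings(self) -> List[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def accepted(self) -> bool:
        return not self.fatal

    def add(self, severity: str, code: str, message: str) -> None:
        self.issues.append(ValidationIssue(severity, code, message))

    def by_code(self, code: str) -> List[ValidationIssue]:
        return [i for i in self.issues if i.code == code]


def validate_series(
    snapshots: Sequence[TissueSnapshot],
    lineages: Sequence[LineageMap],
) -> ValidationReport:
    """Validate a time series of snapshots with its lineage maps.

    The report lists, per interval: orphan children (child whose parent label
    is missing from the earlier snapshot), vanished parents (cells with no
    children, consistent with cells leaving the imaged region — non-fatal),
    unknown child labels, duplicate labels and adjacency violations. The
    series is accepted iff no fatal issue is present. Validation never
    mutates its inputs and is idempotent.
    """
    report = ValidationReport()
    if not snapshots:
        report.add("fatal", "empty-series", "no snapshots supplied")
        return report

    times = [s.time_dai for s in snapshots]
    if sorted(times) != times:
        report.add("fatal", "unsorted", f"snapshots not sorted by time: {times}")
    for s in snapshots:
        if s.n_cells == 0:
            report.add("fatal", "empty-snapshot", f"snapshot at t={s.time_dai} is empty")
        for a, b in s.adjacency:
            if a not in s.cells or b not in s.cells:
                report.add(
                    "fatal",
                    "adjacency",
                    f"t={s.time_dai}: adjacency ({a},{b}) references missing label",
                )

    if len(lineages) != len(snapshots) - 1:
        report.add(
            "fatal",
            "interval-count",
            f"{len(lineages)} lineage maps for {len(snapshots)} snapshots",
        )
        return report

    for k, lin in enumerate(lineages):
        s0, s1 = snapshots[k], snapshots[k + 1]
        if not (np.isclose(lin.t0, s0.time_dai) and np.isclose(lin.t1, s1.time_dai)):
            report.add(
                "fatal",
                "time-mismatch",
                f"lineage ({lin.t0},{lin.t1}) does not match snapshots "
                f"({s0.time_dai},{s1.time_dai})",
            )
            continue
        tag = f"interval {s0.time_dai}->{s1.time_dai}"
        for child, parent in sorted(lin.parent_of.items()):
            if child not in s1.cells:
                report.add("fatal", "unknown-child", f"{tag}: unknown child {child}")
            if parent not in s0.cells:
                report.add("fatal", "unknown-parent", f"{tag}: child {child} has unknown parent {parent}")
        for child in sorted(set(s1.cells) - lin.children):
            report.add("warning", "orphan-child", f"{tag}: cell {child} has no parent")
        for parent in sorted(set(s0.cells) - lin.parents):
            report.add(
                "warning",
                "vanished-parent",
                f"{tag}: cell {parent} has no children (left the imaged region?)",
            )
    return report
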