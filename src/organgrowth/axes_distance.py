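"""Organ axis parameterization and geodesic cell-distance fields.

:class:`AxisGrid` maps surface points to normalized organ coordinates
``(u, v)``: ``u`` is the normalized arclength of the nearest point on a
Bezier curve following the organ's longitudinal axis (0 at the base, 1 at
the tip); ``v`` is the signed perpendicular offset from that curve rescaled
by the organ width (0 on the curve at the medial reference, 1 at the
lateral margin). :func:`cell_distance` computes shortest paths on the cell
adjacency graph with centroid-to-centroid edge weights, the cell-granular
analogue of a surface geodesic; :func:`normalize_distance` rescales a field
by its maximum over an explicitly stated domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Dict, Iterable, Optional, Sequence, Set

import networkx as nx
import numpy as np

from organgrowth.core_model import DistanceField, TissueSnapshot

__all__ = [
    "BezierCurve",
    "AxisGrid",
    "fit_axis_grid",
    "cell_distance",
    "normalize_distance",
    "reference_labels",
]


class BezierCurve:
    """Bezier curve of arbitrary degree with an arclength lookup table."""

    def __init__(self, control_points: np.ndarray, n_samples: int = 1024):
        cp = np.asarray(control_points, dtype=float)
        if cp.ndim != 2 or cp.shape[1] != 2 or len(cp) < 2:
            raise ValueError("need >= 2 control points of dimension 2")
        if np.allclose(cp, cp[0]):
            raise ValueError("control points are degenerate (zero extent)")
        self.control_points = cp
        self._t = np.linspace(0.0, 1.0, n_samples + 1)
        self._pts = self.point(self._t)
        seg = np.linalg.norm(np.diff(self._pts, axis=0), axis=1)
        self._arc = np.concatenate([[0.0], np.cumsum(seg)])
        self.length = float(self._arc[-1])
        if self.length <= 0:
            raise ValueError("curve has zero length")

    def point(self, t) -> np.ndarray:
        """Evaluate by the Bernstein form; vectorized over ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        n = len(self.control_points) - 1
        out = np.zeros((len(t), 2))
        for i, p in enumerate(self.control_points):
            b = comb(n, i) * t**i * (1 - t) ** (n - i)
            out += b[:, None] * p
        return out

    def tangent(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        n = len(self.control_points) - 1
        d = n * np.diff(self.control_points, axis=0)
        out = np.zeros((len(t), 2))
        for i, p in enumerate(d):
            b = comb(n - 1, i) * t**i * (1 - t) ** (n - 1 - i)
            out += b[:, None] * p
        norm = np.linalg.norm(out, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return out / norm

    def arclength_at(self, t) -> np.ndarray:
        return np.interp(np.atleast_1d(t), self._t, self._arc)

    def t_at_arclength(self, s) -> np.ndarray:
        return np.interp(np.atleast_1d(s), self._arc, self._t)

    def project(self, points: np.ndarray, n_refine: int = 40) -> np.ndarray:
        """Parameter of the nearest curve point for each query point.

        Nearest dense sample followed by golden-section refinement.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = ((pts[:, None, :] - self._pts[None, :, :]) ** 2).sum(axis=2)
        idx = np.argmin(d2, axis=1)
        dt = self._t[1] - self._t[0]
        lo = np.clip(self._t[idx] - dt, 0.0, 1.0)
        hi = np.clip(self._t[idx] + dt, 0.0, 1.0)
        phi = (np.sqrt(5.0) - 1.0) / 2.0
        a, b = lo.copy(), hi.copy()
        c = b - phi * (b - a)
        d = a + phi * (b - a)
        fc = ((self.point(c) - pts) ** 2).sum(axis=1)
        fd = ((self.point(d) - pts) ** 2).sum(axis=1)
        for _ in range(n_refine):
            take = fc < fd
            b = np.where(take, d, b)
            a = np.where(take, a, c)
            c = b - phi * (b - a)
            d = a + phi * (b - a)
            fc = ((self.point(c) - pts) ** 2).sum(axis=1)
            fd = ((self.point(d) - pts) ** 2).sum(axis=1)
        return 0.5 * (a + b)


@dataclass
class AxisGrid:
    """Curvilinear organ coordinate frame.

    ``longitudinal`` runs along the organ (medial reference for ``v = 0``);
    ``mediolateral`` spans the organ width and sets the ``v`` length scale.
    """

    longitudinal: BezierCurve
    mediolateral: BezierCurve

    @property
    def width(self) -> float:
        return self.mediolateral.length

    def to_uv(self, points: np.ndarray) -> np.ndarray:
        """Map points (µm) to ``(u, v)`` organ coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        t = self.longitudinal.project(pts)
        foot = self.longitudinal.point(t)
        tan = self.longitudinal.tangent(t)
        offset = pts - foot
        signed = tan[:, 0] * offset[:, 1] - tan[:, 1] * offset[:, 0]
        u = self.longitudinal.arclength_at(t) / self.longitudinal.length
        v = -signed / self.width  # positive toward the lateral side (+x for a +y axis)
        return np.column_stack([u, v])

    def from_uv(self, uv: np.ndarray) -> np.ndarray:
        """Inverse mapping ``(u, v)`` → point (µm)."""
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        s = uv[:, 0] * self.longitudinal.length
        t = self.longitudinal.t_at_arclength(s)
        foot = self.longitudinal.point(t)
        tan = self.longitudinal.tangent(t)
        normal = np.column_stack([tan[:, 1], -tan[:, 0]])  # +v side
        return foot + uv[:, 1, None] * self.width * normal

    def cell_extent(self, vertices: np.ndarray, axis: str) -> float:
        """Cell length (µm) along one axis: extent of the footprint in the
        axis coordinate converted to arclength."""
        uv = self.to_uv(vertices)
        if axis == "longitudinal":
            return float(np.ptp(uv[:, 0]) * self.longitudinal.length)
        if axis == "mediolateral":
            return float(np.ptp(uv[:, 1]) * self.width)
        raise ValueError(f"unknown axis {axis!r}")

    def projection_residual(self, points: np.ndarray) -> float:
        """RMS of the round-trip error (µm) over the given points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        back = self.from_uv(self.to_uv(pts))
        return float(np.sqrt(np.mean(np.sum((back - pts) ** 2, axis=1))))


def fit_axis_grid(
    snapshot: Optional[TissueSnapshot],
    longitudinal_control_points,
    mediolateral_control_points,
) -> AxisGrid:
    """Build an :class:`AxisGrid` from manually placed Bezier control points.

    The snapshot, when given, is only used to report the projection residual
    over cell centroids (stored on the returned grid as ``residual_um``).
    """
    grid = AxisGrid(
        longitudinal=BezierCurve(np.asarray(longitudinal_control_points, dtype=float)),
        mediolateral=BezierCurve(np.asarray(mediolateral_control_points, dtype=float)),
    )
    if snapshot is not None:
        cents = np.array([c.centroid for c in snapshot.cells.values()])
        grid.residual_um = grid.projection_residual(cents)  # type: ignore[attr-defined]
    return grid


def cell_distance(snapshot: TissueSnapshot, source_labels: Iterable[int]) -> DistanceField:
    """Shortest-path distance from a source cell set on the adjacency graph.

    Edge weights are Euclidean centroid-to-centroid distances (µm), the
    cell-granular analogue of a path following the organ surface. Sources
    are at distance 0; unreachable cells get ``inf`` and are flagged.
    """
    sources = {int(s) for s in source_labels}
    if not sources:
        raise ValueError("source label set is empty")
    missing = sources - set(snapshot.cells)
    if missing:
        raise ValueError(f"source labels {sorted(missing)} not in snapshot")
    g = snapshot.graph()
    dist = nx.multi_source_dijkstra_path_length(g, sources, weight="weight")
    distance: Dict[int, float] = {}
    unreachable: Set[int] = set()
    for lab in snapshot.labels:
        if lab in dist:
            distance[lab] = float(dist[lab])
        else:
            distance[lab] = float("inf")
            unreachable.add(lab)
    return DistanceField(source_labels=sources, distance=distance, unreachable=unreachable)


def normalize_distance(field: DistanceField, domain_labels: Iterable[int]) -> DistanceField:
    """Normalize a distance field by its maximum over a stated domain.

    The domain (e.g. valve cells only, or the whole organ) must be declared
    by the caller — it is recorded on the returned field, never defaulted.
    Values are clipped to [0, 1]; the field must be non-degenerate (some
    finite positive distance over the domain).
    """
    domain = {int(l) for l in domain_labels}
    if not domain:
        raise ValueError("degenerate domain: no labels")
    missing = domain - set(field.distance)
    if missing:
        raise ValueError(f"domain labels {sorted(missing)[:5]} not in field")
    finite = [field.distance[l] for l in domain if np.isfinite(field.distance[l])]
    dmax = max(finite) if finite else 0.0
    if dmax <= 0:
        raise ValueError("degenerate domain: max distance is zero")
    normalized = {
        lab: float(np.clip(field.distance[lab] / dmax, 0.0, 1.0))
        for lab in sorted(domain)
        if np.isfinite(field.distance[lab])
    }
    return DistanceField(
        source_labels=set(field.source_labels),
        distance=dict(field.distance),
        normalized=normalized,
        domain_labels=domain,
        unreachable=set(field.unreachable),
    )


def reference_labels(
    snapshot: TissueSnapshot,
    kind: str,
    frac: float = 0.06,
    within: Optional[Iterable[int]] = None,
) -> Set[int]:
    """Standard distance-source sets on a snapshot.

    ``kind``: ``"base"`` (region-tagged base cells, else the lowest band of
    centroids), ``"tip"`` (the highest band), ``"medial"`` (replum/medial
    tagged cells, else a central vertical strip), ``"midline"`` (a central
    vertical strip regardless of tags — the mediolateral reference for
    regions that do not border the replum, e.g. the style). ``frac`` is the
    band width as a fraction of the extent when selecting geometrically;
    ``within`` restricts the candidate cells (e.g. to one region).
    """
    labels = snapshot.labels if within is None else sorted(set(within))
    if not labels:
        raise ValueError("no candidate cells for reference selection")
    cents = {lab: snapshot.cells[lab].centroid for lab in labels}
    ys = np.array([c[1] for c in cents.values()])
    xs = np.array([c[0] for c in cents.values()])
    if kind == "base":
        tagged = {lab for lab in labels if snapshot.cells[lab].region == "base"}
        if tagged:
            return tagged
        cut = ys.min() + frac * np.ptp(ys)
        return {lab for lab, c in cents.items() if c[1] <= cut}
    if kind == "tip":
        cut = ys.max() - frac * np.ptp(ys)
        return {lab for lab, c in cents.items() if c[1] >= cut}
    if kind == "medial":
        tagged = {
            lab
            for lab in labels
            if snapshot.cells[lab].region in ("replum", "medial")
        }
        if tagged:
            return tagged
        kind = "midline"
    if kind == "midline":
        mid = 0.5 * (xs.min() + xs.max())
        cut = max(frac * np.ptp(xs), 1e-9)
        out = {lab for lab, c in cents.items() if abs(c[0] - mid) <= cut}
        if not out:  # widen until non-empty
            nearest = min(labels, key=lambda l: abs(cents[l][0] - mid))
            out = {nearest}
        return out
    raise ValueError(f"unknown reference kind {kind!r}; use base, tip, medial or midline")
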