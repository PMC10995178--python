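"""Per-lineage growth quantities.

Area expansion uses the percentage convention
``(total daughter area / mother area − 1) × 100``. Principal stretches and
the growth anisotropy ratio come from the best-fit (least-squares) linear
map between matched cell junctions at the two time points; its singular
values are the stretches and the left singular vector of the largest one is
the principal growth direction. Directional growth decomposes the same
length convention along the axes of an :class:`~organgrowth.axes_distance.AxisGrid`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.ops import unary_union

from organgrowth.core_model import (
    CellPolygon,
    GrowthRecord,
    LineageMap,
    TissueSnapshot,
)

__all__ = [
    "area_expansion",
    "growth_tensor",
    "anisotropy",
    "directional_expansion",
    "compute_growth_map",
    "GrowthMapResult",
    "ISOTROPY_TOL",
]

# below this anisotropy the principal direction is reported as undefined
ISOTROPY_TOL = 1e-6


def area_expansion(area_t0: float, total_daughter_area_t1: float) -> float:
    """Percent area expansion of one lineage over one interval.

    ``(total_daughter_area_t1 / area_t0 − 1) × 100``; negative for
    shrinkage, 0 for no growth.
    """
    if area_t0 <= 0:
        raise ValueError(f"mother area must be > 0, got {area_t0}")
    if total_daughter_area_t1 < 0:
        raise ValueError("daughter area must be >= 0")
    return (total_daughter_area_t1 / area_t0 - 1.0) * 100.0


def growth_tensor(
    junction_pairs: Sequence[Tuple[Sequence[float], Sequence[float]]],
) -> Tuple[float, float, Optional[np.ndarray], float]:
    """Best-fit linear deformation from matched junction positions.

    Parameters
    ----------
    junction_pairs
        Sequence of ``(p_t0, p_t1)`` coordinate pairs: positions of the same
        cell junctions at the start and end of the interval. At least 3
        non-collinear pairs are required.

    Returns
    -------
    (lambda_max, lambda_min, principal_direction, residual_rms)
        Singular values of the centroid-free least-squares linear map and
        the left singular vector of the largest one (unit vector at t1).
        ``principal_direction`` is ``None`` when the deformation is
        isotropic to within :data:`ISOTROPY_TOL`.
    """
    pairs = list(junction_pairs)
    if len(pairs) < 3:
        raise ValueError(
            f"under-determined deformation: need >= 3 junction pairs, got {len(pairs)}"
        )
    p0 = np.array([p for p, _ in pairs], dtype=float)
    p1 = np.array([q for _, q in pairs], dtype=float)
    q0 = p0 - p0.mean(axis=0)
    q1 = p1 - p1.mean(axis=0)
    # collinearity check on the source configuration
    if np.linalg.matrix_rank(q0, tol=1e-9 * max(1.0, np.abs(q0).max())) < 2:
        raise ValueError("under-determined deformation: collinear junctions")

    # least squares A with q0 @ A.T ~= q1
    At, residuals, _, _ = np.linalg.lstsq(q0, q1, rcond=None)
    A = At.T
    U, S, Vt = np.linalg.svd(A)
    lam_max, lam_min = float(S[0]), float(S[1])
    pred = q0 @ At
    residual_rms = float(np.sqrt(np.mean((pred - q1) ** 2)))
    if lam_min <= 0:
        raise ValueError("degenerate deformation (non-positive stretch)")
    if lam_max / lam_min < 1.0 + ISOTROPY_TOL:
        direction = None
    else:
        direction = U[:, 0].copy()
        if direction[0] < 0 or (direction[0] == 0 and direction[1] < 0):
            direction = -direction
    return lam_max, lam_min, direction, residual_rms


def anisotropy(lambda_max: float, lambda_min: float) -> float:
    """Growth anisotropy: ratio of maximal to minimal principal stretch."""
    if lambda_min <= 0:
        raise ValueError(f"lambda_min must be > 0, got {lambda_min}")
    if lambda_max < lambda_min:
        raise ValueError("lambda_max must be >= lambda_min")
    return lambda_max / lambda_min


def directional_expansion(
    parent: CellPolygon,
    daughters_union,
    grid,
    axis: str,
) -> float:
    """Percent length expansion of a lineage along one organ axis.

    The cell "length" along an axis is the extent of its footprint in the
    axis coordinate of ``grid``, converted to arclength µm; the return value
    is ``(L1 / L0 − 1) × 100``.
    """
    if axis not in ("longitudinal", "mediolateral"):
        raise ValueError(f"axis must be longitudinal or mediolateral, got {axis!r}")
    L0 = grid.cell_extent(parent.vertices, axis)
    if isinstance(daughters_union, Polygon):
        coords = np.array(daughters_union.exterior.coords[:-1])
    else:
        coords = np.asarray(daughters_union, dtype=float)
    L1 = grid.cell_extent(coords, axis)
    if L0 <= 0:
        raise ValueError("degenerate parent footprint along axis")
    return (L1 / L0 - 1.0) * 100.0


@dataclass
class GrowthMapResult:
    """Growth records plus the t1-keyed heat-map table.

    Following the display convention for interval quantities, the heat-map
    table is keyed by second-time-point labels: every daughter carries its
    parent's interval values.
    """

    records: List[GrowthRecord]
    heatmap: pd.DataFrame  # indexed by t1 label
    skipped_parents: List[int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            angle = (
                float(np.degrees(np.arctan2(r.principal_direction[1], r.principal_direction[0])))
                if r.principal_direction is not None
                else np.nan
            )
            rows.append(
                {
                    "t0": r.interval[0],
                    "t1": r.interval[1],
                    "parent_label": r.parent_label,
                    "area_expansion_pct": r.area_expansion_pct,
                    "lambda_max": r.lambda_max,
                    "lambda_min": r.lambda_min,
                    "anisotropy": r.anisotropy,
                    "direction_angle_deg": angle,
                    "n_daughters": r.n_daughters,
                    "residual_rms": r.residual_rms,
                }
            )
        return pd.DataFrame(rows)


def _junction_pairs(
    s0: TissueSnapshot, s1: TissueSnapshot, parent: CellPolygon
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Match the parent's junction vertices to their t1 positions by
    persistent vertex id. Only junctions present at both times are used."""
    if parent.vertex_ids is None:
        return []
    pos1: Dict[int, np.ndarray] = {}
    for c in s1.cells.values():
        if c.vertex_ids is None:
            continue
        for vid, xy in zip(c.vertex_ids, c.vertices):
            pos1[vid] = xy
    pairs = []
    seen = set()
    for vid, xy in zip(parent.vertex_ids, parent.vertices):
        if vid in pos1 and vid not in seen:
            pairs.append((xy, pos1[vid]))
            seen.add(vid)
    return pairs


def compute_growth_map(
    s0: TissueSnapshot,
    s1: TissueSnapshot,
    lineage: LineageMap,
    grid=None,
) -> GrowthMapResult:
    """Growth records for every non-vanished parent of one interval.

    Parents whose junction correspondence is under-determined (fewer than 3
    matched junctions) are reported in ``skipped_parents``. When ``grid`` is
    given, directional expansion along both axes is added to the heat-map
    table.
    """
    records: List[GrowthRecord] = []
    skipped: List[int] = []
    heat_rows: Dict[int, Dict[str, float]] = {}

    daughters_by_parent: Dict[int, List[int]] = {}
    for child, par in sorted(lineage.parent_of.items()):
        daughters_by_parent.setdefault(par, []).append(child)

    for par in sorted(s0.cells):
        if par not in daughters_by_parent:
            continue  # vanished parent: excluded from growth maps
        parent = s0.cells[par]
        children = daughters_by_parent[par]
        total_area = sum(s1.cells[c].area for c in children)
        exp_pct = area_expansion(parent.area, total_area)

        pairs = _junction_pairs(s0, s1, parent)
        try:
            lam_max, lam_min, direction, rms = growth_tensor(pairs)
        except ValueError:
            skipped.append(par)
            continue
        rec = GrowthRecord(
            parent_label=par,
            interval=(s0.time_dai, s1.time_dai),
            area_expansion_pct=exp_pct,
            lambda_max=lam_max,
            lambda_min=lam_min,
            anisotropy=lam_max / lam_min,
            principal_direction=tuple(direction) if direction is not None else None,
            n_daughters=len(children),
            residual_rms=rms,
        )
        records.append(rec)

        row = {
            "parent_label": float(par),
            "area_expansion_pct": exp_pct,
            "anisotropy": lam_max / lam_min,
            "n_daughters": float(len(children)),
        }
        if grid is not None:
            union = unary_union([s1.cells[c].to_shapely() for c in children])
            if union.geom_type == "MultiPolygon":
                union = max(union.geoms, key=lambda g: g.area)
            for axis in ("longitudinal", "mediolateral"):
                row[f"{axis}_expansion_pct"] = directional_expansion(
                    parent, union, grid, axis
                )
        for c in children:
            heat_rows[c] = row

    heatmap = pd.DataFrame.from_dict(heat_rows, orient="index").sort_index()
    heatmap.index.name = "label_t1"
    return GrowthMapResult(records=records, heatmap=heatmap, skipped_parents=skipped)
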