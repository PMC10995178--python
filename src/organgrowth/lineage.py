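"""Lineage algebra: composing parent relations across intervals, reverse
tracing of late region assignments into early sectors, and proliferation
counts."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from organgrowth.core_model import LineageMap, TissueSnapshot

__all__ = [
    "compose",
    "reverse_trace",
    "forward_propagate",
    "proliferation",
    "ReverseTraceResult",
    "MIXED",
]

MIXED = "mixed"


def compose(lineages: Sequence[LineageMap]) -> LineageMap:
    """Compose consecutive lineage maps into one spanning map.

    Each child at the final time is mapped to its ancestor at the initial
    time. Maps must chain (each ``t1`` equal to the next ``t0``). Children
    whose chain breaks (a parent missing from the preceding map) are
    omitted from the result.
    """
    if not lineages:
        raise ValueError("no lineage maps to compose")
    for a, b in zip(lineages, lineages[1:]):
        if not np.isclose(a.t1, b.t0):
            raise ValueError(
                f"lineage maps do not chain: interval ending at t={a.t1} "
                f"followed by interval starting at t={b.t0}"
            )
    if len(lineages) == 1:
        lin = lineages[0]
        return LineageMap(t0=lin.t0, t1=lin.t1, parent_of=dict(lin.parent_of))

    combined: Dict[int, int] = {}
    last = lineages[-1]
    for child in sorted(last.parent_of):
        anc: Optional[int] = child
        for lin in reversed(lineages):
            anc = lin.parent_of.get(anc)  # type: ignore[arg-type]
            if anc is None:
                break
        if anc is not None:
            combined[child] = anc
    return LineageMap(t0=lineages[0].t0, t1=last.t1, parent_of=combined)


@dataclass
class ReverseTraceResult:
    """Early-time sector map produced by :func:`reverse_trace`.

    ``sectors`` maps each traced ancestor label to the region all of its
    descendants agree on, or to :data:`MIXED` when they disagree; mixed
    ancestors are also listed in ``mixed_ancestors`` as a QC signal.
    """

    t0: float
    tk: float
    sectors: Dict[int, str]
    mixed_ancestors: List[int] = field(default_factory=list)

    @property
    def exclusive(self) -> bool:
        return not self.mixed_ancestors


def reverse_trace(
    late_assignment: Mapping[int, str],
    lineages: Sequence[LineageMap],
    late_snapshot: Optional[TissueSnapshot] = None,
) -> ReverseTraceResult:
    """Trace a late region assignment back to early-time sectors.

    Each initial-time cell receives the region of its descendants; when
    descendants disagree the ancestor is tagged ``"mixed"`` and reported,
    so any non-exclusive contribution is surfaced rather than silently
    resolved.
    """
    if late_snapshot is not None:
        missing = sorted(set(late_assignment) - set(late_snapshot.cells))
        if missing:
            raise ValueError(
                f"labels {missing[:5]} in late assignment are absent from the "
                f"snapshot at t={late_snapshot.time_dai}"
            )
    combined = compose(lineages)
    regions_of_ancestor: Dict[int, Set[str]] = {}
    for child, region in sorted(late_assignment.items()):
        anc = combined.parent_of.get(child)
        if anc is None:
            continue
        regions_of_ancestor.setdefault(anc, set()).add(region)

    sectors: Dict[int, str] = {}
    mixed: List[int] = []
    for anc in sorted(regions_of_ancestor):
        regions = regions_of_ancestor[anc]
        if len(regions) == 1:
            sectors[anc] = next(iter(regions))
        else:
            sectors[anc] = MIXED
            mixed.append(anc)
    return ReverseTraceResult(
        t0=combined.t0, tk=combined.t1, sectors=sectors, mixed_ancestors=mixed
    )


def forward_propagate(
    sectors: Mapping[int, str], lineages: Sequence[LineageMap]
) -> Dict[int, str]:
    """Propagate an early sector map forward to the final time point."""
    combined = compose(lineages)
    out: Dict[int, str] = {}
    for child, anc in sorted(combined.parent_of.items()):
        if anc in sectors:
            out[child] = sectors[anc]
    return out


def proliferation(lineage: LineageMap, parent: int) -> Tuple[int, bool]:
    """Daughter count of ``parent`` over the interval.

    Returns ``(count, vanished)``; a vanished parent (no children — the cell
    left the imaged region) yields ``(0, True)``.
    """
    count = sum(1 for p in lineage.parent_of.values() if p == parent)
    return count, count == 0
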