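"""Gradient read-outs: binned profiles versus normalized distance,
rank-correlation gradient statistics with a permutation null, dominant-axis
classification, onset-time detection, and stomata distributions.

A spatial gradient is operationalized as a monotone association between a
per-cell value and normalized distance along an axis: Spearman rank
correlation with a label-shuffling permutation p-value
``(1 + #{|rho_perm| >= |rho_obs|}) / (n_permutations + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from organgrowth.core_model import DistanceField, GradientProfile, TissueSnapshot

__all__ = [
    "GradientStat",
    "profile",
    "gradient_stat",
    "dominant_axis",
    "onset_time",
    "stomata_distribution",
    "cell_size_profile",
    "StomataHistogram",
]

DEFAULT_ALPHA = 0.05
DEFAULT_DELTA = 0.1
DEFAULT_MIN_CONSECUTIVE = 2


@dataclass(frozen=True)
class GradientStat:
    """Strength of one gradient over one interval.

    ``slope`` is value-units per unit normalized distance (OLS);
    ``rank_correlation`` is Spearman's rho; ``permutation_p`` its
    label-shuffling p-value.
    """

    axis: str
    interval: Tuple[float, float]
    slope: float
    rank_correlation: float
    permutation_p: float
    n_cells: int
    flagged: bool = False

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-9 <= self.rank_correlation <= 1.0 + 1e-9):
            raise ValueError("rank correlation out of [-1, 1]")
        if not (0.0 < self.permutation_p <= 1.0):
            raise ValueError("permutation p must lie in (0, 1]")


def _matched(values: Mapping[int, float], normalized: Mapping[int, float]):
    labels = sorted(set(values) & set(normalized))
    if not labels:
        raise ValueError("no labels shared between values and distance field")
    x = np.array([normalized[l] for l in labels], dtype=float)
    y = np.array([values[l] for l in labels], dtype=float)
    return labels, x, y


def profile(
    values: Mapping[int, float],
    distance_field: DistanceField,
    n_bins: int,
    axis: str = "longitudinal",
    interval: Tuple[float, float] = (np.nan, np.nan),
) -> GradientProfile:
    """Bin per-cell values by normalized distance into equal-width bins.

    Cells lacking a (finite) normalized distance are excluded and counted in
    ``n_excluded``; bins holding a single cell report SD 0 and are flagged.
    The SD is the sample standard deviation (ddof 1).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    shared = sorted(set(values) & set(distance_field.normalized))
    if not shared:
        raise ValueError("no labels shared between values and distance field")
    n_excluded = len(set(values)) - len(shared)
    x = np.array([distance_field.normalized[l] for l in shared])
    y = np.array([values[l] for l in shared])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    n = np.zeros(n_bins, dtype=int)
    singleton: List[int] = []
    for b in range(n_bins):
        sel = y[idx == b]
        n[b] = len(sel)
        if len(sel) == 0:
            continue
        mean[b] = sel.mean()
        if len(sel) == 1:
            sd[b] = 0.0
            singleton.append(b)
        else:
            sd[b] = sel.std(ddof=1)
    return GradientProfile(
        axis=axis,
        interval=interval,
        bin_edges=edges,
        mean=mean,
        sd=sd,
        n=n,
        singleton_bins=singleton,
        n_excluded=n_excluded,
    )


def _rank(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a)


def gradient_stat(
    values: Mapping[int, float],
    distance_field: DistanceField,
    n_permutations: int = 999,
    seed: int = 0,
    axis: str = "longitudinal",
    interval: Tuple[float, float] = (np.nan, np.nan),
) -> GradientStat:
    """Gradient strength of per-cell values along a normalized distance.

    Slope by ordinary least squares; Spearman rank correlation; permutation
    p-value by shuffling value labels. Zero-variance values yield rho 0,
    p 1, flagged.
    """
    _, x, y = _matched(values, distance_field.normalized)
    if len(x) < 10:
        raise ValueError(f"need >= 10 cells for a gradient statistic, got {len(x)}")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return GradientStat(
            axis=axis, interval=interval, slope=0.0, rank_correlation=0.0,
            permutation_p=1.0, n_cells=len(x), flagged=True,
        )
    slope = float(np.polyfit(x, y, 1)[0])

    rx = _rank(x)
    ry = _rank(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    rho = float((rxc * ryc).sum() / denom)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(ryc) for _ in range(n_permutations)])
    rho_perm = (perms @ rxc) / denom
    n_ge = int(np.sum(np.abs(rho_perm) >= abs(rho) - 1e-12))
    p = (1 + n_ge) / (n_permutations + 1)
    return GradientStat(
        axis=axis, interval=interval, slope=slope, rank_correlation=rho,
        permutation_p=p, n_cells=len(x),
    )


@dataclass(frozen=True)
class AxisVerdict:
    verdict: str  # "longitudinal" | "mediolateral" | "none"
    longitudinal: GradientStat
    mediolateral: GradientStat


def dominant_axis(
    values: Mapping[int, float],
    u_field: DistanceField,
    v_field: DistanceField,
    alpha: float = DEFAULT_ALPHA,
    delta: float = DEFAULT_DELTA,
    n_permutations: int = 999,
    seed: int = 0,
    interval: Tuple[float, float] = (np.nan, np.nan),
) -> AxisVerdict:
    """Classify which organ axis dominates a per-cell value pattern.

    The axis with the larger |rho| wins when its permutation p-value is
    below ``alpha`` and the other axis' |rho| is smaller by at least
    ``delta``; otherwise the verdict is ``"none"``.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    stat_u = gradient_stat(
        values, u_field, n_permutations, int(ss[0].generate_state(1)[0]),
        axis="longitudinal", interval=interval,
    )
    stat_v = gradient_stat(
        values, v_field, n_permutations, int(ss[1].generate_state(1)[0]),
        axis="mediolateral", interval=interval,
    )
    win, lose = (stat_u, stat_v) if abs(stat_u.rank_correlation) >= abs(
        stat_v.rank_correlation
    ) else (stat_v, stat_u)
    verdict = "none"
    if win.permutation_p < alpha and (
        abs(lose.rank_correlation) <= abs(win.rank_correlation) - delta
    ):
        verdict = win.axis
    return AxisVerdict(verdict=verdict, longitudinal=stat_u, mediolateral=stat_v)


def onset_time(
    series: Sequence[GradientStat],
    alpha: float = DEFAULT_ALPHA,
    min_consecutive: int = DEFAULT_MIN_CONSECUTIVE,
) -> Optional[Tuple[float, float]]:
    """First interval of a sustained gradient, or ``None``.

    Sustained means: permutation p below ``alpha`` for ``min_consecutive``
    consecutive intervals with a consistent sign of rho. Returns the
    interval of the first statistic of the sustained run.
    """
    if not series:
        return None
    n = len(series)
    for i in range(n - min_consecutive + 1):
        run = series[i : i + min_consecutive]
        if all(s.permutation_p < alpha for s in run):
            signs = {np.sign(s.rank_correlation) for s in run}
            if len(signs) == 1 and 0.0 not in signs:
                return run[0].interval
    return None


@dataclass
class StomataHistogram:
    """Stoma counts per normalized-distance bin for one reference set."""

    reference: str
    bin_edges: np.ndarray
    counts: np.ndarray
    total: int
    empty: bool = False


def _stoma_histogram(
    snapshot: TissueSnapshot,
    reference_labels: Iterable[int],
    domain_labels: Iterable[int],
    n_bins: int,
    name: str,
) -> StomataHistogram:
    from organgrowth.axes_distance import cell_distance, normalize_distance

    refs = sorted(set(reference_labels))
    if not refs:
        raise ValueError(f"empty reference set {name!r}")
    fld = cell_distance(snapshot, refs)
    fld = normalize_distance(fld, domain_labels)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    stoma = [
        lab
        for lab in sorted(fld.normalized)
        if snapshot.cells[lab].state == "stoma"
    ]
    counts = np.zeros(n_bins, dtype=int)
    for lab in stoma:
        b = min(int(np.digitize(fld.normalized[lab], edges[1:-1])), n_bins - 1)
        counts[b] += 1
    return StomataHistogram(
        reference=name,
        bin_edges=edges,
        counts=counts,
        total=len(stoma),
        empty=len(stoma) == 0,
    )


def stomata_distribution(
    snapshot: TissueSnapshot,
    base_reference: Iterable[int],
    medial_reference: Iterable[int],
    n_bins: int = 10,
    domain_labels: Optional[Iterable[int]] = None,
) -> Tuple[StomataHistogram, StomataHistogram]:
    """Stoma counts versus normalized distance from two reference sets.

    Returns ``(from_base, from_medial)`` histograms. ``domain_labels``
    states the normalization domain (defaults to all cells of the
    snapshot, which is then recorded explicitly on the fields).
    """
    domain = sorted(domain_labels) if domain_labels is not None else snapshot.labels
    h_base = _stoma_histogram(snapshot, base_reference, domain, n_bins, "base")
    h_medial = _stoma_histogram(snapshot, medial_reference, domain, n_bins, "medial")
    return h_base, h_medial


def cell_size_profile(
    snapshot: TissueSnapshot,
    distance_field: DistanceField,
    n_bins: int = 10,
    axis: str = "longitudinal",
) -> GradientProfile:
    """Binned profile of cell areas (µm²) versus normalized distance."""
    areas = {lab: snapshot.cells[lab].area for lab in snapshot.labels}
    return profile(
        areas,
        distance_field,
        n_bins,
        axis=axis,
        interval=(snapshot.time_dai, snapshot.time_dai),
    )
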