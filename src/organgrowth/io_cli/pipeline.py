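"""End-to-end pipeline driver.

Stage order: simulate (or load) → validate → compose lineages → growth maps
→ axis/distance fields → profiles, gradient statistics and onsets → stomata
distributions. Every numeric output carries the config hash and seed in a
header comment; identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from organgrowth import __version__
from organgrowth.axes_distance import (
    AxisGrid,
    cell_distance,
    fit_axis_grid,
    normalize_distance,
    reference_labels,
)
from organgrowth.core_model import (
    DistanceField,
    LineageMap,
    TissueSnapshot,
    validate_series,
)
from organgrowth.gradients import (
    GradientStat,
    dominant_axis,
    gradient_stat,
    onset_time,
    profile,
    stomata_distribution,
)
from organgrowth.growth_quant import GrowthMapResult, compute_growth_map
from organgrowth.io_cli.config import PipelineConfig
from organgrowth.io_cli.formats import read_lineage, read_snapshot, write_lineage, write_snapshot
from organgrowth.lineage import compose
from organgrowth.synthetic_tissue import SimulationSeries, scenario

__all__ = [
    "run_pipeline",
    "build_series",
    "default_grid",
    "axis_field",
    "interval_axis_stats",
    "PipelineResult",
    "ANALYSIS_PLAN",
]

log = logging.getLogger("organgrowth")

# per analysis group: axis → (distance-source kind, restrict sources to group)
ANALYSIS_PLAN: Dict[str, Dict[str, Tuple[str, bool]]] = {
    "valve": {"longitudinal": ("base", False), "mediolateral": ("medial", False)},
    # the style sits above the replum, so its mediolateral reference is its
    # own midline, not the (longitudinally displaced) replum
    "style": {"longitudinal": ("tip", False), "mediolateral": ("midline", True)},
    "organ": {"longitudinal": ("base", False), "mediolateral": ("medial", False)},
}


def _stage_seed(base_seed: int, tag: str) -> int:
    """Deterministic per-stage seed derived from the top-level seed."""
    return (base_seed * 1000003 + zlib.crc32(tag.encode())) % (2**32)


def build_series(config: PipelineConfig) -> SimulationSeries:
    """Simulate the configured scenario, or load snapshots/lineages."""
    if config.scenario:
        return scenario(config.scenario, overrides=dict(config.overrides), seed=config.seed)
    if not config.snapshot_paths:
        raise ValueError("config needs either a scenario or snapshot_paths")
    snaps = [read_snapshot(p) for p in config.snapshot_paths]
    lins = [read_lineage(p) for p in config.lineage_paths]
    return SimulationSeries(
        name="loaded", snapshots=snaps, lineages=lins, ground_truth=pd.DataFrame(),
        config={"inputs": list(config.snapshot_paths)},
    )


def default_grid(snapshot: TissueSnapshot) -> AxisGrid:
    """Straight rectilinear axis grid from the snapshot's bounding box:
    longitudinal along the organ midline (v = 0 medially), mediolateral
    across the full width."""
    pts = np.vstack([c.vertices for c in snapshot.cells.values()])
    xmin, ymin = pts.min(axis=0)
    xmax, ymax = pts.max(axis=0)
    xmid = 0.5 * (xmin + xmax)
    ymid = 0.5 * (ymin + ymax)
    return fit_axis_grid(
        None,
        [[xmid, ymin], [xmid, ymax]],
        [[xmin, ymid], [xmax, ymid]],
    )


def grid_for(snapshot: TissueSnapshot, config: Optional[PipelineConfig]) -> AxisGrid:
    if (
        config is not None
        and config.longitudinal_control_points
        and config.mediolateral_control_points
    ):
        return fit_axis_grid(
            snapshot,
            config.longitudinal_control_points,
            config.mediolateral_control_points,
        )
    return default_grid(snapshot)


def group_labels(snapshot: TissueSnapshot, group: str) -> Set[int]:
    """Cells belonging to one analysis group (``organ`` = all cells)."""
    if group == "organ":
        return set(snapshot.labels)
    return set(snapshot.region_labels(group))


def axis_field(
    snapshot: TissueSnapshot,
    sources_kind: str,
    domain_labels: Sequence[int],
    within_domain: bool = False,
) -> DistanceField:
    """Normalized distance field from a standard reference set, with the
    normalization domain stated explicitly."""
    sources = reference_labels(
        snapshot, sources_kind, within=domain_labels if within_domain else None
    )
    fld = cell_distance(snapshot, sources)
    return normalize_distance(fld, domain_labels)


def interval_axis_stats(
    series: SimulationSeries,
    growth_results: Sequence[GrowthMapResult],
    group: str,
    axis: str,
    config: PipelineConfig,
) -> List[GradientStat]:
    """Gradient statistic of area expansion per interval, for one analysis
    group along one axis. Values are t1-keyed (display convention)."""
    kind, within = ANALYSIS_PLAN[group][axis]
    stats: List[GradientStat] = []
    for res, s1 in zip(growth_results, series.snapshots[1:]):
        s0 = series.snapshot_at(res.records[0].interval[0]) if res.records else None
        labels = group_labels(s1, group)
        values = {
            int(lab): float(res.heatmap.loc[lab, "area_expansion_pct"])
            for lab in res.heatmap.index
            if lab in labels
        }
        domain = sorted(labels)
        if config.normalization_domain == "organ":
            domain = s1.labels
        try:
            fld = axis_field(s1, kind, domain, within_domain=within)
            interval = (
                res.records[0].interval if res.records else (np.nan, s1.time_dai)
            )
            stat = gradient_stat(
                values,
                fld,
                n_permutations=config.n_permutations,
                seed=_stage_seed(config.seed, f"{group}:{axis}:{s1.time_dai}"),
                axis=axis,
                interval=interval,
            )
        except ValueError as e:
            log.debug("skipping %s/%s at t=%s: %s", group, axis, s1.time_dai, e)
            continue
        stats.append(stat)
    return stats


@dataclass
class PipelineResult:
    """In-memory bundle of everything :func:`run_pipeline` wrote."""

    config: PipelineConfig
    series: SimulationSeries
    growth_results: List[GrowthMapResult]
    stats: Dict[Tuple[str, str], List[GradientStat]]
    verdicts: pd.DataFrame
    onsets: Dict[str, Dict[str, Optional[Tuple[float, float]]]]
    out_dir: Path


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig, index=False) -> None:
    header = f"# config_hash={config.hash}\n# seed={config.seed}\n"
    path.write_text(header + df.to_csv(index=index))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write the output bundle.

    Any stage failure aborts with the stage name and cause. Re-running with
    an identical config reproduces every output byte-for-byte.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    timings: Dict[str, float] = {}

    def _stage(name):
        log.info("stage: %s", name)
        timings[name] = time.perf_counter()
        return name

    def _done(name):
        timings[name] = time.perf_counter() - timings[name]

    stage = _stage("simulate/load")
    try:
        series = build_series(config)
    except Exception as e:
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e
    _done(stage)

    stage = _stage("validate")
    report = validate_series(series.snapshots, series.lineages)
    if not report.accepted:
        msgs = "; ".join(i.message for i in report.fatal[:5])
        raise RuntimeError(f"stage 'validate' failed: {msgs}")
    (out / "validation.txt").write_text(
        "\n".join(f"{i.severity}\t{i.code}\t{i.message}" for i in report.issues) + "\n"
    )
    _done(stage)

    stage = _stage("lineage")
    composed = compose(series.lineages)
    write_lineage(composed, out / "composed_lineage.csv")
    snap_dir = out / "snapshots"
    snap_dir.mkdir(exist_ok=True)
    for s in series.snapshots:
        write_snapshot(s, snap_dir / f"snapshot_t{s.time_dai:05.1f}.json")
    for lin in series.lineages:
        write_lineage(lin, snap_dir / f"lineage_t{lin.t0:05.1f}_t{lin.t1:05.1f}.csv")
    _done(stage)

    stage = _stage("growth")
    growth_results: List[GrowthMapResult] = []
    frames = []
    heat_frames = []
    for s0, s1, lin in zip(series.snapshots, series.snapshots[1:], series.lineages):
        res = compute_growth_map(s0, s1, lin, grid=grid_for(s1, config))
        growth_results.append(res)
        frames.append(res.to_frame())
        hm = res.heatmap.reset_index()
        hm.insert(0, "t1", s1.time_dai)
        heat_frames.append(hm)
    _write_csv(pd.concat(frames, ignore_index=True), out / "growth_records.csv", config)
    _write_csv(pd.concat(heat_frames, ignore_index=True), out / "heatmap_tables.csv", config)
    _done(stage)

    stage = _stage("gradients")
    groups = ["organ"]
    last = series.snapshots[-1]
    for g in ("valve", "style"):
        if any(c.region == g for c in last.cells.values()):
            groups.append(g)
    stats: Dict[Tuple[str, str], List[GradientStat]] = {}
    stat_rows = []
    verdict_rows = []
    prof_rows = []
    for group in groups:
        for axis in ("longitudinal", "mediolateral"):
            st = interval_axis_stats(series, growth_results, group, axis, config)
            stats[(group, axis)] = st
            for s in st:
                stat_rows.append(
                    {
                        "group": group, "axis": axis, "t0": s.interval[0],
                        "t1": s.interval[1], "slope": s.slope,
                        "rank_correlation": s.rank_correlation,
                        "permutation_p": s.permutation_p, "n_cells": s.n_cells,
                    }
                )
        # per-interval dominant axis verdicts
        for res, s1 in zip(growth_results, series.snapshots[1:]):
            labels = group_labels(s1, group)
            values = {
                int(lab): float(res.heatmap.loc[lab, "area_expansion_pct"])
                for lab in res.heatmap.index
                if lab in labels
            }
            try:
                uk, uw = ANALYSIS_PLAN[group]["longitudinal"]
                vk, vw = ANALYSIS_PLAN[group]["mediolateral"]
                u_fld = axis_field(s1, uk, sorted(labels), within_domain=uw)
                v_fld = axis_field(s1, vk, sorted(labels), within_domain=vw)
                verdict = dominant_axis(
                    values, u_fld, v_fld,
                    alpha=config.alpha, delta=config.delta,
                    n_permutations=config.n_permutations,
                    seed=_stage_seed(config.seed, f"verdict:{group}:{s1.time_dai}"),
                    interval=(series.snapshots[0].time_dai, s1.time_dai),
                )
                verdict_rows.append(
                    {
                        "group": group, "t1": s1.time_dai, "verdict": verdict.verdict,
                        "rho_longitudinal": verdict.longitudinal.rank_correlation,
                        "rho_mediolateral": verdict.mediolateral.rank_correlation,
                    }
                )
                prof = profile(
                    values, u_fld, config.n_bins, axis="longitudinal",
                    interval=(s1.time_dai - 1.0, s1.time_dai),
                )
                for b in range(len(prof.n)):
                    prof_rows.append(
                        {
                            "group": group, "axis": "longitudinal", "t1": s1.time_dai,
                            "bin_lo": prof.bin_edges[b], "bin_hi": prof.bin_edges[b + 1],
                            "mean": prof.mean[b], "sd": prof.sd[b], "n": prof.n[b],
                        }
                    )
            except ValueError:
                continue
    _write_csv(pd.DataFrame(stat_rows), out / "gradient_stats.csv", config)
    verdicts = pd.DataFrame(verdict_rows)
    _write_csv(verdicts, out / "dominant_axis.csv", config)
    _write_csv(pd.DataFrame(prof_rows), out / "profiles.csv", config)

    onsets: Dict[str, Dict[str, Optional[Tuple[float, float]]]] = {}
    for group in groups:
        onsets[group] = {}
        for axis in ("longitudinal", "mediolateral"):
            o = onset_time(
                stats[(group, axis)], alpha=config.alpha,
                min_consecutive=config.min_consecutive,
            )
            onsets[group][axis] = o
    (out / "onsets.json").write_text(json.dumps(onsets, indent=1, sort_keys=True) + "\n")
    _done(stage)

    stage = _stage("stomata")
    stoma_rows = []
    for s in series.snapshots:
        if not any(c.state == "stoma" for c in s.cells.values()):
            continue
        valve = group_labels(s, "valve")
        domain = sorted(valve) if valve else s.labels
        try:
            h_base, h_medial = stomata_distribution(
                s,
                reference_labels(s, "base"),
                reference_labels(s, "medial"),
                n_bins=config.n_bins,
                domain_labels=domain,
            )
        except ValueError:
            continue
        for hist in (h_base, h_medial):
            for b, cnt in enumerate(hist.counts):
                stoma_rows.append(
                    {
                        "t": s.time_dai, "reference": hist.reference, "bin": b,
                        "bin_lo": hist.bin_edges[b], "bin_hi": hist.bin_edges[b + 1],
                        "count": int(cnt), "total": hist.total,
                    }
                )
    _write_csv(pd.DataFrame(stoma_rows), out / "stomata.csv", config)
    _done(stage)

    if config.heatmaps:
        stage = _stage("heatmaps")
        _render_heatmaps(series, growth_results, out / "heatmaps")
        _done(stage)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash,
        "seed": config.seed,
        "versions": {
            "organgrowth": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_snapshots": len(series.snapshots),
        "n_cells_final": series.snapshots[-1].n_cells,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    # timings go to the log only: the manifest must be byte-reproducible
    (out / "log.txt").write_text(
        "".join(f"{k}\t{v:.3f}s\n" for k, v in timings.items())
    )
    log.info("pipeline complete: %s", out)
    return PipelineResult(
        config=config, series=series, growth_results=growth_results,
        stats=stats, verdicts=verdicts, onsets=onsets, out_dir=out,
    )


def _render_heatmaps(series, growth_results, out_dir: Path) -> None:
    """Per-cell heat maps of interval area expansion, keyed by the second
    time point of each interval (no spatial smoothing)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection

    out_dir.mkdir(exist_ok=True)
    for res, s1 in zip(growth_results, series.snapshots[1:]):
        if res.heatmap.empty:
            continue
        polys, vals = [], []
        for lab in res.heatmap.index:
            polys.append(s1.cells[int(lab)].vertices)
            vals.append(res.heatmap.loc[lab, "area_expansion_pct"])
        fig, ax = plt.subplots(figsize=(4, 6))
        coll = PolyCollection(polys, array=np.array(vals), cmap="viridis", edgecolor="k", linewidth=0.2)
        ax.add_collection(coll)
        ax.autoscale()
        ax.set_aspect("equal")
        fig.colorbar(coll, ax=ax, label="area expansion (%)")
        ax.set_title(f"area expansion, displayed at t={s1.time_dai}")
        fig.savefig(out_dir / f"growth_t{s1.time_dai:05.1f}.png", dpi=120)
        plt.close(fig)
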