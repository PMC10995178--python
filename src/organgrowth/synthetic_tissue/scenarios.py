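"""Scenario presets: daily time series with known gradient structure.

Each preset encodes, as generative inputs, the qualitative spatio-temporal
structure that the quantification pipeline is expected to recover:

* ``gynoecium`` — valves carry a mediolateral areal-rate gradient (higher
  toward the replum) and a mediolateral differentiation-onset gradient
  (earlier toward the lateral margin) active over days 4–8; the style
  carries a tip-to-base onset/growth gradient from day 9; the replum grows
  slowly with longitudinal anisotropy.
* ``valveless`` — a single organ-wide basipetal (tip-to-base) onset
  gradient from day 7.
* ``sepal`` — basipetal onset from day 4 with a matching longitudinal
  growth gradient.
* ``carpelized_sepal`` — onset increasing toward the organ margin
  (margin cells differentiate later), growth higher near the margin.
* ``split_mutant`` — distal half basipetal from day 5; basal half with a
  weak mediolateral pattern around a reduced medial strip.

Gradient magnitudes are free parameters of this generator (reported in the
series config), not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional

import numpy as np
import pandas as pd

from organgrowth.core_model import LineageMap, TissueSnapshot
from organgrowth.synthetic_tissue.fields import GrowthFieldSpec
from organgrowth.synthetic_tissue.simulator import step
from organgrowth.synthetic_tissue.tessellation import make_initial_tissue

__all__ = ["SCENARIOS", "SimulationSeries", "scenario"]


@dataclass
class SimulationSeries:
    """Daily snapshots + lineage maps + imposed ground truth of one run."""

    name: str
    snapshots: List[TissueSnapshot]
    lineages: List[LineageMap]
    ground_truth: pd.DataFrame
    config: Dict = field(default_factory=dict)

    @property
    def times(self) -> List[float]:
        return [s.time_dai for s in self.snapshots]

    def snapshot_at(self, t: float) -> TissueSnapshot:
        for s in self.snapshots:
            if np.isclose(s.time_dai, t):
                return s
        raise KeyError(f"no snapshot at t={t}; have {self.times}")

    def lineage_for(self, t0: float, t1: float) -> LineageMap:
        for lin in self.lineages:
            if np.isclose(lin.t0, t0) and np.isclose(lin.t1, t1):
                return lin
        raise KeyError(f"no lineage for ({t0}, {t1})")


def _clip01(x):
    return np.clip(x, 0.0, 1.0)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -40.0, 40.0)))


def _softplus(x):
    return np.logaddexp(0.0, x)


def _smooth01(x, w):
    """Smooth approximation of clip(x, 0, 1) with corner width ``w``.

    Hard clip corners concentrate field curvature inside single cells,
    which the straight-edged polygon update cannot follow to 1%.
    """
    return w * (_softplus(x / w) - _softplus((x - 1.0) / w))


class _Frame(dict):
    """Mutable per-day frame the field closures read from.

    Region memberships are smooth logistic ramps around *material* interface
    positions re-measured from the tagged cells each day. Under the
    separable velocity scheme the longitudinal stretch rate is
    x-independent, so horizontal material lines stay horizontal and the
    style interface remains a flat y-level; the medial strip is tracked by
    the spread of replum-tagged centroids.
    """

    def update_from(self, snapshot: TissueSnapshot) -> None:
        cells = [snapshot.cells[lab] for lab in snapshot.labels]
        cents = np.array([c.centroid for c in cells])
        regions = np.array([c.region for c in cells])
        diam = float(np.sqrt(np.median([c.area for c in cells])))
        self["diam"] = diam
        self["ymin"], self["ymax"] = float(cents[:, 1].min()), float(cents[:, 1].max())
        self["xmid"] = float(cents[:, 0].mean())
        # vertex-based half-width: puts the lateral saturation corner of the
        # mediolateral coordinate outside every cell footprint
        all_x = np.concatenate([c.vertices[:, 0] for c in cells])
        self["xhalf"] = float(np.abs(all_x - self["xmid"]).max())
        organ_len = self["ymax"] - self["ymin"]
        style_y = cents[regions == "style", 1]
        below_y = cents[regions != "style", 1]
        if len(style_y) and len(below_y):
            # flat material interface: midpoint of the bracketing centroids
            self["style_y0"] = 0.5 * (
                float(style_y.min()) + float(below_y.max())
            )
        else:
            self["style_y0"] = self["ymax"] + organ_len
        # ramp widths of order one cell diameter: narrower ramps put sharp
        # field variation inside single cells and bias per-cell ground truth
        self["style_w"] = max(0.025 * organ_len, 2.0 * diam)
        rep_x = np.abs(cents[regions == "replum", 0] - self["xmid"])
        self["replum_xhalf"] = float(np.quantile(rep_x, 0.9)) if len(rep_x) else 0.0
        # blur must stay narrower than the structure it smooths
        self["replum_w"] = max(min(1.5 * diam, 0.75 * self["replum_xhalf"]), 1.5)

    def set_noise(self, rng: np.random.Generator, amp: float, n_modes: int = 4) -> None:
        """Draw a fresh smooth growth-variability field for the coming day.

        Real tissues show substantial cell-to-cell growth scatter; a smooth
        random field (cosine modes over the organ, redrawn every day) makes
        the simulated data realistically noisy without breaking the
        shared-vertex kinematics. ``ky`` noise depends on y only, so the
        longitudinal rate stays x-independent.
        """
        self["noise_amp"] = amp
        if amp <= 0:
            return
        # several cycles per organ: long-wavelength noise would mimic a
        # monotone gradient, short wavelengths just add cell-scale scatter
        self._noise_kx = [
            (
                rng.uniform(1.0, 3.0),  # cycles across x
                rng.uniform(0.5, 2.0),  # cycles across y (bounded: shear)
                rng.uniform(0, 2 * np.pi),
            )
            for _ in range(n_modes)
        ]
        self._noise_ky = [
            (rng.uniform(2.0, 5.0), rng.uniform(0, 2 * np.pi))
            for _ in range(n_modes)
        ]

    def _scaled(self, xy: np.ndarray) -> tuple:
        xn = (xy[:, 0] - (self["xmid"] - self["xhalf"])) / max(2 * self["xhalf"], 1e-9)
        yn = (xy[:, 1] - self["ymin"]) / max(self["ymax"] - self["ymin"], 1e-9)
        return xn, yn

    def noise_kx(self, xy: np.ndarray) -> np.ndarray:
        amp = self.get("noise_amp", 0.0)
        if amp <= 0:
            return np.zeros(len(xy))
        xn, yn = self._scaled(xy)
        m = len(self._noise_kx)
        out = np.zeros(len(xy))
        for qx, qy, phi in self._noise_kx:
            out += np.cos(2 * np.pi * (qx * xn + qy * yn) + phi)
        return amp * out / np.sqrt(m)

    def noise_ky(self, xy: np.ndarray) -> np.ndarray:
        amp = self.get("noise_amp", 0.0)
        if amp <= 0:
            return np.zeros(len(xy))
        _, yn = self._scaled(xy)
        m = len(self._noise_ky)
        out = np.zeros(len(xy))
        for qy, phi in self._noise_ky:
            out += np.cos(2 * np.pi * qy * yn + phi)
        return amp * out / np.sqrt(m)

    def yn(self, xy: np.ndarray) -> np.ndarray:
        return _clip01((xy[:, 1] - self["ymin"]) / (self["ymax"] - self["ymin"]))

    def vm(self, xy: np.ndarray) -> np.ndarray:
        """Normalized mediolateral coordinate: 0 at the medial strip edge,
        1 at the lateral margin (smooth at the saturation corners)."""
        r0 = self["replum_xhalf"]
        span = max(self["xhalf"] - r0, 1e-9)
        w = float(np.clip(1.5 * self.get("diam", 1.0) / span, 1e-3, 0.1))
        return _smooth01((np.abs(xy[:, 0] - self["xmid"]) - r0) / span, w)

    def style_yn(self, xy: np.ndarray) -> np.ndarray:
        span = max(self["ymax"] - self["style_y0"], 1e-9)
        w = float(np.clip(1.0 * self.get("diam", 1.0) / span, 1e-3, 0.1))
        return _smooth01((xy[:, 1] - self["style_y0"]) / span, w)

    def style_weight(self, xy: np.ndarray) -> np.ndarray:
        """Smooth membership in the style region (logistic in y)."""
        return _logistic((xy[:, 1] - self["style_y0"]) / self["style_w"])

    def replum_weight(self, xy: np.ndarray) -> np.ndarray:
        """Smooth membership in the medial (replum) strip (logistic in x)."""
        r0 = self["replum_xhalf"]
        if r0 <= 0:
            return np.zeros(len(xy))
        return _logistic((r0 - np.abs(xy[:, 0] - self["xmid"])) / self["replum_w"])


def _rect(w: float, h: float) -> np.ndarray:
    return np.array([[0.0, 0.0], [w, 0.0], [w, h], [0.0, h]])


# --------------------------------------------------------------------------
# preset parameter tables (all magnitudes are generator choices, not
# measurements; they are reported in the series config)

_DEFAULTS: Dict[str, Dict] = {
    "gynoecium": dict(
        # long, narrow organ: length-dominated growth keeps the
        # distance-from-base field nearly orthogonal to the mediolateral one
        width=48.0, height=120.0, n_cells=140, t_start=4.0, t_end=13.0,
        style_frac=0.75, replum_halfwidth=5.0, base_frac=0.05,
        # valves: longitudinal stretch uniform, mediolateral stretch carries
        # the replum-ward growth gradient during the active window
        valve_ky=0.22, valve_kx=0.05, valve_gradient=0.25,
        gradient_window=(4.0, 8.0),
        # style: fast uniform elongation early, tip-to-base gradient late
        style_ky_early=0.22, style_kx_early=0.05,
        style_ky_late_min=0.05, style_ky_gradient=0.35, style_kx_late=0.05,
        style_onset_start=9.0, style_onset_span=3.5,
        valve_onset_start=6.0, valve_onset_span=3.0,
        replum_kx=0.05, replum_onset=11.5,
        division_area_threshold=180.0, enlargement_rate=0.05,
        stomata_rate=0.35, n_substeps=10, noise_amp=0.02,
    ),
    "valveless": dict(
        width=40.0, height=120.0, n_cells=80, t_start=5.0, t_end=10.0,
        base_frac=0.06, ky_early=0.22, kx=0.06,
        ky_late_min=0.05, ky_gradient=0.30,
        onset_start=7.0, onset_span=4.0,
        division_area_threshold=180.0, enlargement_rate=0.05,
        stomata_rate=0.40, n_substeps=10, noise_amp=0.02,
    ),
    "sepal": dict(
        width=50.0, height=100.0, n_cells=80, t_start=3.0, t_end=8.0,
        base_frac=0.06, ky_early=0.25, kx=0.08,
        ky_late_min=0.05, ky_gradient=0.35,
        onset_start=4.0, onset_span=4.0,
        division_area_threshold=160.0, enlargement_rate=0.05,
        stomata_rate=0.30, n_substeps=10, noise_amp=0.02,
    ),
    "carpelized_sepal": dict(
        width=50.0, height=100.0, n_cells=80, t_start=3.0, t_end=8.0,
        base_frac=0.06, ky=0.15, kx_center=0.05, kx_margin_boost=0.25,
        onset_center=5.0, onset_span=3.0,
        division_area_threshold=160.0, enlargement_rate=0.05,
        stomata_rate=0.30, n_substeps=10, noise_amp=0.02,
    ),
    "split_mutant": dict(
        width=60.0, height=120.0, n_cells=100, t_start=4.0, t_end=9.0,
        split_frac=0.55, replum_halfwidth=4.0, base_frac=0.05,
        distal_ky_early=0.22, distal_ky_min=0.05, distal_ky_gradient=0.25,
        distal_kx=0.06, distal_onset_start=5.0, distal_onset_span=3.0,
        basal_ky=0.14, basal_kx=0.06, basal_kx_gradient=0.15,
        basal_onset_start=7.0, basal_onset_span=2.0,
        division_area_threshold=180.0, enlargement_rate=0.05,
        stomata_rate=0.35, n_substeps=10, noise_amp=0.02,
    ),
}


def _gynoecium_spec(p: Dict, frame: _Frame) -> GrowthFieldSpec:
    g_t0, g_t1 = p["gradient_window"]

    def stretch(xy: np.ndarray, t: float):
        ws = frame.style_weight(xy)
        wr = frame.replum_weight(xy)
        vm = frame.vm(xy)
        # longitudinal: uniform below the style (valves + replum + base)
        if t < p["style_onset_start"]:
            ky_style = np.full(len(xy), p["style_ky_early"])
            kx_style = np.full(len(xy), p["style_kx_early"])
        else:
            ky_style = p["style_ky_late_min"] + p["style_ky_gradient"] * (
                1.0 - frame.style_yn(xy)
            )
            kx_style = np.full(len(xy), p["style_kx_late"])
        ky = ws * ky_style + (1.0 - ws) * p["valve_ky"]
        # mediolateral: replum-ward gradient in the valves during the window;
        # the gradient term fades out one interface-width below the style so
        # it cannot bleed a spurious longitudinal signal into the style
        grad = p["valve_gradient"] if g_t0 <= t < g_t1 else 0.0
        fade = 1.0 - _logistic(
            (xy[:, 1] - (frame["style_y0"] - frame["style_w"])) / frame["style_w"]
        )
        kx_valve = p["valve_kx"] + grad * (1.0 - vm) * fade
        kx_below = wr * p["replum_kx"] + (1.0 - wr) * kx_valve
        kx = ws * kx_style + (1.0 - ws) * kx_below
        return kx, ky

    def onset(xy: np.ndarray) -> np.ndarray:
        ws = frame.style_weight(xy)
        wr = frame.replum_weight(xy)
        tau_style = p["style_onset_start"] + p["style_onset_span"] * (
            1.0 - frame.style_yn(xy)
        )
        tau_valve = p["valve_onset_start"] + p["valve_onset_span"] * (
            1.0 - frame.vm(xy)
        )
        below = wr * p["replum_onset"] + (1.0 - wr) * tau_valve
        return ws * tau_style + (1.0 - ws) * below

    w, h = p["width"], p["height"]

    def region_map(x: float, y: float) -> str:
        yn = y / h
        if yn > p["style_frac"]:
            return "style"
        if abs(x - w / 2) < p["replum_halfwidth"]:
            return "replum"
        if yn < p["base_frac"]:
            return "base"
        return "valve"

    return GrowthFieldSpec(
        domain=_rect(w, h),
        stretch_rates=stretch,
        division_area_threshold=p["division_area_threshold"],
        differentiation_onset=onset,
        enlargement_rate=p["enlargement_rate"],
        stomata_rate=p["stomata_rate"],
        region_map=region_map,
        n_substeps=p["n_substeps"],
    )


def _basipetal_spec(p: Dict, frame: _Frame) -> GrowthFieldSpec:
    """Shared builder for the valveless and sepal presets: one organ-wide
    tip-to-base onset gradient with a matching longitudinal growth
    gradient (carried entirely by the longitudinal stretch rate)."""

    def stretch(xy: np.ndarray, t: float):
        if t < p["onset_start"]:
            ky = np.full(len(xy), p["ky_early"])
        else:
            ky = p["ky_late_min"] + p["ky_gradient"] * (1.0 - frame.yn(xy))
        return np.full(len(xy), p["kx"]), ky

    def onset(xy: np.ndarray) -> np.ndarray:
        return p["onset_start"] + p["onset_span"] * (1.0 - frame.yn(xy))

    w, h = p["width"], p["height"]

    def region_map(x: float, y: float) -> str:
        return "base" if y / h < p["base_frac"] else "none"

    return GrowthFieldSpec(
        domain=_rect(w, h),
        stretch_rates=stretch,
        division_area_threshold=p["division_area_threshold"],
        differentiation_onset=onset,
        enlargement_rate=p["enlargement_rate"],
        stomata_rate=p["stomata_rate"],
        region_map=region_map,
        n_substeps=p["n_substeps"],
    )


def _carpelized_spec(p: Dict, frame: _Frame) -> GrowthFieldSpec:
    def vmarg(xy: np.ndarray) -> np.ndarray:
        return _clip01(np.abs(xy[:, 0] - frame["xmid"]) / max(frame["xhalf"], 1e-9))

    def stretch(xy: np.ndarray, t: float):
        kx = p["kx_center"] + p["kx_margin_boost"] * vmarg(xy)
        return kx, np.full(len(xy), p["ky"])

    def onset(xy: np.ndarray) -> np.ndarray:
        # margin cells differentiate later
        return p["onset_center"] + p["onset_span"] * vmarg(xy)

    w, h = p["width"], p["height"]

    def region_map(x: float, y: float) -> str:
        if y / h < p["base_frac"]:
            return "base"
        return "medial" if abs(x - w / 2) < 0.2 * w else "none"

    return GrowthFieldSpec(
        domain=_rect(w, h),
        stretch_rates=stretch,
        division_area_threshold=p["division_area_threshold"],
        differentiation_onset=onset,
        enlargement_rate=p["enlargement_rate"],
        stomata_rate=p["stomata_rate"],
        region_map=region_map,
        n_substeps=p["n_substeps"],
    )


def _split_mutant_spec(p: Dict, frame: _Frame) -> GrowthFieldSpec:
    sf = p["split_frac"]

    def yn_d(xy: np.ndarray) -> np.ndarray:
        return _clip01((frame.yn(xy) - sf) / (1.0 - sf))

    def stretch(xy: np.ndarray, t: float):
        ws = frame.style_weight(xy)  # distal half is tagged "style"
        wr = frame.replum_weight(xy)
        if t < p["distal_onset_start"]:
            ky_d = np.full(len(xy), p["distal_ky_early"])
        else:
            ky_d = p["distal_ky_min"] + p["distal_ky_gradient"] * (1.0 - yn_d(xy))
        ky = ws * ky_d + (1.0 - ws) * p["basal_ky"]
        kx_b = p["basal_kx"] + p["basal_kx_gradient"] * (1.0 - frame.vm(xy))
        kx_below = wr * 0.0 + (1.0 - wr) * kx_b
        kx = ws * p["distal_kx"] + (1.0 - ws) * kx_below
        return kx, ky

    def onset(xy: np.ndarray) -> np.ndarray:
        ws = frame.style_weight(xy)
        tau_d = p["distal_onset_start"] + p["distal_onset_span"] * (1.0 - yn_d(xy))
        tau_b = p["basal_onset_start"] + p["basal_onset_span"] * (1.0 - frame.vm(xy))
        return ws * tau_d + (1.0 - ws) * tau_b

    w, h = p["width"], p["height"]

    def region_map(x: float, y: float) -> str:
        yn = y / h
        if yn > sf:
            return "style"
        if abs(x - w / 2) < p["replum_halfwidth"]:
            return "replum"
        if yn < p["base_frac"]:
            return "base"
        return "valve"

    return GrowthFieldSpec(
        domain=_rect(w, h),
        stretch_rates=stretch,
        division_area_threshold=p["division_area_threshold"],
        differentiation_onset=onset,
        enlargement_rate=p["enlargement_rate"],
        stomata_rate=p["stomata_rate"],
        region_map=region_map,
        n_substeps=p["n_substeps"],
    )


_BUILDERS: Dict[str, Callable[[Dict, _Frame], GrowthFieldSpec]] = {
    "gynoecium": _gynoecium_spec,
    "valveless": _basipetal_spec,
    "sepal": _basipetal_spec,
    "carpelized_sepal": _carpelized_spec,
    "split_mutant": _split_mutant_spec,
}

SCENARIOS = tuple(sorted(_DEFAULTS))


def scenario(
    name: str,
    overrides: Optional[Dict] = None,
    seed: int = 0,
) -> SimulationSeries:
    """Run a named preset and return its daily series with ground truth.

    ``overrides`` may replace any entry of the preset's parameter table
    (e.g. ``{"n_cells": 40, "t_end": 8.0}``). All randomness derives from
    ``seed`` via a spawned seed sequence (one child per day plus one for the
    initial tessellation), so identical calls are bit-reproducible.
    """
    if name not in _DEFAULTS:
        raise ValueError(
            f"unknown scenario {name!r}; available presets: {', '.join(SCENARIOS)}"
        )
    params = dict(_DEFAULTS[name])
    unknown = set(overrides or {}) - set(params)
    if unknown:
        raise ValueError(f"unknown override keys for {name!r}: {sorted(unknown)}")
    params.update(overrides or {})

    frame = _Frame()
    spec = _BUILDERS[name](params, frame)

    # overlay the daily growth-variability field on the preset's rates
    base_stretch = spec.stretch_rates

    def noisy_stretch(xy, t):
        kx, ky = base_stretch(xy, t)
        return kx + frame.noise_kx(xy), ky + frame.noise_ky(xy)

    spec.stretch_rates = noisy_stretch

    n_days = int(round(params["t_end"] - params["t_start"]))
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_days + 1)

    snap = make_initial_tissue(
        params["n_cells"],
        spec.domain,
        seed=int(children[0].generate_state(1)[0]),
        region_map=spec.region_map,
        time_dai=params["t_start"],
    )
    snapshots = [snap]
    lineages: List[LineageMap] = []
    gt_tables: List[pd.DataFrame] = []
    for k in range(n_days):
        frame.update_from(snap)
        day_seeds = children[k + 1].spawn(2)
        frame.set_noise(
            np.random.default_rng(day_seeds[1]), params.get("noise_amp", 0.0)
        )
        snap, lin, gt = step(
            snap, spec, 1.0, seed=int(day_seeds[0].generate_state(1)[0])
        )
        snapshots.append(snap)
        lineages.append(lin)
        gt_tables.append(gt)

    ground_truth = (
        pd.concat(gt_tables, ignore_index=True)
        if gt_tables
        else pd.DataFrame()
    )
    config = {"scenario": name, "seed": seed, **params}
    config["gradient_window"] = list(params.get("gradient_window", []) or [])
    return SimulationSeries(
        name=name,
        snapshots=snapshots,
        lineages=lineages,
        ground_truth=ground_truth,
        config=config,
    )
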