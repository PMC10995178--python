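"""Prescribed growth/differentiation fields driving the simulator.

All field callables are vectorized: they receive an ``(n, 2)`` array of
positions (µm) and return arrays of length ``n``. Rates are exponential
rates per day.

Two ways to prescribe the growth kinematics:

* ``stretch_rates`` — axis-aligned principal stretch rates
  ``(positions, t) -> (kx, ky)``. Vertices then move through the separable
  velocity field

      Vx(x, y) = ∫_{x0}^{x} kx(s, y) ds,   Vy(x, y) = ∫_{y0}^{y} ky(x, s) ds

  whose diagonal velocity-gradient entries are *exactly* the local ``kx``
  and ``ky`` (so the local area rate is exactly ``kx + ky``); off-diagonal
  shear only arises from transverse variation of the rates. This is the
  scheme used by all scenario presets.

* ``areal_rate`` + ``anisotropy`` — a relative area growth rate and an
  anisotropy ``(ratio >= 1, unit direction)``, combined into the local
  tensor ``L = k1 d dᵀ + k2 d⊥ d⊥ᵀ`` with ``k1 + k2 = rate`` and
  ``k1 − k2 = log(ratio)``, and integrated along rays from a fixed anchor:

      V(x) = ∫₀¹ L(x₀ + s (x − x₀)) · (x − x₀) ds

  (exact for spatially uniform fields). Use this for arbitrary,
  non-axis-aligned direction fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np
from numpy.polynomial.legendre import leggauss

__all__ = ["GrowthFieldSpec", "uniform_rate", "uniform_anisotropy", "uniform_stretch"]

ArrayField = Callable[[np.ndarray, float], np.ndarray]
AnisoField = Callable[[np.ndarray, float], Tuple[np.ndarray, np.ndarray]]
StretchField = Callable[[np.ndarray, float], Tuple[np.ndarray, np.ndarray]]


def uniform_rate(rate: float) -> ArrayField:
    def f(xy: np.ndarray, t: float) -> np.ndarray:
        return np.full(len(xy), float(rate))

    return f


def uniform_anisotropy(ratio: float = 1.0, angle: float = 0.0) -> AnisoField:
    d = np.array([np.cos(angle), np.sin(angle)])

    def f(xy: np.ndarray, t: float) -> Tuple[np.ndarray, np.ndarray]:
        return np.full(len(xy), float(ratio)), np.tile(d, (len(xy), 1))

    return f


def uniform_stretch(kx: float, ky: float) -> StretchField:
    def f(xy: np.ndarray, t: float) -> Tuple[np.ndarray, np.ndarray]:
        return np.full(len(xy), float(kx)), np.full(len(xy), float(ky))

    return f


@dataclass
class GrowthFieldSpec:
    """Full prescription of a growing-tissue scenario.

    Parameters
    ----------
    domain
        Organ outline polygon at the initial time, ``(n, 2)`` µm.
    areal_rate
        ``(positions, t) -> rate`` relative area growth per day (>= 0).
        May be omitted when ``stretch_rates`` is given.
    anisotropy
        ``(positions, t) -> (ratio >= 1, unit directions (n, 2))``; only
        used with ``areal_rate``.
    stretch_rates
        ``(positions, t) -> (kx, ky)`` axis-aligned stretch rates per day;
        takes precedence over ``areal_rate``/``anisotropy``.
    division_area_threshold
        Cells above this area (µm²) divide, unless differentiated.
    differentiation_onset
        ``positions -> τ`` (days); at ``t >= τ`` a local cell stops
        proliferating and begins enlarging.
    enlargement_rate
        Extra areal rate (per day) added where ``t >= τ``; models the cell
        enlargement accompanying differentiation. Applied to the
        mediolateral stretch under the separable scheme (keeps shear from
        longitudinal accumulation bounded), isotropically otherwise.
    stomata_rate
        Probability per differentiated cell per day of conversion to a
        stoma; suppressed next to an existing stoma (one-cell spacing).
    region_map
        Optional ``(x, y) -> region tag`` for the initial tissue.
    n_substeps
        Sub-steps per day used to integrate the growth map.
    """

    domain: np.ndarray
    areal_rate: Optional[ArrayField] = None
    anisotropy: AnisoField = field(default_factory=uniform_anisotropy)
    stretch_rates: Optional[StretchField] = None
    division_area_threshold: float = np.inf
    differentiation_onset: Optional[Callable[[np.ndarray], np.ndarray]] = None
    enlargement_rate: float = 0.0
    stomata_rate: float = 0.0
    region_map: Optional[Callable[[float, float], str]] = None
    seed: int = 0
    n_substeps: int = 10
    anchor: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.areal_rate is None and self.stretch_rates is None:
            raise ValueError("provide areal_rate or stretch_rates")
        if self.anchor is None:
            self.anchor = np.asarray(self.domain, dtype=float).mean(axis=0)

    # -- separable scheme ---------------------------------------------------

    def _enlargement(self, xy: np.ndarray, t: float) -> np.ndarray:
        if self.differentiation_onset is None or not self.enlargement_rate:
            return np.zeros(len(xy))
        tau = np.asarray(self.differentiation_onset(xy), dtype=float)
        # one-sided smoothstep over one day: exactly zero before onset (no
        # pre-onset leakage into gradient statistics), C1-smooth across the
        # moving differentiation front so the velocity field stays regular
        s = np.clip(t - tau, 0.0, 1.0)
        return self.enlargement_rate * s * s * (3.0 - 2.0 * s)

    def effective_stretch(self, xy: np.ndarray, t: float) -> Tuple[np.ndarray, np.ndarray]:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        kx, ky = self.stretch_rates(xy, t)  # type: ignore[misc]
        kx = np.asarray(kx, dtype=float) + self._enlargement(xy, t)
        return kx, np.asarray(ky, dtype=float)

    # -- radial (general-direction) scheme ----------------------------------

    def effective_rate(self, xy: np.ndarray, t: float) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        if self.stretch_rates is not None:
            kx, ky = self.effective_stretch(xy, t)
            return kx + ky
        r = np.asarray(self.areal_rate(xy, t), dtype=float)  # type: ignore[misc]
        if np.any(r < -1e-12):
            raise ValueError("areal_rate must be >= 0 everywhere")
        return r + self._enlargement(xy, t)

    def velocity_gradient(self, xy: np.ndarray, t: float) -> np.ndarray:
        """Local tensor L(x) as an ``(n, 2, 2)`` array."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        if self.stretch_rates is not None:
            kx, ky = self.effective_stretch(xy, t)
            L = np.zeros((len(xy), 2, 2))
            L[:, 0, 0] = kx
            L[:, 1, 1] = ky
            return L
        r = self.effective_rate(xy, t)
        ratio, d = self.anisotropy(xy, t)
        ratio = np.asarray(ratio, dtype=float)
        if np.any(ratio < 1 - 1e-9):
            raise ValueError("anisotropy ratio must be >= 1")
        d = np.asarray(d, dtype=float)
        d = d / np.linalg.norm(d, axis=1, keepdims=True)
        la = np.log(ratio)
        k1 = 0.5 * (r + la)
        k2 = 0.5 * (r - la)
        dd = d[:, :, None] * d[:, None, :]
        perp = np.stack([-d[:, 1], d[:, 0]], axis=1)
        pp = perp[:, :, None] * perp[:, None, :]
        return k1[:, None, None] * dd + k2[:, None, None] * pp

    def velocity(
        self, xy: np.ndarray, t: float, n_gauss: int = 6, n_segments: int = 12
    ) -> np.ndarray:
        """Velocity field V(x) by composite Gauss–Legendre integration.

        The separable scheme uses ``n_segments`` panels of ``n_gauss`` nodes
        per coordinate line, so interface features a small fraction of the
        integration range wide are still resolved accurately.
        """
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        nodes, weights = leggauss(n_gauss)
        x0 = self.anchor

        if self.stretch_rates is not None:
            # composite panels on [0, 1]
            edges = np.linspace(0.0, 1.0, n_segments + 1)
            s_all = np.concatenate(
                [
                    e0 + 0.5 * (nodes + 1.0) * (e1 - e0)
                    for e0, e1 in zip(edges[:-1], edges[1:])
                ]
            )
            w_all = np.concatenate(
                [0.5 * weights * (e1 - e0) for e0, e1 in zip(edges[:-1], edges[1:])]
            )
            dx = xy[:, 0] - x0[0]
            dy = xy[:, 1] - x0[1]
            vx = np.zeros(len(xy))
            vy = np.zeros(len(xy))
            for si, wi in zip(s_all, w_all):
                px = np.column_stack([x0[0] + si * dx, xy[:, 1]])
                py = np.column_stack([xy[:, 0], x0[1] + si * dy])
                kx, _ = self.effective_stretch(px, t)
                _, ky = self.effective_stretch(py, t)
                vx += wi * kx * dx
                vy += wi * ky * dy
            return np.column_stack([vx, vy])

        s = 0.5 * (nodes + 1.0)
        w = 0.5 * weights
        dxy = xy - x0
        v = np.zeros_like(dxy)
        for si, wi in zip(s, w):
            L = self.velocity_gradient(x0 + si * dxy, t)
            v += wi * np.einsum("nij,nj->ni", L, dxy)
        return v
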