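"""Sensitivity sweeps, distance-noise studies, and pairwise distance landscapes.

These studies characterise the noisy objective around a fitted optimum: how
strongly each parameter moves the distance (sensitivity), how wide the band
of distances is for a fixed parameter set as a function of the number of
model realisations (noise), and what the surface looks like for pairs of
parameters (landscape).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .distance import evaluate_distance
from .errors import ValidationError
from .fitting import FitBounds, default_bounds, get_parameter, set_parameter
from .params import SystemParameters
from .protocols import ProtocolConfig

__all__ = [
    "SweepRow",
    "SweepTable",
    "sensitivity_sweep",
    "distance_noise_study",
    "LandscapeResult",
    "landscape",
]

DEFAULT_DELTAS = (-0.10, -0.05, -0.01, 0.01, 0.05, 0.10)

#: Convention for the "optimal region": parameter sets whose distance lies
#: within this relative margin of the observed minimum are indistinguishable
#: given the distance noise.
OPTIMAL_REGION_RELATIVE = 0.02


def _spawn_seeds(seed, n):
    root = np.random.SeedSequence(int(seed))
    return [int(c.generate_state(1)[0] >> 1) for c in root.spawn(n)]


@dataclass
class SweepRow:
    """Distance samples for one (parameter, relative delta) perturbation."""

    parameter: str | None          # None marks the unperturbed baseline row
    delta: float
    value: float | None
    distances: np.ndarray
    skipped: bool = False
    reason: str = ""


@dataclass
class SweepTable:
    rows: list[SweepRow] = field(default_factory=list)

    def row(self, parameter, delta) -> SweepRow:
        for r in self.rows:
            if r.parameter == parameter and r.delta == delta:
                return r
        raise KeyError((parameter, delta))

    @property
    def baseline(self) -> SweepRow:
        return self.row(None, 0.0)

    def to_frame(self):
        import pandas as pd

        records = []
        for r in self.rows:
            name = r.parameter if r.parameter is not None else "baseline"
            if r.skipped:
                records.append((name, r.delta, r.value, None, np.nan))
            else:
                for i, d in enumerate(r.distances):
                    records.append((name, r.delta, r.value, i, d))
        return pd.DataFrame(records, columns=["parameter", "delta", "value",
                                              "replicate", "distance"])


def sensitivity_sweep(params: SystemParameters, data,
                      deltas: Sequence[float] = DEFAULT_DELTAS,
                      parameters: Sequence[str] | None = None,
                      n_sets: int = 10, n_realisations: int = 100, seed: int = 0,
                      protocol: ProtocolConfig | None = None,
                      bounds: FitBounds | None = None,
                      n_jobs: int = 1) -> SweepTable:
    """One-at-a-time relative perturbations of each parameter.

    For every parameter and relative delta, the distance is evaluated
    ``n_sets`` times with fresh seeds, the other parameters held at
    ``params``.  A baseline row (delta 0, all parameters unperturbed) is
    always included.  Perturbations leaving the bounds are recorded as
    skipped rather than failing the sweep.
    """
    if not deltas:
        raise ValidationError("deltas must not be empty")
    bounds = bounds or default_bounds(params)
    names = list(parameters) if parameters else ["mu_S", "mu_M", "mu_F", "mu_P", "N"]
    table = SweepTable()

    def band(p, s):
        seeds = _spawn_seeds(s, n_sets)
        return np.array([evaluate_distance(p, data, protocol, n_realisations,
                                           sd, n_jobs=n_jobs).combined
                         for sd in seeds])

    table.rows.append(SweepRow(None, 0.0, None, band(params, seed)))
    for k, name in enumerate(names):
        x = get_parameter(params, name)
        for delta in deltas:
            value = x * (1 + delta)
            b = bounds[name]
            if not (b.lower <= value <= b.upper):
                table.rows.append(SweepRow(name, delta, value, np.empty(0), skipped=True,
                                           reason=f"{value:g} outside [{b.lower:g}, {b.upper:g}]"))
                continue
            perturbed = set_parameter(params, name, b.clip(value))
            row_seed = seed + 1000003 * (k + 1) + round(1e6 * delta) % 997
            table.rows.append(SweepRow(name, delta, value, band(perturbed, row_seed)))
    return table


def distance_noise_study(params: SystemParameters, data,
                         n_realisations: Sequence[int] = (100, 1000),
                         n_repeats: int = 500, seed: int = 0,
                         protocol: ProtocolConfig | None = None,
                         n_jobs: int = 1) -> dict[int, np.ndarray]:
    """Band of combined distances at fixed parameters vs realisation count.

    Repeats the distance evaluation ``n_repeats`` times for each entry of
    ``n_realisations``; larger samples of model realisations produce a
    narrower band (smaller max-min spread), at proportionally higher cost.
    """
    out = {}
    for j, n in enumerate(n_realisations):
        seeds = _spawn_seeds(seed + 7919 * j, n_repeats)
        out[int(n)] = np.array([
            evaluate_distance(params, data, protocol, int(n), sd, n_jobs=n_jobs).combined
            for sd in seeds])
    return out


@dataclass
class LandscapeResult:
    """Distance matrix over a pairwise parameter grid."""

    parameters: tuple[str, str]
    axis_values: tuple[np.ndarray, np.ndarray]
    distances: np.ndarray          # shape (len(axis0), len(axis1))
    centre: SystemParameters
    warnings: list = field(default_factory=list)

    def minimum(self):
        i, j = np.unravel_index(np.argmin(self.distances), self.distances.shape)
        return (self.axis_values[0][i], self.axis_values[1][j], self.distances[i, j])

    def optimal_region(self, relative: float = OPTIMAL_REGION_RELATIVE) -> np.ndarray:
        """Boolean mask of cells within ``relative`` of the grid minimum."""
        lo = self.distances.min()
        return self.distances <= lo * (1 + relative)


def landscape(params: SystemParameters, data, parameter_pair: Sequence[str],
              range_fraction: float = 0.9, grid_shape: Sequence[int] = (11, 11),
              n_realisations: int = 100, seed: int = 0,
              protocol: ProtocolConfig | None = None,
              bounds: FitBounds | None = None,
              n_jobs: int = 1) -> LandscapeResult:
    """Pairwise distance landscape around ``params``.

    The two listed parameters are varied over ``centre*(1 +- range_fraction)``
    on a ``grid_shape`` grid (clipped to bounds with a warning record), all
    other parameters fixed.  A ``(g, 1)`` grid gives a single-parameter
    profile; ``(1, 1)`` a single evaluation at ``params``.
    """
    p0, p1 = parameter_pair
    if p0 == p1:
        raise ValidationError("parameter_pair must name two distinct parameters")
    if not (0 < range_fraction < 1):
        raise ValidationError("range_fraction must lie in (0, 1)")
    bounds = bounds or default_bounds(params)
    warnings = []
    axes = []
    for name, g in zip((p0, p1), grid_shape):
        x = get_parameter(params, name)
        if g == 1:
            axes.append(np.array([x]))
            continue
        lo, hi = x * (1 - range_fraction), x * (1 + range_fraction)
        b = bounds[name]
        if lo < b.lower or hi > b.upper:
            warnings.append(f"{name}: range [{lo:g}, {hi:g}] clipped to "
                            f"[{b.lower:g}, {b.upper:g}]")
        axes.append(np.linspace(max(lo, b.lower), min(hi, b.upper), int(g)))
    seeds = iter(_spawn_seeds(seed, len(axes[0]) * len(axes[1])))
    dist = np.empty((len(axes[0]), len(axes[1])))
    for i, v0 in enumerate(axes[0]):
        for j, v1 in enumerate(axes[1]):
            p = set_parameter(set_parameter(params, p0, v0), p1, v1)
            dist[i, j] = evaluate_distance(p, data, protocol, n_realisations,
                                           next(seeds), n_jobs=n_jobs).combined
    return LandscapeResult((p0, p1), (axes[0], axes[1]), dist, params, warnings)
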