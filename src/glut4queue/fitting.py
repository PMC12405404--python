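"""Line-search parameter inference for the vesicle-trafficking network.

The objective is the hierarchical Wasserstein distance of
:func:`glut4queue.distance.evaluate_distance`, which is noisy: every
evaluation simulates a fresh finite sample of model realisations.  The fitter
is a cyclic coordinate descent.  Each coordinate (a service rate, the
population ``N``, or one activation probability) is minimised by a pattern
line search: probe one step either side of the current point, march while the
objective improves, halve the step otherwise, and stop once the step falls
below the coordinate's tolerance (1e-6 by default; 1000 for the
integer-valued ``N``).  The fit terminates when a full cycle moves every
coordinate by less than its tolerance.

Fresh evaluation seeds per point reproduce the banded, noise-limited
behaviour seen when fitting stochastic simulators; an optional
common-random-numbers mode reuses one seed for every evaluation, giving a
deterministic surrogate surface that is easier to search and to test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .distance import evaluate_distance
from .errors import ValidationError
from .params import SystemParameters
from .protocols import ProtocolConfig

__all__ = [
    "ParameterBound",
    "FitBounds",
    "FitConfig",
    "FitResult",
    "default_bounds",
    "line_search_fit",
    "grid_refine",
    "get_parameter",
    "set_parameter",
    "parameter_names",
]


# ------------------------------------------------------------- param access


def parameter_names(params: SystemParameters, include_N: bool = True) -> list[str]:
    """Canonical fit-parameter names: rates, N, and one ``p(level)`` per level."""
    names = ["mu_S", "mu_M", "mu_F", "mu_P"]
    if include_N:
        names.append("N")
    names += [f"p({lvl:g})" for lvl in params.insulin_levels]
    return names


def get_parameter(params: SystemParameters, name: str) -> float:
    if name.startswith("p(") and name.endswith(")"):
        return params.active_prob[float(name[2:-1])]
    if name in ("mu_S", "mu_M", "mu_F", "mu_P", "N"):
        return float(getattr(params, name))
    raise ValidationError(f"unknown fit parameter {name!r}")


def set_parameter(params: SystemParameters, name: str, value: float) -> SystemParameters:
    if name.startswith("p(") and name.endswith(")"):
        return params.with_active_prob(float(name[2:-1]), value)
    if name == "N":
        return params.replace(N=int(round(value)))
    if name in ("mu_S", "mu_M", "mu_F", "mu_P"):
        return params.replace(**{name: float(value)})
    raise ValidationError(f"unknown fit parameter {name!r}")


# ------------------------------------------------------------------ bounds


@dataclass(frozen=True)
class ParameterBound:
    """Box bound and step tolerance for one fit parameter."""

    lower: float
    upper: float
    tolerance: float = 1e-6   # smallest step before the coordinate terminates
    integer: bool = False

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValidationError("lower bound exceeds upper bound")
        if self.tolerance <= 0:
            raise ValidationError("step tolerance must be positive")

    def clip(self, value: float) -> float:
        v = min(max(value, self.lower), self.upper)
        return float(round(v)) if self.integer else float(v)


@dataclass(frozen=True)
class FitBounds:
    """Per-parameter bounds; unknown names fall back to class defaults."""

    bounds: dict

    def __getitem__(self, name: str) -> ParameterBound:
        if name in self.bounds:
            return self.bounds[name]
        raise ValidationError(f"no bound configured for parameter {name!r}")

    def __contains__(self, name):
        return name in self.bounds

    def check_start(self, params: SystemParameters, names: Sequence[str]) -> None:
        for name in names:
            b = self[name]
            v = get_parameter(params, name)
            if not (b.lower <= v <= b.upper):
                raise ValidationError(
                    f"start value {v:g} for {name} outside bounds [{b.lower:g}, {b.upper:g}]")


def default_bounds(params: SystemParameters) -> FitBounds:
    """Standard fitting bounds: rates >= 1e-6 (no upper bound), activation
    probabilities in [0.01, 1] with step tolerance 1e-6, and the integer
    population N in [25000, 100000] with a minimum step of 1000."""
    b = {name: ParameterBound(1e-6, math.inf) for name in ("mu_S", "mu_M", "mu_F", "mu_P")}
    b["N"] = ParameterBound(25000, 100000, tolerance=1000, integer=True)
    for lvl in params.insulin_levels:
        b[f"p({lvl:g})"] = ParameterBound(0.01, 1.0)
    return FitBounds(b)


# ------------------------------------------------------------------ config


@dataclass(frozen=True)
class FitConfig:
    """Optimiser settings.

    ``objective`` overrides the simulation objective with any callable
    ``f(params, seed) -> float`` (e.g. a deterministic convex surrogate for
    testing the search machinery).  ``common_random_numbers`` reuses one
    evaluation seed throughout, removing distance noise at the cost of a
    slightly biased surface.
    """

    parameters: Sequence[str] | None = None
    n_realisations: int = 100
    protocol: ProtocolConfig | None = None
    max_evaluations: int | None = None
    max_cycles: int | None = None
    common_random_numbers: bool = False
    initial_step_fraction: float = 0.25
    objective: Callable[[SystemParameters, int], float] | None = None
    n_jobs: int = 1


@dataclass
class FitResult:
    """Fitted parameters, final distance, and the full search trajectory."""

    params: SystemParameters
    distance: float
    trajectory: list = field(default_factory=list)  # (name->value dict, distance, seed)
    termination: str = ""
    n_evaluations: int = 0
    warnings: list = field(default_factory=list)

    def parameter(self, name: str) -> float:
        return get_parameter(self.params, name)


class _Budget(Exception):
    pass


class _Evaluator:
    def __init__(self, data, config: FitConfig, seed):
        self.data = data
        self.config = config
        self._root = np.random.SeedSequence(int(seed))
        self._crn_seed = int(self._root.generate_state(1)[0] >> 1)
        self.count = 0
        self.trajectory = []

    def __call__(self, params: SystemParameters) -> float:
        cfg = self.config
        if cfg.max_evaluations is not None and self.count >= cfg.max_evaluations:
            raise _Budget
        if cfg.common_random_numbers:
            seed = self._crn_seed
        else:
            seed = int(self._root.spawn(1)[0].generate_state(1)[0] >> 1)
        if cfg.objective is not None:
            value = float(cfg.objective(params, seed))
        else:
            value = evaluate_distance(params, self.data, cfg.protocol,
                                      cfg.n_realisations, seed, n_jobs=cfg.n_jobs).combined
        self.count += 1
        self.trajectory.append((params.to_dict(), value, seed))
        return value


# -------------------------------------------------------------- line search


def _search_coordinate(name, params, f_current, evaluate, bound, step0):
    """Pattern line search along one coordinate; returns (params, f, |move|)."""
    x_start = get_parameter(params, name)
    best_x, best_f, best_p = x_start, f_current, params
    step = max(step0, bound.tolerance)
    while step >= bound.tolerance:
        moved = False
        for cand in (best_x + step, best_x - step):
            cand = bound.clip(cand)
            if cand == best_x:
                continue
            p_cand = set_parameter(best_p, name, cand)
            f_cand = evaluate(p_cand)
            if f_cand < best_f:
                best_x, best_f, best_p = cand, f_cand, p_cand
                moved = True
                break
        if not moved:
            step /= 2
    return best_p, best_f, abs(best_x - x_start)


def line_search_fit(data, start: SystemParameters, bounds: FitBounds | None = None,
                    config: FitConfig | None = None, seed: int = 0) -> FitResult:
    """Fit the network parameters to replicated observations.

    Cyclic coordinate descent over ``config.parameters`` (default: the four
    service rates, ``N``, and every activation probability), each coordinate
    minimised by a tolerance-bounded pattern search within ``bounds``.
    Terminates when a full cycle moves every coordinate by less than its
    tolerance ("step_tolerance"), or on the optional evaluation/cycle caps.
    """
    config = config or FitConfig()
    bounds = bounds or default_bounds(start)
    names = list(config.parameters) if config.parameters else parameter_names(start)
    bounds.check_start(start, names)

    evaluate = _Evaluator(data, config, seed)
    termination = "step_tolerance"
    params = start
    try:
        f = evaluate(params)
        cycles = 0
        while True:
            displacements = []
            for name in names:
                b = bounds[name]
                x = get_parameter(params, name)
                step0 = config.initial_step_fraction * max(abs(x), 10 * b.tolerance)
                params, f, moved = _search_coordinate(name, params, f, evaluate, b, step0)
                displacements.append((name, moved))
            cycles += 1
            if all(moved < bounds[name].tolerance for name, moved in displacements):
                break
            if config.max_cycles is not None and cycles >= config.max_cycles:
                termination = "max_cycles"
                break
    except _Budget:
        termination = "max_evaluations"
        # fall back to the best point seen so far
        best = min(evaluate.trajectory, key=lambda rec: rec[1])
        params = SystemParameters.from_dict(best[0])
        f = best[1]

    return FitResult(params=params, distance=f, trajectory=evaluate.trajectory,
                     termination=termination, n_evaluations=evaluate.count)


# ------------------------------------------------------------- grid refine


def grid_refine(data, centre: SystemParameters, fraction: float = 0.5,
                grid_points: int = 3, n_realisations: int = 100, seed: int = 0,
                parameters: Sequence[str] | None = None,
                bounds: FitBounds | None = None,
                config: FitConfig | None = None) -> FitResult:
    """Exhaustive distance evaluation on a grid spanning ``centre +- fraction``.

    Used after a line search terminates, to escape local minima: every listed
    parameter is varied over ``grid_points`` equally spaced values in
    ``[x*(1-fraction), x*(1+fraction)]`` (clipped to bounds, with a warning
    record), the full Cartesian product is evaluated, and the grid minimiser
    is returned.  ``grid_points=1`` degenerates to a single evaluation at the
    centre.
    """
    if not (0 < fraction <= 1):
        raise ValidationError("fraction must lie in (0, 1]")
    if grid_points < 1:
        raise ValidationError("grid_points must be >= 1")
    config = config or FitConfig(n_realisations=n_realisations)
    bounds = bounds or default_bounds(centre)
    names = list(parameters) if parameters else parameter_names(centre)

    warnings = []
    axes = []
    for name in names:
        x = get_parameter(centre, name)
        if grid_points == 1:
            axes.append([x])
            continue
        lo, hi = x * (1 - fraction), x * (1 + fraction)
        b = bounds[name]
        if lo < b.lower or hi > b.upper:
            warnings.append(f"{name}: grid [{lo:g}, {hi:g}] clipped to "
                            f"[{b.lower:g}, {b.upper:g}]")
        values = np.linspace(max(lo, b.lower), min(hi, b.upper), grid_points)
        if b.integer:
            values = np.unique(np.round(values))
        axes.append(list(values))

    evaluate = _Evaluator(data, config, seed)
    best_params, best_f = None, math.inf
    try:
        for combo in itertools.product(*axes):
            p = centre
            for name, value in zip(names, combo):
                p = set_parameter(p, name, value)
            f = evaluate(p)
            if f < best_f:
                best_params, best_f = p, f
    except _Budget:
        pass
    return FitResult(params=best_params, distance=best_f,
                     trajectory=evaluate.trajectory, termination="grid",
                     n_evaluations=evaluate.count, warnings=warnings)
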