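"""Simulated transition and uptake assay protocols.

A *transition* experiment holds cells at basal insulin until stationary,
steps the insulin level at protocol time zero, and reads the plasma-membrane
vesicle count on a fixed sample grid.  An *uptake* experiment additionally
lets the stepped system equilibrate, then permanently tags every vesicle on
its first visit to the membrane (vesicles already there count as tagged at
time zero) and reads the cumulative tag count.  Traces are normalised to the
across-realisation mean at the final sample time of the maximal-insulin
(reference) experiment of the same kind, mirroring the plate-assay
normalisation of the data these protocols emulate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateSampleError, ValidationError
from .network import QueueNetwork
from .params import SystemParameters

__all__ = [
    "ProtocolConfig",
    "ExperimentTrace",
    "ModelSample",
    "run_transition",
    "run_uptake",
    "run_realisation",
    "run_protocol_suite",
    "normalise",
    "restrict_protocol",
]

_DEFAULT_TRANSITION_TIMES = (0.0, 0.5, 1, 2, 5, 10, 15, 20, 25, 30, 45, 60)
_DEFAULT_UPTAKE_TIMES = (0.0, 2, 5, 10, 20, 30, 60, 90, 120, 180, 240, 300)


def _check_grid(name, times):
    arr = tuple(float(t) for t in times)
    if not arr:
        raise ValidationError(f"{name} must not be empty")
    if arr[0] < 0 or any(b <= a for a, b in zip(arr, arr[1:])):
        raise ValidationError(f"{name} must be non-negative and strictly increasing")
    return arr


@dataclass(frozen=True)
class ProtocolConfig:
    """Warm-up schedule, sample grids, and insulin panels for the assay suite.

    Durations are minutes.  ``warm_up`` is the basal equilibration before the
    insulin step; ``equilibration`` is the post-step settling period before an
    uptake measurement starts.  The defaults reproduce the standard assay
    design: 4 transition levels x 12 times and 9 uptake levels x 12 times,
    with 100 nM as the normalisation reference.
    """

    warm_up: float = 500.0
    equilibration: float = 500.0
    transition_times: Sequence[float] = _DEFAULT_TRANSITION_TIMES
    uptake_times: Sequence[float] = _DEFAULT_UPTAKE_TIMES
    transition_levels: Sequence[float] = (0.3, 3.0, 30.0, 100.0)
    uptake_levels: Sequence[float] = (0.0, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0)
    reference_insulin: float = 100.0
    trace_increment: float = 0.5

    def __post_init__(self):
        if self.warm_up < 0 or self.equilibration < 0:
            raise ValidationError("warm_up and equilibration must be non-negative")
        object.__setattr__(self, "transition_times", _check_grid("transition_times", self.transition_times))
        object.__setattr__(self, "uptake_times", _check_grid("uptake_times", self.uptake_times))
        object.__setattr__(self, "transition_levels", tuple(float(x) for x in self.transition_levels))
        object.__setattr__(self, "uptake_levels", tuple(float(x) for x in self.uptake_levels))
        ref = float(self.reference_insulin)
        object.__setattr__(self, "reference_insulin", ref)
        if self.transition_levels and ref not in self.transition_levels:
            raise ValidationError("reference_insulin must appear in transition_levels")
        if ref not in self.uptake_levels:
            raise ValidationError("reference_insulin must appear in uptake_levels")
        if self.trace_increment <= 0:
            raise ValidationError("trace_increment must be positive")

    @property
    def experiments(self) -> tuple[tuple[str, float], ...]:
        """All configured (kind, insulin) pairs, transition first."""
        return tuple(("transition", lvl) for lvl in self.transition_levels) + tuple(
            ("uptake", lvl) for lvl in self.uptake_levels
        )


@dataclass
class ExperimentTrace:
    """One realisation's sampled time series for one protocol at one insulin level."""

    kind: str                      # "transition" | "uptake"
    insulin: float                 # nM
    realisation: int
    times: np.ndarray              # minutes, protocol grid
    raw: np.ndarray                # vesicle counts
    normalised: np.ndarray | None = None
    fine_times: np.ndarray | None = None
    fine_raw: np.ndarray | None = None

    @property
    def key(self) -> tuple[str, float]:
        return (self.kind, self.insulin)


@dataclass
class ModelSample:
    """A collection of traces over all configured experiments and realisations."""

    traces: list[ExperimentTrace]
    protocol: ProtocolConfig
    n_realisations: int
    seed: int | None = None
    norm_constants: dict = field(default_factory=dict)

    def values(self, kind: str, insulin: float, normalised: bool = True) -> np.ndarray:
        """(n_realisations x n_times) array for one experiment."""
        rows = [tr for tr in self.traces if tr.kind == kind and tr.insulin == float(insulin)]
        rows.sort(key=lambda tr: tr.realisation)
        if not rows:
            raise ValidationError(f"no traces for experiment ({kind}, {insulin} nM)")
        if normalised:
            if rows[0].normalised is None:
                raise ValidationError("sample has not been normalised")
            return np.vstack([tr.normalised for tr in rows])
        return np.vstack([tr.raw for tr in rows])

    def times(self, kind: str) -> np.ndarray:
        grid = self.protocol.transition_times if kind == "transition" else self.protocol.uptake_times
        return np.asarray(grid, dtype=float)

    def to_frame(self):
        """Long-format table: kind, insulin_nM, realisation, time_min, raw, normalised."""
        import pandas as pd

        rows = []
        for tr in self.traces:
            norm = tr.normalised if tr.normalised is not None else [np.nan] * len(tr.times)
            for t, r, v in zip(tr.times, tr.raw, norm):
                rows.append((tr.kind, tr.insulin, tr.realisation, t, r, v))
        return pd.DataFrame(rows, columns=["kind", "insulin_nM", "realisation",
                                           "time_min", "raw_value", "normalised_value"])


def restrict_protocol(protocol: ProtocolConfig, params: SystemParameters) -> ProtocolConfig:
    """Drop insulin levels the parameter set does not define.

    If the reference level is among the dropped ones, the highest remaining
    uptake level becomes the reference (and is added to the transition panel
    if that panel is non-empty).
    """
    levels = set(params.insulin_levels)
    uptake = [l for l in protocol.uptake_levels if l in levels]
    transition = [l for l in protocol.transition_levels if l in levels]
    if not uptake:
        raise ValidationError("parameter set defines none of the protocol's uptake levels")
    ref = protocol.reference_insulin if protocol.reference_insulin in uptake else max(uptake)
    if transition and ref not in transition:
        transition = sorted(set(transition) | {ref})
    return dataclasses.replace(protocol, transition_levels=tuple(transition),
                               uptake_levels=tuple(uptake), reference_insulin=ref)


# --------------------------------------------------------------------- runs


def _sample_counts(net: QueueNetwork, t0: float, times, read, increment=None):
    """Advance through ``t0 + times`` reading ``read(net)`` at each stop.

    With ``increment`` set, the network is also stopped on the fine half-minute
    grid so a high-resolution trace is recorded alongside the assay grid.
    """
    times = np.asarray(times, dtype=float)
    if increment is None:
        out = np.empty(len(times))
        for i, t in enumerate(times):
            net.advance(t0 + t)
            out[i] = read(net)
        return out, None, None
    fine = np.arange(0.0, times[-1] + 0.5 * increment, increment)
    # make sure every assay time is an explicit stop
    stops = np.union1d(fine, times)
    vals = np.empty(len(stops))
    for i, t in enumerate(stops):
        net.advance(t0 + t)
        vals[i] = read(net)
    idx = np.searchsorted(stops, times)
    fidx = np.searchsorted(stops, fine)
    return vals[idx], fine, vals[fidx]


def run_transition(params: SystemParameters, insulin_final: float, protocol: ProtocolConfig | None = None,
                   seed=0, *, realisation: int = 0, network: QueueNetwork | None = None,
                   fine_trace: bool = False, return_network: bool = False):
    """Simulate one transition experiment: basal warm-up, insulin step, sampling.

    The t=0 sample is taken at the instant of the step, i.e. it reads the
    basal steady-state membrane count.  Pass ``return_network=True`` to keep
    the realisation for chaining an uptake measurement.
    """
    protocol = protocol or ProtocolConfig()
    net = network or QueueNetwork(params, seed)
    net._prob(insulin_final)  # fail fast on unknown levels
    net.advance(net.clock + protocol.warm_up)
    t0 = net.clock
    net.set_insulin(insulin_final)
    vals, ftimes, fvals = _sample_counts(
        net, t0, protocol.transition_times, lambda n: n.n_membrane,
        protocol.trace_increment if fine_trace else None)
    trace = ExperimentTrace("transition", float(insulin_final), realisation,
                            np.asarray(protocol.transition_times), vals,
                            fine_times=ftimes, fine_raw=fvals)
    return (trace, net) if return_network else trace


def run_uptake(params: SystemParameters, insulin: float, protocol: ProtocolConfig | None = None,
               seed=0, *, realisation: int = 0, network: QueueNetwork | None = None,
               fine_trace: bool = False, return_network: bool = False):
    """Simulate one uptake experiment at fixed insulin.

    Standalone mode (no ``network``): basal warm-up, insulin step, a settling
    period of ``protocol.equilibration`` minutes, then tag-and-count.  With a
    chained ``network`` (from :func:`run_transition`), the same realisation
    continues: the step already happened at the end of warm-up, and sampling
    starts once ``equilibration`` minutes have elapsed since the step.
    Cumulative tag counts are non-decreasing by construction; the t=0 value is
    the membrane occupancy at uptake start.
    """
    protocol = protocol or ProtocolConfig()
    if network is None:
        net = QueueNetwork(params, seed)
        net._prob(insulin)
        net.advance(protocol.warm_up)
        net.set_insulin(insulin)
        start = net.clock + protocol.equilibration
    else:
        net = network
        if net.insulin != float(insulin):
            raise ValidationError(
                f"chained network is at {net.insulin} nM, expected {insulin} nM")
        start = protocol.warm_up + protocol.equilibration
        if net.clock > start:
            raise ValidationError("chained network has advanced past the uptake start")
    net.advance(start)
    net.clear_tags()
    vals, ftimes, fvals = _sample_counts(
        net, start, protocol.uptake_times, lambda n: n.n_tagged,
        protocol.trace_increment if fine_trace else None)
    trace = ExperimentTrace("uptake", float(insulin), realisation,
                            np.asarray(protocol.uptake_times), vals,
                            fine_times=ftimes, fine_raw=fvals)
    return (trace, net) if return_network else trace


def run_realisation(params: SystemParameters, protocol: ProtocolConfig, seed,
                    realisation: int = 0) -> list[ExperimentTrace]:
    """One model 'repeat': every configured experiment, one realisation each.

    Each insulin level runs on its own network (insulin never decreases
    within a realisation).  Levels with both a transition and an uptake
    experiment share a network: the uptake continues from the transition
    end-state after the post-step equilibration, matching the sequential
    assay schedule.
    """
    if isinstance(seed, np.random.SeedSequence):
        root = seed
    else:
        root = np.random.SeedSequence(int(seed))
    levels = sorted(set(protocol.transition_levels) | set(protocol.uptake_levels))
    children = root.spawn(len(levels))
    traces: list[ExperimentTrace] = []
    for level, child in zip(levels, children):
        in_trans = level in protocol.transition_levels
        in_upt = level in protocol.uptake_levels
        if in_trans:
            trace, net = run_transition(params, level, protocol, child,
                                        realisation=realisation, return_network=True)
            traces.append(trace)
            if in_upt:
                traces.append(run_uptake(params, level, protocol,
                                         realisation=realisation, network=net))
        elif in_upt:
            traces.append(run_uptake(params, level, protocol, child,
                                     realisation=realisation))
    return traces


def run_protocol_suite(params: SystemParameters, protocol: ProtocolConfig | None = None,
                       n_realisations: int = 100, seed=0, n_jobs: int = 1) -> ModelSample:
    """Run ``n_realisations`` model repeats of the full assay suite.

    Realisation seeds are spawned deterministically from the master seed, so
    the result is reproducible bit-for-bit and realisation-level parallelism
    (``n_jobs``) does not change the output.
    """
    protocol = protocol or ProtocolConfig()
    if n_realisations < 1:
        raise ValidationError("n_realisations must be >= 1")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    children = root.spawn(n_realisations)
    if n_jobs != 1:
        from joblib import Parallel, delayed

        chunks = Parallel(n_jobs=n_jobs)(
            delayed(run_realisation)(params, protocol, child, r)
            for r, child in enumerate(children))
    else:
        chunks = [run_realisation(params, protocol, child, r)
                  for r, child in enumerate(children)]
    traces = [tr for chunk in chunks for tr in chunk]
    master = seed if isinstance(seed, int) else None
    return ModelSample(traces, protocol, n_realisations, seed=master)


# --------------------------------------------------------------- normalise


def normalise(sample: ModelSample, per_realisation: bool = False) -> ModelSample:
    """Normalise a sample to the reference steady state, in place of units.

    Transition traces are divided by the across-realisation mean membrane
    count at the final transition time in reference insulin; uptake traces by
    the mean tag count at the final uptake time in reference insulin.  With
    ``per_realisation=True`` each realisation is divided by its own reference
    value instead of the pooled mean.
    """
    protocol = sample.protocol
    ref = protocol.reference_insulin
    constants = {}
    for kind in ("transition", "uptake"):
        if kind == "transition" and not protocol.transition_levels:
            continue
        raw = sample.values(kind, ref, normalised=False)
        final = raw[:, -1]
        const = final if per_realisation else float(final.mean())
        if np.any(np.asarray(const) == 0):
            raise DegenerateSampleError(
                f"{kind} normalisation constant is zero at {ref} nM")
        constants[kind] = const
    out = dataclasses.replace(sample, traces=list(sample.traces),
                              norm_constants=dict(constants))
    new_traces = []
    for tr in out.traces:
        const = constants[tr.kind]
        c = const[tr.realisation] if per_realisation else const
        new_traces.append(dataclasses.replace(tr, normalised=tr.raw / c))
    out.traces = new_traces
    if per_realisation:
        out.norm_constants = {k: np.asarray(v) for k, v in constants.items()}
    return out
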