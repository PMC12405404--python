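"""Hierarchical Wasserstein-1 distance between model samples and observations.

The discrepancy between the stochastic model and replicated assay data is
built bottom-up: a Wasserstein-1 distance between the realisation values and
the data replicates at each sample time, averaged over the times of an
experiment, and combined across experiments with a Euclidean (L2) norm.  All
experiments and timepoints are weighted equally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, CoverageError, ValidationError
from .params import SystemParameters
from .protocols import ModelSample, ProtocolConfig, normalise, run_protocol_suite

__all__ = [
    "wasserstein1",
    "experiment_distance",
    "combined_distance",
    "DistanceBreakdown",
    "evaluate_distance",
    "sample_distance",
]


def wasserstein1(a, b) -> float:
    """W1 distance between the empirical distributions of two value samples.

    Computed as the area between the two empirical CDFs, which for sorted
    samples reduces to an integral of ``|F_a - F_b|`` over the pooled support.
    Handles unequal sample sizes; symmetric; zero iff the multisets coincide.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValidationError("wasserstein1 requires non-empty samples")
    a = np.sort(a)
    b = np.sort(b)
    support = np.concatenate([a, b])
    support.sort(kind="mergesort")
    deltas = np.diff(support)
    if not deltas.any():
        return 0.0
    cdf_a = np.searchsorted(a, support[:-1], side="right") / a.size
    cdf_b = np.searchsorted(b, support[:-1], side="right") / b.size
    return float(np.sum(np.abs(cdf_a - cdf_b) * deltas))


def experiment_distance(model_values, data_replicates) -> float:
    """Mean over sample times of the per-time W1 distance.

    ``model_values`` is an (n_realisations x n_times) array; ``data_replicates``
    a sequence of replicate-value arrays, one per sample time, on the same
    time grid.
    """
    model_values = np.atleast_2d(np.asarray(model_values, dtype=float))
    if model_values.shape[1] != len(data_replicates):
        raise AlignmentError(
            f"model has {model_values.shape[1]} sample times but data has "
            f"{len(data_replicates)}")
    per_time = [wasserstein1(model_values[:, j], data_replicates[j])
                for j in range(model_values.shape[1])]
    return float(np.mean(per_time))


def combined_distance(per_experiment, expected_count: int | None = None) -> float:
    """Euclidean norm of the per-experiment distance vector."""
    values = np.asarray(
        list(per_experiment.values()) if isinstance(per_experiment, dict) else per_experiment,
        dtype=float)
    if expected_count is not None and values.size != expected_count:
        raise ValidationError(
            f"expected {expected_count} experiment distances, got {values.size}")
    if np.any(values < 0):
        raise ValidationError("experiment distances must be non-negative")
    return float(np.linalg.norm(values))


@dataclass(frozen=True)
class DistanceBreakdown:
    """Per-experiment and combined distances from one (stochastic) evaluation."""

    per_experiment: dict
    combined: float
    n_realisations: int
    seed: int | None


def sample_distance(sample: ModelSample, data) -> DistanceBreakdown:
    """Hierarchical distance between an already-normalised sample and data."""
    protocol = sample.protocol
    per_exp = {}
    available = set(data.experiments())
    for kind, level in protocol.experiments:
        if (kind, level) not in available:
            raise CoverageError(f"observations missing experiment ({kind}, {level:g} nM)")
        grid = sample.times(kind)
        data_times = data.times(kind, level)
        missing = sorted(set(np.round(data_times, 9)) - set(np.round(grid, 9)))
        if missing:
            raise AlignmentError(
                f"data times absent from the model grid for ({kind}, {level:g} nM): {missing}",
                missing_times=missing)
        model = sample.values(kind, level)
        cols = np.searchsorted(grid, data_times)
        reps = [data.replicates(kind, level, t) for t in data_times]
        per_exp[(kind, level)] = experiment_distance(model[:, cols], reps)
    return DistanceBreakdown(per_exp, combined_distance(per_exp), sample.n_realisations,
                             sample.seed)


def evaluate_distance(params: SystemParameters, data, protocol: ProtocolConfig | None = None,
                      n_realisations: int = 100, seed=0, n_jobs: int = 1,
                      per_realisation_norm: bool = False) -> DistanceBreakdown:
    """Simulate the full assay suite and measure its distance to ``data``.

    This is the noisy objective used throughout fitting: repeated calls with
    different seeds return a band of distances, not a single value, because
    each call draws a fresh finite sample of model realisations.
    """
    protocol = protocol or ProtocolConfig()
    sample = run_protocol_suite(params, protocol, n_realisations, seed, n_jobs=n_jobs)
    sample = normalise(sample, per_realisation=per_realisation_norm)
    bd = sample_distance(sample, data)
    master = seed if isinstance(seed, (int, np.integer)) else None
    return DistanceBreakdown(bd.per_experiment, bd.combined, n_realisations, master)
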