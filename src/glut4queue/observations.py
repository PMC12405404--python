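"""Observation tables, synthetic observations, and start-point calculators.

The fitting pipeline consumes replicated assay measurements as a long-format
table with one row per (experiment kind, insulin level, sample time,
replicate).  Values are normalised and dimensionless: each kind is scaled to
its reference steady state in maximal insulin.  A synthetic-observation
generator produces such tables from the simulator itself, standing in for
plate-assay data when none is available and providing known ground truth for
parameter-recovery experiments.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import IncompatibleArchitectureError, SchemaError, ValidationError
from .params import SystemParameters
from .protocols import ProtocolConfig, normalise, run_protocol_suite

__all__ = [
    "OBSERVATION_COLUMNS",
    "ObservationSet",
    "read_observations",
    "write_observations",
    "generate_synthetic_observations",
    "SteadyFractionTable",
    "start_point_active_probs",
]

OBSERVATION_COLUMNS = ("experiment", "insulin_nM", "time_min", "replicate", "value")
_KINDS = ("transition", "uptake")


@dataclass
class ObservationSet:
    """Replicated (experiment, insulin, time, value) records.

    ``provenance`` records where the table came from: ``{"source":
    "experimental"}`` or ``{"source": "synthetic", ...generator settings}``.
    """

    frame: pd.DataFrame
    provenance: dict = field(default_factory=lambda: {"source": "experimental"})

    def __post_init__(self):
        self.frame = _validate_frame(self.frame)

    def experiments(self) -> list[tuple[str, float]]:
        pairs = self.frame[["experiment", "insulin_nM"]].drop_duplicates()
        return sorted(map(tuple, pairs.itertuples(index=False)),
                      key=lambda p: (p[0], p[1]))

    def times(self, kind: str, insulin: float) -> np.ndarray:
        sub = self.frame[(self.frame.experiment == kind)
                         & (self.frame.insulin_nM == float(insulin))]
        return np.sort(sub.time_min.unique())

    def replicates(self, kind: str, insulin: float, time: float) -> np.ndarray:
        sub = self.frame[(self.frame.experiment == kind)
                         & (self.frame.insulin_nM == float(insulin))
                         & (self.frame.time_min == float(time))]
        if sub.empty:
            raise ValidationError(
                f"no replicates for ({kind}, {insulin:g} nM, t={time:g} min)")
        return sub.value.to_numpy(dtype=float)

    def __len__(self):
        return len(self.frame)


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in OBSERVATION_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"observation table missing column(s): {', '.join(missing)}")
    frame = frame.loc[:, list(OBSERVATION_COLUMNS)].copy()
    bad_rows = []
    bad_kind = ~frame.experiment.isin(_KINDS)
    if bad_kind.any():
        bad_rows += [(int(i), f"unknown experiment kind {frame.experiment[i]!r}")
                     for i in frame.index[bad_kind]]
    for col in ("insulin_nM", "time_min", "value"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        nn = coerced.isna() & frame[col].notna() | frame[col].isna()
        if nn.any():
            bad_rows += [(int(i), f"non-numeric {col}") for i in frame.index[nn]]
        frame[col] = coerced
    neg = (frame.value < 0) | (frame.insulin_nM < 0) | (frame.time_min < 0)
    neg &= frame[["value", "insulin_nM", "time_min"]].notna().all(axis=1)
    if neg.any():
        bad_rows += [(int(i), "negative value/insulin/time") for i in frame.index[neg]]
    if bad_rows:
        rows = sorted(set(i for i, _ in bad_rows))
        detail = "; ".join(f"row {i}: {msg}" for i, msg in sorted(bad_rows)[:10])
        raise SchemaError(f"invalid observation rows: {detail}", rows=rows)
    # soft invariant: transition levels should be a subset of uptake levels
    t_levels = set(frame.loc[frame.experiment == "transition", "insulin_nM"])
    u_levels = set(frame.loc[frame.experiment == "uptake", "insulin_nM"])
    if u_levels and not t_levels <= u_levels:
        _warnings.warn("transition insulin levels are not a subset of uptake levels",
                       stacklevel=3)
    return frame.reset_index(drop=True)


def read_observations(path) -> ObservationSet:
    """Read a CSV observation table, reporting schema violations by row number."""
    frame = pd.read_csv(path)
    return ObservationSet(frame)


def write_observations(obs: ObservationSet, path) -> None:
    obs.frame.to_csv(path, index=False)


# ----------------------------------------------------------------- synthetic


def generate_synthetic_observations(true_params: SystemParameters,
                                    protocol: ProtocolConfig | None = None,
                                    n_transition_reps: int = 6,
                                    n_uptake_reps: int = 10,
                                    noise_sd: float = 0.0,
                                    seed: int = 0,
                                    n_jobs: int = 1) -> ObservationSet:
    """Generate a replicated observation table from the simulator itself.

    Independent model realisations supply the replicate values for every
    (kind, insulin, time) cell: ``n_transition_reps`` per transition cell and
    ``n_uptake_reps`` per uptake cell (defaults follow the usual plate-assay
    minima of six and ten).  Optional additive Gaussian measurement noise of
    standard deviation ``noise_sd`` is applied to the normalised values and
    truncated at zero.  The provenance records the generating truth.
    """
    if n_transition_reps < 1 or n_uptake_reps < 1:
        raise ValidationError("replicate counts must be >= 1")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    protocol = protocol or ProtocolConfig()
    n_real = max(n_transition_reps, n_uptake_reps)
    sample = run_protocol_suite(true_params, protocol, n_real, seed, n_jobs=n_jobs)
    sample = normalise(sample)
    noise_rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(1,)))
    rows = []
    for kind, level in protocol.experiments:
        n_reps = n_transition_reps if kind == "transition" else n_uptake_reps
        values = sample.values(kind, level)[:n_reps]
        times = sample.times(kind)
        if noise_sd > 0:
            values = np.maximum(values + noise_rng.normal(0.0, noise_sd, values.shape), 0.0)
        for rep in range(n_reps):
            for t, v in zip(times, values[rep]):
                rows.append((kind, level, t, rep, v))
    frame = pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))
    provenance = {
        "source": "synthetic",
        "true_params": true_params.to_dict(),
        "n_transition_reps": n_transition_reps,
        "n_uptake_reps": n_uptake_reps,
        "noise_sd": noise_sd,
        "seed": int(seed),
    }
    return ObservationSet(frame, provenance)


# --------------------------------------------------------------- start point


@dataclass(frozen=True)
class SteadyFractionTable:
    """Uptake steady-state fraction per insulin level, relative to maximal.

    ``fractions[I]`` is the fraction of the maximal-insulin recycling pool
    observed at insulin ``I``; the reference level maps to 1 by construction.
    """

    fractions: Mapping[float, float]
    reference: float = 100.0

    def __post_init__(self):
        fr = {float(k): float(v) for k, v in dict(self.fractions).items()}
        ref = float(self.reference)
        if ref not in fr:
            raise ValidationError("reference level missing from fraction table")
        if abs(fr[ref] - 1.0) > 1e-9:
            raise ValidationError("fraction at the reference level must equal 1")
        for lvl, f in fr.items():
            if not (0 < f <= 1 + 1e-9):
                raise ValidationError(f"fraction at {lvl:g} nM must lie in (0, 1], got {f}")
        levels = sorted(fr)
        if any(fr[a] > fr[b] + 1e-9 for a, b in zip(levels, levels[1:])):
            _warnings.warn("steady-state fractions are not non-decreasing in insulin",
                           stacklevel=3)
        object.__setattr__(self, "fractions", fr)
        object.__setattr__(self, "reference", ref)

    @classmethod
    def from_observations(cls, obs: ObservationSet, reference: float = 100.0):
        """Estimate fractions as the mean of the last two uptake sample times."""
        levels = sorted(l for k, l in obs.experiments() if k == "uptake")
        if float(reference) not in levels:
            raise ValidationError("reference level has no uptake data")

        def plateau(level):
            times = obs.times("uptake", level)[-2:]
            return float(np.mean([obs.replicates("uptake", level, t).mean() for t in times]))

        ref_val = plateau(reference)
        if ref_val <= 0:
            raise ValidationError("reference uptake plateau is not positive")
        return cls({lvl: plateau(lvl) / ref_val for lvl in levels}, reference)


def start_point_active_probs(fractions: SteadyFractionTable, N: int, M: int, L: int,
                             max_recycling: float = 0.9) -> dict[float, float]:
    """Activation probabilities that reproduce target recycling pools.

    With expected sequestration ``M*L*(1-p)`` (inactive tubes fill to
    capacity), the activation that leaves ``max_recycling * f(I) * N``
    vesicles recycling at insulin ``I`` is::

        p(I) = 1 - N * (1 - max_recycling * f(I)) / (M * L)

    ``max_recycling`` (default 0.9) caps the recycling pool at maximal
    insulin so some sequestration — and hence output variability — remains
    even when fully stimulated.  Results are clipped to the [0.01, 1] fitting
    bounds with a warning; a negative pre-clip value means the required
    sequestration exceeds the microtubule capacity ``M*L`` and raises
    :class:`IncompatibleArchitectureError`.
    """
    if not (0 < max_recycling <= 1):
        raise ValidationError("max_recycling must lie in (0, 1]")
    for name, v in (("N", N), ("M", M), ("L", L)):
        if v < 1:
            raise ValidationError(f"{name} must be >= 1")
    capacity = M * L
    out = {}
    for level, f in sorted(fractions.fractions.items()):
        p = 1.0 - N * (1.0 - max_recycling * f) / capacity
        if p < 0:
            raise IncompatibleArchitectureError(
                f"sequestration target at {level:g} nM ({N * (1 - max_recycling * f):.0f} "
                f"vesicles) exceeds the microtubule capacity M*L = {capacity}")
        if p < 0.01 or p > 1.0:
            _warnings.warn(f"p({level:g}) = {p:.4f} clipped to the [0.01, 1] fitting bounds",
                           stacklevel=2)
        out[level] = min(max(p, 0.01), 1.0)
    return out
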