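"""Tests of the simulated transition and uptake assay protocols."""

import dataclasses

import numpy as np
import pytest

from glut4queue import (ProtocolConfig, QueueNetwork, normalise, run_protocol_suite,
                        run_realisation, run_transition, run_uptake)
from glut4queue.errors import ValidationError


def test_default_protocol_matches_assay_design():
    p = ProtocolConfig()
    assert p.warm_up == 500.0 and p.equilibration == 500.0
    assert p.transition_times == (0, 0.5, 1, 2, 5, 10, 15, 20, 25, 30, 45, 60)
    assert p.uptake_times == (0, 2, 5, 10, 20, 30, 60, 90, 120, 180, 240, 300)
    assert p.transition_levels == (0.3, 3, 30, 100)
    assert p.uptake_levels == (0, 0.03, 0.1, 0.3, 1, 3, 10, 30, 100)
    assert len(p.experiments) == 13


def test_protocol_validation():
    with pytest.raises(ValidationError):
        ProtocolConfig(transition_times=(0, 5, 5))
    with pytest.raises(ValidationError):
        ProtocolConfig(uptake_times=(-1, 5))
    with pytest.raises(ValidationError):
        ProtocolConfig(reference_insulin=7.0)


def test_no_switch_transition_is_stationary(scaled_params, mini_protocol):
    """Stepping to an insulin level with basal activation leaves the trace flat."""
    params = scaled_params.replace(
        active_prob={0.0: 0.45, 100.0: 0.45})  # 'step' changes nothing
    first, last = [], []
    for seed in range(30):
        tr = run_transition(params, 100.0, mini_protocol, seed)
        first.append(tr.raw[0])
        last.append(tr.raw[-1])
    first, last = np.array(first), np.array(last)
    pooled_se = np.sqrt(first.var(ddof=1) / 30 + last.var(ddof=1) / 30)
    assert abs(first.mean() - last.mean()) < 4 * pooled_se


def test_transition_t0_reads_basal_steady_state(scaled_params, mini_protocol):
    """The t=0 sample is the pre-switch (basal) membrane count."""
    tr, net = run_transition(scaled_params, 100.0, mini_protocol, seed=3,
                             return_network=True)
    assert tr.raw[0] <= tr.raw[-1]  # insulin raises the membrane level
    assert net.insulin == 100.0


def test_uptake_trace_monotone_and_t0_equals_membrane(scaled_params, mini_protocol):
    for seed in (0, 1):
        net = QueueNetwork(scaled_params, seed)
        net.advance(mini_protocol.warm_up)
        net.set_insulin(100.0)
        net.advance(mini_protocol.warm_up + mini_protocol.equilibration)
        membrane_at_start = net.n_membrane
        tr = run_uptake(scaled_params, 100.0, mini_protocol, seed)
        assert tr.raw[0] == membrane_at_start  # same seed, same realisation
        assert np.all(np.diff(tr.raw) >= 0)


def test_uptake_long_horizon_reaches_recycling_pool(scaled_params, mini_protocol):
    """Every recycling vesicle eventually visits: limit ~ N - M*L*(1-p)."""
    proto = dataclasses.replace(mini_protocol, uptake_times=(0, 60, 120, 240, 420))
    vals = [run_uptake(scaled_params, 100.0, proto, seed).raw[-1] for seed in range(6)]
    p = 0.9
    expect = scaled_params.N - scaled_params.M * scaled_params.L * (1 - p)  # 1955
    sd = scaled_params.L * np.sqrt(scaled_params.M * p * (1 - p))  # site-count noise
    assert abs(np.mean(vals) - expect) < 3 * sd / np.sqrt(len(vals)) + 20


def test_full_scale_basal_uptake_limit_matches_sequestration_oracle():
    """Start-point network at basal insulin: the uptake limit equals the
    recycling pool N - M*L*(1-p(0)) predicted by the sequestration expectation."""
    from glut4queue import load_reference

    params = load_reference("start")  # N=25000, M=450, L=50, p(0)=0.102
    proto = ProtocolConfig(warm_up=400.0, equilibration=0.0,
                           transition_times=(0.0, 1.0), uptake_times=(0, 150, 300, 450, 600),
                           transition_levels=(), uptake_levels=(0.0,),
                           reference_insulin=0.0)
    vals = [run_uptake(params, 0.0, proto, seed).raw[-1] for seed in range(3)]
    p0 = params.active_prob[0.0]
    expect = params.N - params.M * params.L * (1 - p0)  # 4795
    sd = params.L * np.sqrt(params.M * p0 * (1 - p0))   # inactive-site count noise
    assert abs(np.mean(vals) - expect) < 3 * sd / np.sqrt(len(vals))


def test_realisation_covers_all_experiments(scaled_params, mini_protocol):
    traces = run_realisation(scaled_params, mini_protocol, seed=5)
    keys = sorted(tr.key for tr in traces)
    assert keys == [("transition", 100.0), ("uptake", 0.0), ("uptake", 100.0)]


def test_full_suite_has_13_experiments_per_realisation(scaled_params):
    proto = ProtocolConfig(warm_up=2.0, equilibration=2.0,
                           transition_times=(0, 1), uptake_times=(0, 1))
    params = scaled_params.replace(active_prob={
        0.0: 0.45, 0.03: 0.5, 0.1: 0.55, 0.3: 0.6, 1.0: 0.7,
        3.0: 0.8, 10.0: 0.85, 30.0: 0.88, 100.0: 0.9})
    sample = run_protocol_suite(params, proto, n_realisations=1, seed=0)
    assert len(sample.traces) == 13
    kinds = [tr.kind for tr in sample.traces]
    assert kinds.count("transition") == 4 and kinds.count("uptake") == 9


def test_suite_is_bit_identical_per_master_seed(scaled_params, mini_protocol):
    a = run_protocol_suite(scaled_params, mini_protocol, 2, seed=42)
    b = run_protocol_suite(scaled_params, mini_protocol, 2, seed=42)
    for ta, tb in zip(a.traces, b.traces):
        assert ta.key == tb.key and np.array_equal(ta.raw, tb.raw)
    c = run_protocol_suite(scaled_params, mini_protocol, 2, seed=43)
    assert any(not np.array_equal(ta.raw, tc.raw) for ta, tc in zip(a.traces, c.traces))


def test_normalisation_constants_and_reference_means(scaled_params, mini_protocol):
    sample = normalise(run_protocol_suite(scaled_params, mini_protocol, 6, seed=1))
    ref = mini_protocol.reference_insulin
    tr = sample.values("transition", ref)
    up = sample.values("uptake", ref)
    assert tr[:, -1].mean() == pytest.approx(1.0)
    assert up[:, -1].mean() == pytest.approx(1.0)
    assert sample.norm_constants["transition"] > 0
    assert sample.norm_constants["uptake"] > 0


def test_normalisation_idempotent_given_unit_constants(scaled_params, mini_protocol):
    sample = normalise(run_protocol_suite(scaled_params, mini_protocol, 3, seed=2))
    renorm = dataclasses.replace(sample)
    # dividing the normalised values by the recorded constants again would
    # change them; dividing by 1 (i.e. re-normalising a sample whose
    # reference means are already 1) must not
    again = normalise(dataclasses.replace(
        sample,
        traces=[dataclasses.replace(tr, raw=tr.normalised) for tr in sample.traces]))
    for t1, t2 in zip(renorm.traces, again.traces):
        assert np.allclose(t1.normalised, t2.normalised)


def test_fine_trace_subsamples_to_assay_grid(scaled_params, mini_protocol):
    """Half-minute sampling reproduces the coarse grid values exactly."""
    coarse = run_transition(scaled_params, 100.0, mini_protocol, seed=6)
    fine = run_transition(scaled_params, 100.0, mini_protocol, seed=6, fine_trace=True)
    assert np.array_equal(coarse.raw, fine.raw)
    idx = np.searchsorted(fine.fine_times, np.asarray(mini_protocol.transition_times, float))
    assert np.array_equal(fine.fine_raw[idx], fine.raw)


def test_chained_and_standalone_uptake_statistically_identical(scaled_params, mini_protocol):
    """Continuing from a transition run matches a fresh warm-up in distribution."""
    chained, standalone = [], []
    for seed in range(16):
        _, net = run_transition(scaled_params, 100.0, mini_protocol, seed,
                                return_network=True)
        chained.append(run_uptake(scaled_params, 100.0, mini_protocol,
                                  network=net).raw[-1])
        standalone.append(run_uptake(scaled_params, 100.0, mini_protocol,
                                     seed=1000 + seed).raw[-1])
    chained, standalone = np.array(chained), np.array(standalone)
    se = np.sqrt(chained.var(ddof=1) / 16 + standalone.var(ddof=1) / 16)
    assert abs(chained.mean() - standalone.mean()) < 4 * se


def test_steady_state_consistency_between_protocols(scaled_params, mini_protocol):
    """Late transition samples match the membrane level at uptake start."""
    late, starts = [], []
    for seed in range(16):
        late.append(run_transition(scaled_params, 100.0, mini_protocol, seed).raw[-1])
        starts.append(run_uptake(scaled_params, 100.0, mini_protocol, seed).raw[0])
    late, starts = np.array(late), np.array(starts)
    se = np.sqrt(late.var(ddof=1) / 16 + starts.var(ddof=1) / 16)
    assert abs(late.mean() - starts.mean()) < 4 * se
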