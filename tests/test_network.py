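"""Event-level tests of the closed queuing network."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glut4queue import (QueueNetwork, SystemParameters, initialise,
                        microtubule_departure_time)
from glut4queue.errors import (ConfigurationError, InternalConsistencyError,
                               ValidationError)
from glut4queue.network import MEMBRANE, STORE


def test_parameter_validation_names_offending_field():
    with pytest.raises(ValidationError, match="mu_F"):
        SystemParameters(mu_S=1, mu_M=1, mu_F=0, mu_P=1, N=5, M=2, L=2,
                         active_prob={0.0: 1.0})
    with pytest.raises(ValidationError, match="N"):
        SystemParameters(mu_S=1, mu_M=1, mu_F=1, mu_P=1, N=0, M=2, L=2,
                         active_prob={0.0: 1.0})
    with pytest.raises(ValidationError, match="active_prob"):
        SystemParameters(mu_S=1, mu_M=1, mu_F=1, mu_P=1, N=5, M=2, L=2,
                         active_prob={0.0: 1.5})
    with pytest.raises(ValidationError, match="basal"):
        SystemParameters(mu_S=1, mu_M=1, mu_F=1, mu_P=1, N=5, M=2, L=2,
                         active_prob={100.0: 0.5})


def test_initialise_places_all_vesicles_in_store(small_params):
    net = initialise(small_params, seed=0)
    snap = net.snapshot()
    assert snap.time == 0.0
    assert snap.store == small_params.N
    assert snap.microtubules == snap.fusion_sites == snap.membrane == 0
    assert snap.total == small_params.N
    assert snap.tagged == 0

    single = SystemParameters(mu_S=1, mu_M=1, mu_F=1, mu_P=1, N=1, M=1, L=1,
                              active_prob={0.0: 1.0})
    snap1 = initialise(single, seed=3).snapshot()
    assert snap1.store == 1 and snap1.total == 1


def test_initial_active_site_count_matches_binomial_expectation():
    """Mean active-site count over many seeds ~ Binomial(M, p)."""
    params = SystemParameters(mu_S=1, mu_M=1, mu_F=1, mu_P=1, N=1, M=100, L=1,
                              active_prob={0.0: 0.5})
    counts = [sum(QueueNetwork(params, s).active) for s in range(1000)]
    # Binomial(100, 0.5): mean 50, sd 5; mean of 1000 seeds has SE ~0.16
    assert abs(np.mean(counts) - 50.0) < 0.8


def test_set_insulin_threshold_and_full_activation(small_params):
    net = QueueNetwork(small_params, seed=1)
    net.latent = np.array([0.05, 0.5, 0.95, 0.3, 0.7])
    net.active = (net.latent <= 0.5).tolist()
    assert net.active == [True, True, False, True, False]
    net.set_insulin(100.0)  # p = 1
    assert all(net.active)


def test_unknown_insulin_level_raises(small_params):
    net = QueueNetwork(small_params, seed=1)
    with pytest.raises(ConfigurationError):
        net.set_insulin(42.0)


@settings(max_examples=50, deadline=None)
@given(p1=st.floats(0, 1), p2=st.floats(0, 1), seed=st.integers(0, 2**20))
def test_monotone_activation_under_shared_latents(p1, p2, seed):
    """With coupled latent values, raising p only ever activates more sites."""
    lo, hi = sorted((p1, p2))
    params = SystemParameters(mu_S=1, mu_M=1, mu_F=1, mu_P=1, N=1, M=50, L=1,
                              active_prob={0.0: 0.0, 1.0: lo, 2.0: hi})
    net = QueueNetwork(params, seed=seed)
    net.set_insulin(1.0)
    active_lo = list(net.active)
    net.set_insulin(2.0)
    active_hi = list(net.active)
    assert all(hi_a or not lo_a for lo_a, hi_a in zip(active_lo, active_hi))


def test_routing_is_uniform_over_tubes():
    """Tube choice frequencies are consistent with probability 1/M each."""
    from scipy.stats import chisquare

    n = 100_000
    params = SystemParameters(mu_S=1.0, mu_M=1e-9, mu_F=1.0, mu_P=1.0,
                              N=n, M=4, L=10**9, active_prob={0.0: 0.0})
    net = QueueNetwork(params, seed=7)
    net.advance(40.0)  # essentially every vesicle has routed once
    counts = np.array([len(t) for t in net._tubes])
    assert counts.sum() > 0.99 * n
    assert chisquare(counts).pvalue > 1e-3


def test_route_from_store_admission_and_blocking():
    params = SystemParameters(mu_S=1.0, mu_M=1.0, mu_F=1.0, mu_P=1.0, N=4, M=1, L=2,
                              active_prob={0.0: 0.0})
    net = QueueNetwork(params, seed=0)
    assert net.route_from_store(0) == 0
    assert len(net._tubes[0]) == 1 and net._tubes[0][0][0] == 0
    assert net.route_from_store(1) == 0
    # tube now at capacity: the next attempt stays in the store
    before = net.n_store
    assert net.route_from_store(2) is None
    assert net.n_store == before and net.location[2] == STORE
    with pytest.raises(InternalConsistencyError):
        net.route_from_store(0)  # already in a tube
    net.advance(200.0)
    net.validate()


@pytest.mark.parametrize(
    "arrival,service,d_prev,increment,blocking,expected",
    [
        (1.0, 2.0, 2.5, None, 0.0, 3.0),     # own service dominates
        (1.0, 0.5, 2.5, 0.2, 0.0, 2.7),      # blocked behind predecessor
        (0.0, 1.0, -math.inf, None, 0.0, 1.0),
        (1.0, 2.0, 2.5, None, math.inf, math.inf),  # permanently inactive site
        (1.0, 0.5, 2.5, 0.2, 1.0, 3.7),
    ],
)
def test_departure_time_recursion(arrival, service, d_prev, increment, blocking, expected):
    got = microtubule_departure_time(arrival, service, d_prev, increment, blocking)
    assert got == expected


def test_departure_time_rejects_negative_durations():
    with pytest.raises(ValidationError):
        microtubule_departure_time(-1.0, 1.0)
    with pytest.raises(ValidationError):
        microtubule_departure_time(1.0, 1.0, 5.0, -0.1)


def test_zero_duration_advance_is_identity(small_params):
    net = QueueNetwork(small_params, seed=5)
    net.advance(10.0)
    before = net.snapshot(per_tube=True)
    net.advance(10.0)
    assert net.snapshot(per_tube=True) == before
    with pytest.raises(ValidationError):
        net.advance(9.0)


def test_all_inactive_sites_absorb_into_full_tubes():
    """With every site inactive and N > M*L, tubes fill and the system freezes."""
    params = SystemParameters(mu_S=5.0, mu_M=5.0, mu_F=1.0, mu_P=1.0, N=30, M=3, L=5,
                              active_prob={0.0: 0.0})
    net = QueueNetwork(params, seed=2)
    net.advance(200.0)
    snap = net.snapshot(per_tube=True)
    assert snap.per_tube == (5, 5, 5)
    assert snap.store == 30 - 15
    assert snap.sequestered == 15
    assert snap.membrane == 0 and snap.fusion_sites == 0
    # no further movement, only store retries
    net.advance(400.0)
    assert net.snapshot(per_tube=True).per_tube == (5, 5, 5)
    assert net.snapshot().store == 15


def test_renewal_reward_occupancy_for_single_vesicle_cycle():
    """N=M=L=1, all active: time shares equal mean-service-time proportions."""
    params = SystemParameters(mu_S=1.0, mu_M=2.0, mu_F=3.0, mu_P=1.5, N=1, M=1, L=1,
                              active_prob={0.0: 1.0})
    means = np.array([1.0, 0.5, 1 / 3, 1 / 1.5])
    expected = means / means.sum()
    fracs = []
    for seed in range(8):
        net = QueueNetwork(params, seed=seed, track_occupancy=True)
        net.advance(4000.0)
        fracs.append(net.occupancy_fractions())
    fracs = np.array(fracs)
    se = fracs.std(axis=0, ddof=1) / np.sqrt(len(fracs))
    assert np.all(np.abs(fracs.mean(axis=0) - expected) < 4 * np.maximum(se, 1e-3))


def test_sequestration_matches_binomial_expectation():
    """Long-run sequestered count ~ M*L*(1-p): inactive tubes fill and stay full."""
    params = SystemParameters(mu_S=2.0, mu_M=2.0, mu_F=2.0, mu_P=2.0, N=400, M=30, L=5,
                              active_prob={0.0: 0.6})
    seqs = [QueueNetwork(params, s).advance(150.0).sequestered_count() for s in range(40)]
    expect = 30 * 5 * 0.4  # 60
    # binomial sd of the inactive-site count: sqrt(30*0.6*0.4)*5 ~ 13.3 per seed
    se = 5 * math.sqrt(30 * 0.6 * 0.4) / math.sqrt(len(seqs))
    assert abs(np.mean(seqs) - expect) < 4 * se


def test_conservation_fifo_and_capacity_across_seeds(small_params):
    """Invariant suite: conservation, FIFO departures, capacity, per seed."""
    for seed in range(12):
        net = QueueNetwork(small_params, seed=seed, record_departures=True)
        t = 0.0
        while net.n_events < 10_000:
            t += 25.0
            net.advance(t)
            net.validate()  # conservation + capacity + counter consistency
            if t > 20000:  # pragma: no cover - safety valve
                raise AssertionError("event budget not reached")
        for deps in net.departures:
            assert all(b > a for a, b in zip(deps, deps[1:]))


def test_seed_determinism(small_params):
    a = QueueNetwork(small_params, seed=11).advance(200.0).snapshot(per_tube=True)
    b = QueueNetwork(small_params, seed=11).advance(200.0).snapshot(per_tube=True)
    c = QueueNetwork(small_params, seed=12).advance(200.0).snapshot(per_tube=True)
    assert a == b
    assert a != c


def test_newly_active_site_pulls_ready_head():
    """Activating a site releases a vesicle whose tube service already finished."""
    params = SystemParameters(mu_S=10.0, mu_M=10.0, mu_F=1e-3, mu_P=1e-3, N=8, M=1, L=4,
                              active_prob={0.0: 0.0, 100.0: 1.0})
    net = QueueNetwork(params, seed=4)
    net.advance(100.0)
    assert net.snapshot().sequestered == 4  # tube full behind the inactive site
    net.set_insulin(100.0)
    snap = net.snapshot()
    assert snap.sequestered == 0
    assert snap.fusion_sites == 1  # head moved in instantly
    net.validate()


def test_tag_clearing_counts_membrane_occupants(scaled_params):
    net = QueueNetwork(scaled_params, seed=9)
    net.advance(40.0)
    assert net.n_tagged > 0  # everything that visited so far is tagged
    n0 = net.clear_tags()
    assert n0 == net.n_membrane
    net.advance(60.0)
    assert net.n_tagged >= n0
    net.validate()
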