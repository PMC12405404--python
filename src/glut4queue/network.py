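"""Discrete-event simulator of the closed GLUT4 vesicle-trafficking network.

Stations and dynamics
---------------------
* **Endosome store** — infinite server; each vesicle completes an independent
  exponential(``mu_S``) service, then picks one of the ``M`` microtubules
  uniformly.  If the chosen tube is at capacity the vesicle stays in the store
  with a fresh service time (a later retry re-chooses uniformly among all
  tubes).
* **Microtubules** — ``M`` parallel FIFO queues of capacity ``L`` with
  blocking-after-service.  A vesicle arriving at time ``A`` draws a transit
  (service) time ``S ~ Exp(mu_M)`` immediately.  Departures preserve arrival
  order: the vesicle at the head may leave at ``A + S`` if that is no earlier
  than its predecessor's departure ``D_prev``; otherwise it must first
  manoeuvre into the unloading zone, taking an increment time
  ``I ~ Exp(L * mu_M)`` drawn at the moment the predecessor departs, so it is
  ready at ``D_prev + I``.  A ready head transfers to the paired fusion site
  only when that site is active and empty; until then it blocks its server
  (and, transitively, the whole tube).
* **Fusion sites** — ``M`` single-server, zero-buffer queues, one per tube.
  A site is active with probability ``p(I)`` at insulin level ``I``; inactive
  sites accept nothing, sequestering every vesicle queued on their tube.
  Service is exponential(``mu_F``); on completion the vesicle joins the plasma
  membrane and a ready head vesicle (if any) transfers in instantly.
* **Plasma membrane** — infinite server, exponential(``mu_P``) residence;
  vesicles then return to the store.  All switch times are zero.

Site activation uses a per-site latent value ``u_m ~ U(0,1)`` fixed for the
realisation: site ``m`` is active iff ``u_m <= p(I)``.  This couples the
active sets across insulin levels, so raising insulin (with non-decreasing
``p``) only ever activates additional sites.  Pass ``redraw_activation=True``
to redraw the latent values independently at every insulin change instead.

Simultaneous events are ordered by station priority (fusion completions, then
microtubule head-ready, then membrane completions, then store completions) and
then by vesicle id, making every realisation a deterministic function of its
seed and parameters.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from heapq import heappop, heappush

import numpy as np

from ._rng import ExpStream, UniformStream, substreams
from .errors import ConfigurationError, InternalConsistencyError, ValidationError
from .params import SystemParameters

__all__ = [
    "QueueNetwork",
    "StationSnapshot",
    "initialise",
    "microtubule_departure_time",
    "STORE",
    "TUBE",
    "FUSION",
    "MEMBRANE",
]

# Vesicle location codes (values index the occupancy-time accumulator).
STORE, TUBE, FUSION, MEMBRANE = 0, 1, 2, 3

# Event priorities implement the tie-break: fusion > microtubule > membrane > store.
_EV_FUSION, _EV_TUBE, _EV_MEMBRANE, _EV_STORE = 0, 1, 2, 3

# Microtubule occupant record indices: [vesicle id, arrival time, service time, ready?]
_VID, _ARR, _SRV, _RDY = 0, 1, 2, 3


def microtubule_departure_time(arrival, service, d_prev=-math.inf, increment=None, blocking=0.0):
    """Departure time of a microtubule occupant under FIFO blocking-after-service.

    ``D = A + S + B`` when the occupant's own service outlasts its
    predecessor's departure (``A + S >= D_prev``); otherwise the occupant must
    wait for the predecessor and take an increment time to reach the unloading
    zone, ``D = D_prev + I + B``.  ``blocking`` may be ``math.inf`` (a
    permanently inactive fusion site), in which case the departure never
    occurs.
    """
    if arrival < 0 or service < 0:
        raise ValidationError("arrival and service times must be non-negative")
    if blocking < 0:
        raise ValidationError("blocking time must be non-negative")
    if arrival + service >= d_prev:
        return arrival + service + blocking
    if increment is None:
        raise ValidationError("increment time required when A + S < D_prev")
    if increment < 0:
        raise ValidationError("increment time must be non-negative")
    return d_prev + increment + blocking


@dataclass(frozen=True)
class StationSnapshot:
    """Occupancy counts of every station at one instant (counts sum to N)."""

    time: float
    store: int
    microtubules: int
    fusion_sites: int
    membrane: int
    tagged: int
    sequestered: int
    per_tube: tuple[int, ...] | None = None

    @property
    def total(self) -> int:
        return self.store + self.microtubules + self.fusion_sites + self.membrane


class QueueNetwork:
    """State and event engine of one realisation of the closed network.

    Parameters
    ----------
    params:
        Validated :class:`~glut4queue.params.SystemParameters`.
    seed:
        Integer or ``numpy.random.SeedSequence``; fully determines the
        realisation together with ``params``.
    redraw_activation:
        Redraw the latent site values at every :meth:`set_insulin` call
        instead of keeping them fixed for the realisation.
    record_departures:
        Keep per-tube lists of realised departure times (for FIFO checks).
    """

    def __init__(self, params: SystemParameters, seed, *,
                 redraw_activation: bool = False, record_departures: bool = False,
                 track_occupancy: bool = False):
        if not isinstance(params, SystemParameters):
            params = SystemParameters(**params)
        self.params = params
        streams = substreams(seed)
        self._latent_gen = streams["latent"]
        self._exp_store = ExpStream(streams["store"])
        self._exp_tube = ExpStream(streams["tube"])
        self._exp_incr = ExpStream(streams["increment"])
        self._exp_fusion = ExpStream(streams["fusion"])
        self._exp_membrane = ExpStream(streams["membrane"])
        self._uni_route = UniformStream(streams["routing"])
        self._redraw_activation = redraw_activation

        N, M = params.N, params.M
        self.clock = 0.0
        self.n_events = 0
        self._heap: list[tuple] = []
        # plain lists: scalar reads/writes dominate the event loop
        self.location = [STORE] * N                     # all vesicles start in the store
        self.tagged = [False] * N
        self.n_tagged = 0
        self._sgen = [0] * N                            # store-event generation counters
        self._tubes: list[deque] = [deque() for _ in range(M)]
        self._fusion_occupant = [-1] * M
        self.n_store = N
        self.n_tube = 0
        self.n_fusion = 0
        self.n_membrane = 0
        self._track_occupancy = track_occupancy
        self._occ_time = [0.0, 0.0, 0.0, 0.0]           # station occupancy-time integrals
        self._last_event_time = 0.0
        self.departures: list[list[float]] | None = (
            [[] for _ in range(M)] if record_departures else None
        )

        self.latent = self._latent_gen.random(M)
        self.insulin = 0.0
        self.active = (self.latent <= self._prob(0.0)).tolist()

        inv_mu_S = 1.0 / params.mu_S
        draw = self._exp_store.draw
        heap = self._heap
        for vid in range(N):
            heappush(heap, (draw() * inv_mu_S, _EV_STORE, vid, 0))

    # ------------------------------------------------------------------ util

    def _prob(self, insulin: float) -> float:
        try:
            return self.params.active_prob[float(insulin)]
        except KeyError:
            raise ConfigurationError(
                f"insulin level {insulin!r} nM has no activation probability; "
                f"known levels: {sorted(self.params.active_prob)}"
            ) from None

    # ---------------------------------------------------------------- insulin

    def set_insulin(self, insulin_nM: float) -> "QueueNetwork":
        """Apply an insulin level: re-evaluate site activity against ``p(I)``.

        Newly active sites immediately pull a ready head vesicle from their
        tube.  Newly inactive sites (possible only if ``p`` decreased, or
        under ``redraw_activation``) stop accepting vesicles but let a fusion
        service already in progress complete.
        """
        p = self._prob(insulin_nM)
        if self._redraw_activation:
            self.latent = self._latent_gen.random(self.params.M)
        old_active = self.active
        new_active = (self.latent <= p).tolist()
        self.active = new_active
        self.insulin = float(insulin_nM)
        t = self.clock
        for m in range(self.params.M):
            if new_active[m] and not old_active[m]:
                tube = self._tubes[m]
                if tube and tube[0][_RDY] and self._fusion_occupant[m] < 0:
                    self._transfer(m, t)
        return self

    # ---------------------------------------------------------------- routing

    def route_from_store(self, vesicle_id: int):
        """Route a vesicle whose store service has just completed.

        Returns the joined tube index, or ``None`` if the uniformly chosen
        tube was at capacity (the vesicle then re-enters store service with a
        fresh exponential completion time; a later retry chooses uniformly
        again among all tubes).
        """
        vid = int(vesicle_id)
        if not (0 <= vid < self.params.N) or self.location[vid] != STORE:
            raise InternalConsistencyError(f"vesicle {vid} is not in the endosome store")
        self._sgen[vid] += 1  # invalidate any pending completion event
        m = self._attempt_route(vid, self.clock)
        if m < 0:
            heappush(self._heap,
                     (self.clock + self._exp_store.draw() / self.params.mu_S,
                      _EV_STORE, vid, self._sgen[vid]))
            return None
        return m

    def _attempt_route(self, vid: int, t: float) -> int:
        """Uniform tube choice; admit at the tail if below capacity, else -1."""
        m = int(self._uni_route.draw() * self.params.M)
        tube = self._tubes[m]
        if len(tube) >= self.params.L:
            return -1
        service = self._exp_tube.draw() / self.params.mu_M
        tube.append([vid, t, service, False])
        self.location[vid] = TUBE
        self.n_store -= 1
        self.n_tube += 1
        if len(tube) == 1:
            # Head of an empty tube: ready when its own service completes.
            heappush(self._heap, (t + service, _EV_TUBE, vid, m))
        return m

    # --------------------------------------------------------------- transfers

    def _transfer(self, m: int, t: float) -> None:
        """Move the ready head of tube ``m`` into its (active, empty) fusion site."""
        tube = self._tubes[m]
        occ = tube.popleft()
        vid = occ[_VID]
        self.n_tube -= 1
        self.n_fusion += 1
        self.location[vid] = FUSION
        self._fusion_occupant[m] = vid
        heappush(self._heap, (t + self._exp_fusion.draw() / self.params.mu_F,
                              _EV_FUSION, vid, m))
        if self.departures is not None:
            self.departures[m].append(t)
        if tube:
            head = tube[0]
            own = head[_ARR] + head[_SRV]
            if own >= t:
                ready_at = own
            else:
                # Blocked behind the departed predecessor: draw the increment
                # time now (Exp(L * mu_M)) to reach the unloading zone.
                ready_at = t + self._exp_incr.draw() / (self.params.L * self.params.mu_M)
            heappush(self._heap, (ready_at, _EV_TUBE, head[_VID], m))

    # ----------------------------------------------------------------- advance

    def advance(self, t_end: float) -> "QueueNetwork":
        """Process every pending event with time <= ``t_end``; clock := ``t_end``."""
        if t_end < self.clock:
            raise ValidationError(f"t_end ({t_end}) is before the clock ({self.clock})")
        heap = self._heap
        tubes = self._tubes
        location = self.location
        tagged = self.tagged
        sgen = self._sgen
        params = self.params
        M, L = params.M, params.L
        inv_S = 1.0 / params.mu_S
        inv_M = 1.0 / params.mu_M
        inv_P = 1.0 / params.mu_P
        occ_time = self._occ_time
        track = self._track_occupancy
        draw_store = self._exp_store.draw
        draw_membrane = self._exp_membrane.draw
        fusion_occ = self._fusion_occupant
        active = self.active
        uni = self._uni_route.draw
        draw_tube = self._exp_tube.draw
        n_events = self.n_events
        last_t = self._last_event_time

        while heap and heap[0][0] <= t_end:
            t, ev, vid, m = heappop(heap)
            if ev == _EV_STORE and m != sgen[vid]:
                continue  # superseded by a manual route_from_store call
            if track:
                # occupancy-time integrals up to this event
                dt = t - last_t
                occ_time[STORE] += self.n_store * dt
                occ_time[TUBE] += self.n_tube * dt
                occ_time[FUSION] += self.n_fusion * dt
                occ_time[MEMBRANE] += self.n_membrane * dt
                last_t = t
            self.clock = t
            n_events += 1

            if ev == _EV_STORE:
                # service complete at the store: choose a tube uniformly
                tm = int(uni() * M)
                tube = tubes[tm]
                if len(tube) >= L:
                    # blocked: re-enter store service
                    heappush(heap, (t + draw_store() * inv_S, _EV_STORE, vid, m))
                else:
                    service = draw_tube() * inv_M
                    tube.append([vid, t, service, False])
                    location[vid] = TUBE
                    self.n_store -= 1
                    self.n_tube += 1
                    if len(tube) == 1:
                        heappush(heap, (t + service, _EV_TUBE, vid, tm))
            elif ev == _EV_TUBE:
                # head of tube m is ready to unload
                tube = tubes[m]
                head = tube[0]
                head[_RDY] = True
                if active[m] and fusion_occ[m] < 0:
                    self._transfer(m, t)
            elif ev == _EV_FUSION:
                # fusion complete: deposit to the plasma membrane
                fusion_occ[m] = -1
                self.n_fusion -= 1
                self.n_membrane += 1
                location[vid] = MEMBRANE
                if not tagged[vid]:
                    tagged[vid] = True
                    self.n_tagged += 1
                heappush(heap, (t + draw_membrane() * inv_P, _EV_MEMBRANE, vid, 0))
                tube = tubes[m]
                if active[m] and tube and tube[0][_RDY]:
                    self._transfer(m, t)
            else:
                # membrane residence over: return to the endosome store
                self.n_membrane -= 1
                self.n_store += 1
                location[vid] = STORE
                heappush(heap, (t + draw_store() * inv_S, _EV_STORE, vid, sgen[vid]))

        if track:
            dt = t_end - last_t
            occ_time[STORE] += self.n_store * dt
            occ_time[TUBE] += self.n_tube * dt
            occ_time[FUSION] += self.n_fusion * dt
            occ_time[MEMBRANE] += self.n_membrane * dt
            self._last_event_time = t_end
        self.n_events = n_events
        self.clock = t_end
        return self

    # ------------------------------------------------------------------- tags

    def clear_tags(self) -> int:
        """Reset uptake tags; vesicles currently at the membrane count as tagged.

        Returns the number of tagged vesicles (the membrane occupancy), which
        is the uptake measurement at time zero.
        """
        location = self.location
        self.tagged = [location[vid] == MEMBRANE for vid in range(self.params.N)]
        self.n_tagged = self.n_membrane
        return self.n_tagged

    # ---------------------------------------------------------------- queries

    def sequestered_count(self) -> int:
        """Vesicles sitting in microtubules whose paired fusion site is inactive."""
        tubes = self._tubes
        return sum(len(tubes[m]) for m, a in enumerate(self.active) if not a)

    def snapshot(self, per_tube: bool = False) -> StationSnapshot:
        return StationSnapshot(
            time=self.clock,
            store=self.n_store,
            microtubules=self.n_tube,
            fusion_sites=self.n_fusion,
            membrane=self.n_membrane,
            tagged=self.n_tagged,
            sequestered=self.sequestered_count(),
            per_tube=tuple(len(t) for t in self._tubes) if per_tube else None,
        )

    def occupancy_fractions(self) -> np.ndarray:
        """Time-average fraction of the population at each station since t=0.

        Indexed by the location codes ``STORE, TUBE, FUSION, MEMBRANE``.
        """
        if not self._track_occupancy:
            raise ValidationError("network was built without track_occupancy=True")
        if self.clock <= 0:
            raise ValidationError("occupancy fractions undefined at time zero")
        return np.asarray(self._occ_time) / (self.clock * self.params.N)

    def validate(self) -> None:
        """Assert full internal consistency (used by the invariant test suite)."""
        counts = np.bincount(np.asarray(self.location), minlength=4)
        booked = (self.n_store, self.n_tube, self.n_fusion, self.n_membrane)
        if tuple(counts) != booked:
            raise InternalConsistencyError(f"location counts {tuple(counts)} != counters {booked}")
        if counts.sum() != self.params.N:
            raise InternalConsistencyError("vesicle conservation violated")
        for m, tube in enumerate(self._tubes):
            if len(tube) > self.params.L:
                raise InternalConsistencyError(f"tube {m} holds {len(tube)} > L")
            for occ in tube:
                if self.location[occ[_VID]] != TUBE:
                    raise InternalConsistencyError(f"vesicle {occ[_VID]} booked in tube {m} but not located there")
        occupied = sum(1 for v in self._fusion_occupant if v >= 0)
        if occupied != self.n_fusion:
            raise InternalConsistencyError("fusion occupancy mismatch")
        if self.n_tagged != sum(self.tagged):
            raise InternalConsistencyError("tag counter mismatch")


def initialise(params: SystemParameters, seed, **kwargs) -> QueueNetwork:
    """Build a realisation with all ``N`` vesicles in the endosome store at t=0.

    Latent site values are drawn i.i.d. uniform(0,1) and activity is evaluated
    at basal insulin (0 nM).
    """
    return QueueNetwork(params, seed, **kwargs)
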