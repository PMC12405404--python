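"""Named random substreams with buffered draws.

Every realisation of the simulator owns one substream per purpose (store
services, routing, tube services, increment times, fusion services, membrane
services, latent site activations), all spawned from a single seed via
``numpy.random.SeedSequence``.  Within a substream, draws are consumed strictly
in the order the simulation requests them, so a (seed, parameters) pair fully
determines a realisation.  Buffering amortises the cost of single exponential
draws inside the event loop.
"""

from __future__ import annotations

import numpy as np

#: Substream names in spawn order.  The order is part of the RNG contract:
#: changing it changes every realisation.
SUBSTREAMS = (
    "store",       # endosome-store service times
    "routing",     # uniform microtubule choices
    "tube",        # microtubule service times
    "increment",   # head-of-queue increment times
    "fusion",      # fusion-site service times
    "membrane",    # plasma-membrane residence times
    "latent",      # per-site latent activation values u_m
)


def substreams(seed) -> dict[str, np.random.Generator]:
    """Spawn one independent generator per purpose from ``seed``.

    ``seed`` may be an integer or a ``numpy.random.SeedSequence``.
    """
    if isinstance(seed, np.random.SeedSequence):
        root = seed
    else:
        root = np.random.SeedSequence(int(seed))
    children = root.spawn(len(SUBSTREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(SUBSTREAMS, children)}


class ExpStream:
    """Buffered unit-mean exponential draws; divide by a rate at the call site."""

    __slots__ = ("_gen", "_buf", "_i", "_n")

    def __init__(self, gen: np.random.Generator, block: int = 4096):
        self._gen = gen
        self._n = block
        # plain-float buffer: event times must be Python floats so that heap
        # tuple comparisons stay cheap
        self._buf = gen.standard_exponential(block).tolist()
        self._i = 0

    def draw(self) -> float:
        i = self._i
        if i == self._n:
            self._buf = self._gen.standard_exponential(self._n).tolist()
            i = 0
        self._i = i + 1
        return self._buf[i]


class UniformStream:
    """Buffered uniform(0,1) draws (used for routing choices)."""

    __slots__ = ("_gen", "_buf", "_i", "_n")

    def __init__(self, gen: np.random.Generator, block: int = 4096):
        self._gen = gen
        self._n = block
        self._buf = gen.random(block).tolist()
        self._i = 0

    def draw(self) -> float:
        i = self._i
        if i == self._n:
            self._buf = self._gen.random(self._n).tolist()
            i = 0
        self._i = i + 1
        return self._buf[i]
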