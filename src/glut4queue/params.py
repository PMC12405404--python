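"""System parameters for the closed vesicle-trafficking network.

The model is a closed queuing network of ``N`` GLUT4 storage vesicles cycling
through four stations: an infinite-server endosome store (rate ``mu_S`` per
vesicle), ``M`` finite-capacity FIFO microtubules of capacity ``L`` (service
rate ``mu_M``), ``M`` paired single-server fusion sites (rate ``mu_F``) that
are active with an insulin-dependent probability ``p(I)``, and an
infinite-server plasma membrane (rate ``mu_P``).  All rates are per minute;
insulin levels are in nM.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

from .errors import ValidationError

_RATE_FIELDS = ("mu_S", "mu_M", "mu_F", "mu_P")


@dataclass(frozen=True)
class SystemParameters:
    """All rates, the population, the architecture, and the insulin map.

    Attributes
    ----------
    mu_S, mu_M, mu_F, mu_P:
        Service rates (per minute) of the endosome store, microtubules,
        fusion sites, and plasma membrane.
    N:
        Vesicle population (customers in the closed network).
    M:
        Number of microtubule / fusion-site pairs.
    L:
        Capacity of each microtubule.
    active_prob:
        Map from insulin level (nM, must include 0) to the probability that
        a fusion site is active at that level.
    """

    mu_S: float
    mu_M: float
    mu_F: float
    mu_P: float
    N: int
    M: int
    L: int
    active_prob: Mapping[float, float]

    def __post_init__(self):
        for name in _RATE_FIELDS:
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ValidationError(f"{name} must be a finite positive rate, got {value!r}")
        for name in ("N", "M", "L"):
            value = getattr(self, name)
            if not (float(value).is_integer() and value >= 1):
                raise ValidationError(f"{name} must be an integer >= 1, got {value!r}")
            object.__setattr__(self, name, int(value))
        probs = {}
        for level, p in dict(self.active_prob).items():
            level = float(level)
            if level < 0:
                raise ValidationError(f"active_prob insulin level must be >= 0 nM, got {level}")
            if not (0.0 <= float(p) <= 1.0):
                raise ValidationError(f"active_prob[{level:g}] must lie in [0, 1], got {p!r}")
            probs[level] = float(p)
        if 0.0 not in probs:
            raise ValidationError("active_prob must include the basal level 0 nM")
        object.__setattr__(self, "active_prob", probs)

    # -- convenience -------------------------------------------------------

    @property
    def insulin_levels(self) -> tuple[float, ...]:
        return tuple(sorted(self.active_prob))

    def replace(self, **updates) -> "SystemParameters":
        """Return a copy with fields replaced (``active_prob`` is replaced whole)."""
        return dataclasses.replace(self, **updates)

    def with_active_prob(self, level: float, p: float) -> "SystemParameters":
        probs = dict(self.active_prob)
        probs[float(level)] = float(p)
        return dataclasses.replace(self, active_prob=probs)

    # -- I/O ---------------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "mu_S": self.mu_S,
            "mu_M": self.mu_M,
            "mu_F": self.mu_F,
            "mu_P": self.mu_P,
            "N": self.N,
            "M": self.M,
            "L": self.L,
            "active_prob": {f"{k:g}": v for k, v in sorted(self.active_prob.items())},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SystemParameters":
        missing = [k for k in ("mu_S", "mu_M", "mu_F", "mu_P", "N", "M", "L", "active_prob") if k not in d]
        if missing:
            raise ValidationError(f"parameter document missing keys: {', '.join(missing)}")
        probs = {float(k): float(v) for k, v in dict(d["active_prob"]).items()}
        return cls(
            mu_S=float(d["mu_S"]), mu_M=float(d["mu_M"]),
            mu_F=float(d["mu_F"]), mu_P=float(d["mu_P"]),
            N=int(d["N"]), M=int(d["M"]), L=int(d["L"]),
            active_prob=probs,
        )

    def save(self, path) -> None:
        path = str(path)
        doc = self.to_dict()
        if path.endswith((".yaml", ".yml")):
            import yaml

            with open(path, "w") as fh:
                yaml.safe_dump(doc, fh, sort_keys=False)
        else:
            with open(path, "w") as fh:
                json.dump(doc, fh, indent=2)
                fh.write("\n")

    @classmethod
    def from_file(cls, path) -> "SystemParameters":
        path = str(path)
        if path.endswith((".yaml", ".yml")):
            import yaml

            with open(path) as fh:
                doc = yaml.safe_load(fh)
        else:
            with open(path) as fh:
                doc = json.load(fh)
        return cls.from_dict(doc)


def load_reference(which: str = "fit") -> SystemParameters:
    """Load a packaged reference parameter set for the scaled adipocyte network.

    ``which`` is ``"fit"`` for the fitted optimum or ``"start"`` for the
    optimiser start point (N=25000, M=450, L=50, nine insulin levels).
    """
    if which not in ("fit", "start"):
        raise ValidationError(f"which must be 'fit' or 'start', got {which!r}")
    text = resources.files("glut4queue.data").joinpath(f"reference_{which}.json").read_text()
    return SystemParameters.from_dict(json.loads(text))
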