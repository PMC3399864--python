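"""Stimulation protocols, model variants, in-silico knockouts and scans.

A protocol is a list of timed step events on the four inputs: ``il`` (IL-1β
concentration, µM), ``uv``, ``chx`` and ``mg`` (each 0/1).  The primary
stimulation sits at t = 0 by convention; pre-treatments (e.g. a proteasome
inhibitor added one hour in advance) carry negative event times.  The
relaxation phase to the unstimulated steady state always precedes the
earliest event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import yaml

from .params import ParameterSet, RATE_PARAM_NAMES, il1_step_concentration_uM

INPUT_NAMES = ("il", "uv", "chx", "mg")

#: 10 ng/ml IL-1β at 17 kDa, as a molar step amplitude
IL1_STEP_UM = round(il1_step_concentration_uM(10.0, 17.0), 6)  # 0.000588 uM

VariantTag = Literal["ref", "p", "t"]

#: parameter overrides defining the mechanism-deletion variants:
#: "p" removes UVB-induced PP2Ac deactivation, "t" removes UVB-induced
#: translational inhibition.
VARIANT_OVERRIDES: dict[str, dict[str, float]] = {
    "ref": {},
    "p": {"k_uv": 0.0},
    "t": {"uvinh": 0.0},
}


@dataclass(frozen=True)
class Event:
    time_h: float
    input: str
    value: float

    def __post_init__(self) -> None:
        if self.input not in INPUT_NAMES:
            raise ValueError(
                f"unknown input {self.input!r}; expected one of {INPUT_NAMES}"
            )


@dataclass(frozen=True)
class StimulationProtocol:
    """Named set of step events; right-continuous piecewise-constant inputs."""

    name: str
    events: tuple[Event, ...] = ()

    def __post_init__(self) -> None:
        ev = tuple(sorted(self.events, key=lambda e: e.time_h))
        object.__setattr__(self, "events", ev)
        for e in ev:
            if not (e.time_h == e.time_h and abs(e.time_h) < float("inf")):
                raise ValueError(f"event time must be finite, got {e.time_h!r}")

    @property
    def event_times_h(self) -> tuple[float, ...]:
        return tuple(sorted({e.time_h for e in self.events}))

    def inputs_at(self, t_h: float) -> dict[str, float]:
        """Input values at time ``t_h`` (hours); events are right-continuous."""
        u = {n: 0.0 for n in INPUT_NAMES}
        for e in self.events:
            if e.time_h <= t_h:
                u[e.input] = e.value
        return u

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "events": [[e.time_h, e.input, e.value] for e in self.events],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulationProtocol":
        return cls(d["name"], tuple(Event(t, n, v) for t, n, v in d["events"]))


def _proto(name: str, *events: tuple[float, str, float]) -> StimulationProtocol:
    return StimulationProtocol(name, tuple(Event(*e) for e in events))


def standard_protocols() -> dict[str, StimulationProtocol]:
    """The experimental protocol catalogue.

    IL-1 is 10 ng/ml (0.000588 µM); UVB is a single 300 J/m² dose encoded as
    a persistent unit step; MG132 is added either 1 h before or 15 min after
    the primary stimulation; CHX is applied alone at t = 0.
    """
    il = IL1_STEP_UM
    return {
        p.name: p
        for p in (
            _proto("UNSTIMULATED"),
            _proto("IL1", (0.0, "il", il)),
            _proto("UVB", (0.0, "uv", 1.0)),
            _proto("IL1_UVB", (0.0, "il", il), (0.0, "uv", 1.0)),
            _proto(
                "IL1_UVB_MG_minus1h",
                (-1.0, "mg", 1.0), (0.0, "il", il), (0.0, "uv", 1.0),
            ),
            _proto(
                "IL1_UVB_MG_plus15",
                (0.0, "il", il), (0.0, "uv", 1.0), (0.25, "mg", 1.0),
            ),
            _proto("CHX", (0.0, "chx", 1.0)),
        )
    }


# -- in-silico perturbations -------------------------------------------------

KNOCKOUT_MECHANISMS = ("pp2a_deactivation", "translational_inhibition", "both")


def knockout(params: ParameterSet, mechanism: str) -> ParameterSet:
    """Delete one (or both) of the UVB mechanisms in silico.

    ``pp2a_deactivation`` zeroes ``k_uv``; ``translational_inhibition`` zeroes
    ``uvinh``; ``both`` zeroes both.  Everything else is untouched.
    """
    if mechanism == "pp2a_deactivation":
        return params.replace(k_uv=0.0)
    if mechanism == "translational_inhibition":
        return params.replace(uvinh=0.0)
    if mechanism == "both":
        return params.replace(k_uv=0.0, uvinh=0.0)
    raise ValueError(
        f"unknown mechanism {mechanism!r}; expected one of {KNOCKOUT_MECHANISMS}"
    )


def scan_parameter(
    params: ParameterSet, name: str, factors: Iterable[float]
) -> list[ParameterSet]:
    """One parameter-set copy per multiplicative factor.

    Derived constants and the ``e_1a = 2*i_1a`` constraint are re-enforced by
    construction of each copy.
    """
    if name not in RATE_PARAM_NAMES:
        raise ValueError(f"unknown scannable parameter {name!r}")
    out = []
    for f in factors:
        if not f > 0:
            raise ValueError(f"scan factors must be > 0, got {f!r}")
        out.append(params.replace(**{name: getattr(params, name) * f}))
    return out


def mef_like_scenario(params: ParameterSet) -> ParameterSet:
    """Cell-type scenario with 3-fold constitutive IKKβ phosphorylation and
    PP2Ac activity reduced to 1%.

    PP2Ac "activity" is implemented as the maximal dephosphorylation capacity
    ``k_dp`` because the PP2A state itself is normalised to 1.
    """
    (p3,) = scan_parameter(params, "k_pconst", [3.0])
    (out,) = scan_parameter(p3, "k_dp", [0.01])
    return out


# -- serialisation -----------------------------------------------------------

def protocols_to_yaml(protocols: Iterable[StimulationProtocol], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([p.to_dict() for p in protocols], fh, sort_keys=False)


def protocols_from_yaml(path) -> dict[str, StimulationProtocol]:
    with open(path) as fh:
        items = yaml.safe_load(fh)
    out = {}
    for d in items:
        p = StimulationProtocol.from_dict(d)
        out[p.name] = p
    return out
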