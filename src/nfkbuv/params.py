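"""Model parameters, structural constants and derived quantities.

The model couples a normalised IKKβ phosphorylation module (IL-1 receptor
turnover, receptor-complex formation, Michaelis–Menten dephosphorylation by
PP2A) to a reduced IκBα–NF-κB feedback module.  All rate constants are in
s⁻¹ (bimolecular ones in µM⁻¹ s⁻¹); concentrations are in µM; the IKK-module
states are dimensionless.  Time is seconds internally — the public API
converts from hours at the boundary.

Two parameters encode the UVB mechanisms:

* ``k_uv`` — first-order deactivation rate of the PP2A catalytic subunit
  while the UVB input is on.
* ``uvinh`` — fraction of translation inhibited by UVB (applied to both
  IκBα and IL-1 receptor synthesis), in [0, 1].

The nuclear export rate ``e_1a`` is not free: it is held at exactly
``2 * i_1a`` (a literature-derived constraint) and recomputed whenever a
parameter set is built.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

AVOGADRO = 6.02214076e23  # mol^-1

#: names of the rate/mechanism parameters that may be varied or fitted
RATE_PARAM_NAMES = (
    "k_ilr", "k_act", "k_int", "k_p", "k_pconst", "k_dp", "km",
    "k_uv", "uvinh",
    "a_1", "a_2", "a_3",
    "c_1a", "c_3a", "c_4a", "c_5a", "c_6a",
    "i_1a",
)

#: structural constants (measured, never fitted)
STRUCTURAL_PARAM_NAMES = ("k_v", "volume", "numnfkb")


class ParameterError(ValueError):
    """Raised when a parameter set violates a model invariant."""


@dataclass(frozen=True)
class ParameterSet:
    """All rate constants and structural constants of the model.

    Instances are immutable; use :meth:`replace` to derive modified copies
    (this re-enforces the ``e_1a = 2 * i_1a`` constraint automatically).
    """

    # IKKβ phosphorylation module (normalised, dimensionless states)
    k_ilr: float      # IL-1 receptor turnover, s^-1
    k_act: float      # IL-1-driven receptor-complex formation, uM^-1 s^-1
    k_int: float      # receptor-complex internalisation/decay, s^-1
    k_p: float        # ILRc-driven IKKβ phosphorylation, s^-1
    k_pconst: float   # constitutive IKKβ phosphorylation, s^-1
    k_dp: float       # maximal PP2A-mediated dephosphorylation rate, s^-1
    km: float         # Michaelis constant of IKKβ dephosphorylation (normalised IKK units)
    # UVB mechanisms
    k_uv: float       # UVB-induced PP2Ac deactivation rate, s^-1
    uvinh: float      # UVB translational-inhibition fraction in [0, 1]
    # IκBα–NF-κB module
    a_1: float        # IκBα·NF-κB association, uM^-1 s^-1
    a_2: float        # IKKp-dependent degradation of free IκBα, s^-1 per normalised IKKp
    a_3: float        # IKKp-dependent degradation of complexed IκBα, s^-1 per normalised IKKp
    c_1a: float       # NF-κB-driven IκBα transcription, s^-1
    c_3a: float       # IκBα mRNA degradation, s^-1
    c_4a: float       # IκBα translation, s^-1
    c_5a: float       # constitutive degradation of free IκBα, s^-1
    c_6a: float       # constitutive degradation of complexed IκBα, s^-1
    i_1a: float       # IκBα nuclear import, s^-1
    # structural constants
    k_v: float = 2.9           # cytoplasm:nucleus volume ratio
    volume: float = 2e-12      # total cell volume, l
    numnfkb: float = 60000.0   # NF-κB molecules per cell
    # observable scaling factors (gauge parameters, fitted without bounds)
    scale_ikk: float = 1.0
    scale_ikba: float = 1.0
    scale_nfkb_by_stimulation: Mapping[str, float] = field(default_factory=dict)
    # derived, set in __post_init__
    e_1a: float = field(init=False)    # IκBα nuclear export, s^-1 (= 2*i_1a)
    nfkb_tot: float = field(init=False)  # total NF-κB as cytoplasmic concentration, uM

    def __post_init__(self) -> None:
        object.__setattr__(self, "e_1a", 2.0 * self.i_1a)
        object.__setattr__(
            self, "scale_nfkb_by_stimulation", dict(self.scale_nfkb_by_stimulation)
        )
        dc = derived_constants(self)
        object.__setattr__(self, "nfkb_tot", dc["nfkb_tot"])
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for name in RATE_PARAM_NAMES + STRUCTURAL_PARAM_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ParameterError(f"parameter {name!r} is not finite: {v!r}")
            if v < 0:
                raise ParameterError(f"parameter {name!r} must be >= 0, got {v!r}")
        if not 0.0 <= self.uvinh <= 1.0:
            raise ParameterError(f"uvinh must lie in [0, 1], got {self.uvinh!r}")
        for name in ("k_v", "volume", "numnfkb"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")

    # -- derivation helpers -------------------------------------------------
    def replace(self, **changes: Any) -> "ParameterSet":
        """Return a copy with ``changes`` applied; derived fields recomputed."""
        unknown = set(changes) - {f.name for f in dataclasses.fields(self) if f.init}
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **changes)

    def rates_key(self) -> tuple:
        """Hashable key over everything that affects the dynamics (not scales)."""
        return tuple(
            getattr(self, n) for n in RATE_PARAM_NAMES + STRUCTURAL_PARAM_NAMES
        )

    def to_dict(self) -> dict:
        d = {n: getattr(self, n) for n in RATE_PARAM_NAMES + STRUCTURAL_PARAM_NAMES}
        d["scale_ikk"] = self.scale_ikk
        d["scale_ikba"] = self.scale_ikba
        d["scale_nfkb_by_stimulation"] = dict(self.scale_nfkb_by_stimulation)
        return d


def derived_constants(params: "ParameterSet | Mapping[str, float]") -> dict:
    """Compartment-derived constants.

    Returns ``cytVol`` (cytoplasmic volume, l), ``nfkb_tot`` (concentration of
    NF-κB if located entirely in the cytoplasm, µM) and ``c_1a_max`` (upper
    bound of the transcription rate constant, s⁻¹, from a maximal mRNA
    production rate of 0.16 molecules/s reached when all NF-κB is nuclear,
    with the cytoplasm/nucleus compartment correction).
    """
    get = (lambda n: getattr(params, n)) if isinstance(params, ParameterSet) \
        else (lambda n: params[n])
    volume, k_v, numnfkb = get("volume"), get("k_v"), get("numnfkb")
    if volume <= 0 or k_v <= 0 or numnfkb <= 0:
        raise ParameterError("volume, k_v and numnfkb must all be > 0")
    cyt_vol = volume / (1.0 + 1.0 / k_v)
    nfkb_tot = numnfkb / (AVOGADRO * cyt_vol) * 1e6  # mol/l -> uM
    c_1a_max = 0.16 / (numnfkb * k_v)
    return {"cytVol": cyt_vol, "nfkb_tot": nfkb_tot, "c_1a_max": c_1a_max}


def il1_step_concentration_uM(ng_per_ml: float = 10.0, kda: float = 17.0) -> float:
    """Molar IL-1β concentration (µM) of a mass dose, default 10 ng/ml at 17 kDa."""
    grams_per_litre = ng_per_ml * 1e-9 * 1e3
    return grams_per_litre / (kda * 1e3) * 1e6


def default_parameters() -> ParameterSet:
    """Reference parameterisation of the model.

    Structural constants (k_v, volume, numnfkb) and the parameters carrying
    literature-derived bounds use the measured/printed values; the remaining
    rate constants were calibrated once so that the reference model reproduces
    the benchmark behaviours (IL-1 IKKβ phosphorylation transient, IκBα
    overshoot, sustained NF-κB under IL-1+UVB, ≈6 h IκBα half-life under CHX,
    and the constitutive-phosphorylation scan results under UVB).  See
    docs/methods.md for the calibration rationale.
    """
    return ParameterSet(
        k_ilr=2.0e-5,
        k_act=8.5,
        k_int=1.0e-3,
        k_p=0.05,
        k_pconst=5.0e-6,
        k_dp=2.0e-2,
        km=0.03,
        k_uv=7.0e-4,
        uvinh=0.9,
        a_1=1.0,
        a_2=0.06,
        a_3=0.015,
        c_1a=9.0e-7,
        c_3a=4.0e-4,
        c_4a=0.55,
        c_5a=5.8e-4,
        c_6a=3.1e-5,
        i_1a=3.45e-3,
    )


# -- serialisation -----------------------------------------------------------

def parameters_to_yaml(params: ParameterSet, path) -> None:
    """Write a flat ``name -> {value, unit}`` mapping (scales kept separately)."""
    from .fitting import default_bounds  # local import to avoid a cycle

    bounds = default_bounds(params)
    units = _UNITS
    rec: dict[str, Any] = {}
    for n in RATE_PARAM_NAMES + STRUCTURAL_PARAM_NAMES:
        entry: dict[str, Any] = {"value": float(getattr(params, n)),
                                 "unit": units.get(n, "")}
        if n in bounds:
            lo, hi = bounds[n]
            entry["lower"], entry["upper"] = lo, hi
        entry["fixed"] = n in STRUCTURAL_PARAM_NAMES
        rec[n] = entry
    rec["scale_ikk"] = {"value": float(params.scale_ikk), "unit": "", "fixed": False}
    rec["scale_ikba"] = {"value": float(params.scale_ikba), "unit": "", "fixed": False}
    rec["scale_nfkb_by_stimulation"] = {
        k: float(v) for k, v in params.scale_nfkb_by_stimulation.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(rec, fh, sort_keys=False)


def parameters_from_yaml(path) -> ParameterSet:
    """Load a parameter file written by :func:`parameters_to_yaml`.

    ``e_1a`` and ``nfkb_tot`` are always recomputed from their defining
    relations; an explicit ``e_1a`` entry inconsistent with ``2*i_1a`` is an
    error.
    """
    with open(path) as fh:
        rec = yaml.safe_load(fh)
    kwargs: dict[str, Any] = {}
    for n in RATE_PARAM_NAMES + STRUCTURAL_PARAM_NAMES:
        if n not in rec:
            raise ParameterError(f"parameter file misses {n!r}")
        kwargs[n] = float(rec[n]["value"] if isinstance(rec[n], dict) else rec[n])
    if "e_1a" in rec:
        e_1a = float(rec["e_1a"]["value"] if isinstance(rec["e_1a"], dict) else rec["e_1a"])
        if not math.isclose(e_1a, 2.0 * kwargs["i_1a"], rel_tol=1e-9):
            raise ParameterError("e_1a in file violates the e_1a = 2*i_1a constraint")
    for n in ("scale_ikk", "scale_ikba"):
        if n in rec:
            kwargs[n] = float(rec[n]["value"] if isinstance(rec[n], dict) else rec[n])
    if "scale_nfkb_by_stimulation" in rec:
        kwargs["scale_nfkb_by_stimulation"] = {
            k: float(v) for k, v in rec["scale_nfkb_by_stimulation"].items()
        }
    return ParameterSet(**kwargs)


_UNITS = {
    "k_ilr": "s^-1", "k_act": "uM^-1 s^-1", "k_int": "s^-1", "k_p": "s^-1",
    "k_pconst": "s^-1", "k_dp": "s^-1", "km": "normalised IKK units",
    "k_uv": "s^-1", "uvinh": "dimensionless",
    "a_1": "uM^-1 s^-1", "a_2": "s^-1", "a_3": "s^-1",
    "c_1a": "s^-1", "c_3a": "s^-1", "c_4a": "s^-1", "c_5a": "s^-1",
    "c_6a": "s^-1", "i_1a": "s^-1",
    "k_v": "dimensionless", "volume": "l", "numnfkb": "molecules",
}
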