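"""ODE core: right-hand side, steady-state relaxation and event-aware simulation.

The dynamic state has eight components (in this order):

==========  ==================================================  =========
name        meaning                                             unit
==========  ==================================================  =========
ILR         free IL-1 receptor (normalised)                     –
ILRc        active IL-1 receptor complex (normalised)           –
PP2A        active PP2A catalytic subunit (normalised)          –
IKKp        phosphorylated IKKβ (normalised, in [0, 1])         –
IkBa_t      IκBα mRNA                                           model units
IkBa        free cytosolic IκBα                                 µM
IkBa_n      free nuclear IκBα                                   µM
NFkB_n      nuclear NF-κB                                       µM
==========  ==================================================  =========

Two further quantities are definitions, not integrated states, and follow
from mass conservation of IKK and NF-κB::

    IKK      = 1 - IKKp
    IkBaNFkB = nfkb_tot - NFkB_n / k_v     (cytosolic IκBα·NF-κB complex)

The ``k_v`` division converts the nuclear concentration to its cytoplasmic
equivalent.  Inputs are right-continuous step functions; the integrator is
restarted at every input discontinuity rather than stepping across it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import ParameterSet
from .protocols import (
    INPUT_NAMES,
    VARIANT_OVERRIDES,
    StimulationProtocol,
)

STATE_NAMES = ("ILR", "ILRc", "PP2A", "IKKp", "IkBa_t", "IkBa", "IkBa_n", "NFkB_n")
DERIVED_NAMES = ("IKK", "IkBaNFkB")

HOUR = 3600.0  # s
RELAXATION_HOURS = 120.0

#: default solver tolerances for trajectory simulation
RTOL_DEFAULT = 1e-8
ATOL_DEFAULT = 1e-10


class SimulationError(RuntimeError):
    """Raised when the stiff solver fails to integrate a segment."""


def _rhs_factory(p: ParameterSet, u: Mapping[str, float]) -> Callable:
    """Derivative function for one constant-input segment (time in seconds)."""
    il, uv, chx, mg = (float(u[n]) for n in INPUT_NAMES)
    syn = (1.0 - p.uvinh * uv) * (1.0 - chx)   # gates all protein synthesis
    deg = 1.0 - mg                             # gates proteasomal degradation
    k_ilr, k_act_il, k_int = p.k_ilr, p.k_act * il, p.k_int
    k_p, k_pconst, k_dp, km, k_uv_uv = p.k_p, p.k_pconst, p.k_dp, p.km, p.k_uv * uv
    a_1, a_2, a_3 = p.a_1, p.a_2, p.a_3
    c_1a, c_3a, c_5a, c_6a = p.c_1a, p.c_3a, p.c_5a, p.c_6a
    c_4a_syn = p.c_4a * syn
    i_1a, e_1a, k_v, nfkb_tot = p.i_1a, p.e_1a, p.k_v, p.nfkb_tot

    def f(t: float, y: np.ndarray) -> list[float]:
        ILR, ILRc, PP2A, IKKp, IkBa_t, IkBa, IkBa_n, NFkB_n = y
        denom = km + IKKp
        dephos = k_dp * PP2A * (IKKp / denom) if denom > 0.0 else 0.0
        assoc = a_1 * IkBa_n * NFkB_n
        complex_deg = (a_3 * IKKp + c_6a) * deg
        return [
            k_ilr * syn - k_ilr * ILR - k_act_il * ILR,
            k_act_il * ILR - k_int * ILRc,
            -k_uv_uv * PP2A,
            (k_p * ILRc + k_pconst) * (1.0 - IKKp) - dephos,
            c_1a * NFkB_n - c_3a * IkBa_t,
            # nuclear transport carries compartment factors (amount
            # conservation: nuclear concentrations change k_v-fold faster
            # for the same molecular flux)
            c_4a_syn * IkBa_t - (a_2 * IKKp + c_5a) * deg * IkBa
            - i_1a * IkBa + (e_1a / k_v) * IkBa_n,
            k_v * i_1a * IkBa - e_1a * IkBa_n - assoc,
            k_v * complex_deg * (nfkb_tot - NFkB_n / k_v) - assoc,
        ]

    return f


def rhs(
    state: Sequence[float],
    t: float,
    params: ParameterSet,
    inputs: Mapping[str, float],
) -> np.ndarray:
    """Time derivatives of the eight states (time in seconds).

    Validates finiteness of every state component and input; raises
    ``ValueError`` naming the offending component otherwise.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (len(STATE_NAMES),):
        raise ValueError(f"state must have {len(STATE_NAMES)} components, got {y.shape}")
    for name, value in zip(STATE_NAMES, y):
        if not np.isfinite(value):
            raise ValueError(f"non-finite state component {name!r}: {value!r}")
    u = {n: float(inputs.get(n, 0.0)) for n in INPUT_NAMES}
    for name, value in u.items():
        if not np.isfinite(value):
            raise ValueError(f"non-finite input {name!r}: {value!r}")
    return np.asarray(_rhs_factory(params, u)(float(t), y))


#: initial condition before relaxation: fully unphosphorylated IKK module,
#: all NF-κB in the cytosolic complex, no free IκBα or mRNA.
def initial_state(params: ParameterSet) -> np.ndarray:
    return np.array([1.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0])


_ZERO_INPUTS = {n: 0.0 for n in INPUT_NAMES}

# steady-state cache: relaxation is the costliest part of a chi^2 evaluation
# and depends only on the dynamics parameters and tolerances
_relax_cache: dict[tuple, np.ndarray] = {}
_RELAX_CACHE_MAX = 4096


def relax_to_steady_state(
    params: ParameterSet,
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
    stationarity_tol: float = 1e-10,
) -> np.ndarray:
    """Unstimulated steady state, via a 120 h relaxation integration.

    Integrates from :func:`initial_state` with all inputs zero and returns the
    final state.  Emits a ``RuntimeWarning`` if the largest derivative
    component at the end exceeds ``stationarity_tol``.
    """
    key = (params.rates_key(), rtol, atol)
    cached = _relax_cache.get(key)
    if cached is not None:
        return cached.copy()
    f = _rhs_factory(params, _ZERO_INPUTS)
    sol = solve_ivp(
        f, (0.0, RELAXATION_HOURS * HOUR), initial_state(params),
        method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"steady-state relaxation failed: {sol.message}")
    y = sol.y[:, -1]
    resid = np.abs(f(0.0, y))
    if resid.max() > stationarity_tol:
        warnings.warn(
            "state after 120 h relaxation is not stationary: "
            f"max |dy/dt| = {resid.max():.3e} (component "
            f"{STATE_NAMES[int(resid.argmax())]})",
            RuntimeWarning,
            stacklevel=2,
        )
    if len(_relax_cache) >= _RELAX_CACHE_MAX:
        _relax_cache.clear()
    _relax_cache[key] = y.copy()
    return y


@dataclass(frozen=True)
class Trajectory:
    """Simulated states on a time grid, with the conservation-derived states."""

    times_h: np.ndarray          # shape (n,)
    states: np.ndarray           # shape (n, 8), columns in STATE_NAMES order
    params: ParameterSet
    protocol: StimulationProtocol
    variant: str

    def state(self, name: str) -> np.ndarray:
        if name in STATE_NAMES:
            return self.states[:, STATE_NAMES.index(name)]
        if name == "IKK":
            return 1.0 - self.state("IKKp")
        if name == "IkBaNFkB":
            return self.params.nfkb_tot - self.state("NFkB_n") / self.params.k_v
        raise KeyError(f"unknown state {name!r}")

    def total_ikba(self) -> np.ndarray:
        """Total cellular IκBα: free cytosolic + complexed + nuclear/k_v (µM)."""
        return (
            self.state("IkBa")
            + self.state("IkBaNFkB")
            + self.state("IkBa_n") / self.params.k_v
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame with columns (stimulation, variant, time_h, state, value)."""
        rows = []
        for name in STATE_NAMES + DERIVED_NAMES:
            v = self.state(name)
            rows.append(
                pd.DataFrame(
                    {
                        "stimulation": self.protocol.name,
                        "variant": self.variant,
                        "time_h": self.times_h,
                        "state": name,
                        "value": v,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def apply_variant(params: ParameterSet, variant: str) -> ParameterSet:
    """Parameter set with a model-variant override applied (caller untouched)."""
    try:
        overrides = VARIANT_OVERRIDES[variant.lower()]
    except KeyError:
        raise ValueError(
            f"unknown variant {variant!r}; expected one of {tuple(VARIANT_OVERRIDES)}"
        ) from None
    return params.replace(**overrides) if overrides else params


def simulate(
    params: ParameterSet,
    protocol: StimulationProtocol,
    variant: str = "ref",
    t_grid_h: Sequence[float] | None = None,
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
) -> Trajectory:
    """Simulate a stimulation protocol after steady-state relaxation.

    The integrator is restarted at every input discontinuity.  ``t_grid_h``
    (hours, sorted) defaults to a dense 0–16 h grid.  Events after the end of
    the grid are an error.
    """
    if t_grid_h is None:
        t_grid_h = np.linspace(0.0, 16.0, 481)
    grid = np.asarray(t_grid_h, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("t_grid_h must be a non-empty 1-D sequence of hours")
    if np.any(np.diff(grid) < 0):
        raise ValueError("t_grid_h must be sorted ascending")

    p = apply_variant(params, variant)
    event_times = list(protocol.event_times_h)
    if event_times and event_times[-1] > grid[-1]:
        raise ValueError(
            f"protocol event at {event_times[-1]} h lies outside the "
            f"integration window ending at {grid[-1]} h"
        )
    t_start = min([grid[0], 0.0] + event_times)
    breaks = sorted({t_start, *[t for t in event_times if t > t_start], grid[-1]})
    if breaks[-1] > breaks[0]:
        segments = list(zip(breaks[:-1], breaks[1:]))
    else:  # degenerate single-instant grid
        segments = []

    y = relax_to_steady_state(p, rtol=rtol, atol=atol)
    out = np.empty((grid.size, len(STATE_NAMES)))
    filled = np.zeros(grid.size, dtype=bool)
    at_start = grid == t_start
    out[at_start] = y
    filled |= at_start

    for ta, tb in segments:
        u = protocol.inputs_at(ta)
        f = _rhs_factory(p, u)
        sel = (grid > ta) & (grid <= tb)
        t_eval = np.unique(np.append(grid[sel], tb)) * HOUR
        sol = solve_ivp(
            f, (ta * HOUR, tb * HOUR), y,
            method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval,
        )
        if not sol.success:
            raise SimulationError(
                f"integration failed on [{ta}, {tb}] h under protocol "
                f"{protocol.name!r}: {sol.message}"
            )
        if sel.any():
            tg = grid[sel] * HOUR
            idx = np.searchsorted(sol.t, tg)
            idx = np.clip(idx, 0, sol.t.size - 1)
            out[sel] = sol.y[:, idx].T
            filled |= sel
        y = sol.y[:, -1]

    if not filled.all():
        # grid points before the first breakpoint sit at the steady state
        out[~filled] = relax_to_steady_state(p, rtol=rtol, atol=atol)

    return Trajectory(
        times_h=grid, states=out, params=p, protocol=protocol,
        variant=variant.lower(),
    )
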