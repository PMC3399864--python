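"""χ² objective, literature-derived parameter bounds and multistart fitting.

The objective is the standard SD-weighted sum of squares over all settings,
observables and time points::

    chi2(theta) = sum_i sum_j sum_k ((y_ijk - y(t_ijk, theta, i, j)) / sigma_ijk)**2

Optimisation follows a classical multistart schedule: a sequence of runs, each
launching many local bound-constrained trust-region least-squares fits from
the incumbent best parameter vector perturbed per-coordinate by a factor
``10**eps`` with ``eps ~ Normal(0, n**2)`` (``n`` is the run's perturbation
width; the reference schedule is 4 runs of 1000 fits with n = 4, 1, 0.1,
0.01).  Positive rate constants are handled internally in log10 space, so
the multiplicative perturbation is additive there; the translational
inhibition fraction ``uvinh`` lives on a linear [0, 1] scale.

Scaling factors are fit parameters without bounds.  An optional analytic
profiling mode replaces them by their closed-form weighted-least-squares
optimum per scaling group (same optimum, fewer free coordinates); it is off
by default.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .model import SimulationError, simulate
from .observables import TimeSeriesDataset
from .params import ParameterSet, derived_constants
from .protocols import StimulationProtocol, VARIANT_OVERRIDES, standard_protocols

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

#: parameters fitted on a linear scale (everything else positive -> log10)
LINEAR_SCALE_PARAMS = ("uvinh",)


def default_bounds(params: ParameterSet | None = None) -> dict[str, tuple[float, float]]:
    """Literature-derived fitting bounds for the rate parameters.

    Half-life ranges are converted through ``rate = ln 2 / t_half``.  The
    nuclear export rate ``e_1a`` never appears: it is the derived constraint
    ``2 * i_1a``.  Scaling factors are unbounded and also absent here.
    Parameters without a literature bound (receptor-module rates, ``k_dp``,
    ``km``, ``k_uv``, ``c_4a``, ``c_6a``) are fitted without bounds.
    """
    c_1a_max = derived_constants(params)["c_1a_max"] if params is not None \
        else 0.16 / (60000.0 * 2.9)
    return {
        "k_ilr": (9.3e-6, 2.8e-5),           # from receptor numbers per cell
        "k_p": (0.0, 0.095),                 # upper bound from the IKK module
        "a_1": (0.3, 1.0),                   # IκBα·NF-κB association
        "a_2": (0.0, 0.8),                   # 1 uM^-1 s^-1 x 0.8 uM IKK
        "a_3": (0.0, 0.8),
        "c_1a": (0.0, c_1a_max),             # transcription <= 0.16 molec/s
        "c_3a": (LN2 / 2700.0, LN2 / 900.0),  # mRNA half-life 45..15 min
        "c_5a": (LN2 / 1200.0, LN2 / 360.0),  # free-IκBα half-life 20..6 min
        "uvinh": (0.0, 1.0),                 # complete inhibition at most
        "i_1a": (1.0e-4, 5.0e-2),            # nuclear import, broad range
    }


# ---------------------------------------------------------------------------
# chi-square


def _group_by_stimulation(
    datasets: Sequence[TimeSeriesDataset],
) -> dict[str, list[TimeSeriesDataset]]:
    groups: dict[str, list[TimeSeriesDataset]] = {}
    for ds in datasets:
        groups.setdefault(ds.stimulation, []).append(ds)
    return groups


def _simulate_observables(
    params: ParameterSet,
    protocol: StimulationProtocol,
    variant: str,
    datasets: Sequence[TimeSeriesDataset],
    rtol: float,
    atol: float,
) -> dict[int, np.ndarray]:
    """Unscaled model observables of one stimulation at each dataset's times.

    One simulation serves every dataset of the stimulation: the grid is the
    union of all requested times (plus the protocol's event times so the
    integration window covers them).
    """
    t_union = np.unique(np.concatenate([ds.times_h for ds in datasets]))
    t_end = max(t_union[-1], *(protocol.event_times_h or (0.0,)))
    grid = np.unique(np.append(t_union, t_end))
    traj = simulate(params, protocol, variant=variant, t_grid_h=grid,
                    rtol=rtol, atol=atol)
    raw = {
        "IKKp_obs": traj.state("IKKp"),
        "IkBa_obs": traj.total_ikba(),
        "NFkB_obs": traj.state("NFkB_n"),
    }
    out = {}
    for k, ds in enumerate(datasets):
        idx = np.searchsorted(grid, ds.times_h)
        out[id(ds)] = raw[ds.observable][idx]
    return out


def _scale_key(ds: TimeSeriesDataset) -> tuple:
    """Scaling-group key: IKK and IκBα share one global factor each, NF-κB
    carries one factor per stimulation."""
    if ds.observable == "NFkB_obs":
        return ("NFkB_obs", ds.stimulation)
    return (ds.observable,)


def _scale_value(params: ParameterSet, key: tuple) -> float:
    if key[0] == "IKKp_obs":
        return params.scale_ikk
    if key[0] == "IkBa_obs":
        return params.scale_ikba
    return params.scale_nfkb_by_stimulation.get(key[1], 1.0)


def _profiled_scales(
    datasets: Sequence[TimeSeriesDataset],
    model: Mapping[int, np.ndarray],
) -> dict[tuple, float]:
    """Closed-form optimal scale per scaling group (weighted least squares)."""
    num: dict[tuple, float] = {}
    den: dict[tuple, float] = {}
    for ds in datasets:
        m = model[id(ds)][ds.mask]
        y = ds.values[ds.mask]
        w = 1.0 / ds.sds[ds.mask] ** 2
        key = _scale_key(ds)
        num[key] = num.get(key, 0.0) + float(np.sum(w * y * m))
        den[key] = den.get(key, 0.0) + float(np.sum(w * m * m))
    return {k: (num[k] / den[k] if den[k] > 0 else 1.0) for k in num}


def weighted_residuals(
    params: ParameterSet,
    datasets: Sequence[TimeSeriesDataset],
    variant: str = "ref",
    protocols: Mapping[str, StimulationProtocol] | None = None,
    profile_scales: bool = False,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> np.ndarray:
    """(data - model)/SD over all masked points of all datasets."""
    cat = dict(standard_protocols())
    if protocols:
        cat.update(protocols)
    model: dict[int, np.ndarray] = {}
    for stim, group in _group_by_stimulation(datasets).items():
        if stim not in cat:
            raise KeyError(f"unknown stimulation id {stim!r}")
        model.update(
            _simulate_observables(params, cat[stim], variant, group, rtol, atol)
        )
    scales = (_profiled_scales(datasets, model) if profile_scales
              else {_scale_key(ds): _scale_value(params, _scale_key(ds))
                    for ds in datasets})
    parts = []
    for ds in datasets:
        s = scales[_scale_key(ds)]
        r = (ds.values - s * model[id(ds)]) / ds.sds
        parts.append(r[ds.mask])
    return np.concatenate(parts) if parts else np.empty(0)


def chi_square(
    params: ParameterSet,
    datasets: Sequence[TimeSeriesDataset],
    variant: str = "ref",
    protocols: Mapping[str, StimulationProtocol] | None = None,
    profile_scales: bool = False,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> float:
    """Total χ²; additive over datasets; +inf (with a warning) if the
    simulation fails, so optimisers can reject the point gracefully."""
    try:
        r = weighted_residuals(params, datasets, variant, protocols,
                               profile_scales, rtol, atol)
    except SimulationError as exc:
        logger.warning("simulation failure in chi_square: %s", exc)
        return float("inf")
    return float(np.dot(r, r))


def chi_square_per_dataset(
    params: ParameterSet,
    datasets: Sequence[TimeSeriesDataset],
    variant: str = "ref",
    **kwargs,
) -> dict[tuple, float]:
    """χ² contribution of each (observable, stimulation) dataset."""
    out = {}
    for ds in datasets:
        out[(ds.observable, ds.stimulation)] = chi_square(
            params, [ds], variant, **kwargs
        )
    return out


# ---------------------------------------------------------------------------
# multistart optimisation


@dataclass(frozen=True)
class FitProblem:
    """A fitting task: datasets, variant, free parameters and the start point.

    ``free_params`` lists rate/mechanism parameter names to optimise; names
    forced by the variant (e.g. ``k_uv`` under variant ``p``) are rejected.
    ``fit_scales`` adds the relevant scaling factors as free parameters
    (ignored when ``profile_scales`` is on).
    """

    datasets: tuple[TimeSeriesDataset, ...]
    variant: str = "ref"
    free_params: tuple[str, ...] = ("uvinh", "k_uv", "c_3a", "c_5a")
    start: ParameterSet = None  # type: ignore[assignment]
    seed: int = 0
    bounds: Mapping[str, tuple[float, float]] = None  # type: ignore[assignment]
    profile_scales: bool = False
    fit_scales: bool = True
    rtol: float = 1e-7
    atol: float = 1e-9
    #: half-width (decades) of the default box for parameters without a bound
    open_bound_decades: float = 3.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "datasets", tuple(self.datasets))
        forced = VARIANT_OVERRIDES.get(self.variant.lower(), {})
        bad = [n for n in self.free_params if n in forced]
        if bad:
            raise ValueError(
                f"cannot fit {bad} under variant {self.variant!r} "
                f"(forced to {forced})"
            )
        if self.start is None:
            raise ValueError("FitProblem requires a start ParameterSet")
        if self.bounds is None:
            object.__setattr__(self, "bounds", default_bounds(self.start))

    # -- internal parameter vector ------------------------------------------
    def _scale_keys(self) -> list[tuple]:
        if self.profile_scales or not self.fit_scales:
            return []
        return sorted({_scale_key(ds) for ds in self.datasets})

    def vector_names(self) -> list[str]:
        return list(self.free_params) + [
            "scale:" + ":".join(k) for k in self._scale_keys()
        ]

    def to_vector(self, params: ParameterSet) -> np.ndarray:
        vals = []
        for n in self.free_params:
            v = getattr(params, n)
            vals.append(v if n in LINEAR_SCALE_PARAMS else math.log10(max(v, 1e-300)))
        for key in self._scale_keys():
            vals.append(math.log10(max(_scale_value(params, key), 1e-300)))
        return np.array(vals)

    def from_vector(self, vec: np.ndarray) -> ParameterSet:
        changes: dict = {}
        for n, v in zip(self.free_params, vec):
            changes[n] = float(v) if n in LINEAR_SCALE_PARAMS else 10.0 ** float(v)
        scale_keys = self._scale_keys()
        if scale_keys:
            nfkb = dict(self.start.scale_nfkb_by_stimulation)
            for key, v in zip(scale_keys, vec[len(self.free_params):]):
                s = 10.0 ** float(v)
                if key[0] == "IKKp_obs":
                    changes["scale_ikk"] = s
                elif key[0] == "IkBa_obs":
                    changes["scale_ikba"] = s
                else:
                    nfkb[key[1]] = s
            changes["scale_nfkb_by_stimulation"] = nfkb
        return self.start.replace(**changes)

    def vector_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for n in self.free_params:
            b = self.bounds.get(n)
            if n in LINEAR_SCALE_PARAMS:
                l, h = b if b else (0.0, 1.0)
            else:
                v = getattr(self.start, n)
                span = 10.0 ** self.open_bound_decades
                l = b[0] if b and b[0] > 0 else v / span
                h = b[1] if b and np.isfinite(b[1]) and b[1] > 0 else v * span
                l, h = math.log10(max(l, 1e-300)), math.log10(max(h, 1e-300))
            lo.append(l)
            hi.append(h)
        for key in self._scale_keys():   # scales: unbounded in principle
            v = _scale_value(self.start, key)
            lo.append(math.log10(max(v, 1e-300)) - 6.0)
            hi.append(math.log10(max(v, 1e-300)) + 6.0)
        return np.array(lo), np.array(hi)

    def residuals_vec(self, vec: np.ndarray) -> np.ndarray:
        params = self.from_vector(vec)
        return weighted_residuals(
            params, self.datasets, self.variant, None,
            self.profile_scales, self.rtol, self.atol,
        )

    def chi2_vec(self, vec: np.ndarray) -> float:
        try:
            r = self.residuals_vec(vec)
        except SimulationError:
            return float("inf")
        return float(np.dot(r, r))


@dataclass
class FitResult:
    """Outcome of a multistart fit."""

    params: ParameterSet
    chi2: float
    chi2_per_dataset: dict
    residuals: np.ndarray
    n_fev: int
    trace: list            # records: (run, start, width, chi2_start, chi2_final)
    seed: int
    vector: np.ndarray
    vector_names: list

    def best_per_run(self) -> list[float]:
        """Incumbent χ² after each run (non-increasing)."""
        out, best = [], float("inf")
        run_ids = sorted({rec[0] for rec in self.trace})
        for run in run_ids:
            for rec in self.trace:
                if rec[0] == run and rec[4] < best:
                    best = rec[4]
            out.append(best)
        return out


#: the full reference schedule (perturbation width, number of fits)
DEFAULT_SCHEDULE: tuple[tuple[float, int], ...] = (
    (4.0, 1000), (1.0, 1000), (0.1, 1000), (0.01, 1000)
)
#: reduced schedule for routine/synthetic work
REDUCED_SCHEDULE: tuple[tuple[float, int], ...] = ((1.0, 40), (0.1, 20))


def multistart_fit(
    problem: FitProblem,
    schedule: Sequence[tuple[float, int]] = REDUCED_SCHEDULE,
    max_nfev: int = 500,
    resample_out_of_bounds: bool = False,
) -> FitResult:
    """Sequential multistart runs with per-coordinate 10**eps perturbation.

    Each run draws ``count`` starts from the incumbent best (carried across
    runs); each start is optimised by bound-constrained trust-region least
    squares on the weighted residual vector.  Out-of-bounds perturbed starts
    are clipped into the box (or redrawn if ``resample_out_of_bounds``).
    Perturbations come from per-start substreams seeded by
    ``(seed, run, start)``, so results are reproducible and independent of
    execution order.
    """
    if not schedule:
        raise ValueError("schedule must be non-empty")
    lo, hi = problem.vector_bounds()
    x_best = np.clip(problem.to_vector(problem.start), lo, hi)
    chi2_best = problem.chi2_vec(x_best)
    trace: list[tuple] = []
    n_fev_total = 0
    any_success = math.isfinite(chi2_best)

    for run_idx, (width, count) in enumerate(schedule):
        x_incumbent = x_best.copy()
        for start_idx in range(count):
            rng = np.random.default_rng((problem.seed, run_idx, start_idx))
            for _attempt in range(100):
                eps = rng.normal(0.0, width, size=x_incumbent.size)
                x0 = x_incumbent + eps  # 10**eps factor, additive in log space
                for i, name in enumerate(problem.free_params):
                    if name in LINEAR_SCALE_PARAMS:
                        x0[i] = x_incumbent[i] * 10.0 ** eps[i]
                if not resample_out_of_bounds or (
                    np.all(x0 >= lo) and np.all(x0 <= hi)
                ):
                    break
            x0 = np.clip(x0, lo, hi)
            chi2_start = problem.chi2_vec(x0)
            try:
                sol = least_squares(
                    problem.residuals_vec, x0, bounds=(lo, hi), method="trf",
                    ftol=1e-10, xtol=1e-10, gtol=1e-10, max_nfev=max_nfev,
                )
                chi2_final = float(2.0 * sol.cost)
                n_fev_total += int(sol.nfev)
            except (SimulationError, ValueError) as exc:
                logger.warning("start (%d, %d) failed: %s", run_idx, start_idx, exc)
                trace.append((run_idx, start_idx, width, chi2_start, float("inf")))
                continue
            any_success = True
            trace.append((run_idx, start_idx, width, chi2_start, chi2_final))
            if chi2_final < chi2_best:
                chi2_best, x_best = chi2_final, sol.x.copy()

    if not any_success:
        raise RuntimeError(f"every start failed; trace: {trace}")

    best_params = problem.from_vector(x_best)
    resid = problem.residuals_vec(x_best)
    per_ds = chi_square_per_dataset(
        best_params, list(problem.datasets), problem.variant,
        profile_scales=problem.profile_scales,
        rtol=problem.rtol, atol=problem.atol,
    )
    return FitResult(
        params=best_params,
        chi2=float(np.dot(resid, resid)),
        chi2_per_dataset=per_ds,
        residuals=resid,
        n_fev=n_fev_total,
        trace=trace,
        seed=problem.seed,
        vector=x_best,
        vector_names=problem.vector_names(),
    )
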