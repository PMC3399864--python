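"""Model-variant comparison, discriminating predictions and parameter scans.

The reference model carries two UVB mechanisms; the nested variants delete
one each (``p``: no PP2Ac deactivation, ``t``: no translational inhibition).
Because the variants are nested inside the reference model, a fair fit can
never leave the reference model worse than a variant (up to multistart
noise) — what discriminates is how much worse a variant fits, and which
qualitative features it loses (the IκBα overshoot after IL-1, sustained
IKKβ phosphorylation under IL-1+UVB), plus the proteasome-inhibitor
prediction: adding MG132 shortly after IL-1+UVB stimulation isolates IκBα
synthesis from degradation, and the predicted IκBα recovery level differs
strongly between variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fitting import FitProblem, FitResult, REDUCED_SCHEDULE, multistart_fit
from .model import Trajectory, simulate
from .observables import TimeSeriesDataset
from .params import ParameterSet
from .protocols import standard_protocols

#: qualitative-feature conventions (artifact constants, not measured values)
OVERSHOOT_THRESHOLD = 1.1      # x initial IκBα
SUSTAINED_IKKP_RATIO = 0.2     # IKKp(4 h) / peak
MG_FOLD_BAND = (0.5, 1.5)      # "about the initial level"


# ---------------------------------------------------------------------------
# feature detectors


def has_ikba_overshoot(times_h: np.ndarray, ikba_obs: np.ndarray) -> bool:
    """True if IκBα exceeds OVERSHOOT_THRESHOLD x its initial value after
    its post-stimulation minimum."""
    i_min = int(np.argmin(ikba_obs))
    return bool(np.max(ikba_obs[i_min:]) > OVERSHOOT_THRESHOLD * ikba_obs[0])


def has_sustained_ikkp(times_h: np.ndarray, ikkp_obs: np.ndarray,
                       at_h: float = 4.0) -> bool:
    """True if IKKp at ``at_h`` remains above SUSTAINED_IKKP_RATIO x peak."""
    idx = int(np.searchsorted(times_h, at_h))
    idx = min(idx, len(times_h) - 1)
    peak = float(np.max(ikkp_obs))
    return bool(peak > 0 and ikkp_obs[idx] / peak > SUSTAINED_IKKP_RATIO)


# ---------------------------------------------------------------------------
# variant comparison


@dataclass
class ComparisonReport:
    fits: dict[str, FitResult]
    chi2: dict[str, float]
    delta_chi2: dict[tuple[str, str], float]
    per_dataset: dict[str, dict]
    features: dict[str, dict]
    errors: dict[str, str] = field(default_factory=dict)

    def verdict(self) -> str:
        ok = {v: c for v, c in self.chi2.items() if np.isfinite(c)}
        if not ok:
            return "no variant could be fitted"
        ranked = sorted(ok, key=ok.get)
        lines = [f"best fit: variant {ranked[0]!r} (chi2 = {ok[ranked[0]]:.3g})"]
        for v in ranked[1:]:
            lines.append(
                f"variant {v!r}: chi2 = {ok[v]:.3g} "
                f"(delta = {ok[v] - ok[ranked[0]]:+.3g})"
            )
        return "; ".join(lines)


def compare_variants(
    datasets: Sequence[TimeSeriesDataset],
    variants: Sequence[str] = ("ref", "p", "t"),
    start: ParameterSet = None,
    schedule: Sequence[tuple[float, int]] = REDUCED_SCHEDULE,
    seed: int = 0,
    free_params: Sequence[str] | None = None,
    profile_scales: bool = True,
) -> ComparisonReport:
    """Fit each variant to the same datasets with the same schedule/seed
    policy and report χ², Δχ², residual breakdown and qualitative features.

    Parameters forced to zero by a variant are dropped from its free list.
    A variant whose fit fails entirely is recorded in ``errors`` and shows
    χ² = inf.
    """
    if start is None:
        raise ValueError("compare_variants requires a start ParameterSet")
    free = tuple(free_params) if free_params is not None \
        else ("uvinh", "k_uv", "c_3a", "c_5a")
    fits: dict[str, FitResult] = {}
    errors: dict[str, str] = {}
    for v in variants:
        from .protocols import VARIANT_OVERRIDES
        forced = VARIANT_OVERRIDES[v.lower()]
        problem = FitProblem(
            datasets=tuple(datasets),
            variant=v,
            free_params=tuple(n for n in free if n not in forced),
            start=start,
            seed=seed,
            profile_scales=profile_scales,
        )
        try:
            fits[v] = multistart_fit(problem, schedule=schedule)
        except RuntimeError as exc:
            errors[v] = str(exc)
    chi2 = {v: (fits[v].chi2 if v in fits else float("inf")) for v in variants}
    delta = {
        (a, b): chi2[a] - chi2[b]
        for a in variants for b in variants if a != b
    }
    features = {}
    cat = standard_protocols()
    for v, fr in fits.items():
        feats = {}
        stims = {ds.stimulation for ds in datasets}
        if "IL1" in stims:
            tr = simulate(fr.params, cat["IL1"], variant=v,
                          t_grid_h=np.linspace(0, 4, 121))
            feats["il1_ikba_overshoot"] = has_ikba_overshoot(
                tr.times_h, tr.total_ikba())
        if "IL1_UVB" in stims:
            tr = simulate(fr.params, cat["IL1_UVB"], variant=v,
                          t_grid_h=np.linspace(0, 8, 161))
            feats["iluvb_sustained_ikkp"] = has_sustained_ikkp(
                tr.times_h, tr.state("IKKp"))
        features[v] = feats
    return ComparisonReport(
        fits=fits, chi2=chi2, delta_chi2=delta,
        per_dataset={v: fr.chi2_per_dataset for v, fr in fits.items()},
        features=features, errors=errors,
    )


# ---------------------------------------------------------------------------
# predictions


def predict_mg132(
    params: ParameterSet, variant: str = "ref",
    t_grid_h: np.ndarray | None = None,
) -> dict:
    """Predicted total-IκBα course for IL-1+UVB with MG132 at +15 min.

    Returns the observable course normalised to the pre-stimulation level
    and the fold change at the late plateau (and at 1 h), the prediction
    that discriminates the reference model ("recovery to about the initial
    level") from the translation-intact variant (several-fold overshoot).
    """
    grid = t_grid_h if t_grid_h is not None else np.linspace(0.0, 16.0, 481)
    proto = standard_protocols()["IL1_UVB_MG_plus15"]
    traj = simulate(params, proto, variant=variant, t_grid_h=grid)
    course = traj.total_ikba()
    rel = course / course[0]
    i1h = int(np.searchsorted(grid, 1.0))
    return {
        "times_h": grid,
        "ikba_rel": rel,
        "fold_at_1h": float(rel[min(i1h, rel.size - 1)]),
        "fold_final": float(rel[-1]),
        "within_moderate_band": bool(
            MG_FOLD_BAND[0] <= rel[-1] <= MG_FOLD_BAND[1]
        ),
    }


def predict_chx(
    params: ParameterSet, variant: str = "ref", horizon_h: float = 16.0,
    n_grid: int = 961,
) -> float:
    """Predicted half-life (h) of total IκBα under cycloheximide.

    First time at which the total-IκBα observable falls below half its
    initial value (linear interpolation); ``inf`` if it never does within
    the horizon.
    """
    grid = np.linspace(0.0, horizon_h, n_grid)
    traj = simulate(params, standard_protocols()["CHX"], variant=variant,
                    t_grid_h=grid)
    rel = traj.total_ikba() / traj.total_ikba()[0]
    below = np.nonzero(rel < 0.5)[0]
    if below.size == 0:
        return float("inf")
    i = int(below[0])
    if i == 0:
        return 0.0
    return float(np.interp(0.5, [rel[i], rel[i - 1]], [grid[i], grid[i - 1]]))


def kpconst_scan_summary(
    params: ParameterSet,
    factors: Sequence[float] = (10.0, 1.0, 0.1),
    stimulations: Sequence[str] = ("UVB", "IL1", "IL1_UVB"),
) -> dict:
    """Degraded fractions of total IκBα under a constitutive-phosphorylation
    scan.

    For each factor and stimulation, reports the fraction of the initial
    total IκBα degraded at 4 h and at 16 h, plus (per stimulation) the
    maximal pointwise deviation of the scanned courses from the unscanned
    one — under IL-1(-containing) stimulations the scan should be nearly
    invisible, under UVB alone it is decisive.
    """
    cat = standard_protocols()
    grid = np.linspace(0.0, 16.0, 481)
    out: dict = {"factors": list(factors), "metrics": {}, "max_deviation": {}}
    courses: dict[tuple, np.ndarray] = {}
    for stim in stimulations:
        for f in factors:
            p = params.replace(k_pconst=params.k_pconst * f)
            traj = simulate(p, cat[stim], t_grid_h=grid)
            rel = traj.total_ikba() / traj.total_ikba()[0]
            courses[(stim, f)] = rel
            i4 = int(np.searchsorted(grid, 4.0))
            out["metrics"][(stim, f)] = {
                "degraded_4h": float(1.0 - rel[i4]),
                "degraded_16h": float(1.0 - rel[-1]),
            }
    for stim in stimulations:
        base = courses[(stim, 1.0)] if 1.0 in factors else None
        if base is not None:
            out["max_deviation"][stim] = float(
                max(
                    np.max(np.abs(courses[(stim, f)] - base))
                    for f in factors if f != 1.0
                )
            )
    return out
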