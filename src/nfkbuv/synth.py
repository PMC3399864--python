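"""Synthetic Western-blot/EMSA-like time-course generation.

Produces standardised observable datasets from a known ground-truth
parameter set so that fitting, discrimination and parameter-recovery can be
exercised without experimental data.  The default design mirrors the
structure of the study it emulates: three observables (phospho-IKKβ, total
cellular IκBα, nuclear NF-κB), sparse grids over 0–16 h (minutes-scale for
IL-1 responses, hours-scale for UVB/CHX), three replicates per series,
multiplicative Gaussian noise, and the pooling conventions of
:mod:`nfkbuv.observables` including the 10%-of-max SD floor.

Noise is multiplicative (``value * (1 + eps)``, ``eps ~ N(0, rel_sd**2)``,
truncated at -90%) because blot densitometry errors scale with band
intensity; the choice is an artifact convention, not a measured property.
The ground-truth record returned alongside the datasets is for scoring
only — fitting code never reads it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import simulate
from .observables import TimeSeriesDataset, standardise
from .params import ParameterSet, default_parameters
from .protocols import StimulationProtocol, standard_protocols

#: time grids (hours) mimicking the study's sampling
IL1_GRID = (0.0, 1 / 12, 1 / 6, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0)
IL1_UVB_GRID = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0)
UVB_GRID = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 16.0)
MG_GRID = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
CHX_GRID = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 16.0)


@dataclass(frozen=True)
class SeriesSpec:
    observable: str
    stimulation: str
    times_h: tuple[float, ...]


@dataclass(frozen=True)
class SyntheticDesign:
    """Ground truth, measurement layout and noise model of a synthetic study."""

    truth: ParameterSet
    series: tuple[SeriesSpec, ...]
    rel_sd: float = 0.1
    n_replicates: int = 3
    seed: int = 1
    variant: str = "ref"
    protocols: Mapping[str, StimulationProtocol] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rel_sd < 0:
            raise ValueError("rel_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        cat = dict(standard_protocols())
        cat.update(self.protocols)
        for s in self.series:
            if s.stimulation not in cat:
                raise ValueError(f"unknown stimulation {s.stimulation!r}")
            if max(s.times_h) > 16.0 or min(s.times_h) < 0.0:
                raise ValueError("series grids must lie within [0, 16] h")
        object.__setattr__(self, "protocols", cat)

    @property
    def n_points(self) -> int:
        return sum(len(s.times_h) for s in self.series)


def default_design(
    truth: ParameterSet | None = None, seed: int = 1, rel_sd: float = 0.1
) -> SyntheticDesign:
    """The standard 5-protocol, 11-series design.

    All three observables are measured for IL1, IL1_UVB and UVB; the MG132
    (+15 min) and CHX conditions carry the IκBα observable only, as blots
    were the only readout there.
    """
    series = []
    for stim, grid in (("IL1", IL1_GRID), ("IL1_UVB", IL1_UVB_GRID),
                       ("UVB", UVB_GRID)):
        for obs in ("IKKp_obs", "IkBa_obs", "NFkB_obs"):
            series.append(SeriesSpec(obs, stim, grid))
    series.append(SeriesSpec("IkBa_obs", "IL1_UVB_MG_plus15", MG_GRID))
    series.append(SeriesSpec("IkBa_obs", "CHX", CHX_GRID))
    return SyntheticDesign(
        truth=truth if truth is not None else default_parameters(),
        series=tuple(series),
        rel_sd=rel_sd,
        seed=seed,
    )


def noiseless_observables(design: SyntheticDesign) -> dict[tuple, np.ndarray]:
    """Unscaled noiseless model observables per (observable, stimulation)."""
    out = {}
    by_stim: dict[str, list[SeriesSpec]] = {}
    for s in design.series:
        by_stim.setdefault(s.stimulation, []).append(s)
    for stim, specs in by_stim.items():
        grid = np.unique(np.concatenate([np.asarray(s.times_h) for s in specs]))
        proto = design.protocols[stim]
        t_end = max(grid[-1], *(proto.event_times_h or (0.0,)))
        traj = simulate(design.truth, proto, variant=design.variant,
                        t_grid_h=np.unique(np.append(grid, t_end)))
        full = np.unique(np.append(grid, t_end))
        raw = {
            "IKKp_obs": traj.state("IKKp"),
            "IkBa_obs": traj.total_ikba(),
            "NFkB_obs": traj.state("NFkB_n"),
        }
        for s in specs:
            idx = np.searchsorted(full, np.asarray(s.times_h))
            out[(s.observable, s.stimulation)] = raw[s.observable][idx]
    return out


def generate_floor_noise(
    design: SyntheticDesign, seed: int | None = None
) -> tuple[list[TimeSeriesDataset], dict[tuple, float]]:
    """Calibration variant: noise drawn at exactly the attached (floored) SD.

    Builds the noiseless standardised datasets (whose SDs all sit at the
    10%-of-max floor), then adds Gaussian noise with SD equal to each
    point's attached SD.  At the true parameters the χ² statistic is then a
    sum of squared standard normals, so its expectation equals the number
    of data points — a calibration check of the whole simulate→observe→
    standardise→χ² chain.  Also returns the convention-implied true scaling
    factors (per scaling group) of the noiseless data.
    """
    import dataclasses

    rng = np.random.default_rng(design.seed if seed is None else seed)
    clean_design = dataclasses.replace(design, rel_sd=0.0, n_replicates=1,
                                       protocols={})
    clean, _ = generate(clean_design)
    clean_model = noiseless_observables(design)
    scales: dict[tuple, float] = {}
    for ds in clean:
        m = clean_model[(ds.observable, ds.stimulation)]
        key = (("NFkB_obs", ds.stimulation) if ds.observable == "NFkB_obs"
               else (ds.observable,))
        scales[key] = float(np.sum(ds.values * m) / np.sum(m * m))
    noisy = [
        dataclasses.replace(ds, values=ds.values + rng.normal(0.0, ds.sds))
        for ds in clean
    ]
    return noisy, scales


def generate(
    design: SyntheticDesign, seed: int | None = None
) -> tuple[list[TimeSeriesDataset], dict]:
    """Generate standardised datasets plus a ground-truth record.

    Replicate ``r`` of each series is ``model * (1 + eps)`` with i.i.d.
    ``eps ~ N(0, rel_sd**2)`` truncated at -0.9; the replicates are then
    pooled by :func:`nfkbuv.observables.standardise` (mean-1 / initial-1 /
    max-1 conventions and the SD floor).  Equal seeds give identical output.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    clean = noiseless_observables(design)
    raw: dict[int, np.ndarray] = {}
    for s in design.series:
        m = clean[(s.observable, s.stimulation)]
        eps = rng.normal(0.0, design.rel_sd, size=(design.n_replicates, m.size)) \
            if design.rel_sd > 0 else np.zeros((design.n_replicates, m.size))
        eps = np.maximum(eps, -0.9)
        raw[id(s)] = m[None, :] * (1.0 + eps)
    # phospho-IKK blots share one reference (the maximal phosphorylation of
    # the whole replicate experiment), so all IKK series of a replicate are
    # scaled jointly; a lone IKK series reduces to the per-series convention.
    ikk_specs = [s for s in design.series if s.observable == "IKKp_obs"]
    if ikk_specs:
        joint_max = np.max(
            [raw[id(s)].max(axis=1) for s in ikk_specs], axis=0
        )  # per replicate
        for s in ikk_specs:
            raw[id(s)] = raw[id(s)] / joint_max[:, None]
    datasets = []
    for s in design.series:
        if s.observable == "IKKp_obs":
            reps = raw[id(s)]
            mean = reps.mean(axis=0)
            sd = (reps.std(axis=0, ddof=1) if reps.shape[0] > 1
                  else np.zeros(mean.size))
            from .observables import SD_FLOOR_FRACTION
            datasets.append(
                TimeSeriesDataset(
                    observable=s.observable, stimulation=s.stimulation,
                    times_h=np.asarray(s.times_h), values=mean,
                    sds=np.maximum(sd, SD_FLOOR_FRACTION * mean.max()),
                    n_replicates=reps.shape[0], standardisation="max-1-joint",
                )
            )
        else:
            datasets.append(
                standardise(s.observable, s.stimulation, s.times_h, raw[id(s)])
            )
    truth_record = {
        "params": design.truth.to_dict(),
        "variant": design.variant,
        "rel_sd": design.rel_sd,
        "n_replicates": design.n_replicates,
        "seed": design.seed if seed is None else seed,
        "series": [
            {"observable": s.observable, "stimulation": s.stimulation,
             "times_h": list(s.times_h)}
            for s in design.series
        ],
    }
    return datasets, truth_record
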