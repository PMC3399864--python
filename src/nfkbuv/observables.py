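"""Model observables and the blot/EMSA standardisation conventions.

Three quantities are measured experimentally:

* ``IKKp_obs``  — phosphorylated IKKβ (Western blot), one global scaling
  factor; the data convention references each series to its maximal
  phosphorylation.
* ``IkBa_obs``  — total cellular IκBα (Western blot): free cytosolic +
  complexed + nuclear (volume-corrected by 1/k_v); one global scaling
  factor; data standardised to an initial value of 1.
* ``NFkB_obs``  — nuclear NF-κB (EMSA): no absolute reference exists, so
  each stimulation carries its own scaling factor; data scaled to mean 1
  per replicate before averaging.

Pooled experimental series additionally carry an SD floor: no standard
deviation may be smaller than 10% of the maximum of its pooled time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .model import Trajectory
from .params import ParameterSet

OBSERVABLE_IDS = ("IKKp_obs", "IkBa_obs", "NFkB_obs")

#: SD floor, as a fraction of the maximum of the pooled series
SD_FLOOR_FRACTION = 0.1


class StandardisationError(ValueError):
    """Raised when a raw series cannot be standardised."""


@dataclass(frozen=True)
class TimeSeriesDataset:
    """One pooled, standardised observable time course.

    ``values`` are in the convention of the observable (NF-κB: replicate
    mean after mean-1 scaling; IκBα: initial value 1; IKK: maximum 1) and
    ``sds`` carry the 10%-of-max floor.  ``mask`` marks points included in
    fitting (False = excluded blot artefact).
    """

    observable: str
    stimulation: str
    times_h: np.ndarray
    values: np.ndarray
    sds: np.ndarray
    n_replicates: int = 1
    standardisation: str = ""
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        v = np.asarray(self.values, dtype=float)
        s = np.asarray(self.sds, dtype=float)
        m = (np.ones(t.shape, dtype=bool) if self.mask is None
             else np.asarray(self.mask, dtype=bool))
        if self.observable not in OBSERVABLE_IDS:
            raise ValueError(f"unknown observable {self.observable!r}")
        if not (t.shape == v.shape == s.shape == m.shape) or t.ndim != 1:
            raise ValueError("times, values, sds and mask must be equal-length 1-D")
        if t.size == 0:
            raise StandardisationError("empty time series")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(s <= 0):
            raise ValueError("all SDs must be > 0")
        for name, arr in (("times_h", t), ("values", v), ("sds", s)):
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "mask", m)

    @property
    def n_points(self) -> int:
        return int(self.mask.sum())

    def with_floor(self) -> "TimeSeriesDataset":
        """Copy with the 10%-of-max SD floor (re-)applied."""
        floor = SD_FLOOR_FRACTION * float(np.max(self.values))
        return replace(self, sds=np.maximum(self.sds, floor))


def observe(
    trajectory: Trajectory,
    params: ParameterSet | None = None,
    stimulation: str | None = None,
) -> dict[str, np.ndarray]:
    """Observable time courses of a trajectory.

    ``IKKp_obs = scale_ikk * IKKp``; ``IkBa_obs = scale_ikba * (IkBa +
    IkBaNFkB + IkBa_n/k_v)``; ``NFkB_obs = scale_nfkb[stimulation] *
    NFkB_n``.  The per-stimulation NF-κB factor defaults to 1 if the
    stimulation has no registered factor and ``strict`` semantics are not
    requested via an explicit ``stimulation`` argument.
    """
    p = params if params is not None else trajectory.params
    stim = stimulation if stimulation is not None else trajectory.protocol.name
    scale_nfkb = p.scale_nfkb_by_stimulation
    if stimulation is not None and scale_nfkb and stim not in scale_nfkb:
        raise KeyError(f"no NF-κB scaling factor registered for {stim!r}")
    return {
        "IKKp_obs": p.scale_ikk * trajectory.state("IKKp"),
        "IkBa_obs": p.scale_ikba * trajectory.total_ikba(),
        "NFkB_obs": scale_nfkb.get(stim, 1.0) * trajectory.state("NFkB_n"),
    }


def _pool(reps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and across-replicate sample SD (SD=0 for 1 replicate)."""
    mean = reps.mean(axis=0)
    sd = reps.std(axis=0, ddof=1) if reps.shape[0] > 1 else np.zeros(reps.shape[1])
    return mean, sd


def standardise(
    observable: str,
    stimulation: str,
    times_h: Sequence[float],
    replicates: Sequence[Sequence[float]],
    mask: Sequence[bool] | None = None,
) -> TimeSeriesDataset:
    """Pool raw replicate series under the observable's convention.

    NF-κB: each replicate is scaled to mean 1, then averaged pointwise.
    IκBα: each replicate is divided by its first value (blots standardised
    to the initial level).  IKK: each replicate is divided by its maximum
    (maximal phosphorylation as reference).  The across-replicate SD is then
    floored at 10% of the pooled series' maximum.  All conventions are
    invariant under rescaling a whole replicate by a positive constant.
    """
    t = np.asarray(times_h, dtype=float)
    reps = np.asarray(replicates, dtype=float)
    if t.size == 0:
        raise StandardisationError("empty time series")
    if reps.ndim != 2 or reps.shape[0] < 1 or reps.shape[1] != t.size:
        raise StandardisationError(
            f"need >= 1 replicate series of length {t.size}, got shape {reps.shape}"
        )
    if observable == "NFkB_obs":
        means = reps.mean(axis=1, keepdims=True)
        if np.any(means == 0):
            raise StandardisationError("NF-κB replicate with zero mean")
        scaled = reps / means
    elif observable == "IkBa_obs":
        first = reps[:, :1]
        if np.any(first == 0):
            raise StandardisationError("IκBα replicate with zero initial value")
        scaled = reps / first
    elif observable == "IKKp_obs":
        mx = reps.max(axis=1, keepdims=True)
        if np.any(mx == 0):
            raise StandardisationError("IKK replicate with zero maximum")
        scaled = reps / mx
    else:
        raise ValueError(f"unknown observable {observable!r}")
    mean, sd = _pool(scaled)
    floor = SD_FLOOR_FRACTION * float(mean.max())
    return TimeSeriesDataset(
        observable=observable,
        stimulation=stimulation,
        times_h=t,
        values=mean,
        sds=np.maximum(sd, floor),
        n_replicates=reps.shape[0],
        standardisation={
            "NFkB_obs": "mean-1", "IkBa_obs": "initial-1", "IKKp_obs": "max-1"
        }[observable],
        mask=None if mask is None else np.asarray(mask, dtype=bool),
    )
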