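"""CSV round-tripping for datasets and trajectories, plus run manifests.

Dataset dialect (tidy, one row per point)::

    observable,stimulation,time_h,value,sd,mask,n_replicates,standardisation

Times are hours in all files; the model works in seconds internally.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .observables import SD_FLOOR_FRACTION, TimeSeriesDataset

DATASET_COLUMNS = (
    "observable", "stimulation", "time_h", "value", "sd", "mask",
    "n_replicates", "standardisation",
)


class DatasetFormatError(ValueError):
    """Malformed dataset file."""


def write_datasets(datasets: Sequence[TimeSeriesDataset], path) -> None:
    rows = []
    for ds in datasets:
        for t, v, s, m in zip(ds.times_h, ds.values, ds.sds, ds.mask):
            rows.append(
                (ds.observable, ds.stimulation, t, v, s, bool(m),
                 ds.n_replicates, ds.standardisation)
            )
    pd.DataFrame(rows, columns=DATASET_COLUMNS).to_csv(path, index=False)


def read_datasets(
    path, strict_floor: bool = False
) -> list[TimeSeriesDataset]:
    """Load a dataset CSV; validates schema, time monotonicity and the SD
    floor (warn-and-refloor by default, error under ``strict_floor``)."""
    df = pd.read_csv(path)
    missing = set(DATASET_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise DatasetFormatError(f"{path}: missing columns {sorted(missing)}")
    bad = df[~np.isfinite(df["time_h"]) | ~np.isfinite(df["value"])]
    if len(bad):
        raise DatasetFormatError(
            f"{path}: non-finite time/value at line(s) "
            f"{[int(i) + 2 for i in bad.index[:5]]}"
        )
    out = []
    for (obs, stim), g in df.groupby(["observable", "stimulation"], sort=False):
        t = g["time_h"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise DatasetFormatError(
                f"{path}: non-monotone times within series ({obs}, {stim})"
            )
        v = g["value"].to_numpy(float)
        s = g["sd"].to_numpy(float)
        floor = SD_FLOOR_FRACTION * v.max()
        if np.any(s < floor - 1e-12):
            msg = (f"({obs}, {stim}): SDs below the "
                   f"{SD_FLOOR_FRACTION:.0%}-of-max floor")
            if strict_floor:
                raise DatasetFormatError(f"{path}: {msg}")
            warnings.warn(f"{path}: {msg}; re-flooring", stacklevel=2)
            s = np.maximum(s, floor)
        out.append(
            TimeSeriesDataset(
                observable=obs, stimulation=stim, times_h=t, values=v, sds=s,
                n_replicates=int(g["n_replicates"].iloc[0])
                if "n_replicates" in g else 1,
                standardisation=str(g["standardisation"].iloc[0])
                if "standardisation" in g else "",
                mask=g["mask"].to_numpy(bool) if "mask" in g else None,
            )
        )
    return out


def write_trajectory(trajectory, path) -> None:
    """Tidy CSV with columns (stimulation, variant, time_h, state, value)."""
    trajectory.to_frame().to_csv(path, index=False)


def write_manifest(path, config: dict, seed: int | None,
                   outputs: Iterable[str] = ()) -> None:
    """Machine-readable record (config, package version, seed, content
    hashes of outputs) sufficient to re-run the result."""
    from . import __version__

    hashes = {}
    for out in outputs:
        p = Path(out)
        if p.exists():
            hashes[str(out)] = hashlib.sha256(p.read_bytes()).hexdigest()
    Path(path).write_text(
        json.dumps(
            {"version": __version__, "seed": seed, "config": config,
             "output_sha256": hashes},
            indent=2, default=str,
        )
    )
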