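"""CSV schemas for trajectories, replicate experiments and ensembles.

Three plain-text table formats:

* trajectory — ``time`` plus one column per species (header = species names);
* experiment — long format ``time, experiment, replicate, value``;
* ensemble  — ``time, mean, sd, n``.

Readers validate column presence, time ordering and value signs, and
point at the offending row.  An ensemble with n = 1 at some time point
loads fine — the consistency test refuses such points later with its own
message (deferred validation).
"""

from __future__ import annotations

from typing import List

import numpy as np
import pandas as pd

from .model import ValidationError
from .simulate import Trajectory
from .synthetic import EnsembleDataset, ExperimentTable

__all__ = [
    "SchemaError",
    "write_trajectory", "read_trajectory",
    "write_experiments", "read_experiments",
    "write_ensemble", "read_ensemble",
]


class SchemaError(ValidationError):
    pass


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def write_trajectory(traj: Trajectory, path: str) -> None:
    df = pd.DataFrame(traj.states, columns=list(traj.species))
    df.insert(0, "time", traj.times)
    df.to_csv(path, index=False)


def read_trajectory(path: str) -> Trajectory:
    df = pd.read_csv(path)
    _require_columns(df, ["time"], path)
    times = df["time"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if bad.size:
        raise SchemaError(f"{path}: non-increasing time at row {bad[0] + 3}")
    species = [c for c in df.columns if c != "time"]
    return Trajectory(times, df[species].to_numpy(dtype=float), species)


def write_experiments(tables: List[ExperimentTable], path: str) -> None:
    rows = []
    for t in tables:
        df = t.data.copy()
        df.insert(1, "experiment", t.experiment_id)
        df["assay"] = t.assay
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_experiments(path: str) -> List[ExperimentTable]:
    df = pd.read_csv(path)
    _require_columns(df, ["time", "experiment", "replicate", "value"], path)
    neg = df.index[df["value"] < 0]
    if len(neg):
        raise SchemaError(f"{path}: negative activity value at row {neg[0] + 2}")
    assay = str(df["assay"].iloc[0]) if "assay" in df.columns else "nfkb"
    tables = []
    for eid, group in df.groupby("experiment", sort=False):
        tables.append(ExperimentTable(
            group[["time", "replicate", "value"]].reset_index(drop=True),
            experiment_id=str(eid), assay=assay))
    return tables


def write_ensemble(data: EnsembleDataset, path: str) -> None:
    data.to_frame().to_csv(path, index=False)


def read_ensemble(path: str, assay: str = "nfkb") -> EnsembleDataset:
    df = pd.read_csv(path)
    _require_columns(df, ["time", "mean", "sd", "n"], path)
    times = df["time"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if bad.size:
        raise SchemaError(f"{path}: non-increasing time at row {bad[0] + 3}")
    neg = df.index[(df["mean"] < 0) | (df["sd"] < 0)]
    if len(neg):
        raise SchemaError(f"{path}: negative mean or sd at row {neg[0] + 2}")
    return EnsembleDataset.from_summary(times, df["mean"], df["sd"], df["n"],
                                        assay=assay)
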