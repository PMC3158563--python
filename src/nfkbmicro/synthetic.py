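"""ELISA-like replicate time courses with the noise model the tests assume.

The study's raw plate measurements exist only as figures, so this module
plays two roles: (i) fixed *reference profiles* that encode the dynamic
features the text states for each assay (IKK kinase activity over 0–30
min, NF-κB p65 DNA-binding activity over 0–120 min) on canonical time
grids, and (ii) a generator of replicate experiments around any truth
curve with iid zero-mean Gaussian noise whose standard deviation may vary
with time — exactly the statistical structure the consistency test
assumes — followed by the per-experiment max-mean normalization and
ensemble averaging used for fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .model import ValidationError

__all__ = [
    "ExperimentTable",
    "EnsembleDataset",
    "reference_profiles",
    "generate_experiments",
    "normalize_experiment",
    "ensemble_average",
    "make_ensemble",
    "sample_null_ensembles",
    "reference_curve",
    "default_noise_sd",
    "NFKB_GRID",
    "IKK_GRID",
]

#: Canonical sampling grids (min).  The assays' figure axes are not
#: tabulated anywhere, so these are fixed conventions of this package.
NFKB_GRID = np.array([0.0, 5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0])
IKK_GRID = np.array([0.0, 5.0, 10.0, 15.0, 20.0, 30.0])


@dataclass
class ExperimentTable:
    """One experiment's replicate measurements in long format."""

    data: pd.DataFrame            # columns: time, replicate, value
    experiment_id: str
    assay: str                    # {nfkb | ikk}

    def __post_init__(self) -> None:
        required = {"time", "replicate", "value"}
        if not required.issubset(self.data.columns):
            raise ValidationError(f"experiment table needs columns {sorted(required)}")
        if (self.data["value"] < 0).any():
            raise ValidationError("activity values must be ≥ 0")

    def per_time_means(self) -> pd.Series:
        return self.data.groupby("time")["value"].mean()


@dataclass
class EnsembleDataset:
    """Pooled per-time-point samples (or their summary) with mean, SD and n.

    Built either from raw pooled samples (one array per time point) or,
    e.g. after a CSV round trip, from the (mean, sd, n) summary alone —
    which is all the t-test needs.
    """

    times: np.ndarray
    samples: List[np.ndarray] | None
    assay: str
    meta: Dict = field(default_factory=dict)
    summary: pd.DataFrame | None = None   # columns mean, sd, n if samples absent

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.samples is not None:
            if len(self.samples) != self.times.size:
                raise ValidationError("one sample array required per time point")
        elif self.summary is None or len(self.summary) != self.times.size:
            raise ValidationError("need either samples or a full (mean, sd, n) summary")

    @classmethod
    def from_summary(cls, times, mean, sd, n, assay: str,
                     meta: Dict | None = None) -> "EnsembleDataset":
        df = pd.DataFrame({"mean": np.asarray(mean, dtype=float),
                           "sd": np.asarray(sd, dtype=float),
                           "n": np.asarray(n, dtype=int)})
        return cls(np.asarray(times, dtype=float), None, assay,
                   meta or {}, df)

    @property
    def mean(self) -> np.ndarray:
        if self.samples is None:
            return self.summary["mean"].to_numpy()
        return np.array([np.mean(s) for s in self.samples])

    @property
    def sd(self) -> np.ndarray:
        if self.samples is None:
            return self.summary["sd"].to_numpy()
        return np.array([np.std(s, ddof=1) if len(s) > 1 else np.nan
                         for s in self.samples])

    @property
    def n(self) -> np.ndarray:
        if self.samples is None:
            return self.summary["n"].to_numpy()
        return np.array([len(s) for s in self.samples])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "mean": self.mean,
                             "sd": self.sd, "n": self.n})


def default_noise_sd(truth: Callable[[np.ndarray], np.ndarray]) -> Callable:
    """Measurement-noise convention: SD = 0.05 + 0.05·truth(t), normalized units."""
    return lambda t: 0.05 + 0.05 * np.asarray(truth(t), dtype=float)


# ---------------------------------------------------------------------------
# text-anchored reference profiles
# ---------------------------------------------------------------------------

# Anchors carry provenance tags: "stated" values encode features reported
# for the assays (peak positions, the ~33% IKK level at 10 min, near-basal
# early NF-κB, the smaller-amplitude second NF-κB peak near 90 min);
# "interpolated" grid values come from a monotone pchip through the
# anchors.  Basal level, the trough, and all SD/n values are synthetic
# conventions of this package, not measured quantities.

_IKK_ANCHORS = {0.0: 0.05, 5.0: 1.0, 10.0: 0.33, 30.0: 0.05}
_NFKB_ANCHORS = {0.0: 0.05, 5.0: 0.08, 20.0: 1.0, 60.0: 0.25, 90.0: 0.45, 120.0: 0.35}

_PROFILE_SPECS = {
    "ikk": (IKK_GRID, _IKK_ANCHORS, 3),
    "nfkb": (NFKB_GRID, _NFKB_ANCHORS, 15),
}


def reference_curve(assay: str) -> Callable[[np.ndarray], np.ndarray]:
    """Continuous normalized activity curve through the text anchors."""
    if assay not in _PROFILE_SPECS:
        raise ValidationError(f"unknown assay {assay!r}; expected 'nfkb' or 'ikk'")
    _, anchors, _ = _PROFILE_SPECS[assay]
    t = np.array(sorted(anchors))
    v = np.array([anchors[k] for k in sorted(anchors)])
    interp = PchipInterpolator(t, v, extrapolate=False)

    def curve(x):
        x = np.asarray(x, dtype=float)
        return np.clip(interp(np.clip(x, t[0], t[-1])), 0.0, None)

    return curve


def reference_profiles(assay: str) -> EnsembleDataset:
    """Fixed anchor dataset standing in for the study's ensemble averages.

    Values at anchor times encode the stated dynamic features; remaining
    grid points are monotone-interpolated.  Every point carries SD = 0.1
    (normalized units) and the assay's replication level (n = 15 for
    NF-κB: five experiments in triplicate; n = 3 for IKK).
    """
    if assay not in _PROFILE_SPECS:
        raise ValidationError(f"unknown assay {assay!r}; expected 'nfkb' or 'ikk'")
    grid, anchors, n = _PROFILE_SPECS[assay]
    curve = reference_curve(assay)
    sd = 0.1
    mean = np.array([anchors.get(t, float(curve(t))) for t in grid])
    provenance = {t: ("stated" if t in anchors else "interpolated") for t in grid}
    return EnsembleDataset.from_summary(
        grid, mean, np.full(grid.size, sd), np.full(grid.size, n), assay,
        meta={"provenance": provenance, "sd": sd, "n": n, "synthetic": True})


# ---------------------------------------------------------------------------
# generator → normalization → ensemble pipeline
# ---------------------------------------------------------------------------

def generate_experiments(truth: Callable[[np.ndarray], np.ndarray],
                         grid: Sequence[float], n_experiments: int,
                         n_replicates: int,
                         noise_sd: Callable[[np.ndarray], np.ndarray] | float,
                         seed: int, assay: str = "nfkb") -> List[ExperimentTable]:
    """Sample replicate experiments: value = truth(t) + N(0, sd(t)²), clipped at 0."""
    grid = np.asarray(grid, dtype=float)
    if np.isscalar(noise_sd):
        level = float(noise_sd)
        noise_fn = lambda t: np.full_like(np.asarray(t, dtype=float), level)
    else:
        noise_fn = noise_sd
    sd = np.asarray(noise_fn(grid), dtype=float)
    if np.any(sd < 0):
        raise ValidationError("noise_sd must be ≥ 0 on the grid")
    mu = np.asarray(truth(grid), dtype=float)
    rng = np.random.default_rng(seed)
    tables = []
    for e in range(n_experiments):
        rows = []
        for r in range(n_replicates):
            vals = np.clip(mu + sd * rng.standard_normal(grid.size), 0.0, None)
            rows.append(pd.DataFrame({"time": grid, "replicate": r, "value": vals}))
        tables.append(ExperimentTable(pd.concat(rows, ignore_index=True),
                                      experiment_id=f"exp{e + 1}", assay=assay))
    return tables


def normalize_experiment(table: ExperimentTable) -> ExperimentTable:
    """Divide by the maximum over time of the per-time replicate mean.

    Removes the per-experiment multiplicative gain (optical-absorbance
    variation between days); idempotent, and invariant to scaling all raw
    values by any c > 0.
    """
    means = table.per_time_means()
    peak = means.max()
    if not peak > 0:
        raise ValidationError(f"experiment {table.experiment_id} has no positive mean")
    df = table.data.copy()
    df["value"] = df["value"] / peak
    return ExperimentTable(df, table.experiment_id, table.assay)


def ensemble_average(experiments: Sequence[ExperimentTable]) -> EnsembleDataset:
    """Pool all replicate values across experiments per time point."""
    if not experiments:
        raise ValidationError("need at least one experiment")
    grids = [np.sort(e.data["time"].unique()) for e in experiments]
    for g in grids[1:]:
        if not np.array_equal(g, grids[0]):
            raise ValidationError("experiments must share one time grid")
    grid = grids[0]
    samples = []
    for t in grid:
        vals = np.concatenate([e.data.loc[e.data["time"] == t, "value"].to_numpy()
                               for e in experiments])
        if vals.size < 2:
            raise ValidationError(
                f"need n ≥ 2 samples at t = {t} min to estimate a SD")
        samples.append(vals)
    return EnsembleDataset(grid, samples, experiments[0].assay)


def sample_null_ensembles(truth_values: Sequence[float],
                          sd_values: Sequence[float], n_experiments: int,
                          n_replicates: int, n_datasets: int, seed: int,
                          grid: Sequence[float] | None = None,
                          assay: str = "nfkb") -> List[EnsembleDataset]:
    """Vectorized pooled sampler for calibration experiments.

    Distributionally identical to running ``generate_experiments`` →
    ``ensemble_average`` (without gain normalization) ``n_datasets``
    times: per time point, n_experiments × n_replicates iid draws of
    truth + N(0, sd²), truncated at 0.  One big RNG array instead of
    thousands of per-dataset tables keeps 10³–10⁴-replicate calibration
    runs affordable.
    """
    truth_values = np.asarray(truth_values, dtype=float)
    sd_values = np.asarray(sd_values, dtype=float)
    if np.any(sd_values < 0):
        raise ValidationError("noise sd must be ≥ 0")
    grid = (np.asarray(grid, dtype=float) if grid is not None
            else np.arange(truth_values.size, dtype=float))
    n_pool = n_experiments * n_replicates
    if n_pool < 2:
        raise ValidationError("need n ≥ 2 pooled samples per time point")
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_datasets, truth_values.size, n_pool))
    vals = np.clip(truth_values[None, :, None] + sd_values[None, :, None] * draws,
                   0.0, None)
    return [EnsembleDataset(grid, list(vals[d]), assay) for d in range(n_datasets)]


def make_ensemble(truth: Callable, grid: Sequence[float], n_experiments: int,
                  n_replicates: int, noise_sd, seed: int,
                  assay: str = "nfkb", normalize: bool = True) -> EnsembleDataset:
    """Generate → per-experiment normalize → pool, in one call.

    ``normalize=False`` skips the per-experiment gain correction and pools
    the raw noisy replicates — the exact additive-Gaussian null of the
    consistency test.
    """
    tables = generate_experiments(truth, grid, n_experiments, n_replicates,
                                  noise_sd, seed, assay)
    if normalize:
        tables = [normalize_experiment(t) for t in tables]
    return ensemble_average(tables)
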