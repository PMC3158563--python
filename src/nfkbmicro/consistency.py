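"""A-posteriori model–data consistency testing via Fisher's method.

Each sampled time point contributes a two-sided one-sample t-test of the
experimental replicates against the simulated population mean; the
per-time p-values are combined into a single statistic

    χ²_F = −2 · Σ_i ln p_i ,

which under the shared null (the data come from cell populations whose
population-average time evolution is the model's) follows a chi-square
distribution with 2n degrees of freedom.  A candidate parameter set is
rejected at level α when the combined p-value falls below α.  The module
also provides the plain sum-of-squares error between normalized model and
data curves used as the least-squares objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy import stats

from .model import ValidationError
from .synthetic import EnsembleDataset

__all__ = [
    "StatisticalError",
    "ConsistencyReport",
    "t_test_point",
    "fisher_combine",
    "consistency_test",
    "sse",
]

logger = logging.getLogger(__name__)

#: p-values are floored here before the log so a numerically-zero p cannot
#: produce an infinite statistic; hitting the floor is logged.
P_FLOOR = 1e-300


class StatisticalError(ValueError):
    pass


@dataclass
class ConsistencyReport:
    p_values: np.ndarray      # per-time p_i
    chi2_F: float
    dof: int
    p_F: float
    alpha: float
    reject: bool

    @property
    def n(self) -> int:
        return self.dof // 2


def t_test_point(mu_sim: float, samples: Sequence[float] | None = None, *,
                 mean: float | None = None, sd: float | None = None,
                 n: int | None = None) -> float:
    """Two-sided one-sample t-test p-value of samples against ``mu_sim``.

    Accepts either the raw samples or the sufficient statistics
    (mean, sd, n); t = (x̄ − mu_sim)/(s/√n) with n − 1 degrees of freedom.
    """
    if samples is not None:
        samples = np.asarray(samples, dtype=float)
        n = samples.size
        if n < 2:
            raise StatisticalError("need n ≥ 2 samples for a t-test")
        mean = float(np.mean(samples))
        sd = float(np.std(samples, ddof=1))
    if n is None or mean is None or sd is None or n < 2:
        raise StatisticalError("need samples, or (mean, sd, n) with n ≥ 2")
    if not sd > 0:
        raise StatisticalError("zero sample variance: t-test undefined")
    t = (mean - mu_sim) / (sd / np.sqrt(n))
    return float(2.0 * stats.t.sf(abs(t), df=n - 1))


def fisher_combine(p_list: Sequence[float]) -> tuple[float, int, float]:
    """Combine independent p-values: returns (χ²_F, dof = 2n, p_F)."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValidationError("cannot combine an empty p-value list")
    if np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    if np.any(p <= 0):
        logger.warning("non-positive p-values clipped to %.0e before log", P_FLOOR)
    p = np.clip(p, P_FLOOR, 1.0)
    chi2 = float(-2.0 * np.sum(np.log(p)))
    dof = 2 * p.size
    p_f = float(stats.chi2.sf(chi2, df=dof))
    return chi2, dof, p_f


def consistency_test(sim: Sequence[float], data: EnsembleDataset,
                     alpha: float = 0.05) -> ConsistencyReport:
    """Fisher-combined t-tests of an ensemble dataset against a model curve.

    ``sim`` holds the simulated (normalized) values at exactly
    ``data.times``; every data time point with n ≥ 2 contributes one test.
    """
    sim = np.asarray(sim, dtype=float)
    if sim.size != data.times.size:
        raise ValidationError("sim must be evaluated at every data time point")
    mean, sd, n = data.mean, data.sd, data.n
    if np.any(n < 2):
        bad = data.times[n < 2]
        raise StatisticalError(
            f"time points {bad.tolist()} have n < 2; cannot test them")
    p_i = np.array([t_test_point(sim[i], mean=mean[i], sd=sd[i], n=int(n[i]))
                    for i in range(sim.size)])
    chi2, dof, p_f = fisher_combine(p_i)
    return ConsistencyReport(p_i, chi2, dof, p_f, alpha, reject=bool(p_f < alpha))


def sse(sim: Sequence[float], data: EnsembleDataset) -> float:
    """Sum of squared errors Σ_i (y(t_i, θ) − y_obs(t_i))² on the normalized scale."""
    sim = np.asarray(sim, dtype=float)
    if sim.size != data.times.size:
        raise ValidationError("sim must be evaluated at every data time point")
    return float(np.sum((sim - data.mean) ** 2))
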