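"""Canonical analysis recipes over the model, estimation and statistics layers.

Each function here is one self-contained computational experiment of the
study workflow — baseline simulation metrics, upstream Hill-coefficient
fitting, two-step/four-step structure discrimination, consistency-test
calibration, first-phase sensitivity screening and robustness scans — so
the numbered analysis scripts, the test suite and the acceptance script
all run exactly the same code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .model import (DEFAULT_PARAMS, NEW_MODEL, ModelSystem, ModelVariant,
                    ParameterSet, build_model, nfkb_total)
from .simulate import (DrivenInput, Trajectory, equilibrate,
                       make_driven_input, normalize_trajectory, simulate)
from .synthetic import (NFKB_GRID, EnsembleDataset, default_noise_sd,
                        make_ensemble, reference_profiles,
                        sample_null_ensembles)
from .consistency import consistency_test
from .estimation import (FREE_PARAMS, BoundsTable, FitResult, StageObjective,
                         multistart_fit, structure_comparison)
from .sensitivity import (scan_parameter, screen_significant, sensitivities,
                          time_avg_scores)

__all__ = [
    "BaselineResult",
    "run_baseline",
    "nominal_drives",
    "upstream_hill_recovery",
    "structure_discrimination",
    "fisher_calibration",
    "first_phase_screen",
    "robustness_scans",
    "total_ikba",
    "TOTAL_IKBA_SPECIES",
]

#: Species summed (nuclear ones divided by kv) for the total-IκBα readout.
TOTAL_IKBA_SPECIES = ("IkBa", "IkBa_NFkB", "pIkBa_NFkB", "rIkBa_NFkB",
                      "uIkBa_NFkB")
_TOTAL_IKBA_NUCLEAR = ("IkBan", "IkBan_NFkBn")


def total_ikba(traj: Trajectory, kv: float) -> np.ndarray:
    """Total cellular IκBα (µM, cytoplasmic-concentration scale)."""
    tot = sum(traj[s] for s in TOTAL_IKBA_SPECIES)
    tot = tot + sum(traj[s] for s in _TOTAL_IKBA_NUCLEAR) / kv
    return tot


@dataclass
class BaselineResult:
    """Equilibrium + stimulated trajectory of a variant, with its headline
    dynamic features."""

    system: ModelSystem
    equilibrium: np.ndarray
    trajectory: Trajectory
    metrics: Dict[str, float]


def run_baseline(variant: ModelVariant = NEW_MODEL,
                 params: ParameterSet = DEFAULT_PARAMS,
                 t_end: float = 120.0, dt: float = 0.25) -> BaselineResult:
    """Equilibrate, stimulate with sustained TNFα, and extract the headline
    features: IKK peak time and 10-min fraction, NF-κB first-peak time and
    5-min (delay) fraction, and the total-IκBα drop at 20 min."""
    system = build_model(variant, params)
    xeq = equilibrate(system)
    grid = np.arange(0.0, t_end + dt / 2, dt)
    traj = simulate(system, x0=xeq, t_grid=grid)

    ikka, nfkbn = traj["IKKa"], traj["NFkBn"]
    kv = params["kv"]
    tot = total_ikba(traj, kv)

    def at(t: float) -> int:
        return int(round(t / dt))

    i_peak = int(np.argmax(ikka))
    n_peak = int(np.argmax(nfkbn))
    metrics = {
        "ikk_peak_time_min": float(grid[i_peak]),
        "ikk_peak_uM": float(ikka[i_peak]),
        "ikk_fraction_at_10min": float(ikka[at(10.0)] / ikka[i_peak]),
        "ikk_fraction_at_30min": float(ikka[at(30.0)] / ikka[i_peak]),
        "nfkb_first_peak_time_min": float(grid[n_peak]),
        "nfkb_peak_uM": float(nfkbn[n_peak]),
        "nfkb_fraction_at_5min": float(nfkbn[at(5.0)] / nfkbn[n_peak]),
        "total_ikba_20min_over_initial": float(tot[at(20.0)] / tot[0]),
        "nfkb_conservation_drift": float(
            abs(nfkb_total(traj.states[-1], kv) - nfkb_total(xeq, kv))
            / nfkb_total(xeq, kv)),
    }
    return BaselineResult(system, xeq, traj, metrics)


def nominal_drives(baseline: BaselineResult) -> Tuple[DrivenInput, DrivenInput]:
    """Loop-breaking inputs from the nominal run.

    Returns (ikk_drive, nfkbn_drive): the active-IKK course sampled on a
    measurement-like grid (dense over the 30-min transient, sparser
    later), and the nuclear NF-κB course, both in µM with constant tails.
    """
    traj = baseline.trajectory
    grid = traj.times
    knots_t = np.concatenate([np.arange(0.0, 10.5, 1.0),
                              np.arange(12.5, 30.1, 2.5),
                              np.arange(40.0, grid[-1] + 1e-9, 10.0)])
    ikka = np.clip(np.interp(knots_t, grid, traj["IKKa"]), 0.0, None)
    ikk_drive = make_driven_input(np.column_stack([knots_t, ikka]),
                                  tail_value=float(max(traj["IKKa"][-1], 0.0)))
    nfkbn = np.clip(traj["NFkBn"], 0.0, None)
    nfkbn_drive = make_driven_input(np.column_stack([grid, nfkbn]),
                                    tail_value=float(nfkbn[-1]))
    return ikk_drive, nfkbn_drive


def upstream_hill_recovery(seed: int = 0, n_starts: int = 50,
                           params: ParameterSet = DEFAULT_PARAMS,
                           kind: str = "sse",
                           maxiter: int = 60) -> List[FitResult]:
    """Multistart fit of the upstream IKK/A20 module to the text-anchored
    IKK reference profile (nuclear NF-κB of the nominal model as the fixed
    drive); returns the ranked fits.  The inactivation Hill coefficient of
    the best fit is the quantity of interest."""
    baseline = run_baseline(params=params)
    _, nfkbn_drive = nominal_drives(baseline)
    ikk_ref = reference_profiles("ikk")
    obj = StageObjective("upstream", baseline.system.variant, params,
                         {"ikk": ikk_ref},
                         BoundsTable.for_stage("upstream", params),
                         kind, {"nfkbn": nfkbn_drive})
    return multistart_fit(obj, n_starts, seed, include_nominal=False,
                          maxiter=maxiter)


def structure_discrimination(seed: int = 0, n_starts: int = 20,
                             params: ParameterSet = DEFAULT_PARAMS,
                             kind: str = "chi2F", maxiter: int = 40,
                             data_seed: int | None = None,
                             ) -> Dict[str, List[FitResult]]:
    """Two-step vs four-step downstream fits on synthetic NF-κB ensembles.

    The data are generated from the four-step nominal model (five
    experiments in triplicate, the standard noise convention); both
    structures are fitted with the nominal IKK course as the driven
    input.  Returns ranked fits per structure label.
    """
    baseline = run_baseline(params=params)
    ikk_drive, _ = nominal_drives(baseline)
    nfc = normalize_trajectory(baseline.trajectory, "NFkBn", 20.0)
    grid = baseline.trajectory.times
    truth = lambda t: np.interp(t, grid, nfc)
    data = make_ensemble(truth, NFKB_GRID, n_experiments=5, n_replicates=3,
                         noise_sd=default_noise_sd(truth),
                         seed=seed if data_seed is None else data_seed,
                         normalize=False)
    return structure_comparison(baseline.system.variant, params, data,
                                ikk_drive, n_starts=n_starts, seed=seed,
                                kind=kind, maxiter=maxiter)


def fisher_calibration(seed: int = 0, n_reps: int = 2000, alpha: float = 0.05,
                       params: ParameterSet = DEFAULT_PARAMS,
                       ) -> Dict[str, float]:
    """Null calibration of the combined consistency test.

    Generates ``n_reps`` synthetic ensembles from the nominal model's
    normalized NF-κB curve under the standard noise model and tests each
    against the generating curve; under this exact null the combined
    p-value should be Uniform(0, 1).  Returns the rejection rate at
    ``alpha``, the Kolmogorov–Smirnov distance of the p-values from
    uniformity, and the binomial 99%-CI half-width for the rate.
    """
    from scipy import stats

    baseline = run_baseline(params=params)
    nfc = normalize_trajectory(baseline.trajectory, "NFkBn", 20.0)
    truth_vals = np.interp(NFKB_GRID, baseline.trajectory.times, nfc)
    sd_vals = 0.05 + 0.05 * truth_vals
    datasets = sample_null_ensembles(truth_vals, sd_vals, n_experiments=5,
                                     n_replicates=3, n_datasets=n_reps,
                                     seed=seed, grid=NFKB_GRID)
    p_f = np.array([consistency_test(truth_vals, d, alpha).p_F
                    for d in datasets])
    ks = float(stats.kstest(p_f, "uniform").statistic)
    rate = float(np.mean(p_f < alpha))
    half_width = 2.576 * np.sqrt(alpha * (1 - alpha) / n_reps)
    return {"rejection_rate": rate, "alpha": alpha, "n_reps": n_reps,
            "ks_distance": ks, "ci99_half_width": float(half_width),
            "p_values": p_f}


def first_phase_screen(params: ParameterSet = DEFAULT_PARAMS,
                       T: float = 10.0, threshold_fraction: float = 0.1,
                       ) -> Dict[str, object]:
    """Time-averaged |S| scores of nuclear NF-κB over the first phase.

    Screens which rate parameters matter during the initial activation
    interval; structural constants (volume ratio, totals) are excluded
    from the score table.
    """
    baseline = run_baseline(params=params)
    rate_params = tuple(n for n in params.values
                        if n not in ("kv", "NFkB_tot", "IKK_tot"))
    grid = np.arange(0.0, T + 0.125, 0.25)
    field = sensitivities(baseline.system, x0=baseline.equilibrium,
                          t_grid=grid, outputs=("NFkBn",),
                          param_names=rate_params)
    scores = time_avg_scores(field, T, output="NFkBn")
    significant = screen_significant(scores, threshold_fraction)
    return {"scores": scores, "significant": significant, "field": field}


#: Parameter groups contrasted by the robustness scans: rates of IKK
#: activation/inactivation versus NF-κB-induced IκBα transcription and
#: translation (the feedback loop).
ROBUST_SET = ("ka", "ki")
FRAGILE_SET = ("c1a", "c4a")


def robustness_scans(params: ParameterSet = DEFAULT_PARAMS,
                     names: Sequence[str] | None = None,
                     decades: float = 2.0, n_points: int = 9,
                     ) -> Dict[str, object]:
    """±10-fold scans (default) of selected parameters.

    Returns per-parameter ScanResults plus the max distance over the scan
    for the robust (IKK activation/inactivation) and fragile (induced
    IκBα synthesis) groups.
    """
    system = build_model(NEW_MODEL, params)
    names = tuple(names) if names is not None else ROBUST_SET + FRAGILE_SET
    scans = {n: scan_parameter(system, params, n, decades=decades,
                               n_points=n_points) for n in names}
    out: Dict[str, object] = {"scans": scans}
    if set(ROBUST_SET) <= set(names) and set(FRAGILE_SET) <= set(names):
        out["robust_max"] = float(max(np.nanmax(scans[n].distances)
                                      for n in ROBUST_SET))
        out["fragile_max"] = float(max(np.nanmax(scans[n].distances)
                                       for n in FRAGILE_SET))
    return out
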