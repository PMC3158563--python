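"""Dynamic sensitivity analysis and multi-decade robustness scans.

Time-resolved normalized first-order sensitivity coefficients

    S_ij(t) = (θ_j / y_i(t)) · ∂y_i(t)/∂θ_j

are computed by the forward sensitivity equations: after solving the
state trajectory x(t), each parameter's raw sensitivity s_j(t) solves the
linear time-varying ODE  s_j' = J_x(x(t))·s_j + ∂f/∂θ_j(x(t))  with
s_j(0) = 0 (the initial state — normally the pre-stimulus equilibrium —
is held fixed, so coefficients measure the response of the stimulated
trajectory to a parameter change applied at stimulus onset).  A central
finite-difference evaluator serves as the independent oracle.

Robustness to large perturbations is probed by parameter scans: each rate
is varied over several decades and the Euclidean distance between the
nominal and perturbed (re-equilibrated, re-normalized) nuclear-NF-κB
responses is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

from .model import (PARAM_NAMES, ModelSystem, ParameterSet, ValidationError,
                    _sym)
from .simulate import (SolverOptions, Trajectory, equilibrate, no_stimulus,
                       normalize_trajectory, simulate, step_stimulus)

__all__ = [
    "SensitivityField",
    "ScanResult",
    "sensitivities",
    "time_avg_scores",
    "screen_significant",
    "scan_parameter",
    "Y_FLOOR",
]

#: Concentrations below this floor (µM) make the normalized coefficient
#: undefined; such entries are reported as NaN rather than blowing up.
Y_FLOOR = 1e-12

_SENS_SOLVER = SolverOptions(rtol=1e-10, atol=1e-12)


@dataclass
class SensitivityField:
    """S[i, j, k] over (output i, parameter j, time k); NaN where undefined."""

    outputs: Sequence[str]
    params: Sequence[str]
    times: np.ndarray
    values: np.ndarray            # (n_outputs, n_params, n_times)
    method: str                   # {forward_ode | finite_difference}

    def coefficient(self, output: str, param: str) -> np.ndarray:
        i = list(self.outputs).index(output)
        j = list(self.params).index(param)
        return self.values[i, j]


@dataclass
class ScanResult:
    parameter: str
    factors: np.ndarray
    distances: np.ndarray         # NaN where the perturbed run failed
    curves: Dict[float, np.ndarray] = field(default_factory=dict)
    mode: str = "normalized"


def _param_jacobian_fn(system: ModelSystem):
    """Lambdified ∂f/∂θ of the system's RHS, cached on the instance."""
    fn = system.__dict__.get("_jp_cache")
    if fn is not None:
        return fn
    exprs = system.derivative_exprs()
    x_vec, p_vec = sp.DeferredVector("x"), sp.DeferredVector("p")
    sub = {_sym(name): x_vec[i] for i, name in enumerate(system.species)}
    sub.update({_sym(name): p_vec[j] for j, name in enumerate(PARAM_NAMES)})
    extra = [_sym("TNF")] + ([_sym(system.driven)] if system.driven else [])
    mat = sp.Matrix(exprs).jacobian([_sym(n) for n in PARAM_NAMES]).subs(sub)
    fn = sp.lambdify((x_vec, *extra, p_vec), mat, modules="numpy", cse=True)
    system.__dict__["_jp_cache"] = fn
    return fn


def _solve_states_dense(system: ModelSystem, x0, t_span, stimulus, drive):
    if drive is None:
        fun = lambda t, x: system.rhs(t, x, stimulus)
        jac = lambda t, x: system.jacobian(t, x, stimulus)
    else:
        fun = lambda t, x: system.rhs_driven(t, x, stimulus, drive)
        jac = lambda t, x: system.jacobian_driven(t, x, stimulus, drive)
    sol = solve_ivp(fun, t_span, np.asarray(x0, dtype=float), method="LSODA",
                    jac=jac, dense_output=True,
                    rtol=_SENS_SOLVER.rtol, atol=_SENS_SOLVER.atol)
    if not sol.success:
        raise ValidationError(f"state integration failed: {sol.message}")
    return sol.sol


def sensitivities(system: ModelSystem, params: ParameterSet | None = None, *,
                  x0, t_grid: Sequence[float], outputs: Sequence[str],
                  param_names: Sequence[str] | None = None,
                  stimulus: Callable[[float], float] = step_stimulus,
                  drive: Callable[[float], float] | None = None,
                  method: str = "forward_ode",
                  fd_step: float = 1e-6) -> SensitivityField:
    """Normalized sensitivity coefficients of ``outputs`` w.r.t. parameters.

    ``method="forward_ode"`` integrates the forward sensitivity equations
    along the stored state interpolant; ``method="finite_difference"``
    re-simulates at θ_j(1 ± fd_step) and differences centrally (the
    oracle).  Both hold the initial state fixed.
    """
    if params is not None:
        system = system.with_params(params)
    params = system.params
    t_grid = np.asarray(t_grid, dtype=float)
    names = tuple(param_names) if param_names is not None else PARAM_NAMES
    idx_out = [system.index[o] for o in outputs]
    theta = params.as_array()

    if method == "finite_difference":
        raw = _fd_raw(system, x0, t_grid, stimulus, drive, names, fd_step)
    elif method == "forward_ode":
        raw = _forward_raw(system, x0, t_grid, stimulus, drive, names)
    else:
        raise ValidationError(f"unknown sensitivity method {method!r}")

    # normalize: S = θ_j / y_i(t) · s_ij(t); undefined below the floor
    y = _reference_solution(system, x0, t_grid, stimulus, drive)
    values = np.empty((len(outputs), len(names), t_grid.size))
    for a, i in enumerate(idx_out):
        yi = y[:, i]
        for b, name in enumerate(names):
            j = PARAM_NAMES.index(name)
            s = raw[:, i, b]
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = theta[j] * s / yi
            vals = np.where(yi > Y_FLOOR, vals, np.nan)
            values[a, b] = vals
    return SensitivityField(tuple(outputs), names, t_grid, values, method)


def _reference_solution(system, x0, t_grid, stimulus, drive):
    dense = _solve_states_dense(system, x0, (t_grid[0], t_grid[-1]),
                                stimulus, drive)
    return dense(t_grid).T


def _forward_raw(system, x0, t_grid, stimulus, drive, names):
    """raw[t, i, j] = ∂x_i(t)/∂θ_j by the forward sensitivity equations."""
    dense = _solve_states_dense(system, x0, (t_grid[0], t_grid[-1]),
                                stimulus, drive)
    jp_fn = _param_jacobian_fn(system)
    p = system.params.as_array()
    cols = [PARAM_NAMES.index(n) for n in names]
    n = len(system.species)
    raw = np.zeros((t_grid.size, n, len(names)))

    def args_at(t):
        x = np.maximum(dense(t), 0.0)
        extra = (float(stimulus(t)),) + ((float(drive(t)),) if drive else ())
        return x, extra

    for b, col in enumerate(cols):
        def rhs_s(t, s):
            x, extra = args_at(t)
            # tiny positive floor: Hill-exponent derivatives involve
            # x^h·ln(x), which is NaN at exactly zero concentration
            xq = np.maximum(x, 1e-30)
            jx = np.asarray(system._jac(xq, *extra, p))
            fp = np.asarray(jp_fn(xq, *extra, p))[:, col]
            return jx @ s + fp

        def jac_s(t, s):
            x, extra = args_at(t)
            return np.asarray(system._jac(np.maximum(x, 1e-30), *extra, p))

        sol = solve_ivp(rhs_s, (t_grid[0], t_grid[-1]), np.zeros(n),
                        method="LSODA", jac=jac_s, t_eval=t_grid,
                        rtol=1e-9, atol=1e-12)
        if not sol.success:
            raise ValidationError(
                f"sensitivity integration failed for {names[b]}: {sol.message}")
        raw[:, :, b] = sol.y.T
    return raw


def _fd_raw(system, x0, t_grid, stimulus, drive, names, rel_step):
    """Central finite differences of the trajectory w.r.t. each parameter."""
    raw = np.zeros((t_grid.size, len(system.species), len(names)))
    for b, name in enumerate(names):
        theta = system.params[name]
        h = rel_step * theta if theta != 0 else rel_step
        tr_plus = _states_at(system, name, theta + h, x0, t_grid, stimulus, drive)
        tr_minus = _states_at(system, name, theta - h, x0, t_grid, stimulus, drive)
        raw[:, :, b] = (tr_plus - tr_minus) / (2.0 * h)
    return raw


def _states_at(system, name, value, x0, t_grid, stimulus, drive):
    pset = system.params
    bounds = dict(pset.bounds)
    lo, hi = bounds[name]
    bounds[name] = (min(lo, value), max(hi, value))
    perturbed = ParameterSet({**dict(pset.values), name: value}, bounds)
    sysp = system.with_params(perturbed)
    dense = _solve_states_dense(sysp, x0, (t_grid[0], t_grid[-1]),
                                stimulus, drive)
    return dense(t_grid).T


def time_avg_scores(field: SensitivityField, T: float,
                    output: str | None = None) -> Dict[str, float]:
    """Per-parameter score: (1/T)·∫₀ᵀ |S_ij(t)| dt (trapezoid; NaN → 0)."""
    if T > field.times[-1] + 1e-9:
        raise ValidationError(f"T = {T} exceeds the field's span {field.times[-1]}")
    sel = field.times <= T + 1e-9
    t = field.times[sel]
    i = 0 if output is None else list(field.outputs).index(output)
    scores = {}
    for j, name in enumerate(field.params):
        s = np.abs(np.nan_to_num(field.values[i, j, sel]))
        scores[name] = float(np.trapezoid(s, t) / T)
    return scores


def screen_significant(scores: Dict[str, float],
                       threshold_fraction: float) -> List[str]:
    """Parameters whose score reaches ``threshold_fraction`` of the maximum.

    Ties at the threshold are all included; the result is sorted by
    descending score (then name, for determinism).
    """
    if not scores:
        raise ValidationError("empty score table")
    top = max(scores.values())
    keep = [n for n, v in scores.items() if v >= threshold_fraction * top]
    return sorted(keep, key=lambda n: (-scores[n], n))


def scan_parameter(system: ModelSystem, params: ParameterSet, name: str, *,
                   decades: float = 4.0, n_points: int = 17,
                   output_grid: Sequence[float] | None = None,
                   species: str = "NFkBn", ref_time: float = 20.0,
                   mode: str = "normalized",
                   solver: SolverOptions | None = None) -> ScanResult:
    """Multi-decade robustness scan of one parameter.

    For each multiplicative factor (log-spaced, centered on 1, spanning
    ``decades`` total) the model is re-equilibrated and re-simulated; the
    Euclidean distance to the nominal response is computed on
    ``output_grid``, with each curve normalized at its own ``ref_time``
    value (``mode="normalized"``, the comparison convention) or in
    absolute µM (``mode="absolute"``).  Failures are recorded as NaN.
    """
    if name not in PARAM_NAMES:
        raise ValidationError(f"unknown parameter {name!r}")
    if decades <= 0 or n_points < 3:
        raise ValidationError("need decades > 0 and n_points ≥ 3")
    if mode not in ("normalized", "absolute"):
        raise ValidationError(f"unknown scan mode {mode!r}")
    solver = solver or SolverOptions(rtol=1e-7, atol=1e-10)
    grid = (np.asarray(output_grid, dtype=float) if output_grid is not None
            else np.linspace(0.0, 120.0, 61))
    factors = np.logspace(-decades / 2.0, decades / 2.0, n_points)
    # ensure the nominal point is present exactly
    if not np.any(np.isclose(factors, 1.0)):
        factors = np.sort(np.append(factors, 1.0))

    def response(pset: ParameterSet) -> np.ndarray:
        sysp = system.with_params(pset)
        x0 = equilibrate(sysp, tol=1e-8, solver=solver)
        traj = simulate(sysp, x0=x0, t_grid=grid, solver=solver)
        if mode == "normalized":
            return normalize_trajectory(traj, species, ref_time)
        return traj[species]

    nominal = response(params)
    distances, curves = [], {}
    for f in factors:
        if np.isclose(f, 1.0):
            distances.append(0.0)
            curves[float(f)] = nominal
            continue
        try:
            curve = response(params.scaled(name, float(f)))
            distances.append(float(np.linalg.norm(curve - nominal)))
            curves[float(f)] = curve
        except Exception:
            distances.append(np.nan)
    return ScanResult(name, factors, np.asarray(distances), curves, mode)
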