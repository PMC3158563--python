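"""Equilibrate-then-stimulate protocol and loop-broken driven simulations.

The standard protocol places the whole NF-κB pool as free cytoplasmic
protein and the whole IKK pool in the native state, integrates without
stimulus until the relative rates fall below tolerance, and uses that
fixed point as the initial condition for the stimulated run.  Loop
breaking replaces one species' dynamics (active IKK, or nuclear NF-κB)
by a fixed interpolated input so the two halves of the network can be
studied and fitted independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, Sequence

import warnings

import numpy as np
from scipy.integrate import ODEintWarning, odeint
from scipy.interpolate import PchipInterpolator

from .model import ModelSystem, ParameterSet, ValidationError

__all__ = [
    "IntegrationError",
    "ConvergenceError",
    "Trajectory",
    "DrivenInput",
    "step_stimulus",
    "no_stimulus",
    "SolverOptions",
    "equilibrate",
    "equilibrate_driven",
    "simulate",
    "make_driven_input",
    "run_downstream_driven",
    "run_upstream_driven",
    "normalize_trajectory",
]


class IntegrationError(RuntimeError):
    pass


class ConvergenceError(RuntimeError):
    pass


def no_stimulus(t: float) -> float:
    return 0.0


def step_stimulus(t: float) -> float:
    """Sustained saturating TNFα from t = 0 (the 10 ng/ml protocol)."""
    return 1.0 if t >= 0 else 0.0


@dataclass(frozen=True)
class SolverOptions:
    """Stiff-integrator settings (LSODA with the analytic Jacobian).

    ``mxstep`` caps the internal steps per output interval so that a
    pathologically stiff parameter draw fails fast (and is turned into a
    finite objective penalty by the estimation layer) instead of stalling.
    """

    rtol: float = 1e-8
    atol: float = 1e-10  # µM
    mxstep: int = 500000


DEFAULT_SOLVER = SolverOptions()


@dataclass
class Trajectory:
    """Time grid plus aligned state matrix from one simulation."""

    times: np.ndarray                  # min, strictly increasing
    states: np.ndarray                 # (len(times), n_species)
    species: Sequence[str]
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("trajectory times must be strictly increasing")
        if self.states.shape != (self.times.size, len(self.species)):
            raise ValidationError("state matrix shape does not match times × species")

    def __getitem__(self, species: str) -> np.ndarray:
        return self.states[:, list(self.species).index(species)]


@dataclass(frozen=True)
class DrivenInput:
    """Shape-preserving interpolant of a measured/simulated time course.

    Piecewise cubic Hermite (pchip) between the knots — monotone on
    monotone data segments, so it never overshoots local extrema — and a
    constant ``tail_value`` beyond the last knot.
    """

    knot_times: np.ndarray
    knot_values: np.ndarray
    tail_value: float
    _interp: PchipInterpolator = field(repr=False, default=None)  # type: ignore

    def __call__(self, t):
        if np.isscalar(t):
            # scalar fast path (used inside ODE right-hand sides): direct
            # Horner evaluation of the pchip piece — the generic PPoly
            # call would dominate the integration cost
            t = float(t)
            x = self._interp.x
            if t > x[-1]:
                return self.tail_value
            if t <= x[0]:
                return float(self.knot_values[0])
            i = int(np.searchsorted(x, t, side="right")) - 1
            i = min(i, x.size - 2)
            s = t - x[i]
            c = self._interp.c
            return float(((c[0, i] * s + c[1, i]) * s + c[2, i]) * s + c[3, i])
        t_arr = np.asarray(t, dtype=float)
        return np.where(t_arr > self.knot_times[-1], self.tail_value,
                        self._interp(np.clip(t_arr, None, self.knot_times[-1])))


def make_driven_input(knots: Sequence, tail_value: float) -> DrivenInput:
    """Build a DrivenInput from ``(time, value)`` pairs."""
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 2 or knots.shape[0] < 2:
        raise ValidationError("need at least 2 (time, value) knots")
    t, v = knots[:, 0], knots[:, 1]
    if np.any(np.diff(t) <= 0):
        raise ValidationError("knot times must be strictly increasing (no duplicates)")
    if np.any(v < 0) or tail_value < 0:
        raise ValidationError("driven-input values must be ≥ 0")
    interp = PchipInterpolator(t, v, extrapolate=False)
    return DrivenInput(t, v, float(tail_value), interp)


def _initial_state(system: ModelSystem) -> np.ndarray:
    x0 = np.zeros(len(system.species))
    idx = system.index
    if "NFkB" in idx:
        x0[idx["NFkB"]] = system.params["NFkB_tot"]
    if "IKKn" in idx:
        x0[idx["IKKn"]] = system.params["IKK_tot"]
    return x0


def _integrate(system: ModelSystem, x0: np.ndarray, t_grid: np.ndarray,
               stimulus: Callable[[float], float],
               drive: Callable[[float], float] | None,
               solver: SolverOptions) -> np.ndarray:
    if drive is None:
        fun = lambda t, x: system.rhs(t, x, stimulus)
        jac = lambda t, x: system.jacobian(t, x, stimulus)
    else:
        fun = lambda t, x: system.rhs_driven(t, x, stimulus, drive)
        jac = lambda t, x: system.jacobian_driven(t, x, stimulus, drive)
    with warnings.catch_warnings():
        # failures surface as IntegrationError below; the lsoda warning
        # banner would otherwise spam multistart runs
        warnings.simplefilter("ignore", ODEintWarning)
        out, info = odeint(fun, x0, t_grid, Dfun=jac, tfirst=True,
                           rtol=solver.rtol, atol=solver.atol,
                           mxstep=solver.mxstep, full_output=True,
                           printmessg=False)
    if info["message"] != "Integration successful.":
        t_fail = float(info["tcur"][-1]) if len(info.get("tcur", [])) else t_grid[0]
        raise IntegrationError(
            f"integration failed at t ≈ {t_fail:.3f} min: {info['message']}")
    if not np.all(np.isfinite(out)):
        raise IntegrationError("integration produced non-finite states")
    return out


def equilibrate(system: ModelSystem, params: ParameterSet | None = None, *,
                tol: float = 1e-9, t_max: float = 1e5,
                solver: SolverOptions = DEFAULT_SOLVER) -> np.ndarray:
    """Pre-stimulus fixed point of the system (TNF = 0).

    Starts from the canonical initial condition (all NF-κB free and
    cytoplasmic, all IKK native, everything else zero) and integrates in
    chunks until ``max_i |dx_i/dt| / (|x_i| + ε) < tol`` (units 1/min).
    With TNF = 0 the activation flux vanishes, so active IKK stays at
    exactly zero throughout equilibration.
    """
    if params is not None:
        system = system.with_params(params)
    if tol <= 0:
        raise ValidationError("tol must be > 0")
    x = _initial_state(system)
    eps = 1e-12
    t, chunk = 0.0, 2000.0
    while t < t_max:
        grid = np.array([0.0, chunk])
        x = _integrate(system, x, grid, no_stimulus, None, solver)[-1]
        t += chunk
        rate = system.rhs(0.0, x, no_stimulus)
        resid = float(np.max(np.abs(rate) / (np.abs(x) + eps)))
        if resid < tol:
            return _clean_equilibrium(x)
        chunk = min(2 * chunk, t_max - t) if t_max - t > 0 else chunk
    raise ConvergenceError(
        f"no equilibrium within t_max = {t_max} min (residual {resid:.3e} ≥ tol {tol:.1e})")


def _clean_equilibrium(x: np.ndarray) -> np.ndarray:
    """Zero out negative solver dust on species whose true pre-stimulus
    value is exactly zero (tolerated up to 10⁻⁵ of the largest pool —
    stiff rate constants amplify the wobble)."""
    floor = -1e-5 * max(float(np.max(x)), 1e-30)
    if np.any(x < floor):
        raise ConvergenceError(f"equilibrium has a negative concentration: {x.min()}")
    return np.where(x < 0.0, 0.0, x)


def simulate(system: ModelSystem, params: ParameterSet | None = None, *,
             x0: np.ndarray, t_grid: Sequence[float],
             stimulus: Callable[[float], float] = step_stimulus,
             solver: SolverOptions = DEFAULT_SOLVER) -> Trajectory:
    """Integrate the full model on ``t_grid`` from state ``x0``."""
    if params is not None:
        system = system.with_params(params)
    t_grid = np.asarray(t_grid, dtype=float)
    states = _integrate(system, np.asarray(x0, dtype=float), t_grid,
                        stimulus, None, solver)
    return Trajectory(t_grid, states, system.species,
                      meta={"variant": system.variant, "driven": None})


def _run_driven(system: ModelSystem, drive: DrivenInput,
                t_grid: Sequence[float],
                stimulus: Callable[[float], float],
                x0: np.ndarray | None,
                solver: SolverOptions) -> Trajectory:
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] < drive.knot_times[0]:
        raise ValidationError("driven input undefined at the start of the grid")
    if x0 is None:
        x0 = equilibrate_driven(system, solver=solver)
    states = _integrate(system, np.asarray(x0, dtype=float), t_grid,
                        stimulus, drive, solver)
    return Trajectory(t_grid, states, system.species,
                      meta={"variant": system.variant, "driven": system.driven})


def equilibrate_driven(system: ModelSystem, *, drive_value: float = 0.0,
                       tol: float = 1e-9, t_max: float = 1e5,
                       solver: SolverOptions = DEFAULT_SOLVER) -> np.ndarray:
    """Fixed point of a loop-broken submodule with its input held constant."""
    x = _initial_state(system)
    const = lambda t: drive_value
    eps, t, chunk = 1e-12, 0.0, 2000.0
    while t < t_max:
        x = _integrate(system, x, np.array([0.0, chunk]), no_stimulus, const, solver)[-1]
        t += chunk
        rate = system.rhs_driven(0.0, x, no_stimulus, const)
        resid = float(np.max(np.abs(rate) / (np.abs(x) + eps)))
        if resid < tol:
            return _clean_equilibrium(x)
        chunk = min(2 * chunk, max(t_max - t, chunk))
    raise ConvergenceError(f"driven equilibration did not converge (residual {resid:.3e})")


def run_downstream_driven(system: ModelSystem, ikk_input: DrivenInput,
                          t_grid: Sequence[float], *,
                          x0: np.ndarray | None = None,
                          solver: SolverOptions = DEFAULT_SOLVER) -> Trajectory:
    """Integrate the downstream module with IKKa(t) given by ``ikk_input``.

    The IKK-cycle equations are removed; A20 is still synthesized but has
    no remaining feedback target, mirroring the broken outer loop.
    """
    if system.driven != "IKKa":
        raise ValidationError("system must be built with build_driven_model(..., 'IKKa')")
    return _run_driven(system, ikk_input, t_grid, no_stimulus, x0, solver)


def run_upstream_driven(system: ModelSystem, nfkbn_input: DrivenInput,
                        t_grid: Sequence[float], *,
                        x0: np.ndarray | None = None,
                        stimulus: Callable[[float], float] = step_stimulus,
                        solver: SolverOptions = DEFAULT_SOLVER) -> Trajectory:
    """Integrate the upstream IKK/A20 module with NFkBn(t) as fixed input."""
    if system.driven != "NFkBn":
        raise ValidationError("system must be built with build_driven_model(..., 'NFkBn')")
    return _run_driven(system, nfkbn_input, t_grid, stimulus, x0, solver)


def normalize_trajectory(traj: Trajectory, species: str,
                         ref_time: float) -> np.ndarray:
    """Species time course divided by its value at ``ref_time``.

    The comparison convention for all fitting and testing: nuclear NF-κB
    is normalized at 20 min, active IKK at 5 min.
    """
    times = traj.times
    hit = np.nonzero(np.isclose(times, ref_time))[0]
    if hit.size == 0:
        raise ValidationError(f"ref_time {ref_time} not on the trajectory grid")
    curve = traj[species]
    ref = curve[hit[0]]
    if ref <= 0:
        raise ValidationError(
            f"cannot normalize: {species} at {ref_time} min is {ref}")
    return curve / ref
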