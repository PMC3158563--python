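import numpy as np
import pytest
from scipy.signal import argrelmax

from nfkbmicro.model import SPECIES, ValidationError, nfkb_total
from nfkbmicro.simulate import (SolverOptions, equilibrate,
                                equilibrate_driven, make_driven_input,
                                normalize_trajectory, no_stimulus,
                                run_downstream_driven, run_upstream_driven,
                                simulate)


class TestEquilibrate:
    def test_residual_below_tolerance(self, full_system, equilibrium):
        rate = full_system.rhs(0.0, equilibrium, no_stimulus)
        resid = np.max(np.abs(rate) / (np.abs(equilibrium) + 1e-12))
        assert resid < 1e-9

    def test_deterministic(self, full_system):
        x1 = equilibrate(full_system)
        x2 = equilibrate(full_system)
        assert np.array_equal(x1, x2)

    def test_active_ikk_zero_pre_stimulus(self, full_system, equilibrium):
        assert abs(equilibrium[full_system.index["IKKa"]]) < 1e-12

    def test_nfkb_mostly_inhibitor_bound_at_rest(self, full_system, equilibrium):
        idx = full_system.index
        bound = equilibrium[idx["IkBa_NFkB"]]
        free_nuclear = equilibrium[idx["NFkBn"]] / full_system.params["kv"]
        assert bound > free_nuclear

    def test_bad_tolerance_rejected(self, full_system):
        with pytest.raises(ValidationError):
            equilibrate(full_system, tol=-1.0)


class TestSimulate:
    def test_no_stimulus_holds_equilibrium(self, full_system, equilibrium):
        grid = np.linspace(0.0, 120.0, 61)
        traj = simulate(full_system, x0=equilibrium, t_grid=grid,
                        stimulus=no_stimulus)
        scale = np.abs(equilibrium) + 1e-12
        drift = np.max(np.abs(traj.states - equilibrium) / scale)
        assert drift < 1e-6

    def test_stimulated_shapes(self, baseline):
        """Sustained TNFα: IKKa rises then falls; nuclear NF-κB is delayed
        and biphasic (a second, smaller local maximum)."""
        traj = baseline.trajectory
        ikka, nfkbn = traj["IKKa"], traj["NFkBn"]
        i_peak, n_peak = np.argmax(ikka), np.argmax(nfkbn)
        assert 0 < i_peak < len(ikka) - 1
        assert ikka[-1] < 0.25 * ikka[i_peak]
        assert traj.times[n_peak] > traj.times[i_peak]  # NF-κB lags IKK
        later = argrelmax(nfkbn)[0]
        second = [i for i in later if i > n_peak + 40]
        assert second, "expected a second NF-κB peak"
        assert nfkbn[second[0]] < nfkbn[n_peak]

    def test_nfkb_conservation_along_trajectory(self, baseline, params):
        kv = params["kv"]
        t0 = nfkb_total(baseline.trajectory.states[0], kv)
        worst = max(abs(nfkb_total(row, kv) - t0) / t0
                    for row in baseline.trajectory.states[::40])
        assert worst < 1e-6

    def test_ikk_pool_conservation(self, baseline, params):
        traj = baseline.trajectory
        pool = traj["IKKn"] + traj["IKKa"] + traj["IKKi"]
        assert np.max(np.abs(pool - params["IKK_tot"])) / params["IKK_tot"] < 1e-6

    def test_non_negativity_at_output_points(self, baseline):
        assert baseline.trajectory.states.min() > -1e-9

    def test_solver_tolerance_convergence(self, full_system, equilibrium):
        grid = np.linspace(0.0, 120.0, 61)
        loose = simulate(full_system, x0=equilibrium, t_grid=grid,
                         solver=SolverOptions(rtol=1e-8, atol=1e-10))
        tight = simulate(full_system, x0=equilibrium, t_grid=grid,
                         solver=SolverOptions(rtol=5e-9, atol=5e-11))
        rel = (np.max(np.abs(loose["NFkBn"] - tight["NFkBn"]))
               / np.max(tight["NFkBn"]))
        assert rel < 1e-4


class TestDrivenInput:
    def test_knot_exactness(self):
        knots = [(0.0, 0.1), (5.0, 1.0), (10.0, 0.4), (30.0, 0.05)]
        d = make_driven_input(knots, tail_value=0.02)
        for t, v in knots:
            assert d(t) == pytest.approx(v, abs=1e-12)

    def test_monotone_segments_no_overshoot(self):
        d = make_driven_input([(0, 1.0), (5, 0.6), (10, 0.3), (20, 0.1)],
                              tail_value=0.1)
        ts = np.linspace(0, 20, 400)
        vals = np.array([d(float(t)) for t in ts])
        assert np.all(np.diff(vals) <= 1e-12)
        assert vals.max() <= 1.0 + 1e-12 and vals.min() >= 0.1 - 1e-12

    def test_constant_tail(self):
        d = make_driven_input([(0, 0.0), (30, 1.0)], tail_value=0.05)
        assert d(130.0) == 0.05
        assert d(30.0) == pytest.approx(1.0)

    def test_duplicate_knot_times_rejected(self):
        with pytest.raises(ValidationError):
            make_driven_input([(0, 1.0), (0, 2.0), (5, 0.0)], tail_value=0.0)

    def test_negative_values_rejected(self):
        with pytest.raises(ValidationError):
            make_driven_input([(0, -0.1), (5, 1.0)], tail_value=0.0)

    def test_scalar_matches_vector_evaluation(self):
        d = make_driven_input([(0, 0.2), (4, 1.0), (9, 0.3), (30, 0.02)],
                              tail_value=0.01)
        ts = np.linspace(0, 40, 173)
        vec = d(ts)
        scal = np.array([d(float(t)) for t in ts])
        assert np.allclose(vec, scal, atol=1e-12)


class TestLoopBreaking:
    def test_downstream_self_consistency(self, full_system, downstream_system,
                                         baseline):
        """Feeding the downstream module the full model's own active-IKK
        course reproduces the closed-loop nuclear NF-κB within 0.5%."""
        traj = baseline.trajectory
        drive = make_driven_input(
            np.column_stack([traj.times, np.clip(traj["IKKa"], 0, None)]),
            tail_value=float(max(traj["IKKa"][-1], 0)))
        x0 = np.array([baseline.equilibrium[full_system.index[s]]
                       for s in downstream_system.species])
        ds = run_downstream_driven(downstream_system, drive, traj.times, x0=x0)
        err = (np.max(np.abs(ds["NFkBn"] - traj["NFkBn"]))
               / np.max(traj["NFkBn"]))
        assert err < 0.005

    def test_upstream_self_consistency(self, full_system, upstream_system,
                                       baseline):
        traj = baseline.trajectory
        drive = make_driven_input(
            np.column_stack([traj.times, np.clip(traj["NFkBn"], 0, None)]),
            tail_value=float(max(traj["NFkBn"][-1], 0)))
        x0 = np.array([baseline.equilibrium[full_system.index[s]]
                       for s in upstream_system.species])
        us = run_upstream_driven(upstream_system, drive, traj.times, x0=x0)
        err = np.max(np.abs(us["IKKa"] - traj["IKKa"])) / np.max(traj["IKKa"])
        assert err < 0.005

    def test_zero_drive_keeps_downstream_basal(self, downstream_system):
        x0 = equilibrate_driven(downstream_system)
        zero = make_driven_input([(0.0, 0.0), (120.0, 0.0)], tail_value=0.0)
        traj = run_downstream_driven(downstream_system, zero,
                                     np.linspace(0, 120, 25), x0=x0)
        scale = np.abs(x0) + 1e-12
        assert np.max(np.abs(traj.states - x0) / scale) < 1e-5

    def test_downstream_response_lags_input_onset(self, downstream_system,
                                                  drives):
        """The degradation chain delays NF-κB release: the nuclear NF-κB
        peak comes strictly after the IKK input peak."""
        ikk_drive, _ = drives
        x0 = equilibrate_driven(downstream_system)
        grid = np.linspace(0, 60, 241)
        traj = run_downstream_driven(downstream_system, ikk_drive, grid, x0=x0)
        t_in_peak = ikk_drive.knot_times[np.argmax(ikk_drive.knot_values)]
        t_out_peak = grid[np.argmax(traj["NFkBn"])]
        assert t_out_peak > t_in_peak

    def test_zero_nfkbn_drive_keeps_a20_dark(self, upstream_system, params):
        """Open outer loop with no nuclear NF-κB: A20 stays at zero and IKK
        shows a single unmodulated transient."""
        x0 = np.zeros(len(upstream_system.species))
        x0[upstream_system.index["IKKn"]] = params["IKK_tot"]
        zero = make_driven_input([(0.0, 0.0), (120.0, 0.0)], tail_value=0.0)
        traj = run_upstream_driven(upstream_system, zero,
                                   np.linspace(0, 120, 121), x0=x0)
        assert np.max(traj["A20"]) < 1e-12
        ikka = traj["IKKa"]
        peak = np.argmax(ikka)
        assert 0 < peak < len(ikka) - 1
        assert np.all(np.diff(ikka[peak:]) <= 1e-10)

    def test_faster_recycling_raises_late_ikk(self, upstream_system, drives,
                                              params):
        """Doubling the inactive→native recycling rate raises late-phase
        active IKK when the nuclear NF-κB input is held fixed."""
        _, nfkbn_drive = drives
        grid = np.linspace(0, 120, 61)
        x0 = equilibrate_driven(upstream_system,
                                drive_value=float(nfkbn_drive(0.0)))
        base = run_upstream_driven(upstream_system, nfkbn_drive, grid, x0=x0)
        fast = run_upstream_driven(
            upstream_system.with_params(params.scaled("kp", 2.0)),
            nfkbn_drive, grid, x0=x0)
        assert fast["IKKa"][-1] > base["IKKa"][-1]


class TestNormalize:
    def test_reference_time_maps_to_one(self, baseline):
        curve = normalize_trajectory(baseline.trajectory, "NFkBn", 20.0)
        i = np.nonzero(np.isclose(baseline.trajectory.times, 20.0))[0][0]
        assert curve[i] == 1.0

    def test_constant_trajectory_normalizes_to_one(self, full_system,
                                                   equilibrium):
        grid = np.linspace(0.0, 30.0, 7)
        traj = simulate(full_system, x0=equilibrium, t_grid=grid,
                        stimulus=no_stimulus)
        curve = normalize_trajectory(traj, "IkBa_NFkB", 10.0)
        assert np.allclose(curve, 1.0, atol=1e-6)

    def test_missing_reference_time_rejected(self, baseline):
        with pytest.raises(ValidationError):
            normalize_trajectory(baseline.trajectory, "NFkBn", 17.77)

    def test_zero_at_reference_time_rejected(self, full_system, equilibrium):
        traj = simulate(full_system, x0=equilibrium,
                        t_grid=np.linspace(0, 10, 11), stimulus=no_stimulus)
        with pytest.raises(ValidationError):
            normalize_trajectory(traj, "IKKa", 5.0)  # clamped at zero
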