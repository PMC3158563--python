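import numpy as np
import pytest
from scipy import stats

from nfkbmicro.model import NEW_MODEL, ValidationError
from nfkbmicro.simulate import normalize_trajectory
from nfkbmicro.synthetic import NFKB_GRID, EnsembleDataset, make_ensemble
from nfkbmicro.estimation import (FREE_PARAMS, BoundsTable, StageObjective,
                                  ikk_drive_from_data, multistart_fit,
                                  pvalue_histogram, FitResult, PENALTY)
from nfkbmicro.consistency import ConsistencyReport


@pytest.fixture(scope="module")
def truth_curve(baseline):
    nfc = normalize_trajectory(baseline.trajectory, "NFkBn", 20.0)
    grid = baseline.trajectory.times
    return lambda t: np.interp(t, grid, nfc)


@pytest.fixture(scope="module")
def noiseless_data(truth_curve):
    """Ensemble whose means equal the generating curve exactly (SD kept
    positive so the t-tests are defined)."""
    mu = truth_curve(NFKB_GRID)
    return EnsembleDataset.from_summary(NFKB_GRID, mu,
                                        np.full(mu.size, 0.1),
                                        np.full(mu.size, 15), "nfkb")


@pytest.fixture(scope="module")
def downstream_objective(params, noiseless_data, drives):
    ikk_drive, _ = drives
    return StageObjective("downstream", NEW_MODEL, params,
                          {"nfkb": noiseless_data},
                          BoundsTable.for_stage("downstream", params),
                          "sse", {"ikk": ikk_drive})


class TestObjective:
    def test_sse_vanishes_at_generating_truth(self, downstream_objective,
                                              params):
        # the driven module fed the nominal model's own IKK course must
        # reproduce the curve the data were built from (small interpolation
        # residue aside)
        assert downstream_objective.value(params) < 5e-4

    def test_chi2f_zero_when_every_point_is_centered(self, params,
                                                     noiseless_data, drives):
        ikk_drive, _ = drives
        obj = StageObjective("downstream", NEW_MODEL, params,
                             {"nfkb": noiseless_data},
                             BoundsTable.for_stage("downstream", params),
                             "chi2F", {"ikk": ikk_drive})
        chi2 = obj.value(params)
        # residuals are a small fraction of the SEM at every point, so the
        # combined statistic stays far below its 2n-dof null mean
        assert chi2 < 2.0
        report = obj.reports(params)[0]
        assert report.p_F > 0.999

    def test_perturbing_feedback_rate_increases_error(self, downstream_objective,
                                                      params):
        base = downstream_objective.value(params)
        bent = downstream_objective.value(params.scaled("c1a", 3.0))
        assert bent > base * 10

    def test_invalid_objective_kind_rejected(self, params, noiseless_data):
        with pytest.raises(ValidationError):
            StageObjective("downstream", NEW_MODEL, params,
                           {"nfkb": noiseless_data},
                           BoundsTable.for_stage("downstream", params),
                           "rmse", {})

    def test_encode_decode_round_trip(self, downstream_objective, params):
        vec = downstream_objective.encode(params)
        back = downstream_objective.decode(vec)
        for name in downstream_objective.bounds.free:
            assert back[name] == pytest.approx(params[name], rel=1e-12)

    def test_objectives_rank_perturbation_ladder_concordantly(
            self, params, noiseless_data, drives):
        """SSE and χ²_F orderings agree (Spearman ρ > 0.8) on a ladder of
        progressively perturbed parameter sets."""
        ikk_drive, _ = drives
        kinds = {}
        for kind in ("sse", "chi2F"):
            obj = StageObjective("downstream", NEW_MODEL, params,
                                 {"nfkb": noiseless_data},
                                 BoundsTable.for_stage("downstream", params),
                                 kind, {"ikk": ikk_drive})
            ladder = [obj.value(params.scaled("kc1", f))
                      for f in np.logspace(0.02, 1.0, 20)]
            kinds[kind] = ladder
        rho = stats.spearmanr(kinds["sse"], kinds["chi2F"]).statistic
        assert rho > 0.8


class TestMultistart:
    def test_start_from_truth_recovers_truth(self, downstream_objective,
                                             params):
        fits = multistart_fit(downstream_objective, 1, seed=3,
                              include_nominal=True, maxiter=20)
        best = fits[0]
        assert best.objective_value < 5e-4
        for name in downstream_objective.bounds.free:
            assert best.params[name] == pytest.approx(params[name], rel=0.2)

    def test_seeded_determinism(self, downstream_objective):
        a = multistart_fit(downstream_objective, 2, seed=11, maxiter=5)
        b = multistart_fit(downstream_objective, 2, seed=11, maxiter=5)
        assert [f.objective_value for f in a] == [f.objective_value for f in b]
        for fa, fb in zip(a, b):
            assert fa.params.values == fb.params.values

    def test_results_sorted_by_objective(self, downstream_objective):
        fits = multistart_fit(downstream_objective, 3, seed=5, maxiter=5)
        objs = [f.objective_value for f in fits]
        assert objs == sorted(objs)

    def test_zero_starts_rejected(self, downstream_objective):
        with pytest.raises(ValidationError):
            multistart_fit(downstream_objective, 0, seed=1)


class TestPvalueHistogram:
    @staticmethod
    def _result(p):
        report = ConsistencyReport(np.array([p]), 0.0, 2, p, 0.05, p < 0.05)
        return FitResult(None, 0.0, "sse", [report], 0, True)

    def test_all_top_bin(self):
        results = [self._result(1.0)] * 4
        frac = pvalue_histogram(results, [0, 0.5, 1.0001])
        assert frac[-1] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self):
        results = [self._result(p) for p in (0.001, 0.2, 0.6, 0.97)]
        frac = pvalue_histogram(results, [0, 0.01, 0.5, 1.0001])
        assert frac.sum() == pytest.approx(1.0)

    def test_empty_results_rejected(self):
        with pytest.raises(ValidationError):
            pvalue_histogram([], [0, 1])


class TestDriveFromData:
    def test_scaling_and_tail(self):
        data = EnsembleDataset.from_summary([0, 5, 10, 30],
                                            [0.05, 1.0, 0.33, 0.05],
                                            [0.1] * 4, [3] * 4, "ikk")
        drive = ikk_drive_from_data(data, scale_uM=0.03, tail_fraction=0.05)
        assert drive(5.0) == pytest.approx(0.03)
        assert drive(1000.0) == pytest.approx(0.05 * 0.03)
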