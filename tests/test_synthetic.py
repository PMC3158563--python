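import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nfkbmicro.model import ValidationError
from nfkbmicro.synthetic import (IKK_GRID, NFKB_GRID, EnsembleDataset,
                                 ExperimentTable, default_noise_sd,
                                 ensemble_average, generate_experiments,
                                 make_ensemble, normalize_experiment,
                                 reference_curve, reference_profiles,
                                 sample_null_ensembles)


def _table(times, values_by_replicate, eid="e1", assay="nfkb"):
    rows = []
    for r, vals in enumerate(values_by_replicate):
        rows.append(pd.DataFrame({"time": times, "replicate": r, "value": vals}))
    return ExperimentTable(pd.concat(rows, ignore_index=True), eid, assay)


class TestReferenceProfiles:
    def test_ikk_drop_to_a_third_by_ten_minutes(self):
        prof = reference_profiles("ikk")
        m = dict(zip(prof.times, prof.mean))
        assert m[10.0] / m[5.0] == pytest.approx(0.33, abs=1e-9)

    def test_nfkb_near_basal_at_five_minutes(self):
        prof = reference_profiles("nfkb")
        m = dict(zip(prof.times, prof.mean))
        assert m[5.0] <= 0.15

    def test_peaks_are_exactly_one_at_reference_times(self):
        for assay, t_ref in (("ikk", 5.0), ("nfkb", 20.0)):
            prof = reference_profiles(assay)
            m = dict(zip(prof.times, prof.mean))
            assert max(m.values()) == pytest.approx(1.0, abs=1e-9)
            assert m[t_ref] == pytest.approx(1.0, abs=1e-9)

    def test_replication_and_spread_conventions(self):
        ikk, nfkb = reference_profiles("ikk"), reference_profiles("nfkb")
        assert set(ikk.n) == {3} and set(nfkb.n) == {15}
        assert np.allclose(nfkb.sd, 0.1, atol=1e-9)

    def test_secondary_nfkb_peak_smaller_than_first(self):
        prof = reference_profiles("nfkb")
        m = dict(zip(prof.times, prof.mean))
        assert m[60.0] < m[90.0] < m[20.0]

    def test_provenance_tags_cover_grid(self):
        prof = reference_profiles("ikk")
        prov = prof.meta["provenance"]
        assert prov[10.0] == "stated" and prov[15.0] == "interpolated"

    def test_unknown_assay_rejected(self):
        with pytest.raises(ValidationError):
            reference_profiles("elisa")


class TestGenerator:
    def test_noiseless_limit_reproduces_truth(self):
        truth = reference_curve("ikk")
        tables = generate_experiments(truth, IKK_GRID, 3, 2, 0.0, seed=1,
                                      assay="ikk")
        for t in tables:
            for time, group in t.data.groupby("time"):
                assert np.allclose(group["value"], truth(time))

    def test_seed_reproducibility(self):
        truth = reference_curve("nfkb")
        a = generate_experiments(truth, NFKB_GRID, 5, 3,
                                 default_noise_sd(truth), seed=7)
        b = generate_experiments(truth, NFKB_GRID, 5, 3,
                                 default_noise_sd(truth), seed=7)
        for ta, tb in zip(a, b):
            pd.testing.assert_frame_equal(ta.data, tb.data)

    def test_pooled_mean_tracks_truth(self):
        """Central-limit check: the 5×3-replicate pooled mean stays within
        3·SD/√15 of the generating curve at (almost) every point."""
        truth = reference_curve("nfkb")
        mu = truth(NFKB_GRID)
        sd = default_noise_sd(truth)(NFKB_GRID)
        hits = misses = 0
        for seed in range(10):
            ens = make_ensemble(truth, NFKB_GRID, 5, 3,
                                default_noise_sd(truth), seed=seed,
                                normalize=False)
            ok = np.abs(ens.mean - mu) <= 3 * sd / np.sqrt(15)
            hits += int(ok.sum())
            misses += int((~ok).sum())
        assert misses <= 0.01 * (hits + misses) + 2

    def test_negative_noise_rejected(self):
        truth = reference_curve("ikk")
        with pytest.raises(ValidationError):
            generate_experiments(truth, IKK_GRID, 1, 2, lambda t: -np.ones_like(t),
                                 seed=1)

    def test_values_truncated_at_zero(self):
        truth = lambda t: np.full_like(np.asarray(t, dtype=float), 0.01)
        tables = generate_experiments(truth, IKK_GRID, 5, 3, 0.5, seed=3)
        assert all((t.data["value"] >= 0).all() for t in tables)


class TestNormalization:
    def test_means_divided_by_max_mean(self):
        t = _table([0, 10, 20], [[2, 8, 4], [2, 8, 4]])
        out = normalize_experiment(t)
        assert np.allclose(out.per_time_means().to_numpy(), [0.25, 1.0, 0.5])

    def test_idempotent(self):
        t = _table([0, 10, 20], [[0.2, 1.0, 0.5]])
        once = normalize_experiment(t)
        twice = normalize_experiment(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    @given(c=st.floats(1e-3, 1e3))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, c):
        """The property the step exists to enforce: per-experiment
        multiplicative gains vanish."""
        base = _table([0, 10, 20], [[1.0, 4.0, 2.0], [1.2, 3.8, 2.2]])
        scaled = _table([0, 10, 20], [[c, 4 * c, 2 * c], [1.2 * c, 3.8 * c, 2.2 * c]])
        a = normalize_experiment(base).data["value"].to_numpy()
        b = normalize_experiment(scaled).data["value"].to_numpy()
        assert np.allclose(a, b, rtol=1e-9)

    def test_all_zero_experiment_rejected(self):
        with pytest.raises(ValidationError):
            normalize_experiment(_table([0, 10], [[0.0, 0.0]]))


class TestEnsembleAverage:
    def test_hand_arithmetic(self):
        t = _table([0.0], [[0.9], [1.0], [1.1]])
        ens = ensemble_average([t])
        assert ens.mean[0] == pytest.approx(1.0)
        assert ens.sd[0] == pytest.approx(0.1)
        assert ens.n[0] == 3

    def test_single_replicate_rejected(self):
        with pytest.raises(ValidationError, match="n ≥ 2"):
            ensemble_average([_table([0.0, 5.0], [[1.0, 2.0]])])

    def test_identical_experiments_have_zero_sd(self):
        t1 = _table([0, 5], [[1.0, 2.0]], eid="a")
        t2 = _table([0, 5], [[1.0, 2.0]], eid="b")
        ens = ensemble_average([t1, t2])
        assert np.allclose(ens.sd, 0.0)

    def test_grid_mismatch_rejected(self):
        t1 = _table([0, 5], [[1.0, 2.0], [1.0, 2.0]])
        t2 = _table([0, 10], [[1.0, 2.0], [1.0, 2.0]], eid="e2")
        with pytest.raises(ValidationError, match="grid"):
            ensemble_average([t1, t2])

    def test_noiseless_round_trip_recovers_truth(self):
        truth = reference_curve("ikk")
        ens = make_ensemble(truth, IKK_GRID, 3, 2, 0.0, seed=1, assay="ikk")
        assert np.allclose(ens.mean, truth(IKK_GRID) / truth(IKK_GRID).max())


class TestNullSampler:
    def test_matches_generator_distribution(self):
        """The vectorized calibration sampler agrees with the table-based
        generator pipeline in mean and spread."""
        truth = reference_curve("nfkb")
        mu = truth(NFKB_GRID)
        sd = default_noise_sd(truth)(NFKB_GRID)
        fast = sample_null_ensembles(mu, sd, 5, 3, n_datasets=400, seed=11,
                                     grid=NFKB_GRID)
        fast_means = np.array([d.mean for d in fast])
        slow_means = np.array([
            make_ensemble(truth, NFKB_GRID, 5, 3, default_noise_sd(truth),
                          seed=500 + k, normalize=False).mean
            for k in range(100)])
        assert np.allclose(fast_means.mean(0), slow_means.mean(0), atol=0.02)
        assert np.allclose(fast_means.std(0), slow_means.std(0), atol=0.02)

    def test_summary_only_dataset_round_trip(self):
        ens = EnsembleDataset.from_summary([0.0, 5.0], [1.0, 0.5], [0.1, 0.2],
                                           [3, 3], assay="ikk")
        assert ens.samples is None
        assert np.allclose(ens.mean, [1.0, 0.5])
        assert np.allclose(ens.n, [3, 3])
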