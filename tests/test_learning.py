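import numpy as np
import pytest
from scipy.stats import pearsonr

from movemetric import (CVPlan, WeightVector, baseline_correlations,
                        baseline_grid, compute_pair_deltas, cross_validate,
                        fit_weights, score_pairs, sweep_segments)
from movemetric.io import FeatureSet, standardise
from movemetric.learning import DegenerateTargetError
from movemetric import make_dataset

from conftest import small_config


@pytest.fixture(scope="module")
def small_dataset_module():
    return make_dataset(small_config(seed=7))


@pytest.fixture(scope="module")
def deltas(small_dataset_module):
    ds, truth = small_dataset_module
    return compute_pair_deltas(ds)


class TestFitWeights:
    def test_exactly_linear_ratings_fit_perfectly(self, rng):
        d = rng.normal(size=(60, 5))
        w0 = np.ones(5)
        ratings = np.clip(0.02 * (d @ w0) + 0.1, -1, 1)
        res = fit_weights(d, ratings, "feature")
        assert res.train_corr >= 0.999
        assert res.converged
        np.testing.assert_allclose(res.weights.values, w0, atol=5e-2)

    def test_constraints_hold_to_tolerance(self, deltas):
        res = fit_weights(deltas.channel_deltas, deltas.ratings, "feature")
        assert abs(res.weights.values.mean() - 1) < 1e-6
        assert (res.weights.values > 0).all()
        seg = fit_weights(deltas.segment_deltas(8), deltas.ratings, "segment")
        assert abs(seg.weights.values.sum() - 1) < 1e-6

    def test_recovers_planted_weights_better_than_chance(
            self, small_dataset_module, deltas):
        _, truth = small_dataset_module
        res = fit_weights(deltas.channel_deltas, deltas.ratings, "feature")
        r = pearsonr(res.weights.values,
                     np.array(truth.feature_weights))[0]
        assert r > 0.3

    def test_loss_trace_non_increasing(self, deltas):
        res = fit_weights(deltas.channel_deltas, deltas.ratings, "feature")
        diffs = np.diff(res.loss_trace)
        assert (diffs <= 1e-9).all()

    def test_degenerate_targets_raise(self, rng):
        d = rng.normal(size=(10, 3))
        with pytest.raises(DegenerateTargetError):
            fit_weights(d, np.zeros(10), "feature")
        with pytest.raises(DegenerateTargetError):
            fit_weights(d[:1], np.array([0.5]), "feature")


class TestScorePairs:
    def test_identity_swap_and_uniform_reduction(self, small_dataset_module):
        ds, _ = small_dataset_module
        rec = ds.ratings[0]
        a, b = ds.pair_series(rec.pair_id)
        t = ds.template
        (same,) = score_pairs(t, [(a, a, rec)])
        assert same.delta == pytest.approx(0, abs=1e-12)
        (fwd,) = score_pairs(t, [(a, b, rec)])
        (rev,) = score_pairs(t, [(b, a, rec)])
        assert fwd.delta == pytest.approx(-rev.delta, abs=1e-9)
        w = WeightVector.uniform(t.n_channels, "feature")
        (feat,) = score_pairs(t, [(a, b, rec)], w=w, mode="feature")
        assert feat.delta == pytest.approx(fwd.delta, abs=1e-9)


class TestCrossValidation:
    def test_plan_structure_and_determinism(self):
        parts = [f"P{i:02d}" for i in range(1, 13)]
        plan = CVPlan(participants=parts, seed=3)
        folds = list(plan.folds())
        assert len(folds) == 16
        for _, _, train, test in folds:
            assert len(train) == 6 and len(test) == 6
            assert set(train) | set(test) == set(parts)
            assert not set(train) & set(test)
        plan2 = CVPlan(participants=parts, seed=3)
        assert plan.assignments == plan2.assignments

    def test_sixteen_fold_results_without_leakage(
            self, small_dataset_module, deltas):
        ds, _ = small_dataset_module
        plan = CVPlan(participants=ds.participants, seed=0)
        results = cross_validate(ds, "feature", plan, pair_deltas=deltas)
        assert len(results) == 16
        for res, (_, _, train, test) in zip(results, plan.folds()):
            tr = deltas.rows_for(train)
            te = deltas.rows_for(test)
            assert not (tr & te).any()
            assert (tr | te).all()

    def test_optimised_train_beats_uniform_baseline(
            self, small_dataset_module, deltas):
        ds, _ = small_dataset_module
        plan = CVPlan(participants=ds.participants, seed=0)
        base = baseline_correlations(deltas, plan)
        results = cross_validate(ds, "feature", plan, pair_deltas=deltas)
        for res, b in zip(results, base[:, 0]):
            if res.valid:
                assert res.train_corr >= b - 1e-3

    def test_rerun_is_deterministic(self, small_dataset_module, deltas):
        ds, _ = small_dataset_module
        plan = CVPlan(participants=ds.participants, seed=5)
        r1 = cross_validate(ds, "feature", plan, pair_deltas=deltas)
        r2 = cross_validate(ds, "feature", plan, pair_deltas=deltas)
        np.testing.assert_array_equal(
            [r.test_corr for r in r1], [r.test_corr for r in r2])


class TestSweepSegments:
    def test_single_segment_equals_baseline(self, small_dataset_module,
                                            deltas):
        ds, _ = small_dataset_module
        plan = CVPlan(participants=ds.participants, seed=0)
        tab = sweep_segments(ds, plan, n_list=(1,), pair_deltas=deltas)
        base = baseline_correlations(deltas, plan)
        assert tab.test_mean[0] == pytest.approx(np.nanmean(base[:, 1]),
                                                 abs=1e-9)

    def test_sweep_covers_requested_grid(self, small_dataset_module, deltas):
        ds, _ = small_dataset_module
        plan = CVPlan(participants=ds.participants, seed=0)
        tab = sweep_segments(ds, plan, n_list=(2, 5, 10), pair_deltas=deltas)
        assert list(tab.n_segments) == [2, 5, 10]
        assert tab.notna().all().all()

    def test_segment_count_above_template_length_raises(
            self, small_dataset_module, deltas):
        ds, _ = small_dataset_module
        plan = CVPlan(participants=ds.participants, seed=0)
        with pytest.raises(ValueError):
            sweep_segments(ds, plan, n_list=(ds.template.n_samples + 1,),
                           pair_deltas=deltas)


class TestBaselineGrid:
    def test_grid_rows_and_determinism(self, small_dataset_module):
        ds, _ = small_dataset_module
        plan = CVPlan(participants=ds.participants, seed=0)
        combos = (FeatureSet(("p0",)), FeatureSet(("p0",)),
                  FeatureSet(("acc", "gyr", "p0", "p1", "p2")))
        tab = baseline_grid(ds, plan, combos=combos)
        assert len(tab) == 3
        assert tab.test_mean[0] == pytest.approx(tab.test_mean[1], abs=1e-12)

    def test_all_channels_beat_position_only(self):
        # ratings depend on every channel group, so the full feature set
        # should correlate at least as well as position alone
        ds, _ = make_dataset(small_config(seed=11))
        plan = CVPlan(participants=ds.participants, seed=0)
        combos = (FeatureSet(("p0",)),
                  FeatureSet(("acc", "gyr", "p0", "p1", "p2")))
        tab = baseline_grid(ds, plan, combos=combos)
        assert tab.test_mean[1] >= tab.test_mean[0]


class TestScaleInvariance:
    def test_global_channel_scaling_leaves_correlations_unchanged(
            self, small_dataset_module):
        from dataclasses import replace as drep
        from movemetric.learning import MovementDataset

        ds, _ = small_dataset_module
        scaled_movs = {k: drep(m, samples=m.samples * 3.7)
                       for k, m in ds.movements.items()}
        scaled = MovementDataset(
            template=drep(ds.template, samples=ds.template.samples * 3.7),
            movements=scaled_movs, ratings=ds.ratings, pairs=ds.pairs)
        # re-standardise both; pooled z-scoring removes the common factor
        g1, _ = standardise([ds.template] + list(ds.movements.values()))
        g2, _ = standardise([scaled.template] + list(scaled_movs.values()))
        for a, b in zip(g1, g2):
            np.testing.assert_allclose(a.samples, b.samples, atol=1e-10)
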