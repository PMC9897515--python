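import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from movemetric import (AlignmentPath, MovementSeries, WeightVector, dtw,
                        dtw_feature, dtw_segment, per_channel_errors,
                        per_segment_errors, segment_path)
from movemetric.dtw import dtw_arrays

from oracles import dtw_dp_oracle


def series(arr, channels=None):
    arr = np.atleast_2d(np.asarray(arr, float).T).T
    channels = channels or tuple(f"p0_{a}" for a in "xyz"[: arr.shape[1]])
    return MovementSeries(arr, channels)


class TestBaselineDtw:
    def test_self_distance_zero_diagonal_path(self, rng):
        x = series(rng.normal(size=(20, 3)))
        d, path = dtw(x, x)
        assert d == pytest.approx(0, abs=1e-12)
        np.testing.assert_array_equal(path.steps[:, 0], path.steps[:, 1])

    def test_tiny_example_matches_oracle(self):
        d, steps = dtw_arrays(np.array([0., 2., 4.]), np.array([1., 3.]),
                              radius=100)
        d_or, p_or = dtw_dp_oracle([0., 2., 4.], [1., 3.])
        assert d == pytest.approx(3.0) and d_or == pytest.approx(3.0)
        assert [tuple(s) for s in steps] == p_or

    def test_exact_mode_equals_dp_oracle(self, rng):
        x = rng.normal(size=(30, 3))
        y = rng.normal(size=(40, 3))
        d, steps = dtw_arrays(x, y, radius=100)
        d_or, p_or = dtw_dp_oracle(x, y)
        assert d == pytest.approx(d_or, abs=1e-12)
        assert [tuple(s) for s in steps] == p_or

    def test_symmetry_and_nonnegativity(self, rng):
        x = rng.normal(size=(25, 2))
        y = rng.normal(size=(31, 2))
        dxy, _ = dtw_arrays(x, y, radius=50)
        dyx, _ = dtw_arrays(y, x, radius=50)
        assert dxy == pytest.approx(dyx, abs=1e-9)
        assert dxy >= 0

    def test_approximation_never_undercuts_exact(self, rng):
        for _ in range(10):
            n, m = rng.integers(40, 120, size=2)
            x = rng.normal(size=(int(n), 3))
            y = rng.normal(size=(int(m), 3))
            exact, _ = dtw_arrays(x, y, radius=max(int(n), int(m)))
            approx, _ = dtw_arrays(x, y, radius=10)
            assert approx >= exact - 1e-9

    def test_channel_mismatch_and_short_series_errors(self, rng):
        a = series(rng.normal(size=(10, 3)))
        b = MovementSeries(rng.normal(size=(10, 3)),
                           ("acc_x", "acc_y", "acc_z"))
        with pytest.raises(ValueError, match="mismatch"):
            dtw(a, b)
        with pytest.raises(ValueError, match="2 samples"):
            dtw_arrays(np.ones((1, 2)), np.ones((5, 2)))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(5, 40),
           st.integers(5, 40), st.integers(2, 30))
    def test_path_invariants_property(self, seed, n, m, radius):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, 2))
        y = rng.normal(size=(m, 2))
        d, steps = dtw_arrays(x, y, radius=radius)
        path = AlignmentPath(steps, n, m)  # validates invariants
        assert len(path) >= max(n, m)
        exact, _ = dtw_arrays(x, y, radius=max(n, m))
        assert d >= exact - 1e-9


class TestFeatureWeighting:
    @pytest.mark.parametrize("policy", ["realign", "reuse-baseline-path"])
    def test_uniform_weights_reduce_to_baseline(self, rng, policy):
        t = series(rng.normal(size=(30, 3)))
        a = series(rng.normal(size=(35, 3)))
        w = WeightVector.uniform(3, "feature")
        d0, _ = dtw(t, a, radius=50)
        assert dtw_feature(t, a, w, path_policy=policy, radius=50) \
            == pytest.approx(d0, abs=1e-9)

    def test_uniform_scaling_preserves_path(self, rng):
        t = series(rng.normal(size=(20, 1)), ("p0_x",))
        a = series(rng.normal(size=(25, 1)), ("p0_x",))
        d0, p0 = dtw(t, a, radius=50)
        w = WeightVector(np.array([2.5]), "feature")
        d = dtw_feature(t, a, w, radius=50, check_weights=False)
        assert d == pytest.approx(2.5 * d0, rel=1e-12)
        _, p1 = dtw_arrays(t.samples, a.samples, radius=50,
                           weights=np.array([2.5]))
        np.testing.assert_array_equal(p0.steps, p1)

    def test_linearity_in_weights_on_fixed_path(self, rng):
        t = series(rng.normal(size=(30, 3)))
        a = series(rng.normal(size=(28, 3)))
        w = WeightVector(np.array([0.5, 1.0, 1.5]), "feature")
        d1 = dtw_feature(t, a, w, path_policy="reuse-baseline-path",
                         check_weights=False)
        w2 = WeightVector(2 * w.values, "feature")
        d2 = dtw_feature(t, a, w2, path_policy="reuse-baseline-path",
                         check_weights=False)
        assert d2 == pytest.approx(2 * d1, rel=1e-12)

    def test_constraint_violations_raise(self, rng):
        t = series(rng.normal(size=(10, 3)))
        a = series(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError, match="positive"):
            dtw_feature(t, a, WeightVector(np.array([1., -1., 3.]), "feature"))
        with pytest.raises(ValueError, match="mean"):
            dtw_feature(t, a, WeightVector(np.array([2., 2., 2.]), "feature"))
        with pytest.raises(ValueError):
            dtw_feature(t, a, WeightVector.uniform(4, "feature"))


class TestSegmentation:
    def test_equal_division(self, rng):
        x = rng.normal(size=(100, 2))
        y = rng.normal(size=(100, 2))
        _, steps = dtw_arrays(x, y, radius=100)
        seg = segment_path(AlignmentPath(steps, 100, 100), 25)
        sizes = np.diff(seg.boundaries)
        assert len(sizes) == 25 and (sizes == 4).all()

    def test_remainder_to_earliest_blocks(self, rng):
        x = rng.normal(size=(10, 1))
        y = rng.normal(size=(12, 1))
        _, steps = dtw_arrays(x, y, radius=20)
        seg = segment_path(AlignmentPath(steps, 10, 12), 3)
        assert list(np.diff(seg.boundaries)) == [4, 3, 3]

    @pytest.mark.parametrize("n_seg", [1, 2, 3, 7, 19])
    def test_segments_partition_path(self, rng, n_seg):
        x = rng.normal(size=(37, 2))
        y = rng.normal(size=(45, 2))
        _, steps = dtw_arrays(x, y, radius=50)
        path = AlignmentPath(steps, 37, 45)
        seg = segment_path(path, n_seg)
        total = sum(s.stop - s.start for s in seg.step_slices)
        assert total == len(path)
        covered = np.concatenate(
            [path.steps[s] for s in seg.step_slices])
        np.testing.assert_array_equal(covered, path.steps)

    def test_out_of_range_segments(self, rng):
        x = rng.normal(size=(10, 1))
        _, steps = dtw_arrays(x, x, radius=20)
        with pytest.raises(ValueError):
            segment_path(AlignmentPath(steps, 10, 10), 11)


class TestSegmentWeighting:
    def test_uniform_weights_give_distance_over_n(self, rng):
        t = series(rng.normal(size=(40, 3)))
        a = series(rng.normal(size=(44, 3)))
        d0, _ = dtw(t, a, radius=50)
        for n in (1, 4, 10):
            w = WeightVector.uniform(n, "segment")
            assert dtw_segment(t, a, w, radius=50) \
                == pytest.approx(d0 / n, rel=1e-9)

    def test_concentrated_weight_selects_segment(self, rng):
        t = series(rng.normal(size=(30, 2)))
        a = series(rng.normal(size=(33, 2)))
        _, path = dtw(t, a, radius=50)
        contrib = per_segment_errors(t, a, path, 5)
        w = np.full(5, 1e-9)
        w[2] = 1.0
        d = dtw_segment(t, a, WeightVector(w, "segment"), radius=50,
                        check_weights=False)
        assert d == pytest.approx(contrib[2], rel=1e-6)

    def test_contributions_conserve_total_distance(self, rng):
        for _ in range(5):
            t = series(rng.normal(size=(50, 3)))
            a = series(rng.normal(size=(60, 3)))
            d0, path = dtw(t, a, radius=60)
            for n in (1, 7, 25):
                assert per_segment_errors(t, a, path, n).sum() \
                    == pytest.approx(d0, abs=1e-9)
            assert per_channel_errors(t, a, path).sum() \
                == pytest.approx(d0, abs=1e-9)


class TestWeightVector:
    def test_uniform_constructors(self):
        wf = WeightVector.uniform(5, "feature")
        ws = WeightVector.uniform(5, "segment")
        assert wf.values.mean() == pytest.approx(1)
        assert ws.values.sum() == pytest.approx(1)
        wf.validate()
        ws.validate()

    def test_normalised(self):
        w = WeightVector(np.array([1., 2., 3.]), "feature").normalised()
        assert w.values.mean() == pytest.approx(1)

    def test_alignment_path_invariant_violations(self):
        with pytest.raises(ValueError):
            AlignmentPath(np.array([[1, 0], [2, 1]]), 3, 2)  # bad start
        with pytest.raises(ValueError):
            AlignmentPath(np.array([[0, 0], [2, 1]]), 3, 2)  # jump of 2
        with pytest.raises(ValueError):
            AlignmentPath(np.array([[0, 0], [1, 1]]), 3, 2)  # bad end
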