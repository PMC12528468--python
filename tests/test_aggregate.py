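"""Binned aggregation and slide-level forest regression."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from survbira.aggregate import (
    aggregate_patient,
    binned_features,
    choose_global_bin_count,
    fd_bin_count,
    fit_slide_regressor,
    predict_slide_survival,
)


def fd_oracle(values):
    """Independent direct evaluation of the Freedman-Diaconis count.

    Quartiles by explicit linear interpolation between order statistics.
    """
    v = sorted(float(x) for x in values)
    n = len(v)

    def quantile(q):
        pos = q * (n - 1)
        lo = int(math.floor(pos))
        hi = min(lo + 1, n - 1)
        return v[lo] + (pos - lo) * (v[hi] - v[lo])

    iqr = quantile(0.75) - quantile(0.25)
    if iqr == 0 or v[-1] == v[0]:
        return 1
    m = n ** (1 / 3) * (v[-1] - v[0]) / (2 * iqr)
    return max(1, int(math.floor(m + 0.5)))


class TestFdBinCount:
    @pytest.mark.parametrize(
        "values,expected",
        [
            (list(range(8)), 2),    # 8^(1/3)=2, range 7, IQR 3.5 -> 2
            (list(range(27)), 3),   # 3 * 26 / 26 -> 3
            ([5.0, 5.0, 5.0], 1),   # degenerate IQR
            ([1.0], 1),
        ],
    )
    def test_hand_derived_cases(self, values, expected):
        assert fd_bin_count(values) == expected

    def test_matches_independent_oracle_on_random_arrays(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 501))
            scale = 10.0 ** rng.integers(-2, 4)
            values = rng.normal(0, scale, size=n)
            assert fd_bin_count(values) == fd_oracle(values)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fd_bin_count([])


class TestBinnedFeatures:
    def test_two_bin_hand_case(self):
        feat = binned_features([1, 2, 3, 4], 2)
        assert np.allclose(feat.values, [1.5, 3.5])
        assert np.allclose(feat.bin_edges, [1, 2.5, 4])

    def test_degenerate_range_repeats_value(self):
        feat = binned_features([5, 5, 5], 4)
        assert np.allclose(feat.values, 5.0)

    def test_one_value_per_bin(self):
        assert np.allclose(binned_features([0, 10], 2).values, [0, 10])

    def test_empty_bin_filled_with_overall_mean(self):
        # values 0, 1, 10 with 3 bins: middle bin empty
        feat = binned_features([0, 1, 10], 3)
        assert feat.values[1] == pytest.approx(11 / 3)

    @settings(deadline=None, max_examples=50)
    @given(
        values=st.lists(
            st.floats(-1e3, 1e3, allow_nan=False), min_size=1, max_size=40
        ),
        m=st.integers(1, 8),
        seed=st.integers(0, 100),
    )
    def test_permutation_invariant(self, values, m, seed):
        rng = np.random.default_rng(seed)
        shuffled = list(rng.permutation(values))
        a = binned_features(values, m).values
        b = binned_features(shuffled, m).values
        assert np.allclose(a, b, equal_nan=True)

    def test_mass_conservation_when_no_bin_empty(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 1, 200)
        m = 5
        feat = binned_features(values, m)
        edges = feat.bin_edges
        counts = np.histogram(values, bins=edges)[0]
        assert counts.min() > 0  # precondition of the property
        assert np.dot(counts, feat.values) == pytest.approx(values.sum())

    def test_nonempty_bin_values_within_range(self):
        rng = np.random.default_rng(2)
        values = rng.normal(0, 1, 50)
        feat = binned_features(values, 4)
        assert feat.values.min() >= values.min()
        assert feat.values.max() <= values.max()

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            binned_features([1, 2], 0)


class TestGlobalBinCount:
    def test_median_rule(self):
        slides = [list(range(8)), list(range(27)), list(np.arange(500))]
        ms = [fd_bin_count(s) for s in slides]
        assert choose_global_bin_count(slides) == max(
            2, math.ceil(np.median(ms)))

    def test_clamped_to_two(self):
        assert choose_global_bin_count([[5.0, 5.0]]) == 2

    def test_identical_slides(self):
        slides = [list(range(27))] * 3
        assert choose_global_bin_count(slides) == 3


def toy_features(X, ids=None):
    from survbira.aggregate import SlideFeatureVector

    ids = ids or [f"S{i}" for i in range(len(X))]
    return [
        SlideFeatureVector(
            slide_id=sid, m=len(row), values=np.asarray(row, float),
            bin_edges=np.arange(len(row) + 1, dtype=float),
        )
        for sid, row in zip(ids, X)
    ]


class TestSlideRegressor:
    def test_constant_times_predict_constant(self):
        feats = toy_features(np.random.default_rng(0).random((6, 3)))
        model = fit_slide_regressor(feats, [500.0] * 6, seed=0)
        for f in feats:
            assert predict_slide_survival(model, f).predicted_days == 500.0

    def test_predictions_within_training_range(self):
        rng = np.random.default_rng(1)
        feats = toy_features(rng.random((10, 3)))
        times = list(rng.uniform(100, 900, 10))
        model = fit_slide_regressor(feats, times, seed=0)
        probes = toy_features(rng.uniform(-5, 5, (20, 3)))
        for f in probes:
            pred = predict_slide_survival(model, f).predicted_days
            assert min(times) <= pred <= max(times)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        feats = toy_features(rng.random((8, 4)))
        times = list(rng.uniform(100, 900, 8))
        probes = toy_features(rng.random((5, 4)))
        preds = []
        for _ in range(2):
            model = fit_slide_regressor(feats, times, seed=7)
            preds.append(
                [predict_slide_survival(model, f).predicted_days for f in probes]
            )
        assert preds[0] == preds[1]

    def test_stump_forest_predicts_central_training_time(self):
        # A forest constrained to a single leaf predicts the central value
        # of the training times; with a symmetric set mean and median agree.
        feats = toy_features(np.random.default_rng(3).random((3, 2)))
        times = [300.0, 400.0, 500.0]
        model = fit_slide_regressor(
            feats, times, n_trees=1, seed=0, bootstrap=False,
            min_samples_split=100,
        )
        pred = predict_slide_survival(model, feats[0]).predicted_days
        assert pred == pytest.approx(np.mean(times))

    def test_single_tree_memorizes_training_slides(self):
        # 1 tree, no bootstrap, unlimited depth, distinct features:
        # each training slide gets back its own survival time.
        rng = np.random.default_rng(4)
        feats = toy_features(rng.random((5, 3)))
        times = [200.0, 350.0, 500.0, 650.0, 800.0]
        model = fit_slide_regressor(
            feats, times, n_trees=1, seed=0, bootstrap=False)
        for f, t in zip(feats, times):
            assert predict_slide_survival(model, f).predicted_days == t

    def test_length_mismatch_rejected(self):
        feats = toy_features(np.random.default_rng(5).random((4, 3)))
        with pytest.raises(ValueError):
            fit_slide_regressor(feats, [100.0, 200.0], seed=0)
        model = fit_slide_regressor(feats, [1.0, 2.0, 3.0, 4.0], seed=0)
        probe = toy_features(np.zeros((1, 5)))[0]
        with pytest.raises(ValueError):
            predict_slide_survival(model, probe)


class TestAggregatePatient:
    def test_single_slide_identity(self):
        assert aggregate_patient([400.0]).predicted_days == 400.0

    def test_mean_of_two(self):
        assert aggregate_patient([300.0, 500.0]).predicted_days == 400.0

    def test_permutation_invariant(self):
        vals = [100.0, 250.0, 700.0]
        assert (
            aggregate_patient(vals).predicted_days
            == aggregate_patient(vals[::-1]).predicted_days
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_patient([])
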