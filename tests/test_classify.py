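import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from migsfis import (
    ClassCounts,
    ConfusionMatrix,
    class_counts,
    confusion,
    decision_surfaces,
    mean_class_acc,
    metrics,
    metrics_table,
    pearson_significance,
    round_to_class,
)


class TestRoundToClass:
    @pytest.mark.parametrize(
        "y,expected",
        [
            (1.5, 2), (2.4, 2),      # the documented band [1.5, 2.5) -> 2
            (3.0, 3),                # integer fixed point
            (5.7, 4), (0.2, 1),      # clamped to the code range
            (2.5, 3),                # half-up at the boundary
        ],
    )
    def test_rounding_examples(self, y, expected):
        assert round_to_class(y, 4) == expected

    def test_monotone_nondecreasing(self):
        ys = np.linspace(-1, 6, 500)
        classes = round_to_class(ys, 4)
        assert np.all(np.diff(classes) >= 0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            round_to_class(float("nan"), 4)


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        t = [1, 2, 2, 3, 4, 4, 4]
        m = confusion(t, t, 4)
        assert np.all(m.counts == np.diag([1, 2, 1, 3]))

    def test_single_mismatch_lands_at_true_pred_cell(self):
        m = confusion([2], [3], 4)
        assert m.counts[1, 2] == 1 and m.total == 1

    def test_matches_hand_tally_on_labeled_fixture(self):
        true_ = [1, 1, 2, 2, 2, 3, 3, 4, 4, 4, 4, 1]
        pred = [1, 2, 2, 2, 3, 3, 3, 4, 4, 1, 4, 1]
        m = confusion(true_, pred, 4)
        expected = np.zeros((4, 4), dtype=int)
        for t, p in zip(true_, pred):
            expected[t - 1, p - 1] += 1
        assert np.array_equal(m.counts, expected)

    def test_out_of_range_code_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 5], [1, 1], 4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 2], [1], 4)


class TestClassCounts:
    def test_worked_example_class3_counts(self):
        # 4-class matrix whose class-3 one-vs-rest counts are the published
        # worked example: tp=11, fp=6, fn=3, total 112 => tn=92
        counts = np.array(
            [
                [30, 1, 2, 1],
                [1, 25, 2, 0],
                [1, 1, 11, 1],
                [2, 1, 2, 31],
            ]
        )
        m = ConfusionMatrix(counts=counts)
        assert m.total == 112
        c = class_counts(m, 3)
        assert (c.tp, c.tn, c.fp, c.fn) == (11, 92, 6, 3)

    def test_diagonal_matrix_has_no_errors(self):
        m = ConfusionMatrix(counts=np.diag([5, 3, 2, 7]))
        for k in range(1, 5):
            c = class_counts(m, k)
            assert c.fp == 0 and c.fn == 0

    def test_counts_partition_total_for_every_class(self, rng):
        m = ConfusionMatrix(counts=rng.integers(0, 20, size=(4, 4)))
        for k in range(1, 5):
            assert class_counts(m, k).total == m.total


class TestMetrics:
    def test_worked_example_metric_values(self):
        got = metrics(ClassCounts(tp=11, tn=92, fp=6, fn=3))
        expected = dict(
            tpr=0.7857, tnr=0.9388, ppv=0.6471, npv=0.9684,
            fpr=0.0612, fnr=0.2143, fdr=0.3529, acc=0.9196,
        )
        for name, val in expected.items():
            assert round(getattr(got, name), 4) == val

    def test_empty_class_yields_nan_convention(self):
        got = metrics(ClassCounts(tp=0, tn=50, fp=0, fn=0))
        assert np.isnan(got.tpr) and np.isnan(got.fnr)
        assert got.tnr == 1.0 and got.acc == 1.0

    @given(
        st.tuples(
            st.integers(0, 100), st.integers(0, 100),
            st.integers(0, 100), st.integers(0, 100),
        )
    )
    @settings(max_examples=200, derandomize=True)
    def test_complementarity_identities(self, counts):
        tp, tn, fp, fn = counts
        got = metrics(ClassCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        if tp + fn:
            assert got.tpr + got.fnr == pytest.approx(1.0)
        else:
            assert np.isnan(got.tpr) and np.isnan(got.fnr)
        if tn + fp:
            assert got.tnr + got.fpr == pytest.approx(1.0)
        if tp + fp:
            assert got.ppv + got.fdr == pytest.approx(1.0)

    def test_table_shape_and_diagonal_accuracy(self):
        m = ConfusionMatrix(counts=np.diag([5, 3, 2, 7]))
        table = metrics_table(m)
        assert table.shape == (4, 8)
        assert np.all(table["acc"] == 1.0)
        assert mean_class_acc(m) == 1.0

    def test_trace_and_marginal_identities(self, rng):
        m = ConfusionMatrix(counts=rng.integers(0, 30, size=(4, 4)))
        tps = [class_counts(m, k).tp for k in range(1, 5)]
        assert sum(tps) == np.trace(m.counts)
        assert sum(class_counts(m, k).tp + class_counts(m, k).fn for k in range(1, 5)) == m.total
        assert sum(class_counts(m, k).tp + class_counts(m, k).fp for k in range(1, 5)) == m.total


class TestPearsonSignificance:
    def test_perfect_correlation(self):
        r, p = pearson_significance([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert r == pytest.approx(1.0)
        assert p < 1e-8

    def test_perfect_anticorrelation(self):
        r, _ = pearson_significance([1, 2, 3, 4], [4, 3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_p_value_matches_permutation_oracle(self, rng):
        x = rng.normal(size=20)
        y = 0.6 * x + rng.normal(scale=0.8, size=20)
        r_obs, p = pearson_significance(x, y)
        n_perm = 100_000
        perms = np.array([rng.permutation(y) for _ in range(n_perm)])
        xc = (x - x.mean()) / x.std()
        pc = (perms - perms.mean(axis=1, keepdims=True)) / perms.std(axis=1, keepdims=True)
        r_perm = (pc @ xc) / 20
        p_mc = (np.abs(r_perm) >= abs(r_obs) - 1e-12).mean()
        mc_err = 3 * np.sqrt(p_mc * (1 - p_mc) / n_perm) + 1e-4
        assert p == pytest.approx(p_mc, abs=max(5 * mc_err, 0.005))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_significance([1, 1, 1, 1], [1, 2, 3, 4])


class TestDecisionSurfaces:
    def test_fifteen_pairwise_surfaces(self, two_rule_model, rng):
        X = rng.uniform(-1, 1, size=(30, 6))
        surf = decision_surfaces(two_rule_model, X, grid_size=5)
        assert len(surf) == 15

    def test_grid_shape_contract(self, two_rule_model, rng):
        X = rng.uniform(-1, 1, size=(20, 6))
        surf = decision_surfaces(two_rule_model, X, grid_size=7)
        for grid in surf.values():
            assert grid["z"].shape == (7, 7)

    def test_constant_model_gives_flat_surfaces(self, rng):
        from migsfis import FISModel

        model = FISModel(
            centers=np.zeros((1, 6)),
            sigmas=np.full((1, 6), 0.5),
            consequents=np.array([[0, 0, 0, 0, 0, 0, 2.0]]),
        )
        X = rng.uniform(-1, 1, size=(10, 6))
        for grid in decision_surfaces(model, X, grid_size=4).values():
            np.testing.assert_allclose(grid["z"], 2.0)
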