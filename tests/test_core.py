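"""CPM building blocks against brute-force and closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cpmkit import core


def brute_force_edge_stats(X, y):
    """Independent per-column Pearson r and p (scipy, one column at a time)."""
    out_r, out_p = [], []
    for col in X.T:
        res = stats.pearsonr(col, y)
        out_r.append(res.statistic)
        out_p.append(res.pvalue)
    return np.array(out_r), np.array(out_p)


class TestPearsonColumns:
    def test_matches_brute_force(self, toy_edges):
        X, y = toy_edges
        r, p = core.pearson_columns(X, y)
        br, bp = brute_force_edge_stats(X, y)
        assert np.allclose(r, br, atol=1e-12)
        assert np.allclose(p, bp, atol=1e-12)

    def test_edge_identical_to_outcome(self, toy_edges):
        X, y = toy_edges
        X = X.copy()
        X[:, 2] = y
        r, p = core.pearson_columns(X, y)
        assert r[2] == pytest.approx(1.0)
        assert p[2] < 1e-30

    def test_constant_edge_flagged(self, toy_edges, caplog):
        X, y = toy_edges
        X = X.copy()
        X[:, 0] = 4.2
        with caplog.at_level("WARNING"):
            r, p = core.pearson_columns(X, y)
        assert r[0] == 0.0 and p[0] == 1.0
        assert "constant edge" in caplog.text

    def test_constant_outcome_is_error(self, toy_edges):
        X, _ = toy_edges
        with pytest.raises(core.DegenerateDataError, match="constant"):
            core.pearson_columns(X, np.ones(6))

    def test_critical_r_matches_p_threshold(self):
        n = 64
        rc = core.critical_r(0.01, n)
        for r in (rc * 1.001, rc * 0.999):
            t = r * np.sqrt((n - 2) / (1 - r**2))
            p = 2 * stats.t.sf(t, n - 2)
            assert (p < 0.01) == (r > rc)


class TestSelectFeatures:
    def test_all_insignificant_gives_empty_sets(self):
        mask = core.select_features(np.array([0.1, -0.2]), np.array([1.0, 1.0]), 0.01)
        assert mask.positive.size == 0 and mask.negative.size == 0

    def test_sign_routing(self):
        mask = core.select_features(
            np.array([0.4, 0.4, -0.4]), np.array([0.001, 0.5, 0.001]), 0.01
        )
        assert mask.positive.tolist() == [0]
        assert mask.negative.tolist() == [2]

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            core.FeatureMask(np.array([1, 2]), np.array([2, 3]), 0.01)


class TestSummaryScore:
    def test_combined_two_edges(self):
        mask = core.FeatureMask(np.array([1]), np.array([2]), 0.01)
        vec = np.array([9.0, 2.0, 0.5, 9.0])
        assert core.summary_score(vec, mask, "combined") == pytest.approx(1.5)

    def test_empty_required_side_errors(self):
        mask = core.FeatureMask(np.array([1]), np.array([], dtype=int), 0.01)
        with pytest.raises(core.EmptyMaskError, match="negative"):
            core.summary_score(np.ones(4), mask, "combined")
        assert core.summary_score(np.ones(4), mask, "positive_only") == 1.0

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_combined_equals_positive_minus_negative(self, seed):
        rng = np.random.default_rng(seed)
        e = 30
        idx = rng.permutation(e)
        mask = core.FeatureMask(idx[:5], idx[5:9], 0.01)
        X = rng.normal(size=(7, e))
        combined = core.summary_score(X, mask, "combined")
        pos = core.summary_score(X, mask, "positive_only")
        neg = core.summary_score(X, mask, "negative_only")
        assert np.allclose(combined, pos - neg, atol=1e-12)


class TestFitPredict:
    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(17)
        base = np.arange(8.0)
        X = np.column_stack([base, -base, rng.normal(size=(8, 4))])
        y = 2.0 * (X[:, 0] - X[:, 1]) + 1.0  # combined score of edges {0}+,{1}-
        model = core.fit_cpm(X, y, p_threshold=1e-3)
        assert model.mask.positive.tolist() == [0]
        assert model.mask.negative.tolist() == [1]
        assert model.slope == pytest.approx(2.0, abs=1e-10)
        assert model.intercept == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(core.predict_cpm(model, X), y, atol=1e-8)

    def test_five_subject_closed_form_ols(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(5, 4))
        y = rng.normal(size=5)
        model = core.fit_cpm(X, y, p_threshold=0.9)
        s = np.asarray(core.summary_score(X, model.mask, "combined"))
        slope = ((s - s.mean()) * (y - y.mean())).sum() / ((s - s.mean()) ** 2).sum()
        assert model.slope == pytest.approx(slope, abs=1e-12)
        assert model.intercept == pytest.approx(y.mean() - slope * s.mean(), abs=1e-12)

    def test_zero_variance_scores_error(self):
        X = np.zeros((6, 4))
        X[:, 0] = [1, 2, 3, 4, 5, 6]
        y = np.array([1.0, 2, 3, 4, 5, 6])
        X[:, 1] = 1.0  # constant edge
        mask = core.FeatureMask(np.array([1]), np.array([], dtype=int), 0.5)
        with pytest.raises(core.DegenerateDataError, match="variance"):
            core._fit_linear(mask, core.summary_score(X, mask, "positive_only"), y,
                             "positive_only", 4)

    def test_all_zero_edges_predict_intercept(self, toy_edges):
        X, y = toy_edges
        model = core.fit_cpm(X, y, p_threshold=0.9)
        pred = core.predict_cpm(model, np.zeros((3, X.shape[1])))
        assert np.allclose(pred, model.intercept)

    def test_prediction_local_to_mask(self, toy_edges):
        X, y = toy_edges
        model = core.fit_cpm(X, y, p_threshold=0.9)
        in_mask = set(model.mask.positive) | set(model.mask.negative)
        outside = [e for e in range(X.shape[1]) if e not in in_mask]
        assert outside, "toy fit should leave some edges unselected"
        X2 = X.copy()
        X2[:, outside] += 99.0
        assert np.array_equal(core.predict_cpm(model, X2), core.predict_cpm(model, X))

    def test_edge_count_mismatch_rejected(self, toy_edges):
        X, y = toy_edges
        model = core.fit_cpm(X, y, p_threshold=0.9)
        with pytest.raises(ValueError, match="edge count"):
            core.predict_cpm(model, np.zeros((2, 5)))

    def test_subject_order_invariance_of_full_fit(self, toy_edges):
        X, y = toy_edges
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(y))
        m1 = core.fit_cpm(X, y, p_threshold=0.9)
        m2 = core.fit_cpm(X[perm], y[perm], p_threshold=0.9)
        assert m1.slope == m2.slope and m1.intercept == m2.intercept
        assert np.array_equal(m1.mask.positive, m2.mask.positive)


class TestSplits:
    def test_sizes_and_uniqueness(self):
        scheme = core.SplitScheme(n_splits=100, train_fraction=0.7, seed=4)
        splits = core.generate_splits(92, scheme)
        seen = set()
        for tr, te in splits:
            assert tr.size == 64 and te.size == 28
            assert np.intersect1d(tr, te).size == 0
            seen.add(tuple(tr))
        assert len(seen) == 100

    def test_deterministic_from_seed(self):
        scheme = core.SplitScheme(n_splits=10, seed=9)
        a = core.generate_splits(30, scheme)
        b = core.generate_splits(30, scheme)
        assert all(np.array_equal(x[0], y[0]) for x, y in zip(a, b))

    def test_impossible_unique_splits_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            core.generate_splits(4, core.SplitScheme(n_splits=100, train_fraction=0.5, seed=0))


class TestRunCPM:
    def test_perfect_signal_limit(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 50))
        y = 3.0 * X[:, 7] + 1.0
        res = core.run_cpm(X, y, core.SplitScheme(20, 0.7, 2), p_threshold=0.01,
                           score_mode="positive_only")
        assert res.mean_r >= 0.99

    def test_same_seed_bit_identical(self, tiny_dataset):
        _, conn, behavior, _ = tiny_dataset
        y = behavior.outcome("total")
        scheme = core.SplitScheme(15, 0.7, 21)
        a = core.run_cpm(conn, y, scheme)
        b = core.run_cpm(conn, y, scheme)
        assert np.array_equal(a.per_split_r, b.per_split_r, equal_nan=True)

    def test_covariate_identical_to_outcome_yields_missing_splits(self, tiny_dataset):
        _, conn, behavior, _ = tiny_dataset
        y = behavior.outcome("total")
        res = core.run_cpm(conn, y, core.SplitScheme(5, 0.7, 3), covariate=y)
        assert np.isnan(res.per_split_r).all()

    def test_mostly_empty_masks_abort_with_guidance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 20))
        y = rng.normal(size=30)
        with pytest.raises(RuntimeError, match="p_threshold"):
            core.run_cpm(X, y, core.SplitScheme(20, 0.7, 6), p_threshold=1e-9)


class TestExternalValidation:
    def test_target_equals_training_reproduces_in_sample_r(self, tiny_dataset):
        _, conn, behavior, _ = tiny_dataset
        y = behavior.outcome("total")
        model = core.fit_cpm(conn.edges, y)
        pred = core.predict_cpm(model, conn.edges)
        r_in = stats.pearsonr(pred, y).statistic
        r_ext, _ = core.external_validate(model, conn.edges, y)
        assert r_ext == pytest.approx(r_in, abs=1e-12)

    def test_duplicating_target_subjects_leaves_r_unchanged(self, tiny_dataset):
        _, conn, behavior, _ = tiny_dataset
        y = behavior.outcome("total")
        model = core.fit_cpm(conn.edges, y)
        r1, _ = core.external_validate(model, conn.edges, y)
        r2, _ = core.external_validate(
            model, np.vstack([conn.edges, conn.edges]), np.concatenate([y, y])
        )
        assert r2 == pytest.approx(r1, abs=1e-12)

    def test_tiny_target_rejected(self, tiny_dataset):
        _, conn, behavior, _ = tiny_dataset
        model = core.fit_cpm(conn.edges, behavior.outcome("total"))
        with pytest.raises(core.DegenerateDataError):
            core.external_validate(model, conn.edges[:3], behavior.outcome("total")[:3])


class TestPartialCorrelation:
    def test_orthogonal_covariate_leaves_r_unchanged(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        z = rng.normal(size=50)
        # orthogonalize z against x and y exactly
        basis = np.column_stack([np.ones(50), x, y])
        z = z - basis @ np.linalg.lstsq(basis, z, rcond=None)[0]
        raw = stats.pearsonr(x, y).statistic
        assert core.partial_pearson(x, y, z) == pytest.approx(raw, abs=1e-10)

    def test_three_variable_closed_form(self):
        rng = np.random.default_rng(14)
        x, y, z = rng.normal(size=(3, 40))
        rxy = stats.pearsonr(x, y).statistic
        rxz = stats.pearsonr(x, z).statistic
        ryz = stats.pearsonr(y, z).statistic
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert core.partial_pearson(x, y, z) == pytest.approx(expected, abs=1e-12)

    def test_covariate_equal_to_outcome_undefined(self):
        rng = np.random.default_rng(15)
        x, y = rng.normal(size=(2, 20))
        assert np.isnan(core.partial_pearson(x, y, y))


class TestModelSerialization:
    def test_round_trip(self, tiny_dataset, tmp_path):
        _, conn, behavior, _ = tiny_dataset
        model = core.fit_cpm(conn.edges, behavior.outcome("total"), outcome_name="total")
        path = tmp_path / "model.json"
        core.save_model(model, path)
        back = core.load_model(path)
        assert back.slope == model.slope and back.intercept == model.intercept
        assert np.array_equal(back.mask.positive, model.mask.positive)
        assert np.array_equal(back.mask.negative, model.mask.negative)
        assert back.outcome_name == "total" and back.n_edges == model.n_edges
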