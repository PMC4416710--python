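"""Metrics, folds, inner selection, and nested-CV accounting."""

import numpy as np
import pytest

from sglmri.evaluation import (
    ConfusionCounts,
    discriminative_scores,
    inner_select,
    lambda_grid,
    make_folds,
    mean_loglik,
    metrics,
    nested_cv,
)
from sglmri.model import PenaltyConfig
from sglmri.evaluation import LambdaGrid


class TestMetrics:
    def test_perfect_classification(self):
        m = metrics(ConfusionCounts(tp=31, fn=0, tn=31, fp=0))
        assert all(v == 1.0 for v in m.values())

    def test_hand_computed_counts(self):
        m = metrics(ConfusionCounts(tp=10, fn=5, tn=20, fp=5))
        assert m["sensitivity"] == pytest.approx(2 / 3)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["accuracy"] == pytest.approx(0.75)
        assert m["fscore"] == pytest.approx(10 / 15)

    def test_matches_formula_oracle(self, rng):
        for _ in range(20):
            tp, fn, tn, fp = rng.integers(1, 30, size=4)
            m = metrics(ConfusionCounts(int(tp), int(fn), int(tn), int(fp)))
            assert m["sensitivity"] == pytest.approx(tp / (tp + fn))
            assert m["specificity"] == pytest.approx(tn / (tn + fp))
            assert m["accuracy"] == pytest.approx((tp + tn) / (tp + fn + tn + fp))
            prec, rec = tp / (tp + fp), tp / (tp + fn)
            assert m["fscore"] == pytest.approx(2 / (1 / prec + 1 / rec))
            assert m["recall"] == m["sensitivity"]

    def test_undefined_rates_are_nan_not_zero(self):
        m = metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))
        assert np.isnan(m["sensitivity"])
        assert not np.isnan(m["specificity"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestMeanLoglik:
    def test_all_half_gives_ln_half(self):
        assert mean_loglik(np.full(10, 0.5)) == pytest.approx(np.log(0.5))

    def test_certain_predictions_give_zero(self):
        assert mean_loglik(np.ones(4)) == 0.0

    def test_matches_direct_summation(self, rng):
        p = rng.uniform(0.01, 1.0, size=25)
        assert mean_loglik(p) == pytest.approx(np.mean([np.log(v) for v in p]))
        assert mean_loglik(p) <= 0


class TestDiscriminativeScores:
    def test_single_subject_score_is_unit(self):
        s = discriminative_scores([2.7], [1], [1])
        assert s.scores[0] == 1.0

    def test_symmetric_pair(self):
        s = discriminative_scores([1.3, -1.3], [1, -1], [1, -1])
        assert np.allclose(s.scores, [1.0, -1.0])

    def test_pooled_scores_bounded_with_max_attained(self, rng):
        lo = rng.normal(size=40)
        s = discriminative_scores(lo, np.sign(lo), np.sign(lo))
        assert np.all(np.abs(s.scores) <= 1.0)
        # max-scan oracle: the maximum-magnitude entry maps to +/-1
        k = np.argmax(np.abs(lo))
        assert abs(s.scores[k]) == pytest.approx(1.0)
        assert np.sum(np.isclose(np.abs(s.scores), 1.0)) >= 1


class TestFolds:
    def test_stratified_sizes_for_study_cohort(self):
        labels = np.array([-1] * 31 + [1] * 31)
        folds = make_folds(labels, k=10, rng=0)
        for cls in (-1, 1):
            sizes = np.bincount(folds[labels == cls], minlength=10)
            assert set(sizes) <= {3, 4}
            assert sizes.sum() == 31

    def test_leave_one_out_degenerate(self):
        labels = np.array([-1, -1, -1, 1, 1, 1])
        folds = make_folds(labels, k=3, rng=1)
        for cls in (-1, 1):
            assert sorted(folds[labels == cls]) == [0, 1, 2]

    def test_deterministic_given_seed(self):
        labels = np.array([-1] * 15 + [1] * 15)
        a = make_folds(labels, k=5, rng=7)
        b = make_folds(labels, k=5, rng=7)
        assert np.array_equal(a, b)

    def test_too_small_class_errors(self):
        with pytest.raises(ValueError, match="smaller k"):
            make_folds(np.array([-1, -1, 1, 1]), k=3)


class TestLambdaGrids:
    def test_published_grid_shapes_and_endpoints(self):
        s = lambda_grid("sLASSO", "full")
        g = lambda_grid("gLASSO", "full")
        sg = lambda_grid("sgLASSO", "full")
        assert len(s.values) == 200 and len(g.values) == 100 and len(sg.values) == 200
        assert s.values[0].lambda_s == pytest.approx(0.01)
        assert s.values[-1].lambda_s == pytest.approx(0.2512)
        assert g.values[0].lambda_g == pytest.approx(0.1)
        assert g.values[-1].lambda_g == pytest.approx(0.6310)
        assert all(p.lambda_g == 0 for p in s.values)
        assert all(p.lambda_s == 0 for p in g.values)
        assert min(p.lambda_s for p in sg.values) == pytest.approx(1e-6)
        assert max(p.lambda_g for p in sg.values) == pytest.approx(0.3162)

    def test_algorithm_consistency_enforced(self):
        with pytest.raises(ValueError):
            LambdaGrid("sLASSO", (PenaltyConfig(0.1, 0.1),))


@pytest.fixture(scope="module")
def prepped(small_dataset):
    _, fm, groups, _ = small_dataset
    return fm, groups


class TestInnerSelect:
    def test_single_point_grid_returned(self, prepped):
        fm, groups = prepped
        grid = LambdaGrid("gLASSO", (PenaltyConfig(0.0, 0.3),))
        sel = inner_select(fm.values, fm.labels, groups, grid, k=4, rng=0,
                           tol=1e-6, max_iter=300)
        assert sel.penalty == PenaltyConfig(0.0, 0.3)

    def test_duplicate_grid_points_tie_flagged(self, prepped):
        fm, groups = prepped
        grid = LambdaGrid("gLASSO", (PenaltyConfig(0.0, 0.3), PenaltyConfig(0.0, 0.3)))
        sel = inner_select(fm.values, fm.labels, groups, grid, k=4, rng=0,
                           tol=1e-6, max_iter=300)
        assert sel.tie
        assert sel.penalty == PenaltyConfig(0.0, 0.3)

    def test_selected_mu_logl_is_maximal(self, prepped):
        fm, groups = prepped
        grid = LambdaGrid(
            "gLASSO", tuple(PenaltyConfig(0.0, l) for l in np.geomspace(0.05, 0.6, 6))
        )
        sel = inner_select(fm.values, fm.labels, groups, grid, k=4, rng=3,
                           tol=1e-6, max_iter=300)
        assert sel.mu_logl == pytest.approx(sel.table["mu_logl"].max())


class TestNestedCV:
    def test_accounting_identity_tiny(self, prepped):
        """Every subject scored once; confusion counts sum to n."""
        fm, groups = prepped
        grid = LambdaGrid("gLASSO", (PenaltyConfig(0.0, 0.2), PenaltyConfig(0.0, 0.5)))
        rep = nested_cv(fm.values, fm.labels, groups, grid,
                        n_repeats=1, k=2, seed=0, tol=1e-6, max_iter=300)
        assert len(rep.records) == 2
        all_test = np.concatenate([r.test_indices for r in rep.records])
        assert sorted(all_test) == list(range(fm.n_subjects))
        n_scored = sum(len(r.test_true) for r in rep.records)
        assert n_scored == fm.n_subjects

    def test_no_leakage_provenance(self, prepped):
        """Inner selection sees exactly the outer-training subjects."""
        fm, groups = prepped
        grid = LambdaGrid("gLASSO", (PenaltyConfig(0.0, 0.3),))
        rep = nested_cv(fm.values, fm.labels, groups, grid,
                        n_repeats=1, k=3, seed=1, tol=1e-6, max_iter=300)
        for r in rep.records:
            assert np.array_equal(np.sort(r.inner.train_indices), np.sort(r.train_indices))
            assert not set(r.test_indices) & set(r.inner.train_indices)
            assert not set(r.test_indices) & set(r.train_indices)

    def test_determinism_same_seed(self, prepped):
        fm, groups = prepped
        grid = LambdaGrid("gLASSO", (PenaltyConfig(0.0, 0.3),))
        a = nested_cv(fm.values, fm.labels, groups, grid, n_repeats=1, k=3,
                      seed=9, tol=1e-6, max_iter=300)
        b = nested_cv(fm.values, fm.labels, groups, grid, n_repeats=1, k=3,
                      seed=9, tol=1e-6, max_iter=300)
        assert a.per_repeat.equals(b.per_repeat)
        assert np.array_equal(a.scores.scores, b.scores.scores)

    def test_reported_accuracy_from_pooled_counts(self, prepped):
        fm, groups = prepped
        grid = LambdaGrid("gLASSO", (PenaltyConfig(0.0, 0.3),))
        rep = nested_cv(fm.values, fm.labels, groups, grid, n_repeats=2, k=3,
                        seed=4, tol=1e-6, max_iter=300)
        for rep_id in range(2):
            recs = [r for r in rep.records if r.repeat == rep_id]
            counts = ConfusionCounts(0, 0, 0, 0)
            for r in recs:
                counts = counts + ConfusionCounts.from_labels(r.test_true, r.test_predicted)
            assert rep.per_repeat.loc[rep_id, "accuracy"] == pytest.approx(
                metrics(counts)["accuracy"]
            )
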