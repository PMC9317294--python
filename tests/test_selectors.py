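"""Feature scorers (NCA, chi-square, mRMR-FCQ) against independent oracles,
and the iterative top-k wrapper."""

import numpy as np
import pytest
from scipy import stats as sps

from lungscreen.errors import ConfigurationError, ValidationError
from lungscreen.fixtures import make_feature_table
from lungscreen.selectors import (
    chi2_scores,
    chi2_statistic,
    iterative_select,
    mrmr_fcq_rank,
    nca_assignment_probs,
    nca_fit,
    nca_objective,
    score_features,
)

# ---------------------------------------------------------------------------
# NCA


def _brute_force_probs(X, w):
    """Literal evaluation of the softmax assignment probabilities."""
    n = X.shape[0]
    Z = X * w
    P = np.zeros((n, n))
    for i in range(n):
        d = np.array([np.sum((Z[i] - Z[k]) ** 2) for k in range(n)])
        e = np.exp(-d)
        e[i] = 0.0
        P[i] = e / e.sum()
    return P


class TestNcaProbs:
    def test_two_points_single_neighbor(self):
        P = nca_assignment_probs(np.array([[0.0], [3.0]]), np.ones(1))
        assert np.allclose(P, [[0, 1], [1, 0]])

    def test_three_equidistant_points(self):
        X = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        P = nca_assignment_probs(X, np.ones(2))
        off = P[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.5)
        assert np.allclose(np.diag(P), 0.0)

    def test_matches_brute_force_on_four_point_toy(self, rng):
        X = rng.normal(size=(4, 3))
        w = np.array([1.3, 0.7, 2.0])
        P = nca_assignment_probs(X, w)
        assert np.abs(P - _brute_force_probs(X, w)).max() < 1e-10
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            nca_assignment_probs(np.array([[1.0, 2.0]]), np.ones(2))


class TestNcaObjective:
    def test_pair_same_class(self):
        X = np.array([[0.0], [1.0]])
        assert nca_objective(X, np.array([0, 0]), np.ones(1)) == pytest.approx(2.0)

    def test_pair_different_class(self):
        X = np.array([[0.0], [1.0]])
        assert nca_objective(X, np.array([0, 1]), np.ones(1)) == pytest.approx(0.0)

    def test_upweighting_informative_feature_increases_objective(self, rng):
        y = np.array([0] * 10 + [1] * 10)
        informative = np.where(y == 0, -2.0, 2.0) + 0.05 * rng.normal(size=20)
        X = np.column_stack([informative, rng.normal(size=20)])
        f_uniform = nca_objective(X, y, np.ones(2))
        f_up = nca_objective(X, y, np.array([3.0, 0.3]))
        assert f_up > f_uniform


class TestNcaFit:
    def test_informative_feature_ranked_first(self, rng):
        y = np.array([0] * 25 + [1] * 25)
        X = np.column_stack([np.where(y == 0, -2.0, 2.0)
                             + 0.1 * rng.normal(size=50),
                             rng.normal(size=50)])
        scores = nca_fit(X, y, seed=0)
        assert list(scores.ranking) == [0, 1]

    def test_objective_trace_non_decreasing(self, planted_table):
        scores = nca_fit(planted_table.values[:, :30], planted_table.labels, seed=1)
        trace = scores.diagnostics["objective_trace"]
        assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_row_duplication_preserves_ranking(self, rng):
        y = np.array([0] * 15 + [1] * 15)
        X = np.column_stack([np.where(y == 0, -1.5, 1.5)
                             + 0.2 * rng.normal(size=30),
                             rng.normal(size=30)])
        base = nca_fit(X, y, seed=0).ranking
        dup = nca_fit(np.vstack([X, X]), np.concatenate([y, y]), seed=0).ranking
        assert np.array_equal(base, dup)

    def test_ranking_stable_across_seeds(self, planted_table):
        info = set(planted_table.metadata["informative_indices"])
        for seed in range(5):
            scores = nca_fit(planted_table.values, planted_table.labels, seed=seed)
            assert len(set(scores.ranking[:10].tolist()) & info) >= 9

    def test_affine_rescaling_invariance(self, planted_table):
        """Standardization absorbs per-feature affine maps."""
        X = planted_table.values[:, :20]
        y = planted_table.labels
        base = nca_fit(X, y, seed=0).ranking
        scale = np.linspace(0.1, 50, 20)
        rescaled = nca_fit(X * scale + 3.0, y, seed=0).ranking
        assert np.array_equal(base, rescaled)


# ---------------------------------------------------------------------------
# chi-square


class TestChi2:
    def test_perfect_association_scores_n(self):
        y = np.array([0] * 20 + [1] * 20)
        x = y.astype(float)
        s = chi2_scores(x[:, None], y, n_bins=2)
        assert s.scores[0] == pytest.approx(40.0)

    def test_identical_distribution_scores_zero(self):
        y = np.array([0] * 10 + [1] * 10)
        x = np.tile(np.arange(10, dtype=float), 2)  # same values per class
        s = chi2_scores(x[:, None], y, n_bins=5)
        assert s.scores[0] == pytest.approx(0.0)

    def test_hand_contingency_arithmetic(self):
        assert chi2_statistic(np.array([[10, 20], [20, 10]])) == pytest.approx(20 / 3)

    def test_constant_feature_scores_zero(self):
        y = np.array([0, 0, 1, 1])
        s = chi2_scores(np.ones((4, 1)), y)
        assert s.scores[0] == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_on_prebinned_tables(self, seed):
        """On integer-valued features the equal-width binning reproduces the
        exact contingency table, so scores must equal scipy's chi-square
        statistic (uncorrected)."""
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 3, size=120)
        x = rng.integers(0, 4, size=120).astype(float)
        s = chi2_scores(x[:, None], y, n_bins=4)
        table = np.zeros((3, 4))
        np.add.at(table, (y, x.astype(int)), 1)
        table = table[table.sum(1) > 0][:, table.sum(0) > 0]
        expected = sps.chi2_contingency(table, correction=False)[0]
        assert s.scores[0] == pytest.approx(expected, abs=1e-10)

    def test_bin_preserving_monotone_transform_keeps_ranking(self, planted_table):
        """A strictly increasing affine map preserves equal-width bin
        occupancy, hence every score and the ranking."""
        X, y = planted_table.values, planted_table.labels
        base = chi2_scores(X, y)
        mapped = chi2_scores(X * 2.5 - 7.0, y)
        assert np.allclose(base.scores, mapped.scores)
        assert np.array_equal(base.ranking, mapped.ranking)


# ---------------------------------------------------------------------------
# mRMR (FCQ)


def _exhaustive_greedy(X, y, k):
    """Independent re-implementation of the FCQ greedy order."""
    groups = [X[y == c] for c in np.unique(y)]
    F = sps.f_oneway(*groups)[0]
    F = np.where(np.isfinite(F), F, 0.0)
    d = X.shape[1]
    selected = []
    while len(selected) < k:
        best, best_q = None, -np.inf
        for j in range(d):
            if j in selected:
                continue
            if X[:, j].var() == 0:
                continue
            if not selected:
                q = F[j]
            else:
                corrs = [abs(np.corrcoef(X[:, j], X[:, s])[0, 1])
                         for s in selected]
                q = F[j] / max(np.mean(corrs), 1e-12)
            if q > best_q:
                best, best_q = j, q
        selected.append(best)
    return selected


class TestMrmr:
    def test_first_pick_is_max_f_statistic(self, planted_table):
        X, y = planted_table.values, planted_table.labels
        s = mrmr_fcq_rank(X, y, k_max=5)
        groups = [X[y == c] for c in np.unique(y)]
        F = sps.f_oneway(*groups)[0]
        assert s.ranking[0] == int(np.argmax(F))

    def test_exact_duplicate_of_first_pick_deferred(self, rng):
        """An exact copy of the first pick keeps quotient F/1 = F; a second,
        equally relevant feature with independent noise has |corr| < 1 and
        hence a strictly larger quotient, so the copy loses (quotient
        comparison oracle)."""
        y = np.repeat([0, 1, 2], 20)
        f0 = y + 0.3 * rng.normal(size=60)
        # equally relevant but weakly correlated: permuted class pattern
        f2 = np.array([0.0, 2.0, 1.0])[y] + 0.3 * rng.normal(size=60)
        X = np.column_stack([f0, f0.copy(), f2, rng.normal(size=60)])
        s = mrmr_fcq_rank(X, y, k_max=3)
        # the duplicated pair never occupies both of the first two slots
        assert set(s.ranking[:2].tolist()) != {0, 1}
        assert 2 in s.ranking[:2]

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_exhaustive_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, d = 30, rng.integers(3, 9)
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, d))
        X[:, 0] += y * rng.uniform(0.5, 3.0)
        k = int(min(d, 4))
        ours = mrmr_fcq_rank(X, y, k_max=k).ranking[:k].tolist()
        oracle = _exhaustive_greedy(X, y, k)
        assert ours == oracle

    def test_zero_variance_feature_excluded(self, rng):
        y = np.repeat([0, 1], 10)
        X = np.column_stack([y + 0.1 * rng.normal(size=20), np.full(20, 3.0)])
        s = mrmr_fcq_rank(X, y)
        assert s.diagnostics["excluded_zero_variance"] == [1]
        assert sorted(s.ranking.tolist()) == [0, 1]

    def test_affine_rescaling_invariance(self, planted_table):
        X, y = planted_table.values[:, :20], planted_table.labels
        base = mrmr_fcq_rank(X, y, k_max=10).ranking[:10]
        scale = np.linspace(0.2, 30, 20)
        mapped = mrmr_fcq_rank(X * scale + 1.0, y, k_max=10).ranking[:10]
        assert np.array_equal(base, mapped)


# ---------------------------------------------------------------------------
# iterative wrapper


class TestIterativeSelect:
    def test_degenerate_grid_returns_top_k(self, planted_table):
        X, y = planted_table.values, planted_table.labels
        res = iterative_select("chi2", X, y, k_min=12, k_max=12, step=4, seed=0)
        ranking = chi2_scores(X, y).ranking
        assert res.chosen_k == 12
        assert np.array_equal(res.chosen_indices, ranking[:12])

    @pytest.mark.parametrize("method", ["nca", "chi2", "mrmr_fcq"])
    def test_planted_recovery(self, method, planted_table):
        info = set(planted_table.metadata["informative_indices"])
        res = iterative_select(method, planted_table.values,
                               planted_table.labels, seed=0)
        assert len(set(res.chosen_indices.tolist()) & info) >= 9

    def test_chosen_loss_minimizes_curve(self, planted_table):
        res = iterative_select("chi2", planted_table.values,
                               planted_table.labels, seed=3)
        ki = list(res.k_grid).index(res.chosen_k)
        assert res.loss_curve[ki] == res.loss_curve.min()
        assert res.loss_curve[ki] <= res.loss_curve[-1]
        # tie rule: no smaller k on the grid attains the same loss
        first_min = int(np.argmin(res.loss_curve))
        assert res.k_grid[first_min] == res.chosen_k

    def test_recovery_monotone_in_effect(self):
        """Recovery of planted columns is non-decreasing in effect size."""
        effects = [0.5, 1.0, 2.0, 4.0]
        mean_rec = []
        for effect in effects:
            recs = []
            for seed in range(5):
                fm = make_feature_table(40, 40, 6, effect, seed=seed)
                info = set(fm.metadata["informative_indices"])
                res = iterative_select("chi2", fm.values, fm.labels,
                                       k_min=6, k_max=6, seed=seed)
                recs.append(len(set(res.chosen_indices.tolist()) & info))
            mean_rec.append(np.mean(recs))
        assert all(b >= a - 0.21 for a, b in zip(mean_rec, mean_rec[1:]))
        assert mean_rec[-1] > mean_rec[0]

    def test_unknown_method_rejected(self, planted_table):
        with pytest.raises(ConfigurationError):
            score_features("pca", planted_table.values, planted_table.labels)

    def test_invalid_bounds_rejected(self, planted_table):
        with pytest.raises(ValidationError):
            iterative_select("chi2", planted_table.values,
                             planted_table.labels, k_min=50, k_max=10)
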