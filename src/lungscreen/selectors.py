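"""Feature scoring and iterative top-k selection.

Three scorers rank the fused feature columns:

* **NCA** (neighborhood component analysis): learns one non-negative weight
  per feature by gradient ascent on the expected leave-one-out accuracy of a
  stochastic nearest-neighbor rule; features are ranked by final weight².
  The assignment probability of sample *i* picking neighbor *j* is the
  softmax of the negative squared Euclidean distance in the weighted space,

      p_ij = exp(-d_ij) / sum_{k != i} exp(-d_ik),     p_ii = 0,

  and the objective is f(w) = sum_i sum_{j in S_i} p_ij with S_i the
  same-class neighbors of i.
* **Chi-square**: each feature is discretized into equal-width bins; the
  class x bin contingency table yields the classical dependence statistic
  sum (O - E)^2 / E.
* **mRMR-FCQ** (minimum redundancy, maximum relevance; F-test/correlation
  quotient): greedy ranking maximizing the one-way ANOVA F-statistic of the
  candidate against the class divided by its mean absolute Pearson
  correlation with already-selected features.

The iterative wrapper (iNCA / iChi2 / iMRMR) turns any ranking into a subset:
it scans top-k prefixes over a k-grid, scores each with a light classifier's
cross-validated misclassification loss, and keeps the k with minimum loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.feature_selection import f_classif
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier

from .errors import ConfigurationError, ValidationError

METHODS = ("nca", "chi2", "mrmr_fcq")


@dataclass
class SelectorScores:
    """Per-feature scores and the induced best-first ranking."""

    method: str
    ranking: np.ndarray       # permutation of [0, d), best first
    scores: np.ndarray        # per-feature score (selection-order score for mrmr)
    diagnostics: dict = field(default_factory=dict)


@dataclass
class SelectionResult:
    """Outcome of the iterative top-k loss scan."""

    method: str
    k_grid: np.ndarray
    loss_curve: np.ndarray
    chosen_k: int
    chosen_indices: np.ndarray
    ranking: np.ndarray
    loss_classifier: str = "1nn_cv5"
    seed: int = 0


def _standardize(X: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance columns; constant columns map to zero."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


# ---------------------------------------------------------------------------
# NCA


def _weighted_sqdist(X: np.ndarray, weights: np.ndarray) -> np.ndarray:
    Z = X * weights
    sq = np.sum(Z ** 2, axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * (Z @ Z.T)
    np.maximum(D, 0.0, out=D)
    return D


def nca_assignment_probs(X: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Stochastic-neighbor assignment probabilities p_ij.

    ``p_ij`` is the softmax over ``j != i`` of the negative squared Euclidean
    distance between samples in the feature space scaled per-feature by
    ``weights``; the self-assignment probability is zero and each row sums
    to 1.  (The softmax is evaluated shift-invariantly for numerical range.)
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need at least two samples to define neighbors")
    w = np.asarray(weights, dtype=float)
    if w.shape != (X.shape[1],) or not np.isfinite(w).all():
        raise ValidationError("weights must be a finite vector of length n_features")
    D = _weighted_sqdist(X, w)
    np.fill_diagonal(D, np.inf)          # p_ii = 0
    neg = -D
    row_max = neg.max(axis=1, keepdims=True)
    P = np.exp(neg - row_max)
    P[~np.isfinite(P)] = 0.0
    P /= P.sum(axis=1, keepdims=True)
    return P


def nca_objective(X: np.ndarray, y: np.ndarray, weights: np.ndarray) -> float:
    """f(w) = sum_i sum_{j in S_i} p_ij — expected leave-one-out correct votes."""
    P = nca_assignment_probs(X, weights)
    y = np.asarray(y)
    same = (y[:, None] == y[None, :])
    np.fill_diagonal(same, False)
    return float((P * same).sum())


def _nca_gradient(X: np.ndarray, y: np.ndarray, weights: np.ndarray
                  ) -> tuple[np.ndarray, float]:
    """Gradient of the objective w.r.t. the diagonal weights, plus f(w)."""
    P = nca_assignment_probs(X, weights)
    y = np.asarray(y)
    same = (y[:, None] == y[None, :])
    np.fill_diagonal(same, False)
    Pin = P * same
    p_i = Pin.sum(axis=1)
    f = float(p_i.sum())
    # d f / d w_m = 2 w_m * sum_i [ p_i sum_k P_ik D_ikm - sum_{j in S_i} P_ij D_ijm ]
    # where D_ijm = (x_im - x_jm)^2; both terms are quadratic forms in X.
    W1 = P * p_i[:, None]
    W = W1 - Pin

    def quad(Wmat: np.ndarray) -> np.ndarray:
        r = Wmat.sum(axis=1)
        c = Wmat.sum(axis=0)
        return (r + c) @ (X ** 2) - 2.0 * np.einsum("im,im->m", X, Wmat @ X)

    grad = 2.0 * weights * quad(W)
    return grad, f


def nca_fit(X: np.ndarray, y: np.ndarray, learning_rate: float = 0.1,
            max_iter: int = 100, tol: float = 1e-4, seed: int = 0
            ) -> SelectorScores:
    """Diagonal-metric NCA by gradient ascent with backtracking.

    Features are standardized first; weights start at 1 (plus a tiny seeded
    jitter so initialization is seed-dependent).  Steps that would decrease
    the objective are halved until they do not, so the recorded objective
    trace is non-decreasing.  Features are ranked by final weight².

    The objective is bounded by n and saturates once the stochastic 1-NN
    separates the classes; iterating past saturation lets irrelevant weights
    drift, so the stopping tolerance (expected correct-classification gain
    per step) deliberately halts at saturation onset.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < 2 or np.unique(y).size < 2:
        raise ValidationError("NCA needs >= 2 samples from >= 2 classes")
    Xs = _standardize(X)
    d = Xs.shape[1]
    rng = np.random.default_rng(seed)
    w = 1.0 + 1e-3 * rng.standard_normal(d)
    step = learning_rate
    grad, f = _nca_gradient(Xs, y, w)
    trace = [f]
    converged = False
    for _ in range(max_iter):
        gnorm = np.linalg.norm(grad)
        if gnorm == 0.0:
            converged = True
            break
        accepted = False
        for _ in range(30):
            w_new = w + step * grad / max(gnorm, 1.0)
            grad_new, f_new = _nca_gradient(Xs, y, w_new)
            if f_new >= f:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True
            break
        gain = f_new - f
        w, grad, f = w_new, grad_new, f_new
        trace.append(f)
        step *= 1.2
        if gain < tol:
            converged = True
            break
    if not converged:
        warnings.warn("NCA did not converge within max_iter; "
                      "returning best-so-far weights", RuntimeWarning)
    scores = w ** 2
    ranking = np.argsort(-scores, kind="stable")
    return SelectorScores(method="nca", ranking=ranking, scores=scores,
                          diagnostics={"objective_trace": trace,
                                       "converged": converged,
                                       "n_iterations": len(trace) - 1})


# ---------------------------------------------------------------------------
# Chi-square


def _equal_width_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros(x.shape, dtype=int)
    idx = np.floor((x - lo) / (hi - lo) * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def chi2_statistic(table: np.ndarray) -> float:
    """Classical contingency chi-square sum (O - E)^2 / E.

    Rows/columns with a zero margin contribute nothing and are dropped.
    """
    O = np.asarray(table, dtype=float)
    O = O[O.sum(axis=1) > 0][:, O.sum(axis=0) > 0]
    if O.size == 0:
        return 0.0
    total = O.sum()
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / total
    return float(((O - E) ** 2 / E).sum())


def chi2_scores(X: np.ndarray, y: np.ndarray, n_bins: int = 10) -> SelectorScores:
    """Per-feature chi-square dependence between binned feature and class.

    Each feature is discretized into ``n_bins`` equal-width bins over its
    observed range; a constant feature occupies a single bin and scores 0.
    Ranking is by descending score, ties broken toward the lower index.
    """
    if n_bins < 2:
        raise ValidationError(f"n_bins must be >= 2, got {n_bins}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    n_classes = classes.size
    d = X.shape[1]
    scores = np.empty(d)
    for j in range(d):
        bins = _equal_width_bins(X[:, j], n_bins)
        table = np.zeros((n_classes, n_bins))
        np.add.at(table, (y_idx, bins), 1.0)
        scores[j] = chi2_statistic(table)
    ranking = np.argsort(-scores, kind="stable")
    return SelectorScores(method="chi2", ranking=ranking, scores=scores,
                          diagnostics={"n_bins": n_bins})


# ---------------------------------------------------------------------------
# mRMR (FCQ)


def mrmr_fcq_rank(X: np.ndarray, y: np.ndarray, k_max: int | None = None
                  ) -> SelectorScores:
    """Greedy F-test/correlation-quotient ranking.

    Relevance is the one-way ANOVA F-statistic of the feature against the
    class; redundancy is the mean absolute Pearson correlation with the
    already-selected set.  The first pick maximizes raw relevance (empty
    redundancy set: the quotient is defined as the F-statistic itself); each
    later pick maximizes F / mean|corr|.  Ties break toward the lower index.
    Zero-variance features are excluded from candidacy (logged) and, like
    any features beyond ``k_max``, are appended to the ranking by descending
    relevance so the ranking stays a full permutation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValidationError("mrmr needs >= 2 samples per class")
    if k_max is None:
        k_max = d
    if k_max > d:
        raise ValidationError(f"k_max ({k_max}) > n_features ({d})")
    variances = X.var(axis=0)
    valid = variances > 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, _ = f_classif(X, y)
    F = np.where(np.isfinite(F), F, 0.0)
    F = np.where(valid, F, -np.inf)

    Z = _standardize(X)
    selected: list[int] = []
    sel_scores: list[float] = []
    sum_abs_corr = np.zeros(d)
    candidate = valid.copy()
    while len(selected) < k_max and candidate.any():
        if not selected:
            quotient = F.copy()
        else:
            redundancy = np.maximum(sum_abs_corr / len(selected), 1e-12)
            quotient = F / redundancy
        quotient = np.where(candidate, quotient, -np.inf)
        pick = int(np.argmax(quotient))       # first max -> lowest index on ties
        if not np.isfinite(quotient[pick]):
            break
        selected.append(pick)
        sel_scores.append(float(quotient[pick]))
        candidate[pick] = False
        sum_abs_corr += np.abs(Z.T @ Z[:, pick]) / n
    rest = [j for j in np.argsort(-np.where(np.isfinite(F), F, -1.0), kind="stable")
            if j not in set(selected)]
    ranking = np.asarray(selected + rest, dtype=int)
    scores = np.full(d, -np.inf)
    scores[np.asarray(selected, dtype=int)] = sel_scores
    # tail features scored by raw relevance, shifted below every greedy score
    if rest:
        floor = min(sel_scores) if sel_scores else 0.0
        tailF = np.where(np.isfinite(F[rest]), F[rest], 0.0)
        scores[rest] = floor - 1.0 - (tailF.max() - tailF)
    excluded = np.flatnonzero(~valid).tolist()
    return SelectorScores(
        method="mrmr_fcq", ranking=ranking, scores=scores,
        diagnostics={"excluded_zero_variance": excluded,
                     "greedy_order": list(selected),
                     "relevance": np.where(np.isfinite(F), F, 0.0)})


# ---------------------------------------------------------------------------
# iterative wrapper


def default_loss(seed: int, n_splits: int = 5) -> Callable[[np.ndarray, np.ndarray], float]:
    """1-nearest-neighbor misclassification rate under stratified CV."""

    def loss(X: np.ndarray, y: np.ndarray) -> float:
        counts = np.unique(y, return_counts=True)[1]
        splits = int(min(n_splits, counts.min()))
        if splits < 2:
            raise ValidationError("loss evaluation needs >= 2 samples per class")
        cv = StratifiedKFold(n_splits=splits, shuffle=True, random_state=seed)
        acc = cross_val_score(KNeighborsClassifier(n_neighbors=1), X, y,
                              cv=cv, scoring="accuracy")
        return float(1.0 - acc.mean())

    return loss


def holdout_loss(X_val: np.ndarray, y_val: np.ndarray):
    """1-NN misclassification on a held-out matrix (column-aware loss).

    Used when the scan data contain near-duplicates (e.g. augmented variants
    of one source image): within-set CV is then trivially optimistic, so the
    1-NN is trained on the scan subset and scored on the corresponding
    columns of an independent validation matrix instead.
    """
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val)

    def loss(X: np.ndarray, y: np.ndarray, cols) -> float:
        model = KNeighborsClassifier(n_neighbors=1).fit(X, y)
        return float(1.0 - (model.predict(X_val[:, cols]) == y_val).mean())

    loss.takes_cols = True
    return loss


def score_features(method: str, X: np.ndarray, y: np.ndarray,
                   seed: int = 0, **kwargs) -> SelectorScores:
    """Dispatch to the named scorer ('nca', 'chi2', or 'mrmr_fcq'/'mrmr')."""
    if method == "nca":
        return nca_fit(X, y, seed=seed, **kwargs)
    if method == "chi2":
        return chi2_scores(X, y, **kwargs)
    if method in ("mrmr_fcq", "mrmr"):
        return mrmr_fcq_rank(X, y, **kwargs)
    raise ConfigurationError(f"unknown selector method {method!r}; "
                             f"expected one of {METHODS}")


def iterative_select(method: str, X: np.ndarray, y: np.ndarray,
                     k_min: int = 32, k_max: int | None = None, step: int = 4,
                     loss_spec: Callable[[np.ndarray, np.ndarray], float] | None = None,
                     seed: int = 0, scorer_kwargs: dict | None = None,
                     ) -> SelectionResult:
    """Top-k loss scan over a ranking: the iNCA/iChi2/iMRMR wrapper.

    The named scorer produces a best-first ranking; for every k on the grid
    ``k_min, k_min+step, ..., k_max`` the loss of the top-k columns is
    evaluated (default: seeded stratified 5-fold CV error of a 1-NN
    classifier) and the k with minimum loss wins, ties going to the smaller
    k.  The full loss curve is returned for audit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    d = X.shape[1]
    if k_max is None:
        k_max = d
    if not (1 <= k_min <= k_max <= d):
        raise ValidationError(
            f"need 1 <= k_min <= k_max <= d, got ({k_min}, {k_max}, {d})")
    ranks = score_features(method, X, y, seed=seed, **(scorer_kwargs or {}))
    grid = list(range(k_min, k_max + 1, max(1, step)))
    if grid[-1] != k_max:
        grid.append(k_max)
    loss_fn = loss_spec if loss_spec is not None else default_loss(seed)
    takes_cols = getattr(loss_fn, "takes_cols", False)
    losses = np.empty(len(grid))
    for gi, k in enumerate(grid):
        cols = ranks.ranking[:k]
        try:
            if takes_cols:
                losses[gi] = loss_fn(X[:, cols], y, cols)
            else:
                losses[gi] = loss_fn(X[:, cols], y)
        except Exception as exc:
            raise RuntimeError(f"loss evaluation failed at k={k}: {exc}") from exc
    best = int(np.argmin(losses))             # first min -> smallest k on ties
    chosen_k = grid[best]
    return SelectionResult(
        method=ranks.method,
        k_grid=np.asarray(grid),
        loss_curve=losses,
        chosen_k=chosen_k,
        chosen_indices=np.asarray(ranks.ranking[:chosen_k]),
        ranking=np.asarray(ranks.ranking),
        loss_classifier="1nn_stratified_cv5",
        seed=seed,
    )
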