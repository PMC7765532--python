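"""Shrinkage LDA and forward-backward stepwise feature selection.

The classifier is linear discriminant analysis on the pooled
within-class covariance, regularized toward a scaled identity with an
automatically chosen (Ledoit-Wolf) intensity, so no hyper-parameter is
tuned:  Sigma_hat = (1 - gamma) S + gamma (tr S / d) I,
w = Sigma_hat^-1 (mu_target - mu_nontarget).  The decision threshold
sits at the midpoint of the projected class means (equal effective
priors) because the evaluation metric is balanced accuracy and the
target / non-target epoch counts are imbalanced by design
(1 : n_symbols - 1).

Stepwise selection greedily grows the feature set: the forward step adds
the candidate that most improves an inner cross-validated balanced
accuracy (when it improves by more than ``tol``); the backward step
removes any included feature whose removal costs no more than ``tol``.
Candidate scoring reuses per-fold sufficient statistics (class means,
pooled Gram and squared-Gram matrices), so each candidate costs only a
small dense solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.model_selection import StratifiedKFold

TARGET = "target"


@dataclass
class LdaModel:
    """Fitted shrinkage-LDA discriminant.

    weights/bias act on the columns listed in ``selected_features`` of
    the full feature vector; score = w . x + b and the predicted label
    is target iff score > 0.
    """

    weights: np.ndarray
    bias: float
    shrinkage: float
    mean_target: np.ndarray
    mean_nontarget: np.ndarray
    selected_features: np.ndarray = None
    n_features_in: int = None

    def __post_init__(self):
        d = len(self.weights)
        if self.selected_features is None:
            self.selected_features = np.arange(d)
        self.selected_features = np.asarray(self.selected_features)
        if self.n_features_in is None:
            self.n_features_in = int(self.selected_features.max(initial=-1)) + 1


def _as_target_mask(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == bool:
        return labels
    return labels == TARGET


def _lw_shrinkage_from_stats(G: np.ndarray, H: np.ndarray, n: int) -> float:
    """Ledoit-Wolf shrinkage intensity from cached statistics.

    G = Xc^T Xc and H = (Xc^2)^T (Xc^2) for the pooled class-centred
    data Xc with n rows.  Matches the closed-form intensity computed
    from the raw data (biased covariance S = G / n).
    """
    d = G.shape[0]
    S = G / n
    mu = np.trace(S) / d
    delta_ = float(np.sum(S * S))
    beta_ = float(np.sum(H))
    beta = (beta_ / n - delta_) / (n * d)
    delta = (delta_ - 2.0 * mu * np.trace(S) + d * mu * mu) / d
    if beta <= 0 or delta <= 0:
        return 0.0
    return float(min(beta / delta, 1.0))


def _solve_lda(mu_t, mu_n, G, H, n):
    """Weights, bias and shrinkage from sufficient statistics."""
    d = len(mu_t)
    gamma = _lw_shrinkage_from_stats(G, H, n)
    S = G / n
    sigma = (1.0 - gamma) * S + gamma * (np.trace(S) / d) * np.eye(d)
    try:
        w = scipy.linalg.solve(sigma, mu_t - mu_n, assume_a="pos")
    except scipy.linalg.LinAlgError:
        w = np.linalg.lstsq(sigma, mu_t - mu_n, rcond=None)[0]
    b = -0.5 * float(w @ (mu_t + mu_n))
    return w, b, gamma


def _class_stats(X: np.ndarray, tmask: np.ndarray):
    """Class means and pooled class-centred Gram/squared-Gram matrices."""
    mu_t = X[tmask].mean(axis=0)
    mu_n = X[~tmask].mean(axis=0)
    Xc = np.where(tmask[:, None], X - mu_t, X - mu_n)
    G = Xc.T @ Xc
    Xc2 = Xc * Xc
    H = Xc2.T @ Xc2
    return mu_t, mu_n, G, H, len(X)


def fit_lda(X: np.ndarray, labels, selected_features=None) -> LdaModel:
    """Fit the shrinkage-LDA discriminant.

    X is (n_samples, n_features); labels are "target"/"nontarget"
    strings or a boolean target mask.  Requires both classes with at
    least 2 samples each and finite features.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("features contain NaN or infinite values")
    tmask = _as_target_mask(labels)
    if tmask.sum() < 2 or (~tmask).sum() < 2:
        raise ValueError("need at least 2 samples in each class")
    mu_t, mu_n, G, H, n = _class_stats(X, tmask)
    w, b, gamma = _solve_lda(mu_t, mu_n, G, H, n)
    return LdaModel(
        weights=w,
        bias=b,
        shrinkage=gamma,
        mean_target=mu_t,
        mean_nontarget=mu_n,
        selected_features=selected_features,
        n_features_in=X.shape[1] if selected_features is None else None,
    )


def decision_scores(model: LdaModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] == len(model.weights):
        Xs = X
    elif X.shape[1] >= model.n_features_in:
        Xs = X[:, model.selected_features]
    else:
        raise ValueError(
            f"feature dimension {X.shape[1]} incompatible with model "
            f"({len(model.weights)} selected of {model.n_features_in})"
        )
    return Xs @ model.weights + model.bias


def predict(model: LdaModel, X: np.ndarray):
    """Predicted labels and decision scores; target iff score > 0."""
    scores = decision_scores(model, X)
    labels = np.where(scores > 0, "target", "nontarget")
    return labels, scores


def balanced_accuracy(true_target_mask, pred_target_mask) -> float:
    t = np.asarray(true_target_mask)
    p = np.asarray(pred_target_mask)
    tpr = (p & t).sum() / max(t.sum(), 1)
    tnr = (~p & ~t).sum() / max((~t).sum(), 1)
    return 0.5 * (tpr + tnr)


class _FoldCache:
    """Sufficient statistics of one inner fold for fast subset scoring."""

    def __init__(self, X_train, t_train, X_test, t_test):
        self.mu_t, self.mu_n, self.G, self.H, self.n = _class_stats(X_train, t_train)
        self.X_test = X_test
        self.t_test = t_test

    def score(self, idx: np.ndarray) -> float:
        ix = np.ix_(idx, idx)
        w, b, _ = _solve_lda(
            self.mu_t[idx], self.mu_n[idx], self.G[ix], self.H[ix], self.n
        )
        scores = self.X_test[:, idx] @ w + b
        return balanced_accuracy(self.t_test, scores > 0)


def make_cv_scorer(X: np.ndarray, labels, n_folds: int = 5, seed: int = 0):
    """Inner cross-validated balanced-accuracy scorer over feature subsets.

    Returns a callable ``scorer(index_array) -> float`` evaluating the
    shrinkage LDA restricted to those feature columns, averaged over
    stratified folds of the (training) data.  Deterministic given seed.
    """
    X = np.asarray(X, dtype=float)
    tmask = _as_target_mask(labels)
    n_folds = int(min(n_folds, tmask.sum(), (~tmask).sum()))
    if n_folds < 2:
        raise ValueError("need at least 2 samples per class for inner CV")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    caches = [
        _FoldCache(X[tr], tmask[tr], X[te], tmask[te])
        for tr, te in skf.split(X, tmask)
    ]

    def scorer(idx) -> float:
        idx = np.asarray(idx, dtype=int)
        return float(np.mean([c.score(idx) for c in caches]))

    return scorer


@dataclass
class SelectionResult:
    selected: np.ndarray
    model: LdaModel
    score: float
    history: list = field(default_factory=list)


def stepwise_select(
    X: np.ndarray,
    labels,
    scorer=None,
    tol: float = 0.01,
    seed: int = 0,
    max_features: int | None = None,
    max_sweeps: int = 200,
) -> SelectionResult:
    """Forward-backward stepwise feature selection for the shrinkage LDA.

    Starting from the empty model (score 0.5), the forward step adds the
    candidate maximizing the scorer when it improves the current score
    by more than ``tol`` (ties broken toward the lowest feature index);
    the backward step removes the included feature whose removal
    decreases the score by no more than ``tol``.  Sweeps repeat until
    the selection stabilizes (a visited-set guard prevents add/remove
    cycles).  If no feature ever improves on the empty model, the single
    best-scoring feature is kept.  Returns the selection and the final
    model refitted on all rows.
    """
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    if d < 1:
        raise ValueError("need at least one candidate feature")
    if scorer is None:
        scorer = make_cv_scorer(X, labels, seed=seed)

    selected: list[int] = []
    current = 0.5
    visited = {frozenset()}
    history = []
    best_single = None

    for _ in range(max_sweeps):
        changed = False
        # forward
        if max_features is None or len(selected) < max_features:
            cand = [j for j in range(d) if j not in selected]
            if cand:
                scores = np.array([scorer(np.array(selected + [j])) for j in cand])
                k = int(np.argmax(scores))  # first max -> lowest index wins
                if best_single is None and not selected:
                    best_single = (cand[int(np.argmax(scores))], float(scores.max()))
                trial = frozenset(selected + [cand[k]])
                if scores[k] > current + tol and trial not in visited:
                    selected.append(cand[k])
                    current = float(scores[k])
                    visited.add(trial)
                    history.append(("add", cand[k], current))
                    changed = True
        # backward
        if len(selected) > 1:
            scores = np.array(
                [
                    scorer(np.array([f for f in selected if f != j]))
                    for j in selected
                ]
            )
            k = int(np.argmax(scores))
            trial = frozenset(f for f in selected if f != selected[k])
            if scores[k] >= current - tol and trial not in visited:
                removed = selected.pop(k)
                current = float(scores[k])
                visited.add(trial)
                history.append(("drop", removed, current))
                changed = True
        if not changed:
            break

    if not selected:
        selected = [best_single[0]]
        current = best_single[1]
        history.append(("fallback", selected[0], current))

    idx = np.array(sorted(selected))
    model = fit_lda(X[:, idx], labels, selected_features=idx)
    model.n_features_in = d
    return SelectionResult(selected=idx, model=model, score=current, history=history)
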