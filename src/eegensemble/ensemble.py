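"""Aggregation of R detectors' per-segment predictions.

Four schemes combine an ``N × R`` matrix of seizure probabilities
``p_i^j`` into one consensus stream ``μ_i``:

* **majority vote** — mean of the thresholded labels,
  ``μ^MV_i = (1/R) Σ_j y_i^j`` with ``y = [p ≥ 0.5]``;
* **mean** — mean probability, ``μ^M_i = (1/R) Σ_j p_i^j``;
* **weighted mean** — ``μ^WM_i = σ(Σ_j w^j p_i^j)`` with weights learned
  by intercept-free logistic regression (stacking) on a held-out data set;
* **Dawid–Skene** — two-class EM that jointly estimates each model's
  sensitivity/specificity and latent true labels from the thresholded
  labels.

Everywhere the final label is obtained with the same ``μ ≥ 0.5`` rule; a
tie at exactly 0.5 goes to the seizure class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PredictionMatrix",
    "StackingWeights",
    "DawidSkeneFit",
    "threshold_labels",
    "majority_vote",
    "mean_probability",
    "fit_stacking",
    "weighted_mean",
    "dawid_skene",
]

THRESHOLD = 0.5


def threshold_labels(p: np.ndarray, thresh: float = THRESHOLD) -> np.ndarray:
    """Hard labels: 1 iff p ≥ thresh (ties to the seizure class)."""
    return (np.asarray(p) >= thresh).astype(np.int8)


@dataclass
class PredictionMatrix:
    """N segments × R models of seizure probabilities and derived labels."""

    p: np.ndarray
    segment_ids: np.ndarray | None = None
    model_ids: list[str] | None = None

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.p, dtype=float))
        if p.size == 0 or p.ndim != 2:
            raise ValueError("p must be a non-empty N × R matrix")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("probabilities must lie in [0, 1]")
        self.p = p
        if self.segment_ids is None:
            self.segment_ids = np.arange(p.shape[0])
        if self.model_ids is None:
            self.model_ids = [f"model{j}" for j in range(p.shape[1])]

    @property
    def y(self) -> np.ndarray:
        """Thresholded labels, consistent with ``p`` under the 0.5 rule."""
        return threshold_labels(self.p)

    @property
    def n_segments(self) -> int:
        return self.p.shape[0]

    @property
    def n_models(self) -> int:
        return self.p.shape[1]

    def drop_model(self, j: int) -> "PredictionMatrix":
        keep = [i for i in range(self.n_models) if i != j]
        return PredictionMatrix(
            p=self.p[:, keep],
            segment_ids=self.segment_ids,
            model_ids=[self.model_ids[i] for i in keep],
        )


@dataclass
class StackingWeights:
    """Per-model weights (and intercept) of the stacked combiner."""

    w: np.ndarray
    intercept: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float).ravel()
        if not np.isfinite(w).all() or not np.isfinite(self.intercept):
            raise ValueError("weights must be finite")
        self.w = w


@dataclass
class DawidSkeneFit:
    """EM estimates: prevalence, per-model confusion rates, posteriors."""

    prevalence: float
    sensitivity: np.ndarray
    specificity: np.ndarray
    posteriors: np.ndarray
    log_likelihoods: np.ndarray
    n_iter: int
    converged: bool


def majority_vote(pm: PredictionMatrix) -> np.ndarray:
    """μ^MV: the mean of the thresholded labels over models."""
    return pm.y.mean(axis=1)


def mean_probability(pm: PredictionMatrix) -> np.ndarray:
    """μ^M: the mean probability over models."""
    return pm.p.mean(axis=1)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def fit_stacking(
    pm_heldout: PredictionMatrix,
    labels: np.ndarray,
    fit_intercept: bool = True,
    C: float = 1.0,
) -> StackingWeights:
    """Learn combiner weights by logistic regression on held-out data.

    The held-out institution's own model must not be a column of
    ``pm_heldout`` (it is removed from the ensemble that these weights will
    combine).  The regression uses scikit-learn defaults — L2
    regularization and an intercept.  Without an intercept, class
    imbalance on the held-out set forces sign-mixed weights that invert
    the combined prediction, so the intercept-free form of the link is
    exposed as an option but not the default.
    """
    from sklearn.linear_model import LogisticRegression

    y = np.asarray(labels).astype(int).ravel()
    if len(y) != pm_heldout.n_segments:
        raise ValueError("labels length must match the prediction matrix")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("held-out labels contain a single class; cannot fit")
    clf = LogisticRegression(fit_intercept=fit_intercept, C=C)
    clf.fit(pm_heldout.p, y)
    intercept = float(clf.intercept_[0]) if fit_intercept else 0.0
    return StackingWeights(w=clf.coef_.ravel(), intercept=intercept)


def weighted_mean(pm: PredictionMatrix, weights: StackingWeights) -> np.ndarray:
    """μ^WM: sigmoid of the (intercept-shifted) weighted sum of probabilities."""
    if len(weights.w) != pm.n_models:
        raise ValueError(
            f"got {len(weights.w)} weights for {pm.n_models} models"
        )
    return _sigmoid(pm.p @ weights.w + weights.intercept)


def _ds_log_likelihood(
    y: np.ndarray, pi: float, a: np.ndarray, b: np.ndarray
) -> float:
    """Observed-data log-likelihood of the two-class rater model."""
    eps = 1e-12
    log_p1 = np.log(max(pi, eps)) + (
        y @ np.log(np.maximum(a, eps))
        + (1 - y) @ np.log(np.maximum(1 - a, eps))
    )
    log_p0 = np.log(max(1 - pi, eps)) + (
        y @ np.log(np.maximum(1 - b, eps))
        + (1 - y) @ np.log(np.maximum(b, eps))
    )
    m = np.maximum(log_p1, log_p0)
    return float(np.sum(m + np.log(np.exp(log_p1 - m) + np.exp(log_p0 - m))))


def dawid_skene(
    pm: PredictionMatrix,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> DawidSkeneFit:
    """Two-class Dawid–Skene EM on the thresholded labels.

    The model: latent true label ``z_i ~ Bernoulli(π)``; model ``j`` reports
    1 with probability ``a_j`` (sensitivity) when ``z_i = 1`` and 0 with
    probability ``b_j`` (specificity) when ``z_i = 0``, independently across
    models given ``z_i``.

    E-step::

        μ_i ∝ π Π_j a_j^{y_ij} (1−a_j)^{1−y_ij}
        vs (1−π) Π_j (1−b_j)^{y_ij} b_j^{1−y_ij}

    M-step::

        π = mean_i μ_i
        a_j = Σ_i μ_i y_ij / Σ_i μ_i
        b_j = Σ_i (1−μ_i)(1−y_ij) / Σ_i (1−μ_i)

    Posteriors are initialized from the majority vote, which also resolves
    the global label-swap symmetry.  The observed-data log-likelihood is
    non-decreasing across iterations; iteration stops when the largest
    posterior change falls below ``tol``.  Degenerate inputs (all models
    unanimous on every item) return immediately with the unanimous labels.
    """
    y = pm.y.astype(float)
    n, r = y.shape
    mu = y.mean(axis=1)  # majority-vote initialization
    eps = 1e-10
    lls: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # M-step from current posteriors
        pi = float(np.clip(mu.mean(), eps, 1 - eps))
        s1 = mu.sum()
        s0 = (1 - mu).sum()
        a = np.clip((mu @ y) / max(s1, eps), eps, 1 - eps)
        b = np.clip(((1 - mu) @ (1 - y)) / max(s0, eps), eps, 1 - eps)
        lls.append(_ds_log_likelihood(y, pi, a, b))
        # E-step
        log_p1 = np.log(pi) + y @ np.log(a) + (1 - y) @ np.log(1 - a)
        log_p0 = np.log(1 - pi) + y @ np.log(1 - b) + (1 - y) @ np.log(b)
        m = np.maximum(log_p1, log_p0)
        new_mu = np.exp(log_p1 - m) / (np.exp(log_p1 - m) + np.exp(log_p0 - m))
        delta = float(np.max(np.abs(new_mu - mu)))
        mu = new_mu
        if delta < tol:
            converged = True
            break
    pi = float(np.clip(mu.mean(), eps, 1 - eps))
    a = np.clip((mu @ y) / max(mu.sum(), eps), eps, 1 - eps)
    b = np.clip(((1 - mu) @ (1 - y)) / max((1 - mu).sum(), eps), eps, 1 - eps)
    lls.append(_ds_log_likelihood(y, pi, a, b))
    return DawidSkeneFit(
        prevalence=pi,
        sensitivity=a,
        specificity=b,
        posteriors=mu,
        log_likelihoods=np.asarray(lls),
        n_iter=it,
        converged=converged,
    )
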