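"""Quadratic discriminant analysis on decomposition scores.

Each class k is summarized by its training mean x̄_k, unbiased covariance
Σ_k, and prior π_k = n_k / n.  A sample x is assigned to the class minimizing
the discriminant

    Q_k(x) = (x - x̄_k)ᵀ Σ_k⁻¹ (x - x̄_k) + ln|Σ_k| - 2 ln π_k,

i.e. squared Mahalanobis distance plus log-determinant and log-prior
penalties.  Predictions are invariant under any invertible linear
re-parameterization of the score space (every Q_k shifts by the same
2 ln|det M|), so the PARAFAC/Tucker3 scale indeterminacy cannot affect them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh

_RIDGE_TRIGGER = 1e-10  # eigenvalue ratio below which a ridge is added


@dataclass
class QdaModel:
    classes: tuple[str, ...]
    means: np.ndarray        # (n_classes, dim)
    covariances: np.ndarray  # (n_classes, dim, dim)
    priors: np.ndarray       # (n_classes,)
    n_train: np.ndarray      # per-class counts
    regularized: list[str] = field(default_factory=list)  # classes that needed a ridge

    @property
    def dim(self) -> int:
        return self.means.shape[1]


@dataclass
class QdaScores:
    """Discriminant values Q (samples x classes) and hard predictions.

    Predicted label is the argmin over classes; ties go to the first class in
    the model's declared order.
    """

    classes: tuple[str, ...]
    Q: np.ndarray
    predicted: list[str]


def qda_fit(scores: np.ndarray, labels, classes: tuple[str, ...] | None = None) -> QdaModel:
    """Per-class means, unbiased covariances, and empirical priors.

    Requires every declared class to be present with more samples than score
    dimensions (else the covariance is singular).  If a covariance's smallest
    eigenvalue falls below 1e-10 of its largest, a small ridge is added and
    the class recorded in ``model.regularized``.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2:
        raise ValueError("scores must be 2-D (samples x variables)")
    y = np.asarray([str(l) for l in labels])
    if classes is None:
        classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n, dim = X.shape
    means = np.zeros((len(classes), dim))
    covs = np.zeros((len(classes), dim, dim))
    counts = np.zeros(len(classes), dtype=int)
    regularized = []
    for c, cls in enumerate(classes):
        sel = y == cls
        nk = int(sel.sum())
        if nk == 0:
            raise ValueError(f"class {cls!r} absent from labels")
        if nk <= dim:
            raise ValueError(f"class {cls!r} has {nk} samples <= {dim} variables: covariance singular")
        counts[c] = nk
        means[c] = X[sel].mean(axis=0)
        d = X[sel] - means[c]
        covs[c] = d.T @ d / (nk - 1)
        w = eigh(covs[c], eigvals_only=True)
        if w[0] < _RIDGE_TRIGGER * w[-1]:
            covs[c] += (_RIDGE_TRIGGER * w[-1]) * np.eye(dim)
            regularized.append(cls)
            w = eigh(covs[c], eigvals_only=True)
        if w[0] <= 0:
            raise ValueError(f"class {cls!r}: covariance singular after regularization")
    priors = counts / n
    return QdaModel(classes=classes, means=means, covariances=covs,
                    priors=priors, n_train=counts, regularized=regularized)


def qda_score(model: QdaModel, x: np.ndarray) -> QdaScores:
    """Evaluate Q for each sample and class; lowest Q wins."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != model.dim:
        raise ValueError(f"dimension {X.shape[1]} does not match model ({model.dim})")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite input")
    Q = np.zeros((X.shape[0], len(model.classes)))
    for c in range(len(model.classes)):
        chol = cho_factor(model.covariances[c], lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
        d = X - model.means[c]
        maha = np.sum(d * cho_solve(chol, d.T).T, axis=1)
        Q[:, c] = maha + logdet - 2.0 * np.log(model.priors[c])
    pred = [model.classes[i] for i in np.argmin(Q, axis=1)]  # argmin: first class wins ties
    return QdaScores(classes=model.classes, Q=Q, predicted=pred)
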