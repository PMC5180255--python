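"""Classic perceptron readout and linear-separability certificates.

The perceptron is the probe of problem *order*: it converges in finite time
on any linearly separable (first-order) dataset and cycles forever on
second-order problems such as XOR.  On the cross-arm stimuli this yields the
computational dissociation: the linear task (right-arm height) is separable
in pixel space and in V1 feature space, while the symmetry task is not — its
two class means coincide exactly, which is a sufficient condition for
non-separability (any separating hyperplane would have to put the shared
mean on both of its sides).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_X_y, check_array

__all__ = ["Perceptron", "PerceptronState", "train", "separability_certificate"]


@dataclass
class PerceptronState:
    """Summary of one training run (weights include the trailing bias term)."""

    weights: np.ndarray
    epoch_history: list[float]
    converged: bool
    epochs_run: int


class Perceptron(BaseEstimator, ClassifierMixin):
    """Rosenblatt perceptron with unit learning rate and a bias term.

    Labels are {+1, -1}.  Weights start at zero; a misclassified example is
    added to (or subtracted from) the weight vector.  Training stops early at
    the first epoch with zero updates, which certifies separation of the
    training set.  Activation exactly 0 predicts the distractor class (-1),
    so the all-zero initial weights make errors and learn.

    Parameters
    ----------
    max_epochs : int
        Epoch budget; the classic convergence theorem guarantees early stop
        on separable data for a large enough budget.
    shuffle : bool
        Reshuffle presentation order each epoch (seeded); the converged /
        not-converged outcome is order-independent, only ``epochs_run_``
        may change.
    random_init : bool
        Draw small random initial weights instead of zeros (robustness runs).
    random_state : int or None
        Seed for shuffling / random init.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
    intercept_ : float
    epoch_history_ : list of per-epoch training accuracy on the full set.
    converged_ : bool
    epochs_run_ : int
    """

    def __init__(self, max_epochs: int = 20, shuffle: bool = False,
                 random_init: bool = False, random_state: int | None = None):
        self.max_epochs = max_epochs
        self.shuffle = shuffle
        self.random_init = random_init
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        y = np.asarray(y)
        labels = np.unique(y)
        if not np.isin(labels, (-1, 1)).all():
            raise ValueError("labels must be in {+1, -1}")
        if labels.size < 2:
            raise ValueError("training data must contain both classes")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")

        n, d = X.shape
        Xb = np.hstack([X, np.ones((n, 1))])  # bias as last column
        rng = np.random.default_rng(self.random_state)
        w = rng.normal(scale=1e-3, size=d + 1) if self.random_init else np.zeros(d + 1)

        history: list[float] = []
        converged = False
        order = np.arange(n)
        for _epoch in range(self.max_epochs):
            if self.shuffle:
                rng.shuffle(order)
            updates = 0
            for i in order:
                pred = 1.0 if Xb[i] @ w > 0 else -1.0
                if pred != y[i]:
                    w = w + y[i] * Xb[i]
                    updates += 1
            history.append(float(np.mean(np.where(Xb @ w > 0, 1.0, -1.0) == y)))
            if updates == 0:
                converged = True
                break
        self.coef_ = w[:-1]
        self.intercept_ = float(w[-1])
        self.epoch_history_ = history
        self.converged_ = converged
        self.epochs_run_ = len(history)
        self.classes_ = np.array([-1, 1])
        return self

    def decision_function(self, X):
        X = check_array(X, dtype=np.float64)
        return X @ self.coef_ + self.intercept_

    def predict(self, X):
        return np.where(self.decision_function(X) > 0, 1, -1)

    @property
    def state_(self) -> PerceptronState:
        return PerceptronState(
            weights=np.append(self.coef_, self.intercept_),
            epoch_history=self.epoch_history_,
            converged=self.converged_,
            epochs_run=self.epochs_run_,
        )


def train(X, y, max_epochs: int = 20, seed: int | None = None,
          shuffle: bool = False) -> PerceptronState:
    """Train a perceptron and return its run summary."""
    clf = Perceptron(max_epochs=max_epochs, shuffle=shuffle, random_state=seed).fit(X, y)
    return clf.state_


def separability_certificate(X, y, max_epochs: int = 1000) -> str:
    """Classify a labeled dataset's separability status.

    Returns one of:

    * ``"non-separable-by-mean-collision"`` — the two class means are exactly
      equal vectors, a sufficient condition for linear non-separability.
    * ``"separable"`` — a perceptron run reached a zero-error epoch (its
      final weights are a separating hyperplane, which is the certificate).
    * ``"unknown"`` — neither certificate was obtained.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    pos, neg = X[y == 1], X[y == -1]
    if len(pos) == 0 or len(neg) == 0:
        return "unknown"
    if pos.shape[1] == neg.shape[1] and np.array_equal(pos.mean(axis=0), neg.mean(axis=0)):
        return "non-separable-by-mean-collision"
    state = train(X, y, max_epochs=max_epochs)
    if state.converged:
        return "separable"
    return "unknown"
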