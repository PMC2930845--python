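"""Thin wrapper over an RBF support-vector machine.

Both the subsequence-profile and the peptide-statistics classifiers feed
fixed-dimensional vectors to an SVM; this wrapper fixes the shared
contract: a real-valued decision function whose positive side is the
positive class and whose natural threshold is 0.  Probability calibration
is *not* done here — it is the job of threshold relaxation downstream.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import SVC

from .errors import FitError


class MarginClassifier:
    def __init__(self, C: float = 1.0, gamma: str | float = "scale",
                 kernel: str = "rbf", random_state: int = 0):
        self._svc = SVC(C=C, gamma=gamma, kernel=kernel, random_state=random_state)
        self._fitted = False

    def fit(self, vectors, labels) -> "MarginClassifier":
        X = np.asarray(vectors, dtype=float)
        y = np.asarray(labels, dtype=bool)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("vectors must be 2-D and aligned with labels")
        if y.all() or not y.any():
            raise FitError("training set contains a single class")
        self._svc.fit(X, y.astype(int))
        self._fitted = True
        return self

    def decision_values(self, vectors) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("fit() must be called first")
        return self._svc.decision_function(np.asarray(vectors, dtype=float))


def fit_margin_classifier(vectors, labels, **kwargs) -> MarginClassifier:
    return MarginClassifier(**kwargs).fit(vectors, labels)


def decision_value(model: MarginClassifier, vector) -> float:
    return float(model.decision_values(np.atleast_2d(np.asarray(vector, float)))[0])
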