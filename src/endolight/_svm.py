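"""Thin linear soft-margin SVM wrapper.

The searchlight fits tens of thousands of small SVMs (tens of samples, at
most a few hundred features), and the per-call validation overhead of the
high-level estimator API dominates the actual SMO solve at that size.  This
wrapper calls scikit-learn's bundled libsvm bindings directly with the same
label encoding the high-level estimator uses, so predictions are identical
to ``sklearn.svm.SVC(kernel="linear", C=C)`` (asserted in the test suite)
at a fraction of the per-fit cost.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import _libsvm

_libsvm.set_verbosity_wrap(0)


class LinearSVM:
    """Two-class maximal-margin classifier g(x) = w·x + w0 with hinge slack.

    Parameters
    ----------
    C : float
        Soft-margin penalty. Must be positive.
    tol : float
        SMO stopping tolerance (libsvm default).
    """

    def __init__(self, C: float = 1.0, tol: float = 1e-3):
        if C <= 0:
            raise ValueError(f"C must be positive, got {C}")
        self.C = float(C)
        self.tol = float(tol)
        self._model = None
        self.classes_ = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearSVM":
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(
                f"need exactly two classes to fit, got {classes.tolist()}"
            )
        y_enc = np.ascontiguousarray(
            np.searchsorted(classes, y), dtype=np.float64
        )
        self.classes_ = classes
        self._model = _libsvm.fit(
            X, y_enc, svm_type=0, kernel="linear", C=self.C, tol=self.tol
        )
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("predict() before fit()")
        X = np.ascontiguousarray(X, dtype=np.float64)
        idx = _libsvm.predict(
            X, *self._model[:7], svm_type=0, kernel="linear"
        ).astype(np.intp)
        return self.classes_[idx]
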