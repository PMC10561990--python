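"""Independent naive re-implementation of the stacking pipeline.

Used as a test oracle only: it literally loops over the training and
prediction steps with hand-written deterministic learners (per-fold fits,
out-of-fold collection, pooled ordinary-least-squares meta-fit, per-learner
averaging at prediction), sharing no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def _fit_mean(X, y):
    c = float(np.mean(y))
    return lambda Xn: np.full(len(Xn), c)


def _fit_median(X, y):
    c = float(np.median(y))
    return lambda Xn: np.full(len(Xn), c)


def _fit_ols(X, y):
    A = np.column_stack([np.ones(len(X)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return lambda Xn: np.column_stack([np.ones(len(Xn)), Xn]) @ coef


NAIVE_LEARNERS = {
    "dummy_mean": _fit_mean,
    "dummy_median": _fit_median,
    "linear": _fit_ols,
}


def naive_stack_predict(X, Y, fold_of_sample, learner_names, newX):
    """Hand-executed stacking: CV base fits, pooled OLS meta, averaged fold
    models at prediction.  Returns (out-of-fold table, final predictions)."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    newX = np.asarray(newX, float)
    fold_of_sample = np.asarray(fold_of_sample)
    nfold = int(fold_of_sample.max()) + 1
    n, L = len(Y), len(learner_names)

    oof = np.empty((n, L))
    models = {}
    for f in range(nfold):
        tr = np.flatnonzero(fold_of_sample != f)
        te = np.flatnonzero(fold_of_sample == f)
        for l, name in enumerate(learner_names):
            predict = NAIVE_LEARNERS[name](X[tr], Y[tr])
            models[(f, l)] = predict
            oof[te, l] = predict(X[te])

    A = np.column_stack([np.ones(n), oof])
    meta_coef, *_ = np.linalg.lstsq(A, Y, rcond=None)

    agg = np.empty((len(newX), L))
    for l in range(L):
        agg[:, l] = np.mean([models[(f, l)](newX) for f in range(nfold)], axis=0)
    final = np.column_stack([np.ones(len(newX)), agg]) @ meta_coef
    return oof, final
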