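"""Accuracy metrics: Pearson correlation for regression, Cohen's kappa for
classification.

Both raise :class:`~stackle.exceptions.UndefinedMetricError` on degenerate
inputs (zero-variance vectors; identical constant labels) rather than
returning a silent 0 or NaN.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from .exceptions import UndefinedMetricError


def pearson_correlation(pred, truth) -> float:
    """Product-moment correlation between predictions and true values."""
    pred = np.asarray(pred, dtype=float).reshape(-1)
    truth = np.asarray(truth, dtype=float).reshape(-1)
    if len(pred) != len(truth):
        raise UndefinedMetricError(
            f"length mismatch: pred has {len(pred)}, truth has {len(truth)}"
        )
    if len(pred) < 3:
        raise UndefinedMetricError("pearson correlation needs at least 3 pairs")
    # ptp, not std: a constant vector can have std ~1e-17 from summation rounding
    if np.ptp(pred) == 0 or np.ptp(truth) == 0:
        raise UndefinedMetricError(
            "pearson correlation is undefined for a zero-variance vector"
        )
    return float(stats.pearsonr(pred, truth).statistic)


def cohen_kappa(pred, truth) -> float:
    """Chance-corrected agreement κ = (p_o − p_e)/(1 − p_e).

    The label universe is the union of labels observed in either vector, and
    chance agreement p_e comes from the two marginal label frequencies.
    """
    pred = np.asarray(pred, dtype=object).reshape(-1)
    truth = np.asarray(truth, dtype=object).reshape(-1)
    if len(pred) != len(truth):
        raise UndefinedMetricError(
            f"length mismatch: pred has {len(pred)}, truth has {len(truth)}"
        )
    if len(pred) == 0:
        raise UndefinedMetricError("kappa is undefined for empty vectors")
    labels = sorted(set(map(str, pred)) | set(map(str, truth)))
    if len(labels) == 1:
        # both vectors the same constant label: p_e = 1
        raise UndefinedMetricError(
            "kappa is undefined when both vectors are the same constant label"
        )
    return float(cohen_kappa_score(pred.astype(str), truth.astype(str), labels=labels))
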