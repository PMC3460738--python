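"""Single-feature ROC screening.

Before any multivariate modelling, each texture feature is screened on its
own: a decision threshold is swept from the feature's minimum to its maximum
in fixed increments, sensitivity TP/(TP+FN) and specificity TN/(FP+TN) are
recorded at each threshold, and the area under the resulting ROC curve is
integrated by the trapezoid rule.  The voting direction (whether large
values indicate disease) differs between features, so it is chosen
automatically to make AUC ≥ 0.5 and reported alongside the curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateLabelsError(ValueError):
    """Both classes must be present to compute an ROC curve."""


@dataclass
class RocCurve:
    """Threshold sweep of one feature.

    ``orientation`` is +1 when values at or above a threshold vote
    "disease", −1 when values at or below it do.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    orientation: int


def _sweep(values, labels, thresholds, orientation):
    pos = labels == 1
    neg = ~pos
    n_pos = pos.sum()
    n_neg = neg.sum()
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for k, t in enumerate(thresholds):
        pred = values >= t if orientation > 0 else values <= t
        sens[k] = (pred & pos).sum() / n_pos
        spec[k] = (~pred & neg).sum() / n_neg
    return sens, spec


def _trapezoid_auc(sens, spec):
    # Anchor the curve at (0,0) and (1,1) so the sweep endpoints do not
    # truncate the integral, then integrate over (1-specificity, sensitivity).
    fpr = np.concatenate([[0.0], 1.0 - spec, [1.0]])
    tpr = np.concatenate([[0.0], sens, [1.0]])
    order = np.lexsort((tpr, fpr))
    return float(np.trapezoid(tpr[order], fpr[order]))


def roc_for_feature(values, labels, steps: int = 10) -> RocCurve:
    """ROC curve of one feature over an evenly spaced threshold grid.

    Thresholds sit at ``min + k·(max−min)/steps`` for k = 0..steps (11
    points at the default 10 % increments).  The orientation is flipped if
    the ≥-direction gives AUC < 0.5, so the reported AUC is always ≥ 0.5.

    Raises
    ------
    DegenerateLabelsError
        If only one class is present.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-D arrays")
    if len(np.unique(labels)) < 2:
        raise DegenerateLabelsError("both classes must be present")
    vmin, vmax = values.min(), values.max()
    thresholds = vmin + (vmax - vmin) * np.arange(steps + 1) / steps
    sens, spec = _sweep(values, labels, thresholds, +1)
    auc = _trapezoid_auc(sens, spec)
    orientation = 1
    if auc < 0.5:
        orientation = -1
        sens, spec = _sweep(values, labels, thresholds, -1)
        auc = _trapezoid_auc(sens, spec)
    return RocCurve(thresholds, sens, spec, auc, orientation)


def screen_features(X, y, steps: int = 10, feature_names=None):
    """Per-feature AUC table for a samples × features matrix.

    Returns a DataFrame with columns ``feature``, ``auc``, ``orientation``,
    one row per column of ``X``.
    """
    import pandas as pd

    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"w{j + 1}" for j in range(X.shape[1])]
    rows = []
    for j, name in enumerate(feature_names):
        curve = roc_for_feature(X[:, j], y, steps=steps)
        rows.append({"feature": name, "auc": curve.auc, "orientation": curve.orientation})
    return pd.DataFrame(rows)
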