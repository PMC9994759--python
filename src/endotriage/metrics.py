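"""Evaluation metrics: confusion matrices, triage metrics, Cohen's kappa.

Confusion matrices are reported both as counts and normalized over the true
category (each row divided by its support).  Interobserver agreement uses
the unweighted Cohen's kappa, averaged arithmetically over all rater pairs
when more than two raters scored the same slides.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .slide_model import CLASS_ORDER


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (K, K), rows = true class, columns = predicted
    classes: tuple[str, ...]

    @property
    def normalized(self) -> np.ndarray:
        """Rows divided by row sums; rows with zero support are NaN."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, self.counts / sums, np.nan)

    def to_frame(self, normalized: bool = False) -> pd.DataFrame:
        data = self.normalized if normalized else self.counts
        return pd.DataFrame(data, index=list(self.classes), columns=list(self.classes))


def confusion(preds, truth, classes: tuple[str, ...] = CLASS_ORDER) -> ConfusionMatrix:
    preds, truth = list(preds), list(truth)
    if len(preds) != len(truth):
        raise ValueError("prediction and truth lists differ in length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for p, t in zip(preds, truth):
        if p not in index or t not in index:
            raise ValueError(f"label outside class list: {p!r} / {t!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(classes))


def triage_metrics(cm: ConfusionMatrix) -> tuple[float, dict[str, float]]:
    """Overall accuracy and per-class sensitivity (recall).

    A class with zero support has undefined sensitivity, reported as NaN
    with a warning rather than 0.
    """
    total = cm.counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = float(np.trace(cm.counts) / total)
    sensitivity = {}
    for i, cls in enumerate(cm.classes):
        support = cm.counts[i].sum()
        if support == 0:
            warnings.warn(f"class {cls!r} has zero support; sensitivity undefined",
                          stacklevel=2)
            sensitivity[cls] = float("nan")
        else:
            sensitivity[cls] = float(cm.counts[i, i] / support)
    return accuracy, sensitivity


def cohen_kappa(a, b) -> float:
    """Unweighted Cohen's kappa between two raters.

    When both raters are constant and identical, chance agreement is 1 and
    kappa is undefined; it is reported as 1 with a warning since agreement
    is perfect.
    """
    a, b = list(a), list(b)
    if len(a) != len(b):
        raise ValueError("rater lists differ in length")
    if not a:
        raise ValueError("empty rater lists")
    if len(set(a)) == 1 and set(a) == set(b):
        warnings.warn("both raters constant and equal; kappa defined as 1",
                      stacklevel=2)
        return 1.0
    return float(cohen_kappa_score(a, b))


@dataclass
class KappaReport:
    pairwise: dict[tuple[int, int], float]
    mean: float


def mean_pairwise_kappa(raters: list[list]) -> KappaReport:
    """Kappa for every rater pair and the arithmetic mean over pairs."""
    if len(raters) < 2:
        raise ValueError("at least two raters required")
    pairwise = {}
    for i, j in itertools.combinations(range(len(raters)), 2):
        pairwise[(i, j)] = cohen_kappa(raters[i], raters[j])
    return KappaReport(pairwise, float(np.mean(list(pairwise.values()))))
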