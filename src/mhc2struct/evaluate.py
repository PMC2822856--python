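"""Binder classification, ROC/AUC, Hanley-McNeil standard error, Pearson r.

Peptides are classified as binders when their experimental IC50 is strictly
below a threshold (default 1000 nM; exactly at threshold = non-binder). The
ROC curve is swept from the highest to the lowest prediction score, and the
AUC equals the Mann-Whitney statistic with ties credited 0.5 (identical to
the trapezoidal area under the tie-aware curve).

The closed-form standard error of the AUC (Hanley & McNeil) is

    SE = sqrt([A(1-A) + (n_pos-1)(Q1 - A^2) + (n_neg-1)(Q2 - A^2)]
              / (n_pos * n_neg)),
    Q1 = A / (2 - A),   Q2 = 2 A^2 / (1 + A).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InputError

DEFAULT_IC50_THRESHOLD = 1000.0  # nM
DEFAULT_MAX_IC50 = 50000.0  # nM, affinity-transform ceiling


@dataclass(frozen=True)
class BindingRecord:
    peptide: str
    ic50: float  # nM
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.ic50 > 0:
            raise InputError(f"IC50 must be positive, got {self.ic50}")

    @property
    def label(self) -> str:
        return classify(self.ic50)


@dataclass
class EvaluationResult:
    roc_points: np.ndarray  # (k, 2) of (fpr, tpr), from (0,0) to (1,1)
    auc: float
    n_pos: int
    n_neg: int
    se: float | None = None
    q1: float | None = None
    q2: float | None = None
    pcc: float | None = None


def classify(ic50: float, threshold: float = DEFAULT_IC50_THRESHOLD) -> str:
    """'binder' iff IC50 < threshold (strict); at-threshold is 'non-binder'."""
    if not ic50 > 0:
        raise InputError(f"IC50 must be positive, got {ic50}")
    return "binder" if ic50 < threshold else "non-binder"


def roc_auc(scores, labels) -> EvaluationResult:
    """ROC curve and AUC; higher score = predicted binder.

    ``labels`` are truthy for binders. AUC is the Mann-Whitney statistic
    (tied scores credited 0.5), computed from midranks.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([bool(l) if not isinstance(l, str) else l == "binder" for l in labels])
    if scores.shape != y.shape or scores.ndim != 1:
        raise InputError("scores and labels must be equal-length 1-d sequences")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("both classes required (binders and non-binders)")

    ranks = stats.rankdata(scores)  # midranks handle ties
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # tie-aware ROC: step through distinct thresholds from high to low
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_y = y[order]
    tps = np.cumsum(sorted_y)
    fps = np.cumsum(~sorted_y)
    distinct = np.nonzero(np.diff(sorted_scores))[0]
    idx = np.r_[distinct, len(scores) - 1]
    points = np.column_stack([fps[idx] / n_neg, tps[idx] / n_pos])
    points = np.vstack([[0.0, 0.0], points])

    return EvaluationResult(roc_points=points, auc=float(auc), n_pos=n_pos, n_neg=n_neg)


def hanley_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil closed-form standard error of an AUC."""
    if not 0.0 <= auc <= 1.0:
        raise InputError(f"AUC must be in [0, 1], got {auc}")
    if n_pos < 1 or n_neg < 1:
        raise InputError("n_pos and n_neg must both be at least 1")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def pearson(x, y) -> float:
    """Product-moment correlation; requires length >= 3 and non-zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length 1-d sequences")
    if len(x) < 3:
        raise InputError("pearson requires at least 3 points")
    if np.var(x) == 0 or np.var(y) == 0:
        raise InputError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def ic50_to_affinity(ic50, max_ic50: float = DEFAULT_MAX_IC50) -> np.ndarray:
    """Log-affinity transform 1 - ln(IC50)/ln(max_ic50), clamped to [0, 1]."""
    ic50 = np.asarray(ic50, dtype=float)
    if np.any(ic50 <= 0):
        raise InputError("IC50 values must be positive")
    return np.clip(1.0 - np.log(ic50) / np.log(max_ic50), 0.0, 1.0)


def evaluate_predictions(
    records: list[BindingRecord],
    threshold: float = DEFAULT_IC50_THRESHOLD,
    with_pcc: bool = True,
) -> EvaluationResult:
    """Full evaluation of scored binding records.

    Computes the ROC/AUC for binder discrimination at the IC50 threshold,
    the Hanley-McNeil standard error, and (optionally) the Pearson
    correlation between scores and log-transformed affinities.
    """
    if any(rec.score is None for rec in records):
        raise InputError("all records need a prediction score")
    scores = [rec.score for rec in records]
    labels = [classify(rec.ic50, threshold) for rec in records]
    result = roc_auc(scores, labels)
    result.se = hanley_se(result.auc, result.n_pos, result.n_neg)
    result.q1 = result.auc / (2.0 - result.auc)
    result.q2 = 2.0 * result.auc**2 / (1.0 + result.auc)
    if with_pcc:
        affinities = ic50_to_affinity([rec.ic50 for rec in records])
        try:
            result.pcc = pearson(scores, affinities)
        except InputError:
            result.pcc = None
    return result
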