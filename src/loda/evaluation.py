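"""Classification accuracy and parameter-recovery summaries.

ROC construction follows the convention used throughout: a patient is called
positive iff their positive-group probability strictly exceeds the cutoff,
thresholds run over every distinct score plus -inf/+inf sentinels, and the
operating cutoff is the point closest (in Euclidean distance) to the
top-left corner of the curve.  AUC is the trapezoidal area under the ROC,
which on these threshold sets equals the Mann-Whitney concordance
probability with ties counted half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import (
    DegenerateInputError,
    GroupModelParameters,
    MarkerSpec,
    StructuralError,
    parameter_vector,
)

__all__ = [
    "ClassificationMetrics",
    "roc_curve",
    "auc_score",
    "optimal_cutoff",
    "metrics_at_cutoff",
    "recovery_summary",
]


@dataclass(frozen=True)
class ClassificationMetrics:
    """Accuracy measures at one operating cutoff.

    ``ppv``/``npv`` are NaN when no patient is called positive/negative
    (undefined denominators are reported as missing, not zero).
    """

    cutoff: float
    sensitivity: float
    specificity: float
    pcc: float
    auc: float
    ppv: float
    npv: float

    def as_dict(self) -> dict[str, float]:
        return {
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "pcc": self.pcc,
            "auc": self.auc,
            "ppv": self.ppv,
            "npv": self.npv,
        }


def _check_two_class(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise StructuralError("scores and labels must be 1-d arrays of equal length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise StructuralError("labels must be binary (0 = negative, 1 = positive)")
    if labels.min() == labels.max():
        raise DegenerateInputError("both classes must be present")
    return scores, labels


def roc_curve(scores, labels) -> pd.DataFrame:
    """Receiver operating characteristic curve.

    Returns (cutoff, sensitivity, specificity) triples, ordered by cutoff,
    at every distinct score plus -inf and +inf sentinels, with "positive iff
    score > cutoff".
    """
    scores, labels = _check_two_class(scores, labels)
    cuts = np.concatenate(([-np.inf], np.unique(scores), [np.inf]))
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    sens = np.array([(scores[labels == 1] > c).sum() / n_pos for c in cuts])
    spec = np.array([(scores[labels == 0] <= c).sum() / n_neg for c in cuts])
    return pd.DataFrame({"cutoff": cuts, "sensitivity": sens, "specificity": spec})


def optimal_cutoff(roc: pd.DataFrame) -> float:
    """Cutoff of the ROC point closest to the top-left corner (0, 1).

    Distance is Euclidean in (1 - sensitivity, 1 - specificity); ties go to
    the smaller cutoff.
    """
    if len(roc) == 0:
        raise DegenerateInputError("empty ROC curve")
    d2 = (1.0 - roc["sensitivity"].to_numpy()) ** 2 + (
        1.0 - roc["specificity"].to_numpy()
    ) ** 2
    order = np.argsort(roc["cutoff"].to_numpy(), kind="stable")
    best = order[np.argmin(d2[order])]
    return float(roc["cutoff"].iloc[best])


def auc_score(scores, labels) -> float:
    """Trapezoidal area under the ROC curve."""
    roc = roc_curve(scores, labels)
    fpr = 1.0 - roc["specificity"].to_numpy()
    tpr = roc["sensitivity"].to_numpy()
    order = np.lexsort((tpr, fpr))  # traverse ties in TPR order too
    return float(abs(np.trapezoid(tpr[order], fpr[order])))


def metrics_at_cutoff(scores, labels, cutoff: float) -> ClassificationMetrics:
    """Confusion-matrix accuracy measures at a fixed cutoff, plus AUC."""
    scores, labels = _check_two_class(scores, labels)
    called_pos = scores > cutoff
    tp = int(np.sum(called_pos & (labels == 1)))
    fp = int(np.sum(called_pos & (labels == 0)))
    fn = int(np.sum(~called_pos & (labels == 1)))
    tn = int(np.sum(~called_pos & (labels == 0)))
    return ClassificationMetrics(
        cutoff=float(cutoff),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        pcc=(tp + tn) / labels.size,
        auc=auc_score(scores, labels),
        ppv=tp / (tp + fp) if (tp + fp) else float("nan"),
        npv=tn / (tn + fn) if (tn + fn) else float("nan"),
    )


def recovery_summary(
    replicate_summaries: list[pd.DataFrame],
    truth: GroupModelParameters | dict,
    specs: list[MarkerSpec] | None = None,
) -> pd.DataFrame:
    """Parameter recovery across replicated fits.

    ``replicate_summaries`` are posterior summaries (one per replicate, as
    produced by ``posterior_summary``: columns mean/hpd_low/hpd_high/sd
    indexed by parameter).  For every parameter the table reports the truth,
    the average posterior mean, the across-replicate SD of the posterior
    means, bias, MSE and the coverage of the HPD intervals.
    """
    if len(replicate_summaries) == 0:
        raise StructuralError("at least one replicate summary is required")
    if isinstance(truth, GroupModelParameters):
        if specs is None:
            raise StructuralError("marker specs are required to flatten the truth")
        truth = parameter_vector(truth, specs)
    names = list(replicate_summaries[0].index)
    for i, summ in enumerate(replicate_summaries):
        if list(summ.index) != names:
            raise StructuralError(f"replicate {i}: parameter names do not match")
    missing = [n for n in names if n not in truth]
    if missing:
        raise StructuralError(f"no true value for parameters: {missing}")
    rows = []
    for name in names:
        t = float(truth[name])
        means = np.array([s.loc[name, "mean"] for s in replicate_summaries])
        covered = np.array(
            [
                s.loc[name, "hpd_low"] <= t <= s.loc[name, "hpd_high"]
                for s in replicate_summaries
            ]
        )
        rows.append(
            {
                "parameter": name,
                "truth": t,
                "mean": float(means.mean()),
                "sd": float(means.std(ddof=1)) if means.size > 1 else 0.0,
                "bias": float(means.mean() - t),
                "mse": float(((means - t) ** 2).mean()),
                "coverage": float(covered.mean()),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
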