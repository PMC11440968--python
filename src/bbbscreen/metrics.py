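"""Binary-classification statistics for screening evaluation.

Ten statistics over a 2×2 confusion table: accuracy (ACC), error rate
(ER = 1 − ACC), sensitivity (Se), specificity (Sp), false negative and
false positive rates (FNR = 1 − Se, FPR = 1 − Sp), positive and negative
predictive values (PPV, NPV), Matthews correlation coefficient (MCC, the
phi coefficient of the table) and the corrected classification rate
(CCR = (Se + Sp)/2). MCC and CCR are the statistics of choice for the
imbalanced cohorts this package screens (many more successful than
unsuccessful tracers).

Zero-denominator conventions: a ratio whose denominator is zero is
reported as ``None`` and its name recorded in ``undefined`` — it is never
silently coerced to 0 or NaN. MCC with a zero marginal is reported as 0.0
(the standard convention) and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

from .errors import ValidationError
from .profiles import Label
from .rules import Classification

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "metrics", "percent"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValidationError(f"{name} must be a non-negative int, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def p(self) -> int:
        """Actual positives."""
        return self.tp + self.fn

    @property
    def neg(self) -> int:
        """Actual negatives."""
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricsReport:
    counts: ConfusionCounts
    acc: Optional[float]
    er: Optional[float]
    se: Optional[float]
    sp: Optional[float]
    fnr: Optional[float]
    fpr: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    mcc: Optional[float]
    ccr: Optional[float]
    undefined: Tuple[str, ...] = ()

    def as_dict(self) -> Dict[str, Optional[float]]:
        c = self.counts
        out = {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn, "n": c.n}
        for name in ("acc", "er", "se", "sp", "fnr", "fpr", "ppv", "npv", "mcc", "ccr"):
            out[name] = getattr(self, name)
        out["undefined"] = list(self.undefined)
        return out


def confusion(
    predicted: Sequence[Classification],
    labels: Sequence[Label],
) -> ConfusionCounts:
    """Tally a confusion table; successful tracer = positive class.

    TP: successful predicted CNS+; TN: unsuccessful predicted CNS−.
    Lengths must match and every record must be labeled and carry a
    determinate CNS+/CNS− prediction.
    """
    if len(predicted) != len(labels):
        raise ValidationError(
            f"length mismatch: {len(predicted)} predictions vs {len(labels)} labels"
        )
    if len(predicted) == 0:
        raise ValidationError("empty input")
    tp = fp = tn = fn = 0
    for pred, lab in zip(predicted, labels):
        if lab is Label.UNLABELED or lab is None:
            raise ValidationError("unlabeled record in confusion input")
        if pred not in (Classification.CNS_PLUS, Classification.CNS_MINUS):
            raise ValidationError(f"indeterminate prediction {pred!r}")
        positive = lab is Label.SUCCESSFUL
        predicted_plus = pred is Classification.CNS_PLUS
        if positive and predicted_plus:
            tp += 1
        elif positive:
            fn += 1
        elif predicted_plus:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int):
    return num / den if den else None


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Compute the full statistics suite from confusion counts."""
    if c.n == 0:
        raise ValidationError("cannot compute metrics on zero counts")
    undefined = []

    acc = (c.tp + c.tn) / c.n
    er = (c.fp + c.fn) / c.n
    se = _ratio(c.tp, c.p)
    sp = _ratio(c.tn, c.neg)
    fnr = None if se is None else 1.0 - se
    fpr = None if sp is None else 1.0 - sp
    ppv = _ratio(c.tp, c.tp + c.fp)
    npv = _ratio(c.tn, c.tn + c.fn)
    for name, value in (
        ("se", se), ("sp", sp), ("fnr", fnr), ("fpr", fpr),
        ("ppv", ppv), ("npv", npv),
    ):
        if value is None:
            undefined.append(name)

    denom = c.p * c.neg * (c.tp + c.fp) * (c.tn + c.fn)
    if denom == 0:
        mcc = 0.0
        undefined.append("mcc_zero_marginal")
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)

    if se is None or sp is None:
        ccr = None
        undefined.append("ccr")
    else:
        ccr = 0.5 * (se + sp)

    return MetricsReport(
        counts=c, acc=acc, er=er, se=se, sp=sp, fnr=fnr, fpr=fpr,
        ppv=ppv, npv=npv, mcc=mcc, ccr=ccr, undefined=tuple(undefined),
    )


def percent(fraction: float) -> int:
    """Round a fraction to the nearest integer percent, half away from zero."""
    return int(math.floor(fraction * 100 + 0.5))
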