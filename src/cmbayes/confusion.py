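"""2x2 confusion-matrix container and the standard evaluation metrics.

Conventions
-----------
Rows are **true** classes, columns are **predicted** classes.  Cell
``z_ij`` counts test examples of true class *i* predicted as class *j*.
The row margins ``n1, n2`` are the number of test examples per true
class (fixed by the test-set design), ``m = n1 + n2`` is the test-set
size and ``e = z12 + z21`` the number of misclassified examples.

Metrics that need a positive/negative class assignment (TPR, FPR, SPC,
MCC, F1, Youden's J) take a :class:`PositiveClassConvention`; by default
row 2 (conventionally the pathological class) is positive.  Prediction
accuracy and the kappa statistic are invariant to that choice.

A metric whose defining ratio has a zero denominator is *undefined*:
it is reported as ``None``, never silently coerced to 0 and never
raised as an exception, because undefinedness is itself informative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = [
    "ConfusionMatrix2",
    "PositiveClassConvention",
    "MetricReport",
    "EmptyMatrixError",
    "prediction_accuracy",
    "rates",
    "mcc",
    "f1_score",
    "kappa",
    "youden_j",
    "full_report",
    "REPORT_DECIMALS",
]

#: decimals used when rounding metrics for serialized reports
REPORT_DECIMALS = 4


class EmptyMatrixError(ValueError):
    """Raised when a metric is requested for a matrix with no examples."""


@dataclass(frozen=True)
class ConfusionMatrix2:
    """2x2 table of non-negative integer counts, rows = true classes."""

    z11: int
    z12: int
    z21: int
    z22: int

    def __post_init__(self) -> None:
        for name in ("z11", "z12", "z21", "z22"):
            v = getattr(self, name)
            if isinstance(v, bool) or not isinstance(v, (int,)):
                # accept numpy integers as well
                try:
                    iv = int(v)
                except (TypeError, ValueError):
                    raise ValueError(f"cell {name} must be an integer, got {v!r}")
                if iv != v:
                    raise ValueError(f"cell {name} must be an integer, got {v!r}")
                object.__setattr__(self, name, iv)
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} must be non-negative, got {v!r}")

    # -- derived quantities -------------------------------------------------
    @property
    def n1(self) -> int:
        """Row-1 margin (true-class-1 test examples)."""
        return self.z11 + self.z12

    @property
    def n2(self) -> int:
        """Row-2 margin (true-class-2 test examples)."""
        return self.z21 + self.z22

    @property
    def m(self) -> int:
        """Total test-set size."""
        return self.n1 + self.n2

    @property
    def e(self) -> int:
        """Misclassified count (off-diagonal sum)."""
        return self.z12 + self.z21

    # -- constructors / views ----------------------------------------------
    @classmethod
    def from_rows(cls, rows: Sequence[Sequence[int]]) -> "ConfusionMatrix2":
        if len(rows) != 2 or any(len(r) != 2 for r in rows):
            raise ValueError("confusion matrix must be 2x2")
        return cls(rows[0][0], rows[0][1], rows[1][0], rows[1][1])

    def to_rows(self) -> list[list[int]]:
        return [[self.z11, self.z12], [self.z21, self.z22]]

    def swap_rows_cols(self) -> "ConfusionMatrix2":
        """Simultaneous row and column permutation (relabel both classes)."""
        return ConfusionMatrix2(self.z22, self.z21, self.z12, self.z11)

    def _require_nonempty(self) -> None:
        if self.m == 0:
            raise EmptyMatrixError("confusion matrix has no examples (m = 0)")


@dataclass(frozen=True)
class PositiveClassConvention:
    """Which true-class row (1 or 2) is the positive / patient class."""

    positive_row: int = 2

    def __post_init__(self) -> None:
        if self.positive_row not in (1, 2):
            raise ValueError("positive_row must be 1 or 2")


DEFAULT_CONVENTION = PositiveClassConvention()


def _cells(cm: ConfusionMatrix2, conv: PositiveClassConvention) -> tuple[int, int, int, int]:
    """Map the table to (TP, TN, FP, FN) under the given convention."""
    if conv.positive_row == 2:
        return cm.z22, cm.z11, cm.z12, cm.z21
    return cm.z11, cm.z22, cm.z21, cm.z12


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def prediction_accuracy(cm: ConfusionMatrix2) -> float:
    """Fraction of correctly classified examples, (m - e) / m."""
    cm._require_nonempty()
    return (cm.m - cm.e) / cm.m


def rates(
    cm: ConfusionMatrix2, conv: PositiveClassConvention = DEFAULT_CONVENTION
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(TPR, FPR, SPC); a rate with an empty denominator is ``None``."""
    cm._require_nonempty()
    tp, tn, fp, fn = _cells(cm, conv)
    tpr = _ratio(tp, tp + fn)
    fpr = _ratio(fp, fp + tn)
    spc = _ratio(tn, fp + tn)
    return tpr, fpr, spc


def mcc(
    cm: ConfusionMatrix2, conv: PositiveClassConvention = DEFAULT_CONVENTION
) -> Optional[float]:
    """Matthews correlation coefficient; ``None`` if any margin factor is 0."""
    cm._require_nonempty()
    tp, tn, fp, fn = _cells(cm, conv)
    factors = [tp + fp, tp + fn, tn + fp, tn + fn]
    if any(f == 0 for f in factors):
        return None
    return (tp * tn - fp * fn) / math.sqrt(math.prod(factors))


def f1_score(
    cm: ConfusionMatrix2, conv: PositiveClassConvention = DEFAULT_CONVENTION
) -> Optional[float]:
    """F1 = 2 TP / (2 TP + FP + FN); ``None`` when the denominator is 0."""
    cm._require_nonempty()
    tp, _tn, fp, fn = _cells(cm, conv)
    return _ratio(2 * tp, 2 * tp + fp + fn)


def random_agreement(cm: ConfusionMatrix2) -> float:
    """Agreement expected under marginal independence (rPA)."""
    cm._require_nonempty()
    tp, tn, fp, fn = _cells(cm, DEFAULT_CONVENTION)
    return ((tn + fp) * (tn + fn) + (fn + tp) * (fp + tp)) / cm.m**2


def kappa(
    cm: ConfusionMatrix2, conv: PositiveClassConvention = DEFAULT_CONVENTION
) -> Optional[float]:
    """Chance-corrected agreement (PA - rPA) / (1 - rPA); convention-free."""
    cm._require_nonempty()
    rpa = random_agreement(cm)
    if rpa == 1.0:
        return None
    return (prediction_accuracy(cm) - rpa) / (1.0 - rpa)


def youden_j(
    cm: ConfusionMatrix2, conv: PositiveClassConvention = DEFAULT_CONVENTION
) -> Optional[float]:
    """J = TPR + SPC - 1; ``None`` if either rate is undefined."""
    tpr, _fpr, spc = rates(cm, conv)
    if tpr is None or spc is None:
        return None
    return tpr + spc - 1.0


@dataclass(frozen=True)
class MetricReport:
    """All standard metrics for one matrix; ``None`` marks undefined."""

    pa: float
    tpr: Optional[float]
    fpr: Optional[float]
    spc: Optional[float]
    mcc: Optional[float]
    f1: Optional[float]
    kappa: Optional[float]
    rpa: float
    youden_j: Optional[float]

    def to_dict(self, round_to: Optional[int] = REPORT_DECIMALS) -> dict:
        """Serialize; undefined metrics become null, values are rounded."""

        def conv(v: Optional[float]) -> Optional[float]:
            if v is None:
                return None
            return round(v, round_to) if round_to is not None else v

        return {
            "pa": conv(self.pa),
            "tpr": conv(self.tpr),
            "fpr": conv(self.fpr),
            "spc": conv(self.spc),
            "mcc": conv(self.mcc),
            "f1": conv(self.f1),
            "kappa": conv(self.kappa),
            "rpa": conv(self.rpa),
            "youden_j": conv(self.youden_j),
        }


def full_report(
    cm: ConfusionMatrix2, conv: PositiveClassConvention = DEFAULT_CONVENTION
) -> MetricReport:
    """Compute every metric for one matrix."""
    tpr, fpr, spc = rates(cm, conv)
    return MetricReport(
        pa=prediction_accuracy(cm),
        tpr=tpr,
        fpr=fpr,
        spc=spc,
        mcc=mcc(cm, conv),
        f1=f1_score(cm, conv),
        kappa=kappa(cm, conv),
        rpa=random_agreement(cm),
        youden_j=youden_j(cm, conv),
    )
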