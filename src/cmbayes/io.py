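"""Reading confusion matrices from files and assembling evaluation reports."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .bayes import BayesFactorResult, min_log_bayes_factor
from .confusion import (
    ConfusionMatrix2,
    MetricReport,
    PositiveClassConvention,
    full_report,
)

__all__ = ["LabeledMatrix", "EvaluationReport", "read_confusion_matrix", "evaluate"]

DEFAULT_ROW_LABELS = ("H", "P")


@dataclass(frozen=True)
class LabeledMatrix:
    matrix: ConfusionMatrix2
    row_labels: tuple[str, str] = DEFAULT_ROW_LABELS
    col_labels: tuple[str, str] = DEFAULT_ROW_LABELS


def _parse_cell(token: str, where: str) -> int:
    token = token.strip()
    try:
        value = int(token)
    except ValueError:
        raise ValueError(f"non-integer cell {token!r} in {where}") from None
    if value < 0:
        raise ValueError(f"negative cell {value} in {where}")
    return value


def _read_delimited(text: str, source: str) -> ConfusionMatrix2:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) != 2:
        raise ValueError(f"{source}: expected 2 rows, found {len(lines)}")
    rows = []
    for ln in lines:
        delim = "\t" if "\t" in ln else ","
        cells = [c for c in ln.split(delim) if c.strip()]
        if len(cells) != 2:
            raise ValueError(f"{source}: expected 2 columns, found {len(cells)}")
        rows.append([_parse_cell(c, source) for c in cells])
    return ConfusionMatrix2.from_rows(rows)


def _read_json(text: str, source: str) -> LabeledMatrix:
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{source}: invalid JSON ({exc})") from None
    if not isinstance(obj, dict) or "matrix" not in obj:
        raise ValueError(f'{source}: JSON input must be an object with a "matrix" key')
    rows = obj["matrix"]
    if (
        not isinstance(rows, list)
        or len(rows) != 2
        or any(not isinstance(r, list) or len(r) != 2 for r in rows)
    ):
        raise ValueError(f"{source}: matrix must be a 2x2 array")
    for r in rows:
        for c in r:
            if not isinstance(c, int) or isinstance(c, bool):
                raise ValueError(f"{source}: non-integer cell {c!r}")
            if c < 0:
                raise ValueError(f"{source}: negative cell {c}")
    cm = ConfusionMatrix2.from_rows(rows)

    def labels(key: str) -> tuple[str, str]:
        val = obj.get(key)
        if val is None:
            return DEFAULT_ROW_LABELS
        if not isinstance(val, list) or len(val) != 2:
            raise ValueError(f"{source}: {key} must be a list of 2 labels")
        return (str(val[0]), str(val[1]))

    return LabeledMatrix(cm, labels("row_labels"), labels("col_labels"))


def read_confusion_matrix(source: str | Path) -> LabeledMatrix:
    """Read a 2x2 matrix from a headerless CSV/TSV file or a JSON file.

    Rows are true classes, columns predicted classes.  JSON input may
    carry ``row_labels`` / ``col_labels``; delimited input gets the
    default "H", "P" labels.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        labeled = _read_json(text, str(path))
    else:
        labeled = LabeledMatrix(_read_delimited(text, str(path)))
    if labeled.matrix.m == 0:
        raise ValueError(f"{path}: empty matrix (all cells are zero)")
    return labeled


@dataclass(frozen=True)
class EvaluationReport:
    """Everything about one evaluation: input echo, metrics, evidence."""

    input: LabeledMatrix
    metrics: MetricReport
    bayes: BayesFactorResult
    positive_row: int
    ref_column: int

    def to_dict(self) -> dict:
        return {
            "version": __version__,
            "input": {
                "matrix": self.input.matrix.to_rows(),
                "row_labels": list(self.input.row_labels),
                "col_labels": list(self.input.col_labels),
            },
            "config": {
                "positive_row": self.positive_row,
                "ref_column": self.ref_column,
                "t_max": self.bayes.grid.t_max,
                "prior_odds": self.bayes.prior_odds,
            },
            "metrics": self.metrics.to_dict(),
            "bayes": self.bayes.to_dict(),
        }


def evaluate(
    labeled: LabeledMatrix | ConfusionMatrix2,
    t_max: Optional[int] = None,
    prior_odds: float = 1.0,
    positive_row: int = 2,
    ref_column: int = 1,
) -> EvaluationReport:
    """Full evaluation: standard metrics plus the conservative Bayes factor."""
    if isinstance(labeled, ConfusionMatrix2):
        labeled = LabeledMatrix(labeled)
    cm = labeled.matrix
    metrics = full_report(cm, PositiveClassConvention(positive_row))
    bayes = min_log_bayes_factor(
        cm, t_max=t_max, ref_column=ref_column, prior_odds=prior_odds
    )
    return EvaluationReport(
        input=labeled,
        metrics=metrics,
        bayes=bayes,
        positive_row=positive_row,
        ref_column=ref_column,
    )
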