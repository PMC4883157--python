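"""Synthetic confusion matrices under the row-binomial sampling model.

Each scenario fixes the row margins (class sizes) and the per-row
probability of landing in the reference column; replicate matrices are
drawn as two independent binomials.  Fixed matrices of interest can be
carried verbatim as degenerate scenarios so the same reporting path
covers both simulated and tabulated cases.

Randomness is counter-based: the generator for a replicate is keyed by
(seed, scenario_index, rep_index), so replicates are reproducible
independently of execution order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bayes import EVIDENCE_LABELS, min_log_bayes_factor
from .confusion import ConfusionMatrix2, full_report

__all__ = [
    "SimulationScenario",
    "sample_matrix",
    "run_comparison",
    "load_scenarios",
    "reference_cases_path",
]

_METRIC_KEYS = ("pa", "tpr", "fpr", "spc", "mcc", "f1", "kappa", "rpa", "youden_j")


@dataclass(frozen=True)
class SimulationScenario:
    """Row-binomial generative model for one batch of replicate matrices.

    When ``matrix`` is given the scenario is degenerate: every replicate
    is exactly that matrix and (n1, n2, p1, p2) are ignored.
    """

    n1: int = 0
    n2: int = 0
    p1: float = 0.0
    p2: float = 0.0
    n_reps: int = 1
    seed: int = 0
    name: Optional[str] = None
    matrix: Optional[tuple[tuple[int, int], tuple[int, int]]] = None

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.matrix is not None:
            rows = tuple(tuple(int(v) for v in r) for r in self.matrix)
            ConfusionMatrix2.from_rows(rows)  # validate
            object.__setattr__(self, "matrix", rows)
            return
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("row margins n1, n2 must be positive")
        if not (0.0 <= self.p1 <= 1.0 and 0.0 <= self.p2 <= 1.0):
            raise ValueError("p1 and p2 must lie in [0, 1]")


def sample_matrix(
    sc: SimulationScenario, rep_index: int, scenario_index: int = 0
) -> ConfusionMatrix2:
    """Draw one replicate matrix; deterministic in (seed, indices)."""
    if sc.matrix is not None:
        return ConfusionMatrix2.from_rows(sc.matrix)
    rng = np.random.default_rng([sc.seed, scenario_index, rep_index])
    z1 = int(rng.binomial(sc.n1, sc.p1))
    z2 = int(rng.binomial(sc.n2, sc.p2))
    return ConfusionMatrix2(z1, sc.n1 - z1, z2, sc.n2 - z2)


def _scenario_label(sc: SimulationScenario, index: int) -> str:
    return sc.name if sc.name is not None else f"scenario_{index}"


def run_comparison(
    scenarios: Sequence[SimulationScenario], t_max: Optional[int] = None
) -> tuple[pd.DataFrame, dict]:
    """Evaluate every replicate of every scenario.

    Returns a tidy table (one row per replicate per metric, evidence
    label included as a string-valued metric) and a per-scenario summary
    with means, quantiles of the conservative log Bayes factor and the
    fraction of replicates falling in each evidence band.
    """
    records: list[dict] = []
    summary: dict = {"t_max": t_max, "scenarios": []}
    for s_idx, sc in enumerate(scenarios):
        label = _scenario_label(sc, s_idx)
        log_bfs: list[float] = []
        band_counts = {lab: 0 for lab in EVIDENCE_LABELS}
        metric_values: dict[str, list[float]] = {k: [] for k in _METRIC_KEYS}
        for rep in range(sc.n_reps):
            cm = sample_matrix(sc, rep, scenario_index=s_idx)
            report = full_report(cm).to_dict(round_to=None)
            bf = min_log_bayes_factor(cm, t_max=t_max)
            for key in _METRIC_KEYS:
                val = report[key]
                records.append(
                    {"scenario": label, "rep": rep, "metric": key, "value": val}
                )
                if val is not None:
                    metric_values[key].append(val)
            records.append(
                {
                    "scenario": label,
                    "rep": rep,
                    "metric": "log_b10",
                    "value": bf.log_b10_min,
                }
            )
            records.append(
                {
                    "scenario": label,
                    "rep": rep,
                    "metric": "evidence",
                    "value": bf.evidence_label,
                }
            )
            log_bfs.append(bf.log_b10_min)
            band_counts[bf.evidence_label] += 1
        arr = np.asarray(log_bfs)
        summary["scenarios"].append(
            {
                "scenario": label,
                "n_reps": sc.n_reps,
                "log_b10": {
                    "mean": float(arr.mean()),
                    "median": float(np.median(arr)),
                    "q05": float(np.quantile(arr, 0.05)),
                    "q95": float(np.quantile(arr, 0.95)),
                },
                "metric_means": {
                    k: (float(np.mean(v)) if v else None)
                    for k, v in metric_values.items()
                },
                "evidence_fractions": {
                    lab: band_counts[lab] / sc.n_reps for lab in EVIDENCE_LABELS
                },
            }
        )
    table = pd.DataFrame.from_records(
        records, columns=["scenario", "rep", "metric", "value"]
    )
    return table, summary


def load_scenarios(path: str | Path) -> list[SimulationScenario]:
    """Read a JSON list of scenario objects."""
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise ValueError("scenario file must contain a JSON list")
    scenarios = []
    for entry in raw:
        if not isinstance(entry, dict):
            raise ValueError("each scenario must be a JSON object")
        if "matrix" in entry and entry["matrix"] is not None:
            entry = dict(entry)
            entry["matrix"] = tuple(tuple(r) for r in entry["matrix"])
        scenarios.append(SimulationScenario(**entry))
    return scenarios


def reference_cases_path() -> Path:
    """Bundled scenario file with the four fixed 100-example test cases."""
    return Path(__file__).parent / "data" / "fig1_cases.json"
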