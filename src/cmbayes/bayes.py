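"""Intrinsic-prior Bayes factor for independence in a 2x2 confusion matrix.

Sampling model (one margin fixed): the row margins ``n1, n2`` are known
and each row is a binomial draw, ``z_i ~ Bin(n_i, p_i)``, where ``z_i``
is the count in a designated reference column.  H0 states that the
prediction is independent of the true class (``p1 = p2 = p`` with a
uniform prior on ``p``); H1 states dependence, with the two
probabilities drawn from an *intrinsic* prior that concentrates mass
around the null.  The degree of concentration is controlled by
non-negative integer parameters ``t1, t2``, one per row.

The intrinsic prior is the mixture of Beta products

    pi(p1, p2 | t1, t2) = sum_{i=0}^{t1} sum_{j=0}^{t2}
        C(t1,i) C(t2,j) G(i+j+1) G(t1+t2-i-j+1) / G(t1+t2+2)
        * Beta(p1 | i+1, t1-i+1) * Beta(p2 | j+1, t2-j+1)

and the Bayes factor B10 (marginal likelihood ratio H1 : H0) has the
closed form

    B10(z1, z2, t1, t2) =
        (n1+n2+1) / ((n1+t1+1)(n2+t2+1))
      * (t1+1)(t2+1) / (t1+t2+1)
      * C(n1+n2, z1+z2)
      * sum_{i,j} C(t1,i)^2 C(t2,j)^2
          / ( C(t1+t2, i+j) C(n1+t1, z1+i) C(n2+t2, z2+j) ).

All terms are positive; everything is evaluated through log-gamma and
accumulated with log-sum-exp, so the computation is stable for test
sets of tens of thousands of examples.

The reported statistic is the *conservative* Bayes factor: the minimum
of ``log B10`` over a grid of concentration parameters.  ``t_i`` plays
the role of an imaginary training-sample size for row *i*, so the grid
bounds each ``t_i`` by the observed row margin ``n_i``; an optional
global cap ``t_max`` (default ``m``) can truncate the grid further.
All logarithms are natural.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .confusion import ConfusionMatrix2

__all__ = [
    "RowCounts",
    "ConcentrationParams",
    "BayesFactorGrid",
    "BayesFactorResult",
    "EVIDENCE_LABELS",
    "STABILITY_SPREAD_WARNING",
    "intrinsic_prior_log_density",
    "log_bayes_factor",
    "min_log_bayes_factor",
    "interpret_evidence",
    "posterior_odds",
]

#: evidence bands for log B10, left-closed / right-open
EVIDENCE_LABELS = ("negative", "bare_mention", "positive", "strong", "decisive")
_BAND_EDGES = (0.0, 1.0, 3.0, 5.0)

#: grid spread (max - min of log B10, natural-log units) above which the
#: result is flagged as unstable w.r.t. the concentration parameters
STABILITY_SPREAD_WARNING = 2.0


@dataclass(frozen=True)
class RowCounts:
    """Reference-column counts and fixed margins of the two rows."""

    z1: int
    z2: int
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError(
                "row margins n1, n2 must be positive: a row with no examples "
                "makes the row-binomial model degenerate"
            )
        if not (0 <= self.z1 <= self.n1 and 0 <= self.z2 <= self.n2):
            raise ValueError("counts must satisfy 0 <= z_i <= n_i")

    @classmethod
    def from_matrix(cls, cm: ConfusionMatrix2, ref_column: int = 1) -> "RowCounts":
        if ref_column not in (1, 2):
            raise ValueError("ref_column must be 1 or 2")
        if ref_column == 1:
            return cls(cm.z11, cm.z21, cm.n1, cm.n2)
        return cls(cm.z12, cm.z22, cm.n1, cm.n2)

    def reflect(self) -> "RowCounts":
        """Swap the reference column: z_i -> n_i - z_i."""
        return RowCounts(self.n1 - self.z1, self.n2 - self.z2, self.n1, self.n2)


@dataclass(frozen=True)
class ConcentrationParams:
    """Per-row intrinsic-prior concentration parameters."""

    t1: int
    t2: int

    def __post_init__(self) -> None:
        if self.t1 < 0 or self.t2 < 0:
            raise ValueError("t1 and t2 must be non-negative integers")


def _log_binom(n, k):
    """log C(n, k) via log-gamma; supports array arguments."""
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def intrinsic_prior_log_density(p1: float, p2: float, t: ConcentrationParams) -> float:
    """Natural log of the intrinsic-prior density at (p1, p2).

    Evaluated as a log-sum-exp over the (t1+1)(t2+1) mixture terms; the
    mixture weights are C(t1,i) C(t2,j) G(i+j+1) G(t1+t2-i-j+1) / G(t1+t2+2).
    """
    if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise ValueError("p1 and p2 must lie strictly inside (0, 1)")
    t1, t2 = t.t1, t.t2
    i = np.arange(t1 + 1)
    j = np.arange(t2 + 1)
    # log Beta(p | a, b) = (a-1) log p + (b-1) log(1-p) - log B(a, b)
    # with a = i+1, b = t1-i+1: log B(a,b) = gammaln(a)+gammaln(b)-gammaln(t1+2)
    log_beta1 = (
        i * math.log(p1)
        + (t1 - i) * math.log1p(-p1)
        - (gammaln(i + 1) + gammaln(t1 - i + 1) - gammaln(t1 + 2))
    )
    log_beta2 = (
        j * math.log(p2)
        + (t2 - j) * math.log1p(-p2)
        - (gammaln(j + 1) + gammaln(t2 - j + 1) - gammaln(t2 + 2))
    )
    log_w = (
        _log_binom(t1, i)[:, None]
        + _log_binom(t2, j)[None, :]
        + gammaln(i[:, None] + j[None, :] + 1)
        + gammaln(t1 + t2 - i[:, None] - j[None, :] + 1)
        - gammaln(t1 + t2 + 2)
    )
    return float(logsumexp(log_w + log_beta1[:, None] + log_beta2[None, :]))


def log_bayes_factor(rc: RowCounts, t: ConcentrationParams) -> float:
    """Natural-log Bayes factor of dependence vs. independence at fixed t."""
    z1, z2, n1, n2 = rc.z1, rc.z2, rc.n1, rc.n2
    t1, t2 = t.t1, t.t2
    prefactor = (
        math.log(n1 + n2 + 1)
        - math.log(n1 + t1 + 1)
        - math.log(n2 + t2 + 1)
        + math.log(t1 + 1)
        + math.log(t2 + 1)
        - math.log(t1 + t2 + 1)
        + _log_binom(n1 + n2, z1 + z2)
    )
    i = np.arange(t1 + 1)
    j = np.arange(t2 + 1)
    a = 2.0 * _log_binom(t1, i) - _log_binom(n1 + t1, z1 + i)
    b = 2.0 * _log_binom(t2, j) - _log_binom(n2 + t2, z2 + j)
    c = -_log_binom(t1 + t2, i[:, None] + j[None, :])
    return float(prefactor + logsumexp(a[:, None] + b[None, :] + c))


@dataclass(frozen=True)
class BayesFactorGrid:
    """log B10 over the concentration grid, with summary diagnostics.

    ``log_b10[t1, t2]`` covers t1 in 0..t1_max, t2 in 0..t2_max (per-row
    bounds min(t_max, n_i)).
    """

    t_max: int
    t1_max: int
    t2_max: int
    log_b10: np.ndarray = field(repr=False)
    truncated: bool

    @property
    def grid_min(self) -> float:
        return float(self.log_b10.min())

    @property
    def grid_max(self) -> float:
        return float(self.log_b10.max())

    @property
    def grid_spread(self) -> float:
        return self.grid_max - self.grid_min

    @property
    def unstable(self) -> bool:
        """Diagnostic only: spread exceeds one evidence-band width."""
        return self.grid_spread > STABILITY_SPREAD_WARNING


@dataclass(frozen=True)
class BayesFactorResult:
    """Conservative (grid-minimum) log Bayes factor and its context."""

    log_b10_min: float
    argmin_t1: int
    argmin_t2: int
    evidence_label: str
    posterior_odds: float
    prior_odds: float
    grid: BayesFactorGrid

    def to_dict(self) -> dict:
        return {
            "log_b10_min": self.log_b10_min,
            "argmin": [self.argmin_t1, self.argmin_t2],
            "evidence": self.evidence_label,
            "posterior_odds": self.posterior_odds,
            "prior_odds": self.prior_odds,
            "grid_spread": self.grid.grid_spread,
            "grid_min": self.grid.grid_min,
            "grid_max": self.grid.grid_max,
            "unstable": self.grid.unstable,
            "t_max": self.grid.t_max,
            "truncated_grid": self.grid.truncated,
        }


def min_log_bayes_factor(
    cm: ConfusionMatrix2,
    t_max: int | None = None,
    ref_column: int = 1,
    prior_odds: float = 1.0,
) -> BayesFactorResult:
    """Conservative Bayes factor: minimize log B10 over the (t1, t2) grid.

    The grid is t_i in {0 .. min(t_max, n_i)} with ``t_max`` defaulting
    to ``m``; since t_i acts as an imaginary training-sample size for
    row i it never usefully exceeds the row margin.  Ties in the
    arg-min break to the lexicographically smallest (t1, t2).
    """
    rc = RowCounts.from_matrix(cm, ref_column=ref_column)
    m = cm.m
    if t_max is None:
        t_max = m
    if t_max < 0:
        raise ValueError("t_max must be non-negative")
    t1_max = min(t_max, rc.n1)
    t2_max = min(t_max, rc.n2)
    grid = np.empty((t1_max + 1, t2_max + 1))
    for t1 in range(t1_max + 1):
        for t2 in range(t2_max + 1):
            grid[t1, t2] = log_bayes_factor(rc, ConcentrationParams(t1, t2))
    flat_arg = int(grid.argmin())  # C order = lexicographic (t1, t2)
    a1, a2 = divmod(flat_arg, t2_max + 1)
    log_min = float(grid[a1, a2])
    bf_grid = BayesFactorGrid(
        t_max=t_max,
        t1_max=t1_max,
        t2_max=t2_max,
        log_b10=grid,
        truncated=t_max < m,
    )
    return BayesFactorResult(
        log_b10_min=log_min,
        argmin_t1=a1,
        argmin_t2=a2,
        evidence_label=interpret_evidence(log_min),
        posterior_odds=posterior_odds(log_min, prior_odds),
        prior_odds=prior_odds,
        grid=bf_grid,
    )


def interpret_evidence(log_b10: float) -> str:
    """Map a natural-log Bayes factor onto the qualitative evidence scale.

    Bands (left-closed, right-open): (-inf, 0) negative, [0, 1)
    bare_mention, [1, 3) positive, [3, 5) strong, [5, inf) decisive.
    """
    if not math.isfinite(log_b10):
        raise ValueError(f"log Bayes factor must be finite, got {log_b10!r}")
    idx = 0
    for edge in _BAND_EDGES:
        if log_b10 >= edge:
            idx += 1
        else:
            break
    return EVIDENCE_LABELS[idx]


def posterior_odds(log_b10: float, prior_odds: float = 1.0) -> float:
    """Posterior odds of dependence: prior_odds * exp(log_b10)."""
    if not prior_odds > 0:
        raise ValueError("prior odds must be positive")
    return prior_odds * math.exp(log_b10)
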