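"""Independent oracles for the Bayes-factor computation.

The closed-form Bayes factor in :mod:`cmbayes.bayes` is never trusted
blindly: this module recomputes both marginal likelihoods from first
principles via beta-binomial identities (each mixture component of the
intrinsic prior integrates against the binomial likelihood in closed
form), and, as a second independent layer, via adaptive numerical
quadrature of the raw integrands.  The test suite asserts agreement of
all three routes on an exhaustive small-instance grid.

The oracles have exponential cost in t1, t2 and are meant for auditing
reported values at small scale, not for production use.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate, stats
from scipy.special import betaln, gammaln, logsumexp

from .bayes import ConcentrationParams, RowCounts

__all__ = [
    "MarginalLikelihoods",
    "oracle_log_m0",
    "oracle_log_m1",
    "oracle_log_b10",
    "marginal_likelihoods",
    "quadrature_log_m0",
    "quadrature_log_m1",
]


def _log_binom(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def oracle_log_m0(rc: RowCounts) -> float:
    """Log marginal likelihood under independence (common p, uniform prior).

    integral over p of Bin(z1|n1,p) Bin(z2|n2,p) dp
        = C(n1,z1) C(n2,z2) B(z1+z2+1, n1+n2-z1-z2+1)
    """
    return (
        _log_binom(rc.n1, rc.z1)
        + _log_binom(rc.n2, rc.z2)
        + float(betaln(rc.z1 + rc.z2 + 1, rc.n1 + rc.n2 - rc.z1 - rc.z2 + 1))
    )


def oracle_log_m1(rc: RowCounts, t: ConcentrationParams) -> float:
    """Log marginal likelihood under dependence with the intrinsic prior.

    Each mixture component is a product of two beta-binomial integrals,
    integral Bin(z|n,p) Beta(p|a,b) dp = C(n,z) B(z+a, n-z+b) / B(a,b),
    combined with the mixture weights by log-sum-exp.
    """
    t1, t2 = t.t1, t.t2
    terms = np.empty((t1 + 1, t2 + 1))
    for i in range(t1 + 1):
        row1 = (
            _log_binom(rc.n1, rc.z1)
            + betaln(rc.z1 + i + 1, rc.n1 - rc.z1 + t1 - i + 1)
            - betaln(i + 1, t1 - i + 1)
        )
        for j in range(t2 + 1):
            log_w = (
                _log_binom(t1, i)
                + _log_binom(t2, j)
                + gammaln(i + j + 1)
                + gammaln(t1 + t2 - i - j + 1)
                - gammaln(t1 + t2 + 2)
            )
            row2 = (
                _log_binom(rc.n2, rc.z2)
                + betaln(rc.z2 + j + 1, rc.n2 - rc.z2 + t2 - j + 1)
                - betaln(j + 1, t2 - j + 1)
            )
            terms[i, j] = log_w + row1 + row2
    return float(logsumexp(terms))


def oracle_log_b10(rc: RowCounts, t: ConcentrationParams) -> float:
    """Oracle log Bayes factor: log m1 - log m0."""
    return oracle_log_m1(rc, t) - oracle_log_m0(rc)


class MarginalLikelihoods:
    """Both log marginal likelihoods for one set of row counts."""

    def __init__(self, log_m0: float, log_m1: float):
        if not (math.isfinite(log_m0) and math.isfinite(log_m1)):
            raise ValueError("marginal likelihoods must be finite")
        self.log_m0 = log_m0
        self.log_m1 = log_m1

    @property
    def log_b10(self) -> float:
        return self.log_m1 - self.log_m0


def marginal_likelihoods(rc: RowCounts, t: ConcentrationParams) -> MarginalLikelihoods:
    return MarginalLikelihoods(oracle_log_m0(rc), oracle_log_m1(rc, t))


# ---------------------------------------------------------------------------
# second layer: direct quadrature of the raw integrands
# ---------------------------------------------------------------------------

def quadrature_log_m0(rc: RowCounts, epsabs: float = 1e-12) -> float:
    """Adaptive quadrature of integral Bin(z1|n1,p) Bin(z2|n2,p) dp."""

    def integrand(p: float) -> float:
        return stats.binom.pmf(rc.z1, rc.n1, p) * stats.binom.pmf(rc.z2, rc.n2, p)

    val, _err = integrate.quad(integrand, 0.0, 1.0, epsabs=epsabs, limit=200)
    return math.log(val)


def quadrature_log_m1(rc: RowCounts, t: ConcentrationParams, epsabs: float = 1e-12) -> float:
    """2-D quadrature of the likelihood against the intrinsic-prior mixture.

    The prior density is rebuilt here directly from scipy Beta pdfs, not
    from :func:`cmbayes.bayes.intrinsic_prior_log_density`, so this path
    shares no code with the implementation it checks.
    """
    t1, t2 = t.t1, t.t2
    weights = np.empty((t1 + 1, t2 + 1))
    for i in range(t1 + 1):
        for j in range(t2 + 1):
            weights[i, j] = (
                math.comb(t1, i)
                * math.comb(t2, j)
                * math.factorial(i + j)
                * math.factorial(t1 + t2 - i - j)
                / math.factorial(t1 + t2 + 1)  # G(t1+t2+2) = (t1+t2+1)!
            )

    def prior(p1: float, p2: float) -> float:
        total = 0.0
        for i in range(t1 + 1):
            for j in range(t2 + 1):
                total += (
                    weights[i, j]
                    * stats.beta.pdf(p1, i + 1, t1 - i + 1)
                    * stats.beta.pdf(p2, j + 1, t2 - j + 1)
                )
        return total

    def integrand(p2: float, p1: float) -> float:
        return (
            stats.binom.pmf(rc.z1, rc.n1, p1)
            * stats.binom.pmf(rc.z2, rc.n2, p2)
            * prior(p1, p2)
        )

    val, _err = integrate.dblquad(integrand, 0.0, 1.0, 0.0, 1.0, epsabs=epsabs)
    return math.log(val)
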