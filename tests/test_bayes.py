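import math

import numpy as np
import pytest
from scipy import integrate

from cmbayes.bayes import (
    ConcentrationParams,
    RowCounts,
    interpret_evidence,
    intrinsic_prior_log_density,
    log_bayes_factor,
    min_log_bayes_factor,
    posterior_odds,
)
from cmbayes.confusion import ConfusionMatrix2


def T(t1, t2):
    return ConcentrationParams(t1, t2)


class TestIntrinsicPrior:
    def test_t_zero_is_uniform(self):
        assert intrinsic_prior_log_density(0.3, 0.8, T(0, 0)) == pytest.approx(0.0)

    def test_normalization(self):
        t = T(3, 2)
        val, _ = integrate.dblquad(
            lambda p2, p1: math.exp(intrinsic_prior_log_density(p1, p2, t)),
            0.0, 1.0, 0.0, 1.0, epsabs=1e-9,
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_term_by_term_high_precision(self):
        # independent brute-force sum of the 4 mixture terms at t1=t2=1
        import mpmath as mp

        mp.mp.dps = 50
        p1 = p2 = mp.mpf("0.5")
        total = mp.mpf(0)
        t1 = t2 = 1
        for i in range(t1 + 1):
            for j in range(t2 + 1):
                w = (
                    mp.binomial(t1, i) * mp.binomial(t2, j)
                    * mp.gamma(i + j + 1) * mp.gamma(t1 + t2 - i - j + 1)
                    / mp.gamma(t1 + t2 + 2)
                )
                b1 = p1**i * (1 - p1) ** (t1 - i) / mp.beta(i + 1, t1 - i + 1)
                b2 = p2**j * (1 - p2) ** (t2 - j) / mp.beta(j + 1, t2 - j + 1)
                total += w * b1 * b2
        expected = float(mp.log(total))
        got = intrinsic_prior_log_density(0.5, 0.5, T(1, 1))
        assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("p1,p2", [(0.0, 0.5), (0.5, 1.0), (-0.1, 0.5), (0.5, 1.5)])
    def test_p_out_of_open_interval_raises(self, p1, p2):
        with pytest.raises(ValueError, match="inside"):
            intrinsic_prior_log_density(p1, p2, T(1, 1))

    def test_negative_t_rejected(self):
        with pytest.raises(ValueError):
            ConcentrationParams(-1, 0)


class TestLogBayesFactor:
    def test_smallest_case_closed_form(self):
        # at t = 0 the factor is (n1+n2+1) C(n1+n2, z1+z2)
        #   / ((n1+1)(n2+1) C(n1,z1) C(n2,z2)) = 3*2/(2*2) = 1.5
        rc = RowCounts(z1=1, z2=0, n1=1, n2=1)
        assert log_bayes_factor(rc, T(0, 0)) == pytest.approx(math.log(1.5))

    def test_t_zero_closed_form_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n1, n2 = rng.integers(1, 40, size=2)
            z1 = int(rng.integers(0, n1 + 1))
            z2 = int(rng.integers(0, n2 + 1))
            rc = RowCounts(z1, z2, int(n1), int(n2))
            expected = (
                math.log(n1 + n2 + 1)
                + math.lgamma(n1 + n2 + 1)
                - math.lgamma(z1 + z2 + 1)
                - math.lgamma(n1 + n2 - z1 - z2 + 1)
                - math.log((n1 + 1) * (n2 + 1))
                - (math.lgamma(n1 + 1) - math.lgamma(z1 + 1) - math.lgamma(n1 - z1 + 1))
                - (math.lgamma(n2 + 1) - math.lgamma(z2 + 1) - math.lgamma(n2 - z2 + 1))
            )
            assert log_bayes_factor(rc, T(0, 0)) == pytest.approx(expected, abs=1e-12)

    def test_reflection_invariance(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n1, n2 = (int(v) for v in rng.integers(1, 60, size=2))
            z1 = int(rng.integers(0, n1 + 1))
            z2 = int(rng.integers(0, n2 + 1))
            t = T(int(rng.integers(0, 8)), int(rng.integers(0, 8)))
            rc = RowCounts(z1, z2, n1, n2)
            assert log_bayes_factor(rc, t) == pytest.approx(
                log_bayes_factor(rc.reflect(), t), abs=1e-9
            )

    def test_row_swap_symmetry(self):
        rc = RowCounts(z1=7, z2=2, n1=20, n2=9)
        swapped = RowCounts(z1=2, z2=7, n1=9, n2=20)
        assert log_bayes_factor(rc, T(3, 5)) == pytest.approx(
            log_bayes_factor(swapped, T(5, 3)), abs=1e-12
        )

    def test_degenerate_row_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            RowCounts(0, 3, 0, 5)

    def test_finite_for_large_m(self):
        rc = RowCounts(z1=4900, z2=300, n1=9000, n2=1000)
        for t in (T(0, 0), T(100, 100), T(5000, 1000), T(9000, 1000)):
            assert math.isfinite(log_bayes_factor(rc, t))


class TestMinLogBayesFactor:
    def test_perfect_prediction(self, cm_perfect):
        res = min_log_bayes_factor(cm_perfect, t_max=100)
        assert res.log_b10_min == pytest.approx(19.61, abs=0.01)
        assert res.evidence_label == "decisive"

    def test_random_prediction(self, cm_random):
        res = min_log_bayes_factor(cm_random, t_max=100)
        assert res.log_b10_min == pytest.approx(-0.94, abs=0.01)
        assert res.evidence_label == "negative"

    def test_errors_in_dominant(self, cm_errors_in_dominant):
        res = min_log_bayes_factor(cm_errors_in_dominant, t_max=100)
        assert res.log_b10_min == pytest.approx(10.67, abs=0.01)

    def test_minimum_matches_grid(self, cm_errors_fifth):
        res = min_log_bayes_factor(cm_errors_fifth)
        grid = res.grid.log_b10
        assert res.log_b10_min == grid.min()
        assert grid[res.argmin_t1, res.argmin_t2] == res.log_b10_min
        assert res.grid.grid_min <= res.grid.grid_max
        assert res.grid.grid_spread == pytest.approx(
            res.grid.grid_max - res.grid.grid_min
        )

    def test_column_convention_invariance(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n1, n2 = (int(v) for v in rng.integers(1, 12, size=2))
            z1 = int(rng.integers(0, n1 + 1))
            z2 = int(rng.integers(0, n2 + 1))
            cm = ConfusionMatrix2(z1, n1 - z1, z2, n2 - z2)
            r1 = min_log_bayes_factor(cm, ref_column=1)
            r2 = min_log_bayes_factor(cm, ref_column=2)
            assert r1.log_b10_min == pytest.approx(r2.log_b10_min, abs=1e-9)

    def test_evidence_direction_on_reference_family(
        self, cm_always_dominant, cm_errors_in_dominant
    ):
        bad = min_log_bayes_factor(cm_always_dominant)
        good = min_log_bayes_factor(cm_errors_in_dominant)
        assert good.log_b10_min > bad.log_b10_min
        assert bad.log_b10_min < 0  # no printed value; qualitative only

    def test_sample_size_sensitivity(self, cm_errors_in_dominant, cm_errors_fifth):
        big = min_log_bayes_factor(cm_errors_in_dominant)
        small = min_log_bayes_factor(cm_errors_fifth)
        assert big.log_b10_min > small.log_b10_min

    def test_truncated_grid_flag(self):
        cm = ConfusionMatrix2(1, 0, 0, 1)
        res = min_log_bayes_factor(cm, t_max=0)
        assert res.grid.truncated
        assert res.log_b10_min == pytest.approx(math.log(1.5))
        full = min_log_bayes_factor(cm)
        assert not full.grid.truncated

    def test_argmin_tie_break_is_lexicographic(self):
        # row-swap symmetric matrix: grid is symmetric, argmin must be the
        # lexicographically smallest of the tied entries
        cm = ConfusionMatrix2(3, 1, 3, 1)
        res = min_log_bayes_factor(cm)
        grid = res.grid.log_b10
        ties = np.argwhere(grid == grid.min())
        assert (res.argmin_t1, res.argmin_t2) == tuple(int(v) for v in ties[0])

    def test_degenerate_row_propagates(self):
        with pytest.raises(ValueError, match="degenerate"):
            min_log_bayes_factor(ConfusionMatrix2(0, 0, 5, 5))

    def test_negative_t_max_rejected(self):
        with pytest.raises(ValueError, match="t_max"):
            min_log_bayes_factor(ConfusionMatrix2(1, 1, 1, 1), t_max=-1)


class TestInterpretEvidence:
    @pytest.mark.parametrize(
        "value,label",
        [
            (-0.94, "negative"),
            (-1e-9, "negative"),
            (0.0, "bare_mention"),
            (0.5, "bare_mention"),
            (1.0, "positive"),
            (1.84, "positive"),
            (2.98, "positive"),
            (3.0, "strong"),
            (4.44, "strong"),
            (5.0, "decisive"),
            (9.58, "decisive"),
            (19.61, "decisive"),
        ],
    )
    def test_banding(self, value, label):
        assert interpret_evidence(value) == label

    @pytest.mark.parametrize("bad", [math.nan, math.inf, -math.inf])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(ValueError, match="finite"):
            interpret_evidence(bad)


class TestPosteriorOdds:
    def test_even_odds(self):
        assert posterior_odds(0.0, 1.0) == pytest.approx(1.0)

    def test_multiplication(self):
        assert posterior_odds(math.log(2), 3.0) == pytest.approx(6.0)

    def test_paper_scale_value(self):
        assert posterior_odds(19.61, 1.0) == pytest.approx(math.exp(19.61))

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_non_positive_prior_odds_rejected(self, bad):
        with pytest.raises(ValueError, match="positive"):
            posterior_odds(0.0, bad)
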