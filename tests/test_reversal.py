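from fractions import Fraction
from math import atanh, comb, sqrt

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from degrank import (
    AnalysisConfig,
    ParameterError,
    ReversalSimTruth,
    binomial_direction_test,
    classify_reversal,
    fc_correlation,
    reversal_report,
    simulate_reversal_pair,
    steiger_dependent_test,
)

from conftest import make_deg_table


def mutant_table(fcs, ps=None):
    n = len(fcs)
    return make_deg_table(
        gene_ids=[f"g{i}" for i in range(n)],
        log2fc=fcs,
        mean_expr=[50.0] * n,
        p_value=ps if ps is not None else [0.01] * n,
    )


def effect_series(values):
    return pd.Series(values, index=[f"g{i}" for i in range(len(values))])


class TestClassifyReversal:
    def test_exact_negation_reverses_everything(self):
        mutant = mutant_table([1.0, 2.0, -1.0, -0.5])
        counts = classify_reversal(mutant, effect_series([-1.0, -2.0, 1.0, 0.5]))
        assert (counts.n_up, counts.k_up_reversed) == (2, 2)
        assert (counts.n_down, counts.k_down_reversed) == (2, 2)

    def test_zero_effect_counts_as_not_reversed(self):
        mutant = mutant_table([1.0])
        counts = classify_reversal(mutant, effect_series([0.0]))
        assert counts.k_up_reversed == 0

    def test_mixed_signs_counted(self):
        mutant = mutant_table([1.0, 1.0, 1.0, 1.0])
        counts = classify_reversal(mutant, effect_series([-0.2, -3.0, 0.4, 0.0]))
        assert (counts.n_up, counts.k_up_reversed) == (4, 2)

    def test_missing_genes_excluded_and_reported(self):
        mutant = mutant_table([1.0, 1.0, -1.0])
        effect = pd.Series({"g0": -0.5})
        counts = classify_reversal(mutant, effect)
        assert counts.n_up == 1 and counts.n_down == 0
        assert counts.missing_genes == ("g1", "g2")

    def test_empty_intersection_rejected(self):
        mutant = mutant_table([1.0])
        with pytest.raises(ParameterError):
            classify_reversal(mutant, pd.Series({"zz": 1.0}))

    def test_invariant_under_positive_rescaling(self, rng):
        fcs = rng.normal(size=30)
        eff = rng.normal(size=30)
        mutant = mutant_table(list(fcs))
        a = classify_reversal(mutant, effect_series(eff))
        b = classify_reversal(mutant, effect_series(eff * 17.3))
        assert (a.k_up_reversed, a.k_down_reversed) == (
            b.k_up_reversed,
            b.k_down_reversed,
        )


class TestBinomialDirectionTest:
    def test_most_probable_outcome_gives_p_one(self):
        assert binomial_direction_test(5, 10) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [1, 4, 9, 17, 30])
    def test_symmetry_about_half(self, n):
        for k in range(n + 1):
            assert binomial_direction_test(k, n) == pytest.approx(
                binomial_direction_test(n - k, n), rel=1e-12
            )

    @pytest.mark.parametrize("n", [1, 2, 5, 12, 23, 30])
    def test_matches_pmf_enumeration(self, n):
        """Two-sided P equals the exact rational sum of all outcomes no more
        probable than the observed one (point-probability definition)."""
        for k in range(n + 1):
            obs = comb(n, k)
            oracle = Fraction(
                sum(comb(n, i) for i in range(n + 1) if comb(n, i) <= obs), 2**n
            )
            assert binomial_direction_test(k, n) == pytest.approx(
                float(oracle), rel=1e-12
            )

    def test_extreme_tail_keeps_precision(self):
        # around 1e-41: far beyond naive summation accuracy, well inside double range
        p = binomial_direction_test(1300, 2000)
        assert p > 0
        assert p == pytest.approx(2 * stats.binom.sf(1299, 2000, 0.5), rel=1e-9)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ParameterError):
            binomial_direction_test(5, 0)
        with pytest.raises(ParameterError):
            binomial_direction_test(11, 10)


class TestFcCorrelation:
    def test_perfect_anticorrelation(self):
        a = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        r, p, n = fc_correlation(a, -a)
        assert r == pytest.approx(-1.0)
        assert n == 3

    def test_constant_vector_rejected(self):
        a = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        with pytest.raises(ParameterError):
            fc_correlation(a, pd.Series({"a": 5.0, "b": 5.0, "c": 5.0}))

    def test_five_point_closed_form(self):
        # r = 10 / sqrt(10 * 14.8) = 0.8220 for these pairs
        a = pd.Series(dict(zip("abcde", [1.0, 2.0, 3.0, 4.0, 5.0])))
        b = pd.Series(dict(zip("abcde", [2.0, 1.0, 4.0, 3.0, 6.0])))
        r, _, n = fc_correlation(a, b)
        assert r == pytest.approx(10 / sqrt(10 * 14.8), rel=1e-12)
        assert n == 5

    def test_too_few_shared_genes_rejected(self):
        with pytest.raises(ParameterError):
            fc_correlation(
                pd.Series({"a": 1.0, "b": 2.0}), pd.Series({"a": 1.0, "b": 3.0})
            )


def steiger_oracle(r_jk, r_jh, r_kh, n):
    """Independent re-derivation: pooled-correlation covariance of the
    Fisher transforms, assembled via the determinant form of psi."""
    rbar = 0.5 * (r_jk + r_jh)
    rbar2 = rbar * rbar
    # psi(r_jk=r_jh=rbar): r_kh(1 - rbar^2 - rbar^2) - 0.5 rbar*rbar *
    #   (1 - rbar^2 - rbar^2 - r_kh^2), written without reuse of the
    #   implementation's grouping
    psi = r_kh * (1.0 - rbar2 - rbar2) - 0.5 * (rbar * rbar) * (
        (1.0 - rbar2) + (-rbar2) + (-(r_kh**2))
    )
    cov = psi / ((1.0 - rbar2) * (1.0 - rbar2))
    z = (atanh(r_jk) - atanh(r_jh)) * sqrt((n - 3.0) / (2.0 * (1.0 - cov)))
    return z, 2.0 * stats.norm.sf(abs(z))


class TestSteiger:
    def test_equal_correlations_are_null(self):
        z, p = steiger_dependent_test(0.4, 0.4, 0.2, 50)
        assert z == 0.0
        assert p == 1.0

    def test_matches_independent_implementation(self):
        z, p = steiger_dependent_test(0.319, 0.195, 0.8, 1000)
        z2, p2 = steiger_oracle(0.319, 0.195, 0.8, 1000)
        assert z == pytest.approx(z2, abs=1e-10)
        assert p == pytest.approx(p2, abs=1e-10)

    @pytest.mark.parametrize(
        "r_jk,r_jh,r_kh,n", [(0.6, 0.2, 0.3, 40), (-0.3, 0.5, 0.1, 120)]
    )
    def test_antisymmetric_in_the_two_correlations(self, r_jk, r_jh, r_kh, n):
        z1, p1 = steiger_dependent_test(r_jk, r_jh, r_kh, n)
        z2, p2 = steiger_dependent_test(r_jh, r_jk, r_kh, n)
        assert z1 == pytest.approx(-z2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ParameterError):
            steiger_dependent_test(1.0, 0.5, 0.5, 100)
        with pytest.raises(ParameterError):
            steiger_dependent_test(0.5, 0.4, 0.3, 3)


class TestReversalReport:
    def test_noiseless_full_reversal(self):
        mutant, effect = simulate_reversal_pair(
            ReversalSimTruth(
                n_deg_up=60, n_deg_down=40, reversal_prob=1.0,
                damping=1.0, noise_sd=0.0, seed=2,
            )
        )
        # treated comparison: attenuated, noisier copy of the mutant signature;
        # reference: independently noised copy so correlations stay inside (-1, 1)
        rng = np.random.default_rng(8)
        ref = make_deg_table(
            gene_ids=list(mutant.data["gene_id"]),
            log2fc=mutant.data["log2fc"].to_numpy() + rng.normal(0, 0.05, 100),
            mean_expr=list(mutant.data["mean_expr"]),
            p_value=list(mutant.data["p_value"]),
        )
        treated = make_deg_table(
            gene_ids=list(mutant.data["gene_id"]),
            log2fc=0.3 * mutant.data["log2fc"].to_numpy()
            + rng.normal(0, 0.4, 100),
            mean_expr=list(mutant.data["mean_expr"]),
            p_value=list(mutant.data["p_value"]),
        )
        summary = reversal_report(mutant, effect, treated, ref)
        assert summary.frac_up == 1.0 and summary.frac_down == 1.0
        assert summary.r_effect == pytest.approx(-1.0)
        assert summary.r_untreated > summary.r_treated
        assert summary.steiger_p < 0.01

    def test_low_expression_genes_excluded(self):
        mutant, effect = simulate_reversal_pair(
            ReversalSimTruth(
                n_deg_up=50, n_deg_down=50, reversal_prob=1.0,
                noise_sd=0.0, below_floor_fraction=0.2, seed=4,
            )
        )
        rng = np.random.default_rng(9)
        ref = make_deg_table(
            gene_ids=list(mutant.data["gene_id"]),
            log2fc=mutant.data["log2fc"].to_numpy() + rng.normal(0, 0.1, 100),
            mean_expr=list(mutant.data["mean_expr"]),
            p_value=list(mutant.data["p_value"]),
        )
        treated = make_deg_table(
            gene_ids=list(effect.data["gene_id"]),
            log2fc=effect.data["log2fc"].to_numpy() + rng.normal(0, 0.1, 100),
            mean_expr=list(effect.data["mean_expr"]),
            p_value=list(effect.data["p_value"]),
        )
        summary = reversal_report(mutant, effect, treated, ref)
        assert summary.n_up + summary.n_down == 80
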