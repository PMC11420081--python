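from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest

from degrank import (
    ClusterProfile,
    GeneSet,
    IntegrityError,
    ParameterError,
    composition_test,
    fit_expected_degs,
    heritability_slot,
    hypergeometric_overlap,
    residual_pvalue,
    select_top_degs,
)
from degrank.synth import ClusterSimTruth, simulate_cluster_profiles

from conftest import make_deg_table


class TestHypergeometricOverlap:
    def test_disjoint_set_gives_p_one(self):
        res = hypergeometric_overlap(
            {"a", "b"}, GeneSet("s", "", frozenset({"x", "y"})), {"a", "b", "c"}
        )
        assert res.k == 0
        assert res.p_value == 1.0

    def test_complete_overlap_small_universe(self):
        # all 5 draws inside a 5-gene set in a 10-gene universe: 1 / C(10,5)
        universe = {f"g{i}" for i in range(10)}
        gs = GeneSet("s", "", frozenset({f"g{i}" for i in range(5)}))
        res = hypergeometric_overlap({f"g{i}" for i in range(5)}, gs, universe)
        assert res.p_value == pytest.approx(1 / 252, rel=1e-12)

    def test_partial_overlap_enumeration_value(self):
        # N=20, K=6, n=5, k=3 -> 2036/15504 by subset enumeration
        universe = {f"g{i}" for i in range(20)}
        gs = GeneSet("s", "", frozenset({f"g{i}" for i in range(6)}))
        degs = {"g0", "g1", "g2", "g10", "g11"}
        res = hypergeometric_overlap(degs, gs, universe)
        assert res.p_value == pytest.approx(2036 / 15504, rel=1e-12)

    def test_gene_set_intersected_with_universe(self):
        universe = {"a", "b", "c", "d"}
        gs = GeneSet("s", "", frozenset({"a", "zz", "qq"}))
        res = hypergeometric_overlap({"a"}, gs, universe)
        assert res.K_set == 1

    def test_deg_outside_universe_rejected(self):
        with pytest.raises(IntegrityError):
            hypergeometric_overlap(
                {"zz"}, GeneSet("s", "", frozenset({"a"})), {"a", "b"}
            )

    def test_empty_universe_rejected(self):
        with pytest.raises(ParameterError):
            hypergeometric_overlap(set(), GeneSet("s", "", frozenset({"a"})), set())

    def test_matches_subset_enumeration_oracle(self):
        """Inclusive upper tail agrees with brute-force enumeration of every
        n-subset of small universes."""
        rng = np.random.default_rng(0)
        for N, K, n in [(7, 3, 4), (9, 4, 3), (10, 5, 5), (12, 6, 4)]:
            universe = [f"g{i}" for i in range(N)]
            gs = GeneSet("s", "", frozenset(universe[:K]))
            overlaps = [
                len(set(sub) & gs.members) for sub in combinations(universe, n)
            ]
            degs = set(rng.choice(universe, size=n, replace=False))
            k = len(degs & gs.members)
            oracle = sum(1 for o in overlaps if o >= k) / comb(N, n)
            res = hypergeometric_overlap(degs, gs, universe)
            assert res.p_value == pytest.approx(oracle, rel=1e-12)


def profiles_from_counts(cells, counts):
    out = []
    gid = 0
    background = {f"g{i}" for i in range(2000)}
    for j, (c, n) in enumerate(zip(cells, counts)):
        ids = [f"g{i}" for i in range(gid, gid + n)]
        gid += n
        table = make_deg_table(
            gene_ids=ids,
            log2fc=[1.0] * n,
            mean_expr=[30.0] * n,
            p_value=[0.01] * n,
        )
        empty = make_deg_table(gene_ids=[], log2fc=[], mean_expr=[], p_value=[])
        out.append(
            ClusterProfile(f"c{j}", c, table, empty, background)
        )
    return out


class TestFitExpectedDegs:
    def test_perfectly_linear_counts_have_unit_correlation(self):
        fit = fit_expected_degs(profiles_from_counts((100, 200, 300), (10, 20, 30)))
        assert fit.pearson_r == pytest.approx(1.0)
        np.testing.assert_allclose(fit.expected, (10, 20, 30), atol=1e-9)

    def test_three_point_closed_form(self):
        # OLS on (100,10),(200,20),(300,33): slope 0.115, intercept -2
        fit = fit_expected_degs(profiles_from_counts((100, 200, 300), (10, 20, 33)))
        assert fit.slope == pytest.approx(0.115, rel=1e-12)
        assert fit.intercept == pytest.approx(-2.0, rel=1e-12)
        np.testing.assert_allclose(fit.expected, (9.5, 21.0, 32.5), rtol=1e-12)

    def test_expected_counts_floored(self):
        fit = fit_expected_degs(profiles_from_counts((100, 200, 300, 400), (0, 0, 0, 40)))
        assert min(fit.expected) == 0.5

    def test_too_few_clusters_rejected(self):
        with pytest.raises(ParameterError, match="3 clusters"):
            fit_expected_degs(profiles_from_counts((100, 200), (10, 20)))

    def test_identical_cell_counts_rejected(self):
        with pytest.raises(ParameterError, match="singular"):
            fit_expected_degs(profiles_from_counts((100, 100, 100), (10, 20, 30)))


class TestResidualPvalue:
    def test_observed_equal_expected_is_null(self):
        results = residual_pvalue([10, 20, 30], [10.0, 20.0, 30.0])
        for r in results:
            assert r.std_residual == pytest.approx(0.0, abs=1e-12)
            assert r.p_one_tailed == pytest.approx(0.5)

    def test_matches_independent_adjusted_residual_oracle(self):
        """Residuals equal statsmodels' adjusted standardized residuals of
        the same 2xK table."""
        sm = pytest.importorskip("statsmodels.api")
        observed = [30, 10]
        expected = [20.0, 20.0]
        ours = residual_pvalue(observed, expected)
        table = np.array([observed, [20, 20]], dtype=float)
        oracle = sm.stats.Table(table).standardized_resids[0]
        for r, want in zip(ours, oracle):
            assert r.std_residual == pytest.approx(want, abs=1e-12)

    def test_excess_cluster_alone_is_significant(self):
        results = residual_pvalue([60, 20, 30, 40], [30.0, 20.0, 30.0, 40.0])
        assert results[0].p_one_tailed < 0.05
        assert all(r.p_one_tailed > 0.05 for r in results[1:])

    @pytest.mark.parametrize("bump", [1, 5, 20])
    def test_antitone_in_observed_excess(self, bump):
        base = residual_pvalue([30, 20, 25], [25.0, 22.0, 24.0])[0].p_one_tailed
        more = residual_pvalue([30 + bump, 20, 25], [25.0, 22.0, 24.0])[0].p_one_tailed
        assert more < base

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ParameterError):
            residual_pvalue([10, 20], [5.0, 0.0])

    def test_deviation_sign_matches_residual_sign(self):
        results = residual_pvalue([40, 10, 25], [25.0, 25.0, 25.0])
        assert results[0].std_residual > 0 and results[0].p_one_tailed < 0.5
        assert results[1].std_residual < 0 and results[1].p_one_tailed > 0.5


class TestSelectTopDegs:
    def test_smallest_p_values_selected(self):
        table = make_deg_table(
            gene_ids=list("abcde"),
            log2fc=[1, 1, 1, 1, 1],
            mean_expr=[30] * 5,
            p_value=[0.5, 0.01, 0.3, 0.02, 0.04],
        )
        assert select_top_degs(table, 3) == ["b", "d", "e"]

    def test_tie_broken_by_larger_fold_change(self):
        table = make_deg_table(
            gene_ids=["a", "b", "c"],
            log2fc=[0.5, 2.0, 1.0],
            mean_expr=[30] * 3,
            p_value=[0.01, 0.01, 0.001],
        )
        assert select_top_degs(table, 2) == ["c", "b"]

    def test_short_table_returned_whole_with_warning(self, caplog):
        table = make_deg_table()
        with caplog.at_level("WARNING", logger="degrank"):
            got = select_top_degs(table, 10)
        assert len(got) == 3
        assert "top-10" in caplog.text


class TestHeritabilitySlot:
    def test_external_pass_through(self):
        assert heritability_slot([], source={"cluster0_up": 0.0116}, label="cluster0_up") == 0.0116

    def test_missing_label_raises(self):
        with pytest.raises(KeyError):
            heritability_slot([], source={"a": 0.5}, label="b")

    def test_constant_scores_give_p_one_never_zero(self, rng):
        universe = [f"g{i}" for i in range(100)]
        scores = {g: 1.0 for g in universe}
        p = heritability_slot(
            universe[:10], scores=scores, universe=universe, mc_reps=199, rng=rng
        )
        assert p == 1.0

    def test_top_scoring_list_attains_minimum_p(self, rng):
        universe = [f"g{i}" for i in range(100)]
        scores = {g: (1.0 if i < 10 else 0.0) for i, g in enumerate(universe)}
        p = heritability_slot(
            universe[:10], scores=scores, universe=universe, mc_reps=999, rng=rng
        )
        assert p == pytest.approx(1 / 1000)


class TestCompositionTest:
    def test_exact_enumeration_diagonal_table(self):
        # [[5,0],[0,5]]: only the two diagonal tables are as improbable
        p = composition_test([[5, 0], [0, 5]], method="exact")
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_exact_matches_fraction_oracle_2x3(self):
        table = [[4, 1, 2], [1, 3, 3]]
        rows = [7, 7]
        cols = [5, 4, 5]
        # exact null: P(a,b,c) = C(5,a) C(4,b) C(5,c) / C(14,7)
        def prob(a, b, c):
            return Fraction(comb(5, a) * comb(4, b) * comb(5, c), comb(14, 7))

        obs = prob(4, 1, 2)
        total = Fraction(0)
        for a in range(0, 6):
            for b in range(0, 5):
                c = 7 - a - b
                if 0 <= c <= 5 and prob(a, b, c) <= obs:
                    total += prob(a, b, c)
        p = composition_test(table, method="exact")
        assert p == pytest.approx(float(total), rel=1e-9)

    def test_identical_rows_not_significant(self):
        p = composition_test([[50, 60, 70], [50, 60, 70]], mc_reps=2000, seed=1)
        assert p > 0.5

    def test_same_seed_reproduces_p(self):
        t = [[10, 5, 3], [4, 9, 6]]
        assert composition_test(t, mc_reps=500, seed=42) == composition_test(
            t, mc_reps=500, seed=42
        )

    def test_monte_carlo_close_to_exact(self):
        t = [[8, 3, 4], [2, 7, 6]]
        exact = composition_test(t, method="exact")
        mc = composition_test(t, mc_reps=10000, seed=3)
        se = np.sqrt(exact * (1 - exact) / 10000)
        assert abs(mc - exact) < 3 * se + 2 / 10001

    def test_zero_margin_rejected(self):
        with pytest.raises(ParameterError):
            composition_test([[0, 0], [1, 2]])
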