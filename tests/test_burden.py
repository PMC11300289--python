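"""Gene burden matrix, score/permutation test, Cauchy combination, Fisher
test and the gene scan."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from cscakut.burden import (
    burden_score_test,
    cauchy_combine,
    compute_burden_matrix,
    fisher_nominal_test,
    qq_points,
    run_gene_scan,
)
from cscakut.io_formats import SampleTable

from conftest import make_masked, make_variant


def masked_in_gene(gene, carriers, weight, n, pos, level=4, flag=True):
    g = np.zeros(n, dtype=np.int8)
    g[list(carriers)] = 1
    return make_masked(make_variant(pos, g), gene, mask_level=level,
                       missense_flag=flag, weight=weight)


class TestBurdenMatrix:
    def test_max_weight_wins(self, tiny_samples):
        n = len(tiny_samples)
        mvs = [
            masked_in_gene("G1", [0], 0.5, n, 10),
            masked_in_gene("G1", [0], 1.0, n, 20, level=1, flag=False),
        ]
        bm = compute_burden_matrix(mvs, tiny_samples)
        assert bm.column("G1")[0] == 1.0

    def test_non_carrier_is_zero(self, tiny_samples):
        n = len(tiny_samples)
        bm = compute_burden_matrix([masked_in_gene("G1", [0], 0.5, n, 10)], tiny_samples)
        assert bm.column("G1")[1] == 0.0

    def test_shared_variant_gives_both_carriers_weight(self, tiny_samples):
        n = len(tiny_samples)
        bm = compute_burden_matrix(
            [masked_in_gene("G1", [2, 5], 0.9, n, 10, level=2, flag=False)], tiny_samples
        )
        col = bm.column("G1")
        assert col[2] == 0.9 and col[5] == 0.9 and col.sum() == pytest.approx(1.8)

    def test_invariant_to_variant_order(self, tiny_samples):
        n = len(tiny_samples)
        mvs = [
            masked_in_gene("G1", [0, 3], 0.5, n, 10),
            masked_in_gene("G1", [3, 7], 0.9, n, 20, level=2, flag=False),
            masked_in_gene("G2", [1], 1.0, n, 30, level=1, flag=False),
        ]
        a = compute_burden_matrix(mvs, tiny_samples)
        b = compute_burden_matrix(mvs[::-1], tiny_samples)
        assert np.array_equal(a.values, b.values) and a.genes == b.genes


def exhaustive_permutation_p(x, case_mask):
    """Oracle: full enumeration of case-label assignments (two-sided T = U^2)."""
    n = len(x)
    n1 = int(case_mask.sum())
    ybar = n1 / n
    xbar = np.mean(x)
    v = ybar * (1 - ybar) * np.sum((np.asarray(x) - xbar) ** 2)
    t_obs = (np.dot(x, case_mask - ybar)) ** 2 / v
    count = 0
    total = math.comb(n, n1)
    for case_idx in itertools.combinations(range(n), n1):
        u = sum(x[i] for i in case_idx) - n1 * xbar
        if u * u / v >= t_obs * (1 - 1e-12):
            count += 1
    return count / total


class TestBurdenScoreTest:
    def test_all_case_carriers_matches_enumeration_oracle(self):
        # 5 carriers all cases in a 50/50 cohort of 100
        x = np.zeros(100)
        x[:5] = 0.9
        y = np.zeros(100, dtype=bool)
        y[:50] = True
        res = burden_score_test(x, y, mode="conservative")
        # closed form: both all-case and all-control assignments are extreme
        closed = 2 * math.comb(95, 45) / math.comb(100, 50)
        assert res.p_conservative == pytest.approx(closed, rel=1e-9)

    def test_matches_oracle_on_small_mixed_cohorts(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = 16
            x = np.zeros(n)
            carriers = rng.choice(n, size=4, replace=False)
            x[carriers] = rng.choice([0.3, 0.5, 0.9, 1.0], size=4)
            y = np.zeros(n, dtype=bool)
            y[rng.choice(n, size=6, replace=False)] = True
            res = burden_score_test(x, y, mode="conservative")
            assert res.p_conservative == pytest.approx(
                exhaustive_permutation_p(x, y), rel=1e-9
            )

    def test_constant_column_untestable(self):
        y = np.array([True] * 3 + [False] * 5)
        assert burden_score_test(np.full(8, 0.5), y).untestable
        assert burden_score_test(np.zeros(8), y).untestable

    def test_randomized_p_bracketed_by_tail_components(self):
        x = np.zeros(60)
        x[:3] = [0.5, 0.9, 1.0]
        y = np.zeros(60, dtype=bool)
        y[:10] = True
        rng = np.random.default_rng(0)
        res = burden_score_test(x, y, rng=rng)
        assert res.p_gt <= res.p <= res.p_gt + res.p_eq

    def test_null_fuzzy_p_is_uniform(self):
        # carriers assigned independently of labels -> p ~ Uniform(0,1)
        rng = np.random.default_rng(11)
        ps = []
        y = np.zeros(200, dtype=bool)
        y[:20] = True
        for _ in range(400):
            x = np.zeros(200)
            x[rng.choice(200, size=rng.integers(1, 6), replace=False)] = rng.choice(
                [0.3, 0.5, 0.9, 1.0], size=1
            )
            ps.append(burden_score_test(x, y, rng=rng).p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_permutation_and_score_test_agree_for_moderate_carriers(self):
        # 10-30 carriers: asymptotic p within Monte-Carlo error of permutation p
        rng = np.random.default_rng(5)
        n = 400
        for n_carriers in (15, 25):
            x = np.zeros(n)
            idx = rng.choice(n, size=n_carriers, replace=False)
            x[idx] = rng.choice([0.3, 0.5, 0.9, 1.0], size=n_carriers)
            y = np.zeros(n, dtype=bool)
            y[rng.choice(n, size=60, replace=False)] = True
            asym = burden_score_test(x, y)
            perm = burden_score_test(x, y, n_permutations=10_000, rng=rng)
            se = np.sqrt(perm.p * (1 - perm.p) / 10_000)
            assert abs(asym.p - perm.p) < max(4 * se, 0.01)


class TestCauchyCombine:
    def test_identity_on_single_input(self):
        assert cauchy_combine([0.03]) == pytest.approx(0.03, abs=1e-12)

    def test_fixed_point_on_identical_inputs(self):
        assert cauchy_combine([0.2, 0.2, 0.2]) == pytest.approx(0.2, abs=1e-12)

    def test_two_input_value_against_direct_formula(self):
        t = 0.5 * (math.tan((0.5 - 0.01) * math.pi) + math.tan((0.5 - 0.5) * math.pi))
        expected = 0.5 - math.atan(t) / math.pi
        assert cauchy_combine([0.01, 0.5]) == pytest.approx(expected, abs=1e-12)

    def test_tiny_p_stable(self):
        p = cauchy_combine([1e-20, 0.4])
        assert 0 < p < 1e-19

    def test_clamps_boundary_with_warning(self):
        with pytest.warns(UserWarning):
            p = cauchy_combine([0.0, 0.5])
        assert 0 < p < 1

    @given(
        st.lists(st.floats(1e-6, 1 - 1e-6), min_size=2, max_size=6),
        st.integers(0, 5),
        st.floats(0.1, 0.99),
    )
    @settings(max_examples=150, deadline=None)
    def test_monotone_in_each_input(self, ps, idx, factor):
        idx = idx % len(ps)
        smaller = list(ps)
        smaller[idx] = ps[idx] * factor
        assert cauchy_combine(smaller) <= cauchy_combine(ps) + 1e-12


class TestFisherNominal:
    def test_symmetric_table(self):
        r = fisher_nominal_test(1, 2, 1, 2)
        assert r.p == 1.0 and r.odds_ratio == 1.0

    def test_diagonal_table_enumeration_value(self):
        # [[2,0],[0,2]]: only the X=2 and X=0 tables are as extreme -> 1/3
        r = fisher_nominal_test(2, 2, 0, 2)
        assert r.p == pytest.approx(1 / 3, rel=1e-12)

    def test_cross_product_odds_ratio(self):
        r = fisher_nominal_test(2, 39, 2, 2764)
        assert r.odds_ratio == pytest.approx((2 * 2762) / (37 * 2), rel=1e-12)

    def test_haldane_correction_on_zero_cell(self):
        r = fisher_nominal_test(1, 39, 0, 2764)
        expected = (1.5 * 2764.5) / (38.5 * 0.5)
        assert r.odds_ratio == pytest.approx(expected, rel=1e-12)
        assert r.ci95_low < r.odds_ratio < r.ci95_high

    def test_zero_margin_untestable(self):
        assert fisher_nominal_test(0, 10, 0, 20).untestable


class TestGeneScan:
    def test_one_row_per_gene_with_eligible_variants(self, tiny_samples):
        n = len(tiny_samples)
        mvs = [masked_in_gene("G1", [0], 0.5, n, 10)]
        results = run_gene_scan(mvs, tiny_samples)
        assert [r.gene_symbol for r in results] == ["G1"]

    def test_tally_serialization_matches_table_syntax(self, tiny_samples):
        from cscakut.io_formats import format_mask_tally

        n = len(tiny_samples)
        mvs = [
            masked_in_gene("G1", [0], 0.9, n, 10, level=2, flag=False),
            masked_in_gene("G1", [1], 0.5, n, 20, level=4, flag=True),
        ]
        (res,) = run_gene_scan(mvs, tiny_samples)
        assert format_mask_tally(*res.case_tally) == "2/4:1_mask2|1_mask4m"
        assert format_mask_tally(*res.control_tally) == "0/8:"

    def test_deterministic_given_seed(self, tiny_samples):
        n = len(tiny_samples)
        mvs = [
            masked_in_gene("G1", [0, 5], 0.5, n, 10),
            masked_in_gene("G2", [1, 6], 0.9, n, 20, level=2, flag=False),
        ]
        a = run_gene_scan(mvs, tiny_samples, seed=7)
        b = run_gene_scan(mvs, tiny_samples, seed=7)
        assert [(r.gene_symbol, r.p_burden) for r in a] == [
            (r.gene_symbol, r.p_burden) for r in b
        ]


class TestQQ:
    def test_uniform_grid_on_diagonal(self):
        n = 200
        p = (np.arange(1, n + 1) - 0.5) / n
        expected, observed, lam = qq_points(p)
        assert np.allclose(expected, observed)
        assert lam == pytest.approx(1.0, abs=1e-3)  # even-n median interpolation

    def test_halving_p_shifts_observed_by_log10_2(self):
        n = 100
        p = (np.arange(1, n + 1) - 0.5) / n
        _, obs_full, _ = qq_points(p)
        _, obs_half, _ = qq_points(p / 2)
        assert np.allclose(obs_half - obs_full, np.log10(2))
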