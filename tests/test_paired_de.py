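import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from proteopair.io import IntensityMatrix
from proteopair.paired_de import (
    benjamini_hochberg,
    min_rank_list,
    paired_t_test,
    run_differential_expression,
    volcano_table,
    wilcoxon_signed_rank,
)


def wilcoxon_enumeration_oracle(d):
    """Two-sided exact Wilcoxon p by brute force over all sign patterns."""
    d = [v for v in d if v != 0]
    m = len(d)
    absd = [abs(v) for v in d]
    # average ranks
    ranks = []
    for v in absd:
        smaller = sum(1 for u in absd if u < v)
        equal = sum(1 for u in absd if u == v)
        ranks.append(smaller + (equal + 1) / 2)
    w_obs = sum(r for r, v in zip(ranks, d) if v > 0)
    mu = m * (m + 1) / 4
    count = 0
    for signs in itertools.product((0, 1), repeat=m):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / 2**m


def t_density(x, df):
    return (
        math.gamma((df + 1) / 2)
        / (math.sqrt(df * math.pi) * math.gamma(df / 2))
        * (1 + x**2 / df) ** (-(df + 1) / 2)
    )


class TestPairedT:
    def test_zero_mean_differences(self):
        t, p = paired_t_test([1, 0, 1, 0], [0, 1, 0, 1])
        assert t == 0.0 and p == 1.0

    def test_against_integrated_t_density(self):
        # d = [1, 2, 3, 4]: closed-form t, p by numerical tail integration
        t, p = paired_t_test([1, 2, 3, 4], [0, 0, 0, 0])
        d = np.array([1.0, 2, 3, 4])
        sd = d.std(ddof=1)
        t_expected = d.mean() / (sd / 2)
        assert math.isclose(t, t_expected, rel_tol=1e-12)
        assert math.isclose(t, 3.872983, rel_tol=1e-6)
        tail, _ = integrate.quad(t_density, abs(t), np.inf, args=(3,))
        assert math.isclose(p, 2 * tail, rel_tol=1e-8)
        assert math.isclose(p, 0.030466, rel_tol=1e-4)

    def test_constant_nonzero_differences_undefined(self):
        t, p = paired_t_test([2, 2, 2], [1, 1, 1])
        assert math.isnan(t) and math.isnan(p)

    def test_n_below_2_errors(self):
        with pytest.raises(ValueError):
            paired_t_test([1], [2])

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_swap_negates_t_keeps_p(self, x):
        y = [0.0] * len(x)
        t1, p1 = paired_t_test(x, y)
        t2, p2 = paired_t_test(y, x)
        if math.isnan(t1):
            assert math.isnan(t2)
        else:
            assert math.isclose(t1, -t2, rel_tol=1e-9, abs_tol=1e-12)
            assert math.isclose(p1, p2, rel_tol=1e-9)


class TestWilcoxon:
    def test_all_positive_n5_exact(self):
        w, p = wilcoxon_signed_rank([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert w == 15.0
        assert p == 2 / 32  # enumeration: only the two extreme sign patterns

    def test_all_zero_differences_undefined(self):
        w, p = wilcoxon_signed_rank([1, 1, 1, 1], [1, 1, 1, 1])
        assert math.isnan(p)

    def test_too_few_nonzero_undefined(self):
        w, p = wilcoxon_signed_rank([1, 2, 0, 0], [0, 0, 0, 0], min_nonzero=3)
        assert math.isnan(p)

    def test_swap_antisymmetry(self):
        x, y = [3.0, 1.0, 4.0, 1.5, 9.0], [2.0, 2.0, 2.0, 2.0, 2.0]
        _, p1 = wilcoxon_signed_rank(x, y)
        _, p2 = wilcoxon_signed_rank(y, x)
        assert math.isclose(p1, p2, rel_tol=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_matches_enumeration_random_no_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        d = rng.normal(0.5, 1.0, size=n)
        while len(np.unique(np.abs(d))) < n or (d == 0).any():
            d = rng.normal(0.5, 1.0, size=n)
        _, p = wilcoxon_signed_rank(d, np.zeros(n))
        assert math.isclose(p, wilcoxon_enumeration_oracle(d), rel_tol=1e-12)

    def test_ties_use_normal_approximation(self):
        # tied |d| values force the approximate branch; p must stay in (0, 1]
        d = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 4.0])
        _, p = wilcoxon_signed_rank(d, np.zeros_like(d))
        assert 0 < p <= 1

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(0)
        d = rng.normal(1, 1, size=20)
        _, p = wilcoxon_signed_rank(d, np.zeros_like(d))
        assert 0 < p < 0.05


class TestBenjaminiHochberg:
    def test_hand_step_up_three_values(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2]), [0.2])

    def test_all_equal_p(self):
        np.testing.assert_allclose(benjamini_hochberg([0.05] * 5), [0.05] * 5)

    def test_general_hand_case(self):
        # p sorted: .01, .04, .03 -> ascending .01,.03,.04
        # q: .01*3/1=.03; .03*3/2=.045; .04*3/3=.04 -> step-up: .03, .04, .04
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04]
        )

    def test_nan_excluded_from_m(self):
        q = benjamini_hochberg([0.01, math.nan, 0.02])
        assert math.isnan(q[1])
        np.testing.assert_allclose([q[0], q[2]], [0.02, 0.02])  # m = 2

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=150, deadline=None)
    def test_properties(self, ps):
        q = benjamini_hochberg(ps)
        assert (q >= np.asarray(ps) - 1e-12).all()
        assert (q <= 1).all()
        order = np.argsort(ps, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()  # monotone along sorted p

    @pytest.mark.parametrize("ps", [[0.01, 0.02, 0.03], [0.05] * 5, [0.5]])
    def test_idempotent_on_flat_adjusted_cases(self, ps):
        # adjusted values that come out tied (or singleton) are fixed points;
        # BH is NOT idempotent in general (e.g. [0.1, 0.5] -> [0.2, 0.5] -> [0.4, 0.5])
        q = benjamini_hochberg(ps)
        np.testing.assert_allclose(benjamini_hochberg(q), q)


def _matrix_from_values(values, n_subjects):
    n_proteins = values.shape[0]
    samples = [f"S{i}_A" for i in range(n_subjects)] + [f"S{i}_B" for i in range(n_subjects)]
    from proteopair.io import PairedDesign

    design = PairedDesign(
        subjects=[f"S{i}" for i in range(n_subjects)],
        condition_a="A",
        condition_b="B",
        pairs={f"S{i}": {"A": f"S{i}_A", "B": f"S{i}_B"} for i in range(n_subjects)},
    )
    m = IntensityMatrix(
        protein_ids=[f"P{i:03d}" for i in range(n_proteins)],
        sample_ids=samples,
        values=values,
    )
    return m, design


class TestRunDifferentialExpression:
    def test_synthetic_invariants(self, small_synthetic):
        (m, d, _), _ = small_synthetic
        de = run_differential_expression(m, d)
        df = de.table
        assert len(df) == 50
        n = len(df)
        for fam in ("t", "w", "prop"):
            p = df[f"{'w_p' if fam == 'w' else fam + '_p'}"]
            q = df[f"q_{fam}"]
            mask = ~p.isna()
            assert ((p[mask] >= 0) & (p[mask] <= 1)).all()
            assert (q[mask] >= p[mask] - 1e-12).all()
            r = df[f"rank_{fam}"]
            assert ((r >= 1) & (r <= n)).all()
        assert (df["min_rank"] <= df[["rank_t", "rank_w", "rank_prop"]].min(axis=1)).all()
        assert ((df["min_rank"] >= 1) & (df["min_rank"] <= n)).all()

    def test_never_observed_protein_gets_max_rank(self):
        rng = np.random.default_rng(1)
        values = rng.lognormal(3, 1, size=(5, 12))
        values[2, :] = 0.0
        m, d = _matrix_from_values(values, 6)
        de = run_differential_expression(m, d)
        row = de.table.iloc[2]
        assert math.isnan(row["t_p"]) and math.isnan(row["w_p"]) and math.isnan(row["prop_p"])
        assert row["min_rank"] == 5

    def test_planted_extreme_shift_gets_min_rank_1(self):
        rng = np.random.default_rng(2)
        n_sub = 10
        values = rng.lognormal(3, 0.5, size=(30, 2 * n_sub))
        values[0, :n_sub] = 1e6 + rng.random(n_sub)  # hugely shifted, all pairs positive
        values[0, n_sub:] = 0.0  # and condition-unique: extreme under all tests
        m, d = _matrix_from_values(values, n_sub)
        de = run_differential_expression(m, d)
        assert de.table.iloc[0]["min_rank"] == 1

    def test_log_transform_changes_effect_scale(self, small_synthetic):
        (m, d, _), _ = small_synthetic
        raw = run_differential_expression(m, d, transform="raw")
        logd = run_differential_expression(m, d, transform="log2p1")
        assert not np.allclose(
            raw.table["effect"].to_numpy(), logd.table["effect"].to_numpy()
        )

    def test_unknown_transform_errors(self, small_synthetic):
        (m, d, _), _ = small_synthetic
        with pytest.raises(ValueError):
            run_differential_expression(m, d, transform="sqrt")


class TestMinRankList:
    def test_permutation_of_ids(self, small_synthetic):
        (m, d, _), _ = small_synthetic
        de = run_differential_expression(m, d)
        ranked = min_rank_list(de)
        assert sorted(ranked) == sorted(de.table["protein_id"])

    def test_order_follows_min_rank(self, small_synthetic):
        (m, d, _), _ = small_synthetic
        de = run_differential_expression(m, d)
        ranked = min_rank_list(de)
        mr = dict(zip(de.table["protein_id"], de.table["min_rank"]))
        vals = [mr[p] for p in ranked]
        assert vals == sorted(vals)

    def test_ties_broken_by_prop_p_then_id(self):
        import pandas as pd

        from proteopair.paired_de import DifferentialResultTable

        df = pd.DataFrame(
            {
                "protein_id": ["B", "A", "C"],
                "min_rank": [1, 1, 1],
                "prop_p": [0.5, 0.5, 0.1],
            }
        )
        ranked = min_rank_list(DifferentialResultTable(table=df))
        assert ranked == ["C", "A", "B"]


class TestVolcanoTable:
    def test_neg_log10_values(self, small_synthetic):
        (m, d, _), _ = small_synthetic
        de = run_differential_expression(m, d)
        vt = volcano_table(de, "wilcoxon")
        assert (vt["neg_log10_p"] >= 0).all()
        n_defined = de.table["w_p"].notna().sum()
        assert len(vt) == n_defined

    def test_p_one_maps_to_zero(self):
        import pandas as pd

        from proteopair.paired_de import DifferentialResultTable

        df = pd.DataFrame(
            {"protein_id": ["A", "B"], "effect": [1.0, -1.0], "w_p": [1.0, 0.01]}
        )
        vt = volcano_table(DifferentialResultTable(table=df), "wilcoxon")
        np.testing.assert_allclose(vt["neg_log10_p"], [0.0, 2.0])

    def test_unknown_test_errors(self, small_synthetic):
        (m, d, _), _ = small_synthetic
        de = run_differential_expression(m, d)
        with pytest.raises(ValueError):
            volcano_table(de, "anova")
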