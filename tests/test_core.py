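import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rax2 import RaxError
from rax2.core import (
    ChiSquarePair,
    TwoByTwoSeries,
    build_two_by_two,
    chi2_pairs,
    compute_chi2_pairs,
    declare,
    declared_sets,
    null_chi2,
    pearson_chi2,
    rank_profiles,
    scan_thresholds,
    series_matrix,
    treatment_chi2,
)

from conftest import make_table


def generic_chi2(table):
    """Independent oracle: sum over cells of (O - E)^2 / E."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    e = np.outer(rows, cols) / n
    return float(((t - e) ** 2 / e).sum())


# ---------------------------------------------------------------------------
# pearson_chi2
# ---------------------------------------------------------------------------

class TestPearsonChi2:
    def test_independent_table_zero(self):
        assert pearson_chi2([[10, 10], [10, 10]]) == 0.0

    def test_closed_form_example(self):
        # [DERIVED] 60 * 300^2 / 30^4 = 6.666...
        assert pearson_chi2([[20, 10], [10, 20]]) == pytest.approx(20 / 3, abs=1e-12)

    def test_diagonal_example(self):
        # [DERIVED] 10 * 25^2 / 5^4 = 10
        assert pearson_chi2([[5, 0], [0, 5]]) == pytest.approx(10.0, abs=1e-12)

    def test_negative_entry_errors(self):
        with pytest.raises(RaxError, match="negative"):
            pearson_chi2([[1, -1], [2, 3]])

    def test_zero_marginal_returns_zero(self):
        assert pearson_chi2([[0, 0], [3, 4]]) == 0.0
        assert pearson_chi2([[0, 3], [0, 4]]) == 0.0

    @given(st.lists(st.floats(0.01, 1e4), min_size=4, max_size=4))
    @settings(max_examples=200, deadline=None)
    def test_matches_generic_form(self, cells):
        table = np.array(cells).reshape(2, 2)
        assert pearson_chi2(table) == pytest.approx(generic_chi2(table), rel=1e-10)

    @given(st.lists(st.floats(0.01, 100), min_size=4, max_size=4),
           st.floats(0.01, 50))
    @settings(max_examples=100, deadline=None)
    def test_degree_one_homogeneity(self, cells, c):
        table = np.array(cells).reshape(2, 2)
        assert pearson_chi2(c * table) == pytest.approx(
            c * pearson_chi2(table), rel=1e-9)


# ---------------------------------------------------------------------------
# series construction
# ---------------------------------------------------------------------------

class TestBuildTwoByTwo:
    def test_complement_is_other_tag(self, two_tag_table):
        s = build_two_by_two(two_tag_table, "t000")
        np.testing.assert_array_equal(s.cells[0, 0], [1, 2, 3])
        np.testing.assert_array_equal(s.cells[0, 1], [4, 5, 6])
        np.testing.assert_array_equal(s.cells[1, 0], [6, 5, 4])
        np.testing.assert_array_equal(s.cells[1, 1], [3, 2, 1])

    def test_three_tag_complement(self):
        counts = np.arange(12, dtype=float).reshape(3, 4)
        t = make_table([3], counts, r=2)
        s = build_two_by_two(t, "t000")
        np.testing.assert_array_equal(
            s.cells[1].ravel(), (counts[1] + counts[2]))

    def test_row_sums_match_gene_totals(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 50, size=(4, 6)).astype(float)
        t = make_table([4], counts)
        gene_total = counts.sum(axis=0)
        for tag in t.tag_ids:
            s = build_two_by_two(t, tag)
            got = (s.cells[0] + s.cells[1])  # (2, r) in condition blocks
            np.testing.assert_array_equal(got.ravel(), gene_total)

    def test_single_tag_gene_errors(self, toy_table):
        with pytest.raises(RaxError, match="single-tag"):
            build_two_by_two(toy_table, "t002")


# ---------------------------------------------------------------------------
# treatment and null chi-squares
# ---------------------------------------------------------------------------

class TestTreatmentChi2:
    def test_r1_equals_single_table(self):
        s = TwoByTwoSeries("x", np.array([[20, 10], [10, 20]], float)[..., None])
        assert treatment_chi2(s) == pearson_chi2([[20, 10], [10, 20]])

    def test_identical_replicates(self):
        one = np.array([[7, 3], [2, 9]], float)
        s = TwoByTwoSeries("x", np.repeat(one[..., None], 3, axis=2))
        assert treatment_chi2(s) == pytest.approx(pearson_chi2(one), abs=1e-12)

    def test_heterogeneous_replicates_mean_table(self):
        # [DERIVED] replicates averaging to [[20,10],[10,20]] -> 6.6667
        cells = np.zeros((2, 2, 2))
        cells[0, 0] = [10, 30]
        cells[0, 1] = [5, 15]
        cells[1, 0] = [12, 8]
        cells[1, 1] = [25, 15]
        s = TwoByTwoSeries("x", cells)
        assert treatment_chi2(s) == pytest.approx(20 / 3, abs=1e-12)


class TestNullChi2:
    def test_identical_within_condition_zero(self):
        cells = np.zeros((2, 2, 3))
        cells[:, 0, :] = np.array([[4.0], [6.0]])
        cells[:, 1, :] = np.array([[9.0], [1.0]])
        assert null_chi2(TwoByTwoSeries("x", cells)) == 0.0

    def test_proportional_pair_contributes_zero(self):
        # [DERIVED] pair table [[3,6],[9,18]] has det 3*18-6*9 = 0
        cells = np.zeros((2, 2, 2))
        cells[0, 0] = [3, 6]
        cells[1, 0] = [9, 18]
        cells[0, 1] = [5, 5]
        cells[1, 1] = [5, 5]
        assert null_chi2(TwoByTwoSeries("x", cells)) == 0.0

    def test_r2_max_of_condition_pair_chi2(self):
        # [DERIVED by hand] r=2: one pair table per condition; the null value
        # is the larger of the two pair chi-squares (noisier condition).
        cells = np.zeros((2, 2, 2))
        cells[0, 0] = [20, 10]
        cells[1, 0] = [10, 20]   # condition 1 pair table [[20,10],[10,20]]
        cells[0, 1] = [5, 0]
        cells[1, 1] = [0, 5]     # condition 2 pair table [[5,0],[0,5]]
        got = null_chi2(TwoByTwoSeries("x", cells))
        assert got == pytest.approx(max(20 / 3, 10.0), abs=1e-12)

    def test_r_must_be_at_least_two(self):
        s = TwoByTwoSeries("x", np.ones((2, 2, 1)))
        with pytest.raises(RaxError, match="replicates required"):
            null_chi2(s)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(5)
        cells = rng.integers(0, 30, size=(20, 2, 2, 4)).astype(float)
        treat, null = compute_chi2_pairs(cells)
        for k in range(20):
            s = TwoByTwoSeries(f"t{k}", cells[k])
            assert treat[k] == pytest.approx(treatment_chi2(s), abs=1e-10)
            assert null[k] == pytest.approx(null_chi2(s), abs=1e-10)

    def test_condition_swap_invariance(self):
        rng = np.random.default_rng(6)
        cells = rng.integers(0, 30, size=(2, 2, 3)).astype(float)
        s = TwoByTwoSeries("x", cells)
        swapped = TwoByTwoSeries("x", cells[:, ::-1, :])
        assert treatment_chi2(s) == pytest.approx(treatment_chi2(swapped), abs=1e-12)
        assert null_chi2(s) == pytest.approx(null_chi2(swapped), abs=1e-12)

    def test_tag_state_swap_invariance(self):
        rng = np.random.default_rng(7)
        cells = rng.integers(0, 30, size=(2, 2, 3)).astype(float)
        s = TwoByTwoSeries("x", cells)
        swapped = TwoByTwoSeries("x", cells[::-1, :, :])
        assert treatment_chi2(s) == pytest.approx(treatment_chi2(swapped), abs=1e-12)
        assert null_chi2(s) == pytest.approx(null_chi2(swapped), abs=1e-12)


def test_tag_scaling_scales_treatment_chi2():
    rng = np.random.default_rng(8)
    cells = rng.integers(1, 30, size=(2, 2, 3)).astype(float)
    s = TwoByTwoSeries("x", cells)
    for c in (0.5, 2.0, 7.3):
        sc = TwoByTwoSeries("x", c * cells)
        assert treatment_chi2(sc) == pytest.approx(
            c * treatment_chi2(s), rel=1e-10)


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

class TestRankProfiles:
    def test_independent_sorting(self):
        pairs = [ChiSquarePair("a", 5, 1), ChiSquarePair("b", 1, 3)]
        p = rank_profiles(pairs)
        np.testing.assert_array_equal(p.sorted_treat, [1, 5])
        np.testing.assert_array_equal(p.sorted_null, [1, 3])
        assert p.treat_tags == ["b", "a"]

    def test_null_max_is_last(self):
        pairs = [ChiSquarePair(f"t{k}", k, 10 - k) for k in range(5)]
        p = rank_profiles(pairs)
        assert p.chi2_null_max == max(q.chi2_null for q in pairs)
        assert p.chi2_null_max == p.sorted_null[-1]

    def test_back_map(self):
        pairs = [ChiSquarePair("a", 5, 1), ChiSquarePair("b", 1, 3),
                 ChiSquarePair("c", 3, 2)]
        p = rank_profiles(pairs)
        assert p.rank_of("b") == 1
        assert p.rank_of("c") == 2
        assert p.rank_of("a") == 3

    def test_ties_broken_by_tag_id(self):
        pairs = [ChiSquarePair("z", 2, 1), ChiSquarePair("a", 2, 1)]
        p = rank_profiles(pairs)
        assert p.treat_tags == ["a", "z"]

    def test_degenerate_null_errors(self):
        pairs = [ChiSquarePair("a", 1, 0), ChiSquarePair("b", 2, 0)]
        with pytest.raises(RaxError, match="degenerate null"):
            rank_profiles(pairs)

    def test_too_few_pairs(self):
        with pytest.raises(RaxError, match="at least 2"):
            rank_profiles([ChiSquarePair("a", 1, 1)])


# ---------------------------------------------------------------------------
# threshold scan: brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_scan(sorted_treat, sorted_null, r, n_grid, x=None):
    """Position-by-position enumeration of a, b, N, F for every grid delta."""
    S = len(sorted_treat)
    null_max = sorted_null[-1]
    if x is None:
        x = (2.0 * r / null_max) ** 2
    out = []
    for g in range(n_grid + 1):
        delta = (g / n_grid) * null_max
        d = [t - e for t, e in zip(sorted_treat, sorted_null)]
        a = None
        for cand in range(1, S + 1):  # smallest a with ALL later d > delta
            if all(d[s] > delta for s in range(cand - 1, S)):
                a = cand
                break
        if a is None:
            out.append((delta, 0, 0, 0, 0.0, None))
            continue
        N = S - a + 1
        b = None
        for t in range(1, S + 1):
            if sorted_null[t - 1] - sorted_null[a - 1] > delta:
                b = t
                break
        if b is None:
            F = 0.0
        else:
            F = sum(((sorted_null[t - 1] * t) / (null_max * S)) ** x
                    for t in range(b, S + 1))
        out.append((delta, a, b or 0, N, F, min(1.0, F / N)))
    return out


class TestScanThresholds:
    def test_matches_brute_force_10_tags(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            treat = np.sort(rng.gamma(2, 2, size=10))
            null = np.sort(rng.gamma(1, 1, size=10)) + 0.01
            pairs = [ChiSquarePair(f"t{k}", float(treat[k]), float(null[k]))
                     for k in range(10)]
            p = rank_profiles(pairs)
            curve = scan_thresholds(p, r=3, n_grid=13)
            oracle = brute_force_scan(p.sorted_treat.tolist(),
                                      p.sorted_null.tolist(), r=3, n_grid=13)
            for rec, (delta, a, b, N, F, fdr) in zip(
                    curve.table.itertuples(), oracle):
                assert rec.delta == pytest.approx(delta, abs=1e-12)
                if fdr is None:
                    assert not rec.defined
                    assert rec.N == 0 and rec.F == 0
                else:
                    assert rec.defined
                    assert (rec.a, rec.b, rec.N) == (a, b, N)
                    assert rec.F == pytest.approx(F, rel=1e-10)
                    assert rec.fdr == pytest.approx(fdr, rel=1e-10)

    def test_delta_zero_all_d_positive(self):
        pairs = [ChiSquarePair(f"t{k}", k + 2.0, k + 1.0) for k in range(6)]
        p = rank_profiles(pairs)
        curve = scan_thresholds(p, r=3, n_grid=10)
        rec0 = curve.table.iloc[0]
        assert rec0.defined and rec0.a == 1 and rec0.N == 6

    def test_x_zero_counts_null_points(self):
        # [PAPER-verified limit] x -> 0 => p -> 1 and F -> S - b + 1
        pairs = [ChiSquarePair(f"t{k}", 3.0 * (k + 1), float(k + 1))
                 for k in range(8)]
        p = rank_profiles(pairs)
        curve = scan_thresholds(p, r=3, n_grid=4, x=0.0)
        for rec in curve.table.itertuples():
            if rec.defined and rec.b > 0:
                assert rec.F == pytest.approx(p.S - rec.b + 1, abs=1e-12)

    def test_top_position_probability_is_one(self):
        # t* = S* has p = 1 for any x: force b = S and check F = 1
        null = [1.0, 1.0, 1.0, 1.0, 10.0]
        treat = [20, 21, 22, 23, 24.0]
        pairs = [ChiSquarePair(f"t{k}", treat[k], null[k]) for k in range(5)]
        p = rank_profiles(pairs)
        curve = scan_thresholds(p, r=3, n_grid=2)  # deltas 0, 5, 10
        rec = curve.table.iloc[1]  # delta = 5: b must be position 5 (value 10)
        assert rec.defined and rec.b == 5
        assert rec.F == pytest.approx(1.0, abs=1e-12)

    def test_monotone_N_and_F(self):
        rng = np.random.default_rng(12)
        treat = np.sort(rng.gamma(3, 2, size=40))
        null = np.sort(rng.gamma(1, 1, size=40)) + 0.01
        pairs = [ChiSquarePair(f"t{k}", float(treat[k]), float(null[k]))
                 for k in range(40)]
        p = rank_profiles(pairs)
        curve = scan_thresholds(p, r=3)
        d = curve.table[curve.table.defined]
        assert (np.diff(d.N) <= 0).all()
        assert (np.diff(d.F) <= 1e-12).all()
        # undefined records form a suffix of the grid
        flags = curve.table.defined.to_numpy()
        assert not np.any(~flags[:-1] & flags[1:])

    def test_x_default_formula(self):
        pairs = [ChiSquarePair("a", 2, 1), ChiSquarePair("b", 4, 2)]
        p = rank_profiles(pairs)
        curve = scan_thresholds(p, r=5)
        assert curve.x == pytest.approx((2 * 5 / 2.0) ** 2)


# ---------------------------------------------------------------------------
# declaration
# ---------------------------------------------------------------------------

class TestDeclare:
    def _profile(self):
        # strong separation at the top: last 3 tags way above null
        treat = [0.5, 0.6, 0.7, 0.8, 10.0, 12.0, 15.0]
        null = [0.4, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2]
        pairs = [ChiSquarePair(f"t{k}", treat[k], null[k]) for k in range(7)]
        return rank_profiles(pairs)

    def test_alpha_one_largest_set(self):
        p = self._profile()
        curve = scan_thresholds(p, r=3)
        decl = declare(p, curve, alpha=1.0)
        defined = curve.defined()
        largest = defined.N.max()
        assert len(decl.declared) == largest

    def test_all_d_nonpositive_empty(self):
        pairs = [ChiSquarePair(f"t{k}", 0.5 * (k + 1), float(k + 1))
                 for k in range(5)]
        p = rank_profiles(pairs)
        curve = scan_thresholds(p, r=3)
        with pytest.warns(UserWarning, match="no threshold"):
            decl = declare(p, curve, alpha=0.05)
        assert decl.declared == set()
        assert not curve.table.defined.any()

    def test_declared_size_equals_N(self):
        p = self._profile()
        curve = scan_thresholds(p, r=3)
        decl = declare(p, curve, alpha=0.5)
        assert decl.record is not None
        assert len(decl.declared) == decl.record["N"]
        # declared set = top-N by treatment chi-square
        ranks = [p.rank_of(tag) for tag in decl.declared]
        assert sorted(ranks) == list(range(p.S - len(decl.declared) + 1, p.S + 1))

    def test_report_columns_and_flags(self):
        p = self._profile()
        curve = scan_thresholds(p, r=3)
        decl = declare(p, curve, alpha=0.5)
        rep = decl.report
        assert list(rep.columns) == ["tagid", "chi2_treat", "chi2_null",
                                     "rank", "declared", "fdr",
                                     "delta_at_declaration"]
        assert rep.declared.sum() == len(decl.declared)
        declared_rows = rep[rep.declared]
        assert declared_rows.fdr.notna().all()

    def test_declared_sets_align_with_curve(self):
        p = self._profile()
        curve = scan_thresholds(p, r=3)
        sets = declared_sets(p, curve)
        for rec, s in zip(curve.table.itertuples(), sets):
            if rec.defined:
                assert len(s) == rec.N
            else:
                assert s is None


def test_chi2_pairs_table_roundtrip(two_tag_table):
    pairs = chi2_pairs(two_tag_table)
    assert {p.tag_id for p in pairs} == {"t000", "t001"}
    s = build_two_by_two(two_tag_table, "t000")
    byid = {p.tag_id: p for p in pairs}
    assert byid["t000"].chi2_treat == pytest.approx(treatment_chi2(s))
    assert byid["t000"].chi2_null == pytest.approx(null_chi2(s))


def test_series_matrix_skips_single_tag_genes(toy_table):
    cells, tags = series_matrix(toy_table)
    assert tags == ["t000", "t001"]
    assert cells.shape == (2, 2, 2, 3)
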