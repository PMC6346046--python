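"""Contingency tables, Haldane correction, margin-conditioned sampling, and
the cross-tissue ratio-of-odds-ratios permutation test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from purkinet import ror
from purkinet.io import GeneSet


def _null_tables(rng, margins):
    tables = {}
    for key, (r, c) in margins.items():
        draw = ror.patefield_sample(r, c, 1, rng=rng)[0]
        tables[key] = ror.ContingencyTable(draw, tissue=key[0],
                                           list_name=key[1])
    return tables


MARGINS = {("A", "ID"): ((40, 400), (60, 380)),
           ("A", "ID_free"): ((45, 395), (60, 380)),
           ("B", "ID"): ((40, 400), (55, 385)),
           ("B", "ID_free"): ((45, 395), (55, 385))}


class TestTables:
    def test_build_two_by_two_printed_counts(self):
        # 30-gene ID list, 8 in cluster -> first row (8, 22)
        universe = GeneSet("u", [f"g{i}" for i in range(500)])
        id_list = GeneSet("id", [f"g{i}" for i in range(30)])
        cluster = GeneSet("c", [f"g{i}" for i in range(8)]
                          + [f"g{i}" for i in range(100, 150)])
        t = ror.build_two_by_two(id_list, cluster, universe)
        assert t.cells[0].tolist() == [8, 22]
        assert t.cells[1].tolist() == [50, 420]
        assert t.total == 500

    def test_degenerate_set_equals_cluster_equals_universe(self):
        u = GeneSet("u", [f"g{i}" for i in range(7)])
        t = ror.build_two_by_two(u, u, u)
        assert t.cells.tolist() == [[7, 0], [0, 0]]

    def test_haldane_rules(self):
        t = ror.ContingencyTable([[8, 22], [0, 11]])
        c = ror.haldane_correct(t)
        assert c.cells.tolist() == [[8.5, 22.5], [0.5, 11.5]] and c.corrected
        clean = ror.ContingencyTable([[1, 29], [3, 8]])
        assert ror.haldane_correct(clean) is clean
        assert ror.haldane_correct(c) is c  # no double correction


class TestOddsRatios:
    def test_printed_counts_oracle(self):
        assert ror.odds_ratio(ror.ContingencyTable([[1, 29], [3, 8]])) == (
            pytest.approx(8 / 87, rel=1e-12))
        corrected = ror.haldane_correct(ror.ContingencyTable([[8, 22], [0, 11]]))
        assert ror.odds_ratio(corrected) == pytest.approx(97.75 / 11.25,
                                                          rel=1e-12)

    def test_symmetric_table_is_one(self):
        assert ror.odds_ratio(ror.ContingencyTable([[4, 4], [4, 4]])) == 1.0

    def test_uncorrected_zero_is_error(self):
        with pytest.raises(ValueError, match="haldane"):
            ror.odds_ratio(ror.ContingencyTable([[3, 0], [2, 5]]))

    def test_delta_on_printed_syndromic_counts(self):
        or_neo = ror.odds_ratio(
            ror.haldane_correct(ror.ContingencyTable([[8, 22], [0, 11]])))
        or_pc = ror.odds_ratio(ror.ContingencyTable([[1, 29], [3, 8]]))
        delta = ror.ror_statistic(or_neo, 1.0, or_pc, 1.0)
        expected = abs(np.log10((8.5 / 22.5) / (0.5 / 11.5))
                       - np.log10((1 / 29) / (3 / 8)))
        assert delta == pytest.approx(expected, rel=1e-12)
        assert delta == pytest.approx(1.9754, abs=1e-4)

    def test_delta_symmetries(self):
        assert ror.ror_statistic(2.0, 1.0, 2.0, 1.0) == 0.0
        a = ror.ror_statistic(3.0, 0.5, 0.2, 1.5)
        b = ror.ror_statistic(0.2, 1.5, 3.0, 0.5)
        assert a == pytest.approx(b)
        with pytest.raises(ValueError):
            ror.ror_statistic(0.0, 1.0, 1.0, 1.0)


def _enumerate_tables(rows, cols):
    """All tables with the given margins, with their exact probabilities."""
    support = []
    r, c = len(rows), len(cols)
    from scipy.special import gammaln

    def log_fact(x):
        return gammaln(np.asarray(x) + 1.0)

    cells_iter = itertools.product(
        *[range(min(rows[i // c], cols[i % c]) + 1) for i in range(r * c)])
    for flat in cells_iter:
        t = np.array(flat).reshape(r, c)
        if (t.sum(axis=1) == rows).all() and (t.sum(axis=0) == cols).all():
            logp = (log_fact(rows).sum() + log_fact(cols).sum()
                    - log_fact(sum(rows)) - log_fact(t).sum())
            support.append((t, np.exp(logp)))
    return support


class TestPatefieldSampler:
    def test_margins_always_reproduced(self):
        rng = np.random.default_rng(0)
        draws = ror.patefield_sample((3, 2), (2, 2, 1), 500, rng=rng)
        assert (draws.sum(axis=2) == [3, 2]).all()
        assert (draws.sum(axis=1) == [2, 2, 1]).all()

    def test_2x2_enumeration_probabilities(self):
        # margins (2,2)/(2,2): P(a11=0)=1/6, P(1)=4/6, P(2)=1/6
        draws = ror.patefield_sample((2, 2), (2, 2), 100_000, seed=1)
        a = draws[:, 0, 0]
        obs = np.bincount(a, minlength=3)
        chi2, p = stats.chisquare(obs, 100_000 * np.array([1, 4, 1]) / 6)
        assert p > 0.01

    def test_2x3_matches_full_enumeration(self):
        rows, cols = (3, 2), (2, 2, 1)
        support = _enumerate_tables(rows, cols)
        assert abs(sum(p for _, p in support) - 1) < 1e-12
        n = 100_000
        draws = ror.patefield_sample(rows, cols, n, seed=2)
        for t, p in support:
            obs = (draws == t).all(axis=(1, 2)).sum()
            se = np.sqrt(n * p * (1 - p))
            assert abs(obs - n * p) <= 3 * se + 1e-9

    def test_cell_means_match_independence_expectation(self):
        rng = np.random.default_rng(3)
        for rows, cols in [((40, 400), (60, 380)), ((10, 5), (7, 8))]:
            n = 100_000
            draws = ror.patefield_sample(rows, cols, n, rng=rng)
            N = sum(rows)
            expect = np.outer(rows, cols) / N
            sd = np.sqrt(np.maximum(draws.var(axis=0), 1e-12) / n)
            assert np.all(np.abs(draws.mean(axis=0) - expect) <= 3 * sd + 1e-9)

    def test_agrees_with_scipy_random_table(self):
        # independent oracle: scipy's fixed-margin table sampler
        rows, cols = (8, 12), (10, 10)
        ours = ror.patefield_sample(rows, cols, 50_000, seed=4)
        scipy_draws = stats.random_table(rows, cols).rvs(
            50_000, random_state=np.random.default_rng(5))
        for k in range(min(rows[0], cols[0]) + 1):
            f1 = (ours[:, 0, 0] == k).mean()
            f2 = (scipy_draws[:, 0, 0] == k).mean()
            se = np.sqrt(max(f2 * (1 - f2), 1e-8) / 50_000) * 2
            assert abs(f1 - f2) <= 3 * se + 0.003

    def test_margin_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ror.patefield_sample((3, 2), (2, 2, 2), 1)


class TestPermutationTest:
    def test_determinism_and_add_one_convention(self):
        rng = np.random.default_rng(7)
        tables = _null_tables(rng, MARGINS)
        r1 = ror.ror_permutation_test(tables, 2000, seed=42)
        r2 = ror.ror_permutation_test(tables, 2000, seed=42)
        assert r1.exceedances == r2.exceedances
        assert r1.pvalue == (r1.exceedances + 1) / 2001
        assert r1.pvalue > 0

    def test_identical_tissues_delta_zero_p_high(self):
        t = ror.ContingencyTable([[10, 30], [50, 410]])
        tables = {(ts, l): ror.ContingencyTable(t.cells.copy(), tissue=ts,
                                                list_name=l)
                  for ts in ("A", "B") for l in ("ID", "ID_free")}
        res = ror.ror_permutation_test(tables, 2000, seed=0)
        assert res.delta == 0.0
        assert res.pvalue >= 0.5

    def test_null_calibration(self):
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(300):
            tables = _null_tables(rng, MARGINS)
            res = ror.ror_permutation_test(
                tables, 2000, seed=int(rng.integers(2 ** 31)))
            pvals.append(res.pvalue)
        pvals = np.array(pvals)
        rate = (pvals <= 0.05).mean()
        assert 0.02 <= rate <= 0.08
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_exceedances_monotone_in_observed_delta(self):
        # same margins and seed, increasingly extreme observed tables:
        # the exceedance count must be non-increasing in the observed delta
        def tables_for(a11):
            t = {}
            for ts in ("A", "B"):
                shift = a11 if ts == "A" else 6  # tissue A varies, B fixed
                t[(ts, "ID")] = ror.ContingencyTable(
                    [[shift, 40 - shift], [60 - shift, 400 + shift - 60]],
                    tissue=ts, list_name="ID")
                t[(ts, "ID_free")] = ror.ContingencyTable(
                    [[6, 39], [54, 341]], tissue=ts, list_name="ID_free")
            return t

        runs = [ror.ror_permutation_test(tables_for(a), 5000, seed=11)
                for a in (6, 12, 20, 30)]
        deltas = [r.delta for r in runs]
        assert deltas == sorted(deltas)
        exceed = [r.exceedances for r in runs]
        assert exceed == sorted(exceed, reverse=True)

    def test_zero_margin_rejected(self):
        bad = {k: ror.ContingencyTable([[0, 0], [5, 5]], tissue=k[0],
                                       list_name=k[1])
               for k in MARGINS}
        with pytest.raises(ValueError, match="margin"):
            ror.ror_permutation_test(bad, 10, seed=0)

    def test_converges_to_enumeration_on_tiny_margins(self):
        # tiny margins allow exhaustive enumeration of the null law of delta
        margins = {("A", "ID"): ((2, 3), (2, 3)),
                   ("A", "ID_free"): ((2, 3), (2, 3)),
                   ("B", "ID"): ((2, 3), (2, 3)),
                   ("B", "ID_free"): ((2, 3), (2, 3))}
        obs_cells = {("A", "ID"): [[2, 0], [0, 3]],
                     ("A", "ID_free"): [[1, 1], [1, 2]],
                     ("B", "ID"): [[0, 2], [2, 1]],
                     ("B", "ID_free"): [[2, 0], [0, 3]]}
        tables = {k: ror.ContingencyTable(obs_cells[k], tissue=k[0],
                                          list_name=k[1])
                  for k in margins}
        support = _enumerate_tables((2, 3), (2, 3))

        def table_or(t):
            c = t.astype(float)
            if (c == 0).any():
                c = c + 0.5
            return (c[0, 0] * c[1, 1]) / (c[0, 1] * c[1, 0])

        obs_or = {k: ror.odds_ratio(ror.haldane_correct(t))
                  for k, t in tables.items()}
        delta_obs = ror.ror_statistic(
            obs_or[("A", "ID")], obs_or[("A", "ID_free")],
            obs_or[("B", "ID")], obs_or[("B", "ID_free")])
        exact = 0.0
        for ta, pa in support:
            for tb, pb in support:
                for tc_, pc in support:
                    for td, pd_ in support:
                        d = abs(np.log10(table_or(ta) / table_or(tb))
                                - np.log10(table_or(tc_) / table_or(td)))
                        if d >= delta_obs - 1e-12:
                            exact += pa * pb * pc * pd_
        assert 0 < delta_obs
        res = ror.ror_permutation_test(tables, 100_000, seed=3)
        se = np.sqrt(exact * (1 - exact) / 100_000)
        assert abs(res.pvalue - exact) <= 2 * se + 2 / 100_000


class TestStratifiedFDR:
    def test_bh_across_strata(self):
        def mk(p, stratum):
            return ror.RORTestResult({}, {}, 1.0, 100, int(p * 101) - 1, p, 0,
                                     stratum=stratum)
        results = [mk(0.001, "syndromic_only"), mk(0.04, "categories_1_4")]
        out = ror.stratified_fdr(results)
        assert out[0].qvalue == pytest.approx(0.002)
        assert out[1].qvalue == pytest.approx(0.04)

    def test_single_stratum_identity(self):
        r = ror.RORTestResult({}, {}, 1.0, 100, 10, 0.1089, 0)
        assert ror.stratified_fdr([r])[0].qvalue == pytest.approx(0.1089)


class TestOverlapDepletion:
    def test_printed_study_counts_exact_tail(self):
        # 182 genes, |A|=59, |B|=39, overlap 1: exact lower tail
        genes = [f"g{i}" for i in range(182)]
        universe = GeneSet("u", genes)
        a = GeneSet("a", genes[:59])
        b = GeneSet("b", genes[58:96])  # overlap {g58}, |B|=38+1=39? fix below
        b = GeneSet("b", [genes[58]] + genes[59:97])
        overlap, p = ror.overlap_depletion_test(a, b, universe, tail="less")
        assert overlap == ["g58"]
        exact = sum(stats.hypergeom.pmf(k, 182, 59, 39) for k in (0, 1))
        assert p == pytest.approx(exact, rel=1e-9)
        assert p < 1e-5  # far below the printed 5.8e-4 (universe ambiguity)

    def test_boundary_cases(self):
        genes = [f"g{i}" for i in range(20)]
        u = GeneSet("u", genes)
        a = GeneSet("a", genes[:10])
        b = GeneSet("b", genes[10:])
        overlap, p = ror.overlap_depletion_test(a, b, u, tail="less")
        assert overlap == [] and p == pytest.approx(
            stats.hypergeom.pmf(0, 20, 10, 10))
        overlap2, p2 = ror.overlap_depletion_test(a, a, u, tail="greater")
        assert len(overlap2) == 10
        assert p2 == pytest.approx(stats.hypergeom.pmf(10, 20, 10, 10))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(1, 30), st.integers(1, 30), st.integers(1, 30),
       st.integers(1, 30))
def test_haldane_preserves_or_sign_relation(a, b, c, d):
    """Haldane on a zero-free table is the identity; OR stays (a d)/(b c)."""
    t = ror.ContingencyTable([[a, b], [c, d]])
    out = ror.haldane_correct(t)
    assert out is t
    assert ror.odds_ratio(out) == pytest.approx((a * d) / (b * c))
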