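from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from rddmkit.core import GenomeLayout, ParameterError, Tiling
from rddmkit.methylation import bin_context_levels, call_dmrs, dmr_test, site_level


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact-rational two-sided Fisher p for the table [[a, b], [c, d]]."""
    r1, r2, n = a + b, c + d, a + c
    denom = comb(r1 + r2, n)

    def pmf(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, n - x), denom)

    p_obs = pmf(a)
    total = Fraction(0)
    for x in range(max(0, n - r2), min(n, r1) + 1):
        px = pmf(x)
        if px <= p_obs:
            total += px
    return float(total)


def _sites(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]
    )


class TestSiteLevel:
    @pytest.mark.parametrize(
        "m,u,expected", [(4, 6, 0.4), (0, 10, 0.0), (10, 0, 1.0)]
    )
    def test_defined_levels(self, m, u, expected):
        assert site_level(m, u) == pytest.approx(expected)

    def test_below_coverage_floor_undefined(self):
        assert site_level(2, 2) is None  # coverage 4 < 5

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            site_level(-1, 3)


class TestBinLevels:
    def _tiling(self, length=300):
        return Tiling(GenomeLayout((("Chr1", length),)), 100, 100)

    def test_coverage_weighted_pooling(self):
        sites = _sites(
            [("Chr1", 10, "+", "CHH", 5, 5), ("Chr1", 20, "+", "CHH", 10, 0)]
        )
        out = bin_context_levels(sites, self._tiling(), "CHH")
        assert out["level"].iloc[0] == pytest.approx(15 / 20)
        assert out["n_sites"].iloc[0] == 2

    def test_low_coverage_site_dropped(self):
        sites = _sites([("Chr1", 10, "+", "CHH", 2, 2)])
        out = bin_context_levels(sites, self._tiling(), "CHH")
        assert np.isnan(out["level"].iloc[0])
        assert out["n_sites"].iloc[0] == 0

    def test_empty_bin_undefined(self):
        out = bin_context_levels(_sites([]), self._tiling(), "CG")
        assert out["level"].isna().all()

    def test_context_filtering(self):
        sites = _sites(
            [("Chr1", 10, "+", "CG", 10, 0), ("Chr1", 20, "+", "CHH", 0, 10)]
        )
        out = bin_context_levels(sites, self._tiling(), "CG")
        assert out["level"].iloc[0] == 1.0

    def test_agrees_with_direct_recomputation(self, rng):
        tiling = Tiling(GenomeLayout((("Chr1", 2000),)), 100, 50)
        rows = []
        for _ in range(300):
            rows.append(
                ("Chr1", int(rng.integers(0, 2000)), "+", "CHH",
                 int(rng.integers(0, 20)), int(rng.integers(0, 20)))
            )
        sites = _sites(rows)
        out = bin_context_levels(sites, tiling, "CHH", min_reads=5)
        # brute-force oracle over bins
        for b in range(tiling.n_total):
            s = (b % tiling.n_bins_of("Chr1")) * 50
            sel = sites[(sites.pos >= s) & (sites.pos < s + 100)]
            sel = sel[sel.n_meth + sel.n_unmeth >= 5]
            if len(sel) == 0:
                assert np.isnan(out["level"].iloc[b])
            else:
                want = sel.n_meth.sum() / (sel.n_meth.sum() + sel.n_unmeth.sum())
                assert out["level"].iloc[b] == pytest.approx(want)


class TestDmrTest:
    def test_identical_tables(self):
        p, diff = dmr_test(10, 10, 10, 10)
        assert p == 1.0 and diff == 0.0

    def test_strong_difference_matches_oracle(self):
        p, diff = dmr_test(40, 10, 10, 40)
        assert p == pytest.approx(fisher_two_sided_oracle(40, 10, 10, 40), abs=1e-10)
        assert diff == pytest.approx(0.6)

    def test_all_unmethylated(self):
        p, diff = dmr_test(0, 20, 0, 20)
        assert p == 1.0 and diff == 0.0

    def test_symmetry_under_genotype_swap(self, rng):
        for _ in range(20):
            t = [int(x) for x in rng.integers(1, 40, size=4)]
            p1, d1 = dmr_test(*t)
            p2, d2 = dmr_test(t[2], t[3], t[0], t[1])
            assert p1 == pytest.approx(p2, abs=1e-12)
            assert d1 == pytest.approx(-d2)

    def test_random_tables_match_hypergeometric_enumeration(self, rng):
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 60, size=4))
            if (a + b) == 0 or (c + d) == 0:
                continue
            p, _ = dmr_test(a, b, c, d)
            assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), abs=1e-10)


class TestCallDmrs:
    def _inputs(self, rng, n_planted=50, n_null=100, cov=30):
        tiling = Tiling(
            GenomeLayout((("Chr1", 100 * (n_planted + n_null)),)), 100, 100
        )
        rows_wt, rows_mut = [], []
        for b in range(n_planted + n_null):
            wt_level, mut_level = (0.6, 0.1) if b < n_planted else (0.3, 0.3)
            for k in range(8):
                pos = b * 100 + 10 * k
                for rows, level in ((rows_wt, wt_level), (rows_mut, mut_level)):
                    c = int(rng.poisson(cov))
                    m = int(rng.binomial(c, level))
                    rows.append(("Chr1", pos, "+", "CHH", m, c - m))
        return _sites(rows_wt), _sites(rows_mut), tiling

    def test_planted_loss_fully_recovered(self, rng):
        wt, mut, tiling = self._inputs(rng)
        out = call_dmrs(wt, mut, tiling, "CHH", min_diff=0.25, max_fdr=0.01)
        assert out["is_dmr"].iloc[:50].all()
        assert out["is_dmr"].iloc[50:].sum() <= 2

    def test_minimum_difference_gates_significant_bins(self, rng):
        # large difference in counts but level change 0.2 < 0.25: not a DMR
        tiling = Tiling(GenomeLayout((("Chr1", 100),)), 100, 100)
        wt = _sites([("Chr1", 10, "+", "CHH", 400, 600)])
        mut = _sites([("Chr1", 10, "+", "CHH", 200, 800)])
        out = call_dmrs(wt, mut, tiling, "CHH", min_diff=0.25, max_fdr=0.01)
        assert out["q"].iloc[0] < 0.01  # highly significant...
        assert not out["is_dmr"].iloc[0]  # ...but below the minimum difference

    def test_empty_input_empty_calls(self):
        tiling = Tiling(GenomeLayout((("Chr1", 1000),)), 100, 50)
        out = call_dmrs(_sites([]), _sites([]), tiling, "CHH", min_diff=0.25)
        assert not out["is_dmr"].any()
        assert not out["tested"].any()

    def test_null_false_positive_rate(self, rng):
        tiling = Tiling(GenomeLayout((("Chr1", 100 * 2000),)), 100, 100)
        rows_wt, rows_mut = [], []
        for b in range(2000):
            pos = b * 100 + 50
            for rows in (rows_wt, rows_mut):
                c = int(rng.poisson(30))
                m = int(rng.binomial(c, 0.3))
                rows.append(("Chr1", pos, "+", "CG", m, c - m))
        out = call_dmrs(_sites(rows_wt), _sites(rows_mut), tiling, "CG", min_diff=0.01)
        frac = (out.loc[out["tested"], "q"] < 0.01).mean()
        assert frac <= 0.02
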