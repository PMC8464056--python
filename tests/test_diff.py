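import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import nbinom, poisson

from rddmkit.core import GenomeLayout, Tiling
from rddmkit.counts import BinCountMatrix
from rddmkit.diff import (
    DispersionModel,
    bh_adjust,
    classify_diff,
    estimate_common_dispersion,
    exact_nb_test,
    gfold_score,
    gfold_table,
    run_exact_contrast,
)


def oracle_exact_p(a: int, b: int, n_a: int, n_b: int, phi: float, tie_rel=1e-9) -> float:
    """Independent enumeration of the conditional split test via scipy pmfs."""
    total = a + b
    mu = total / (n_a + n_b)
    k = np.arange(total + 1)
    if phi == 0:
        fa = poisson.pmf(k, n_a * mu)
        fb = poisson.pmf(total - k, n_b * mu)
    else:
        ra, rb = n_a / phi, n_b / phi
        fa = nbinom.pmf(k, ra, ra / (ra + n_a * mu))
        fb = nbinom.pmf(total - k, rb, rb / (rb + n_b * mu))
    w = fa * fb
    w = w / w.sum()
    return float(min(1.0, w[w <= w[a] * (1 + tie_rel)].sum()))


class TestExactNBTest:
    def test_balanced_split_is_modal(self):
        assert exact_nb_test([3], [3], phi=0.0) == 1.0

    def test_extreme_split_matches_binomial_tails(self):
        # phi = 0, equal single-sample groups: conditional law is Binomial(10, 1/2)
        assert exact_nb_test([0], [10], phi=0.0) == pytest.approx(2 / 1024, abs=1e-15)

    def test_negative_counts_rejected(self):
        from rddmkit.core import ParameterError

        with pytest.raises(ParameterError):
            exact_nb_test([-1], [3])

    def test_zero_total_returns_one(self):
        assert exact_nb_test([0, 0], [0, 0], phi=0.1) == 1.0

    @pytest.mark.parametrize("phi", [0.0, 0.1])
    def test_matches_enumeration_oracle(self, phi):
        for total in range(0, 31, 3):
            for a in range(total + 1):
                got = exact_nb_test([a], [total - a], phi=phi)
                want = oracle_exact_p(a, total - a, 1, 1, phi)
                assert got == pytest.approx(want, abs=1e-10)

    def test_replicated_groups_use_group_dispersion(self):
        # 2 vs 2: totals pooled, dispersion phi/2 per group total
        got = exact_nb_test([5, 7], [1, 2], phi=0.2)
        want = oracle_exact_p(12, 3, 2, 2, 0.2)
        assert got == pytest.approx(want, abs=1e-10)

    def test_size_factors_rescale_counts(self):
        # doubling one group's library halves its adjusted counts
        p_eq = exact_nb_test([10], [20], phi=0.0, b_size_factors=[2.0])
        assert p_eq == pytest.approx(1.0)


class TestBH:
    def test_examples(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx([0.04] * 4)
        assert bh_adjust([0.5]).tolist() == [0.5]
        assert bh_adjust([0.005, 1.0]).tolist() == pytest.approx([0.01, 1.0])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(200)
        q = bh_adjust(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm)

    def test_untested_excluded_from_multiplicity(self):
        p = np.array([0.01, 1.0, 0.01])
        tested = np.array([True, False, True])
        q = bh_adjust(p, tested)
        assert np.isnan(q[1])
        # n = 2 tested, tied p: step-up gives p * n / n = 0.01
        assert q[0] == pytest.approx(0.01)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_monotone_and_order_invariant(self, p):
        p = np.asarray(p)
        q = bh_adjust(p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)
        perm = np.random.default_rng(0).permutation(p.size)
        assert np.allclose(bh_adjust(p[perm]), q[perm])


class TestClassify:
    def test_threshold_application(self):
        q = np.array([0.03, 0.95, 0.03])
        fold = np.array([0.3, 1.1, 3.0])
        mean_a = np.array([10.0, 10.0, 10.0])
        mean_b = mean_a * fold
        status = classify_diff(q, fold, mean_a, mean_b)
        assert status.tolist() == ["reduced", "unchanged", "other"]

    def test_partition_of_tested_bins(self, rng):
        q = rng.random(500)
        fold = np.exp(rng.normal(size=500))
        mean_a = np.full(500, 10.0)
        status = classify_diff(q, fold, mean_a, mean_a * fold)
        assert set(status) <= {"reduced", "unchanged", "other"}


class TestDispersion:
    def _matrix(self, counts, genotypes=("g1", "g1", "g2", "g2")):
        n = counts.shape[0]
        layout = GenomeLayout((("Chr1", 100 * n),))
        tiling = Tiling(layout, 100, 100)
        samples = [f"s{i}" for i in range(counts.shape[1])]
        return BinCountMatrix(
            tiling, samples, dict(zip(samples, genotypes)), counts,
            np.full(counts.shape[1], 1e6),
        )

    def test_identical_replicates_give_zero(self):
        base = np.arange(1, 51)[:, None]
        m = self._matrix(np.repeat(base, 4, axis=1))
        model = estimate_common_dispersion(m, [[0, 1], [2, 3]])
        assert model.phi == 0.0

    def test_poisson_counts_estimate_near_zero(self, rng):
        counts = rng.poisson(50, size=(2000, 4))
        m = self._matrix(counts)
        model = estimate_common_dispersion(m, [[0, 1], [2, 3]])
        assert model.phi < 0.02

    def test_size_factors_normalized(self, rng):
        counts = rng.poisson(50, size=(100, 4))
        m = self._matrix(counts)
        m.library_sizes = np.array([1e6, 2e6, 1e6, 2e6])
        model = estimate_common_dispersion(m, [[0, 1], [2, 3]])
        assert np.exp(np.mean(np.log(model.size_factors))) == pytest.approx(1.0)


class TestGfold:
    def test_symmetric_posterior_scores_zero(self):
        res = gfold_score(100, 100, 1e6, 1e6, n_draws=20_000, seed=3)
        assert res.score == 0.0
        assert res.status == "unchanged"

    def test_strong_loss_is_reduced(self):
        res = gfold_score(200, 0, 1e6, 1e6, n_draws=100_000, seed=3)
        assert res.score >= 1.0
        assert res.status == "reduced"

    def test_antisymmetry(self):
        a = gfold_score(150, 30, 1e6, 1e6, n_draws=100_000, seed=5)
        b = gfold_score(30, 150, 1e6, 1e6, n_draws=100_000, seed=6)
        assert a.score == pytest.approx(-b.score, abs=0.05)

    def test_low_draws_warns(self):
        with pytest.warns(UserWarning, match="n_draws"):
            gfold_table([10], [10], 1e6, 1e6, n_draws=100, seed=0)


def test_exact_contrast_table_statuses(rng):
    layout = GenomeLayout((("Chr1", 100 * 200),))
    tiling = Tiling(layout, 100, 100)
    wt = rng.poisson(60, size=(200, 2))
    mut = rng.poisson(60, size=(200, 2))
    mut[:20] = rng.poisson(5, size=(20, 2))  # planted reductions
    counts = np.hstack([wt, mut])
    samples = ["w1", "w2", "m1", "m2"]
    m = BinCountMatrix(
        tiling, samples, {"w1": "col0", "w2": "col0", "m1": "mut", "m2": "mut"},
        counts, np.full(4, 1e6),
    )
    model = DispersionModel(0.0, np.ones(4))
    df = run_exact_contrast(m, ["w1", "w2"], ["m1", "m2"], model)
    assert (df["status"].iloc[:20] == "reduced").all()
    assert (df["status"].iloc[20:] == "unchanged").mean() > 0.5
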