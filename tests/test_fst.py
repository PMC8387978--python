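"""Weir-Cockerham theta: textbook oracle, degenerate sites, outlier ranking."""

import numpy as np
import pytest

import tagport as tp
from tagport.fst import FstResult
from tagport.io_genotypes import MISSING

from conftest import matrix_from_dosages, two_pop_assignment


def textbook_wc_oracle(d1, d2):
    """Independently coded 1984 variance components for two populations.

    Written directly from the published definitions (sum-form, population
    index loops, no vectorized reuse of the implementation) as a check on
    ``tagport.fst.wc_components``.
    """
    pops = [np.asarray(d1, dtype=float), np.asarray(d2, dtype=float)]
    r = 2
    n_i = [len(d) for d in pops]
    p_i = [d.sum() / (2 * len(d)) for d in pops]
    h_i = [np.mean(d == 1) for d in pops]
    nbar = sum(n_i) / r
    nc = (sum(n_i) - sum(n * n for n in n_i) / sum(n_i)) / (r - 1)
    pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - 1.0 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


class TestThetaEstimator:
    def test_printed_dosage_table_matches_textbook_oracle(self):
        """5-diploid two-population table agrees term by term with the oracle."""
        pop1 = [2, 1, 1, 0, 2]
        pop2 = [0, 0, 1, 0, 1]
        g = matrix_from_dosages([[d] for d in pop1 + pop2])
        res = tp.wc_theta(g, two_pop_assignment(g, 5), ("POP1", "POP2"))[0]
        a, b, c = textbook_wc_oracle(pop1, pop2)
        assert res.a == pytest.approx(a, abs=1e-12)
        assert res.b == pytest.approx(b, abs=1e-12)
        assert res.c == pytest.approx(c, abs=1e-12)
        assert res.theta == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_fixed_difference_gives_theta_one(self):
        g = matrix_from_dosages([[2]] * 6 + [[0]] * 6)
        res = tp.wc_theta(g, two_pop_assignment(g, 6), ("POP1", "POP2"))[0]
        assert res.theta == pytest.approx(1.0, abs=1e-12)

    def test_monomorphic_in_both_is_flagged_not_zero(self):
        g = matrix_from_dosages([[0]] * 10)
        res = tp.wc_theta(g, two_pop_assignment(g, 5), ("POP1", "POP2"))[0]
        assert not res.defined
        assert np.isnan(res.theta)

    def test_pop_label_swap_invariance(self, rng):
        dosages = rng.integers(0, 3, size=(20, 3))
        g = matrix_from_dosages(dosages)
        pops = two_pop_assignment(g, 8)
        fwd = tp.wc_theta(g, pops, ("POP1", "POP2"))
        rev = tp.wc_theta(g, pops, ("POP2", "POP1"))
        for x, y in zip(fwd, rev):
            assert x.theta == pytest.approx(y.theta, abs=1e-12)

    def test_global_allele_flip_invariance(self, rng):
        dosages = rng.integers(0, 3, size=(20, 3))
        g = matrix_from_dosages(dosages)
        g_flip = matrix_from_dosages(2 - dosages)
        pops = two_pop_assignment(g, 9)
        for x, y in zip(
            tp.wc_theta(g, pops, ("POP1", "POP2")),
            tp.wc_theta(g_flip, pops, ("POP1", "POP2")),
        ):
            assert x.theta == pytest.approx(y.theta, abs=1e-12)

    def test_missing_data_uses_complete_cases(self):
        pop1 = [2, 1, MISSING, 0, 2]
        pop2 = [0, MISSING, 1, 0, 1]
        g = matrix_from_dosages([[d] for d in pop1 + pop2])
        res = tp.wc_theta(g, two_pop_assignment(g, 5), ("POP1", "POP2"))[0]
        assert res.n_per_pop == (4, 4)
        a, b, c = textbook_wc_oracle([2, 1, 0, 2], [0, 1, 0, 1])
        assert res.theta == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_too_few_called_samples_flagged(self):
        g = matrix_from_dosages([[2], [MISSING], [MISSING], [0], [1], [1]])
        res = tp.wc_theta(g, two_pop_assignment(g, 3), ("POP1", "POP2"))[0]
        assert not res.defined and res.n_per_pop == (1, 3)

    def test_errors(self):
        g = matrix_from_dosages([[0], [1]])
        pops = two_pop_assignment(g, 1)
        with pytest.raises(ValueError, match="distinct"):
            tp.wc_theta(g, pops, ("POP1", "POP1"))
        with pytest.raises(ValueError, match="unknown population"):
            tp.wc_theta(g, pops, ("POP1", "NOPE"))


def _results(thetas):
    return [
        FstResult(f"v{i}", ("P1", "P2"), 0.0, 0.0, 0.0, t, (10, 10))
        for i, t in enumerate(thetas)
    ]


class TestEmpiricalPercentile:
    def test_unique_maximum_in_71_snp_set_is_top_five_percent(self):
        thetas = list(np.linspace(0.0, 0.5, 70)) + [0.9]
        rank = tp.empirical_percentile(_results(thetas), "v70")
        assert rank.set_size == 71
        assert rank.percentile == pytest.approx(100 / 71)
        assert rank.percentile < 5.0

    def test_total_tie_gives_100(self):
        rank = tp.empirical_percentile(_results([0.2] * 5), "v0")
        assert rank.percentile == 100.0

    def test_hand_counted_rank(self):
        rank = tp.empirical_percentile(_results([0.1, 0.2, 0.3, 0.4]), "v2")
        assert rank.percentile == 50.0

    def test_focal_missing_or_undefined_errors(self):
        results = _results([0.1, 0.2])
        with pytest.raises(ValueError, match="not in result set"):
            tp.empirical_percentile(results, "vX")
        undef = _results([0.1, float("nan")])
        with pytest.raises(ValueError, match="undefined"):
            tp.empirical_percentile(undef, "v1")
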