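"""Two-locus LD: hand-worked statistics, EM vs oracles, invariances."""

import numpy as np
import pytest

import tagport as tp
from tagport.io_genotypes import GenotypeMatrix, PopulationAssignment, VariantRecord
from tagport.ld import LDUndefinedError

from conftest import grid_max_p11


def freqs(p11, p12, p21, p22, **kw):
    defaults = dict(
        locus1="L1", locus2="L2", method="phased_count", n_chromosomes=100,
        population="P1",
    )
    defaults.update(kw)
    return tp.HaplotypeFreqs(
        p11=p11, p12=p12, p21=p21, p22=p22, pA=p11 + p12, pB=p11 + p21, **defaults
    )


def matrix_from_haplotype_counts(counts, locus_ids=("L1", "L2"), pop="P1"):
    """Phased diploids assembled from (AB, Ab, aB, ab) chromosome counts."""
    classes = np.repeat(np.arange(4), counts)
    assert classes.size % 2 == 0
    allele_a = np.array([1, 1, 0, 0], dtype=np.int8)
    allele_b = np.array([1, 0, 1, 0], dtype=np.int8)
    n = classes.size // 2
    haps = np.stack([allele_a[classes], allele_b[classes]], axis=1).reshape(n, 2, 2)
    variants = [
        VariantRecord("1", 100, locus_ids[0], "A", "G"),
        VariantRecord("1", 200, locus_ids[1], "C", "T"),
    ]
    samples = [f"s{i}" for i in range(n)]
    g = GenotypeMatrix(
        variants, samples, haps.sum(axis=1), np.ones((n, 2), dtype=bool), haps
    )
    return g, PopulationAssignment({s: pop for s in samples})


class TestLdStats:
    def test_hand_worked_example_to_1e9(self):
        r = tp.ld_stats(freqs(0.30, 0.10, 0.15, 0.45))
        assert r.D == pytest.approx(0.12, abs=1e-9)
        assert r.Dprime == pytest.approx(0.12 / 0.22, abs=1e-9)
        assert r.r2 == pytest.approx(0.12**2 / (0.4 * 0.6 * 0.45 * 0.55), abs=1e-9)

    def test_equilibrium_gives_all_zero(self):
        r = tp.ld_stats(freqs(0.25, 0.25, 0.25, 0.25))
        assert r.D == pytest.approx(0.0, abs=1e-12)
        assert r.Dprime == 0.0 and r.r2 == 0.0

    def test_perfect_coupling_gives_all_one(self):
        r = tp.ld_stats(freqs(0.5, 0.0, 0.0, 0.5))
        assert r.D == pytest.approx(0.25, abs=1e-12)
        assert r.Dprime == 1.0 and r.r2 == 1.0

    def test_dprime_is_one_when_a_haplotype_class_is_absent(self):
        r = tp.ld_stats(freqs(0.3, 0.0, 0.3, 0.4))  # Ab class empty, D > 0
        assert r.D > 0 and r.Dprime == pytest.approx(1.0, abs=1e-12)

    def test_monomorphic_locus_raises_named_error(self):
        with pytest.raises(LDUndefinedError, match="L2"):
            tp.ld_stats(freqs(0.6, 0.0, 0.4, 0.0))  # pB = 1

    @pytest.mark.parametrize("seed", range(6))
    def test_flip_invariance_of_dprime_and_r2(self, seed):
        """Relabeling ALT<->REF at either locus permutes the haplotype classes
        but leaves D' and r2 unchanged (D changes sign under a single flip)."""
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(4))
        base = tp.ld_stats(freqs(*p))
        flip1 = tp.ld_stats(freqs(p[2], p[3], p[0], p[1]))  # flip locus 1
        flip2 = tp.ld_stats(freqs(p[1], p[0], p[3], p[2]))  # flip locus 2
        both = tp.ld_stats(freqs(p[3], p[2], p[1], p[0]))
        for other, sign in ((flip1, -1), (flip2, -1), (both, 1)):
            assert other.D == pytest.approx(sign * base.D, abs=1e-12)
            assert other.Dprime == pytest.approx(base.Dprime, abs=1e-9)
            assert other.r2 == pytest.approx(base.r2, abs=1e-9)
        assert 0 <= base.Dprime <= 1 and 0 <= base.r2 <= 1


class TestPhasedCounting:
    def test_hand_counted_haplotype_frequencies(self):
        g, pops = matrix_from_haplotype_counts([30, 10, 15, 45])
        h = tp.haplotype_freqs_phased(g, pops, "L1", "L2", "P1")
        assert (h.p11, h.pA, h.pB) == pytest.approx((0.30, 0.40, 0.45), abs=1e-12)
        assert h.n_chromosomes == 100 and h.method == "phased_count"

    def test_perfect_coupling_counts(self):
        g, pops = matrix_from_haplotype_counts([20, 0, 0, 20])
        h = tp.haplotype_freqs_phased(g, pops, "L1", "L2", "P1")
        assert (h.p11, h.p22, h.p12, h.p21) == (0.5, 0.5, 0.0, 0.0)

    def test_equilibrium_counts(self):
        g, pops = matrix_from_haplotype_counts([10, 10, 10, 10])
        h = tp.haplotype_freqs_phased(g, pops, "L1", "L2", "P1")
        assert h.as_tuple() == (0.25, 0.25, 0.25, 0.25)

    def test_requires_haplotype_panel(self):
        g, pops = matrix_from_haplotype_counts([10, 10, 10, 10])
        with pytest.raises(ValueError, match="fully phased"):
            tp.haplotype_freqs_phased(g.erase_phase(), pops, "L1", "L2", "P1")


class TestEM:
    def test_no_double_heterozygotes_equals_direct_count(self):
        # dosage pairs chosen so the phase-ambiguous (1,1) class never occurs
        d1 = np.array([2, 2, 1, 0, 0, 2, 1, 0, 2, 0])
        d2 = np.array([2, 2, 2, 0, 0, 0, 0, 1, 1, 0])
        from conftest import matrix_from_dosages

        gm = matrix_from_dosages(np.column_stack([d1, d2]), variant_ids=["L1", "L2"])
        pops = PopulationAssignment({s: "P1" for s in gm.samples})
        h = tp.em_haplotype_freqs(gm, pops, "L1", "L2", "P1")
        assert h.em_iterations <= 2
        # with unambiguous phase, haplotype counts are determined exactly
        assert h.p11 == pytest.approx(grid_max_p11(d1, d2), abs=1e-6)

    def test_all_double_heterozygotes_equilibrium_is_stationary(self):
        from conftest import matrix_from_dosages

        gm = matrix_from_dosages(np.ones((20, 2), dtype=int), variant_ids=["L1", "L2"])
        pops = PopulationAssignment({s: "P1" for s in gm.samples})
        h = tp.em_haplotype_freqs(gm, pops, "L1", "L2", "P1")
        assert h.p11 == pytest.approx(0.25, abs=1e-12)  # pA*pB stays put

    def test_em_matches_grid_search_oracle(self):
        g, pops = tp.simulate_two_locus(0.5, 0.5, 0.8, 50, seed=42,
                                        phased_output=False)
        # underlying haplotype freqs here are (0.45, 0.05, 0.05, 0.45)
        h = tp.em_haplotype_freqs(g, pops, "snpA", "snpB", "POP1")
        d1 = g.dosage[:, 0]
        d2 = g.dosage[:, 1]
        assert h.p11 == pytest.approx(grid_max_p11(d1, d2), abs=1e-6)

    def test_loglik_nondecreasing_every_iteration(self):
        for seed in range(5):
            g, pops = tp.simulate_two_locus(0.4, 0.45, 0.55, 80, seed=seed,
                                            phased_output=False)
            h = tp.em_haplotype_freqs(g, pops, "snpA", "snpB", "POP1")
            diffs = np.diff(h.loglik_history)
            assert (diffs >= -1e-9).all()

    def test_multiple_initializations_agree(self):
        rng = np.random.default_rng(7)
        g, pops = tp.simulate_two_locus(0.4, 0.3, 0.6, 100, seed=9,
                                        phased_output=False)
        ref = tp.em_haplotype_freqs(g, pops, "snpA", "snpB", "POP1")
        for _ in range(3):
            init = tuple(rng.dirichlet(np.ones(4)))
            h = tp.em_haplotype_freqs(g, pops, "snpA", "snpB", "POP1", init=init)
            assert h.p11 == pytest.approx(ref.p11, abs=1e-6)

    def test_phased_and_em_agree_at_large_n(self):
        g, pops = tp.simulate_two_locus(0.4, 0.45, 0.5454, 5000, seed=3)
        r_phased = tp.ld_stats(tp.haplotype_freqs_phased(g, pops, "snpA", "snpB", "POP1"))
        r_em = tp.ld_stats(tp.em_haplotype_freqs(g.erase_phase(), pops, "snpA", "snpB", "POP1"))
        assert r_em.r2 == pytest.approx(r_phased.r2, abs=0.01)


class TestCompositeFallback:
    def test_composite_close_to_phased_truth(self):
        g, pops = tp.simulate_two_locus(0.4, 0.45, 0.5454, 2000, seed=17)
        truth = tp.ld_stats(tp.haplotype_freqs_phased(g, pops, "snpA", "snpB", "POP1"))
        comp = tp.composite_haplotype_freqs(g.erase_phase(), pops, "snpA", "snpB", "POP1")
        assert comp.method == "composite"
        assert tp.ld_stats(comp).D == pytest.approx(truth.D, abs=0.02)


class TestTagPortability:
    def test_contrasting_populations_yield_opposite_verdicts(self):
        eas, eas_pops = tp.simulate_two_locus(
            0.4, 0.38, 0.97, 400, seed=21, pop_label="EAS_LIKE")
        nat, nat_pops = tp.simulate_two_locus(
            0.85, 0.30, 0.12, 400, seed=22, pop_label="NAT_LIKE")
        g = tp.merge_matrices([eas, nat])
        pops = PopulationAssignment(
            {**eas_pops.sample_to_pop, **nat_pops.sample_to_pop})
        results = tp.tag_portability(g, pops, "snpA", "snpB")
        by_pop = {r.population: r for r in results}
        assert by_pop["EAS_LIKE"].is_tag and by_pop["EAS_LIKE"].r2 > 0.8
        assert not by_pop["NAT_LIKE"].is_tag and by_pop["NAT_LIKE"].r2 < 0.3

    def test_threshold_zero_makes_any_nonzero_d_a_tag(self):
        g, pops = tp.simulate_two_locus(0.4, 0.45, 0.5, 200, seed=5)
        results = tp.tag_portability(g, pops, "snpA", "snpB", threshold=0.0)
        assert results[0].D != 0 and results[0].is_tag

    def test_monomorphic_population_becomes_flagged_row(self):
        ok, ok_pops = tp.simulate_two_locus(0.4, 0.45, 0.9, 100, seed=6, pop_label="OK")
        mono, _ = tp.simulate_two_locus(0.4, 0.45, 0.9, 100, seed=7, pop_label="MONO")
        mono.dosage[:, 1] = 0  # functional locus fixed REF in MONO
        mono.haplotypes[:, :, 1] = 0
        g = tp.merge_matrices([ok, mono])
        pops = PopulationAssignment(
            {s: ("OK" if s.startswith("OK") else "MONO") for s in g.samples})
        results = tp.tag_portability(g, pops, "snpA", "snpB")
        by_pop = {r.population: r for r in results}
        assert by_pop["OK"].error is None
        assert by_pop["MONO"].error is not None and "snpB" in by_pop["MONO"].error
        assert not by_pop["MONO"].is_tag
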