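"""Shared helpers: small VCF fixtures and the brute-force LD likelihood oracle."""

from __future__ import annotations

import numpy as np
import pytest

from tagport.io_genotypes import GenotypeMatrix, PopulationAssignment, VariantRecord
from tagport.ld import genotype_class_counts, two_locus_loglik


def grid_max_p11(d1: np.ndarray, d2: np.ndarray,
                 coarse: float = 1e-4, fine: float = 1e-7) -> float:
    """Brute-force maximizer of the two-locus genotype likelihood over p11.

    The marginal allele frequencies are the sample frequencies (their MLEs,
    which any maximizer shares), leaving a one-dimensional search over p11
    in its feasible interval. A coarse grid locates every local maximum; a
    fine grid at step ``fine`` refines around each. Independent of the EM
    iteration it is used to check.
    """
    counts = genotype_class_counts(d1, d2)
    n_chrom = 2 * d1.size
    pA = d1.sum() / n_chrom
    pB = d2.sum() / n_chrom
    lo = max(0.0, pA + pB - 1.0)
    hi = min(pA, pB)

    def loglik_of(p11: np.ndarray) -> np.ndarray:
        p = np.stack(
            [p11, pA - p11, pB - p11, 1.0 - pA - pB + p11], axis=-1
        )
        return two_locus_loglik(p, counts)

    grid = np.arange(lo, hi + coarse / 2, coarse)
    grid = np.clip(grid, lo, hi)
    ll = np.atleast_1d(loglik_of(grid))
    # local maxima of the coarse scan (including endpoints)
    is_max = np.ones(grid.size, dtype=bool)
    if grid.size > 1:
        is_max[1:] &= ll[1:] >= ll[:-1]
        is_max[:-1] &= ll[:-1] >= ll[1:]
    best_p, best_ll = None, -np.inf
    for center in grid[is_max]:
        local = np.arange(
            max(lo, center - 2 * coarse), min(hi, center + 2 * coarse) + fine / 2, fine
        )
        local = np.clip(local, lo, hi)
        lll = np.atleast_1d(loglik_of(local))
        k = int(np.argmax(lll))
        if lll[k] > best_ll:
            best_ll, best_p = float(lll[k]), float(local[k])
    return best_p


def matrix_from_dosages(dosages, variant_ids=None, phased=False) -> GenotypeMatrix:
    """Build an unphased GenotypeMatrix from an (n_samples, n_variants) list."""
    dosage = np.asarray(dosages, dtype=np.int8)
    if dosage.ndim == 1:
        dosage = dosage[:, None]
    n, m = dosage.shape
    if variant_ids is None:
        variant_ids = [f"v{j + 1}" for j in range(m)]
    variants = [
        VariantRecord(chrom="1", pos=100 + j, id=vid, ref="A", alt="G")
        for j, vid in enumerate(variant_ids)
    ]
    samples = [f"s{i + 1}" for i in range(n)]
    return GenotypeMatrix(
        variants=variants,
        samples=samples,
        dosage=dosage,
        phased=np.full(dosage.shape, phased, dtype=bool),
        haplotypes=None,
    )


def two_pop_assignment(g: GenotypeMatrix, split: int) -> PopulationAssignment:
    """Assign the first `split` samples to POP1 and the rest to POP2."""
    mapping = {
        s: ("POP1" if i < split else "POP2") for i, s in enumerate(g.samples)
    }
    return PopulationAssignment(sample_to_pop=mapping)


@pytest.fixture
def rng():
    return np.random.default_rng(20210825)
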