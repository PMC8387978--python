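"""Weir & Cockerham (1984) FST and empirical outlier ranking.

For a bi-allelic site observed in ``r`` populations with per-population
sample sizes ``n_i``, ALT frequencies ``p_i`` and observed heterozygote
fractions ``h_i``, the three variance components are

.. math::

    a &= \\frac{\\bar n}{n_c}\\left[s^2 - \\frac{1}{\\bar n - 1}
         \\left(\\bar p(1-\\bar p) - \\frac{r-1}{r}s^2
         - \\frac{\\bar h}{4}\\right)\\right] \\\\
    b &= \\frac{\\bar n}{\\bar n - 1}\\left[\\bar p(1-\\bar p)
         - \\frac{r-1}{r}s^2
         - \\frac{2\\bar n - 1}{4\\bar n}\\bar h\\right] \\\\
    c &= \\bar h / 2

with :math:`\\bar n` the mean sample size, :math:`n_c` the variance-corrected
size, :math:`\\bar p` and :math:`\\bar h` the weighted mean frequency and
heterozygosity, and :math:`s^2` the weighted among-population frequency
variance. The single-site estimate is ``theta = a / (a + b + c)``; it may be
negative and is never clamped, because clamping biases the empirical
percentile used for outlier ranking. Multi-SNP summaries use the
ratio-of-sums combination (sum of ``a`` over sum of ``a+b+c``), the less
biased standard choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_genotypes import MISSING, GenotypeMatrix, PopulationAssignment

__all__ = [
    "FstResult",
    "OutlierRank",
    "wc_components",
    "wc_theta",
    "theta_ratio_of_sums",
    "empirical_percentile",
]

COLUMNS = ["variant_id", "pop1", "pop2", "a", "b", "c", "theta", "n1", "n2", "defined"]


@dataclass(frozen=True)
class FstResult:
    """Single-site Weir-Cockerham components for one population pair."""

    variant_id: str
    pop_pair: tuple[str, str]
    a: float
    b: float
    c: float
    theta: float  # NaN when undefined
    n_per_pop: tuple[int, int]

    @property
    def defined(self) -> bool:
        return not np.isnan(self.theta)


@dataclass(frozen=True)
class OutlierRank:
    """Empirical percentile of a focal SNP's theta within a SNP set.

    ``percentile`` is ``100 * |{theta_i >= theta_focal}| / set_size`` over
    the SNPs with defined theta; ties count toward the numerator, which is
    the conservative direction for an outlier claim.
    """

    focal_variant_id: str
    percentile: float
    set_size: int


def wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray) -> tuple[float, float, float]:
    """Variance components (a, b, c) from per-population summaries.

    Parameters are per-population diploid sample sizes ``n``, ALT allele
    frequencies ``p`` and observed heterozygote fractions ``h``. Requires
    every ``n_i >= 2`` (the ``n - 1`` denominators) and at least two
    populations of unequal size or frequency to be informative.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = n.size
    if r < 2:
        raise ValueError("need at least two populations")
    if (n < 2).any():
        raise ValueError("each population needs >= 2 called diploids")
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return float(a), float(b), float(c)


def wc_theta(
    g: GenotypeMatrix,
    pops: PopulationAssignment,
    pop_pair: tuple[str, str],
) -> list[FstResult]:
    """Per-variant Weir-Cockerham theta for one population pair.

    Sites where either population has fewer than 2 called diploids, and
    sites monomorphic in both populations (``a + b + c = 0``), are returned
    with ``theta = NaN`` — flagged, never silently zero.
    """
    pop1, pop2 = pop_pair
    if pop1 == pop2:
        raise ValueError(f"population pair must be distinct, got {pop_pair}")
    known = set(pops.populations)
    for pop in pop_pair:
        if pop not in known:
            raise ValueError(f"unknown population label {pop!r}")
    in_matrix = set(g.samples)
    idx1 = g.sample_indices([s for s in pops.samples_in(pop1) if s in in_matrix])
    idx2 = g.sample_indices([s for s in pops.samples_in(pop2) if s in in_matrix])

    results: list[FstResult] = []
    for j, variant in enumerate(g.variants):
        d1 = g.dosage[idx1, j]
        d2 = g.dosage[idx2, j]
        d1 = d1[d1 != MISSING]
        d2 = d2[d2 != MISSING]
        n1, n2 = d1.size, d2.size
        if n1 < 2 or n2 < 2:
            results.append(
                FstResult(variant.id, pop_pair, np.nan, np.nan, np.nan, np.nan, (n1, n2))
            )
            continue
        n = np.array([n1, n2], dtype=float)
        p = np.array([d1.sum() / (2 * n1), d2.sum() / (2 * n2)])
        h = np.array([(d1 == 1).mean(), (d2 == 1).mean()])
        a, b, c = wc_components(n, p, h)
        denom = a + b + c
        theta = a / denom if denom > 0 else np.nan
        results.append(FstResult(variant.id, pop_pair, a, b, c, theta, (n1, n2)))
    return results


def theta_ratio_of_sums(results: list[FstResult]) -> float:
    """Multi-SNP theta: sum of a over sum of (a+b+c), defined sites only."""
    defined = [res for res in results if res.defined]
    if not defined:
        raise ValueError("no sites with defined variance components")
    num = sum(res.a for res in defined)
    den = sum(res.a + res.b + res.c for res in defined)
    return num / den


def empirical_percentile(results: list[FstResult], focal: str) -> OutlierRank:
    """Rank a focal SNP's theta within the empirical distribution of a set."""
    by_id = {res.variant_id: res for res in results}
    if focal not in by_id:
        raise ValueError(f"focal variant {focal!r} not in result set")
    focal_res = by_id[focal]
    if not focal_res.defined:
        raise ValueError(f"focal variant {focal!r} has undefined theta")
    thetas = np.array([res.theta for res in results if res.defined])
    n_ge = int((thetas >= focal_res.theta).sum())
    return OutlierRank(focal, 100.0 * n_ge / thetas.size, int(thetas.size))


def results_to_frame(results: list[FstResult]) -> pd.DataFrame:
    """Tabular view of a list of :class:`FstResult` (TSV-ready)."""
    return pd.DataFrame(
        [
            dict(
                variant_id=res.variant_id,
                pop1=res.pop_pair[0],
                pop2=res.pop_pair[1],
                a=res.a,
                b=res.b,
                c=res.c,
                theta=res.theta,
                n1=res.n_per_pop[0],
                n2=res.n_per_pop[1],
                defined=res.defined,
            )
            for res in results
        ],
        columns=COLUMNS,
    )
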