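"""Two-locus linkage disequilibrium per population.

Haplotype frequencies for an (ALT, ALT) orientation pair come from direct
counting when phase is known, or from the classic two-locus EM over the
nine unphased genotype classes when it is not: only the double-heterozygote
class is phase-ambiguous, and each E-step splits it between the cis
(AB/ab) and trans (Ab/aB) configurations in proportion to
``p11*p22 : p12*p21``. A Burrows-style composite estimator is available as
a labelled fallback for comparison; it is never the default.

From the haplotype frequencies:

* ``D  = p11 - pA*pB``
* ``D' = |D| / Dmax`` with ``Dmax = min(pA*(1-pB), (1-pA)*pB)`` if D > 0,
  else ``min(pA*pB, (1-pA)*(1-pB))`` (absolute-value convention, D' in [0,1])
* ``r2 = D**2 / (pA*(1-pA)*pB*(1-pB))``

A locus that is monomorphic within the population makes D' and r2
undefined; this raises a named error rather than propagating NaN. The
tag-SNP verdict is the strict inequality ``r2 > threshold`` (default 0.80).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_genotypes import MISSING, GenotypeMatrix, PopulationAssignment

__all__ = [
    "HaplotypeFreqs",
    "LDResult",
    "LDUndefinedError",
    "haplotype_freqs_phased",
    "em_haplotype_freqs",
    "composite_haplotype_freqs",
    "genotype_class_counts",
    "two_locus_loglik",
    "ld_stats",
    "tag_portability",
]

DEFAULT_TAG_THRESHOLD = 0.80


class LDUndefinedError(ValueError):
    """LD statistics are undefined (a locus is monomorphic or data is empty)."""


@dataclass
class HaplotypeFreqs:
    """Two-locus haplotype frequencies, '1' meaning the ALT allele.

    ``(p11, p12, p21, p22)`` are the frequencies of the ALT-ALT, ALT-REF,
    REF-ALT and REF-REF haplotypes at (locus1, locus2); ``pA``/``pB`` are
    the marginal ALT frequencies. ``method`` records how they were obtained
    (``phased_count``, ``em`` or ``composite``).
    """

    locus1: str
    locus2: str
    p11: float
    p12: float
    p21: float
    p22: float
    pA: float
    pB: float
    method: str
    n_chromosomes: int
    em_iterations: int = 0
    em_loglik: float = float("nan")
    loglik_history: list[float] = field(default_factory=list, repr=False)
    population: str | None = None

    def __post_init__(self) -> None:
        total = self.p11 + self.p12 + self.p21 + self.p22
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, expected 1")
        if abs(self.p11 + self.p12 - self.pA) > 1e-9:
            raise ValueError("marginal pA inconsistent with haplotype frequencies")
        if abs(self.p11 + self.p21 - self.pB) > 1e-9:
            raise ValueError("marginal pB inconsistent with haplotype frequencies")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p11, self.p12, self.p21, self.p22)


@dataclass
class LDResult:
    """LD statistics for one locus pair in one population."""

    locus1: str
    locus2: str
    population: str | None
    D: float
    Dprime: float
    r2: float
    freqs: HaplotypeFreqs | None
    is_tag: bool
    threshold: float = DEFAULT_TAG_THRESHOLD
    error: str | None = None

    @property
    def defined(self) -> bool:
        return self.error is None


def _pair_data(
    g: GenotypeMatrix,
    pops: PopulationAssignment,
    locus1: str,
    locus2: str,
    population: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample indices and pairwise-complete dosages at the two loci."""
    j1 = g.variant_index(locus1)
    j2 = g.variant_index(locus2)
    in_matrix = set(g.samples)
    members = [s for s in pops.samples_in(population) if s in in_matrix]
    if not members:
        raise LDUndefinedError(f"population {population!r} has no samples in the matrix")
    idx = g.sample_indices(members)
    d1 = g.dosage[idx, j1]
    d2 = g.dosage[idx, j2]
    keep = (d1 != MISSING) & (d2 != MISSING)
    return idx[keep], d1[keep], d2[keep]


def haplotype_freqs_phased(
    g: GenotypeMatrix,
    pops: PopulationAssignment,
    locus1: str,
    locus2: str,
    population: str,
) -> HaplotypeFreqs:
    """Haplotype frequencies by direct counting of phased chromosomes.

    Requires the matrix's haplotype panel (present when every call is
    phased). Samples missing at either locus are dropped pairwise.
    """
    if g.haplotypes is None:
        raise ValueError(
            "haplotype_freqs_phased requires fully phased data; use "
            "em_haplotype_freqs for unphased or mixed-phase genotypes"
        )
    j1 = g.variant_index(locus1)
    j2 = g.variant_index(locus2)
    idx, _, _ = _pair_data(g, pops, locus1, locus2, population)
    if idx.size == 0:
        raise LDUndefinedError(
            f"no pairwise-complete samples for {locus1}/{locus2} in {population!r}"
        )
    h1 = g.haplotypes[idx][:, :, j1].ravel()  # 2n chromosomes
    h2 = g.haplotypes[idx][:, :, j2].ravel()
    n_chrom = h1.size
    p11 = float(((h1 == 1) & (h2 == 1)).sum() / n_chrom)
    p12 = float(((h1 == 1) & (h2 == 0)).sum() / n_chrom)
    p21 = float(((h1 == 0) & (h2 == 1)).sum() / n_chrom)
    p22 = float(((h1 == 0) & (h2 == 0)).sum() / n_chrom)
    return HaplotypeFreqs(
        locus1=locus1,
        locus2=locus2,
        p11=p11,
        p12=p12,
        p21=p21,
        p22=p22,
        pA=p11 + p12,
        pB=p11 + p21,
        method="phased_count",
        n_chromosomes=n_chrom,
        population=population,
    )


def genotype_class_counts(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """3x3 table of joint dosage counts, rows = locus1 dosage 0/1/2."""
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (d1.astype(int), d2.astype(int)), 1)
    return counts


def two_locus_loglik(p: np.ndarray, counts: np.ndarray) -> float | np.ndarray:
    """Multinomial log-likelihood of the 9 genotype classes.

    ``p`` is ``(p11, p12, p21, p22)`` (last axis when vectorized over a
    grid); genotype-class probabilities follow from random union of
    gametes. Zero-probability classes with zero counts contribute 0.
    """
    p = np.asarray(p, dtype=float)
    p11, p12, p21, p22 = p[..., 0], p[..., 1], p[..., 2], p[..., 3]
    # genotype (i alt alleles at locus1, k at locus2) probabilities
    probs = np.empty(p.shape[:-1] + (3, 3))
    probs[..., 0, 0] = p22**2
    probs[..., 0, 1] = 2 * p21 * p22
    probs[..., 0, 2] = p21**2
    probs[..., 1, 0] = 2 * p12 * p22
    probs[..., 1, 1] = 2 * (p11 * p22 + p12 * p21)
    probs[..., 1, 2] = 2 * p11 * p21
    probs[..., 2, 0] = p12**2
    probs[..., 2, 1] = 2 * p11 * p12
    probs[..., 2, 2] = p11**2
    counts = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * np.log(probs)
    terms = np.where(counts == 0, 0.0, terms)
    ll = terms.sum(axis=(-2, -1))
    return float(ll) if ll.ndim == 0 else ll


def em_haplotype_freqs(
    g: GenotypeMatrix,
    pops: PopulationAssignment,
    locus1: str,
    locus2: str,
    population: str,
    tol: float = 1e-10,
    max_iter: int = 1000,
    init: tuple[float, float, float, float] | None = None,
) -> HaplotypeFreqs:
    """Maximum-likelihood haplotype frequencies from unphased genotypes (EM).

    Only the double-heterozygote class is phase-ambiguous; each E-step
    splits it between cis and trans in proportion to ``p11*p22`` vs
    ``p12*p21``, and the M-step renormalizes expected haplotype counts.
    Convergence: max absolute change in any haplotype frequency < ``tol``,
    or ``max_iter`` reached. Deterministic given the input; by default
    initialized at linkage equilibrium (``p11 = pA*pB``), which keeps the
    marginal allele frequencies fixed at their sample values throughout.

    ``init`` overrides the starting point (used by multimodality checks).
    """
    _, d1, d2 = _pair_data(g, pops, locus1, locus2, population)
    if d1.size == 0:
        raise LDUndefinedError(
            f"no pairwise-complete samples for {locus1}/{locus2} in {population!r}"
        )
    counts = genotype_class_counts(d1, d2)
    n_chrom = 2 * d1.size
    pA = float(d1.sum() / n_chrom)
    pB = float(d2.sum() / n_chrom)

    if init is None:
        p = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    else:
        p = np.asarray(init, dtype=float)
        if p.min() < 0 or abs(p.sum() - 1) > 1e-9:
            raise ValueError("init must be a point on the haplotype simplex")

    # haplotype counts contributed by the 8 phase-unambiguous classes:
    # class (i,k) with i,k dosages; e.g. (2,1) contributes one 11 and one 10.
    fixed = np.zeros(4)  # 11, 10, 01, 00
    c = counts
    fixed[0] = 2 * c[2, 2] + c[2, 1] + c[1, 2]
    fixed[1] = 2 * c[2, 0] + c[2, 1] + c[1, 0]
    fixed[2] = 2 * c[0, 2] + c[0, 1] + c[1, 2]
    fixed[3] = 2 * c[0, 0] + c[0, 1] + c[1, 0]
    n_dh = int(c[1, 1])  # double heterozygotes: cis 11/00 or trans 10/01

    history = [two_locus_loglik(p, counts)]
    iterations = 0
    for iterations in range(1, max_iter + 1):
        cis = p[0] * p[3]
        trans = p[1] * p[2]
        denom = cis + trans
        w_cis = cis / denom if denom > 0 else 0.5
        expected = fixed.copy()
        expected[0] += n_dh * w_cis
        expected[3] += n_dh * w_cis
        expected[1] += n_dh * (1 - w_cis)
        expected[2] += n_dh * (1 - w_cis)
        p_new = expected / n_chrom
        history.append(two_locus_loglik(p_new, counts))
        delta = np.abs(p_new - p).max()
        p = p_new
        if delta < tol:
            break
    if not np.isfinite(history[-1]):
        raise ValueError("non-finite likelihood in EM (degenerate input)")

    return HaplotypeFreqs(
        locus1=locus1,
        locus2=locus2,
        p11=float(p[0]),
        p12=float(p[1]),
        p21=float(p[2]),
        p22=float(p[3]),
        pA=float(p[0] + p[1]),
        pB=float(p[0] + p[2]),
        method="em",
        n_chromosomes=n_chrom,
        em_iterations=iterations,
        em_loglik=float(history[-1]),
        loglik_history=[float(x) for x in history],
        population=population,
    )


def composite_haplotype_freqs(
    g: GenotypeMatrix,
    pops: PopulationAssignment,
    locus1: str,
    locus2: str,
    population: str,
) -> HaplotypeFreqs:
    """Burrows-style composite estimator (labelled fallback, not default).

    Estimates D as the half-covariance of dosages,
    ``Delta = mean(d1*d2)/2 - 2*pA*pB``, which is consistent for D under
    Hardy-Weinberg but does not maximize the haplotype likelihood. The
    implied haplotype frequencies are clipped into the feasible interval.
    """
    _, d1, d2 = _pair_data(g, pops, locus1, locus2, population)
    if d1.size == 0:
        raise LDUndefinedError(
            f"no pairwise-complete samples for {locus1}/{locus2} in {population!r}"
        )
    n = d1.size
    pA = float(d1.sum() / (2 * n))
    pB = float(d2.sum() / (2 * n))
    delta = float((d1 * d2).mean() / 2 - 2 * pA * pB)
    lo = max(0.0, pA + pB - 1.0) - pA * pB
    hi = min(pA, pB) - pA * pB
    delta = float(np.clip(delta, lo, hi))
    p11 = pA * pB + delta
    return HaplotypeFreqs(
        locus1=locus1,
        locus2=locus2,
        p11=p11,
        p12=pA - p11,
        p21=pB - p11,
        p22=1 - pA - pB + p11,
        pA=pA,
        pB=pB,
        method="composite",
        n_chromosomes=2 * n,
        population=population,
    )


def ld_stats(
    h: HaplotypeFreqs, threshold: float = DEFAULT_TAG_THRESHOLD
) -> LDResult:
    """D, D' (absolute convention) and r2 from haplotype frequencies.

    Raises :class:`LDUndefinedError`, naming the locus, when either locus
    is monomorphic (pA or pB in {0, 1}) — the ``r2 > threshold`` tag
    criterion is meaningless there.
    """
    for locus, freq in ((h.locus1, h.pA), (h.locus2, h.pB)):
        if freq <= 0.0 or freq >= 1.0:
            raise LDUndefinedError(
                f"LD undefined: locus {locus} is monomorphic "
                f"(ALT frequency {freq:g}) in this population"
            )
    D = h.p11 - h.pA * h.pB
    if D > 0:
        dmax = min(h.pA * (1 - h.pB), (1 - h.pA) * h.pB)
    else:
        dmax = min(h.pA * h.pB, (1 - h.pA) * (1 - h.pB))
    dprime = abs(D) / dmax if dmax > 0 else 0.0
    r2 = D**2 / (h.pA * (1 - h.pA) * h.pB * (1 - h.pB))
    # guard tiny float excursions outside [0,1]
    dprime = float(min(max(dprime, 0.0), 1.0))
    r2 = float(min(max(r2, 0.0), 1.0))
    return LDResult(
        locus1=h.locus1,
        locus2=h.locus2,
        population=h.population,
        D=float(D),
        Dprime=dprime,
        r2=r2,
        freqs=h,
        is_tag=bool(r2 > threshold),
        threshold=threshold,
    )


def tag_portability(
    g: GenotypeMatrix,
    pops: PopulationAssignment,
    tag_locus: str,
    functional_locus: str,
    populations: list[str] | None = None,
    threshold: float = DEFAULT_TAG_THRESHOLD,
) -> list[LDResult]:
    """Per-population LD between a tag SNP and its putative functional SNP.

    The estimation method is auto-selected: direct counting when the matrix
    is fully phased, EM otherwise. Per-population failures (monomorphic
    locus, no samples) become flagged rows with ``error`` set, never a
    global failure.
    """
    g.variant_index(tag_locus)
    g.variant_index(functional_locus)
    if populations is None:
        populations = pops.populations
    results: list[LDResult] = []
    for pop in populations:
        try:
            if g.fully_phased():
                h = haplotype_freqs_phased(g, pops, tag_locus, functional_locus, pop)
            else:
                h = em_haplotype_freqs(g, pops, tag_locus, functional_locus, pop)
            results.append(ld_stats(h, threshold=threshold))
        except LDUndefinedError as exc:
            results.append(
                LDResult(
                    locus1=tag_locus,
                    locus2=functional_locus,
                    population=pop,
                    D=float("nan"),
                    Dprime=float("nan"),
                    r2=float("nan"),
                    freqs=None,
                    is_tag=False,
                    threshold=threshold,
                    error=str(exc),
                )
            )
    return results


def results_to_frame(results: list[LDResult]):
    """Tabular view of LD results (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            dict(
                population=res.population,
                locus1=res.locus1,
                locus2=res.locus2,
                method=res.freqs.method if res.freqs else "",
                n_chromosomes=res.freqs.n_chromosomes if res.freqs else 0,
                D=res.D,
                Dprime=res.Dprime,
                r2=res.r2,
                is_tag=res.is_tag,
                em_iterations=res.freqs.em_iterations if res.freqs else 0,
                error=res.error or "",
            )
            for res in results
        ]
    )
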