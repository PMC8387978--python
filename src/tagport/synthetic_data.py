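"""Synthetic genotype datasets with controllable population structure.

Every analysis stage in this package is testable offline because this
module generates data with exactly the statistical structure the stages
estimate:

* differentiated population allele frequencies under the Balding-Nichols
  model, ``p_i ~ Beta(p(1-F)/F, (1-p)(1-F)/F)``, whose mean is the
  ancestral frequency ``p`` and whose variance is ``F*p*(1-p)`` — so ``F``
  is the target FST;
* two-locus haplotype structure at a requested D' (positive-D convention),
  drawn multinomially over the four haplotype classes and paired at random
  into diploids;
* admixed populations whose allele frequency is the ancestry-weighted
  mixture of component frequencies (admixture is modelled at the
  population-frequency level, matching a population-level frequency~
  ancestry regression; individual ancestry tracts are out of scope).

Genotypes are drawn under Hardy-Weinberg within each population. All
generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_genotypes import GenotypeMatrix, PopulationAssignment, VariantRecord

__all__ = [
    "SimulationConfig",
    "balding_nichols_freqs",
    "simulate_genotypes",
    "simulate_two_locus",
    "simulate_admixed",
    "merge_matrices",
    "simulate_from_config",
]


@dataclass
class SimulationConfig:
    """Parameters for a reproducible synthetic dataset.

    Either the Balding-Nichols block (``ancestral_freq``, ``F``,
    ``n_snps``), the two-locus block (``two_locus``) or the admixture block
    (``admixture``) drives the frequencies; see :func:`simulate_from_config`.
    """

    seed: int
    n_pops: int = 2
    n_diploids: list[int] = field(default_factory=lambda: [100, 100])
    ancestral_freq: float = 0.5
    F: float = 0.1
    n_snps: int = 1
    phased_output: bool = True
    pop_labels: list[str] | None = None
    # two_locus: {"pA": {pop: f}, "pB": {pop: f}, "dprime": {pop: f}}
    two_locus: dict | None = None
    # admixture: {"component_freqs": {anc: f}, "alphas": [{anc: a}, ...]}
    admixture: dict | None = None

    def labels(self) -> list[str]:
        if self.pop_labels is not None:
            return list(self.pop_labels)
        return [f"POP{i + 1}" for i in range(self.n_pops)]


def balding_nichols_freqs(
    p: float, F: float, n_pops: int, seed, n_snps: int = 1
) -> np.ndarray:
    """Per-population allele frequencies under the Balding-Nichols model.

    Returns an ``(n_pops, n_snps)`` array of independent draws from
    ``Beta(p(1-F)/F, (1-p)(1-F)/F)``; squeezed to ``(n_pops,)`` when
    ``n_snps == 1``.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"ancestral frequency must be in (0,1), got {p}")
    if not 0.0 < F < 1.0:
        raise ValueError(f"F must be in (0,1), got {F}")
    rng = np.random.default_rng(seed)
    scale = (1 - F) / F
    freqs = rng.beta(p * scale, (1 - p) * scale, size=(n_pops, n_snps))
    return freqs[:, 0] if n_snps == 1 else freqs


def _matrix_from_haplotypes(
    haps: np.ndarray,
    variants: list[VariantRecord],
    samples: list[str],
    phased_output: bool,
) -> GenotypeMatrix:
    """Assemble a GenotypeMatrix from an (n, 2, m) binary haplotype array."""
    dosage = haps.sum(axis=1).astype(np.int8)
    phased = np.full(dosage.shape, phased_output, dtype=bool)
    return GenotypeMatrix(
        variants=variants,
        samples=samples,
        dosage=dosage,
        phased=phased,
        haplotypes=haps.astype(np.int8) if phased_output else None,
    )


def _default_variants(n_snps: int, chrom: str = "21", start: int = 1_000_000):
    return [
        VariantRecord(chrom=chrom, pos=start + 1000 * j, id=f"snp{j + 1}", ref="A", alt="G")
        for j in range(n_snps)
    ]


def simulate_genotypes(
    pop_freqs,
    n_diploids,
    seed,
    phased_output: bool = True,
    pop_labels: list[str] | None = None,
    variants: list[VariantRecord] | None = None,
) -> tuple[GenotypeMatrix, PopulationAssignment]:
    """Hardy-Weinberg genotypes at given per-population allele frequencies.

    Parameters
    ----------
    pop_freqs:
        ``(n_pops,)`` or ``(n_pops, n_snps)`` ALT-allele frequencies.
    n_diploids:
        Per-population diploid sample sizes (int or list).
    """
    freqs = np.asarray(pop_freqs, dtype=float)
    if freqs.ndim == 1:
        freqs = freqs[:, None]
    n_pops, n_snps = freqs.shape
    if (freqs < 0).any() or (freqs > 1).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    if np.isscalar(n_diploids):
        n_diploids = [int(n_diploids)] * n_pops
    if len(n_diploids) != n_pops or min(n_diploids) < 1:
        raise ValueError("need a positive diploid count per population")
    labels = pop_labels or [f"POP{i + 1}" for i in range(n_pops)]
    if variants is None:
        variants = _default_variants(n_snps)

    rng = np.random.default_rng(seed)
    hap_blocks, samples, sample_to_pop = [], [], {}
    for i, (label, n) in enumerate(zip(labels, n_diploids)):
        haps = (rng.random((n, 2, n_snps)) < freqs[i]).astype(np.int8)
        hap_blocks.append(haps)
        for k in range(n):
            sid = f"{label}_{k + 1}"
            samples.append(sid)
            sample_to_pop[sid] = label
    g = _matrix_from_haplotypes(
        np.concatenate(hap_blocks, axis=0), variants, samples, phased_output
    )
    return g, PopulationAssignment(sample_to_pop=sample_to_pop)


def two_locus_haplotype_freqs(pA: float, pB: float, dprime: float) -> np.ndarray:
    """Haplotype frequencies (p11, p12, p21, p22) at a target D' (D >= 0)."""
    if not (0 < pA < 1 and 0 < pB < 1):
        raise ValueError("marginal frequencies must be in (0,1)")
    if not 0.0 <= dprime <= 1.0:
        raise ValueError(f"D' target must be in [0,1], got {dprime}")
    dmax = min(pA * (1 - pB), (1 - pA) * pB)
    D = dprime * dmax
    p = np.array(
        [pA * pB + D, pA * (1 - pB) - D, (1 - pA) * pB - D, (1 - pA) * (1 - pB) + D]
    )
    if (p < -1e-12).any():
        raise ValueError("implied haplotype frequency is negative")
    return np.clip(p, 0.0, 1.0)


def simulate_two_locus(
    pA: float,
    pB: float,
    dprime_target: float,
    n_diploids: int,
    seed,
    phased_output: bool = True,
    pop_label: str = "POP1",
    locus_ids: tuple[str, str] = ("snpA", "snpB"),
) -> tuple[GenotypeMatrix, PopulationAssignment]:
    """Two linked loci at a target D' (positive-D convention).

    ``2 * n_diploids`` haplotypes are drawn multinomially from the implied
    four-class distribution and paired at random into diploids; phase is
    erased unless ``phased_output``.
    """
    if n_diploids < 1:
        raise ValueError("n_diploids must be >= 1")
    probs = two_locus_haplotype_freqs(pA, pB, dprime_target)
    rng = np.random.default_rng(seed)
    n_chrom = 2 * n_diploids
    classes = rng.choice(4, size=n_chrom, p=probs)
    rng.shuffle(classes)  # random pairing into diploids
    # class -> (allele at locus A, allele at locus B)
    allele_a = np.array([1, 1, 0, 0], dtype=np.int8)
    allele_b = np.array([1, 0, 1, 0], dtype=np.int8)
    haps = np.stack(
        [allele_a[classes], allele_b[classes]], axis=1
    ).reshape(n_diploids, 2, 2)
    variants = [
        VariantRecord(chrom="21", pos=41_000_000, id=locus_ids[0], ref="A", alt="G"),
        VariantRecord(chrom="21", pos=41_010_000, id=locus_ids[1], ref="C", alt="T"),
    ]
    samples = [f"{pop_label}_{k + 1}" for k in range(n_diploids)]
    g = _matrix_from_haplotypes(haps, variants, samples, phased_output)
    return g, PopulationAssignment(sample_to_pop={s: pop_label for s in samples})


def simulate_admixed(
    component_freqs: dict[str, float],
    alphas: list[dict[str, float]],
    n_diploids,
    seed,
    phased_output: bool = True,
    pop_labels: list[str] | None = None,
) -> tuple[GenotypeMatrix, PopulationAssignment]:
    """Admixed populations with ancestry-weighted allele frequencies.

    Population ``k`` gets allele frequency ``sum_anc alpha[k][anc] *
    component_freqs[anc]`` and Hardy-Weinberg genotypes at that frequency;
    the ancestry vectors are recorded in the returned assignment.
    """
    for vec in alphas:
        for anc in vec:
            if anc not in component_freqs:
                raise ValueError(f"unknown ancestry label {anc!r}")
        if abs(sum(vec.values()) - 1.0) > 1e-6:
            raise ValueError(f"ancestry proportions {vec} do not sum to 1")
    labels = pop_labels or [f"ADM{i + 1}" for i in range(len(alphas))]
    mixed = np.array(
        [sum(a * component_freqs[anc] for anc, a in vec.items()) for vec in alphas]
    )
    g, pops = simulate_genotypes(
        mixed, n_diploids, seed, phased_output=phased_output, pop_labels=labels
    )
    ancestry = {
        label: {anc: float(a) for anc, a in vec.items()}
        for label, vec in zip(labels, alphas)
    }
    return g, PopulationAssignment(sample_to_pop=pops.sample_to_pop, ancestry=ancestry)


def merge_matrices(matrices: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Stack matrices sample-wise (same variants, disjoint samples)."""
    first = matrices[0]
    for m in matrices[1:]:
        if m.variants != first.variants:
            raise ValueError("matrices must share an identical variant list")
    samples = [s for m in matrices for s in m.samples]
    if len(set(samples)) != len(samples):
        raise ValueError("sample ids must be disjoint across matrices")
    dosage = np.concatenate([m.dosage for m in matrices], axis=0)
    phased = np.concatenate([m.phased for m in matrices], axis=0)
    haplotypes = None
    if all(m.haplotypes is not None for m in matrices):
        haplotypes = np.concatenate([m.haplotypes for m in matrices], axis=0)
    return GenotypeMatrix(list(first.variants), samples, dosage, phased, haplotypes)


def simulate_from_config(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, PopulationAssignment]:
    """Build a dataset from a :class:`SimulationConfig`.

    Precedence: the two-locus block, then the admixture block, then the
    Balding-Nichols block. Two-locus populations are simulated one by one
    (independent child-seeds derived from ``seed``) and merged.
    """
    labels = config.labels()
    if config.two_locus is not None:
        tl = config.two_locus
        blocks, sample_to_pop = [], {}
        child_seeds = np.random.SeedSequence(config.seed).spawn(len(labels))
        for i, label in enumerate(labels):
            g, pops = simulate_two_locus(
                pA=tl["pA"][label],
                pB=tl["pB"][label],
                dprime_target=tl["dprime"][label],
                n_diploids=config.n_diploids[i],
                seed=child_seeds[i],
                phased_output=config.phased_output,
                pop_label=label,
                locus_ids=tuple(tl.get("locus_ids", ("snpA", "snpB"))),
            )
            blocks.append(g)
            sample_to_pop.update(pops.sample_to_pop)
        return merge_matrices(blocks), PopulationAssignment(sample_to_pop=sample_to_pop)
    if config.admixture is not None:
        return simulate_admixed(
            component_freqs=config.admixture["component_freqs"],
            alphas=config.admixture["alphas"],
            n_diploids=config.n_diploids,
            seed=config.seed,
            phased_output=config.phased_output,
            pop_labels=config.pop_labels,
        )
    freqs = balding_nichols_freqs(
        config.ancestral_freq, config.F, config.n_pops, config.seed, config.n_snps
    )
    return simulate_genotypes(
        freqs,
        config.n_diploids,
        seed=np.random.SeedSequence(config.seed).spawn(1)[0],
        phased_output=config.phased_output,
        pop_labels=config.pop_labels,
    )
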