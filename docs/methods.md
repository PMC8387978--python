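# Methods

This note documents the estimators, the generative models behind the test
fixtures, the numerical choices, and the limits of what the synthetic
validation demonstrates.

## Genotype representation

The central container is a samples × variants matrix of diploid ALT-allele
dosages in {0, 1, 2} with a per-cell phase flag, plus a samples × 2 ×
variants haplotype panel that exists only when every non-missing call is
phased. Coordinates are 1-based inclusive (VCF convention) throughout; no
0-based surface is exposed anywhere.

Deliberate restrictions, enforced with explicit errors rather than silent
coercion:

* **Strictly diploid.** Haploid calls (e.g. male X; relevant to genes on
  Xp22.2) are out of scope and rejected.
* **Bi-allelic only.** Multi-allelic records are skipped with a warning,
  not split: the two-locus LD machinery and the Weir–Cockerham components
  are bi-allelic statistics.
* **Half-calls are missing.** A call like `0/.` has no unambiguous dosage,
  and every downstream estimator needs one.
* **Missing data is complete-case, per locus (pairwise for LD).** No
  imputation. This is the simplest defensible estimator; `n_called` is
  always reported so callers can filter on it.

## Allele frequencies

Per population, the frequency of a *stated* effect allele among non-missing
calls: `freq = allele_count / (2·n_called)`, exact in rational arithmetic
because both terms are integer counts. Orientation is never inferred from
frequency — flipping the effect allele maps `p → 1 − p` exactly, and
forcing the caller to state it prevents silent `1 − p` errors when mixing
array and sequencing data.

## Weir–Cockerham θ̂

For two populations with per-population sizes `n_i`, ALT frequencies `p_i`
and observed heterozygote fractions `h_i`, the three 1984 variance
components are computed exactly as published (among populations `a`, among
individuals within populations `b`, within individuals `c`), and
`θ̂ = a/(a+b+c)` per site. Choices:

* **Negative θ̂ retained.** Clamping at 0 would bias the empirical outlier
  percentile, which ranks the raw distribution.
* **Monomorphic-in-both sites flagged**, never reported as 0: with
  `a+b+c = 0` the estimand does not exist.
* **Multi-SNP summary by ratio of sums** (`Σa / Σ(a+b+c)`), the standard
  less-biased combination; the per-site average of ratios is noticeably
  biased at these sample sizes.
* **Outlier percentile** of a focal SNP in a set counts ties in the
  numerator (`100·|{θ̂_i ≥ θ̂_focal}|/N`) — the conservative direction for
  an outlier claim.
* Each population needs ≥ 2 called diploids at a site (the `n − 1`
  denominators); thinner sites are flagged.

The unit tests check the components term by term against an independently
coded sum-form transcription of the published formulas (agreement to
1e-12), and the estimator end to end against the generative F of the
Balding–Nichols model (below).

## Two-locus LD

Haplotype frequencies `(p11, p12, p21, p22)` for the ALT/REF combinations
at two loci, from one of three estimators (recorded in the result):

* `phased_count` — direct counting over 2n chromosomes when the haplotype
  panel exists. The reference path.
* `em` — the classic two-locus EM for unphased diploid genotypes. Of the
  nine joint-dosage classes only the double heterozygote is
  phase-ambiguous; the E-step splits it between cis (AB/ab) and trans
  (Ab/aB) with weight `p11·p22 / (p11·p22 + p12·p21)` and the M-step
  renormalizes expected haplotype counts. Initialized at linkage
  equilibrium `p11 = pA·pB` (which keeps the marginal allele frequencies
  fixed at their sample MLEs across iterations, reducing the problem to a
  1-D likelihood in `p11`), tolerance 1e-10 on the max frequency change,
  max 1000 iterations; fully deterministic given the input. The
  log-likelihood history is retained and asserted non-decreasing in tests,
  and agreement from random simplex initializations is tested to flag
  multimodality.
* `composite` — a Burrows-style half-covariance of dosages, offered as a
  labelled fallback for comparison only; it is consistent for D under HWE
  but does not maximize the haplotype likelihood and is never
  auto-selected.

From the frequencies: `D = p11 − pA·pB`; `D′ = |D|/Dmax` with
`Dmax = min(pA(1−pB), (1−pA)pB)` for `D > 0` and
`min(pA·pB, (1−pA)(1−pB))` otherwise (absolute-value convention,
`D′ ∈ [0,1]`; the signed D is retained alongside); `r² = D²/(pA qA pB qB)`.
A monomorphic locus raises an error naming the locus — the tag criterion is
meaningless there, and NaN propagation would hide it. The tag verdict is
the strict inequality `r² > threshold`, default 0.80, configurable.

`tag_portability` auto-selects the method (counting iff fully phased, else
EM) and converts per-population failures into flagged rows rather than
aborting the other populations.

**EM validation.** The EM is checked against a brute-force maximizer of the
same nine-class multinomial likelihood: with the marginals fixed at their
MLEs the likelihood is a function of `p11` alone on
`[max(0, pA+pB−1), min(pA, pB)]`; a coarse 1e-4 scan locates every local
maximum and a 1e-7 grid refines around each. On 25 unphased fixtures
(n = 50) the EM `p̂11` matches the grid maximizer to 1e-6.

**Phase-erasure consistency.** On data simulated phased and then stripped
of phase, the EM estimate is compared with the phased count of the same
samples. The difference is exactly the information lost to double-
heterozygote ambiguity; it is a mean-zero random quantity whose size
shrinks with n, not an implementation error, so the consistency check
bounds its *typical* size: RMS r² difference ≤ 0.02 over 50 seeds at
n = 500 (measured ≈ 0.016 at pA = 0.4, pB = 0.45, D′ = 0.5454), and
agreement within 0.01 at n = 5000.

## Ancestry regression

Ordinary least squares of per-population effect-allele frequency on a
per-population ancestry proportion, one point per population, unweighted by
default (a sample-size-weighted variant sits behind a flag). Requires ≥ 3
populations and non-constant ancestry; a constant response is reported as
slope 0, r = 0 with a zero-variance flag instead of a 0/0 NaN. Under
two-way admixture the population frequency is
`α·p_anc + (1−α)·p_other`, so the expected slope is `p_anc − p_other` —
the identity the recovery tests exploit. No p-values: the relationship is
descriptive, and with ~10 population-level points inferential machinery
would suggest more than the design supports.

## Synthetic data: what it emulates, what it does not

The generator produces data with precisely the structure the estimators
assume, which is what makes closed-form recovery tests possible:

* **Balding–Nichols frequencies**: each population's allele frequency is an
  independent `Beta(p(1−F)/F, (1−p)(1−F)/F)` draw around ancestral `p`,
  so the mean is `p` and the variance `F·p(1−p)` — F *is* the target FST.
  Chosen over coalescent simulation because it targets F directly, is
  closed-form testable, and runs in milliseconds. Defaults used by the
  recovery checks: `p = 0.5`, `F = 0.1`, 2 populations × 100 diploids,
  500 SNPs, for which the ratio-of-sums θ̂ lands in [0.08, 0.12].
* **Two-locus haplotypes at a target D′** (positive-D convention):
  `D = D′·Dmax(pA, pB)`, the four class frequencies follow, 2n haplotypes
  are drawn multinomially and paired at random into diploids (so HWE holds
  at the haplotype level, as the EM assumes); phase is erased on request.
  Negative-D structure is covered by allele-flip invariance tests rather
  than a second code path.
* **Admixed populations**: frequency `Σ_anc α_anc·p_anc`, genotypes under
  HWE at that mixed frequency, ancestry vectors recorded. Admixture is
  modelled at the population-frequency level because the regression it
  feeds is population-level; individual ancestry tracts are not simulated.

Everything is bit-reproducible given (config, seed); independent
sub-simulations derive child seeds from the master seed.

What passing these tests does **not** show about real data: no
recombination maps or LD decay, no site-frequency-spectrum realism, no
genotyping error, batch effects or array/sequencing platform differences,
no selection, and HWE holds exactly within populations. The synthetic
checks validate the *estimators*; conclusions about any real tag/functional
pair still depend on the quality of the input genotypes.

## Pipeline

`run_pipeline` chains frequencies → FST (skipped with a logged notice for a
single population) → per-population LD → ancestry regression (skipped
without ancestry proportions or with < 3 populations), writes each stage as
a TSV, and renders the portability report. Populations with undefined LD
are reported *untestable*, not failing — a monomorphic functional locus is
a different situation from demonstrated LD breakdown. Every stage logs one
structured line (inputs, drops, parameters): the workflow exists because of
silent assumptions, so it narrates its own. Output is a pure function of
(input files, config); reruns are byte-identical, which the tests assert
with a file-level diff.

## Problem sizes

The validation suite uses: n = 50 diploids × 25 fixtures for the EM/grid
check; n = 500 × 50 seeds for phase-erasure consistency; 500 SNPs × 2 × 100
diploids for FST recovery; n = 5000 (×30 replicates for the Monte-Carlo
standard error) for D′ recovery; 10 populations × 200 diploids × 200 seeds
for slope recovery; 71 SNPs × 2 × 150 diploids for the outlier percentile.
These sizes put Monte-Carlo noise well inside each stated band while the
whole suite runs in well under a minute.

## Known limitations

* Single-ALT VCF records only; no BCF, tabix or imputation.
* LD is pairwise two-locus; no multi-locus phasing, blocks, or decay
  curves.
* The EM assumes random union of gametes within the population; strong
  inbreeding or substructure within a labelled population violates it.
* Ancestry proportions are consumed as given (population-level); the
  package does not infer them.
* The composite estimator is provided for comparison and clipped into the
  feasible haplotype simplex; treat it as diagnostic, not inferential.
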