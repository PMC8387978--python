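"""Per-population effect-allele frequency estimation.

The effect allele is always an explicit input (e.g. the G allele of a tag
SNP): allele/strand flips between genotyping arrays and sequencing are a
classic silent failure mode, so orientation is never inferred from
frequency. Estimation is per-variant complete-case within each population
(no imputation), and ``n_called`` is always reported so the caller can
apply any minimum-sample filter.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

from .io_genotypes import MISSING, GenotypeMatrix, PopulationAssignment

__all__ = ["effect_allele_frequency"]

#: Column order of the allele-frequency table.
COLUMNS = [
    "variant_id",
    "population",
    "effect_allele",
    "freq",
    "allele_count",
    "n_called",
    "no_calls",
]


def effect_allele_frequency(
    g: GenotypeMatrix,
    pops: PopulationAssignment,
    effect_allele_map: Mapping[str, str],
) -> pd.DataFrame:
    """Frequency of each stated effect allele in each population.

    Parameters
    ----------
    g:
        Genotype matrix.
    pops:
        Population assignment; samples absent from ``g`` are ignored,
        samples of ``g`` absent from ``pops`` are excluded.
    effect_allele_map:
        ``variant id -> allele``; each allele must equal the variant's REF
        or ALT. Variants not in the map are skipped.

    Returns
    -------
    pandas.DataFrame
        One row per (variant, population) with ``freq = allele_count /
        (2 * n_called)``. Populations with no called genotypes at a variant
        get ``freq = NaN`` and ``no_calls = True`` (with a warning).
    """
    import warnings

    rows = []
    pop_members = {
        pop: g.sample_indices([s for s in pops.samples_in(pop) if s in set(g.samples)])
        for pop in pops.populations
    }
    for j, variant in enumerate(g.variants):
        if variant.id not in effect_allele_map:
            continue
        allele = effect_allele_map[variant.id]
        if allele == variant.alt:
            count_effect = lambda d: int(d.sum())
        elif allele == variant.ref:
            count_effect = lambda d: int(2 * d.size - d.sum())
        else:
            raise ValueError(
                f"effect allele {allele!r} for variant {variant.id} matches "
                f"neither REF ({variant.ref}) nor ALT ({variant.alt})"
            )
        for pop, idx in pop_members.items():
            d = g.dosage[idx, j] if len(idx) else np.empty(0, dtype=np.int8)
            d = d[d != MISSING]
            n_called = d.size
            if n_called == 0:
                warnings.warn(
                    f"population {pop!r} has no called genotypes at {variant.id}",
                    stacklevel=2,
                )
                rows.append(
                    dict(
                        variant_id=variant.id,
                        population=pop,
                        effect_allele=allele,
                        freq=np.nan,
                        allele_count=0,
                        n_called=0,
                        no_calls=True,
                    )
                )
                continue
            allele_count = count_effect(d)
            rows.append(
                dict(
                    variant_id=variant.id,
                    population=pop,
                    effect_allele=allele,
                    freq=allele_count / (2 * n_called),
                    allele_count=allele_count,
                    n_called=n_called,
                    no_calls=False,
                )
            )
    return pd.DataFrame(rows, columns=COLUMNS)
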