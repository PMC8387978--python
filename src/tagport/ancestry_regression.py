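"""Population-level regression of allele frequency on ancestry proportion.

Each population contributes one (ancestry proportion, allele frequency)
point; the fit is ordinary least squares, unweighted by default so that
small reference populations count as much as large cohorts in the
population-level scatter. Under a two-way admixture model where population
``k`` has frequency ``alpha_k * p_anc + (1 - alpha_k) * p_other``, the
expected slope is ``p_anc - p_other``. The relationship is reported
descriptively (slope, intercept, Pearson r); no p-value machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_genotypes import PopulationAssignment

__all__ = ["AncestryRegressionResult", "freq_ancestry_regression"]


@dataclass(frozen=True)
class AncestryRegressionResult:
    """OLS fit of per-population frequency on an ancestry component."""

    variant_id: str
    ancestry: str
    slope: float
    intercept: float
    pearson_r: float
    n_populations: int
    zero_variance_freq: bool = False


def freq_ancestry_regression(
    freqs: pd.DataFrame,
    pops: PopulationAssignment,
    variant_id: str,
    ancestry: str,
    weighted: bool = False,
) -> AncestryRegressionResult:
    """Regress a variant's per-population frequency on ancestry proportion.

    Parameters
    ----------
    freqs:
        Allele-frequency table from
        :func:`tagport.allele_freq.effect_allele_frequency`.
    ancestry:
        Component label (``NAT``, ``EUR``, ``AFR`` or ``EAS``).
    weighted:
        If True, weight populations by ``n_called`` (off by default; the
        population-level scatter treats populations equally).

    Requires >= 3 populations with both a defined frequency and an
    ancestry proportion, and non-constant ancestry proportions. A constant
    response is reported as ``slope = 0, pearson_r = 0`` with
    ``zero_variance_freq = True`` rather than a division-by-zero NaN.
    """
    sub = freqs[(freqs["variant_id"] == variant_id) & (~freqs["no_calls"])]
    points = []
    for _, row in sub.iterrows():
        props = pops.ancestry.get(row["population"])
        if props is None or ancestry not in props:
            continue
        points.append((props[ancestry], float(row["freq"]), int(row["n_called"])))
    if len(points) < 3:
        raise ValueError(
            f"need >= 3 populations with frequency and {ancestry} ancestry for "
            f"{variant_id}, got {len(points)}"
        )
    x, y, n_called = map(np.asarray, zip(*points))
    if np.ptp(x) == 0:
        raise ValueError(f"zero variance in {ancestry} ancestry proportions")

    if np.ptp(y) == 0:
        return AncestryRegressionResult(
            variant_id=variant_id,
            ancestry=ancestry,
            slope=0.0,
            intercept=float(y[0]),
            pearson_r=0.0,
            n_populations=len(points),
            zero_variance_freq=True,
        )

    if weighted:
        w = n_called.astype(float)
        wls = np.polyfit(x, y, deg=1, w=np.sqrt(w))
        slope, intercept = float(wls[0]), float(wls[1])
        r = float(stats.pearsonr(x, y).statistic)
    else:
        fit = stats.linregress(x, y)
        slope, intercept, r = float(fit.slope), float(fit.intercept), float(fit.rvalue)
    return AncestryRegressionResult(
        variant_id=variant_id,
        ancestry=ancestry,
        slope=slope,
        intercept=intercept,
        pearson_r=r,
        n_populations=len(points),
    )
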