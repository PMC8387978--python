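"""Genotype containers and standard-format I/O.

The central object is :class:`GenotypeMatrix`, a samples x variants table of
diploid ALT-allele dosages with per-cell phase flags, optionally backed by a
haplotype panel when every call is phased. VCF v4.2 is the on-disk format
(read via cyvcf2, written by a minimal emitter); population membership and
population-level ancestry proportions come from a two-column TSV with
optional ancestry columns.

Conventions
-----------
* Coordinates are 1-based inclusive everywhere (VCF convention).
* Genotypes are strictly diploid; haploid calls are rejected.
* Only bi-allelic records are kept; multi-allelic records are skipped with
  a warning.
* Half-calls (``0/.``) and ``./.`` are treated as missing: every downstream
  estimator needs an unambiguous dosage.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

__all__ = [
    "MISSING",
    "VariantRecord",
    "GenotypeMatrix",
    "PopulationAssignment",
    "read_vcf",
    "write_vcf",
    "read_population_map",
    "write_population_map",
]

#: Sentinel dosage for a missing diploid call.
MISSING: int = -1

ANCESTRY_LABELS = ("NAT", "EUR", "AFR", "EAS")

_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


class VCFError(ValueError):
    """Raised for malformed or unusable VCF input."""


@dataclass(frozen=True)
class VariantRecord:
    """A bi-allelic SNV/indel site.

    ``pos`` is 1-based; ``id`` is never empty (``chrom:pos`` is synthesized
    when the VCF ID column is ``.``).
    """

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"REF and ALT must differ at {self.chrom}:{self.pos}")
        if not self.id:
            raise ValueError("variant id must be non-empty")


@dataclass
class GenotypeMatrix:
    """Samples x variants diploid dosage matrix with phase information.

    Attributes
    ----------
    variants:
        Ordered variant records (columns).
    samples:
        Ordered sample identifiers (rows).
    dosage:
        ``(n_samples, n_variants)`` int array of ALT-allele counts in
        ``{0, 1, 2}`` or :data:`MISSING`.
    phased:
        ``(n_samples, n_variants)`` bool array; ``True`` where the call was
        phased (``|`` separator).
    haplotypes:
        ``(n_samples, 2, n_variants)`` binary array, present only when every
        non-missing call is phased and no call is missing-with-phase
        ambiguity; missing cells carry :data:`MISSING` in both haplotypes.
        ``None`` otherwise.
    """

    variants: list[VariantRecord]
    samples: list[str]
    dosage: np.ndarray
    phased: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.phased = np.asarray(self.phased, dtype=bool)
        shape = (len(self.samples), len(self.variants))
        if self.dosage.shape != shape:
            raise ValueError(f"dosage shape {self.dosage.shape} != {shape}")
        if self.phased.shape != shape:
            raise ValueError(f"phased shape {self.phased.shape} != {shape}")
        valid = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("dosages must be in {0, 1, 2, MISSING}")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (len(self.samples), 2, len(self.variants)):
                raise ValueError("haplotypes shape inconsistent with matrix")
            hsum = self.haplotypes.sum(axis=1)
            miss = self.dosage == MISSING
            if not np.array_equal(hsum[~miss], self.dosage[~miss]):
                raise ValueError("haplotypes inconsistent with dosage")
            for k in (0, 1):
                if not (self.haplotypes[:, k, :][miss] == MISSING).all():
                    raise ValueError("missing dosage must propagate to haplotypes")
            if not self.phased[~miss].all():
                raise ValueError("haplotype panel present but unphased calls exist")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def variant_index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"variant {variant_id!r} not in matrix") from None

    def sample_indices(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from None

    def fully_phased(self) -> bool:
        """True when every non-missing call is phased (haplotype panel exists)."""
        return self.haplotypes is not None

    def erase_phase(self) -> "GenotypeMatrix":
        """Return a copy with all phase information dropped (array-like data)."""
        return GenotypeMatrix(
            variants=list(self.variants),
            samples=list(self.samples),
            dosage=self.dosage.copy(),
            phased=np.zeros_like(self.phased),
            haplotypes=None,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        if self.variants != other.variants or self.samples != other.samples:
            return False
        if not np.array_equal(self.dosage, other.dosage):
            return False
        if not np.array_equal(self.phased, other.phased):
            return False
        if (self.haplotypes is None) != (other.haplotypes is None):
            return False
        if self.haplotypes is not None and not np.array_equal(
            self.haplotypes, other.haplotypes
        ):
            return False
        return True


@dataclass
class PopulationAssignment:
    """Sample-to-population map plus optional population ancestry proportions.

    ``ancestry`` maps a population label to a dict over the continental
    components ``NAT/EUR/AFR/EAS``; proportions must sum to 1 within 1e-6.
    """

    sample_to_pop: dict[str, str]
    ancestry: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop, props in self.ancestry.items():
            for label, value in props.items():
                if label not in ANCESTRY_LABELS:
                    raise ValueError(f"unknown ancestry label {label!r} for {pop}")
                if not 0.0 <= value <= 1.0:
                    raise ValueError(f"ancestry proportion out of [0,1] for {pop}")
            total = sum(props.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"ancestry proportions for population {pop!r} sum to "
                    f"{total:.8f}, expected 1"
                )

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.sample_to_pop.values():
            seen.setdefault(pop, None)
        return list(seen)

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.sample_to_pop.items() if p == population]


def _parse_region(region: str) -> tuple[str, int, int]:
    m = _REGION_RE.match(region)
    if not m:
        raise ValueError(
            f"region must look like 'chrom:start-end' (1-based inclusive), got {region!r}"
        )
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if start < 1 or end < start:
        raise ValueError(f"invalid region bounds in {region!r}")
    return chrom, start, end


def read_vcf(path: str | os.PathLike, region: str | None = None) -> GenotypeMatrix:
    """Read a diploid, GT-bearing VCF v4.2 into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path:
        VCF file (plain or bgzipped).
    region:
        Optional ``chrom:start-end`` restriction, 1-based inclusive; applied
        by streaming filter so no index is required.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    VCFError
        If the VCF lacks a GT FORMAT field, contains haploid calls, or the
        (possibly region-restricted) file yields zero variants while samples
        are present.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"VCF file not found: {path}")
    vcf = VCF(str(path))
    if "##FORMAT=<ID=GT" not in vcf.raw_header and vcf.samples:
        raise VCFError(f"VCF {path} has samples but no GT FORMAT field")
    samples = list(vcf.samples)

    bounds = _parse_region(region) if region is not None else None

    variants: list[VariantRecord] = []
    dosage_cols: list[np.ndarray] = []
    phased_cols: list[np.ndarray] = []
    hap_cols: list[np.ndarray] = []

    for var in vcf:
        if bounds is not None:
            chrom, start, end = bounds
            if var.CHROM != chrom or not (start <= var.POS <= end):
                continue
        if len(var.ALT) != 1:
            warnings.warn(
                f"skipping multi-allelic record {var.CHROM}:{var.POS} "
                f"(ALT={','.join(var.ALT) or '.'})",
                stacklevel=2,
            )
            continue
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        variants.append(
            VariantRecord(chrom=var.CHROM, pos=var.POS, id=vid, ref=var.REF, alt=var.ALT[0])
        )
        dcol = np.empty(len(samples), dtype=np.int8)
        pcol = np.zeros(len(samples), dtype=bool)
        hcol = np.empty((len(samples), 2), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            *alleles, is_phased = gt
            if len(alleles) != 2:
                raise VCFError(
                    f"non-diploid call ({len(alleles)} allele(s)) for sample "
                    f"{samples[i]} at {var.CHROM}:{var.POS}; only diploid data "
                    "is supported (haploid X handling is out of scope)"
                )
            a, b = alleles
            if a < 0 or b < 0:  # ./., half-calls
                dcol[i] = MISSING
                hcol[i] = (MISSING, MISSING)
                pcol[i] = False
            else:
                dcol[i] = a + b
                hcol[i] = (a, b)
                pcol[i] = bool(is_phased)
        dosage_cols.append(dcol)
        phased_cols.append(pcol)
        hap_cols.append(hcol)

    if not variants:
        if region is not None:
            raise VCFError(f"zero variants in region {region!r} of {path}")
        if samples:
            raise VCFError(f"VCF {path} contains no usable variants")
        # header-only, zero-sample VCF: legal degenerate matrix
        return GenotypeMatrix(
            variants=[],
            samples=[],
            dosage=np.empty((0, 0), dtype=np.int8),
            phased=np.empty((0, 0), dtype=bool),
            haplotypes=np.empty((0, 2, 0), dtype=np.int8),
        )

    dosage = np.column_stack(dosage_cols)
    phased = np.column_stack(phased_cols)
    miss = dosage == MISSING
    haplotypes = None
    if phased[~miss].all():
        haplotypes = np.stack(hap_cols, axis=2)  # (samples, 2, variants)
    return GenotypeMatrix(variants, samples, dosage, phased, haplotypes)


def write_vcf(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a :class:`GenotypeMatrix` as minimal VCF v4.2.

    Phase is encoded with ``|`` vs ``/`` per the phase flags and the
    haplotype panel when present; a phased heterozygote without a haplotype
    panel is emitted as ``0|1`` (the container does not store allele order
    for mixed-phase data). Missing calls are ``./.``. Round-trips through
    :func:`read_vcf` to an equal :class:`GenotypeMatrix`.
    """
    lines = ["##fileformat=VCFv4.2"]
    for chrom in dict.fromkeys(v.chrom for v in g.variants):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if g.samples:
        header += ["FORMAT"] + list(g.samples)
    lines.append("\t".join(header))

    for j, v in enumerate(g.variants):
        fields = [v.chrom, str(v.pos), v.id, v.ref, v.alt, ".", ".", "."]
        if g.samples:
            fields.append("GT")
            for i in range(g.n_samples):
                d = g.dosage[i, j]
                if d == MISSING:
                    fields.append("./.")
                    continue
                sep = "|" if g.phased[i, j] else "/"
                if g.haplotypes is not None:
                    a, b = g.haplotypes[i, :, j]
                else:
                    a, b = (0, 1) if d == 1 else (d // 2, d // 2)
                fields.append(f"{a}{sep}{b}")
        lines.append("\t".join(fields))

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_population_map(path: str | os.PathLike) -> PopulationAssignment:
    """Read a ``sample<TAB>population`` TSV with optional ancestry columns.

    The optional columns ``NAT, EUR, AFR, EAS`` give population-level
    ancestry proportions (repeated on each of the population's rows); they
    must agree within a population and sum to 1 within 1e-6.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "population": str})
    for col in ("sample", "population"):
        if col not in df.columns:
            raise ValueError(f"population map {path} lacks required column {col!r}")
    dup = df["sample"][df["sample"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample(s) in population map: {sorted(set(dup))}")

    sample_to_pop = dict(zip(df["sample"], df["population"]))
    anc_cols = [c for c in ANCESTRY_LABELS if c in df.columns]
    ancestry: dict[str, dict[str, float]] = {}
    if anc_cols:
        for pop, grp in df.groupby("population", sort=False):
            block = grp[anc_cols].astype(float)
            if block.isna().all(axis=None):
                continue
            if block.isna().any(axis=None):
                raise ValueError(f"partial ancestry row(s) for population {pop!r}")
            if (block.nunique() > 1).any():
                raise ValueError(
                    f"ancestry proportions differ between samples of population {pop!r}"
                )
            ancestry[pop] = dict(zip(anc_cols, block.iloc[0]))
    return PopulationAssignment(sample_to_pop=sample_to_pop, ancestry=ancestry)


def write_population_map(pops: PopulationAssignment, path: str | os.PathLike) -> None:
    """Write the TSV counterpart of :func:`read_population_map`."""
    import pandas as pd

    rows = []
    has_anc = bool(pops.ancestry)
    for sample, pop in pops.sample_to_pop.items():
        row: dict[str, object] = {"sample": sample, "population": pop}
        if has_anc:
            props = pops.ancestry.get(pop, {})
            for label in ANCESTRY_LABELS:
                row[label] = props.get(label, "") if props else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
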