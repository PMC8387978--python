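"""Pipeline orchestration and the tag-SNP portability report.

A tag SNP is a proxy genotyped in place of a functional variant; the proxy
is valid only in populations where the two are in strong LD (strict
``r2 > threshold``, default 0.80). ``run_pipeline`` chains allele
frequencies, between-population FST (with an optional empirical outlier
percentile for the tag SNP), per-population LD, and the optional
frequency~ancestry regression, writes every stage as a TSV, and renders a
Markdown report whose every number is traceable to a stage TSV.

Populations where LD is undefined (a monomorphic locus) are reported as
*untestable*, not failing. Each stage logs one structured line with input
counts and parameters; the output is a pure function of (input files,
config), so reruns are diff-clean.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import allele_freq, ancestry_regression, fst, ld
from .io_genotypes import read_population_map, read_vcf

__all__ = ["PortabilityReport", "run_pipeline"]

logger = logging.getLogger("tagport")


@dataclass
class PortabilityReport:
    """Per-population portability of a tag SNP for a functional variant."""

    tag: str
    functional: str
    threshold: float
    rows: pd.DataFrame  # population, tag_freq, theta_vs_ref, r2, Dprime, is_tag, status
    verdict: str
    failing_populations: list[str] = field(default_factory=list)
    untestable_populations: list[str] = field(default_factory=list)

    def to_markdown(self) -> str:
        lines = [
            f"# Tag-SNP portability report: {self.tag} -> {self.functional}",
            "",
            f"Tag criterion: r² > {self.threshold:g} (strict).",
            "",
            "| population | tag allele freq | theta vs ref | r2 | D' | verdict |",
            "|---|---|---|---|---|---|",
        ]
        for _, r in self.rows.iterrows():
            def fmt(x):
                return "-" if pd.isna(x) else f"{x:.4f}"

            lines.append(
                f"| {r['population']} | {fmt(r['tag_freq'])} | "
                f"{fmt(r['theta_vs_ref'])} | {fmt(r['r2'])} | {fmt(r['Dprime'])} | "
                f"{r['status']} |"
            )
        lines += ["", f"**Overall:** {self.verdict}", ""]
        return "\n".join(lines)


class ConfigError(ValueError):
    """Pipeline configuration schema violation (reported with field names)."""


def _load_config(config) -> dict:
    if isinstance(config, (str, os.PathLike)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("pipeline config must be a mapping")
    missing = [k for k in ("vcf", "pops", "tag", "functional") if k not in config]
    if missing:
        raise ConfigError(f"pipeline config missing required field(s): {missing}")
    return config


def run_pipeline(config, outdir: str | os.PathLike | None = None) -> PortabilityReport:
    """Run the full portability analysis from a config mapping or YAML path.

    Config fields
    -------------
    vcf, pops : paths (required)
    tag, functional : variant ids (required)
    effect_alleles : {variant id: allele}; defaults to each variant's ALT
    reference_population : FST reference (default: first population)
    threshold : tag r2 threshold (default 0.80)
    ancestry_component : regression component (default NAT when ancestry
        proportions are present)
    outdir : where stage TSVs and report.md/report.tsv go (argument wins)

    Returns the :class:`PortabilityReport`; stage TSVs are written when an
    output directory is configured.
    """
    cfg = _load_config(config)
    outdir = outdir or cfg.get("outdir")
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)

    def emit(name: str, frame: pd.DataFrame) -> None:
        if outdir is not None:
            frame.to_csv(os.path.join(outdir, name), sep="\t", index=False)

    g = read_vcf(cfg["vcf"], region=cfg.get("region"))
    pops = read_population_map(cfg["pops"])
    pop_list = [p for p in pops.populations if any(
        s in set(g.samples) for s in pops.samples_in(p)
    )]
    tag, functional = cfg["tag"], cfg["functional"]
    threshold = float(cfg.get("threshold", ld.DEFAULT_TAG_THRESHOLD))
    logger.info(
        "stage=load vcf=%s pops=%s n_samples=%d n_variants=%d n_populations=%d",
        cfg["vcf"], cfg["pops"], g.n_samples, g.n_variants, len(pop_list),
    )

    by_id = {v.id: v for v in g.variants}
    for vid in (tag, functional):
        if vid not in by_id:
            raise ConfigError(f"variant {vid!r} not present in the VCF")
    effect_alleles = dict(cfg.get("effect_alleles") or {})
    for vid in (tag, functional):
        effect_alleles.setdefault(vid, by_id[vid].alt)

    # --- allele frequencies ---------------------------------------------------
    freq_table = allele_freq.effect_allele_frequency(g, pops, effect_alleles)
    emit("allele_freq.tsv", freq_table)
    logger.info("stage=allele_freq n_rows=%d variants=%d",
                len(freq_table), freq_table["variant_id"].nunique())

    # --- FST vs reference population -----------------------------------------
    fst_frames: list[pd.DataFrame] = []
    theta_vs_ref: dict[str, float] = {}
    percentile = None
    reference = cfg.get("reference_population", pop_list[0] if pop_list else None)
    if len(pop_list) >= 2:
        if reference not in pop_list:
            raise ConfigError(f"reference_population {reference!r} not in data")
        for pop in pop_list:
            if pop == reference:
                continue
            results = fst.wc_theta(g, pops, (reference, pop))
            fst_frames.append(fst.results_to_frame(results))
            for res in results:
                if res.variant_id == tag:
                    theta_vs_ref[pop] = res.theta
            if pop == cfg.get("outlier_population", pop_list[-1]):
                defined = [r for r in results if r.defined]
                if any(r.variant_id == tag for r in defined):
                    rank = fst.empirical_percentile(results, tag)
                    percentile = rank
        fst_all = pd.concat(fst_frames, ignore_index=True)
        emit("fst.tsv", fst_all)
        if percentile is not None:
            emit(
                "fst_outlier.tsv",
                pd.DataFrame(
                    [dict(variant_id=tag, percentile=percentile.percentile,
                          set_size=percentile.set_size)]
                ),
            )
        logger.info("stage=fst reference=%s n_pairs=%d n_rows=%d",
                    reference, len(fst_frames), len(fst_all))
    else:
        logger.info("stage=fst skipped reason=single-population")

    # --- per-population LD ----------------------------------------------------
    ld_results = ld.tag_portability(
        g, pops, tag, functional, populations=pop_list, threshold=threshold
    )
    ld_frame = ld.results_to_frame(ld_results)
    emit("ld.tsv", ld_frame)
    logger.info(
        "stage=ld tag=%s functional=%s method=%s threshold=%g n_pops=%d n_flagged=%d",
        tag, functional, "phased_count" if g.fully_phased() else "em",
        threshold, len(ld_results), sum(r.error is not None for r in ld_results),
    )

    # --- ancestry regression --------------------------------------------------
    regression = None
    component = cfg.get("ancestry_component", "NAT" if pops.ancestry else None)
    if component is not None and pops.ancestry:
        try:
            regression = ancestry_regression.freq_ancestry_regression(
                freq_table, pops, tag, component
            )
            emit(
                "ancestry_regression.tsv",
                pd.DataFrame(
                    [dict(variant_id=tag, ancestry=component,
                          slope=regression.slope, intercept=regression.intercept,
                          pearson_r=regression.pearson_r,
                          n_populations=regression.n_populations)]
                ),
            )
            logger.info("stage=regression component=%s slope=%.4f r=%.4f",
                        component, regression.slope, regression.pearson_r)
        except ValueError as exc:
            logger.info("stage=regression skipped reason=%s", exc)
    else:
        logger.info("stage=regression skipped reason=no-ancestry-proportions")

    # --- assemble the report --------------------------------------------------
    tag_freqs = {
        r["population"]: r["freq"]
        for _, r in freq_table[freq_table["variant_id"] == tag].iterrows()
    }
    rows = []
    failing, untestable = [], []
    for res in ld_results:
        pop = res.population
        if res.error is not None:
            status = "untestable"
            untestable.append(pop)
        elif res.is_tag:
            status = "portable"
        else:
            status = "not portable"
            failing.append(pop)
        rows.append(
            dict(
                population=pop,
                tag_freq=tag_freqs.get(pop, float("nan")),
                theta_vs_ref=theta_vs_ref.get(pop, float("nan")),
                r2=res.r2,
                Dprime=res.Dprime,
                is_tag=res.is_tag,
                status=status,
            )
        )
    rows_frame = pd.DataFrame(rows)
    if failing:
        verdict = "not portable to: " + ", ".join(failing)
    elif not rows_frame.empty and (rows_frame["status"] == "portable").any():
        verdict = "portable to all tested populations"
    else:
        verdict = "no testable populations"
    report = PortabilityReport(
        tag=tag,
        functional=functional,
        threshold=threshold,
        rows=rows_frame,
        verdict=verdict,
        failing_populations=failing,
        untestable_populations=untestable,
    )
    emit("report.tsv", rows_frame)
    if outdir is not None:
        with open(os.path.join(outdir, "report.md"), "w") as fh:
            fh.write(report.to_markdown())
    logger.info("stage=report verdict=%r failing=%d untestable=%d",
                verdict, len(failing), len(untestable))
    return report
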