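"""One-command orchestration: inputs in, filtered/segregating/enriched
outputs and a human-readable report out.

Stage order: io -> filter cascade -> segregation (both groups, both models)
-> group summaries -> over-representation per group -> enrichment map ->
report. Every number in the rendered report is recomputable from the emitted
TSVs.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__, enrichment, io_formats, qc_filtering, segregation
from .types import GenotypeState, Model, Phenotype

logger = logging.getLogger("sibseg")


@dataclass
class RunConfig:
    vcf: str
    ped: str
    annotations: str
    gmt: Optional[str] = None
    curated: Optional[str] = None
    outdir: str = "sibseg_run"
    gq_floor: float = 20.0
    alt_cov: int = 30
    gmaf_rare: float = 0.01
    min_families: int = 3
    exclusivity_mode: str = "same_model"
    member_rule: str = "all"
    q_cutoff: float = 0.05
    similarity_cutoff: float = 0.375
    similarity_metric: str = "overlap"
    min_set_size: int = 3
    max_set_size: int = 500
    strict_pedigree: bool = True
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class RunReport:
    config: dict
    version: str
    qc: dict
    trace_rows: list
    summaries: list            # group summary dict rows
    n_calls: int
    enrichment_top: dict       # group -> list of top result dicts
    network_summary: dict      # group -> {nodes, edges}
    incomplete: bool = False


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _pct(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage with round-half-up at the given number of decimals."""
    if denominator == 0:
        return 0.0
    scale = 10 ** decimals
    return int(100.0 * numerator / denominator * scale + 0.5) / scale


def run_pipeline(config: RunConfig) -> RunReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    def stage(name, fn):
        logger.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - abort with the stage name
            (outdir / "INCOMPLETE").write_text(f"failed at stage {name}: {exc}\n")
            raise StageError(name, exc) from exc

    variants, genotypes = stage("read_vcf", lambda: io_formats.read_vcf(config.vcf))
    pedigree = stage("read_pedigree",
                     lambda: io_formats.read_pedigree(config.ped, strict=config.strict_pedigree))
    annotations = stage("read_annotations", lambda: io_formats.read_annotations(config.annotations))
    genesets = stage("read_genesets",
                     lambda: io_formats.read_genesets(config.gmt)) if config.gmt else None
    curated = stage("read_curated",
                    lambda: io_formats.read_gene_list(config.curated)) if config.curated else set()

    qc = stage("qc_report", lambda: qc_filtering.qc_report(genotypes, variants))

    cascade_config = qc_filtering.CascadeConfig(
        gq_floor=config.gq_floor, alt_cov_threshold=config.alt_cov)
    result = stage("filter_cascade", lambda: qc_filtering.run_filter_cascade(
        variants, genotypes, annotations, cascade_config))
    pd.DataFrame(result.trace.to_rows()).to_csv(outdir / "filter_trace.tsv",
                                                sep="\t", index=False)

    seg_config = segregation.SegregationConfig(
        min_families=config.min_families,
        exclusivity_mode=config.exclusivity_mode,
        member_rule=config.member_rule,
    )
    states = {
        k: {c.sample_id: c.state for c in result.masked_genotypes[k]}
        for k in result.surviving
    }
    genes = {k: annotations[k].gene for k in result.surviving}
    calls = stage("segregation", lambda: segregation.call_variants(
        result.surviving, states, genes, pedigree, seg_config))
    call_records = segregation.calls_to_records(calls)
    pd.DataFrame(call_records, columns=[
        "gene", "chrom", "pos", "ref", "alt", "model", "group",
        "confirming_families", "n_confirming", "exclusive", "subthreshold",
    ]).to_csv(outdir / "segregation_calls.tsv", sep="\t", index=False)

    summaries = stage("summarize", lambda: segregation.summarize(calls, curated))
    summary_rows = [
        {"group": s.group.value, "model": s.model.value, "n_genes": s.n_genes,
         "n_variants": s.n_variants, "n_immune_genes": s.n_immune_genes,
         "immune_pct": s.immune_pct}
        for s in summaries
    ]
    pd.DataFrame(summary_rows, columns=[
        "group", "model", "n_genes", "n_variants", "n_immune_genes", "immune_pct",
    ]).to_csv(outdir / "group_summary.tsv", sep="\t", index=False)

    # universe = genes with >=1 post-cascade variant (declared default)
    universe = set(genes.values())
    enrichment_top: dict = {}
    network_summary: dict = {}
    if genesets is not None:
        for group in (Phenotype.AFFECTED, Phenotype.NON_AFFECTED):
            # the discordant design asks which pathways the group-exclusive
            # genes hit, so non-exclusive calls are left out of the query
            query = {c.gene for c in calls
                     if c.group == group and c.exclusive is not False}
            if not query:
                enrichment_top[group.value] = []
                network_summary[group.value] = {"nodes": 0, "edges": 0}
                continue
            results = stage(f"enrichment_{group.value}", lambda q=query: enrichment.run_ora(
                q, genesets, universe,
                min_size=config.min_set_size, max_size=config.max_set_size))
            enrichment.write_results_tsv(
                str(outdir / f"enrichment_{group.value}.tsv"), results)
            graph = enrichment.build_enrichment_map(
                results, genesets, q_cutoff=config.q_cutoff,
                similarity_cutoff=config.similarity_cutoff,
                metric=config.similarity_metric, universe=universe)
            enrichment.write_sif(str(outdir / f"network_{group.value}.sif"), graph,
                                 str(outdir / f"network_{group.value}_edges.tsv"))
            enrichment_top[group.value] = [
                {"set_id": r.set_id, "k": r.k, "K": r.K, "p_value": r.p_value,
                 "q_value": r.q_value}
                for r in results[:5]
            ]
            network_summary[group.value] = {
                "nodes": graph.number_of_nodes(), "edges": graph.number_of_edges(),
            }

    qc_dict = {
        "mean_depth": qc.mean_depth,
        "frac_ge_20x": qc.frac_ge_20x,
        "uniformity": qc.uniformity,
        "uniformity_definition": qc.UNIFORMITY_DEFINITION,
        "titv": qc.titv,
    }
    report = RunReport(
        config=asdict(config), version=__version__, qc=qc_dict,
        trace_rows=result.trace.to_rows(), summaries=summary_rows,
        n_calls=len(calls), enrichment_top=enrichment_top,
        network_summary=network_summary,
    )
    with open(outdir / "report.json", "w") as fh:
        json.dump(asdict(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    (outdir / "report.txt").write_text(report_render(report))
    return report


def report_render(report: RunReport) -> str:
    """Deterministic plain-text rendering: same report -> identical bytes.

    Summary percentages are integers; fraction breakdowns use one decimal.
    """
    lines = [
        f"sibseg v{report.version} run report",
        "=" * 34,
        "",
        "QC",
        "--",
    ]
    if report.qc.get("mean_depth"):
        for sample in sorted(report.qc["mean_depth"]):
            lines.append(
                f"  {sample}: mean depth {report.qc['mean_depth'][sample]:.1f}, "
                f">=20X {_pct(report.qc['frac_ge_20x'][sample], 1.0):.1f}%, "
                f"uniformity {_pct(report.qc['uniformity'][sample], 1.0):.1f}%"
            )
        lines.append(f"  uniformity = {report.qc['uniformity_definition']}")
    else:
        lines.append("  no depth data")
    titv = report.qc.get("titv")
    lines.append(f"  Ti/Tv: {'undefined' if titv is None else f'{titv:.2f}'}")
    lines += ["", "Filter cascade", "--------------"]
    for row in report.trace_rows:
        lines.append(f"  {row['stage']} [{row['remaining']}] (-{row['removed']})")
    total = report.trace_rows[0]["remaining"] if report.trace_rows else 0
    final = report.trace_rows[-1]["remaining"] if report.trace_rows else 0
    lines.append(f"  surviving: {final} of {total}"
                 + (f" ({_pct(final, total):.1f}%)" if total else ""))
    lines += ["", "Segregation", "-----------", f"  calls: {report.n_calls}"]
    for s in report.summaries:
        lines.append(
            f"  {s['group']}/{s['model']}: {s['n_genes']} genes, "
            f"{s['n_variants']} variants, immune {s['immune_pct']}%"
        )
    if report.enrichment_top:
        lines += ["", "Enrichment", "----------"]
        for group in sorted(report.enrichment_top):
            lines.append(f"  {group}:")
            for r in report.enrichment_top[group]:
                lines.append(
                    f"    {r['set_id']} k={r['k']}/{r['K']} "
                    f"p={r['p_value']:.3g} q={r['q_value']:.3g}"
                )
            ns = report.network_summary.get(group, {})
            lines.append(
                f"    network: {ns.get('nodes', 0)} nodes, {ns.get('edges', 0)} edges"
            )
    lines += ["", "Config echo", "-----------"]
    for key in sorted(report.config):
        lines.append(f"  {key}: {report.config[key]}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Worked-example (genotype-table) mode: the cascade is upstream of the
# printed tables, so only segregation and summaries run.
# ---------------------------------------------------------------------------

def run_genotype_tables(affected_rows, non_affected_rows, subjects, curated_genes,
                        k: int = 3, rescue_subthreshold: bool = True):
    """Classify published-style genotype tables and summarize per block.

    Returns (calls, summaries). Exclusivity is not evaluable in this mode
    (tables carry only the listed group's genotypes).
    """
    calls = []
    if affected_rows:
        calls += segregation.classify_genotype_table(
            affected_rows, subjects, Phenotype.AFFECTED, k=k,
            rescue_subthreshold=rescue_subthreshold)
    if non_affected_rows:
        calls += segregation.classify_genotype_table(
            non_affected_rows, subjects, Phenotype.NON_AFFECTED, k=k,
            rescue_subthreshold=rescue_subthreshold)
    return calls, segregation.summarize(calls, curated_genes)


def verify_report_consistency(outdir) -> list:
    """Cross-check report.json numbers against the emitted TSVs.

    Returns a list of mismatch descriptions (empty = consistent).
    """
    outdir = Path(outdir)
    with open(outdir / "report.json") as fh:
        report = json.load(fh)
    problems = []
    trace = pd.read_csv(outdir / "filter_trace.tsv", sep="\t")
    for row, expected in zip(report["trace_rows"], trace.to_dict("records")):
        if row["stage"] != expected["stage"] or row["remaining"] != expected["remaining"]:
            problems.append(f"trace mismatch at {row['stage']}")
    calls = pd.read_csv(outdir / "segregation_calls.tsv", sep="\t")
    if len(calls) != report["n_calls"]:
        problems.append(f"n_calls {report['n_calls']} != {len(calls)} rows")
    summary = pd.read_csv(outdir / "group_summary.tsv", sep="\t")
    for s in report["summaries"]:
        match = summary[(summary.group == s["group"]) & (summary.model == s["model"])]
        if len(match) != 1 or int(match.n_variants.iloc[0]) != s["n_variants"]:
            problems.append(f"summary mismatch for {s['group']}/{s['model']}")
        block = calls[(calls.group == s["group"]) & (calls.model == s["model"])]
        if len(block) != s["n_variants"] or block.gene.nunique() != s["n_genes"]:
            problems.append(f"calls/summary mismatch for {s['group']}/{s['model']}")
    return problems
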