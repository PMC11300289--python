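"""End-to-end pipeline orchestration: simulate -> filter -> burden ->
pathway -> cnv -> report, with a single config, stage-level logging and a
run manifest recording every filter's input/output counts.

All randomness flows from one seed; identical config + seed produces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .burden import GeneAssociationResult, compute_burden_matrix, qq_points, run_gene_scan
from .cnv import run_cnv_scan
from .io_formats import (
    SampleTable,
    format_mask_tally,
    read_annotation_table,
    read_bed_genes,
    read_cnv_table,
    read_gmt,
    read_phenotypes,
    read_vcf,
    write_results,
)
from .masks import default_scheme, prioritize, read_mask_scheme
from .pathways import run_pathway_scan
from .simulate import SimulationConfig, simulate_all

logger = logging.getLogger("cscakut")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "results"
    seed: int = 0
    # stage toggles
    run_simulate: bool = True
    run_filter: bool = True
    run_burden: bool = True
    run_pathway: bool = True
    run_cnv: bool = True
    run_report: bool = True
    # inputs (ignored for stages fed by the simulate stage)
    vcf: str | None = None
    annotations: str | None = None
    phenotypes: str | None = None
    gmt: str | None = None
    bed: str | None = None
    cnvs: str | None = None
    mask_scheme: str | None = None
    # thresholds
    af_popmax_max: float = 0.001
    af_cohort_max: float = 0.001
    mac_max: int = 5
    alpha: float = 0.05
    top_k: int = 15
    top_genes: int = 10
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest.

    A stage failure aborts the run with the failing stage named; outputs
    written before the failure are renamed with a ``.partial`` suffix.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "af_popmax_max": config.af_popmax_max,
            "af_cohort_max": config.af_cohort_max,
            "mac_max": config.mac_max,
            "alpha": config.alpha,
            "top_k": config.top_k,
        },
        "stages": {},
        "outputs": {},
    }
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        manifest["outputs"][name] = _file_hash(path)
        return path

    stage = "simulate"
    try:
        if config.run_simulate:
            sim_conf = SimulationConfig.from_dict({"seed": config.seed, **config.simulation})
            cohort = simulate_all(sim_conf, out_dir=out / "inputs")
            for f in sorted((out / "inputs").iterdir()):
                written.append(f)
                manifest["outputs"][f"inputs/{f.name}"] = _file_hash(f)
            samples = cohort.samples
            variants, annotations = cohort.variants, cohort.annotations
            gene_models, gene_sets, cnvs = cohort.gene_models, cohort.gene_sets, cohort.cnvs
            manifest["stages"]["simulate"] = {
                "status": "complete",
                "n_variants": len(variants),
                "n_samples": len(samples),
                "n_gene_sets": len(gene_sets),
                "n_cnvs": len(cnvs),
            }
        else:
            for key in ("vcf", "annotations", "phenotypes"):
                if getattr(config, key) is None:
                    raise StageError("load", f"missing input path '{key}'")
            samples = read_phenotypes(config.phenotypes)
            variants = read_vcf(config.vcf, samples)
            annotations = read_annotation_table(config.annotations)
            gene_sets = read_gmt(config.gmt) if config.gmt else None
            gene_models = read_bed_genes(config.bed) if config.bed else None
            cnvs = read_cnv_table(config.cnvs, samples) if config.cnvs else None
            manifest["stages"]["load"] = {
                "status": "complete",
                "n_variants": len(variants),
                "n_samples": len(samples),
            }
        logger.info("inputs ready: %d variants, %d samples", len(variants), len(samples))

        scheme = (
            read_mask_scheme(
                config.mask_scheme,
                af_popmax_max=config.af_popmax_max,
                af_cohort_max=config.af_cohort_max,
                mac_max=config.mac_max,
            )
            if config.mask_scheme
            else default_scheme(
                af_popmax_max=config.af_popmax_max,
                af_cohort_max=config.af_cohort_max,
                mac_max=config.mac_max,
            )
        )

        stage = "filter"
        eligible = None
        if config.run_filter:
            eligible, excluded = prioritize(variants, annotations, scheme)
            emit("eligible.tsv", lambda p: _write_masked(eligible, samples, p))
            emit("excluded.tsv", lambda p: _write_excluded(excluded, p))
            manifest["stages"]["filter"] = {
                "status": "complete",
                "n_in": len(variants),
                "n_eligible": len(eligible),
                "n_excluded": len(excluded),
                "n_dropped_af": len(variants) - len(eligible) - len(excluded),
            }
            logger.info("filter: %d -> %d eligible", len(variants), len(eligible))

        stage = "burden"
        gene_results: list[GeneAssociationResult] = []
        burden_matrix = None
        if config.run_burden:
            if eligible is None:
                raise StageError(stage, "burden requires the filter stage")
            burden_matrix = compute_burden_matrix(eligible, samples)
            gene_results = run_gene_scan(eligible, samples, seed=config.seed)
            if gene_results:
                emit("genes.tsv", lambda p: write_results(gene_results, p))
            ps = [r.p_burden for r in gene_results if r.p_burden is not None]
            if ps:
                expected, observed, lam = qq_points(ps)
                emit(
                    "qq.tsv",
                    lambda p: pd.DataFrame(
                        {"expected_neglog10": expected, "observed_neglog10": observed}
                    ).to_csv(p, sep="\t", index=False, float_format="%.12g"),
                )
            else:
                lam = None
            manifest["stages"]["burden"] = {
                "status": "complete",
                "n_in": len(eligible),
                "n_genes_tested": len(ps),
                "qq_lambda": lam,
            }
            logger.info("burden: %d genes tested, lambda=%s", len(ps), lam)

        stage = "pathway"
        if config.run_pathway:
            if burden_matrix is None or gene_sets is None:
                raise StageError(stage, "pathway requires burden results and gene sets")
            pathway_results, forest = run_pathway_scan(
                burden_matrix, gene_sets, samples, top_k=config.top_k
            )
            if pathway_results:
                emit("pathways.tsv", lambda p: write_results(pathway_results, p))
            if forest:
                emit("forest.tsv", lambda p: write_results(forest, p))
            manifest["stages"]["pathway"] = {
                "status": "complete",
                "n_in": len(gene_sets),
                "n_testable": sum(1 for r in pathway_results if not r.untestable),
            }
        else:
            pathway_results, forest = [], []

        stage = "cnv"
        cnv_results, cnv_summary = [], {}
        if config.run_cnv:
            if cnvs is None or gene_models is None:
                raise StageError(stage, "cnv requires CNV calls and gene models")
            cnv_results, cnv_summary = run_cnv_scan(cnvs, gene_models, samples)
            emit("cnv_genes.tsv", lambda p: _write_cnv_results(cnv_results, p))
            manifest["stages"]["cnv"] = {
                "status": "complete",
                "n_in": len(cnvs),
                "n_gene_class_pairs": len(cnv_results),
                "classification": cnv_summary,
            }

        stage = "report"
        if config.run_report:
            report = render_report(
                manifest,
                gene_results=gene_results,
                pathway_forest=forest,
                cnv_results=cnv_results,
                top_genes=config.top_genes,
            )
            emit("report.md", lambda p: Path(p).write_text(report))
            manifest["stages"]["report"] = {"status": "complete"}
    except StageError:
        _mark_partial(written)
        raise
    except Exception as exc:
        _mark_partial(written)
        raise StageError(stage, str(exc)) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _mark_partial(written: list[Path]) -> None:
    for path in written:
        if path.exists():
            path.rename(path.with_suffix(path.suffix + ".partial"))


def _write_masked(eligible, samples: SampleTable, path: Path) -> None:
    rows = []
    for mv in eligible:
        carriers = ";".join(samples.sample_ids[i] for i in mv.carriers())
        rows.append(
            {
                "variant_id": mv.variant.variant_id,
                "gene_symbol": mv.gene_symbol,
                "mask_level": mv.mask_level,
                "missense_flag": int(mv.missense_flag),
                "weight": mv.weight,
                "mac": mv.mac,
                "cohort_af": f"{mv.cohort_af:.12g}",
                "carrier_samples": carriers,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_excluded(excluded, path: Path) -> None:
    rows = [
        {"variant_id": mv.variant.variant_id, "gene_symbol": mv.gene_symbol, "reason": reason}
        for mv, reason in excluded
    ]
    pd.DataFrame(rows, columns=["variant_id", "gene_symbol", "reason"]).to_csv(
        path, sep="\t", index=False
    )


def _write_cnv_results(results, path: Path) -> None:
    rows = []
    for r in results:
        rows.append(
            {
                "gene": r.gene_symbol,
                "dosage_class": r.dosage_class,
                "case_carriers": r.case_carriers,
                "control_carriers": r.control_carriers,
                "chi2": "NA" if r.chi2_stat is None else f"{r.chi2_stat:.12g}",
                "p_asymptotic": "NA" if r.p_asymptotic is None else f"{r.p_asymptotic:.12E}",
                "permutation_p": "NA" if r.permutation_p is None else f"{r.permutation_p:.12E}",
                "p_value": "NA" if r.p_value is None else f"{r.p_value:.12E}",
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "gene", "dosage_class", "case_carriers", "control_carriers",
            "chi2", "p_asymptotic", "permutation_p", "p_value",
        ],
    ).to_csv(path, sep="\t", index=False)


def render_report(
    manifest: dict,
    gene_results=(),
    pathway_forest=(),
    cnv_results=(),
    top_genes: int = 10,
) -> str:
    """Deterministic markdown run report: top-gene table, pathway forest
    table, CNV hits and stage bookkeeping."""
    lines = ["# Rare-variant association run report", ""]
    lines.append(f"Seed: {manifest.get('seed')}  ")
    lines.append("")

    lines.append("## Stage summary")
    lines.append("")
    for name, info in manifest.get("stages", {}).items():
        counts = ", ".join(f"{k}={v}" for k, v in info.items() if k != "status")
        lines.append(f"- **{name}**: {info.get('status')} ({counts})")
    lines.append("")

    lines.append(f"## Top genes (gene-based weighted burden, top {top_genes})")
    lines.append("")
    if gene_results:
        lines.append("| Rank | Gene | Case masks | Control masks | Burden p | Nominal p | OR (95% CI) |")
        lines.append("|---|---|---|---|---|---|---|")
        for rank, r in enumerate(list(gene_results)[:top_genes], start=1):
            or_str = (
                f"{r.odds_ratio:.3g} ({r.ci95_low:.3g}-{r.ci95_high:.3g})"
                if r.odds_ratio is not None
                else "NA"
            )
            pb = f"{r.p_burden:.2E}" if r.p_burden is not None else "NA"
            pn = f"{r.p_nominal:.2E}" if r.p_nominal is not None else "NA"
            lines.append(
                f"| {rank} | {r.gene_symbol} | {format_mask_tally(*r.case_tally)} | "
                f"{format_mask_tally(*r.control_tally)} | {pb} | {pn} | {or_str} |"
            )
    else:
        lines.append("no testable genes")
    lines.append("")

    lines.append("## Top pathways (logistic enrichment forest)")
    lines.append("")
    if pathway_forest:
        lines.append("| Set | Source | OR | 95% CI | p |")
        lines.append("|---|---|---|---|---|")
        for r in pathway_forest:
            lines.append(
                f"| {r.set_name} | {r.source} | {r.odds_ratio:.3g} | "
                f"{r.ci95_low:.3g}-{r.ci95_high:.3g} | {r.p_value:.2E} |"
            )
    else:
        lines.append("no testable sets")
    lines.append("")

    lines.append("## CNV gene-level hits")
    lines.append("")
    testable_cnv = [r for r in cnv_results if r.p_value is not None]
    if testable_cnv:
        lines.append("| Gene | Class | Case carriers | Control carriers | chi2 | p |")
        lines.append("|---|---|---|---|---|---|")
        for r in testable_cnv[:top_genes]:
            lines.append(
                f"| {r.gene_symbol} | {r.dosage_class} | {r.case_carriers} | "
                f"{r.control_carriers} | {r.chi2_stat:.3g} | {r.p_value:.2E} |"
            )
    else:
        lines.append("no testable CNV gene scores")
    lines.append("")
    return "\n".join(lines)
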