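"""Synthetic case/control cohort generator.

Produces every input the pipeline consumes — genotypes (VCF), a variant
annotation table, phenotypes, gene sets (GMT), gene models (BED) and CNV
calls — with the statistical structure the downstream analysis assumes:

* a toy genome of ``n_genes`` genes tiled along two contigs;
* carrier-level simulation: per gene a control carrier rate ``q`` (drawn
  per gene from ``baseline_carrier_rate`` when a range is given), cases
  carry with probability ``OR*q / (1 - q + OR*q)`` where ``OR`` is the
  gene's configured carrier odds ratio (1 for non-risk genes);
* each carrier receives 1-2 private heterozygous ultra-rare variants whose
  mask level is drawn from ``mask_distribution`` and whose annotation
  fields deterministically reproduce that mask under the default scheme;
* gene sets drawn uniformly, one designated set containing all risk genes;
* sparse per-sample CNV calls (Poisson per sample, intragenic/multigenic/
  intergenic placements) with configurable excess case losses over a few
  recurrently deleted genes.

The full output is a pure function of (config, seed): identical
configuration and seed give byte-identical files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    AnnotationRecord,
    CNVRecord,
    GeneModel,
    GeneSetCollection,
    SampleTable,
    VariantRecord,
    write_annotation_table,
    write_bed_genes,
    write_cnv_table,
    write_gmt,
    write_phenotypes,
    write_vcf,
)

_SOURCES = ("BioCarta", "GOBP", "HPO", "KEGG", "MPO", "PID", "Reactome", "WP")

# inverse mapping from a mask level to annotation fields that land there
# under the default scheme (n_damaging drawn for missense masks)
_MASK_TO_ANNOTATION = {
    1: dict(consequence_class="lof", lof_confidence="high"),
    2: dict(consequence_class="lof", lof_confidence="low"),
    3: dict(consequence_class="inframe_indel"),
    4: dict(consequence_class="missense"),  # n_damaging >= 3
    5: dict(consequence_class="missense"),  # n_damaging < 3
    6: dict(consequence_class="synonymous"),
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; defaults emulate the study design
    (tens of cases against ~2,800 controls, ultra-rare carriers, a handful
    of strong-effect risk genes, one enriched gene set, sparse CNVs)."""

    n_cases: int = 40
    n_controls: int = 2764
    n_genes: int = 2000
    genes_per_set: int = 50
    n_sets: int = 10
    # scalar rate, or (low, high) for a per-gene uniform draw
    baseline_carrier_rate: float | tuple[float, float] = (5e-4, 2e-3)
    risk_genes: dict[str, float] = field(
        default_factory=lambda: {
            "GENE0042": 20.0,
            "GENE0137": 35.0,
            "GENE0501": 50.0,
            "GENE1203": 80.0,
        }
    )
    mask_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.05, 2: 0.10, 3: 0.05, 4: 0.25, 5: 0.35, 6: 0.20}
    )
    p_second_variant: float = 0.2
    popmax_missing_rate: float = 0.2
    n_decoy_common: int = 0
    cnv_rate: float = 2.0
    cnv_baseline_loss_rate: float = 0.004
    cnv_risk_genes: dict[str, float] = field(default_factory=lambda: {"GENE0777": 30.0})
    enriched_set: str = "ENRICHED"
    seed: int = 0
    # toy genome geometry
    n_chromosomes: int = 2
    gene_length: int = 5000
    gene_spacing: int = 10000

    def validate(self) -> None:
        rates = {
            "p_second_variant": self.p_second_variant,
            "popmax_missing_rate": self.popmax_missing_rate,
            "cnv_baseline_loss_rate": self.cnv_baseline_loss_rate,
        }
        lo, hi = self.rate_bounds()
        rates["baseline_carrier_rate"] = hi
        for name, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} = {r} outside [0, 1]")
        if lo > hi:
            raise ValueError("baseline_carrier_rate range inverted")
        total = sum(self.mask_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mask_distribution sums to {total}, not 1")
        names = set(self.gene_names())
        for gene, odds in {**self.risk_genes}.items():
            if odds <= 0:
                raise ValueError(f"carrier odds ratio for {gene} must be > 0")
            if gene not in names:
                raise ValueError(f"risk gene {gene} not in simulated genome")
            if _case_rate(hi, odds) > 1:
                raise ValueError(f"case carrier probability > 1 for {gene}")
        for gene, mult in self.cnv_risk_genes.items():
            if mult <= 0:
                raise ValueError(f"CNV multiplier for {gene} must be > 0")
            if gene not in names:
                raise ValueError(f"CNV risk gene {gene} not in simulated genome")
            if self.cnv_baseline_loss_rate * mult > 1:
                raise ValueError(f"CNV loss rate > 1 for {gene}")
        if self.genes_per_set < len(self.risk_genes):
            raise ValueError("enriched set smaller than the risk gene count")
        if self.cnv_rate < 0:
            raise ValueError("cnv_rate must be >= 0")

    def rate_bounds(self) -> tuple[float, float]:
        if isinstance(self.baseline_carrier_rate, (tuple, list)):
            lo, hi = self.baseline_carrier_rate
            return float(lo), float(hi)
        r = float(self.baseline_carrier_rate)
        return r, r

    def gene_names(self) -> list[str]:
        return [f"GENE{i:04d}" for i in range(self.n_genes)]

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load from a flat TOML key-value file (dotted keys for the maps)."""
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        kwargs = dict(raw)
        if "baseline_carrier_rate" in kwargs and isinstance(kwargs["baseline_carrier_rate"], list):
            kwargs["baseline_carrier_rate"] = tuple(kwargs["baseline_carrier_rate"])
        if "mask_distribution" in kwargs:
            kwargs["mask_distribution"] = {
                int(k): float(v) for k, v in kwargs["mask_distribution"].items()
            }
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


def _case_rate(q: float, odds_ratio: float) -> float:
    """Case carrier probability with the given carrier odds ratio over rate q."""
    return odds_ratio * q / (1 - q + odds_ratio * q)


def simulate_gene_models(config: SimulationConfig) -> list[GeneModel]:
    """Genes tiled every ``gene_spacing`` bp across the toy contigs."""
    names = config.gene_names()
    per_chrom = -(-config.n_genes // config.n_chromosomes)
    models = []
    for i, name in enumerate(names):
        chrom = f"chr{i // per_chrom + 1}"
        start = (i % per_chrom) * config.gene_spacing + 1000
        models.append(GeneModel(name, chrom, start, start + config.gene_length))
    return models


def simulate_sample_table(config: SimulationConfig) -> SampleTable:
    ids = [f"CASE{i:04d}" for i in range(config.n_cases)] + [
        f"CTRL{i:04d}" for i in range(config.n_controls)
    ]
    phen = ["case"] * config.n_cases + ["control"] * config.n_controls
    return SampleTable(ids, phen)


def simulate_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[VariantRecord], list[AnnotationRecord], SampleTable]:
    """Carrier-level genotype and annotation simulation.

    Every emitted variant is a private heterozygote (cohort AF 1/(2N)) with
    popmax AF <= 0.1%, unless ``n_decoy_common`` > 0 injects common decoys
    (popmax AF 5%) that the rare-variant filter must remove.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    samples = simulate_sample_table(config)
    n = len(samples)
    n_cases = config.n_cases
    lo, hi = config.rate_bounds()
    models = simulate_gene_models(config)
    model_by_name = {m.gene_symbol: m for m in models}

    levels = sorted(config.mask_distribution)
    level_p = np.array([config.mask_distribution[k] for k in levels])
    # baseline_carrier_rate is the probability of carrying >= 1 *qualifying*
    # variant, so every carrier's first variant draws from the weight-bearing
    # mask levels (level 6 carries weight 0 under the default scheme); the
    # level-6 mass is exercised by carriers' additional variants.
    q_levels = [lv for lv in levels if lv != 6]
    if not q_levels:
        raise ValueError("mask_distribution has no weight-bearing levels")
    q_p = np.array([config.mask_distribution[k] for k in q_levels])
    q_p = q_p / q_p.sum()

    variants: list[VariantRecord] = []
    annotations: list[AnnotationRecord] = []
    for gene in config.gene_names():
        q = float(rng.uniform(lo, hi)) if lo < hi else lo
        p_case = _case_rate(q, config.risk_genes.get(gene, 1.0))
        draws = rng.random(n)
        carrier_idx = np.flatnonzero(
            np.where(np.arange(n) < n_cases, draws < p_case, draws < q)
        )
        if carrier_idx.size == 0:
            continue
        n_vars = 1 + (rng.random(carrier_idx.size) < config.p_second_variant).astype(int)
        total = int(n_vars.sum())
        gm = model_by_name[gene]
        offsets = rng.choice(config.gene_length, size=total, replace=False)
        pos_iter = iter(sorted(int(o) for o in offsets))
        for sample_i, k in zip(carrier_idx, n_vars):
            for j in range(k):
                pos = gm.start + next(pos_iter) + 1  # 1-based VCF position
                if j == 0:
                    level = int(rng.choice(q_levels, p=q_p))
                else:
                    level = int(rng.choice(levels, p=level_p))
                geno = np.zeros(n, dtype=np.int8)
                geno[sample_i] = 1
                ref, alt = "A", "T"
                v = VariantRecord(chrom=gm.chrom, pos=pos, ref=ref, alt=alt, genotypes=geno)
                ann_fields = dict(_MASK_TO_ANNOTATION[level])
                if level == 4:
                    ann_fields["n_damaging_predictors"] = int(rng.integers(3, 6))
                elif level == 5:
                    ann_fields["n_damaging_predictors"] = int(rng.integers(0, 3))
                popmax = 0.0 if rng.random() < config.popmax_missing_rate else float(
                    rng.uniform(1e-6, 1e-3)
                )
                annotations.append(
                    AnnotationRecord(
                        variant_id=v.variant_id,
                        gene_symbol=gene,
                        consequence_class=ann_fields["consequence_class"],
                        lof_confidence=ann_fields.get("lof_confidence", "not_applicable"),
                        n_damaging_predictors=ann_fields.get("n_damaging_predictors", 0),
                        popmax_af=popmax,
                        canonical_transcript=f"NM_{gene[4:]}.1",
                    )
                )
                variants.append(v)

    # common decoy variants that must be removed by the AF filter
    for d in range(config.n_decoy_common):
        gene = config.gene_names()[int(rng.integers(config.n_genes))]
        gm = model_by_name[gene]
        pos = gm.end + 100 + d  # outside the tiled variant positions
        geno = (rng.random(n) < 0.05).astype(np.int8)
        v = VariantRecord(chrom=gm.chrom, pos=pos, ref="G", alt="C", genotypes=geno)
        variants.append(v)
        annotations.append(
            AnnotationRecord(
                variant_id=v.variant_id,
                gene_symbol=gene,
                consequence_class="missense",
                n_damaging_predictors=3,
                popmax_af=0.05,
            )
        )
    return variants, annotations, samples


def simulate_gene_sets(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GeneSetCollection:
    """Uniformly drawn gene sets; ``enriched_set`` contains all risk genes.

    Sets may overlap (membership is drawn independently per set).
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 1)
    names = config.gene_names()
    if config.genes_per_set > config.n_genes:
        raise ValueError("genes_per_set exceeds available genes")
    coll = GeneSetCollection()
    risk = sorted(config.risk_genes)
    fill_pool = [g for g in names if g not in set(risk)]
    fill = rng.choice(len(fill_pool), size=config.genes_per_set - len(risk), replace=False)
    coll.add(
        config.enriched_set,
        risk + [fill_pool[i] for i in sorted(fill)],
        source=_SOURCES[0],
    )
    for s in range(config.n_sets - 1):
        members = rng.choice(config.n_genes, size=config.genes_per_set, replace=False)
        coll.add(
            f"SET_{s:03d}",
            [names[i] for i in sorted(members)],
            source=_SOURCES[(s + 1) % len(_SOURCES)],
        )
    return coll


def simulate_cnvs(
    config: SimulationConfig,
    gene_models: list[GeneModel],
    rng: np.random.Generator | None = None,
) -> list[CNVRecord]:
    """Sparse per-sample CNV calls: Poisson(``cnv_rate``) background events
    mixing intragenic, multigenic and intergenic placements, plus excess
    case losses over ``cnv_risk_genes`` at the configured multiplier."""
    config.validate()
    if not gene_models:
        raise ValueError("empty gene models")
    rng = rng or np.random.default_rng(config.seed + 2)
    samples = simulate_sample_table(config)
    by_chrom: dict[str, list[GeneModel]] = {}
    for gm in gene_models:
        by_chrom.setdefault(gm.chrom, []).append(gm)
    for models in by_chrom.values():
        models.sort(key=lambda m: m.start)
    chroms = sorted(by_chrom)
    model_by_name = {m.gene_symbol: m for m in gene_models}

    records: list[CNVRecord] = []
    for sample_id, phenotype in zip(samples.sample_ids, samples.phenotypes):
        for _ in range(int(rng.poisson(config.cnv_rate))):
            chrom = chroms[int(rng.integers(len(chroms)))]
            models = by_chrom[chrom]
            kind = rng.random()
            dosage = "loss" if rng.random() < 0.6 else "gain"
            if kind < 0.4:  # intragenic
                gm = models[int(rng.integers(len(models)))]
                a = int(rng.integers(gm.start, gm.end - 1))
                b = int(rng.integers(a + 1, gm.end + 1))
                records.append(CNVRecord(sample_id, chrom, a, b, dosage))
            elif kind < 0.6 and len(models) >= 2:  # multigenic
                i = int(rng.integers(len(models) - 1))
                span = min(int(rng.integers(2, 4)), len(models) - i)
                first, last = models[i], models[i + span - 1]
                a = int(rng.integers(first.start, first.end))
                b = int(rng.integers(last.start + 1, last.end + 1))
                if b <= a:
                    a, b = first.start, last.end
                records.append(CNVRecord(sample_id, chrom, a, b, dosage))
            else:  # intergenic, in the gap after a random gene
                i = int(rng.integers(len(models)))
                gm = models[i]
                gap_start = gm.end + 10
                gap_end = gm.end + config.gene_spacing - config.gene_length - 10
                if gap_end <= gap_start + 1:
                    continue
                a = int(rng.integers(gap_start, gap_end - 1))
                b = int(rng.integers(a + 1, gap_end))
                records.append(CNVRecord(sample_id, chrom, a, b, dosage))
        # recurrent risk-gene losses
        for gene in sorted(config.cnv_risk_genes):
            mult = config.cnv_risk_genes[gene] if phenotype == "case" else 1.0
            if rng.random() < config.cnv_baseline_loss_rate * mult:
                gm = model_by_name[gene]
                records.append(CNVRecord(sample_id, gm.chrom, gm.start, gm.end, "loss"))
    return records


@dataclass
class SyntheticCohort:
    variants: list[VariantRecord]
    annotations: list[AnnotationRecord]
    samples: SampleTable
    gene_models: list[GeneModel]
    gene_sets: GeneSetCollection
    cnvs: list[CNVRecord]


def simulate_all(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SyntheticCohort:
    """Generate the complete input bundle; optionally write all files.

    File names under ``out_dir``: cohort.vcf, annotations.tsv,
    phenotypes.tsv, gene_sets.gmt, genes.bed, cnvs.tsv.
    """
    config.validate()
    variants, annotations, samples = simulate_cohort(config)
    gene_models = simulate_gene_models(config)
    gene_sets = simulate_gene_sets(config)
    cnvs = simulate_cnvs(config, gene_models)
    cohort = SyntheticCohort(variants, annotations, samples, gene_models, gene_sets, cnvs)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(variants, samples, out / "cohort.vcf")
        write_annotation_table(annotations, out / "annotations.tsv")
        write_phenotypes(samples, out / "phenotypes.tsv")
        write_gmt(gene_sets, out / "gene_sets.gmt")
        write_bed_genes(gene_models, out / "genes.bed")
        write_cnv_table(cnvs, out / "cnvs.tsv")
    return cohort
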