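"""Domain types and readers/writers for every external format the pipeline touches.

Formats handled: multi-sample VCF 4.x (genotypes), variant annotation TSV,
sample phenotype TSV, GMT gene-set collections (Broad dialect), BED4 gene
models, CNV call TSV, and the result tables the association stages emit.

Coordinate conventions
----------------------
Genomic *intervals* (gene models, CNV calls) are stored 0-based half-open,
i.e. BED-native; VCF variant positions are kept 1-based as in the file.
Variants never enter interval arithmetic, so the two conventions do not mix.

Missing genotypes are encoded as ``MISSING`` (-1) in the per-sample dosage
vector and are excluded from allele-count denominators downstream.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

CONSEQUENCE_CLASSES = frozenset({"lof", "missense", "inframe_indel", "synonymous", "other"})
LOF_CONFIDENCES = frozenset({"high", "low", "not_applicable"})
PHENOTYPES = frozenset({"case", "control"})
DOSAGE_CLASSES = frozenset({"loss", "gain"})
GENE_SET_SOURCES = frozenset(
    {"BioCarta", "GOBP", "HPO", "KEGG", "MPO", "PID", "Reactome", "WP", "custom"}
)


class FormatError(ValueError):
    """Raised when an input file violates its documented contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class VariantRecord:
    """One biallelic small variant with per-sample alt-allele dosages.

    ``pos`` is the 1-based VCF position; ``genotypes`` is an int8 vector of
    alt dosages in {0, 1, 2} with ``MISSING`` (-1) for uncalled genotypes,
    ordered as the cohort's :class:`SampleTable`.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.pos < 1:
            raise FormatError(f"variant position must be >= 1, got {self.pos}")
        if self.alt == self.ref:
            raise FormatError(f"alt equals ref at {self.chrom}:{self.pos}")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}"


@dataclass(frozen=True)
class AnnotationRecord:
    """Distilled functional annotation for one variant (one row per variant).

    ``popmax_af`` is the gnomAD population-max allele frequency; a missing
    value is treated as 0 (never observed in reference populations).
    """

    variant_id: str
    gene_symbol: str
    consequence_class: str
    lof_confidence: str = "not_applicable"
    n_damaging_predictors: int = 0
    popmax_af: float = 0.0
    canonical_transcript: str = ""

    def __post_init__(self) -> None:
        if self.consequence_class not in CONSEQUENCE_CLASSES:
            raise FormatError(f"unknown consequence_class {self.consequence_class!r}")
        if self.lof_confidence not in LOF_CONFIDENCES:
            raise FormatError(f"unknown lof_confidence {self.lof_confidence!r}")
        if self.n_damaging_predictors < 0:
            raise FormatError("n_damaging_predictors must be >= 0")
        if not 0.0 <= self.popmax_af <= 1.0:
            raise FormatError(f"popmax_af {self.popmax_af} outside [0, 1]")


@dataclass
class SampleTable:
    """Cohort samples with case/control phenotype labels."""

    sample_ids: list[str]
    phenotypes: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.phenotypes):
            raise FormatError("sample_ids and phenotypes differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        bad = set(self.phenotypes) - PHENOTYPES
        if bad:
            raise FormatError(f"unknown phenotypes: {sorted(bad)}")
        if self.n_cases == 0 or self.n_controls == 0:
            raise FormatError("need at least one case and one control")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([p == "case" for p in self.phenotypes], dtype=bool)

    @property
    def n_cases(self) -> int:
        return sum(p == "case" for p in self.phenotypes)

    @property
    def n_controls(self) -> int:
        return sum(p == "control" for p in self.phenotypes)

    def index_of(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(sample_id) from None


@dataclass(frozen=True)
class GeneSet:
    source: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.source not in GENE_SET_SOURCES:
            raise FormatError(f"unknown gene-set source {self.source!r}")
        if not self.genes:
            raise FormatError("empty gene set")


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def add(self, name: str, genes: Iterable[str], source: str = "custom") -> None:
        if name in self.sets:
            raise FormatError(f"duplicate gene-set name {name!r}")
        # preserve order, drop duplicates
        uniq = tuple(dict.fromkeys(genes))
        self.sets[name] = GeneSet(source=source, genes=uniq)


@dataclass(frozen=True)
class GeneModel:
    """One gene interval, 0-based half-open."""

    gene_symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise FormatError(
                f"gene {self.gene_symbol}: start {self.start} must be < end {self.end}"
            )


@dataclass(frozen=True)
class CNVRecord:
    """One per-sample CNV call, 0-based half-open interval."""

    sample_id: str
    chrom: str
    start: int
    end: int
    dosage_class: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise FormatError(f"CNV start {self.start} must be < end {self.end}")
        if self.dosage_class not in DOSAGE_CLASSES:
            raise FormatError(f"unknown dosage_class {self.dosage_class!r}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path, sample_table: SampleTable) -> list[VariantRecord]:
    """Read a VCF into per-alt-allele :class:`VariantRecord` objects.

    Multiallelic sites are split into one record per alt allele; genotype
    dosages are reordered to match ``sample_table``; ``./.`` is recorded as
    missing, not 0.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    vcf_samples = list(vcf.samples)
    extra = [s for s in vcf_samples if s not in set(sample_table.sample_ids)]
    if extra:
        raise FormatError(f"VCF samples absent from sample table: {extra}")
    missing_from_vcf = [s for s in sample_table.sample_ids if s not in set(vcf_samples)]
    if missing_from_vcf:
        raise FormatError(f"sample-table samples absent from VCF: {missing_from_vcf}")
    order = np.array([vcf_samples.index(s) for s in sample_table.sample_ids])

    records: list[VariantRecord] = []
    seen: set[str] = set()
    for site in vcf:
        gts = site.genotype.array()  # (n_samples, ploidy+1); last col phasing
        alleles = gts[:, :-1]
        for alt_idx, alt in enumerate(site.ALT, start=1):
            dos = (alleles == alt_idx).sum(axis=1).astype(np.int8)
            dos[(alleles < 0).any(axis=1)] = MISSING
            rec = VariantRecord(
                chrom=site.CHROM,
                pos=site.POS,
                ref=site.REF,
                alt=alt,
                genotypes=dos[order],
            )
            if rec.variant_id in seen:
                raise FormatError(f"duplicate variant id {rec.variant_id}")
            seen.add(rec.variant_id)
            records.append(rec)
    return records


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(
    variants: Sequence[VariantRecord], sample_table: SampleTable, path: str | Path
) -> None:
    """Write biallelic records as a plain-text VCF 4.2 with GT only."""
    contigs = sorted({v.chrom for v in variants})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_table.sample_ids)
    )
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        gts = "\t".join(_GT_STRINGS[int(d)] for d in v.genotypes)
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TSV / GMT / BED readers & writers
# ---------------------------------------------------------------------------


def read_phenotypes(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "phenotype"):
        if col not in df.columns:
            raise FormatError(f"phenotype table missing column {col!r}")
    return SampleTable(list(df["sample_id"]), list(df["phenotype"]))


def write_phenotypes(sample_table: SampleTable, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": sample_table.sample_ids, "phenotype": sample_table.phenotypes}
    ).to_csv(path, sep="\t", index=False)


def read_annotation_table(path: str | Path) -> list[AnnotationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {
        "variant_id",
        "gene_symbol",
        "consequence_class",
        "lof_confidence",
        "n_damaging_predictors",
        "popmax_af",
    }
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"annotation table missing columns: {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        raw_af = row.popmax_af.strip()
        try:
            af = 0.0 if raw_af in ("", "NA", ".") else float(raw_af)
        except ValueError:
            raise FormatError(f"row {i}: unparsable popmax_af {raw_af!r}") from None
        try:
            records.append(
                AnnotationRecord(
                    variant_id=row.variant_id,
                    gene_symbol=row.gene_symbol,
                    consequence_class=row.consequence_class,
                    lof_confidence=row.lof_confidence or "not_applicable",
                    n_damaging_predictors=int(row.n_damaging_predictors),
                    popmax_af=af,
                    canonical_transcript=getattr(row, "canonical_transcript", ""),
                )
            )
        except (FormatError, ValueError) as exc:
            raise FormatError(f"row {i}: {exc}") from None
    return records


def write_annotation_table(records: Sequence[AnnotationRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in records],
            "gene_symbol": [r.gene_symbol for r in records],
            "consequence_class": [r.consequence_class for r in records],
            "lof_confidence": [r.lof_confidence for r in records],
            "n_damaging_predictors": [r.n_damaging_predictors for r in records],
            "popmax_af": [("" if r.popmax_af == 0 else f"{r.popmax_af:.12g}") for r in records],
            "canonical_transcript": [r.canonical_transcript for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path, source_map: Mapping[str, str] | None = None) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name TAB description TAB gene...

    ``source_map`` optionally assigns a source database per set name; the
    description field is also used as a source when it names a known one.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc = fields[0], fields[1]
            source = "custom"
            if source_map and name in source_map:
                source = source_map[name]
            elif desc in GENE_SET_SOURCES:
                source = desc
            coll.add(name, [g for g in fields[2:] if g], source=source)
    return coll


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, gs.source, *gs.genes]) for name, gs in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed_genes(path: str | Path) -> list[GeneModel]:
    models: list[GeneModel] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"BED line {lineno}: need 4 columns (chrom start end name)")
            chrom, start, end, name = fields[0], fields[1], fields[2], fields[3]
            try:
                model = GeneModel(name, chrom, int(start), int(end))
            except (FormatError, ValueError) as exc:
                raise FormatError(f"BED line {lineno}: {exc}") from None
            key = (name, chrom)
            if key in seen:
                raise FormatError(f"BED line {lineno}: duplicate gene {name} on {chrom}")
            seen.add(key)
            models.append(model)
    return models


def write_bed_genes(models: Sequence[GeneModel], path: str | Path) -> None:
    lines = [f"{m.chrom}\t{m.start}\t{m.end}\t{m.gene_symbol}" for m in models]
    Path(path).write_text("\n".join(lines) + "\n")


def read_cnv_table(
    path: str | Path, sample_table: SampleTable | None = None
) -> list[CNVRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "chrom", "start", "end", "dosage_class"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"CNV table missing columns: {sorted(missing)}")
    known = set(sample_table.sample_ids) if sample_table is not None else None
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if known is not None and row.sample_id not in known:
            raise FormatError(f"row {i}: sample {row.sample_id!r} not in sample table")
        try:
            records.append(
                CNVRecord(row.sample_id, row.chrom, int(row.start), int(row.end), row.dosage_class)
            )
        except (FormatError, ValueError) as exc:
            raise FormatError(f"row {i}: {exc}") from None
    return records


def write_cnv_table(records: Sequence[CNVRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "chrom": [r.chrom for r in records],
            "start": [r.start for r in records],
            "end": [r.end for r in records],
            "dosage_class": [r.dosage_class for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Mask-tally serialization ("2/39:1_mask2|1_mask4m")
# ---------------------------------------------------------------------------

_TALLY_ITEM = re.compile(r"^(\d+)_mask(\d)(m?)$")


def format_mask_tally(carriers: int, denominator: int, mask_counts: Mapping[str, int]) -> str:
    """Serialize a carrier tally, e.g. ``2/39:1_mask2|1_mask4m``.

    ``mask_counts`` maps labels like ``"mask4m"`` to carried-variant counts;
    items are ordered by mask level then missense flag for determinism. An
    empty tally serializes as ``"0/39:"``.
    """

    def key(label: str) -> tuple[int, int]:
        m = _TALLY_ITEM.match(f"0_{label}")
        if not m:
            raise ValueError(f"bad mask label {label!r}")
        return int(m.group(2)), (1 if m.group(3) else 0)

    items = "|".join(
        f"{mask_counts[label]}_{label}" for label in sorted(mask_counts, key=key)
    )
    return f"{carriers}/{denominator}:{items}"


def parse_mask_tally(text: str) -> tuple[int, int, dict[str, int]]:
    """Inverse of :func:`format_mask_tally`."""
    head, _, tail = text.partition(":")
    carriers_s, _, denom_s = head.partition("/")
    carriers, denom = int(carriers_s), int(denom_s)
    counts: dict[str, int] = {}
    if tail:
        for item in tail.split("|"):
            m = _TALLY_ITEM.match(item)
            if not m:
                raise FormatError(f"bad mask-tally item {item!r}")
            label = f"mask{m.group(2)}{m.group(3)}"
            if label in counts:
                raise FormatError(f"duplicate mask label {label!r} in tally")
            counts[label] = int(m.group(1))
    return carriers, denom, counts


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

_P_FMT = "{:.12E}"
_F_FMT = "{:.12g}"


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return _F_FMT.format(x)


def _fmt_p(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return _P_FMT.format(x)


def write_results(results: Sequence, path: str | Path) -> None:
    """Write gene-association or pathway results as a deterministic TSV.

    Dispatches on result type; p-values are written in scientific notation
    with 13 significant digits so a read-back reproduces them to 12.
    """
    if not results:
        raise ValueError("no results to write")
    first = results[0]
    if hasattr(first, "p_burden"):  # GeneAssociationResult
        rows = []
        for r in results:
            rows.append(
                {
                    "gene": r.gene_symbol,
                    "case_tally": format_mask_tally(*r.case_tally),
                    "control_tally": format_mask_tally(*r.control_tally),
                    "p_burden": _fmt_p(r.p_burden),
                    "p_nominal": _fmt_p(r.p_nominal),
                    "odds_ratio": _fmt(r.odds_ratio),
                    "ci95_low": _fmt(r.ci95_low),
                    "ci95_high": _fmt(r.ci95_high),
                    "n_eligible_variants": r.n_eligible_variants,
                    "p_burden_bonferroni": _fmt_p(getattr(r, "p_bonferroni", None)),
                    "p_burden_bh": _fmt_p(getattr(r, "p_bh", None)),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    elif hasattr(first, "set_name"):  # PathwayResult
        rows = []
        for r in results:
            rows.append(
                {
                    "set_name": r.set_name,
                    "source": r.source,
                    "odds_ratio": _fmt(r.odds_ratio),
                    "ci95_low": _fmt(r.ci95_low),
                    "ci95_high": _fmt(r.ci95_high),
                    "p_value": _fmt_p(r.p_value),
                    "n_case_nonzero": r.n_case_nonzero,
                    "n_control_nonzero": r.n_control_nonzero,
                    "separation_flag": int(r.separation_flag),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise TypeError(f"do not know how to serialize {type(first).__name__}")
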