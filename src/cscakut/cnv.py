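"""Gene-level CNV association.

Each CNV call is matched against gene boundaries (0-based half-open
intervals, non-strict containment) and classified:

* ``intragenic`` — fully contained in a single gene (coterminous counts);
* ``multigenic`` — overlaps two or more genes;
* ``partial``    — overlaps exactly one gene but extends beyond it;
* ``intergenic`` — overlaps no gene.

Per (gene, dosage class) the samples carrying >= 1 overlapping CNV are
counted (a sample counts once however many of its CNVs hit the gene;
losses and gains are aggregated and tested separately) and the resulting
2x2 case/control carrier table is tested with the Pearson chi-square
(1 df, no Yates correction by default).  When any expected cell is below 5
the complete label-permutation distribution of the statistic — the
hypergeometric tail, equivalent to exhaustive label shuffling — is
enumerated and reported as the gene's p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .io_formats import CNVRecord, GeneModel, SampleTable


@dataclass
class CNVGeneOverlap:
    cnv: CNVRecord
    classification: str  # intragenic | multigenic | partial | intergenic
    genes: tuple[str, ...]


@dataclass
class CNVGeneScore:
    gene_symbol: str
    dosage_class: str
    case_carriers: int
    control_carriers: int
    chi2_stat: float | None
    p_asymptotic: float | None
    permutation_p: float | None
    p_value: float | None  # permutation p when sparse, else asymptotic
    untestable: bool = False


class GeneIntervalIndex:
    """Per-chromosome sorted gene intervals for overlap queries."""

    def __init__(self, gene_models: Sequence[GeneModel]):
        if not gene_models:
            raise ValueError("empty gene models")
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        self._bounds: dict[str, tuple[int, int]] = {
            m.gene_symbol: (m.start, m.end) for m in gene_models
        }
        grouped: dict[str, list[GeneModel]] = {}
        for gm in gene_models:
            grouped.setdefault(gm.chrom, []).append(gm)
        for chrom, models in grouped.items():
            models.sort(key=lambda m: (m.start, m.end, m.gene_symbol))
            starts = np.array([m.start for m in models])
            ends = np.array([m.end for m in models])
            names = [m.gene_symbol for m in models]
            self.by_chrom[chrom] = (starts, ends, names)

    def overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        """Genes whose half-open interval intersects [start, end)."""
        if chrom not in self.by_chrom:
            return []
        starts, ends, names = self.by_chrom[chrom]
        hit = (starts < end) & (ends > start)
        return [names[i] for i in np.flatnonzero(hit)]

    def bounds(self, gene: str) -> tuple[int, int]:
        return self._bounds[gene]


def classify_cnv(
    cnv: CNVRecord, gene_models: Sequence[GeneModel] | GeneIntervalIndex
) -> CNVGeneOverlap:
    """Deterministic classification of one CNV against gene boundaries."""
    index = gene_models if isinstance(gene_models, GeneIntervalIndex) else GeneIntervalIndex(gene_models)
    genes = index.overlapping(cnv.chrom, cnv.start, cnv.end)
    if not genes:
        cls = "intergenic"
    elif len(genes) >= 2:
        cls = "multigenic"
    else:
        g_start, g_end = index.bounds(genes[0])
        contained = cnv.start >= g_start and cnv.end <= g_end
        cls = "intragenic" if contained else "partial"
    return CNVGeneOverlap(cnv=cnv, classification=cls, genes=tuple(genes))


def gene_cnv_scores(
    cnvs: Sequence[CNVRecord],
    gene_models: Sequence[GeneModel] | GeneIntervalIndex,
    sample_table: SampleTable,
    score_mode: str = "carriers",
) -> dict[tuple[str, str], tuple[float, float]]:
    """Per-(gene, dosage class) case/control aggregates.

    ``score_mode``:

    * ``carriers`` (default) — samples with >= 1 overlapping CNV, counted
      once per sample (the scores that are association-tested);
    * ``count_events`` — raw overlapping-CNV event counts;
    * ``bp_overlap`` — summed overlap lengths in bp.

    Invariant under CNV input order; duplicating a record never changes
    carrier counts.
    """
    if score_mode not in {"carriers", "count_events", "bp_overlap"}:
        raise ValueError(f"unknown score_mode {score_mode!r}")
    index = gene_models if isinstance(gene_models, GeneIntervalIndex) else GeneIntervalIndex(gene_models)
    case_ids = {s for s, p in zip(sample_table.sample_ids, sample_table.phenotypes) if p == "case"}

    carriers: dict[tuple[str, str], set[str]] = {}
    events: dict[tuple[str, str], dict[str, float]] = {}
    for cnv in cnvs:
        for gene in index.overlapping(cnv.chrom, cnv.start, cnv.end):
            key = (gene, cnv.dosage_class)
            carriers.setdefault(key, set()).add(cnv.sample_id)
            per_sample = events.setdefault(key, {})
            if score_mode == "bp_overlap":
                g_start, g_end = index.bounds(gene)
                per_sample[cnv.sample_id] = per_sample.get(cnv.sample_id, 0.0) + (
                    min(cnv.end, g_end) - max(cnv.start, g_start)
                )
            else:
                per_sample[cnv.sample_id] = per_sample.get(cnv.sample_id, 0.0) + 1.0

    out: dict[tuple[str, str], tuple[float, float]] = {}
    for key in carriers:
        if score_mode == "carriers":
            case_v = float(sum(1 for s in carriers[key] if s in case_ids))
            ctrl_v = float(len(carriers[key]) - case_v)
        else:
            case_v = float(sum(v for s, v in events[key].items() if s in case_ids))
            ctrl_v = float(sum(v for s, v in events[key].items() if s not in case_ids))
        out[key] = (case_v, ctrl_v)
    return out


def _log_choose(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _pearson_chi2(a: float, n1: int, c: float, n2: int) -> float:
    """Pearson statistic for the 2x2 table [[a, n1-a], [c, n2-c]]."""
    n = n1 + n2
    c1 = a + c
    return n * (a * (n2 - c) - (n1 - a) * c) ** 2 / (n1 * n2 * c1 * (n - c1))


def cnv_chisq_test(
    case_carriers: int,
    n_cases: int,
    control_carriers: int,
    n_controls: int,
    yates: bool = False,
) -> tuple[float | None, float | None, float | None]:
    """Pearson chi-square (1 df) on the carrier 2x2 table.

    Returns (chi2, asymptotic p, permutation p). The permutation p — the
    exhaustive label-permutation tail P(chi2 >= observed), computed via the
    hypergeometric distribution of the case carrier count — is filled in
    whenever any expected cell is < 5, and None otherwise.  Zero-margin
    tables return (None, None, None).
    """
    a, c = case_carriers, control_carriers
    n = n_cases + n_controls
    c1 = a + c
    if c1 == 0 or c1 == n or min(a, c) < 0 or a > n_cases or c > n_controls:
        if c1 == 0 or c1 == n:
            return None, None, None
        raise ValueError("inconsistent carrier counts")
    if yates:
        e_a = n_cases * c1 / n
        e_b = n_cases * (n - c1) / n
        e_c = n_controls * c1 / n
        e_d = n_controls * (n - c1) / n
        obs = [a, n_cases - a, c, n_controls - c]
        exp = [e_a, e_b, e_c, e_d]
        chi2 = sum((abs(o - e) - 0.5) ** 2 / e for o, e in zip(obs, exp))
    else:
        chi2 = _pearson_chi2(a, n_cases, c, n_controls)
    p_asym = float(chi2_dist.sf(chi2, 1))

    expected_min = min(
        n_cases * c1 / n, n_cases * (n - c1) / n, n_controls * c1 / n, n_controls * (n - c1) / n
    )
    perm_p = None
    if expected_min < 5:
        lo = max(0, c1 - n_controls)
        hi = min(n_cases, c1)
        log_denom = _log_choose(n, c1)
        tail = 0.0
        for x in range(lo, hi + 1):
            stat = _pearson_chi2(x, n_cases, c1 - x, n_controls)
            if stat >= chi2 * (1 - 1e-12):
                tail += math.exp(
                    _log_choose(n_cases, x) + _log_choose(n_controls, c1 - x) - log_denom
                )
        perm_p = min(tail, 1.0)
    return float(chi2), p_asym, perm_p


def run_cnv_scan(
    cnvs: Sequence[CNVRecord],
    gene_models: Sequence[GeneModel],
    sample_table: SampleTable,
    score_mode: str = "carriers",
    yates: bool = False,
) -> tuple[list[CNVGeneScore], dict[str, int]]:
    """Ranked per-(gene, class) CNV association plus a classification summary.

    Only ``score_mode="carriers"`` is association-tested; the other modes
    report aggregate scores with no p-value. Sorted ascending by p (the
    permutation p when emitted), ties by gene then class.
    """
    index = GeneIntervalIndex(gene_models)
    summary: dict[str, int] = {"intragenic": 0, "multigenic": 0, "partial": 0, "intergenic": 0}
    for cnv in cnvs:
        summary[classify_cnv(cnv, index).classification] += 1

    scores = gene_cnv_scores(cnvs, index, sample_table, score_mode=score_mode)
    n1, n2 = sample_table.n_cases, sample_table.n_controls
    results: list[CNVGeneScore] = []
    for (gene, dosage_class), (case_v, ctrl_v) in scores.items():
        if score_mode == "carriers":
            chi2, p_asym, perm_p = cnv_chisq_test(int(case_v), n1, int(ctrl_v), n2, yates=yates)
            p = perm_p if perm_p is not None else p_asym
            results.append(
                CNVGeneScore(
                    gene_symbol=gene,
                    dosage_class=dosage_class,
                    case_carriers=int(case_v),
                    control_carriers=int(ctrl_v),
                    chi2_stat=chi2,
                    p_asymptotic=p_asym,
                    permutation_p=perm_p,
                    p_value=p,
                    untestable=chi2 is None,
                )
            )
        else:
            results.append(
                CNVGeneScore(
                    gene_symbol=gene,
                    dosage_class=dosage_class,
                    case_carriers=int(case_v),
                    control_carriers=int(ctrl_v),
                    chi2_stat=None,
                    p_asymptotic=None,
                    permutation_p=None,
                    p_value=None,
                    untestable=True,
                )
            )
    results.sort(
        key=lambda r: (
            r.p_value if r.p_value is not None else 2.0,
            r.gene_symbol,
            r.dosage_class,
        )
    )
    return results, summary
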