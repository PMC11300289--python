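"""Ultra-rare variant selection and mask/weight assignment.

Variants surviving the allele-frequency filters (gnomAD popmax AF <= 0.1%
and cohort AF <= 0.1%, both inclusive) are classified into six severity
*mask levels* carrying weights from 1 down to 0:

====  =========================================  ======  ====
mask  default predicate                          weight  "m"
====  =========================================  ======  ====
1     high-confidence LoF                        1.0
2     low-confidence LoF                         0.9
3     in-frame indel                             0.7
4     missense, >= 3 damaging predictor calls    0.5     m
5     other missense                             0.3     m
6     synonymous / other (catch-all)             0.0
====  =========================================  ======  ====

The "m" flag marks missense-derived masks (the suffix seen in result
tallies).  The whole scheme is configuration, overridable from a TSV; the
weights must be non-increasing in mask level and level 1 must carry weight
1.  Burden eligibility additionally requires weight > 0 and cohort minor
allele count (MAC) <= 5 (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, AnnotationRecord, FormatError, SampleTable, VariantRecord

# predicate registry: name -> test over an AnnotationRecord
PREDICATES: dict[str, Callable[[AnnotationRecord], bool]] = {
    "lof_high": lambda a: a.consequence_class == "lof" and a.lof_confidence == "high",
    "lof_low": lambda a: a.consequence_class == "lof" and a.lof_confidence != "high",
    "inframe_indel": lambda a: a.consequence_class == "inframe_indel",
    "missense_damaging3": lambda a: a.consequence_class == "missense"
    and a.n_damaging_predictors >= 3,
    "missense_other": lambda a: a.consequence_class == "missense",
    "any": lambda a: True,
}


@dataclass(frozen=True)
class MaskRule:
    mask_level: int
    missense_flag: bool
    predicate_name: str

    def matches(self, annotation: AnnotationRecord) -> bool:
        return PREDICATES[self.predicate_name](annotation)


@dataclass
class MaskScheme:
    """Ordered first-match-wins mask rules plus thresholds."""

    rules: list[MaskRule]
    weights: dict[int, float]
    af_popmax_max: float = 0.001
    af_cohort_max: float = 0.001
    mac_max: int = 5

    def __post_init__(self) -> None:
        levels = sorted(self.weights)
        if not levels or levels[0] != 1:
            raise ValueError("mask scheme must define level 1")
        if self.weights[1] != 1.0:
            raise ValueError("level 1 weight must be 1.0")
        for lo, hi in zip(levels, levels[1:]):
            if self.weights[hi] > self.weights[lo]:
                raise ValueError("weights must be non-increasing in mask level")
        for rule in self.rules:
            if rule.predicate_name not in PREDICATES:
                raise ValueError(f"unknown predicate {rule.predicate_name!r}")
            if rule.mask_level not in self.weights:
                raise ValueError(f"rule for level {rule.mask_level} has no weight")
        if not (0 < self.af_popmax_max <= 1) or not (0 < self.af_cohort_max <= 1):
            raise ValueError("AF thresholds must lie in (0, 1]")
        if self.mac_max < 1:
            raise ValueError("mac_max must be a positive integer")


def default_scheme(**overrides) -> MaskScheme:
    """The default six-level mask scheme (weights 1 -> 0)."""
    return MaskScheme(
        rules=[
            MaskRule(1, False, "lof_high"),
            MaskRule(2, False, "lof_low"),
            MaskRule(3, False, "inframe_indel"),
            MaskRule(4, True, "missense_damaging3"),
            MaskRule(5, True, "missense_other"),
            MaskRule(6, False, "any"),
        ],
        weights={1: 1.0, 2: 0.9, 3: 0.7, 4: 0.5, 5: 0.3, 6: 0.0},
        **overrides,
    )


def read_mask_scheme(path: str | Path, **thresholds) -> MaskScheme:
    """Load a scheme from TSV (columns mask_level, missense_flag, predicate_name, weight)."""
    df = pd.read_csv(path, sep="\t")
    required = {"mask_level", "missense_flag", "predicate_name", "weight"}
    if required - set(df.columns):
        raise FormatError(f"mask scheme needs columns {sorted(required)}")
    rules, weights = [], {}
    for row in df.itertuples(index=False):
        level = int(row.mask_level)
        rules.append(MaskRule(level, bool(int(row.missense_flag)), str(row.predicate_name)))
        weights[level] = float(row.weight)
    return MaskScheme(rules=rules, weights=weights, **thresholds)


def write_mask_scheme(scheme: MaskScheme, path: str | Path) -> None:
    pd.DataFrame(
        {
            "mask_level": [r.mask_level for r in scheme.rules],
            "missense_flag": [int(r.missense_flag) for r in scheme.rules],
            "predicate_name": [r.predicate_name for r in scheme.rules],
            "weight": [scheme.weights[r.mask_level] for r in scheme.rules],
        }
    ).to_csv(path, sep="\t", index=False)


@dataclass
class MaskedVariant:
    """A qualifying variant with its mask assignment and cohort statistics."""

    variant: VariantRecord
    annotation: AnnotationRecord
    mask_level: int
    missense_flag: bool
    weight: float
    mac: int
    cohort_af: float

    @property
    def gene_symbol(self) -> str:
        return self.annotation.gene_symbol

    @property
    def mask_label(self) -> str:
        return f"mask{self.mask_level}{'m' if self.missense_flag else ''}"

    def carriers(self) -> np.ndarray:
        """Indices of samples carrying >= 1 alt allele (het or hom alike)."""
        return np.flatnonzero(self.variant.genotypes > 0)


def compute_cohort_af_mac(variant: VariantRecord) -> tuple[float, int]:
    """Cohort alt-allele frequency and minor allele count.

    Missing genotypes are excluded from the denominator; AF is the alt count
    over 2x the non-missing samples, MAC the smaller of the alt and ref
    allele counts.
    """
    g = variant.genotypes
    called = g != MISSING
    n_called = int(called.sum())
    if n_called == 0:
        raise ValueError(f"all genotypes missing for {variant.variant_id}")
    ac = int(g[called].sum())
    total = 2 * n_called
    return ac / total, min(ac, total - ac)


def assign_mask(annotation: AnnotationRecord, scheme: MaskScheme) -> tuple[int, bool, float]:
    """First matching rule wins; returns (mask_level, missense_flag, weight)."""
    for rule in scheme.rules:
        if rule.matches(annotation):
            return rule.mask_level, rule.missense_flag, scheme.weights[rule.mask_level]
    raise ValueError(f"no mask rule matched {annotation.variant_id}")


def filter_rare(
    variants: Sequence[VariantRecord],
    annotations: Sequence[AnnotationRecord],
    scheme: MaskScheme,
) -> list[MaskedVariant]:
    """Retain ultra-rare variants (popmax AF and cohort AF both <= threshold).

    Both comparisons are inclusive. A variant without an annotation row is
    treated as consequence ``other`` (it lands in the zero-weight catch-all
    mask and is removed later by the MAC gate).
    """
    ann_by_id = {a.variant_id: a for a in annotations}
    out: list[MaskedVariant] = []
    for v in variants:
        ann = ann_by_id.get(v.variant_id)
        if ann is None:
            ann = AnnotationRecord(
                variant_id=v.variant_id, gene_symbol="__unannotated__", consequence_class="other"
            )
        if ann.popmax_af > scheme.af_popmax_max:
            continue
        af, mac = compute_cohort_af_mac(v)
        if af > scheme.af_cohort_max:
            continue
        level, flag, weight = assign_mask(ann, scheme)
        out.append(
            MaskedVariant(
                variant=v,
                annotation=ann,
                mask_level=level,
                missense_flag=flag,
                weight=weight,
                mac=mac,
                cohort_af=af,
            )
        )
    return out


def apply_mac_gate(
    masked_variants: Sequence[MaskedVariant], scheme: MaskScheme
) -> tuple[list[MaskedVariant], list[tuple[MaskedVariant, str]]]:
    """Partition into burden-eligible variants and excluded ones with reasons.

    Eligibility requires weight > 0 and MAC <= ``mac_max`` (inclusive).
    Every input appears exactly once across the two outputs.
    """
    eligible: list[MaskedVariant] = []
    excluded: list[tuple[MaskedVariant, str]] = []
    for mv in masked_variants:
        if mv.weight <= 0:
            excluded.append((mv, "zero_weight"))
        elif mv.mac > scheme.mac_max:
            excluded.append((mv, "mac_gt_threshold"))
        else:
            eligible.append(mv)
    return eligible, excluded


def prioritize(
    variants: Sequence[VariantRecord],
    annotations: Sequence[AnnotationRecord],
    scheme: MaskScheme | None = None,
) -> tuple[list[MaskedVariant], list[tuple[MaskedVariant, str]]]:
    """Full selection stage: AF filter, mask assignment, MAC gate."""
    scheme = scheme or default_scheme()
    return apply_mac_gate(filter_rare(variants, annotations, scheme), scheme)
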