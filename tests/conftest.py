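import numpy as np
import pytest

from cscakut.io_formats import AnnotationRecord, SampleTable, VariantRecord
from cscakut.masks import MaskedVariant


@pytest.fixture
def tiny_samples() -> SampleTable:
    """4 cases and 8 controls."""
    ids = [f"CASE{i}" for i in range(4)] + [f"CTRL{i}" for i in range(8)]
    return SampleTable(ids, ["case"] * 4 + ["control"] * 8)


def make_variant(pos: int, genotypes, chrom: str = "chr1", ref: str = "A", alt: str = "T"):
    return VariantRecord(chrom, pos, ref, alt, np.asarray(genotypes, dtype=np.int8))


def make_masked(
    variant,
    gene: str,
    mask_level: int = 4,
    missense_flag: bool = True,
    weight: float = 0.5,
    mac: int = 1,
    cohort_af: float = 1e-4,
) -> MaskedVariant:
    ann = AnnotationRecord(
        variant_id=variant.variant_id, gene_symbol=gene, consequence_class="missense"
    )
    return MaskedVariant(
        variant=variant,
        annotation=ann,
        mask_level=mask_level,
        missense_flag=missense_flag,
        weight=weight,
        mac=mac,
        cohort_af=cohort_af,
    )
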