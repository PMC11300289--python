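"""Synthetic cohort generator: determinism, null structure, effect sizes."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from cscakut.io_formats import read_annotation_table, read_bed_genes, read_cnv_table, \
    read_gmt, read_phenotypes, read_vcf
from cscakut.masks import default_scheme, prioritize
from cscakut.simulate import (
    SimulationConfig,
    simulate_all,
    simulate_cnvs,
    simulate_cohort,
    simulate_gene_models,
    simulate_gene_sets,
)


def small_config(**kw):
    base = dict(
        n_cases=30,
        n_controls=120,
        n_genes=40,
        genes_per_set=8,
        n_sets=4,
        baseline_carrier_rate=0.02,
        risk_genes={},
        cnv_risk_genes={},
        cnv_baseline_loss_rate=0.01,
        seed=11,
    )
    base.update(kw)
    return SimulationConfig(**base)


def carrier_counts(variants, annotations, gene, n_cases):
    ids = {a.variant_id for a in annotations if a.gene_symbol == gene}
    carriers = set()
    for v in variants:
        if v.variant_id in ids:
            carriers.update(np.flatnonzero(v.genotypes > 0).tolist())
    n_case = sum(1 for i in carriers if i < n_cases)
    return n_case, len(carriers) - n_case


class TestDeterminism:
    def test_identical_config_and_seed_give_identical_bytes(self, tmp_path):
        conf = small_config()
        hashes = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            simulate_all(conf, out_dir=out)
            digest = hashlib.sha256()
            for f in sorted(Path(out).iterdir()):
                digest.update(f.name.encode())
                digest.update(f.read_bytes())
            hashes.append(digest.hexdigest())
        assert hashes[0] == hashes[1]

    def test_different_seed_changes_output(self):
        v1, _, _ = simulate_cohort(small_config(seed=1))
        v2, _, _ = simulate_cohort(small_config(seed=2))
        assert [v.variant_id for v in v1] != [v.variant_id for v in v2]


class TestGeneratedFilesPassReaders:
    def test_all_outputs_load_cleanly(self, tmp_path):
        conf = small_config()
        simulate_all(conf, out_dir=tmp_path)
        samples = read_phenotypes(tmp_path / "phenotypes.tsv")
        variants = read_vcf(tmp_path / "cohort.vcf", samples)
        annotations = read_annotation_table(tmp_path / "annotations.tsv")
        sets = read_gmt(tmp_path / "gene_sets.gmt")
        models = read_bed_genes(tmp_path / "genes.bed")
        cnvs = read_cnv_table(tmp_path / "cnvs.tsv", samples)
        assert len(variants) == len(annotations) > 0
        assert len(models) == conf.n_genes and len(sets) == conf.n_sets
        assert len(samples) == conf.n_cases + conf.n_controls
        assert all(c.sample_id in set(samples.sample_ids) for c in cnvs)

    def test_study_scale_variants_are_ultra_rare(self):
        conf = SimulationConfig(
            n_cases=40, n_controls=2764, n_genes=60, risk_genes={}, cnv_risk_genes={},
            seed=3,
        )
        variants, annotations, _ = simulate_cohort(conf)
        ann = {a.variant_id: a for a in annotations}
        n = conf.n_cases + conf.n_controls
        for v in variants:
            assert ann[v.variant_id].popmax_af <= 1e-3
            assert v.genotypes.sum() / (2 * n) <= 1e-3

    def test_decoy_variants_removed_by_filter(self):
        conf = small_config(n_decoy_common=5)
        variants, annotations, _ = simulate_cohort(conf)
        scheme = default_scheme(af_cohort_max=1.0)  # popmax filter does the work
        eligible, _ = prioritize(variants, annotations, scheme)
        decoy_ids = {a.variant_id for a in annotations if a.popmax_af > 1e-3}
        assert len(decoy_ids) == 5
        assert decoy_ids.isdisjoint({mv.variant.variant_id for mv in eligible})


class TestEffectInjection:
    def test_null_config_has_balanced_carrier_rates(self):
        # pooled over genes, case vs control carrier frequency within binomial CI
        conf = small_config(n_cases=200, n_controls=200, n_genes=150, seed=4)
        variants, annotations, _ = simulate_cohort(conf)
        case_total = ctrl_total = 0
        for gene in conf.gene_names():
            nc, nn = carrier_counts(variants, annotations, gene, conf.n_cases)
            case_total += nc
            ctrl_total += nn
        total = case_total + ctrl_total
        # under the null, case carriers ~ Binomial(total, 1/2)
        se = np.sqrt(total * 0.25)
        assert abs(case_total - total / 2) < 3 * se

    def test_risk_gene_carrier_odds_ratio_recovered(self):
        # Monte-Carlo over replicates: empirical carrier OR near the target
        target = 12.0
        case_carr = ctrl_carr = 0
        n_cases, n_controls = 150, 800
        reps = 60
        for seed in range(reps):
            conf = SimulationConfig(
                n_cases=n_cases, n_controls=n_controls, n_genes=3,
                genes_per_set=2, n_sets=2,
                baseline_carrier_rate=0.01,
                risk_genes={"GENE0001": target}, cnv_risk_genes={}, seed=100 + seed,
            )
            variants, annotations, _ = simulate_cohort(conf)
            nc, nn = carrier_counts(variants, annotations, "GENE0001", n_cases)
            case_carr += nc
            ctrl_carr += nn
        p_case = case_carr / (reps * n_cases)
        p_ctrl = ctrl_carr / (reps * n_controls)
        emp_or = (p_case / (1 - p_case)) / (p_ctrl / (1 - p_ctrl))
        assert 0.7 * target < emp_or < 1.4 * target

    def test_infeasible_cnv_config_rejected_before_generation(self):
        with pytest.raises(ValueError, match="> 1"):
            small_config(
                cnv_risk_genes={"GENE0001": 200.0}, cnv_baseline_loss_rate=0.01
            ).validate()


class TestGeneSets:
    def test_sizes_and_risk_gene_membership(self):
        conf = small_config(risk_genes={"GENE0005": 10.0, "GENE0020": 20.0})
        coll = simulate_gene_sets(conf)
        assert all(len(gs.genes) == conf.genes_per_set for gs in coll.sets.values())
        assert {"GENE0005", "GENE0020"} <= set(coll[conf.enriched_set].genes)

    def test_enriched_set_smaller_than_risk_genes_rejected(self):
        conf = small_config(
            genes_per_set=2,
            risk_genes={"GENE0001": 5.0, "GENE0002": 5.0, "GENE0003": 5.0},
        )
        with pytest.raises(ValueError):
            simulate_gene_sets(conf)

    def test_sets_may_overlap(self):
        conf = small_config(n_genes=12, genes_per_set=8, n_sets=4, seed=0)
        coll = simulate_gene_sets(conf)
        names = list(coll.sets)
        overlaps = [
            len(set(coll[a].genes) & set(coll[b].genes))
            for i, a in enumerate(names)
            for b in names[i + 1:]
        ]
        assert max(overlaps) > 0  # 8+8 from 12 must intersect


class TestCnvSimulation:
    def test_zero_rate_and_no_risk_genes_gives_no_cnvs(self):
        conf = small_config(cnv_rate=0.0, cnv_baseline_loss_rate=0.0)
        models = simulate_gene_models(conf)
        assert simulate_cnvs(conf, models) == []

    def test_empty_gene_models_rejected(self):
        with pytest.raises(ValueError):
            simulate_cnvs(small_config(), [])

    def test_null_multiplier_balances_case_control_losses(self):
        conf = small_config(
            n_cases=400, n_controls=400,
            cnv_rate=0.0, cnv_risk_genes={"GENE0003": 1.0},
            cnv_baseline_loss_rate=0.2, seed=6,
        )
        models = simulate_gene_models(conf)
        cnvs = simulate_cnvs(conf, models)
        case = sum(1 for c in cnvs if c.sample_id.startswith("CASE"))
        ctrl = len(cnvs) - case
        se = np.sqrt(len(cnvs) * 0.25)
        assert abs(case - len(cnvs) / 2) < 3 * se
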