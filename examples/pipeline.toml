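# Full pipeline configuration: simulate a cohort, then run every analysis
# stage. Thresholds default to the study design (popmax AF <= 0.1%,
# cohort AF <= 0.1%, MAC <= 5); they are rescaled here because the demo
# cohort is small.

out_dir = "demo_run"
seed = 1
af_cohort_max = 0.05
mac_max = 30
top_k = 15
top_genes = 10

[simulation]
n_cases = 40
n_controls = 500
n_genes = 200
genes_per_set = 20
n_sets = 6
baseline_carrier_rate = 0.01
cnv_baseline_loss_rate = 0.01

[simulation.risk_genes]
GENE0042 = 40.0

[simulation.cnv_risk_genes]
GENE0077 = 25.0
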