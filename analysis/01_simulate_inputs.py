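#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Emits, under scratch/fixtures/ (regenerable, not part of the reported
results): the three-sample cohort VCF with class-conditional site
metrics, the truth panel (alleles of true-labelled sites), two reference
panels with a planted 7% novel fraction, and a toy genome with
transcript models.  A summary of the planted conditions is written to
results/simulation_summary.tsv.
"""

from pathlib import Path

import pandas as pd

from popnovel.synthetic_data import (
    SimulationConfig,
    simulate_cohort_vcf,
    simulate_gene_models,
    simulate_panels,
)

SEED = 20260930
ROOT = Path(__file__).resolve().parents[1]
FIXTURES = ROOT / "scratch" / "fixtures"


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    gene_sim = simulate_gene_models(cfg, FIXTURES)
    cohort_path, truth = simulate_cohort_vcf(
        cfg, FIXTURES / "cohort.vcf", genome=gene_sim.genome)
    panel_paths = simulate_panels(cfg, truth, FIXTURES)

    n_true = sum(1 for v in truth.site_labels.values() if v == "true")
    rows = [
        ("seed", SEED),
        ("n_samples", cfg.n_samples),
        ("n_sites", cfg.n_sites),
        ("n_true_sites", n_true),
        ("n_other_sites", len(truth.site_labels) - n_true),
        ("n_snv_alleles", len(truth.snv_allele_keys)),
        ("panel_overlap", cfg.panel_overlap),
        ("expected_novel_fraction_kg",
         round(truth.expected_novel_fraction["kg"], 6)),
        ("expected_novel_fraction_gnomad",
         round(truth.expected_novel_fraction["gnomad"], 6)),
        ("n_gene_models", len(gene_sim.models)),
        ("n_planted_alleles", len(gene_sim.planted)),
    ]
    out = ROOT / "results" / "simulation_summary.tsv"
    pd.DataFrame(rows, columns=["quantity", "value"]).to_csv(
        out, sep="\t", index=False)
    print(f"cohort: {cohort_path}")
    for name, p in panel_paths.items():
        print(f"panel {name}: {p}")
    print(f"summary: {out}")


if __name__ == "__main__":
    main()
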