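"""End-to-end orchestration of the synthetic study.

``run_pipeline`` generates the synthetic inputs, then runs
normalize -> prefilter -> QC cascade -> novelty -> annotation ->
spectra/bins -> ancestry, writing one TSV per product plus a manifest
with input digests.  Reruns with the same configuration are byte-stable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import numpy as np

from popnovel import __version__
from popnovel import qc as qc_mod
from popnovel.ancestry import (
    SiteSelectionConfig,
    apply_query_filters,
    fit_pca,
    ld_prune,
    project_samples,
    remove_regions,
    select_sites,
)
from popnovel.annotation import annotate_alleles, fasta_lookup, read_gene_table, summarize_classes
from popnovel.novelty import assess_novelty, build_panel, novelty_table
from popnovel.spectra_bins import allele_spectrum, bin_density
from popnovel.synthetic_data import (
    SimulationConfig,
    query_records_from_matrix,
    simulate_cohort_vcf,
    simulate_gene_models,
    simulate_panels,
    simulate_populations,
)
from popnovel.vcf_io import normalize_site_alleles, read_vcf

logger = logging.getLogger("popnovel.pipeline")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int
    sim: SimulationConfig | None = None
    qc_enabled: bool = True
    ancestry_enabled: bool = True
    score_threshold: float = qc_mod.DEFAULT_SCORE_THRESHOLD
    selection: SiteSelectionConfig = field(default_factory=SiteSelectionConfig)
    n_components: int = 2

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.sim is None:
            self.sim = SimulationConfig(seed=self.seed)


@dataclass
class PipelineResult:
    outputs: dict[str, Path]
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage on fresh synthetic fixtures and write the report
    bundle under ``config.outdir``."""
    out = config.outdir
    fixtures = out / "fixtures"
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    sim = config.sim

    def stage(name):
        logger.info("stage: %s", name)
        return name

    try:
        name = stage("simulate")
        gene_sim = simulate_gene_models(sim, fixtures)
        cohort_path, truth = simulate_cohort_vcf(
            sim, fixtures / "cohort.vcf", genome=gene_sim.genome)
        panel_paths = simulate_panels(sim, truth, fixtures)

        name = stage("prefilter")
        records = list(read_vcf(cohort_path))
        records = qc_mod.prefilter_sites(records)

        name = stage("classify")
        truth_panel = qc_mod.TruthPanel.from_vcf(panel_paths["truth"])
        labels = qc_mod.classify_sites(records, [truth_panel])

        name = stage("qc")
        if config.qc_enabled:
            stages = qc_mod.default_stages(
                seed=config.seed, score_threshold=config.score_threshold)
            kept, report = qc_mod.apply_qc_cascade(records, labels, stages)
            outputs["qc_report"] = _write_tsv(report.to_frame(),
                                              out / "qc_report.tsv")
        else:
            pairs = [(r, l) for r, l in zip(records, labels) if r.is_snv()]
            kept = [p[0] for p in pairs]
            report = None

        name = stage("novelty")
        kept_alleles = [a for r in kept for a in normalize_site_alleles(r)
                        if a.is_snv()]
        panels = {
            "kg": build_panel(panel_paths["kg"], "kg", snv_only=True),
            "gnomad": build_panel(
                panel_paths["gnomad"], "gnomad", use_filter_column=True,
                excluded_chroms={sim.panel_excluded_chrom}, snv_only=True),
        }
        novelty_results = {n: assess_novelty(kept_alleles, p)
                           for n, p in panels.items()}
        outputs["novelty"] = _write_tsv(
            novelty_table(list(novelty_results.values())), out / "novelty.tsv")

        name = stage("annotation")
        models = read_gene_table(gene_sim.genes_path)
        lookup = fasta_lookup(gene_sim.genome)
        ann = annotate_alleles(kept_alleles, models, genome_lookup=lookup)
        subsets = {
            "all": None,
            "novel_kg": novelty_results["kg"].novel_allele_keys(),
            "novel_gnomad": novelty_results["gnomad"].novel_allele_keys(),
        }
        outputs["annotation_summary"] = _write_tsv(
            summarize_classes(ann, subsets), out / "annotation_summary.tsv")

        name = stage("spectra_bins")
        spec_frames = []
        for sub_name, keys in subsets.items():
            spec = allele_spectrum(kept, subset=keys)
            s = spec.as_series().rename_axis("copies").reset_index()
            s.insert(0, "subset", sub_name)
            s["n_sites_excluded_missing"] = spec.n_sites_excluded_missing
            spec_frames.append(s)
        outputs["spectra"] = _write_tsv(pd.concat(spec_frames),
                                        out / "spectra.tsv")
        lengths = sim.all_chrom_lengths(with_gene_chrom=True)
        sites = sorted({(r.chrom, r.pos) for r in kept})
        outputs["bins"] = _write_tsv(
            bin_density(sites, lengths).to_frame(), out / "bins.tsv")

        name = stage("ancestry")
        if config.ancestry_enabled:
            pop = simulate_populations(sim)
            catalogue = [(k[0], k[1]) for k in pop.panel.site_keys]
            selected, attrition = select_sites(pop.panel, catalogue,
                                               config.selection)
            query_records = query_records_from_matrix(pop.query)
            query_matrix, excluded = apply_query_filters(
                query_records, selected, config.selection,
                sample_names=pop.query.samples)
            shared = remove_regions(query_matrix.site_keys,
                                    config.selection.excluded_regions)
            panel_sub = pop.panel.subset_sites(shared).impute_missing()
            pruned = ld_prune(panel_sub, config.selection.ld_window,
                              config.selection.ld_step,
                              config.selection.vif_max)
            panel_final = panel_sub.subset_sites(pruned)
            model = fit_pca(panel_final, config.n_components)
            q_scores = project_samples(model, query_matrix.subset_sites(pruned))
            ref = model.reference_scores.copy()
            ref.insert(0, "population",
                       [pop.panel_populations[s] for s in ref.index])
            q = q_scores.copy()
            q.insert(0, "population", "query")
            scores = pd.concat([ref, q]).rename_axis("sample").reset_index()
            outputs["pca_scores"] = _write_tsv(scores, out / "pca_scores.tsv")
            ancestry_info = {
                "selected_sites": len(selected),
                "attrition": attrition,
                "query_excluded": len(excluded),
                "pruned_sites": len(pruned),
            }
        else:
            ancestry_info = None

        name = stage("manifest")
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "inputs": {p.name: _sha256(p)
                       for p in sorted([cohort_path, *panel_paths.values(),
                                        gene_sim.genes_path,
                                        gene_sim.fasta_path])},
            "n_input_sites": sim.n_sites,
            "n_prefiltered": len(records),
            "n_kept": len(kept),
            "qc": None if report is None else {
                "overall_true_retention": report.overall_true_retention,
                "overall_ratio_increase": report.overall_ratio_increase,
                "overall_removed_fraction": report.overall_removed_fraction,
            },
            "novelty": {n: {"novel_fraction": r.novel_fraction,
                            "n_novel_sites": r.n_novel_sites}
                        for n, r in novelty_results.items()},
            "ancestry": ancestry_info,
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        outputs["manifest"] = manifest_path
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        if isinstance(exc, StageError):
            raise
        raise StageError(name, exc) from exc
    return PipelineResult(outputs=outputs, manifest=manifest)
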