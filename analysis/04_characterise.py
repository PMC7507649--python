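#!/usr/bin/env python
"""Characterise QC-passed alleles: annotation classes, effects, spectra
and 10 Mb densities.

Annotates every SNV allele against the toy transcript models (precedence-
resolved to one class and, for exonic alleles, one effect), tallies the
allele-count spectrum over the three samples, and bins SNV sites into
10 Mb blocks per chromosome.  Subsets are reported for all alleles and
for alleles novel to each reference panel.
"""

from pathlib import Path

import pandas as pd

from popnovel.annotation import annotate_alleles, fasta_lookup, read_gene_table, summarize_classes
from popnovel.novelty import NOVEL
from popnovel.spectra_bins import allele_spectrum, bin_density
from popnovel.synthetic_data import SimulationConfig
from popnovel.vcf_io import normalize_site_alleles, read_vcf

import pyfaidx

SEED = 20260930
ROOT = Path(__file__).resolve().parents[1]
FIXTURES = ROOT / "scratch" / "fixtures"


def main() -> None:
    records = [r for r in read_vcf(FIXTURES / "passed.vcf")]
    alleles = [a for r in records for a in normalize_site_alleles(r)
               if a.is_snv()]

    novelty = pd.read_csv(ROOT / "scratch" / "novelty.tsv", sep="\t")
    subsets = {"all": None}
    for panel in ("kg", "gnomad"):
        sub = novelty[(novelty.panel_name == panel)
                      & (novelty.status == NOVEL)]
        subsets[f"novel_{panel}"] = {
            (r.chrom, r.pos, r.ref, r.alt) for r in sub.itertuples()}

    models = read_gene_table(FIXTURES / "genes.txt")
    genome = pyfaidx.Fasta(str(FIXTURES / "toy_genome.fa"))
    ann = annotate_alleles(alleles, models, genome_lookup=fasta_lookup(genome))
    table = summarize_classes(ann, subsets)
    table.to_csv(ROOT / "results" / "annotation_summary.tsv", sep="\t",
                 index=False, float_format="%.6g")
    exonic = table[(table.subset == "all")
                   & (table.ladder == "sequence_class")
                   & (table.category.isin(["exonic", "splicing"]))]
    print(f"exon or splice-site alleles: {exonic['count'].sum()} "
          f"({exonic.percent.sum():.2f}% of all alleles)")

    frames = []
    for name, keys in subsets.items():
        spec = allele_spectrum(records, subset=keys)
        s = spec.as_series().rename_axis("copies").reset_index()
        s.insert(0, "subset", name)
        frames.append(s)
        print(f"spectrum [{name}]: "
              + ", ".join(f"{c}x:{n}" for c, n in sorted(spec.counts.items()))
              + f" ({spec.n_sites_excluded_missing} sites with missing "
              f"genotypes excluded)")
    pd.concat(frames).to_csv(ROOT / "results" / "spectra.tsv", sep="\t",
                             index=False)

    lengths = SimulationConfig(seed=SEED).all_chrom_lengths(
        with_gene_chrom=True)
    sites = sorted({(r.chrom, r.pos) for r in records})
    density = bin_density(sites, lengths)
    density.to_frame().to_csv(ROOT / "results" / "bins.tsv", sep="\t",
                              index=False)
    for chrom in sorted(density.blocks):
        print(f"{chrom}: {density.blocks[chrom]} sites per 10 Mb block")


if __name__ == "__main__":
    main()
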