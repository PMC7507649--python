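"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the shape of a three-sample WGS call set and its
companion resources: a multi-sample VCF whose site metrics are drawn from
class-conditional distributions for "true" and "error" sites, truth and
reference panels with configured overlap and quality-fail fractions, a
toy genome with transcript models and planted alleles of known class and
effect, and reference/admixed genotype matrices under the
Balding-Nichols model.  Everything is deterministic under the seed.

What is emulated: metric separability between good and bad calls, panel
overlap with a known novel fraction, allele-frequency structure between
two diverged source populations, and transcript geometry for annotation.
What is not: read-level error processes, realistic genome-wide LD, or
real allele-frequency spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from popnovel.ancestry import GenotypeMatrix
from popnovel.annotation import (
    AnnotationClass,
    EffectClass,
    GeneModel,
    write_gene_table,
)
from popnovel.vcf_io import NormalizedAllele, SampleCall, SiteRecord, write_vcf

AlleleKey = tuple[str, int, str, str]

_BASES = np.array(list("ACGT"))


class SimulationConfigError(ValueError):
    pass


#: Class-conditional metric models: family, mean, sd.  "truncnorm0"
#: clips at zero, which also gives FS an exact point mass at 0 as GATK
#: output does.  Separations are set so the packaged threshold rules
#: retain nearly all true sites while discriminating (DF > 1).
DEFAULT_METRIC_MODELS: dict[str, dict[str, tuple[str, float, float]]] = {
    "true": {
        "QD": ("truncnorm0", 20.0, 5.0),
        "MQ": ("truncnorm0", 60.0, 3.0),
        "MQRankSum": ("normal", 0.0, 0.4),
        "ReadPosRankSum": ("normal", 0.0, 1.0),
        "FS": ("truncnorm0", 1.5, 1.5),
        "SOR": ("truncnorm0", 1.0, 0.4),
        "DP": ("truncnorm0", 90.0, 25.0),
    },
    "other": {
        "QD": ("truncnorm0", 8.0, 6.0),
        "MQ": ("truncnorm0", 48.0, 8.0),
        "MQRankSum": ("normal", -1.2, 1.8),
        "ReadPosRankSum": ("normal", 0.8, 1.6),
        "FS": ("truncnorm0", 8.0, 8.0),
        "SOR": ("truncnorm0", 2.2, 1.0),
        "DP": ("truncnorm0", 60.0, 40.0),
    },
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study-scale defaults
    (three diploid query samples, 10,000 sites, two source populations
    of 100 samples)."""

    seed: int
    n_samples: int = 3
    n_sites: int = 10_000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 50_000_000, "chr2": 40_000_000})
    true_fraction: float = 0.6
    metric_models: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_METRIC_MODELS.items()})
    indel_fraction: float = 0.03
    multiallelic_fraction: float = 0.05
    nonautosomal_fraction: float = 0.0
    missing_qd_fraction: float = 0.0
    zero_dp_fraction: float = 0.0
    zero_ad_fraction: float = 0.0
    missing_gt_fraction: float = 0.0
    # panels
    panel_overlap: float = 0.93
    panel_extra_fraction: float = 0.2
    panel_fail_fraction: float = 0.0
    panel_excluded_chrom: str = "chrY"
    # populations (Balding-Nichols)
    fst: float = 0.1
    n_pop_samples: int = 100
    pca_n_sites: int = 5_000
    maf_floor: float = 0.05
    admixture_alphas: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    # gene models
    gene_model_count: int = 20
    gene_chrom: str = "chr21"
    gene_chrom_length: int = 300_000
    gene_site_fraction: float = 0.05
    planted_exon_snvs: int = 200
    nonsense_fraction: float = 0.01
    nonsense_enrichment: float = 4.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        bad = []
        fracs = ["true_fraction", "indel_fraction", "multiallelic_fraction",
                 "nonautosomal_fraction", "missing_qd_fraction",
                 "zero_dp_fraction", "zero_ad_fraction",
                 "missing_gt_fraction", "panel_overlap",
                 "panel_extra_fraction", "panel_fail_fraction",
                 "gene_site_fraction"]
        for name in fracs:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad.append(name)
        if not 0.0 < self.fst < 1.0:
            bad.append("fst")
        if not isinstance(self.seed, (int, np.integer)):
            bad.append("seed")
        if not 0 < self.maf_floor < 0.5:
            bad.append("maf_floor")
        for name in ["n_samples", "n_sites", "n_pop_samples", "pca_n_sites",
                     "gene_model_count"]:
            if getattr(self, name) < 1:
                bad.append(name)
        if bad:
            raise SimulationConfigError(
                f"invalid configuration fields: {sorted(set(bad))}")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator."""
        return np.random.default_rng([self.seed, stream])

    def all_chrom_lengths(self, with_gene_chrom: bool = False) -> dict[str, int]:
        out = dict(self.chrom_lengths)
        if with_gene_chrom:
            out[self.gene_chrom] = self.gene_chrom_length
        return out


@dataclass
class GroundTruth:
    """Per-site and per-allele ground truth emitted with the cohort."""

    site_labels: dict[tuple[str, int], str] = field(default_factory=dict)
    snv_allele_keys: list[AlleleKey] = field(default_factory=list)
    panel_membership: dict[str, set[AlleleKey]] = field(default_factory=dict)
    panel_fail: dict[str, set[AlleleKey]] = field(default_factory=dict)
    expected_novel_fraction: dict[str, float] = field(default_factory=dict)


def _draw_metric(rng, family: str, mean: float, sd: float) -> float:
    v = rng.normal(mean, sd)
    if family == "truncnorm0":
        v = max(0.0, v)
    return round(float(v), 3)


def _random_base(rng, exclude: str | None = None) -> str:
    choices = [b for b in "ACGT" if b != exclude]
    return str(rng.choice(choices))


def simulate_cohort_vcf(
    config: SimulationConfig,
    out_path: str | Path,
    genome: Mapping[str, str] | None = None,
) -> tuple[Path, GroundTruth]:
    """Write the synthetic multi-sample cohort VCF.

    Site metrics are drawn from the class-conditional models; genotypes,
    AD/DP/GQ/RGQ follow a simple depth model.  When a toy ``genome`` is
    given, ``gene_site_fraction`` of sites are placed on the gene-model
    chromosome with reference bases taken from that genome so annotation
    has something to chew on.
    """
    rng = config.rng(1)
    lengths = dict(config.chrom_lengths)
    n_gene_sites = 0
    if genome is not None and config.gene_site_fraction > 0:
        n_gene_sites = int(round(config.gene_site_fraction * config.n_sites))
        lengths[config.gene_chrom] = config.gene_chrom_length
    n_main = config.n_sites - n_gene_sites
    total_len = sum(config.chrom_lengths.values())

    chrom_pos: list[tuple[str, int]] = []
    remaining = n_main
    items = sorted(config.chrom_lengths.items())
    for i, (chrom, length) in enumerate(items):
        n_c = (remaining if i == len(items) - 1
               else int(round(n_main * length / total_len)))
        remaining -= n_c
        pos = set()
        while len(pos) < n_c:
            pos.update(rng.integers(1, length + 1,
                                    size=n_c - len(pos)).tolist())
        chrom_pos.extend((chrom, p) for p in sorted(pos))
    if n_gene_sites:
        pos = set()
        while len(pos) < n_gene_sites:
            pos.update(rng.integers(1, config.gene_chrom_length + 1,
                                    size=n_gene_sites - len(pos)).tolist())
        chrom_pos.extend((config.gene_chrom, p) for p in sorted(pos))

    truth = GroundTruth()
    records: list[SiteRecord] = []
    n = len(chrom_pos)
    labels = np.where(rng.random(n) < config.true_fraction, "true", "other")
    kinds = rng.random(n)
    non_auto = rng.random(n) < config.nonautosomal_fraction
    miss_qd = rng.random(n) < config.missing_qd_fraction
    zero_dp = rng.random(n) < config.zero_dp_fraction
    zero_ad = rng.random(n) < config.zero_ad_fraction
    miss_gt = rng.random(n) < config.missing_gt_fraction

    for i, (chrom, pos) in enumerate(chrom_pos):
        if non_auto[i]:
            chrom = "chrX" if rng.random() < 0.5 else "chrY"
            pos = int(rng.integers(1, 1_000_001))
        if genome is not None and chrom == config.gene_chrom:
            ref = genome[chrom][pos - 1]
        else:
            ref = _random_base(rng)
        is_indel = kinds[i] < config.indel_fraction
        is_multi = (not is_indel and
                    kinds[i] < config.indel_fraction + config.multiallelic_fraction)
        if is_indel:
            if rng.random() < 0.5:
                alts = [ref + _random_base(rng)]          # insertion
            else:
                ref = ref + _random_base(rng)
                alts = [ref[0]]                            # deletion
        elif is_multi:
            a1 = _random_base(rng, exclude=ref)
            a2 = _random_base(rng, exclude=ref)
            while a2 == a1:
                a2 = _random_base(rng, exclude=ref)
            alts = [a1, a2]
        else:
            alts = [_random_base(rng, exclude=ref)]

        label = str(labels[i])
        metrics = {
            m: _draw_metric(rng, *params)
            for m, params in config.metric_models[label].items()
        }
        if "DP" in metrics:
            metrics["DP"] = float(int(round(metrics["DP"])))
        if miss_qd[i]:
            metrics.pop("QD", None)

        n_alleles = 1 + len(alts)
        if n_alleles == 2:
            p = rng.uniform(0.15, 0.85)
            gts = rng.binomial(2, p, size=config.n_samples)
            if gts.sum() == 0:
                gts[int(rng.integers(config.n_samples))] = 1
            gt_pairs = [((0, 0), (0, 1), (1, 1))[g] for g in gts]
        else:
            probs = rng.dirichlet([4.0, 2.0, 2.0])
            draws = rng.choice(3, size=(config.n_samples, 2), p=probs)
            if not (draws == 1).any():
                draws[0, 0] = 1
            if not (draws == 2).any():
                draws[-1, 1] = 2
            gt_pairs = [tuple(sorted(d)) for d in draws]

        samples = []
        for s_idx in range(config.n_samples):
            gt = gt_pairs[s_idx]
            dp = int(rng.poisson(30)) + 1
            if zero_dp[i]:
                dp = 0
            ad = [0] * n_alleles
            for a in range(n_alleles):
                copies = sum(1 for g in gt if g == a)
                if copies and dp:
                    ad[a] = int(rng.binomial(dp, min(0.95, 0.5 * copies)))
            if sum(ad) > dp and dp:
                scale = dp / sum(ad)
                ad = [int(x * scale) for x in ad]
            if zero_ad[i]:
                ad = [ad[0]] + [0] * len(alts)
            hom_ref = gt == (0, 0)
            gq = int(np.clip(rng.normal(70, 20), 1, 99))
            call = SampleCall(
                gt=None if (miss_gt[i] and s_idx == 0) else gt,
                ad=tuple(ad),
                dp=dp,
                gq=None if hom_ref else gq,
                rgq=gq if hom_ref else None,
            )
            samples.append(call)

        rec = SiteRecord(
            chrom=chrom, pos=pos, ref=ref, alts=alts,
            qual=round(float(abs(rng.normal(500, 300))), 1),
            filter=[], metrics=metrics, samples=samples)
        records.append(rec)
        truth.site_labels[(chrom, pos)] = label
        if len(ref) == 1:
            for alt in alts:
                if len(alt) == 1:
                    truth.snv_allele_keys.append((chrom, pos, ref, alt))

    path = write_vcf(records, out_path,
                     sample_names=[f"M{i + 1}" for i in range(config.n_samples)])
    return path, truth


def _alleles_to_records(alleles: Sequence[tuple[AlleleKey, bool]],
                        merge_multiallelic: bool) -> list[SiteRecord]:
    """Panel alleles -> sites-only records; optionally merged into
    multiallelic lines at shared (chrom, pos, ref)."""
    records = []
    if merge_multiallelic:
        grouped: dict[tuple[str, int, str], list[str]] = {}
        for (chrom, pos, ref, alt), _ in alleles:
            grouped.setdefault((chrom, pos, ref), []).append(alt)
        for (chrom, pos, ref), alts in sorted(grouped.items()):
            records.append(SiteRecord(chrom=chrom, pos=pos, ref=ref,
                                      alts=sorted(set(alts)), filter=["PASS"]))
    else:
        for (chrom, pos, ref, alt), passed in sorted(alleles):
            records.append(SiteRecord(
                chrom=chrom, pos=pos, ref=ref, alts=[alt],
                filter=["PASS"] if passed else ["RF"]))
    return records


def simulate_panels(
    config: SimulationConfig,
    truth: GroundTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the truth panel and two reference panels.

    The truth panel holds exactly the SNV alleles of true-labelled sites.
    Reference panel "kg" (multiallelic-merged, no FILTER use) and
    "gnomad" (per-allele lines, FILTER flags, one excluded chromosome)
    each contain ``panel_overlap`` of the assessable cohort SNV alleles
    plus panel-only extras; fail flags are planted on member alleles at
    ``panel_fail_fraction`` (counted novel downstream by default).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = config.rng(2)
    paths: dict[str, Path] = {}

    true_alleles = [k for k in truth.snv_allele_keys
                    if truth.site_labels[(k[0], k[1])] == "true"]
    paths["truth"] = write_vcf(
        _alleles_to_records([(k, True) for k in true_alleles], True),
        outdir / "truth_panel.vcf")

    used_positions = {(k[0], k[1]) for k in truth.snv_allele_keys}

    def extra_alleles(n_extra: int, stream_rng) -> list[AlleleKey]:
        out = []
        chroms = sorted(config.chrom_lengths)
        while len(out) < n_extra:
            chrom = chroms[int(stream_rng.integers(len(chroms)))]
            pos = int(stream_rng.integers(1, config.chrom_lengths[chrom] + 1))
            if (chrom, pos) in used_positions:
                continue
            used_positions.add((chrom, pos))
            ref = _random_base(stream_rng)
            out.append((chrom, pos, ref, _random_base(stream_rng, exclude=ref)))
        return out

    for name, merge, excluded in (
        ("kg", True, frozenset()),
        ("gnomad", False, frozenset({config.panel_excluded_chrom})),
    ):
        assessable = [k for k in truth.snv_allele_keys if k[0] not in excluded]
        n_members = int(round(config.panel_overlap * len(assessable)))
        member_idx = rng.choice(len(assessable), size=n_members, replace=False)
        members = [assessable[i] for i in sorted(member_idx)]
        n_fail = int(round(config.panel_fail_fraction * n_members))
        fail_idx = set(rng.choice(n_members, size=n_fail, replace=False).tolist())
        flagged = [(k, i not in fail_idx) for i, k in enumerate(members)]
        extras = extra_alleles(
            int(round(config.panel_extra_fraction * len(assessable))), rng)
        flagged.extend((k, True) for k in extras)
        paths[name] = write_vcf(
            _alleles_to_records(flagged, merge), outdir / f"panel_{name}.vcf")
        truth.panel_membership[name] = {k for k, p in flagged if p}
        truth.panel_fail[name] = {k for k, p in flagged if not p}
        n_known = sum(1 for k, p in flagged if p and k in set(assessable))
        truth.expected_novel_fraction[name] = (
            (len(assessable) - n_known) / len(assessable))
    return paths


# ---------------------------------------------------------------------------
# Populations (Balding-Nichols)
# ---------------------------------------------------------------------------

@dataclass
class PopulationSim:
    panel: GenotypeMatrix
    panel_populations: dict[str, str]          # sample -> "pop1"/"pop2"
    query: GenotypeMatrix
    query_alphas: dict[str, float]             # sample -> admixture alpha
    ancestral_freq: np.ndarray
    pop_freqs: tuple[np.ndarray, np.ndarray]


def simulate_populations(config: SimulationConfig) -> PopulationSim:
    """Two Balding-Nichols populations and admixed query samples.

    Population frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F) around an
    ancestral frequency p ~ U(maf_floor, 1-maf_floor); genotypes are
    Binomial(2, freq); an alpha-admixed query draws from
    alpha*p_pop1 + (1-alpha)*p_pop2.
    """
    rng = config.rng(3)
    m = config.pca_n_sites
    F = config.fst
    p_anc = rng.uniform(config.maf_floor, 1 - config.maf_floor, size=m)
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    p1 = rng.beta(a, b)
    p2 = rng.beta(a, b)

    site_keys: list[AlleleKey] = []
    pos = 10_000
    for _ in range(m):
        ref = _random_base(rng)
        site_keys.append(("chr1", pos, ref, _random_base(rng, exclude=ref)))
        pos += 1_000

    n = config.n_pop_samples
    g1 = rng.binomial(2, p1, size=(n, m)).astype(float)
    g2 = rng.binomial(2, p2, size=(n, m)).astype(float)
    names = [f"P1_{i + 1:03d}" for i in range(n)] + \
            [f"P2_{i + 1:03d}" for i in range(n)]
    panel = GenotypeMatrix(names, site_keys, np.vstack([g1, g2]))
    pops = {s: ("pop1" if s.startswith("P1") else "pop2") for s in names}

    q_rows, q_names, alphas = [], [], {}
    for alpha in config.admixture_alphas:
        freq = alpha * p1 + (1 - alpha) * p2
        q_rows.append(rng.binomial(2, freq, size=m).astype(float))
        name = f"Q_alpha_{alpha:.2f}"
        q_names.append(name)
        alphas[name] = float(alpha)
    query = GenotypeMatrix(q_names, site_keys, np.vstack(q_rows))
    return PopulationSim(panel, pops, query, alphas, p_anc, (p1, p2))


def query_records_from_matrix(
    query: GenotypeMatrix,
    *,
    qual: float = 100.0,
    dp: int = 30,
    gq: int = 80,
    rgq: int = 80,
) -> list[SiteRecord]:
    """Materialize query genotypes as site records with passing metrics,
    for exercising the query-side filters."""
    records = []
    gt_of = {0.0: (0, 0), 1.0: (0, 1), 2.0: (1, 1)}
    for j, (chrom, pos, ref, alt) in enumerate(query.site_keys):
        col = query.values[:, j]
        hom_ref = bool((col == 0).all())
        samples = [
            SampleCall(
                gt=gt_of[v], dp=dp, gq=gq,
                rgq=rgq if v == 0 else None,
            )
            for v in col
        ]
        records.append(SiteRecord(chrom=chrom, pos=pos, ref=ref, alts=[alt],
                                  qual=qual, samples=samples))
    return records


# ---------------------------------------------------------------------------
# Gene models, toy genome and planted alleles
# ---------------------------------------------------------------------------

@dataclass
class PlantedAllele:
    allele: NormalizedAllele
    expected_class: AnnotationClass
    expected_effect: EffectClass | None = None
    stratum: str | None = None


@dataclass
class GeneSimulation:
    models: list[GeneModel]
    genome: dict[str, str]
    genes_path: Path
    fasta_path: Path
    planted: list[PlantedAllele]


def retranslation_effect(
    model: GeneModel, genome: Mapping[str, str], pos: int, alt: str
) -> EffectClass:
    """Effect of a CDS SNV by translating the whole CDS before and after."""
    positions = model.cds_positions()
    idx = positions.index(pos)
    seq = "".join(genome[model.chrom][p - 1] for p in positions).upper()
    mutated = seq[:idx] + alt.upper() + seq[idx + 1:]
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
        mutated = str(Seq(mutated).reverse_complement())
        idx = len(positions) - 1 - idx
    usable = len(seq) // 3 * 3
    if idx >= usable:
        return EffectClass.unknown
    before = str(Seq(seq[:usable]).translate())
    after = str(Seq(mutated[:usable]).translate())
    if before == after:
        return EffectClass.synonymous
    i = next(i for i, (x, y) in enumerate(zip(before, after)) if x != y)
    if after[i] == "*" and before[i] != "*":
        return EffectClass.stop_gain
    if before[i] == "*" and after[i] != "*":
        return EffectClass.stop_loss
    return EffectClass.nonsynonymous


def _cds_substitutions(
    model: GeneModel, genome: Mapping[str, str]
) -> dict[EffectClass, list[tuple[int, str, str]]]:
    """Enumerate every CDS single-base substitution by effect."""
    by_effect: dict[EffectClass, list[tuple[int, str, str]]] = {
        e: [] for e in EffectClass}
    for pos in model.cds_positions():
        ref = genome[model.chrom][pos - 1].upper()
        for alt in "ACGT":
            if alt == ref:
                continue
            eff = retranslation_effect(model, genome, pos, alt)
            by_effect[eff].append((pos, ref, alt))
    return by_effect


def simulate_gene_models(
    config: SimulationConfig, outdir: str | Path
) -> GeneSimulation:
    """Build the toy genome, transcript models and planted alleles.

    Transcripts are non-overlapping, three exons each, alternating
    coding/non-coding and +/- strand.  Planted alleles cover every
    sequence class, and two strata of exonic SNVs ("base" and "novel")
    carry nonsense changes at ``nonsense_fraction`` and
    ``nonsense_fraction * nonsense_enrichment`` respectively.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = config.rng(4)
    chrom = config.gene_chrom
    L = config.gene_chrom_length
    seq = "".join(rng.choice(_BASES, size=L))
    genome = {chrom: seq}

    exon_len, intron_len, gap = 150, 300, 8_000
    models: list[GeneModel] = []
    cursor = 5_000
    for i in range(config.gene_model_count):
        exons = []
        s = cursor
        for _ in range(3):
            exons.append((s, s + exon_len - 1))
            s += exon_len + intron_len
        coding = i % 2 == 0
        strand = "+" if i % 4 < 2 else "-"
        cds_start = exons[0][0] + 30 if coding else None
        cds_end = exons[-1][1] - 30 if coding else None
        models.append(GeneModel(
            transcript_id=f"TX{i + 1:03d}", gene=f"GENE{i + 1:03d}",
            chrom=chrom, strand=strand, exons=exons,
            cds_start=cds_start, cds_end=cds_end))
        cursor = exons[-1][1] + gap
        if cursor + 3 * (exon_len + intron_len) > L - 5_000:
            break

    planted: list[PlantedAllele] = []

    def plant(pos: int, expected: AnnotationClass, model: GeneModel | None,
              effect: EffectClass | None = None, stratum: str | None = None,
              alt: str | None = None, ref: str | None = None):
        ref = ref or seq[pos - 1]
        alt = alt or _random_base(rng, exclude=ref)
        planted.append(PlantedAllele(
            NormalizedAllele(chrom, pos, ref, alt), expected, effect, stratum))

    coding_models = [m for m in models if m.coding]
    nc_models = [m for m in models if not m.coding]

    for m in coding_models[:3]:
        intron1_start = m.exons[0][1] + 1
        plant(intron1_start + 1, AnnotationClass.splicing, m)      # intron base 2
        plant(m.exons[1][1] + intron_len // 2, AnnotationClass.intronic, m)
        utr_pos = m.exons[0][0] + 5                                 # before CDS
        plant(utr_pos,
              AnnotationClass.UTR5 if m.strand == "+" else AnnotationClass.UTR3,
              m)
        flank_pos = m.tx_start - 200
        plant(flank_pos,
              AnnotationClass.upstream if m.strand == "+"
              else AnnotationClass.downstream, m)
    for m in nc_models[:3]:
        plant(m.exons[1][0] + 10, AnnotationClass.ncRNA_exonic, m)
        plant(m.exons[0][1] + 2, AnnotationClass.ncRNA_splicing, m)
        plant(m.exons[1][1] + intron_len // 2, AnnotationClass.ncRNA_intronic, m)
    # intergenic: midway through the gap after the first transcript
    plant(models[0].tx_end + gap // 2, AnnotationClass.intergenic, None)

    # exonic effect strata
    sub_catalogue = {m.transcript_id: _cds_substitutions(m, genome)
                     for m in coding_models}
    used: set[int] = set()
    for stratum, rate in (
        ("base", config.nonsense_fraction),
        ("novel", min(1.0, config.nonsense_fraction * config.nonsense_enrichment)),
    ):
        n_planted = 0
        attempts = 0
        while n_planted < config.planted_exon_snvs and attempts < 50_000:
            attempts += 1
            m = coding_models[int(rng.integers(len(coding_models)))]
            want_nonsense = rng.random() < rate
            pool_key = (EffectClass.stop_gain if want_nonsense else
                        (EffectClass.synonymous if rng.random() < 0.4
                         else EffectClass.nonsynonymous))
            pool = sub_catalogue[m.transcript_id][pool_key]
            if not pool:
                continue
            pos, ref, alt = pool[int(rng.integers(len(pool)))]
            if pos in used:
                continue
            used.add(pos)
            plant(pos, AnnotationClass.exonic, m, pool_key, stratum,
                  alt=alt, ref=ref)
            n_planted += 1

    genes_path = write_gene_table(models, outdir / "genes.txt")
    fasta_path = outdir / "toy_genome.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, L, 60):
            fh.write(seq[i:i + 60] + "\n")
    return GeneSimulation(models, genome, genes_path, fasta_path, planted)
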