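"""Functional annotation of SNV alleles against transcript models.

Each allele is annotated against every overlapping or flanking transcript
and the multiple annotations are collapsed to a single sequence class and
(for exonic alleles) a single coding effect by two fixed precedence
ladders:

* sequence class, high to low: exonic, splicing (first or last two bases
  of an intron of a coding transcript), ncRNA_exonic, ncRNA_splicing,
  UTR5, UTR3, intronic, ncRNA_intronic, upstream, downstream, intergenic;
* exonic effect, high to low: stop_gain, stop_loss, nonsynonymous,
  synonymous, unknown.

"exonic" and "splicing" share the top tier conceptually; exonic is ranked
above splicing so that every allele resolves to exactly one class.
"""

from __future__ import annotations

import enum
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from Bio.Seq import Seq

from popnovel.vcf_io import NormalizedAllele

AlleleKey = tuple[str, int, str, str]
GenomeLookup = Callable[[str, int], str]


class AnnotationClass(enum.IntEnum):
    """Sequence classes; smaller value = higher precedence."""

    exonic = 0
    splicing = 1
    ncRNA_exonic = 2
    ncRNA_splicing = 3
    UTR5 = 4
    UTR3 = 5
    intronic = 6
    ncRNA_intronic = 7
    upstream = 8
    downstream = 9
    intergenic = 10


class EffectClass(enum.IntEnum):
    """Coding effects; smaller value = higher precedence."""

    stop_gain = 0
    stop_loss = 1
    nonsynonymous = 2
    synonymous = 3
    unknown = 4


#: Bases of an intron (from either end) that count as splice-site.
SPLICE_BASES = 2


class AnnotationError(ValueError):
    pass


class DataInconsistencyError(ValueError):
    """Reference base in the allele disagrees with the genome sequence."""


@dataclass
class GeneModel:
    """One transcript: exons as 1-based inclusive intervals plus an
    optional CDS span.  ``cds_start``/``cds_end`` are ``None`` for
    non-coding transcripts."""

    transcript_id: str
    gene: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must be set together")
        if self.coding and not (
            self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end
        ):
            raise ValueError(f"{self.transcript_id}: CDS outside exon span")

    @property
    def coding(self) -> bool:
        return self.cds_start is not None

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    def cds_positions(self) -> list[int]:
        """Genomic positions of the CDS in genomic order."""
        if not self.coding:
            return []
        out = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                out.extend(range(lo, hi + 1))
        return out


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read transcript models from a 12-column refFlat-like TSV.

    Columns: gene, transcript, chrom, strand, txStart, txEnd, cdsStart,
    cdsEnd, exonCount, exonStarts (comma-joined), exonEnds, biotype
    (``coding``/``noncoding``).  Starts are 0-based and ends half-open,
    as in refFlat; they are converted to 1-based inclusive internally.
    """
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, "
                                 f"got {len(parts)}")
            (gene, tx, chrom, strand, _txs, _txe, cdss, cdse,
             n_exons, ex_starts, ex_ends, biotype) = parts
            starts = [int(x) for x in ex_starts.rstrip(",").split(",")]
            ends = [int(x) for x in ex_ends.rstrip(",").split(",")]
            if len(starts) != int(n_exons) or len(ends) != int(n_exons):
                raise ValueError(f"{path}:{lineno}: exon count mismatch")
            exons = [(s + 1, e) for s, e in zip(starts, ends)]
            coding = biotype == "coding" and int(cdss) < int(cdse)
            models.append(GeneModel(
                transcript_id=tx, gene=gene, chrom=chrom, strand=strand,
                exons=exons,
                cds_start=int(cdss) + 1 if coding else None,
                cds_end=int(cdse) if coding else None,
            ))
    return models


def write_gene_table(models: Sequence[GeneModel], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for m in models:
            starts = ",".join(str(s - 1) for s, _ in m.exons)
            ends = ",".join(str(e) for _, e in m.exons)
            cdss = m.cds_start - 1 if m.coding else m.tx_start - 1
            cdse = m.cds_end if m.coding else m.tx_start - 1
            fh.write("\t".join(map(str, [
                m.gene, m.transcript_id, m.chrom, m.strand,
                m.tx_start - 1, m.tx_end, cdss, cdse, len(m.exons),
                starts, ends, "coding" if m.coding else "noncoding",
            ])) + "\n")
    return path


class GeneModelIndex:
    """Searchable per-chromosome collection of transcripts."""

    def __init__(self, models: Iterable[GeneModel]):
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for m in models:
            self._by_chrom.setdefault(m.chrom, []).append(m)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda m: (m.tx_start, m.tx_end))

    def candidates(self, chrom: str, pos: int, flank_bp: int) -> list[GeneModel]:
        return [
            m for m in self._by_chrom.get(chrom, [])
            if m.tx_start - flank_bp <= pos <= m.tx_end + flank_bp
        ]


@dataclass
class TranscriptAnnotation:
    """One allele's annotation against one transcript (``model`` is
    ``None`` for the intergenic placeholder)."""

    model: GeneModel | None
    klass: AnnotationClass
    effect: EffectClass | None = None


def _classify_in_transcript(pos: int, m: GeneModel) -> AnnotationClass:
    for i, (s, e) in enumerate(m.exons):
        if s <= pos <= e:
            if not m.coding:
                return AnnotationClass.ncRNA_exonic
            if m.cds_start <= pos <= m.cds_end:
                return AnnotationClass.exonic
            if pos < m.cds_start:
                return (AnnotationClass.UTR5 if m.strand == "+"
                        else AnnotationClass.UTR3)
            return (AnnotationClass.UTR3 if m.strand == "+"
                    else AnnotationClass.UTR5)
    # intronic: locate the surrounding exon pair
    for (s1, e1), (s2, e2) in zip(m.exons, m.exons[1:]):
        if e1 < pos < s2:
            near_edge = pos <= e1 + SPLICE_BASES or pos >= s2 - SPLICE_BASES
            if m.coding:
                return (AnnotationClass.splicing if near_edge
                        else AnnotationClass.intronic)
            return (AnnotationClass.ncRNA_splicing if near_edge
                    else AnnotationClass.ncRNA_intronic)
    raise AssertionError("position inside span but in no exon or intron")


def annotate_allele(
    allele: NormalizedAllele,
    index: GeneModelIndex,
    *,
    flank_bp: int = 1000,
    genome_lookup: GenomeLookup | None = None,
) -> list[TranscriptAnnotation]:
    """Per-transcript annotations for a single-base substitution.

    When ``genome_lookup`` is provided, coding-exonic annotations also
    carry the codon-level effect.
    """
    if not allele.is_snv():
        raise AnnotationError(f"only SNVs are annotated, got {allele}")
    pos = allele.pos
    out: list[TranscriptAnnotation] = []
    for m in index.candidates(allele.chrom, pos, flank_bp):
        if m.tx_start <= pos <= m.tx_end:
            klass = _classify_in_transcript(pos, m)
        elif pos < m.tx_start:
            klass = (AnnotationClass.upstream if m.strand == "+"
                     else AnnotationClass.downstream)
        else:
            klass = (AnnotationClass.downstream if m.strand == "+"
                     else AnnotationClass.upstream)
        effect = None
        if klass is AnnotationClass.exonic and genome_lookup is not None:
            effect = effect_of(allele, m, genome_lookup)
        out.append(TranscriptAnnotation(m, klass, effect))
    if not out:
        out.append(TranscriptAnnotation(None, AnnotationClass.intergenic))
    return out


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def effect_of(
    allele: NormalizedAllele, model: GeneModel, genome_lookup: GenomeLookup
) -> EffectClass:
    """Codon-level effect of a CDS SNV under the standard genetic code.

    The codon containing the allele is translated before and after the
    substitution with strand-aware complementing.  A codon truncated at a
    CDS edge yields ``unknown``.
    """
    if not model.coding:
        raise AnnotationError(f"{model.transcript_id} is non-coding")
    cds = model.cds_positions()
    if allele.pos not in cds:
        raise AnnotationError(
            f"{allele.chrom}:{allele.pos} not in CDS of {model.transcript_id}")
    ref_base = genome_lookup(allele.chrom, allele.pos).upper()
    if ref_base != allele.ref:
        raise DataInconsistencyError(
            f"reference mismatch at {allele.chrom}:{allele.pos}: "
            f"allele says {allele.ref}, genome says {ref_base}")
    if model.strand == "-":
        cds = cds[::-1]
    idx = cds.index(allele.pos)
    codon_positions = cds[(idx // 3) * 3: (idx // 3) * 3 + 3]
    if len(codon_positions) < 3:
        return EffectClass.unknown
    bases = [genome_lookup(allele.chrom, p).upper() for p in codon_positions]
    alt = allele.alt
    if model.strand == "-":
        bases = [b.translate(_COMPLEMENT) for b in bases]
        alt = alt.translate(_COMPLEMENT)
    old_codon = "".join(bases)
    new_bases = list(bases)
    new_bases[idx % 3] = alt
    new_codon = "".join(new_bases)
    old_aa = str(Seq(old_codon).translate())
    new_aa = str(Seq(new_codon).translate())
    if new_aa == "*" and old_aa != "*":
        return EffectClass.stop_gain
    if old_aa == "*" and new_aa != "*":
        return EffectClass.stop_loss
    if old_aa == new_aa:
        return EffectClass.synonymous
    return EffectClass.nonsynonymous


@dataclass
class AnnotationResult:
    """The single precedence-resolved class (and effect) for one allele."""

    allele: NormalizedAllele
    per_transcript: list[TranscriptAnnotation]
    klass: AnnotationClass
    effect: EffectClass | None


def resolve_precedence(
    allele: NormalizedAllele, annotations: Sequence[TranscriptAnnotation]
) -> AnnotationResult:
    """Collapse per-transcript annotations to one class and effect.

    The class is the highest-precedence class across transcripts; the
    effect is resolved only when the class is exonic, as the highest-
    precedence effect across coding-exonic annotations.
    """
    if not annotations:
        raise AnnotationError("empty annotation list")
    klass = min(a.klass for a in annotations)
    effect = None
    if klass is AnnotationClass.exonic:
        effects = [a.effect for a in annotations
                   if a.klass is AnnotationClass.exonic and a.effect is not None]
        if effects:
            effect = min(effects)
    return AnnotationResult(allele, list(annotations), klass, effect)


def annotate_alleles(
    alleles: Iterable[NormalizedAllele],
    models: Sequence[GeneModel] | GeneModelIndex,
    *,
    flank_bp: int = 1000,
    genome_lookup: GenomeLookup | None = None,
) -> list[AnnotationResult]:
    index = models if isinstance(models, GeneModelIndex) else GeneModelIndex(models)
    return [
        resolve_precedence(
            a, annotate_allele(a, index, flank_bp=flank_bp,
                               genome_lookup=genome_lookup))
        for a in alleles
    ]


def summarize_classes(
    results: Sequence[AnnotationResult],
    subsets: Mapping[str, set[AlleleKey] | None] | None = None,
):
    """Counts and percentages per class per subset (and per effect among
    exonic alleles).  ``None`` as a subset means all alleles."""
    import pandas as pd

    if subsets is None:
        subsets = {"all": None}
    rows = []
    for name, keys in subsets.items():
        chosen = [r for r in results if keys is None or r.allele.key in keys]
        n = len(chosen)
        for klass in AnnotationClass:
            count = sum(1 for r in chosen if r.klass is klass)
            rows.append({
                "subset": name, "ladder": "sequence_class",
                "category": klass.name, "count": count,
                "percent": 100.0 * count / n if n else 0.0})
        exonic = [r for r in chosen if r.klass is AnnotationClass.exonic
                  and r.effect is not None]
        n_ex = len(exonic)
        for eff in EffectClass:
            count = sum(1 for r in exonic if r.effect is eff)
            rows.append({
                "subset": name, "ladder": "exonic_effect",
                "category": eff.name, "count": count,
                "percent": 100.0 * count / n_ex if n_ex else 0.0})
    return pd.DataFrame(rows)


def fasta_lookup(fasta) -> GenomeLookup:
    """Wrap a ``pyfaidx.Fasta`` (or dict of sequences) as a base lookup."""
    if isinstance(fasta, dict):
        return lambda chrom, pos: fasta[chrom][pos - 1].upper()
    return lambda chrom, pos: str(fasta[chrom][pos - 1]).upper()
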