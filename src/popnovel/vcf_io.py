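"""VCF/BED input-output, the site data model, and allele normalization.

The data model is deliberately narrow: one multi-sample VCF site with the
seven site metrics used for quality control (QD, MQ, MQRankSum,
ReadPosRankSum, FS, SOR, DP) and the per-sample fields GT, AD, DP, GQ and
RGQ.  Multiallelic sites are split into per-allele records and indels are
left-aligned to their minimal representation so alleles can be compared
across call sets by exact (chrom, pos, ref, alt) identity.

External coordinates follow the VCF convention (1-based inclusive);
interval arithmetic on masks follows the BED convention (0-based
half-open).
"""

from __future__ import annotations

import gzip
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pysam

#: Site-level INFO metrics carried by :class:`SiteRecord`.
METRIC_NAMES = ("QD", "MQ", "MQRankSum", "ReadPosRankSum", "FS", "SOR", "DP")

#: Sentinel allele index used after multiallelic splitting for a genotype
#: that carries a *different* alternative allele than the one kept in the
#: split record.  Such haplotypes are non-reference but contribute zero
#: copies to the focal allele's count.
OTHER_ALT = -2

_DNA = frozenset("ACGTN")


class VcfParseError(ValueError):
    """Raised when a VCF file cannot be parsed; names the offending record."""


class BedParseError(ValueError):
    """Raised for malformed BED input."""


@dataclass
class SampleCall:
    """Genotype data for one sample at one site.

    ``gt`` is a pair of allele indices (0 = ref, 1.. = alts, ``OTHER_ALT``
    after splitting) or ``None`` when the genotype is missing.  ``ad`` is
    the per-allele read depth in allele order.
    """

    gt: tuple[int, int] | None = None
    ad: tuple[int, ...] | None = None
    dp: int | None = None
    gq: int | None = None
    rgq: int | None = None

    def __post_init__(self) -> None:
        if self.ad is not None:
            self.ad = tuple(int(a) for a in self.ad)
            if any(a < 0 for a in self.ad):
                raise ValueError("negative allele depth")
        if self.dp is not None and self.dp < 0:
            raise ValueError("negative depth")

    def is_missing(self) -> bool:
        return self.gt is None

    def allele_copies(self, allele_index: int) -> int:
        """Number of copies of ``allele_index`` carried (0 if missing)."""
        if self.gt is None:
            return 0
        return sum(1 for a in self.gt if a == allele_index)


@dataclass
class SiteRecord:
    """One VCF site: position, alleles, site metrics and sample calls."""

    chrom: str
    pos: int
    ref: str
    alts: list[str]
    id: str | None = None
    qual: float | None = None
    filter: list[str] = field(default_factory=list)
    metrics: dict[str, float] = field(default_factory=dict)
    samples: list[SampleCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        self.ref = self.ref.upper()
        self.alts = [a.upper() for a in self.alts]
        if not self.alts:
            raise ValueError("at least one alternative allele required")
        for a in (self.ref, *self.alts):
            if not a or not set(a) <= _DNA:
                raise ValueError(f"invalid allele string {a!r}")
        unknown = set(self.metrics) - set(METRIC_NAMES)
        if unknown:
            raise ValueError(f"unsupported metrics: {sorted(unknown)}")

    def is_snv(self) -> bool:
        """True when ref and every alt are single bases."""
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    def key(self) -> tuple[str, int, str, tuple[str, ...]]:
        return (self.chrom, self.pos, self.ref, tuple(self.alts))


@dataclass(frozen=True, order=True)
class NormalizedAllele:
    """An atomic (chrom, pos, ref, alt) after splitting and left alignment."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("position must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if min(len(self.ref), len(self.alt)) > 1 and self.ref[-1] == self.alt[-1]:
            raise ValueError("allele is not in minimal representation")

    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


class MaskRegions:
    """Per-chromosome sets of 0-based half-open intervals (e.g. a strict
    accessibility mask).  Intervals are merged at construction."""

    def __init__(self, intervals: dict[str, Iterable[tuple[int, int]]] | None = None):
        self._ivals: dict[str, list[tuple[int, int]]] = {}
        self._starts: dict[str, list[int]] = {}
        for chrom, ivs in (intervals or {}).items():
            self._ivals[chrom] = self._merge(ivs)
            self._starts[chrom] = [s for s, _ in self._ivals[chrom]]

    @staticmethod
    def _merge(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
        out: list[tuple[int, int]] = []
        for s, e in sorted(ivs):
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        return out

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        return list(self._ivals.get(chrom, []))

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect_right(starts, pos - 1) - 1
        if i < 0:
            return False
        s, e = self._ivals[chrom][i]
        return s <= pos - 1 < e


def _short_float(v: float | None) -> float | None:
    """Round-trip a value through float32 and back to its shortest decimal.

    htslib stores QUAL and Float INFO values as 32-bit floats; taking the
    shortest decimal representation makes parse-write-parse a fixed point.
    """
    if v is None:
        return None
    return float(np.format_float_positional(np.float32(v), unique=True, trim="-"))


def _tuple_or_none(v) -> tuple | None:
    if v is None:
        return None
    t = tuple(v)
    if not t or all(x is None for x in t):
        return None
    return t


def read_vcf(path: str | Path) -> Iterator[SiteRecord]:
    """Stream :class:`SiteRecord` objects from a plain or gzipped VCF.

    Absent INFO/FORMAT fields map to absent metric keys / ``None`` sample
    fields.  Raises :class:`VcfParseError` naming the record number on
    malformed input.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: cannot parse VCF header: {exc}") from exc
    n = 0
    try:
        for rec in vf:
            n += 1
            try:
                yield _to_site_record(rec)
            except (ValueError, KeyError, TypeError) as exc:
                raise VcfParseError(
                    f"{path}: malformed record #{n} at "
                    f"{rec.chrom}:{rec.pos}: {exc}"
                ) from exc
    finally:
        vf.close()


def _to_site_record(rec: pysam.VariantRecord) -> SiteRecord:
    metrics: dict[str, float] = {}
    for m in METRIC_NAMES:
        if m in rec.info:
            v = rec.info[m]
            if isinstance(v, tuple):
                v = v[0]
            if v is not None:
                metrics[m] = _short_float(float(v))
    samples = []
    for s in rec.samples.values():
        gt = _tuple_or_none(s.get("GT"))
        if gt is not None and any(a is None for a in gt):
            gt = None
        ad = _tuple_or_none(s.get("AD"))
        samples.append(
            SampleCall(
                gt=gt,
                ad=ad,
                dp=s.get("DP"),
                gq=s.get("GQ"),
                rgq=s.get("RGQ"),
            )
        )
    filters = list(rec.filter.keys())
    return SiteRecord(
        chrom=rec.chrom,
        pos=rec.pos,
        id=rec.id,
        ref=rec.ref,
        alts=list(rec.alts or []),
        qual=_short_float(rec.qual),
        filter=filters,
        metrics=metrics,
        samples=samples,
    )


def vcf_sample_names(path: str | Path) -> list[str]:
    with pysam.VariantFile(str(path)) as vf:
        return list(vf.header.samples)


_INFO_TYPES = {m: ("Integer" if False else "Float") for m in METRIC_NAMES}


def _build_header(
    records: Sequence[SiteRecord], sample_names: Sequence[str]
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    seen: list[str] = []
    filters: list[str] = []
    for r in records:
        if r.chrom not in seen:
            seen.append(r.chrom)
        for f in r.filter:
            if f not in filters and f != "PASS":
                filters.append(f)
    for chrom in seen:
        header.contigs.add(chrom)
    for m in METRIC_NAMES:
        # site-level DP is integral in practice; Integer avoids a header
        # type clash with the FORMAT DP field
        header.info.add(m, 1, "Integer" if m == "DP" else "Float",
                        f"Site metric {m}")
    for f in filters:
        header.filters.add(f, None, None, f"Filter flag {f}")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("RGQ", 1, "Integer", "Reference genotype quality")
    for name in sample_names:
        header.add_sample(name)
    return header


def write_vcf(
    records: Iterable[SiteRecord],
    path: str | Path,
    sample_names: Sequence[str] | None = None,
) -> Path:
    """Write records to a VCF (bgzipped when the path ends in ``.gz``).

    ``read_vcf(write_vcf(x))`` reproduces ``x`` field-for-field on the
    supported field set.  Genotype entries equal to :data:`OTHER_ALT`
    (produced by :func:`split_multiallelic`) are emitted as missing
    alleles, since the carried allele is not present in the record.
    """
    records = list(records)
    n_samples = {len(r.samples) for r in records}
    if len(n_samples) > 1:
        raise ValueError(f"inconsistent sample counts across records: {n_samples}")
    n = n_samples.pop() if n_samples else 0
    if sample_names is None:
        sample_names = [f"S{i + 1}" for i in range(n)]
    if len(sample_names) != n and records:
        raise ValueError("sample_names length does not match records")
    header = _build_header(records, sample_names)
    path = Path(path)
    mode = "wz" if path.suffix == ".gz" else "w"
    with pysam.VariantFile(str(path), mode, header=header) as out:
        for r in records:
            rec = out.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                alleles=(r.ref, *r.alts),
                id=r.id,
                qual=r.qual,
            )
            for f in r.filter:
                rec.filter.add(f)
            for m, v in r.metrics.items():
                rec.info[m] = int(round(v)) if m == "DP" else v
            for name, call in zip(sample_names, r.samples):
                out_s = rec.samples[name]
                if call.gt is not None:
                    out_s["GT"] = tuple(
                        None if a == OTHER_ALT else a for a in call.gt
                    )
                else:
                    out_s["GT"] = (None, None)
                if call.ad is not None:
                    out_s["AD"] = call.ad
                if call.dp is not None:
                    out_s["DP"] = call.dp
                if call.gq is not None:
                    out_s["GQ"] = call.gq
                if call.rgq is not None:
                    out_s["RGQ"] = call.rgq
            out.write(rec)
    return path


def split_multiallelic(site: SiteRecord) -> list[SiteRecord]:
    """Split a site into one record per alternative allele.

    Genotypes are recoded relative to the kept allele: 0 stays reference,
    the focal allele becomes 1, and any *other* alternative allele becomes
    :data:`OTHER_ALT` so it contributes nothing to the focal allele's
    count.  AD is subset to (ref, focal).  Biallelic sites are returned
    unchanged (as a singleton list).
    """
    if len(site.alts) == 1:
        return [site]
    out = []
    for j, alt in enumerate(site.alts, start=1):
        samples = []
        for call in site.samples:
            gt = None
            if call.gt is not None:
                gt = tuple(
                    0 if a == 0 else (1 if a == j else OTHER_ALT) for a in call.gt
                )
            ad = None
            if call.ad is not None and len(call.ad) > j:
                ad = (call.ad[0], call.ad[j])
            samples.append(
                SampleCall(gt=gt, ad=ad, dp=call.dp, gq=call.gq, rgq=call.rgq)
            )
        out.append(replace(site, alts=[alt], samples=samples))
    return out


ReferenceLookup = Callable[[str, int], str]


def left_align(
    allele: NormalizedAllele | tuple[str, int, str, str],
    reference_lookup: ReferenceLookup,
) -> NormalizedAllele:
    """Return the minimal left-shifted representation of an allele.

    Implements the standard normalization: trim shared trailing bases
    (extending to the left with reference bases when one allele would
    become empty), then trim shared leading bases, always keeping at least
    one base on each side.  SNVs are fixed points.  Raises ``ValueError``
    when left-extension would run off the start of the chromosome.
    """
    if isinstance(allele, NormalizedAllele):
        chrom, pos, ref, alt = allele.chrom, allele.pos, allele.ref, allele.alt
    else:
        chrom, pos, ref, alt = allele
        ref, alt = ref.upper(), alt.upper()
    if len(ref) == 1 and len(alt) == 1:
        return NormalizedAllele(chrom, pos, ref, alt)
    while True:
        if ref[-1] == alt[-1]:
            if len(ref) > 1 and len(alt) > 1:
                ref, alt = ref[:-1], alt[:-1]
            else:
                if pos <= 1:
                    raise ValueError(
                        f"cannot left-extend past start of {chrom} "
                        f"(pos={pos}, ref={ref}, alt={alt})"
                    )
                base = reference_lookup(chrom, pos - 1).upper()
                ref, alt = base + ref[:-1], base + alt[:-1]
                pos -= 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return NormalizedAllele(chrom, pos, ref, alt)


def normalize_site_alleles(
    site: SiteRecord, reference_lookup: ReferenceLookup | None = None
) -> list[NormalizedAllele]:
    """Split a site and return one normalized allele per alt.

    Without a reference lookup, only trimming that needs no left-extension
    is applied (sufficient for SNVs and padded indel spellings).
    """
    alleles = []
    for rec in split_multiallelic(site):
        ref, alt, pos = rec.ref, rec.alts[0], rec.pos
        if reference_lookup is not None and (len(ref) > 1 or len(alt) > 1):
            alleles.append(left_align((rec.chrom, pos, ref, alt), reference_lookup))
            continue
        # lookup-free trimming: shared trailing then leading bases
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        alleles.append(NormalizedAllele(rec.chrom, pos, ref, alt))
    return alleles


def read_bed(path: str | Path) -> MaskRegions:
    """Read a BED3+ file into :class:`MaskRegions` (merging overlaps)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    intervals: dict[str, list[tuple[int, int]]] = {}
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            intervals.setdefault(chrom, []).append((start, end))
    return MaskRegions(intervals)
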