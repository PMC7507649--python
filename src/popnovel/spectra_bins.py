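"""Allele-count spectra and genomic density binning.

The allele count spectrum tallies, for each non-reference allele, the
number of copies carried across all samples (1..2N for N diploid
samples).  Sites with a missing genotype in any sample are excluded and
counted separately.  Density binning counts SNV *sites* per fixed-size
block (default 10 Mb) along each chromosome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from popnovel.vcf_io import SiteRecord, normalize_site_alleles

AlleleKey = tuple[str, int, str, str]


@dataclass
class AlleleCountSpectrum:
    """Map copies -> number of alleles, plus the missing-genotype tally."""

    counts: dict[int, int] = field(default_factory=dict)
    n_samples: int = 0
    n_sites_excluded_missing: int = 0

    def total_alleles(self) -> int:
        return sum(self.counts.values())

    def as_series(self):
        import pandas as pd

        idx = range(1, 2 * self.n_samples + 1)
        return pd.Series([self.counts.get(i, 0) for i in idx], index=idx,
                         name="n_alleles")


def allele_spectrum(
    records: Sequence[SiteRecord],
    subset: set[AlleleKey] | None = None,
) -> AlleleCountSpectrum:
    """Spectrum of non-reference allele copies across samples.

    ``records`` must share one sample count; multiallelic records are
    split so each alternative allele contributes its own copy count.
    ``subset`` restricts the tally to the given normalized allele keys.
    A site (one split record) with any missing genotype is excluded and
    counted in ``n_sites_excluded_missing``.
    """
    n_set = {len(r.samples) for r in records}
    if len(n_set) > 1:
        raise ValueError(f"records carry inconsistent sample counts: {n_set}")
    n_samples = n_set.pop() if n_set else 0
    spec = AlleleCountSpectrum(n_samples=n_samples)
    for rec in records:
        from popnovel.vcf_io import split_multiallelic

        for split, allele in zip(split_multiallelic(rec),
                                 normalize_site_alleles(rec)):
            if subset is not None and allele.key not in subset:
                continue
            if any(s.gt is None for s in split.samples):
                spec.n_sites_excluded_missing += 1
                continue
            copies = sum(s.allele_copies(1) for s in split.samples)
            if copies > 0:
                spec.counts[copies] = spec.counts.get(copies, 0) + 1
    return spec


@dataclass
class BinDensity:
    """Per-chromosome counts of SNV sites in fixed-size blocks."""

    block_bp: int
    blocks: dict[str, list[int]] = field(default_factory=dict)

    def chrom_total(self, chrom: str) -> int:
        return sum(self.blocks.get(chrom, []))

    def to_frame(self):
        import pandas as pd

        rows = []
        for chrom in sorted(self.blocks):
            for i, c in enumerate(self.blocks[chrom]):
                rows.append({
                    "chrom": chrom, "block": i,
                    "start": i * self.block_bp + 1,
                    "end": (i + 1) * self.block_bp,
                    "n_sites": c})
        return pd.DataFrame(rows, columns=["chrom", "block", "start", "end",
                                           "n_sites"])


def bin_density(
    sites: Iterable[tuple[str, int]],
    chrom_lengths: Mapping[str, int],
    block_bp: int = 10_000_000,
) -> BinDensity:
    """Count sites per block; block i covers 1-based positions
    [i*block_bp + 1, (i+1)*block_bp], final partial block included."""
    density = BinDensity(
        block_bp=block_bp,
        blocks={c: [0] * max(1, math.ceil(l / block_bp))
                for c, l in chrom_lengths.items()},
    )
    for chrom, pos in sites:
        if chrom not in chrom_lengths:
            raise ValueError(f"no length known for chromosome {chrom}")
        if pos > chrom_lengths[chrom] or pos < 1:
            raise ValueError(
                f"{chrom}:{pos} outside chromosome length "
                f"{chrom_lengths[chrom]}")
        density.blocks[chrom][(pos - 1) // block_bp] += 1
    return density
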