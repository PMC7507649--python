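"""Novelty assessment of normalized SNV alleles against reference panels.

An allele is *known* when its exact normalized (chrom, pos, ref, alt)
matches a panel entry whose quality flag qualifies, *novel* otherwise,
and *not assessed* on chromosomes a panel excludes (e.g. a gnomAD-style
panel carries no Y-chromosome calls, so those "could not be compared").

Panel entries flagged as having failed the panel's own quality control
are excluded from the panel by default: a query allele matching only a
failed entry counts as novel (``treat_fail_as="novel"``).  This reduces
the chance that a "novel" call is merely a shared false positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from popnovel.vcf_io import (
    NormalizedAllele,
    ReferenceLookup,
    normalize_site_alleles,
    read_vcf,
)

AlleleKey = tuple[str, int, str, str]

KNOWN = "known"
NOVEL = "novel"
NOT_ASSESSED = "not_assessed"


@dataclass
class ReferencePanel:
    """A reference variant panel: normalized alleles with pass/fail flags.

    ``entries`` maps allele key -> True (passed the panel's QC) or False
    (called but filtered out).  Exact hashed membership comfortably covers
    the 1e8-allele conceptual scale at ~100 bytes/entry; correctness tests
    run far smaller.
    """

    name: str
    entries: dict[AlleleKey, bool] = field(default_factory=dict)
    excluded_chroms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.entries = {
            k: v for k, v in self.entries.items() if k[0] not in self.excluded_chroms
        }
        self._positions = {(c, p) for c, p, _, _ in self.entries}

    def add(self, allele: NormalizedAllele, passed: bool = True) -> None:
        if allele.chrom in self.excluded_chroms:
            return
        self.entries[allele.key] = passed
        self._positions.add((allele.chrom, allele.pos))

    def has_position(self, chrom: str, pos: int) -> bool:
        return (chrom, pos) in self._positions

    def __len__(self) -> int:
        return len(self.entries)


def build_panel(
    vcf_path,
    name: str = "panel",
    *,
    use_filter_column: bool = False,
    excluded_chroms: Iterable[str] = (),
    reference_lookup: ReferenceLookup | None = None,
    snv_only: bool = False,
) -> ReferencePanel:
    """Build a :class:`ReferencePanel` from a panel VCF.

    Alleles are multiallelic-split and left-aligned before storage so
    membership tests agree with normalized query alleles.  When
    ``use_filter_column`` is set, entries whose FILTER is neither PASS nor
    empty are stored with a fail flag.
    """
    panel = ReferencePanel(name, excluded_chroms=frozenset(excluded_chroms))
    for rec in read_vcf(vcf_path):
        passed = (not use_filter_column) or (
            not rec.filter or rec.filter == ["PASS"]
        )
        for allele in normalize_site_alleles(rec, reference_lookup):
            if snv_only and not allele.is_snv():
                continue
            # keep the "worst" flag if an allele is seen twice
            if allele.key in panel.entries:
                passed = passed and panel.entries[allele.key]
            panel.add(allele, passed)
    return panel


@dataclass
class NoveltyResult:
    """Per-allele novelty statuses plus site-level summary counts.

    A *site* is a (chrom, pos) with at least one query allele; a novel
    site carries at least one novel allele.  Sites whose position exists
    in the panel but whose query alleles are all unmatched are tallied as
    "known position, different allele".
    """

    panel_name: str
    status: dict[AlleleKey, str]
    n_novel_sites: int
    n_multiallelic_novel_sites: int
    n_sites_known_position_different_allele: int

    @property
    def n_alleles(self) -> int:
        return len(self.status)

    @property
    def n_assessed(self) -> int:
        return sum(1 for s in self.status.values() if s != NOT_ASSESSED)

    @property
    def n_novel(self) -> int:
        return sum(1 for s in self.status.values() if s == NOVEL)

    @property
    def n_known(self) -> int:
        return sum(1 for s in self.status.values() if s == KNOWN)

    @property
    def novel_fraction(self) -> float:
        """Fraction of *assessed* alleles that are novel."""
        return self.n_novel / self.n_assessed

    def novel_allele_keys(self) -> set[AlleleKey]:
        return {k for k, s in self.status.items() if s == NOVEL}


def assess_novelty(
    query_alleles: Sequence[NormalizedAllele],
    panel: ReferencePanel,
    *,
    treat_fail_as: str = NOVEL,
) -> NoveltyResult:
    """Classify each query allele as known / novel / not assessed.

    ``treat_fail_as`` controls how a query allele matching a fail-flagged
    panel entry is counted; the default (``"novel"``) excludes failed
    panel entries from the comparison.
    """
    if treat_fail_as not in (KNOWN, NOVEL):
        raise ValueError("treat_fail_as must be 'known' or 'novel'")
    status: dict[AlleleKey, str] = {}
    by_site: dict[tuple[str, int], list[str]] = {}
    for a in query_alleles:
        if a.chrom in panel.excluded_chroms:
            st = NOT_ASSESSED
        else:
            flag = panel.entries.get(a.key)
            if flag is None:
                st = NOVEL
            elif flag:
                st = KNOWN
            else:
                st = treat_fail_as
        status[a.key] = st
        by_site.setdefault((a.chrom, a.pos), []).append(st)
    n_novel_sites = 0
    n_multi_novel = 0
    n_diff_allele = 0
    for (chrom, pos), sts in by_site.items():
        if NOVEL in sts:
            n_novel_sites += 1
            if len(sts) > 1:
                n_multi_novel += 1
            if KNOWN not in sts and panel.has_position(chrom, pos):
                n_diff_allele += 1
    return NoveltyResult(
        panel_name=panel.name,
        status=status,
        n_novel_sites=n_novel_sites,
        n_multiallelic_novel_sites=n_multi_novel,
        n_sites_known_position_different_allele=n_diff_allele,
    )


def novelty_table(results: Sequence[NoveltyResult]):
    """Long-format table: chrom, pos, ref, alt, panel_name, status."""
    import pandas as pd

    rows = []
    for res in results:
        for (chrom, pos, ref, alt), st in sorted(res.status.items()):
            rows.append(
                {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                 "panel_name": res.panel_name, "status": st})
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "panel_name", "status"])
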