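"""Ancestry inference by PCA projection onto a reference genotype model.

A high-quality marker set is selected from a reference panel by a filter
cascade (minor allele frequency > 5%, no other variant within 5 bp,
inside an accessibility mask, Hardy-Weinberg exact P >= 1e-6), thinned by
removing regions of extended LD and by sliding-window VIF pruning
(PLINK ``--indep 50 5 2`` semantics), and encoded as 0/1/2 counts of the
alternative allele.  PCA is fitted on the centred and scaled reference
matrix (the `prcomp(center=TRUE, scale=TRUE)` construction) and query
samples are projected with the fitted means, scales and loadings —
never refitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from popnovel.vcf_io import MaskRegions, NormalizedAllele, SiteRecord

AlleleKey = tuple[str, int, str, str]


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Samples x sites matrix of alternative-allele counts (0/1/2).

    Missing genotypes are ``nan``.  ``site_keys`` are normalized allele
    keys in genomic order.
    """

    samples: list[str]
    site_keys: list[AlleleKey]
    values: np.ndarray  # (n_samples, n_sites), float with nan for missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.site_keys)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.site_keys)} sites")
        valid = np.isnan(self.values) | np.isin(self.values, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("genotype values must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.site_keys)

    def subset_sites(self, keys: Sequence[AlleleKey]) -> "GenotypeMatrix":
        index = {k: j for j, k in enumerate(self.site_keys)}
        cols = [index[k] for k in keys]
        return GenotypeMatrix(self.samples, list(keys), self.values[:, cols])

    def allele_frequency(self) -> np.ndarray:
        """Per-site alternative-allele frequency over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0) / 2.0

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        col = self.values[:, j]
        col = col[~np.isnan(col)]
        return (int((col == 0).sum()), int((col == 1).sum()),
                int((col == 2).sum()))

    def impute_missing(self) -> "GenotypeMatrix":
        """Mean-impute missing genotypes per site (values leave {0,1,2};
        returned matrix is for numerical use only)."""
        vals = self.values.copy()
        col_mean = np.nanmean(vals, axis=0)
        ii, jj = np.where(np.isnan(vals))
        vals[ii, jj] = col_mean[jj]
        out = object.__new__(GenotypeMatrix)
        out.samples = list(self.samples)
        out.site_keys = list(self.site_keys)
        out.values = vals
        return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Conditional on the observed allele counts, the probability of each
    possible heterozygote count (same parity as the rare-allele count) is

        P(h) = C(n; (nA-h)/2, h, (na-h)/2) * 2^h * nA! na! / (2n)!

    and the P value is the sum of probabilities not exceeding the
    observed configuration's.  Monomorphic sites return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    if n_A == 0 or n_a == 0:
        return 1.0
    rare = min(n_A, n_a)

    def log_prob(h: int) -> float:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            gammaln(n + 1)
            - gammaln(hom_common + 1) - gammaln(h + 1) - gammaln(hom_rare + 1)
            + h * math.log(2.0)
            + gammaln(n_A + 1) + gammaln(n_a + 1) - gammaln(2 * n + 1)
        )

    hets = range(rare % 2, rare + 1, 2)
    logs = {h: log_prob(h) for h in hets}
    obs = logs[n_Aa]
    # tolerance guards against ties lost to floating-point rounding
    p = sum(math.exp(l) for l in logs.values() if l <= obs + 1e-9)
    return min(1.0, p)


# ---------------------------------------------------------------------------
# Site selection cascade
# ---------------------------------------------------------------------------

@dataclass
class SiteSelectionConfig:
    """Thresholds for reference-side site selection and query-side
    genotype filters."""

    maf_min: float = 0.05
    proximity_bp: int = 5
    hwe_p_min: float = 1e-6
    mask: MaskRegions | None = None
    excluded_regions: list[tuple[str, int, int]] = field(default_factory=list)
    ld_window: int = 50
    ld_step: int = 5
    vif_max: float = 2.0
    qual_min: float = 30.0
    dp_min: int = 10
    rgq_min: int = 20
    gq_min: int = 20

    def __post_init__(self) -> None:
        if self.ld_window <= self.ld_step:
            raise ValueError("ld_window must exceed ld_step")


#: Default extended-LD exclusions (MHC on chr6, the chr8 inversion).
DEFAULT_EXCLUDED_REGIONS = [
    ("chr6", 25_000_000, 35_000_000),
    ("chr8", 7_000_000, 14_000_000),
]


def select_sites(
    panel_matrix: GenotypeMatrix,
    variant_positions: Iterable[tuple[str, int]],
    config: SiteSelectionConfig,
) -> tuple[list[AlleleKey], dict[str, int]]:
    """Apply the reference-side cascade MAF -> proximity -> mask -> HWE.

    ``variant_positions`` is the full variant catalogue (SNVs and indels)
    used for the proximity test; a site within ``proximity_bp`` (<=,
    inclusive) of *another* variant is excluded.  Returns surviving site
    keys in input order plus per-stage attrition counts.
    """
    keys = list(panel_matrix.site_keys)
    attrition: dict[str, int] = {}

    freq = panel_matrix.allele_frequency()
    maf = np.minimum(freq, 1 - freq)
    kept = [k for k, m in zip(keys, maf) if m > config.maf_min]
    attrition["maf"] = len(keys) - len(kept)

    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in variant_positions:
        by_chrom.setdefault(chrom, []).append(pos)
    for lst in by_chrom.values():
        lst.sort()
    survivors = []
    for k in kept:
        chrom, pos = k[0], k[1]
        neighbours = by_chrom.get(chrom, [])
        i = np.searchsorted(neighbours, pos)
        crowded = False
        for j in range(max(0, i - 3), min(len(neighbours), i + 3)):
            if neighbours[j] != pos and abs(neighbours[j] - pos) <= config.proximity_bp:
                crowded = True
                break
        if not crowded:
            survivors.append(k)
    attrition["proximity"] = len(kept) - len(survivors)
    kept = survivors

    if config.mask is not None:
        survivors = [k for k in kept if config.mask.contains(k[0], k[1])]
        attrition["mask"] = len(kept) - len(survivors)
        kept = survivors
    else:
        attrition["mask"] = 0

    index = {k: j for j, k in enumerate(panel_matrix.site_keys)}
    survivors = []
    for k in kept:
        p = hwe_exact_test(*panel_matrix.genotype_counts(index[k]))
        if p >= config.hwe_p_min:
            survivors.append(k)
    attrition["hwe"] = len(kept) - len(survivors)
    kept = survivors

    if not kept:
        raise ValueError("site selection cascade removed every site")
    return kept, attrition


def remove_regions(
    keys: Sequence[AlleleKey], regions: Sequence[tuple[str, int, int]]
) -> list[AlleleKey]:
    """Drop sites inside any (chrom, start, end) region (1-based incl.)."""
    out = []
    for k in keys:
        chrom, pos = k[0], k[1]
        if any(c == chrom and s <= pos <= e for c, s, e in regions):
            continue
        out.append(k)
    return out


# ---------------------------------------------------------------------------
# Query-side filters
# ---------------------------------------------------------------------------

def apply_query_filters(
    query_records: Sequence[SiteRecord],
    selected_sites: Sequence[AlleleKey],
    config: SiteSelectionConfig,
    sample_names: Sequence[str] | None = None,
) -> tuple[GenotypeMatrix, list[tuple[AlleleKey, str]]]:
    """Genotype the query cohort at the selected sites, applying the
    query-side rules.

    A site is dropped when: it is absent or any genotype is missing
    ("uncalled"); its alternative allele differs from the panel's
    ("different_alt"); it is within ``proximity_bp`` of another variant
    position in the query data ("query_proximity"); it is homozygous
    reference in all samples but fails QUAL/DP/RGQ ("homref_quality");
    or it is variant but fails DP/GQ in any sample ("variant_quality").
    The surviving site list is shared by query matrix and PCA model.
    """
    by_pos: dict[tuple[str, int], SiteRecord] = {}
    variant_positions: dict[str, list[int]] = {}
    for rec in query_records:
        by_pos[(rec.chrom, rec.pos)] = rec
        if any(s.gt is not None and any(a > 0 for a in s.gt) for s in rec.samples):
            variant_positions.setdefault(rec.chrom, []).append(rec.pos)
    for lst in variant_positions.values():
        lst.sort()

    kept: list[AlleleKey] = []
    rows: list[list[float]] = []
    excluded: list[tuple[AlleleKey, str]] = []
    sample_count = None
    for key in selected_sites:
        chrom, pos, ref, alt = key
        rec = by_pos.get((chrom, pos))
        if rec is None or any(s.gt is None for s in rec.samples):
            excluded.append((key, "uncalled"))
            continue
        if sample_count is None:
            sample_count = len(rec.samples)
        if rec.ref != ref or list(rec.alts) != [alt]:
            hom_ref_all = all(s.gt == (0, 0) for s in rec.samples)
            if not hom_ref_all:
                excluded.append((key, "different_alt"))
                continue
        neighbours = variant_positions.get(chrom, [])
        i = int(np.searchsorted(neighbours, pos))
        crowded = any(
            neighbours[j] != pos and abs(neighbours[j] - pos) <= config.proximity_bp
            for j in range(max(0, i - 3), min(len(neighbours), i + 3))
        )
        if crowded:
            excluded.append((key, "query_proximity"))
            continue
        hom_ref_all = all(s.gt == (0, 0) for s in rec.samples)
        if hom_ref_all:
            ok = (
                rec.qual is not None and rec.qual >= config.qual_min
                and all(s.dp is not None and s.dp >= config.dp_min
                        for s in rec.samples)
                and all(s.rgq is not None and s.rgq >= config.rgq_min
                        for s in rec.samples)
            )
            if not ok:
                excluded.append((key, "homref_quality"))
                continue
        else:
            ok = all(
                s.dp is not None and s.dp >= config.dp_min
                and s.gq is not None and s.gq >= config.gq_min
                for s in rec.samples
            )
            if not ok:
                excluded.append((key, "variant_quality"))
                continue
        kept.append(key)
        rows.append([float(sum(1 for a in s.gt if a > 0)) for s in rec.samples])
    n = sample_count if sample_count is not None else (
        len(sample_names) if sample_names else 0)
    values = (np.array(rows, dtype=float).T if rows
              else np.empty((n, 0)))
    if sample_names is None:
        sample_names = [f"Q{i + 1}" for i in range(values.shape[0])]
    elif len(sample_names) != values.shape[0]:
        raise ValueError("sample_names length mismatches query records")
    return GenotypeMatrix(list(sample_names), kept, values), excluded


# ---------------------------------------------------------------------------
# LD pruning by variance inflation factor
# ---------------------------------------------------------------------------

def _window_vifs(X: np.ndarray) -> np.ndarray:
    """VIF of each column of a standardized window matrix.

    VIF_j = 1/(1 - R^2_j) equals the j-th diagonal of the inverse
    correlation matrix; perfectly collinear windows give inf.
    """
    m = X.shape[1]
    if m < 2:
        return np.ones(m)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (Z.shape[0] - 1)
    try:
        inv = np.linalg.inv(corr)
        vifs = np.diag(inv).copy()
        if np.any(vifs < 0.999):  # numerically broken inverse
            raise np.linalg.LinAlgError
        return vifs
    except np.linalg.LinAlgError:
        # singular: fall back to per-column regression
        vifs = np.empty(m)
        for j in range(m):
            others = np.delete(Z, j, axis=1)
            beta, *_ = np.linalg.lstsq(others, Z[:, j], rcond=None)
            resid = Z[:, j] - others @ beta
            tss = float(Z[:, j] @ Z[:, j])
            r2 = 1 - float(resid @ resid) / tss if tss > 0 else 0.0
            vifs[j] = math.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
        return vifs


def ld_prune(
    matrix: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    vif_max: float = 2.0,
) -> list[AlleleKey]:
    """Sliding-window VIF pruning (PLINK ``--indep`` semantics).

    Windows of ``window`` consecutive retained sites advance by ``step``;
    within a window the site with the highest VIF is removed (ties broken
    towards the lower genomic position) until all VIFs are at most
    ``vif_max``.  Passes repeat until no site is removed, so pruning an
    already-pruned set is a no-op and the VIF bound holds in every final
    window.
    """
    if window < 2:
        raise ValueError("window must be at least 2")
    if np.isnan(matrix.values).any():
        raise ValueError("ld_prune requires no missing genotypes; impute first")
    order = {k: j for j, k in enumerate(matrix.site_keys)}
    retained = list(matrix.site_keys)
    while True:
        removed_any = False
        start = 0
        while start < len(retained):
            win = retained[start:start + window]
            while len(win) >= 2:
                cols = [order[k] for k in win]
                vifs = _window_vifs(matrix.values[:, cols])
                worst = vifs.max()
                if worst <= vif_max:
                    break
                # highest VIF, ties to the lowest genomic position
                j = int(np.flatnonzero(vifs == worst)[0])
                victim = win[j]
                win.remove(victim)
                retained.remove(victim)
                removed_any = True
            start += step
        if not removed_any:
            break
    return retained


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Per-site means/scales and loadings fitted on a reference matrix."""

    site_keys: list[AlleleKey]
    mean: np.ndarray           # (p,)
    scale: np.ndarray          # (p,)
    loadings: np.ndarray       # (p, k), orthonormal columns
    reference_scores: pd.DataFrame  # samples x PC1..PCk
    singular_values: np.ndarray


def fit_pca(matrix: GenotypeMatrix, k: int = 2) -> PCAModel:
    """PCA of the centred and scaled genotype matrix.

    Columns are centred by their mean and divided by the sample standard
    deviation (n-1 denominator); loadings are the top-k right singular
    vectors.  Zero-variance sites raise an error naming the first such
    site (the MAF filter should have removed them).
    """
    X = matrix.values
    if np.isnan(X).any():
        raise ValueError("fit_pca requires no missing genotypes; impute first")
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    k = min(k, matrix.n_samples, matrix.n_sites)
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    if np.any(scale == 0):
        bad = matrix.site_keys[int(np.flatnonzero(scale == 0)[0])]
        raise ValueError(f"zero-variance site {bad}; exclude monomorphic sites")
    Z = (X - mean) / scale
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = Vt[:k].T
    # deterministic sign: largest-magnitude loading entry positive
    for j in range(loadings.shape[1]):
        i = int(np.abs(loadings[:, j]).argmax())
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
    scores = Z @ loadings
    cols = [f"PC{j + 1}" for j in range(k)]
    return PCAModel(
        site_keys=list(matrix.site_keys),
        mean=mean,
        scale=scale,
        loadings=loadings,
        reference_scores=pd.DataFrame(scores, index=matrix.samples, columns=cols),
        singular_values=S[:k],
    )


def project_samples(model: PCAModel, query: GenotypeMatrix) -> pd.DataFrame:
    """Project query samples with the fitted model (no refitting)."""
    missing = [k for k in model.site_keys if k not in set(query.site_keys)]
    if missing:
        raise ValueError(
            f"query matrix lacks {len(missing)} model sites, e.g. {missing[:3]}")
    q = query.subset_sites(model.site_keys)
    if np.isnan(q.values).any():
        raise ValueError("query matrix has missing genotypes after filtering")
    Z = (q.values - model.mean) / model.scale
    scores = Z @ model.loadings
    return pd.DataFrame(scores, index=query.samples,
                        columns=model.reference_scores.columns)
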