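"""HWE exact test, site selection, LD pruning and PCA projection."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy.stats import spearmanr

from popnovel.ancestry import (
    GenotypeMatrix,
    SiteSelectionConfig,
    apply_query_filters,
    fit_pca,
    hwe_exact_test,
    ld_prune,
    project_samples,
    remove_regions,
    select_sites,
)
from popnovel.vcf_io import MaskRegions, SampleCall, SiteRecord


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Exact-fraction enumeration of the conditional heterozygote
    distribution, independent of the log-gamma implementation."""
    n = n_AA + n_Aa + n_aa
    n_A, n_a = 2 * n_AA + n_Aa, 2 * n_aa + n_Aa
    if n_A == 0 or n_a == 0:
        return 1.0
    rare = min(n_A, n_a)
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        # multinomial count of genotype configurations times 2^h phasings
        weights[h] = Fraction(
            comb(n, h) * comb(n - h, hom_rare) * 2 ** h)
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= obs))


class TestHWE:
    def test_two_hets_among_two_samples(self):
        # 2 A and 2 a alleles in 2 individuals: configurations are
        # {het=2} (modal) and {het=0}; both qualify, so p = 1
        assert hwe_exact_test(0, 2, 0) == pytest.approx(1.0)

    def test_monomorphic_site_p_one(self):
        assert hwe_exact_test(10, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 7) == 1.0

    def test_strong_het_deficit_is_extreme(self):
        assert hwe_exact_test(50, 0, 50) < 1e-20

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 31))
            n_aa = int(rng.integers(0, n + 1))
            n_ab = int(rng.integers(0, n - n_aa + 1))
            n_bb = n - n_aa - n_ab
            got = hwe_exact_test(n_aa, n_ab, n_bb)
            want = hwe_enumeration_oracle(n_aa, n_ab, n_bb)
            assert got == pytest.approx(want, rel=1e-9), (n_aa, n_ab, n_bb)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


def _matrix(values, start_pos=100, spacing=1000):
    values = np.asarray(values, dtype=float)
    keys = [("chr1", start_pos + j * spacing, "A", "C")
            for j in range(values.shape[1])]
    names = [f"S{i}" for i in range(values.shape[0])]
    return GenotypeMatrix(names, keys, values)


class TestSelectSites:
    def _hw_matrix(self, rng, n=200, m=30, maf=0.3):
        vals = rng.binomial(2, maf, size=(n, m)).astype(float)
        return _matrix(vals)

    def test_maf_exactly_at_threshold_excluded(self, rng):
        vals = self._hw_matrix(rng).values
        vals[:, 0] = 0.0
        vals[:20, 0] = 1.0  # 20 het of 200 samples -> MAF exactly 0.05
        mat = _matrix(vals)
        freq = mat.allele_frequency()[0]
        assert min(freq, 1 - freq) == pytest.approx(0.05)
        kept, attrition = select_sites(
            mat, [(k[0], k[1]) for k in mat.site_keys], SiteSelectionConfig())
        assert mat.site_keys[0] not in kept

    def test_proximity_at_exactly_five_bp_excluded(self, rng):
        mat = self._hw_matrix(rng, m=10)
        catalogue = [(k[0], k[1]) for k in mat.site_keys]
        catalogue.append(("chr1", mat.site_keys[3][1] + 5))  # an indel 5 bp away
        kept, attrition = select_sites(mat, catalogue, SiteSelectionConfig())
        assert mat.site_keys[3] not in kept
        assert attrition["proximity"] == 1

    def test_mask_restricts_to_accessible_regions(self, rng):
        mat = self._hw_matrix(rng, m=10)
        first_pos = mat.site_keys[0][1]
        mask = MaskRegions({"chr1": [(first_pos - 1, first_pos + 5000)]})
        cfg = SiteSelectionConfig(mask=mask)
        kept, attrition = select_sites(
            mat, [(k[0], k[1]) for k in mat.site_keys], cfg)
        assert all(mask.contains(k[0], k[1]) for k in kept)
        assert attrition["mask"] > 0

    def test_planted_hwe_violators_removed(self):
        rng = np.random.default_rng(31)
        n, m = 500, 40
        good = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        # inbreeding F=0.5: draw both alleles identical half the time
        p = 0.4
        inbred = np.where(rng.random((n, 5)) < 0.5,
                          2 * rng.binomial(1, p, (n, 5)),
                          rng.binomial(1, p, (n, 5)) + rng.binomial(1, p, (n, 5)))
        mat = _matrix(np.hstack([good, inbred.astype(float)]))
        kept, attrition = select_sites(
            mat, [(k[0], k[1]) for k in mat.site_keys], SiteSelectionConfig())
        violator_keys = set(mat.site_keys[m:])
        assert not violator_keys & set(kept)
        assert attrition["hwe"] >= 5

    def test_attritions_sum_to_input_minus_output(self, rng):
        mat = self._hw_matrix(rng, m=50)
        kept, attrition = select_sites(
            mat, [(k[0], k[1]) for k in mat.site_keys], SiteSelectionConfig())
        assert sum(attrition.values()) == mat.n_sites - len(kept)

    def test_empty_survivor_set_rejected(self, rng):
        vals = np.zeros((50, 5))
        vals[0, :] = 1.0  # MAF 0.01 < 0.05 everywhere
        with pytest.raises(ValueError):
            select_sites(_matrix(vals),
                         [("chr1", 100 + j * 1000) for j in range(5)],
                         SiteSelectionConfig())


def _query_record(key, gts, qual=100.0, dp=30, gq=80, rgq=80):
    chrom, pos, ref, alt = key
    samples = [SampleCall(gt=g, dp=dp, gq=gq,
                          rgq=rgq if g == (0, 0) else None) for g in gts]
    return SiteRecord(chrom=chrom, pos=pos, ref=ref, alts=[alt], qual=qual,
                      samples=samples)


class TestQueryFilters:
    KEYS = [("chr1", 1000 + j * 500, "A", "C") for j in range(6)]

    def test_homref_site_with_low_qual_excluded(self):
        recs = [_query_record(self.KEYS[0], [(0, 0)] * 3, qual=29.0)]
        mat, excluded = apply_query_filters(recs, self.KEYS[:1],
                                            SiteSelectionConfig())
        assert excluded == [(self.KEYS[0], "homref_quality")]
        assert mat.n_sites == 0

    def test_variant_site_with_one_low_gq_excluded(self):
        recs = [_query_record(self.KEYS[0], [(0, 1), (0, 0), (0, 0)], gq=19)]
        _, excluded = apply_query_filters(recs, self.KEYS[:1],
                                          SiteSelectionConfig())
        assert excluded == [(self.KEYS[0], "variant_quality")]

    def test_uncalled_and_different_alt_excluded(self):
        k0, k1, k2 = self.KEYS[:3]
        rec1 = _query_record((k1[0], k1[1], "A", "G"),
                             [(0, 1), (0, 0), (0, 0)])
        rec2 = _query_record(k2, [None, (0, 1), (0, 0)])
        mat, excluded = apply_query_filters([rec1, rec2], [k0, k1, k2],
                                            SiteSelectionConfig())
        assert dict(excluded) == {k0: "uncalled", k1: "different_alt",
                                  k2: "uncalled"}

    def test_query_proximity_exclusion(self):
        k0 = self.KEYS[0]
        near = (k0[0], k0[1] + 4, "G", "T")
        recs = [_query_record(k0, [(0, 1), (0, 0), (0, 0)]),
                _query_record(near, [(0, 1), (0, 0), (0, 0)])]
        _, excluded = apply_query_filters(recs, [k0], SiteSelectionConfig())
        assert excluded == [(k0, "query_proximity")]

    def test_matches_naive_rule_scan_on_random_fixtures(self, rng):
        cfg = SiteSelectionConfig()
        keys = [("chr1", 10_000 + j * 100, "A", "C") for j in range(60)]
        recs, expect = [], {}
        for key in keys:
            gts = [tuple(sorted(rng.integers(0, 2, 2).tolist()))
                   for _ in range(3)]
            qual = float(rng.choice([20.0, 100.0]))
            dp = int(rng.choice([5, 30]))
            gq = int(rng.choice([10, 80]))
            recs.append(_query_record(key, gts, qual=qual, dp=dp, gq=gq))
            hom_ref = all(g == (0, 0) for g in gts)
            if hom_ref:
                keep = qual >= 30 and dp >= 10 and 80 >= 20  # rgq fixed at 80
            else:
                keep = dp >= 10 and gq >= 20
            expect[key] = keep
        mat, excluded = apply_query_filters(recs, keys, cfg)
        assert set(mat.site_keys) == {k for k, keep in expect.items() if keep}

    def test_surviving_sites_shared_with_model_list(self):
        recs = [_query_record(k, [(0, 1), (0, 0), (0, 0)])
                for k in self.KEYS[:4]]
        mat, excluded = apply_query_filters(recs, self.KEYS[:5],
                                            SiteSelectionConfig())
        assert mat.site_keys == self.KEYS[:4]
        assert excluded == [(self.KEYS[4], "uncalled")]


def _audit_vifs(matrix, retained, window, step):
    """Direct per-site regression audit of every final window."""
    order = {k: j for j, k in enumerate(matrix.site_keys)}
    worst = 1.0
    start = 0
    while start < len(retained):
        win = retained[start:start + window]
        if len(win) >= 2:
            cols = [order[k] for k in win]
            X = matrix.values[:, cols]
            sd = X.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Z = (X - X.mean(axis=0)) / sd
            for j in range(Z.shape[1]):
                others = np.delete(Z, j, axis=1)
                beta, *_ = np.linalg.lstsq(others, Z[:, j], rcond=None)
                resid = Z[:, j] - others @ beta
                r2 = 1 - (resid @ resid) / (Z[:, j] @ Z[:, j])
                worst = max(worst, 1 / (1 - min(r2, 1 - 1e-12)))
        start += step
    return worst


class TestLdPrune:
    def test_perfectly_correlated_pair_keeps_one(self, rng):
        a = rng.binomial(2, 0.5, 100).astype(float)
        mat = _matrix(np.column_stack([a, a]))
        retained = ld_prune(mat, window=50, step=5, vif_max=2.0)
        assert len(retained) == 1

    def test_independent_sites_all_retained(self):
        rng = np.random.default_rng(13)
        vals = rng.binomial(2, 0.5, size=(600, 40)).astype(float)
        mat = _matrix(vals)
        retained = ld_prune(mat, window=50, step=5, vif_max=2.0)
        assert retained == mat.site_keys

    def test_vif_bound_holds_under_direct_audit(self):
        rng = np.random.default_rng(17)
        base = rng.binomial(2, 0.5, size=(120, 200)).astype(float)
        # plant correlated duplicates
        for j in range(0, 200, 9):
            base[:, j] = np.clip(base[:, (j + 1) % 200]
                                 + rng.binomial(1, 0.1, 120), 0, 2)
        mat = _matrix(base)
        retained = ld_prune(mat, window=50, step=5, vif_max=2.0)
        worst = _audit_vifs(mat, retained, 50, 5)
        assert worst <= 2.0 + 1e-6

    def test_pruning_is_idempotent(self):
        rng = np.random.default_rng(19)
        base = rng.binomial(2, 0.4, size=(100, 120)).astype(float)
        mat = _matrix(base)
        retained = ld_prune(mat, window=50, step=5, vif_max=2.0)
        again = ld_prune(mat.subset_sites(retained), window=50, step=5,
                         vif_max=2.0)
        assert again == retained

    def test_window_must_be_at_least_two(self, rng):
        mat = _matrix(rng.binomial(2, 0.5, size=(20, 5)).astype(float))
        with pytest.raises(ValueError):
            ld_prune(mat, window=1, step=0.5, vif_max=2.0)


class TestPCA:
    def test_antipodal_samples_give_symmetric_pc1(self):
        vals = np.array([[0, 0, 2, 2], [2, 2, 0, 0]], dtype=float)
        model = fit_pca(_matrix(vals), k=1)
        s = model.reference_scores["PC1"].to_numpy()
        assert s[0] == pytest.approx(-s[1])

    def test_projection_reproduces_training_scores(self, rng):
        vals = rng.binomial(2, 0.4, size=(40, 60)).astype(float)
        mat = _matrix(vals + (vals.std(axis=0) == 0))  # avoid zero variance
        mat = _matrix(np.clip(vals + rng.binomial(1, 0.05, vals.shape), 0, 2))
        model = fit_pca(mat, k=3)
        back = project_samples(model, mat)
        assert np.max(np.abs(back.to_numpy()
                             - model.reference_scores.to_numpy())) <= 1e-8

    def test_score_covariance_diagonal_equals_eigenvalues(self, rng):
        vals = rng.binomial(2, 0.5, size=(50, 30)).astype(float)
        mat = _matrix(vals)
        model = fit_pca(mat, k=5)
        scores = model.reference_scores.to_numpy()
        cov = scores.T @ scores / (mat.n_samples - 1)
        expected = np.diag(model.singular_values ** 2 / (mat.n_samples - 1))
        assert np.allclose(cov, expected, atol=1e-8)

    def test_zero_variance_site_raises_with_site_name(self, rng):
        vals = rng.binomial(2, 0.5, size=(20, 4)).astype(float)
        vals[:, 2] = 1.0
        mat = _matrix(vals)
        with pytest.raises(ValueError, match=str(mat.site_keys[2][1])):
            fit_pca(mat, k=2)

    def test_mean_genotype_query_projects_to_origin(self, rng):
        vals = rng.binomial(2, 0.5, size=(30, 20)).astype(float)
        mat = _matrix(vals)
        model = fit_pca(mat, k=2)
        q = GenotypeMatrix(["mean"], mat.site_keys,
                           vals.mean(axis=0, keepdims=True).round(0))
        # exact mean is generally non-integral; use the centring identity
        Z = (vals.mean(axis=0, keepdims=True) - model.mean) / model.scale
        assert np.allclose(Z @ model.loadings, 0.0, atol=1e-12)

    def test_missing_model_sites_in_query_rejected(self, rng):
        vals = rng.binomial(2, 0.5, size=(20, 10)).astype(float)
        mat = _matrix(vals)
        model = fit_pca(mat, k=2)
        q = mat.subset_sites(mat.site_keys[:5])
        with pytest.raises(ValueError, match="lacks"):
            project_samples(model, q)


class TestAdmixtureRecovery:
    @staticmethod
    def _fit(pop):
        selected, _ = select_sites(
            pop.panel, [(k[0], k[1]) for k in pop.panel.site_keys],
            SiteSelectionConfig())
        model = fit_pca(pop.panel.subset_sites(selected), k=2)
        return model, project_samples(model, pop.query.subset_sites(selected))

    def test_pc1_monotone_in_admixture_fraction(self, population_sim):
        pop = population_sim
        _, scores = self._fit(pop)
        alphas = [pop.query_alphas[s] for s in scores.index]
        rho = spearmanr(alphas, scores["PC1"]).statistic
        assert abs(rho) == pytest.approx(1.0)

    def test_half_admixed_query_between_population_centroids(self,
                                                             population_sim):
        pop = population_sim
        model, scores = self._fit(pop)
        ref = model.reference_scores
        c1 = ref.loc[[s for s in ref.index
                      if pop.panel_populations[s] == "pop1"], "PC1"].mean()
        c2 = ref.loc[[s for s in ref.index
                      if pop.panel_populations[s] == "pop2"], "PC1"].mean()
        mid = scores.loc["Q_alpha_0.50", "PC1"]
        assert min(c1, c2) < mid < max(c1, c2)


class TestRegions:
    def test_remove_regions_inclusive_bounds(self):
        keys = [("chr6", 24_999_999, "A", "C"), ("chr6", 25_000_000, "A", "C"),
                ("chr6", 35_000_000, "A", "C"), ("chr6", 35_000_001, "A", "C")]
        out = remove_regions(keys, [("chr6", 25_000_000, 35_000_000)])
        assert out == [keys[0], keys[3]]
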