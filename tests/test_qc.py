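"""Truth-panel labelling, filter evaluation and the mixture score."""

import math

import numpy as np
import pytest

from popnovel import qc
from popnovel.synthetic_data import SimulationConfig, simulate_cohort_vcf
from popnovel.vcf_io import NormalizedAllele, SampleCall, SiteRecord, read_vcf


def _site(chrom="chr1", pos=100, metrics=None, alts=None, ref="A",
          samples=None):
    return SiteRecord(
        chrom=chrom, pos=pos, ref=ref, alts=alts or ["C"],
        metrics=metrics if metrics is not None else {"QD": 10.0},
        samples=samples if samples is not None
        else [SampleCall(gt=(0, 1), ad=(5, 5), dp=10)])


class TestPrefilter:
    def test_non_autosome_dropped(self):
        recs = [_site(chrom="chrX"), _site(chrom="chr5")]
        assert [r.chrom for r in qc.prefilter_sites(recs)] == ["chr5"]

    def test_all_sample_dp_zero_dropped(self):
        rec = _site(samples=[SampleCall(gt=(0, 1), ad=(0, 3), dp=0),
                             SampleCall(gt=(0, 0), ad=(0, 0), dp=0)])
        assert qc.prefilter_sites([rec]) == []

    def test_all_alt_ad_zero_dropped(self):
        rec = _site(samples=[SampleCall(gt=(0, 1), ad=(9, 0), dp=9)])
        assert qc.prefilter_sites([rec]) == []

    def test_matches_naive_scan_on_randomized_deficiencies(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_sites=200, missing_qd_fraction=0.2,
                               zero_dp_fraction=0.2, zero_ad_fraction=0.2,
                               nonautosomal_fraction=0.1)
        path, _ = simulate_cohort_vcf(cfg, tmp_path / "c.vcf")
        recs = list(read_vcf(path))
        expected = [
            r for r in recs
            if r.chrom in qc.AUTOSOMES
            and "QD" in r.metrics
            and any(s.dp for s in r.samples)
            and any(s.ad and any(a > 0 for a in s.ad[1:]) for s in r.samples)
        ]
        assert qc.prefilter_sites(recs) == expected


class TestClassify:
    def test_union_over_panels(self):
        rec = _site(pos=7)
        p1 = qc.TruthPanel(frozenset())
        p2 = qc.TruthPanel(frozenset({("chr1", 7, "A", "C")}))
        assert qc.classify_sites([rec], [p1, p2]) == ["true"]

    def test_any_allele_rule_for_multiallelics(self):
        rec = _site(pos=7, alts=["C", "T"],
                    samples=[SampleCall(gt=(1, 2))])
        panel = qc.TruthPanel(frozenset({("chr1", 7, "A", "T")}))
        assert qc.classify_sites([rec], [panel]) == ["true"]

    def test_recovers_generator_labels_exactly(self, cohort, panels):
        vcf_path, truth = cohort
        recs = list(read_vcf(vcf_path))
        labels = qc.classify_sites(
            recs, [qc.TruthPanel.from_vcf(panels["truth"])])
        for rec, lab in zip(recs, labels):
            if not any(len(a) == 1 for a in rec.alts) or len(rec.ref) != 1:
                continue  # indel-only sites can't be in the SNV truth panel
            assert lab == truth.site_labels[(rec.chrom, rec.pos)]


class TestRules:
    def test_packaged_stage1_matches_two_clause_reading(self):
        rule = qc.parse_rule(qc.DEFAULT_STAGE1_EXPR)
        def direct(m, q):
            return (-2.5 < m < 1 and q > 7) or (q > 0.5 and -0.01 < m < 0.01)
        for m in (-3.0, -2.5, -1.0, -0.005, 0.0, 0.5, 0.999, 1.0, 2.0):
            for q in (0.0, 0.5, 0.6, 7.0, 7.5, 30.0):
                got = rule.evaluate({"MQRankSum": m, "QD": q})
                assert got == direct(m, q), (m, q)

    def test_packaged_stage2_matches_two_clause_reading(self):
        rule = qc.parse_rule(qc.DEFAULT_STAGE2_EXPR)
        def direct(mq, fs):
            return mq > 50 or (fs == 0 and mq > 40)
        for mq in (35.0, 40.0, 41.0, 50.0, 50.1, 60.0):
            for fs in (0.0, 0.001, 5.0):
                assert rule.evaluate({"MQ": mq, "FS": fs}) == direct(mq, fs)

    def test_missing_metric_fails_conservatively(self):
        rule = qc.parse_rule("QD > 5")
        assert rule.evaluate({}) is False
        assert rule.evaluate({}, missing_fails=False) is True

    def test_absent_fs_treated_as_zero_for_equality(self):
        rule = qc.parse_rule("FS = 0 and MQ > 40")
        assert rule.evaluate({"MQ": 45.0}) is True
        assert rule.evaluate({"MQ": 45.0}, absent_fs_is_zero=False) is False

    def test_parentheses_override_precedence(self):
        rule = qc.parse_rule("MQ > 50 or (FS = 0 and MQ > 40)")
        assert rule.evaluate({"MQ": 45.0, "FS": 0.0}) is True

    def test_unicode_minus_and_operators(self):
        rule = qc.parse_rule("−2.5 < MQRankSum and MQRankSum ≤ 1")
        assert rule.evaluate({"MQRankSum": 1.0}) is True
        assert rule.evaluate({"MQRankSum": -2.5}) is False


class TestEvaluateFilter:
    def _cohort(self, rng, n=400):
        recs, labels = [], []
        for i in range(n):
            label = "true" if rng.random() < 0.5 else "other"
            mu = 20.0 if label == "true" else 8.0
            recs.append(_site(pos=i + 1,
                              metrics={"QD": float(rng.normal(mu, 4))}))
            labels.append(label)
        return recs, labels

    def test_noop_filter_has_df_exactly_one(self, rng):
        recs, labels = self._cohort(rng)
        _, _, ev = qc.evaluate_filter(recs, labels, qc.parse_rule("QD > -1000"))
        assert ev.true_retention == 1.0
        assert ev.other_retention == 1.0
        assert ev.discrimination_factor == 1.0

    def test_keep_only_true_gives_infinite_df(self):
        recs = [_site(pos=1, metrics={"QD": 100.0}),
                _site(pos=2, metrics={"QD": 1.0})]
        labels = ["true", "other"]
        _, _, ev = qc.evaluate_filter(recs, labels, qc.parse_rule("QD > 50"))
        assert ev.other_retention == 0.0
        assert ev.discrimination_factor == math.inf

    def test_retentions_match_direct_counting_at_quantile(self, rng):
        recs, labels = self._cohort(rng)
        thr = float(np.quantile([r.metrics["QD"] for r in recs], 0.3))
        _, _, ev = qc.evaluate_filter(recs, labels,
                                      qc.parse_rule(f"QD > {thr}"))
        t_direct = [r.metrics["QD"] > thr
                    for r, l in zip(recs, labels) if l == "true"]
        o_direct = [r.metrics["QD"] > thr
                    for r, l in zip(recs, labels) if l == "other"]
        assert ev.n_true_kept == sum(t_direct)
        assert ev.n_other_kept == sum(o_direct)

    def test_df_invariant_to_duplicating_every_record(self, rng):
        recs, labels = self._cohort(rng, n=100)
        rule = qc.parse_rule("QD > 12")
        _, _, ev1 = qc.evaluate_filter(recs, labels, rule)
        _, _, ev2 = qc.evaluate_filter(recs + recs, labels + labels, rule)
        assert ev1.discrimination_factor == pytest.approx(
            ev2.discrimination_factor)

    def test_nested_rule_retention_monotone(self, rng):
        recs, labels = self._cohort(rng)
        wide = qc.parse_rule("QD > 5")
        narrow = qc.parse_rule("QD > 5 and QD > 15")  # subset of wide
        _, _, ev_wide = qc.evaluate_filter(recs, labels, wide)
        _, _, ev_narrow = qc.evaluate_filter(recs, labels, narrow)
        assert ev_narrow.true_retention <= ev_wide.true_retention

    def test_single_class_input_rejected(self):
        recs = [_site(pos=1)]
        with pytest.raises(qc.UndefinedRetentionError):
            qc.evaluate_filter(recs, ["true"], qc.parse_rule("QD > 1"))


class TestMixtureModel:
    def _records_from(self, X, metrics=("DP", "SOR")):
        return [
            _site(pos=i + 1,
                  metrics={m: float(v) for m, v in zip(metrics, row)})
            for i, row in enumerate(X)
        ]

    def test_single_gaussian_parameter_recovery(self):
        rng = np.random.default_rng(42)
        true_mean = np.array([3.0, -1.0])
        X = rng.normal(true_mean, [1.0, 2.0], size=(5000, 2))
        model = qc.fit_mixture_model(self._records_from(X), ("DP", "SOR"),
                                     k=1, seed=1)
        # means are on the standardized scale; invert the standardization
        got = model.positive.means[0] * model.standardize_sd + \
            model.standardize_mean
        se = np.array([1.0, 2.0]) / math.sqrt(5000)
        assert np.all(np.abs(got - true_mean) < 3 * se)

    def test_log_likelihood_trace_monotone(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(0, 1, (500, 2)),
                       rng.normal(4, 1, (500, 2))])
        model = qc.fit_mixture_model(self._records_from(X), ("DP", "SOR"),
                                     k=2, seed=3)
        diffs = np.diff(model.positive_ll_trace)
        assert np.all(diffs >= -1e-9)

    def test_two_cluster_weight_recovery(self):
        rng = np.random.default_rng(8)
        n1, n2 = 3000, 1000
        X = np.vstack([rng.normal([0, 0], 0.5, (n1, 2)),
                       rng.normal([8, 8], 0.5, (n2, 2))])
        model = qc.fit_mixture_model(self._records_from(X), ("DP", "SOR"),
                                     k=2, seed=5)
        w = np.sort(model.positive.weights)
        assert abs(w[0] - 0.25) < 0.05 and abs(w[1] - 0.75) < 0.05

    def test_agrees_with_sklearn_reference_fit(self):
        sklearn = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(-3, 1, (2000, 2)),
                       rng.normal(3, 1, (2000, 2))])
        model = qc.fit_mixture_model(self._records_from(X), ("DP", "SOR"),
                                     k=2, seed=2)
        Z = model.standardize(X)
        ref = sklearn.GaussianMixture(2, random_state=0, n_init=3).fit(Z)
        ours = np.sort(model.positive.means[:, 0])
        theirs = np.sort(ref.means_[:, 0])
        assert np.allclose(ours, theirs, atol=0.05)

    def test_insufficient_training_sites_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="training sites"):
            qc.fit_mixture_model(self._records_from(X), ("DP", "SOR"),
                                 k=2, seed=1)


class TestScoring:
    def _toy_model(self):
        d = 2
        pos = qc.GaussianMixture(np.array([1.0]), np.zeros((1, d)),
                                 np.eye(d)[None])
        neg = qc.GaussianMixture(np.array([1.0]), np.full((1, d), 4.0),
                                 np.eye(d)[None])
        return qc.MixtureScoreModel(("DP", "SOR"), np.zeros(d), np.ones(d),
                                    pos, neg)

    def test_positive_at_positive_mean(self):
        model = self._toy_model()
        rec = _site(metrics={"DP": 0.0, "SOR": 0.0})
        (s,) = qc.score_sites(model, [rec])
        assert s > 0

    def test_swapping_models_negates_scores(self):
        model = self._toy_model()
        swapped = qc.MixtureScoreModel(
            model.metric_names, model.standardize_mean, model.standardize_sd,
            model.negative, model.positive)
        recs = [_site(pos=i + 1, metrics={"DP": float(i), "SOR": 1.0})
                for i in range(10)]
        s1 = qc.score_sites(model, recs)
        s2 = qc.score_sites(swapped, recs)
        assert np.allclose(np.asarray(s1), -np.asarray(s2))

    def test_missing_metric_scores_minus_inf(self):
        model = self._toy_model()
        rec = _site(metrics={"DP": 1.0})
        assert qc.score_sites(model, [rec]) == [-math.inf]

    def test_true_sites_score_higher_than_error_sites(self):
        rng = np.random.default_rng(21)
        true_train = rng.normal(0, 1, (2000, 2))
        true_held = rng.normal(0, 1, (500, 2))
        errors = rng.normal(3, 2, (500, 2))
        mk = TestMixtureModel()._records_from
        model = qc.fit_mixture_model(mk(true_train), ("DP", "SOR"), k=2,
                                     seed=11)
        s_true = np.mean(qc.score_sites(model, mk(true_held)))
        s_err = np.mean(qc.score_sites(model, mk(errors)))
        assert s_true > s_err


class TestCascade:
    def _labelled_cohort(self, seed, n=600):
        rng = np.random.default_rng(seed)
        recs, labels = [], []
        for i in range(n):
            label = "true" if rng.random() < 0.55 else "other"
            mu = {"QD": 20, "MQ": 60, "MQRankSum": 0, "ReadPosRankSum": 0,
                  "FS": 1, "SOR": 1, "DP": 90} if label == "true" else \
                 {"QD": 8, "MQ": 48, "MQRankSum": -1, "ReadPosRankSum": 1,
                  "FS": 8, "SOR": 2, "DP": 60}
            metrics = {m: float(max(0, rng.normal(v, 3))) if m != "MQRankSum"
                       else float(rng.normal(v, 1)) for m, v in mu.items()}
            recs.append(_site(pos=i + 1, metrics=metrics))
            labels.append(label)
        return recs, labels

    def test_noop_stage_removes_nothing(self, rng):
        recs, labels = self._labelled_cohort(1)
        stage = qc.RuleStage("noop", qc.parse_rule("QD > -1"))
        kept, report = qc.apply_qc_cascade(recs, labels, [stage])
        assert report.overall_removed_fraction == 0.0
        assert report.overall_ratio_increase == pytest.approx(1.0)

    def test_overall_ratio_increase_is_product_of_stage_dfs(self):
        for seed in (2, 3, 4):
            recs, labels = self._labelled_cohort(seed)
            stages = [
                qc.RuleStage("s1", qc.parse_rule(qc.DEFAULT_STAGE1_EXPR)),
                qc.RuleStage("s2", qc.parse_rule(qc.DEFAULT_STAGE2_EXPR)),
            ]
            _, report = qc.apply_qc_cascade(recs, labels, stages)
            assert report.overall_ratio_increase == pytest.approx(
                report.stage_df_product())

    def test_non_snv_records_excluded_before_stage_one(self):
        recs, labels = self._labelled_cohort(5, n=50)
        indel = _site(pos=999, ref="AT", alts=["A"],
                      metrics={"QD": 30.0})
        kept, report = qc.apply_qc_cascade(
            recs + [indel], labels + ["other"],
            [qc.RuleStage("noop", qc.parse_rule("QD > -1"))])
        assert report.n_input_sites == 50
        assert indel not in kept

    def test_score_retention_monotone_in_threshold(self):
        recs, labels = self._labelled_cohort(6, n=1500)
        true_recs = [r for r, l in zip(recs, labels) if l == "true"]
        model = qc.fit_mixture_model(true_recs, k=2, seed=4)
        scores = np.asarray(qc.score_sites(model, recs))
        is_true = np.asarray([l == "true" for l in labels])
        retentions = [np.mean(scores[is_true] > thr)
                      for thr in np.linspace(-5, 5, 21)]
        assert all(a >= b for a, b in zip(retentions, retentions[1:]))

    def test_df_optimal_threshold_respects_retention_floor(self):
        recs, labels = self._labelled_cohort(7, n=1500)
        true_recs = [r for r, l in zip(recs, labels) if l == "true"]
        model = qc.fit_mixture_model(true_recs, k=2, seed=4)
        scores = qc.score_sites(model, recs)
        thr = qc.choose_score_threshold(scores, labels,
                                        true_retention_floor=0.99)
        kept_true = sum(1 for s, l in zip(scores, labels)
                        if l == "true" and s > thr)
        n_true = labels.count("true")
        assert kept_true / n_true >= 0.99


class TestPublishedArithmetic:
    def test_stage_factor_composition(self):
        got = qc.compose_stage_factors([1.088, 1.054, 1.024])
        assert got == pytest.approx((1.088 * 1.054 * 1.024 - 1) * 100)

    def test_implied_removed_fraction_definition(self):
        # with retention t and ratio increase g the other-class retention
        # is t/(1+g); check against a directly constructed cohort
        t, g, r = 0.95, 0.25, 1.5
        n_true, n_other = 3000, 2000
        assert n_true / n_other == r
        kept_true = t * n_true
        kept_other = (t / (1 + g)) * n_other
        direct = 100 * (1 - (kept_true + kept_other) / (n_true + n_other))
        assert qc.implied_removed_fraction(r, t, g) == pytest.approx(direct)
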