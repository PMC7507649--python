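"""Truth-panel-guided SNV quality control.

Sites are labelled "true" when one of their alleles is present in a
high-confidence truth panel (HapMap/Omni-style) and "other" otherwise.
A filter is judged by the fraction of true sites it keeps and by the
*discrimination factor*: the ratio of true-site retention to other-site
retention, i.e. the factor by which filtering increases the true:other
ratio.  Threshold filters over the seven site metrics are applied first;
surviving sites are then scored with a VQSLOD-style log-odds under a
positive/negative Gaussian-mixture model of selected metrics and cut at a
score threshold.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from popnovel.vcf_io import METRIC_NAMES, NormalizedAllele, SiteRecord, normalize_site_alleles

#: Chromosome names accepted as autosomes (with or without "chr" prefix).
AUTOSOMES = frozenset(
    [str(i) for i in range(1, 23)] + [f"chr{i}" for i in range(1, 23)]
)

# The two packaged threshold stages, written exactly as two alternative
# clauses: (A and B) or (C and D).
DEFAULT_STAGE1_EXPR = "-2.5 < MQRankSum < 1 and QD > 7 or QD > 0.5 and -0.01 < MQRankSum < 0.01"
DEFAULT_STAGE2_EXPR = "MQ > 50 or FS = 0 and MQ > 40"
DEFAULT_SCORE_THRESHOLD = -0.5
DEFAULT_SCORE_METRICS = ("DP", "SOR", "ReadPosRankSum", "FS")


class FilterRuleError(ValueError):
    pass


class UndefinedRetentionError(ValueError):
    """Raised when retentions are undefined (no true or no other sites)."""


# ---------------------------------------------------------------------------
# Filter rules
# ---------------------------------------------------------------------------

_OPS = {
    "<": lambda a, b: a < b,
    ">": lambda a, b: a > b,
    "=": lambda a, b: a == b,
    "<=": lambda a, b: a <= b,
    ">=": lambda a, b: a >= b,
}


@dataclass(frozen=True)
class Cmp:
    """A single comparison ``metric op threshold``."""

    metric: str
    op: str
    threshold: float

    def __post_init__(self):
        if self.metric not in METRIC_NAMES:
            raise FilterRuleError(f"unknown metric {self.metric!r}")
        if self.op not in _OPS:
            raise FilterRuleError(f"unknown operator {self.op!r}")

    def evaluate(self, metrics: Mapping[str, float], *, missing_fails: bool = True,
                 absent_fs_is_zero: bool = True) -> bool:
        if self.metric in metrics:
            return _OPS[self.op](metrics[self.metric], self.threshold)
        # GATK omits FS at some sites; an absent FS compared for equality
        # with zero is treated as zero when the switch is on.
        if (absent_fs_is_zero and self.metric == "FS"
                and self.op == "=" and self.threshold == 0):
            return True
        return not missing_fails

    def metrics_used(self) -> set[str]:
        return {self.metric}

    def __str__(self) -> str:
        return f"{self.metric} {self.op} {self.threshold:g}"


@dataclass(frozen=True)
class And:
    children: tuple = ()

    def evaluate(self, metrics, **kw) -> bool:
        return all(c.evaluate(metrics, **kw) for c in self.children)

    def metrics_used(self) -> set[str]:
        return set().union(*(c.metrics_used() for c in self.children))

    def __str__(self) -> str:
        return "(" + " and ".join(str(c) for c in self.children) + ")"


@dataclass(frozen=True)
class Or:
    children: tuple = ()

    def evaluate(self, metrics, **kw) -> bool:
        return any(c.evaluate(metrics, **kw) for c in self.children)

    def metrics_used(self) -> set[str]:
        return set().union(*(c.metrics_used() for c in self.children))

    def __str__(self) -> str:
        return "(" + " or ".join(str(c) for c in self.children) + ")"


FilterRule = Cmp | And | Or

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>[-−–]?\d+(?:\.\d+)?)|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op><=|>=|≤|≥|<|>|=)|(?P<paren>[()]))"
)
_OP_ALIASES = {"≤": "<=", "≥": ">="}


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens, i = [], 0
    while i < len(text):
        m = _TOKEN_RE.match(text, i)
        if not m:
            raise FilterRuleError(f"cannot tokenize rule at: {text[i:]!r}")
        i = m.end()
        if m.lastgroup == "num":
            tokens.append(("num", m.group().strip().replace("−", "-").replace("–", "-")))
        elif m.lastgroup == "name":
            word = m.group().strip()
            if word.lower() in ("and", "or"):
                tokens.append((word.lower(), word))
            else:
                tokens.append(("name", word))
        elif m.lastgroup == "op":
            op = m.group().strip()
            tokens.append(("op", _OP_ALIASES.get(op, op)))
        else:
            tokens.append((m.group().strip(), m.group().strip()))
    return tokens


_FLIP = {"<": ">", ">": "<", "<=": ">=", ">=": "<=", "=": "="}


class _Parser:
    """Recursive-descent parser; ``and`` binds tighter than ``or``, so the
    packaged expressions read as two alternative clauses."""

    def __init__(self, tokens: list[tuple[str, str]]):
        self.tokens = tokens
        self.i = 0

    def peek(self):
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def take(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def parse(self) -> FilterRule:
        node = self.or_expr()
        if self.peek() is not None:
            raise FilterRuleError(f"trailing tokens: {self.tokens[self.i:]}")
        return node

    def or_expr(self) -> FilterRule:
        parts = [self.and_expr()]
        while self.peek() == "or":
            self.take()
            parts.append(self.and_expr())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def and_expr(self) -> FilterRule:
        parts = [self.atom()]
        while self.peek() == "and":
            self.take()
            parts.append(self.atom())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def atom(self) -> FilterRule:
        if self.peek() == "(":
            self.take()
            node = self.or_expr()
            if self.peek() != ")":
                raise FilterRuleError("unbalanced parenthesis")
            self.take()
            return node
        return self.comparison()

    def comparison(self) -> FilterRule:
        # operand (op operand)+, chains like "-2.5 < MQRankSum < 1" expand
        # to conjunctions of binary comparisons.
        operands, ops = [self.take()], []
        while self.peek() == "op":
            ops.append(self.take()[1])
            operands.append(self.take())
        if not ops:
            raise FilterRuleError(f"expected comparison near {operands[0]!r}")
        cmps = []
        for (lk, lv), op, (rk, rv) in zip(operands, ops, operands[1:]):
            if lk == "name" and rk == "num":
                cmps.append(Cmp(lv, op, float(rv)))
            elif lk == "num" and rk == "name":
                cmps.append(Cmp(rv, _FLIP[op], float(lv)))
            else:
                raise FilterRuleError(
                    f"comparison must pair a metric with a number: {lv} {op} {rv}")
        return cmps[0] if len(cmps) == 1 else And(tuple(cmps))


def parse_rule(text: str) -> FilterRule:
    """Parse a threshold-rule expression into a :class:`FilterRule` tree."""
    return _Parser(_tokenize(text)).parse()


# ---------------------------------------------------------------------------
# Pre-exclusion and truth labelling
# ---------------------------------------------------------------------------

def prefilter_sites(
    records: Iterable[SiteRecord], autosomes: frozenset[str] | set[str] = AUTOSOMES
) -> list[SiteRecord]:
    """Apply the pre-exclusion rules.

    A site is dropped when QD is absent, when every sample's DP is zero,
    when every alternative-allele AD is zero in every sample, or when it
    lies outside the autosomes.
    """
    kept = []
    for r in records:
        if r.chrom not in autosomes:
            continue
        if "QD" not in r.metrics:
            continue
        if not any(s.dp is not None and s.dp > 0 for s in r.samples):
            continue
        if not any(
            s.ad is not None and any(a > 0 for a in s.ad[1:]) for s in r.samples
        ):
            continue
        kept.append(r)
    return kept


@dataclass
class TruthPanel:
    """A set of high-confidence SNV alleles used to label sites "true"."""

    alleles: frozenset[tuple[str, int, str, str]]

    @classmethod
    def from_alleles(cls, alleles: Iterable[NormalizedAllele]) -> "TruthPanel":
        keys = set()
        for a in alleles:
            if not a.is_snv():
                raise ValueError(f"truth panels hold SNVs only, got {a}")
            keys.add(a.key)
        return cls(frozenset(keys))

    @classmethod
    def from_vcf(cls, path) -> "TruthPanel":
        from popnovel.vcf_io import read_vcf

        keys = set()
        for rec in read_vcf(path):
            for a in normalize_site_alleles(rec):
                if a.is_snv():
                    keys.add(a.key)
        return cls(frozenset(keys))

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self.alleles

    def __len__(self) -> int:
        return len(self.alleles)


def classify_sites(
    records: Sequence[SiteRecord], panels: Sequence[TruthPanel]
) -> list[str]:
    """Label each record "true" iff any alt allele matches any panel."""
    labels = []
    for r in records:
        keys = {a.key for a in normalize_site_alleles(r)}
        is_true = any(k in p for p in panels for k in keys)
        labels.append("true" if is_true else "other")
    return labels


# ---------------------------------------------------------------------------
# Filter evaluation
# ---------------------------------------------------------------------------

@dataclass
class FilterEvaluation:
    """Retention of true and other sites under one filter stage."""

    name: str
    n_true_before: int
    n_true_kept: int
    n_other_before: int
    n_other_kept: int

    @property
    def true_retention(self) -> float:
        return self.n_true_kept / self.n_true_before

    @property
    def other_retention(self) -> float:
        return self.n_other_kept / self.n_other_before

    @property
    def discrimination_factor(self) -> float:
        if self.other_retention == 0:
            return math.inf if self.true_retention > 0 else math.nan
        return self.true_retention / self.other_retention


def evaluate_filter(
    records: Sequence[SiteRecord],
    labels: Sequence[str],
    rule: FilterRule,
    *,
    name: str | None = None,
    missing_fails: bool = True,
    absent_fs_is_zero: bool = True,
) -> tuple[list[SiteRecord], list[str], FilterEvaluation]:
    """Apply one threshold rule and report retentions and the DF."""
    if len(records) != len(labels):
        raise ValueError("records and labels must align")
    n_true = sum(1 for l in labels if l == "true")
    n_other = len(labels) - n_true
    if n_true == 0 or n_other == 0:
        raise UndefinedRetentionError(
            f"retention undefined: {n_true} true and {n_other} other sites")
    kept_records, kept_labels = [], []
    for r, l in zip(records, labels):
        if rule.evaluate(r.metrics, missing_fails=missing_fails,
                         absent_fs_is_zero=absent_fs_is_zero):
            kept_records.append(r)
            kept_labels.append(l)
    ev = FilterEvaluation(
        name=name or str(rule),
        n_true_before=n_true,
        n_true_kept=sum(1 for l in kept_labels if l == "true"),
        n_other_before=n_other,
        n_other_kept=sum(1 for l in kept_labels if l == "other"),
    )
    return kept_records, kept_labels, ev


# ---------------------------------------------------------------------------
# Gaussian-mixture score (VQSLOD analogue)
# ---------------------------------------------------------------------------

class MixtureFitError(RuntimeError):
    pass


@dataclass
class GaussianMixture:
    """Parameters of a K-component multivariate Gaussian mixture."""

    weights: np.ndarray          # (K,)
    means: np.ndarray            # (K, d)
    covariances: np.ndarray      # (K, d, d)

    def log_density(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        parts = np.empty((X.shape[0], len(self.weights)))
        for k in range(len(self.weights)):
            parts[:, k] = np.log(self.weights[k]) + multivariate_normal.logpdf(
                X, mean=self.means[k], cov=self.covariances[k],
                allow_singular=False)
        return logsumexp(parts, axis=1)


@dataclass
class MixtureScoreModel:
    """Positive/negative mixtures over standardized site metrics.

    The score of a site is the log-density under the positive model minus
    the log-density under the negative model, i.e. the log-odds of being a
    good variant — the same construction as GATK's VQSLOD.
    """

    metric_names: tuple[str, ...]
    standardize_mean: np.ndarray
    standardize_sd: np.ndarray
    positive: GaussianMixture
    negative: GaussianMixture
    positive_ll_trace: list[float] = field(default_factory=list)
    negative_ll_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.standardize_mean) / self.standardize_sd


def _fit_gmm(
    X: np.ndarray, k: int, *, max_iterations: int, tol: float,
    rng: np.random.Generator, reg: float,
) -> tuple[GaussianMixture, list[float], int]:
    """Plain EM for a full-covariance Gaussian mixture.

    Returns the fitted mixture, the per-iteration mean-log-likelihood
    trace (non-decreasing up to ``tol``), and the iteration count.
    """
    n, d = X.shape
    idx = rng.choice(n, size=k, replace=False)
    means = X[idx].copy()
    base_cov = np.cov(X, rowvar=False).reshape(d, d) + reg * np.eye(d)
    covs = np.stack([base_cov.copy() for _ in range(k)])
    weights = np.full(k, 1.0 / k)
    trace: list[float] = []
    it = 0
    for it in range(1, max_iterations + 1):
        # E step
        log_parts = np.empty((n, k))
        try:
            for j in range(k):
                log_parts[:, j] = np.log(weights[j]) + multivariate_normal.logpdf(
                    X, mean=means[j], cov=covs[j])
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise MixtureFitError(
                "EM failed on a singular covariance; increase the "
                "covariance regularization (reg)") from exc
        log_norm = logsumexp(log_parts, axis=1)
        ll = float(np.mean(log_norm))
        resp = np.exp(log_parts - log_norm[:, None])
        # M step
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            raise MixtureFitError(
                "a mixture component collapsed to zero weight; reduce k "
                "or increase the covariance regularization (reg)")
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        for j in range(k):
            diff = X - means[j]
            covs[j] = (resp[:, j][:, None] * diff).T @ diff / nk[j]
            covs[j] += reg * np.eye(d)
        if trace and ll - trace[-1] < tol:
            trace.append(ll)
            break
        trace.append(ll)
    return GaussianMixture(weights, means, covs), trace, it


def _metric_matrix(
    records: Sequence[SiteRecord], metrics: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Rows of metric values; second return is a bool mask of complete rows."""
    X = np.full((len(records), len(metrics)), np.nan)
    for i, r in enumerate(records):
        for j, m in enumerate(metrics):
            if m in r.metrics:
                X[i, j] = r.metrics[m]
    complete = ~np.isnan(X).any(axis=1)
    return X, complete


def fit_mixture_model(
    records_true_subset: Sequence[SiteRecord],
    metrics: Sequence[str] = DEFAULT_SCORE_METRICS,
    k: int = 2,
    *,
    max_iterations: int = 500,
    tol: float = 1e-6,
    seed: int,
    negative_fraction: float = 0.05,
    reg: float = 1e-6,
) -> MixtureScoreModel:
    """Fit the positive/negative mixture score model.

    The positive mixture is fitted by EM on the standardized metrics of
    truth-matching sites; the negative mixture is fitted on the lowest
    ``negative_fraction`` of those sites ranked by positive-model density.
    """
    X, complete = _metric_matrix(records_true_subset, metrics)
    X = X[complete]
    if X.shape[0] < 10 * k:
        raise ValueError(
            f"need at least {10 * k} complete training sites, got {X.shape[0]}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    rng = np.random.default_rng(seed)
    positive, pos_trace, n_iter = _fit_gmm(
        Z, k, max_iterations=max_iterations, tol=tol, rng=rng, reg=reg)
    pos_scores = positive.log_density(Z)
    n_neg = max(10 * k, int(math.ceil(negative_fraction * Z.shape[0])))
    worst = np.argsort(pos_scores)[:n_neg]
    negative, neg_trace, _ = _fit_gmm(
        Z[worst], min(k, max(1, len(worst) // 10)),
        max_iterations=max_iterations, tol=tol, rng=rng, reg=reg)
    return MixtureScoreModel(
        metric_names=tuple(metrics),
        standardize_mean=mean,
        standardize_sd=sd,
        positive=positive,
        negative=negative,
        positive_ll_trace=pos_trace,
        negative_ll_trace=neg_trace,
        n_iterations=n_iter,
    )


def score_sites(
    model: MixtureScoreModel,
    records: Sequence[SiteRecord],
    *,
    missing: str = "minus_inf",
) -> list[float | None]:
    """VQSLOD-style score per record: log p_pos(z) − log p_neg(z).

    Sites missing a model metric score ``-inf`` (``missing="minus_inf"``,
    the conservative default) or ``None`` (``missing="drop"``).
    """
    if missing not in ("minus_inf", "drop"):
        raise ValueError("missing must be 'minus_inf' or 'drop'")
    X, complete = _metric_matrix(records, model.metric_names)
    scores: list[float | None] = [None] * len(records)
    if complete.any():
        Z = model.standardize(X[complete])
        vals = model.positive.log_density(Z) - model.negative.log_density(Z)
        for i, v in zip(np.flatnonzero(complete), vals):
            scores[i] = float(v)
    fill = -math.inf if missing == "minus_inf" else None
    return [fill if s is None else s for s in scores]


def choose_score_threshold(
    scores: Sequence[float],
    labels: Sequence[str],
    *,
    true_retention_floor: float = 0.99,
) -> float:
    """DF-optimal score threshold subject to a true-retention floor.

    Candidate thresholds are the observed scores; among thresholds keeping
    at least ``true_retention_floor`` of true sites, the one with the
    highest discrimination factor is returned.
    """
    pairs = sorted(zip(scores, labels))
    n_true = sum(1 for l in labels if l == "true")
    n_other = len(labels) - n_true
    if n_true == 0 or n_other == 0:
        raise UndefinedRetentionError("need both true and other sites")
    best_thr, best_df = -math.inf, -math.inf
    true_kept, other_kept = n_true, n_other
    # threshold below the minimum keeps everything
    candidates = [(-math.inf, true_kept, other_kept)]
    for s, l in pairs:
        if l == "true":
            true_kept -= 1
        else:
            other_kept -= 1
        candidates.append((s, true_kept, other_kept))
    for thr, tk, ok in candidates:
        tr = tk / n_true
        if tr < true_retention_floor:
            continue
        df = math.inf if ok == 0 and tk > 0 else (
            (tr / (ok / n_other)) if ok > 0 else math.nan)
        if df > best_df:
            best_df, best_thr = df, thr
    return best_thr


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

@dataclass
class RuleStage:
    name: str
    rule: FilterRule


@dataclass
class ScoreStage:
    """Fit the mixture model on the current true sites, then cut at a
    score threshold."""

    name: str
    threshold: float = DEFAULT_SCORE_THRESHOLD
    metrics: tuple[str, ...] = DEFAULT_SCORE_METRICS
    k: int = 2
    seed: int = 0
    max_iterations: int = 500
    tol: float = 1e-6
    negative_fraction: float = 0.05
    reg: float = 1e-6


def default_stages(seed: int = 0, score_threshold: float = DEFAULT_SCORE_THRESHOLD) -> list:
    """The packaged three-stage cascade: two threshold rules followed by
    the mixture-score cut."""
    return [
        RuleStage("threshold_1", parse_rule(DEFAULT_STAGE1_EXPR)),
        RuleStage("threshold_2", parse_rule(DEFAULT_STAGE2_EXPR)),
        ScoreStage("vqslod_analogue", threshold=score_threshold, seed=seed),
    ]


@dataclass
class QCReport:
    stages: list[FilterEvaluation]
    n_input_sites: int
    n_kept_sites: int
    overall_true_retention: float
    overall_other_retention: float
    overall_ratio_increase: float
    overall_removed_fraction: float

    def stage_df_product(self) -> float:
        out = 1.0
        for s in self.stages:
            out *= s.discrimination_factor
        return out

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "stage": s.name,
                "n_true_before": s.n_true_before,
                "n_true_kept": s.n_true_kept,
                "n_other_before": s.n_other_before,
                "n_other_kept": s.n_other_kept,
                "true_retention": s.true_retention,
                "other_retention": s.other_retention,
                "discrimination_factor": s.discrimination_factor,
            }
            for s in self.stages
        ]
        return pd.DataFrame(rows)


def apply_qc_cascade(
    records: Sequence[SiteRecord],
    labels: Sequence[str],
    stages: Sequence[RuleStage | ScoreStage],
    *,
    snv_only: bool = True,
    missing_fails: bool = True,
    absent_fs_is_zero: bool = True,
) -> tuple[list[SiteRecord], QCReport]:
    """Apply threshold and score stages sequentially.

    Non-SNV records are excluded before stage 1 (quality control is
    developed for SNVs only).  Each stage's retentions are measured on
    that stage's input, so the overall ratio increase telescopes into the
    product of stage discrimination factors.
    """
    if not stages:
        raise ValueError("at least one stage required")
    if snv_only:
        pairs = [(r, l) for r, l in zip(records, labels) if r.is_snv()]
        records = [p[0] for p in pairs]
        labels = [p[1] for p in pairs]
    else:
        records, labels = list(records), list(labels)
    n_input = len(records)
    n_true0 = sum(1 for l in labels if l == "true")
    n_other0 = n_input - n_true0
    if n_true0 == 0 or n_other0 == 0:
        raise UndefinedRetentionError("cascade input must contain both classes")
    evaluations: list[FilterEvaluation] = []
    for stage in stages:
        if isinstance(stage, RuleStage):
            records, labels, ev = evaluate_filter(
                records, labels, stage.rule, name=stage.name,
                missing_fails=missing_fails,
                absent_fs_is_zero=absent_fs_is_zero)
        else:
            true_records = [r for r, l in zip(records, labels) if l == "true"]
            model = fit_mixture_model(
                true_records, stage.metrics, stage.k, seed=stage.seed,
                max_iterations=stage.max_iterations, tol=stage.tol,
                negative_fraction=stage.negative_fraction, reg=stage.reg)
            scores = score_sites(model, records)
            keep = [s > stage.threshold for s in scores]
            ev = FilterEvaluation(
                name=stage.name,
                n_true_before=sum(1 for l in labels if l == "true"),
                n_true_kept=sum(1 for k_, l in zip(keep, labels)
                                if k_ and l == "true"),
                n_other_before=sum(1 for l in labels if l == "other"),
                n_other_kept=sum(1 for k_, l in zip(keep, labels)
                                 if k_ and l == "other"),
            )
            records = [r for r, k_ in zip(records, keep) if k_]
            labels = [l for l, k_ in zip(labels, keep) if k_]
        evaluations.append(ev)
    n_true_kept = sum(1 for l in labels if l == "true")
    n_other_kept = len(labels) - n_true_kept
    overall_true = n_true_kept / n_true0
    overall_other = n_other_kept / n_other0 if n_other0 else math.nan
    ratio_increase = (
        math.inf if overall_other == 0 and overall_true > 0
        else overall_true / overall_other)
    report = QCReport(
        stages=evaluations,
        n_input_sites=n_input,
        n_kept_sites=len(records),
        overall_true_retention=overall_true,
        overall_other_retention=overall_other,
        overall_ratio_increase=ratio_increase,
        overall_removed_fraction=1 - len(records) / n_input,
    )
    return records, report


# ---------------------------------------------------------------------------
# Arithmetic over published stage summaries
# ---------------------------------------------------------------------------

def compose_stage_factors(stage_dfs: Sequence[float]) -> float:
    """Overall percentage increase of the true:other ratio implied by
    sequential stages with the given discrimination factors."""
    out = 1.0
    for d in stage_dfs:
        out *= d
    return (out - 1.0) * 100.0


def implied_removed_fraction(
    start_true_other_ratio: float,
    overall_true_retention: float,
    overall_ratio_increase: float,
) -> float:
    """Overall percentage of sites removed implied by a starting
    true:other ratio, the overall true-site retention and the overall
    ratio increase.

    With ratio r = T/O before filtering, true retention t and ratio
    increase g, other-site retention is t/(1+g) and the removed fraction
    is 1 − (t·r + t/(1+g)) / (r + 1).
    """
    r = start_true_other_ratio
    t = overall_true_retention
    o = t / (1.0 + overall_ratio_increase)
    kept = (t * r + o) / (r + 1.0)
    return (1.0 - kept) * 100.0
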