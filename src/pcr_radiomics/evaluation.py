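"""External-validation statistics.

ROC/AUC (Mann-Whitney form) with DeLong or bootstrap confidence intervals,
Youden-index threshold selection, confusion-matrix metrics with
Clopper-Pearson exact intervals, Cohen's kappa, cohort-comparison tests
(chi-square without continuity correction; Mann-Whitney U) and subgroup
validation by scanner field strength.  Also reconstructs integer confusion
matrices from metrics printed to two decimals, for auditing published
performance tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import (
    DegenerateCohortError,
    InvalidTableError,
    ReconstructionError,
    UndefinedKappaError,
)

POSITIVE_LABEL = 1  # positive class = pCR throughout

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "npv", "ppv")


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn}


@dataclass
class MetricEstimate:
    """Point estimate with a (lo, hi) CI, or a reason it is undefined."""

    name: str
    value: float | None
    ci: tuple[float, float] | None = None
    numerator: int | None = None
    denominator: int | None = None
    undefined_reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "value": self.value,
            "ci": list(self.ci) if self.ci is not None else None,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "undefined_reason": self.undefined_reason,
        }


# ---------------------------------------------------------------------------
# ROC / AUC


def _split_scores(scores, labels):
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal-length")
    pos = s[y == POSITIVE_LABEL]
    neg = s[y != POSITIVE_LABEL]
    if pos.size == 0 or neg.size == 0:
        raise DegenerateCohortError("both outcome classes must be present")
    return s, y, pos, neg


def auc(scores, labels) -> float:
    """AUC as P(score_pos > score_neg) + 0.5 P(equal), via midranks."""
    s, y, pos, neg = _split_scores(scores, labels)
    ranks = stats.rankdata(s)  # average ranks handle ties
    n_pos, n_neg = pos.size, neg.size
    rank_sum_pos = ranks[np.asarray(y) == POSITIVE_LABEL].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_points(scores, labels) -> np.ndarray:
    """ROC operating points as an array of (fpr, tpr, threshold) rows.

    Thresholds are the descending unique score values (call positive iff
    score >= threshold), book-ended by an all-negative point at +inf.
    """
    s, y, pos, neg = _split_scores(scores, labels)
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    # count >= t via searchsorted on the finite thresholds
    tp = pos.size - np.searchsorted(pos_sorted, thresholds[1:], side="left")
    fp = neg.size - np.searchsorted(neg_sorted, thresholds[1:], side="left")
    tpr = np.concatenate(([0.0], tp / pos.size))
    fpr = np.concatenate(([0.0], fp / neg.size))
    return np.column_stack([fpr, tpr, thresholds])


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """DeLong point estimate and variance of the AUC via placement values."""
    m, n = pos.size, neg.size

    def placements(a, b):
        # for each a_i: fraction of b_j strictly below + half ties
        out = np.empty(a.size)
        for i, ai in enumerate(a):
            out[i] = (np.sum(b < ai) + 0.5 * np.sum(b == ai)) / b.size
        return out

    v10 = placements(pos, neg)  # per-positive
    v01 = 1.0 - placements(neg, pos)  # per-negative, oriented toward AUC
    theta = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(theta), float(s10 / m + s01 / n)


def auc_ci(scores, labels, level: float = 0.95, method: str = "delong",
           n_boot: int = 2000, seed: int | None = None) -> tuple[float, float]:
    """Confidence interval for the AUC, clipped to [0, 1].

    ``method="delong"`` uses the DeLong variance of the Mann-Whitney
    estimator; ``method="bootstrap"`` a stratified percentile bootstrap.
    """
    s, y, pos, neg = _split_scores(scores, labels)
    if pos.size < 2 or neg.size < 2:
        raise DegenerateCohortError("need at least 2 members per class for a CI")
    if method == "delong":
        theta, var = _delong_variance(pos, neg)
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * math.sqrt(max(var, 0.0))
        return (max(0.0, theta - half), min(1.0, theta + half))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        vals = np.empty(n_boot)
        for b in range(n_boot):
            bp = rng.choice(pos, size=pos.size, replace=True)
            bn = rng.choice(neg, size=neg.size, replace=True)
            bs = np.concatenate([bp, bn])
            by = np.concatenate([np.ones(pos.size, int), np.zeros(neg.size, int)])
            vals[b] = auc(bs, by)
        alpha = 1.0 - level
        lo, hi = np.quantile(vals, [alpha / 2.0, 1.0 - alpha / 2.0])
        return (float(max(0.0, lo)), float(min(1.0, hi)))
    raise ValueError(f"unknown AUC CI method {method!r}")


def youden_threshold(scores, labels) -> tuple[float, float, float, float]:
    """(threshold, J, sensitivity, specificity) maximising J = sens + spec - 1.

    Candidate thresholds are the observed score values; ties in J are broken
    toward the lowest threshold.
    """
    s, y, pos, neg = _split_scores(scores, labels)
    ts = np.unique(s)  # ascending
    sens = 1.0 - np.searchsorted(np.sort(pos), ts, side="left") / pos.size
    spec = np.searchsorted(np.sort(neg), ts, side="left") / neg.size
    j = sens + spec - 1.0
    i = int(np.argmax(j))  # first occurrence -> lowest maximising threshold
    return float(ts[i]), float(j[i]), float(sens[i]), float(spec[i])


# ---------------------------------------------------------------------------
# threshold metrics


def confusion_at_threshold(scores, labels, threshold: float) -> ConfusionMatrix:
    """Confusion matrix calling positive iff score >= threshold."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    called = s >= threshold
    pos = y == POSITIVE_LABEL
    return ConfusionMatrix(
        tp=int(np.sum(called & pos)),
        fn=int(np.sum(~called & pos)),
        fp=int(np.sum(called & ~pos)),
        tn=int(np.sum(~called & ~pos)),
    )


def _metric_fractions(cm: ConfusionMatrix) -> dict:
    return {
        "accuracy": (cm.tp + cm.tn, cm.n),
        "sensitivity": (cm.tp, cm.tp + cm.fn),
        "specificity": (cm.tn, cm.tn + cm.fp),
        "npv": (cm.tn, cm.tn + cm.fn),
        "ppv": (cm.tp, cm.tp + cm.fp),
    }


def threshold_metrics(cm: ConfusionMatrix, level: float = 0.95) -> dict:
    """Accuracy/sens/spec/NPV/PPV with Clopper-Pearson exact intervals.

    A metric with a zero denominator is reported as undefined with a reason,
    never as NaN.
    """
    out = {}
    for name, (num, den) in _metric_fractions(cm).items():
        if den == 0:
            out[name] = MetricEstimate(
                name, None, None, num, den,
                undefined_reason=f"{name} denominator is 0 for this matrix",
            )
            continue
        lo, hi = proportion_confint(num, den, alpha=1.0 - level, method="beta")
        out[name] = MetricEstimate(name, num / den, (float(lo), float(hi)), num, den)
    return out


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa (p_o - p_e)/(1 - p_e) with p_e from marginal products."""
    n = cm.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = (cm.tp + cm.tn) / n
    p_e = ((cm.tp + cm.fn) * (cm.tp + cm.fp) + (cm.fp + cm.tn) * (cm.fn + cm.tn)) / n**2
    if p_e == 1.0:
        raise UndefinedKappaError("expected agreement is 1; kappa undefined")
    return float((p_o - p_e) / (1.0 - p_e))


def cohens_kappa_ci(cm: ConfusionMatrix, level: float = 0.95) -> tuple[float, float]:
    """Large-sample kappa interval from the asymptotic standard error."""
    n = cm.n
    k = cohens_kappa(cm)
    p_o = (cm.tp + cm.tn) / n
    p_e = ((cm.tp + cm.fn) * (cm.tp + cm.fp) + (cm.fp + cm.tn) * (cm.fn + cm.tn)) / n**2
    se = math.sqrt(p_o * (1.0 - p_o) / (n * (1.0 - p_e) ** 2))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (max(-1.0, k - z * se), min(1.0, k + z * se))


def youden_index(sensitivity: float, specificity: float) -> float:
    """J = sensitivity + specificity - 1."""
    return sensitivity + specificity - 1.0


# ---------------------------------------------------------------------------
# reconstruction of printed matrices


def reconstruction_candidates(
    n: int, n_pos: int, printed: dict
) -> tuple[int, list[ConfusionMatrix]]:
    """Best-fitting integer matrices for a printed 2-d.p. metric column.

    Returns (number of metrics matched by the best fit, the matrices
    attaining it) over all matrices with margins (n_pos, n - n_pos).
    """
    unknown = set(printed) - set(METRIC_NAMES)
    if unknown:
        raise ValueError(f"unknown metric names {sorted(unknown)}")
    n_neg = n - n_pos
    best_mismatch = None
    candidates: list[ConfusionMatrix] = []
    for tp in range(n_pos + 1):
        for fp in range(n_neg + 1):
            cm = ConfusionMatrix(tp=tp, fn=n_pos - tp, fp=fp, tn=n_neg - fp)
            mism = 0
            fracs = _metric_fractions(cm)
            for name, target in printed.items():
                num, den = fracs[name]
                if den == 0 or round(num / den, 2) != round(float(target), 2):
                    mism += 1
            if best_mismatch is None or mism < best_mismatch:
                best_mismatch = mism
                candidates = [cm]
            elif mism == best_mismatch:
                candidates.append(cm)
    return len(printed) - best_mismatch, candidates


def reconstruct_confusion_matrix(n: int, n_pos: int, printed: dict) -> ConfusionMatrix:
    """Recover the integer confusion matrix behind a published metric column.

    Exhaustively searches matrices with the stated class margins and returns
    the one minimising the number of metrics whose 2-d.p. rounding disagrees
    with the printed values.  Ambiguity (several matrices tie at the minimum)
    or a poor best fit (fewer than 3 of 5 metrics matched) raises
    :class:`ReconstructionError`.
    """
    n_matched, candidates = reconstruction_candidates(n, n_pos, printed)
    if len(printed) >= 3 and n_matched < 3:
        raise ReconstructionError(
            f"no matrix reproduces at least 3 of {len(printed)} printed metrics "
            f"(best matched {n_matched})",
            candidates=candidates,
        )
    if len(candidates) > 1:
        listing = ", ".join(str(c.to_dict()) for c in candidates)
        raise ReconstructionError(
            f"ambiguous reconstruction; {len(candidates)} matrices tie: {listing}",
            candidates=candidates,
        )
    return candidates[0]


# ---------------------------------------------------------------------------
# cohort comparison


def compare_cohorts(a, b, kind: str = "categorical") -> tuple[float, float]:
    """Compare two cohorts; returns (statistic, p-value).

    ``categorical``: Pearson chi-square without continuity correction on the
    2 x k table whose rows are the per-cohort category counts.
    ``continuous``: two-sided Mann-Whitney U with normal approximation and
    tie correction.
    """
    if kind == "categorical":
        table = np.asarray([a, b], dtype=np.float64)
        if np.any(table < 0):
            raise InvalidTableError("counts must be non-negative")
        exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        if np.any(exp == 0):
            raise InvalidTableError("zero expected cell count")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(chi2), float(p)
    if kind == "continuous":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown comparison kind {kind!r}")


# ---------------------------------------------------------------------------
# validation reports


@dataclass
class ThresholdBlock:
    """Metrics of one operating point (one threshold) on one cohort."""

    label: str
    threshold: float
    confusion: ConfusionMatrix
    metrics: dict
    kappa: float | None
    kappa_ci: tuple[float, float] | None
    youden_j: float | None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "threshold": self.threshold,
            "confusion": self.confusion.to_dict(),
            "metrics": {k: v.to_dict() for k, v in self.metrics.items()},
            "kappa": self.kappa,
            "kappa_ci": list(self.kappa_ci) if self.kappa_ci else None,
            "youden_j": self.youden_j,
        }


@dataclass
class ValidationReport:
    """Full validation result for one cohort (optionally with subgroups)."""

    n: int
    n_positive: int
    auc: float | None
    auc_ci: tuple[float, float] | None
    auc_ci_method: str
    ci_level: float
    roc: np.ndarray | None
    blocks: list[ThresholdBlock] = field(default_factory=list)
    subgroups: dict = field(default_factory=dict)
    comparisons: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_positive": self.n_positive,
            "prevalence": self.n_positive / self.n if self.n else None,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci) if self.auc_ci else None,
            "auc_ci_method": self.auc_ci_method,
            "ci_level": self.ci_level,
            "roc": self.roc.tolist() if self.roc is not None else None,
            "blocks": [b.to_dict() for b in self.blocks],
            "subgroups": {str(k): v.to_dict() for k, v in self.subgroups.items()},
            "comparisons": self.comparisons,
            "config": self.config,
            "flags": self.flags,
        }


def _make_block(label, scores, labels, threshold, level) -> ThresholdBlock:
    cm = confusion_at_threshold(scores, labels, threshold)
    metrics = threshold_metrics(cm, level=level)
    try:
        kappa = cohens_kappa(cm)
        kci = cohens_kappa_ci(cm, level=level)
    except UndefinedKappaError:
        kappa, kci = None, None
    sens = metrics["sensitivity"].value
    spec = metrics["specificity"].value
    j = youden_index(sens, spec) if sens is not None and spec is not None else None
    return ThresholdBlock(label, float(threshold), cm, metrics, kappa, kci, j)


def validate_cohort(
    scores,
    labels,
    published_threshold: float,
    level: float = 0.95,
    auc_ci_method: str = "delong",
    extra_thresholds: dict | None = None,
    seed: int | None = None,
) -> ValidationReport:
    """Validate model scores against outcomes at fixed and re-optimised cut-offs.

    The published threshold is reported first (it is part of the model under
    test); the locally re-optimised Youden threshold is secondary.
    ``extra_thresholds`` maps labels to thresholds to apply instead of
    recomputing Youden locally (used to apply pooled thresholds to subgroups).
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    n = s.size
    n_pos = int(np.sum(y == POSITIVE_LABEL))
    flags = []
    try:
        a = auc(s, y)
        roc = roc_points(s, y)
        try:
            ci = auc_ci(s, y, level=level, method=auc_ci_method, seed=seed)
        except DegenerateCohortError as exc:
            ci = None
            flags.append(f"AUC CI undefined: {exc}")
    except DegenerateCohortError as exc:
        a, ci, roc = None, None, None
        flags.append(f"AUC undefined: {exc}")
    report = ValidationReport(
        n=n, n_positive=n_pos, auc=a, auc_ci=ci,
        auc_ci_method=auc_ci_method, ci_level=level, roc=roc, flags=flags,
    )
    report.blocks.append(_make_block("published", s, y, published_threshold, level))
    if extra_thresholds is None:
        try:
            t, j, _, _ = youden_threshold(s, y)
            report.blocks.append(_make_block("youden-local", s, y, t, level))
        except DegenerateCohortError as exc:
            flags.append(f"local Youden threshold undefined: {exc}")
    else:
        for lbl, t in extra_thresholds.items():
            report.blocks.append(_make_block(lbl, s, y, t, level))
    return report


def subgroup_validation(
    scores,
    labels,
    groups,
    published_threshold: float,
    level: float = 0.95,
    auc_ci_method: str = "delong",
    seed: int | None = None,
) -> ValidationReport:
    """Pooled validation plus per-group sub-reports at identical thresholds.

    Thresholds (published and pooled-Youden) are fixed on the pooled cohort
    and applied unchanged in every subgroup; a single-class subgroup is
    flagged, not fatal.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    g = np.asarray(groups)
    pooled = validate_cohort(
        s, y, published_threshold, level=level,
        auc_ci_method=auc_ci_method, seed=seed,
    )
    fixed = {b.label: b.threshold for b in pooled.blocks}
    for key in sorted(set(g.tolist())):
        sel = g == key
        pooled.subgroups[key] = validate_cohort(
            s[sel], y[sel], published_threshold, level=level,
            auc_ci_method=auc_ci_method,
            extra_thresholds={k: v for k, v in fixed.items() if k != "published"},
            seed=seed,
        )
    return pooled
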