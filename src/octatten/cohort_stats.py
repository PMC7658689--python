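"""Two-group comparison, regression and ROC machinery for cohort metrics.

Comparisons are normality-gated: each index is tested with Shapiro-Wilk in
both groups, and the unpaired Student t-test is used only when both groups
look Gaussian at the gate level (otherwise the Mann-Whitney U test with
normal approximation, continuity and tie correction).  Association between
indices uses simple linear regression on z-scored variables, whose slope
(the standardized beta) equals the Pearson correlation.  Diagnostic
performance uses the area under the ROC curve via the Mann-Whitney
identity, with variances, covariances and paired-difference tests from the
DeLong placement estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import study_defaults
from .regional import decrease_ratio

__all__ = [
    "GroupComparison",
    "RegressionResult",
    "AUCResult",
    "IndexROC",
    "ROCComparison",
    "normality_test",
    "compare_groups",
    "standardized_beta",
    "auc",
    "delong_test",
    "build_table1",
    "build_table2",
    "table1_to_frame",
    "table2_to_frame",
]


# ---------------------------------------------------------------------------
# Result containers


@dataclass
class GroupComparison:
    """One Table-style row comparing patients and controls on one index."""

    index: str = ""
    layer: str = ""
    region: str = ""
    patient_mean: float = float("nan")
    patient_sd: float = float("nan")
    control_mean: float = float("nan")
    control_sd: float = float("nan")
    test: str = ""  # "t-test" or "mann-whitney"
    statistic: float = float("nan")
    p_value: float = float("nan")
    significant: bool = False
    decrease_ratio_pct: float | None = None


@dataclass
class RegressionResult:
    predictor: str
    response: str
    beta: float  # standardized: equals Pearson r for simple regression
    p_value: float
    n: int


@dataclass
class AUCResult:
    auc: float
    direction: str  # "positive-high" | "positive-low"


@dataclass
class IndexROC:
    index: str
    auc: float
    se: float
    ci: tuple
    p_value: float  # vs AUC = 0.5
    direction: str


@dataclass
class ROCComparison:
    """Per-layer ROC summary plus the pairwise DeLong difference."""

    layer: str = ""
    entries: dict = field(default_factory=dict)  # index -> IndexROC
    pair: tuple = ()
    delta_auc: float = float("nan")
    delta_se: float = float("nan")
    delta_ci: tuple = ()
    p_value: float = float("nan")


# ---------------------------------------------------------------------------
# Elementary tests


def normality_test(sample):
    """Shapiro-Wilk test of composite normality.

    Returns ``(W, p)``.  Valid for 3 <= n <= 5000; a constant sample is
    degenerate and rejected.
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1:
        raise ValueError("sample must be 1-D")
    if not (3 <= x.size <= 5000):
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n = {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("sample is constant (zero variance); normality undefined")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def _looks_normal(x, alpha: float) -> bool:
    try:
        _, p = normality_test(x)
    except ValueError:
        return False  # constant samples fall through to the rank test
    return p >= alpha


def compare_groups(patients, controls, alpha: float = 0.05, equal_var: bool = True) -> GroupComparison:
    """Two-sided patient/control comparison with a Shapiro-Wilk gate.

    Both groups must pass the gate at ``alpha`` for the unpaired t-test
    branch (Student's by default, Welch with ``equal_var=False``);
    otherwise the Mann-Whitney U test with normal approximation,
    continuity correction and tie correction is used.
    """
    a = np.asarray(patients, dtype=float)
    b = np.asarray(controls, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 finite observations")
    if _looks_normal(a, alpha) and _looks_normal(b, alpha):
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        test = "t-test"
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        test = "mann-whitney"
        statistic, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        patient_mean=float(a.mean()),
        patient_sd=float(a.std(ddof=1)),
        control_mean=float(b.mean()),
        control_sd=float(b.std(ddof=1)),
        test=test,
        statistic=statistic,
        p_value=p,
        significant=p < alpha,
    )


def standardized_beta(x, y, predictor: str = "x", response: str = "y") -> RegressionResult:
    """Slope of z-scored ``y`` on z-scored ``x`` (the standardized beta).

    For simple regression this equals the Pearson correlation; the
    two-sided P value comes from the t distribution with n - 2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D samples of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return RegressionResult(
        predictor=predictor, response=response, beta=float(r), p_value=float(p), n=int(x.size)
    )


# ---------------------------------------------------------------------------
# ROC / DeLong


def _placement_matrix(pos, neg):
    """Pairwise win matrix: 1 if pos > neg, 0.5 on ties, else 0."""
    pos = np.asarray(pos, dtype=float)[:, None]
    neg = np.asarray(neg, dtype=float)[None, :]
    return (pos > neg) + 0.5 * (pos == neg)


def auc(pos, neg) -> AUCResult:
    """AUC via the Mann-Whitney identity, oriented so AUC >= 0.5.

    ``auc = U / (n_pos * n_neg)`` with ties counting one half; the
    recorded direction says whether high scores indicate the positive
    class.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    raw = float(_placement_matrix(pos, neg).mean())
    if raw >= 0.5:
        return AUCResult(auc=raw, direction="positive-high")
    return AUCResult(auc=1.0 - raw, direction="positive-low")


def _delong_components(scores, labels):
    """AUC and DeLong placement vectors for one score index."""
    psi = _placement_matrix(scores[labels], scores[~labels])
    return float(psi.mean()), psi.mean(axis=1), psi.mean(axis=0)


def delong_test(scores1, scores2, labels, names=("index1", "index2"), alpha: float = 0.05) -> ROCComparison:
    """DeLong comparison of two correlated AUCs scored on the same subjects.

    ``labels`` marks the positive class.  Returns per-index AUC, standard
    error, Wald 95% CI (truncated to [0, 1]) and P versus AUC = 0.5, plus
    the paired-difference z-test for ``AUC1 - AUC2``.
    """
    scores1 = np.asarray(scores1, dtype=float)
    scores2 = np.asarray(scores2, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not (scores1.shape == scores2.shape == labels.shape):
        raise ValueError("scores and labels must have identical shape")
    m = int(labels.sum())
    n = int((~labels).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present in labels")

    aucs = []
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    for k, scores in enumerate((scores1, scores2)):
        a, v10[k], v01[k] = _delong_components(scores, labels)
        aucs.append(a)
    s10 = np.cov(v10, ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01, ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n

    zcrit = stats.norm.ppf(1 - 0.05 / 2)
    entries = {}
    for k, name in enumerate(names):
        se = float(np.sqrt(max(cov[k, k], 0.0)))
        if se > 0:
            p = 2.0 * stats.norm.sf(abs(aucs[k] - 0.5) / se)
        else:
            p = 1.0 if aucs[k] == 0.5 else 0.0
        ci = (max(aucs[k] - zcrit * se, 0.0), min(aucs[k] + zcrit * se, 1.0))
        entries[name] = IndexROC(
            index=name, auc=aucs[k], se=se, ci=ci, p_value=float(p), direction="positive-high"
        )

    delta = aucs[0] - aucs[1]
    var_delta = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    se_delta = float(np.sqrt(max(var_delta, 0.0)))
    if se_delta > 0:
        p_delta = float(2.0 * stats.norm.sf(abs(delta) / se_delta))
    else:
        p_delta = 1.0 if delta == 0 else 0.0
    return ROCComparison(
        entries=entries,
        pair=tuple(names),
        delta_auc=float(delta),
        delta_se=se_delta,
        delta_ci=(delta - zcrit * se_delta, delta + zcrit * se_delta),
        p_value=p_delta,
    )


# ---------------------------------------------------------------------------
# Report builders


def _collect(metrics, layer, region, index, group):
    vals = [m.get(layer, region, index) for m in metrics if m.group == group]
    arr = np.asarray(vals, dtype=float)
    return arr[np.isfinite(arr)]


def build_table1(metrics, alpha: float = 0.05, holm: bool = False):
    """Group-comparison rows for every index x layer x region.

    Returns 30 :class:`GroupComparison` rows (3 indices x 2 layers x 5
    regions); thickness rows carry the percent decrease ratio.  With
    ``holm=True`` a Holm step-down correction is applied to the P values
    (none by default).
    """
    rows = []
    for layer in study_defaults.LAYERS:
        for index in study_defaults.INDICES:
            for region in study_defaults.REGIONS:
                a = _collect(metrics, layer, region, index, "patient")
                b = _collect(metrics, layer, region, index, "control")
                row = compare_groups(a, b, alpha=alpha)
                row.index, row.layer, row.region = index, layer, region
                if index == "thickness" and row.control_mean > 0:
                    row.decrease_ratio_pct = decrease_ratio(row.control_mean, row.patient_mean)
                rows.append(row)
    if holm:
        ps = np.array([r.p_value for r in rows])
        order = np.argsort(ps)
        adj = np.empty_like(ps)
        running = 0.0
        k = len(ps)
        for rank, i in enumerate(order):
            running = max(running, (k - rank) * ps[i])
            adj[i] = min(running, 1.0)
        for r, p in zip(rows, adj):
            r.p_value = float(p)
            r.significant = p < alpha
    return rows


def build_table2(metrics, alpha: float = 0.05):
    """Per-layer ROC summary with a pairwise DeLong comparison.

    For each layer the three overall-mean indices are scored on all
    subjects (each oriented so its AUC is at least 0.5) and the two
    best-performing indices significant against AUC = 0.5 are compared
    pairwise; if fewer than two reach significance the two largest AUCs
    are compared.
    """
    labels = np.array([m.group == "patient" for m in metrics])
    if labels.all() or not labels.any():
        raise ValueError("metrics must contain both patients and controls")
    results = []
    for layer in study_defaults.LAYERS:
        oriented = {}
        directions = {}
        for index in study_defaults.INDICES:
            scores = np.array([m.get(layer, "average", index) for m in metrics])
            res = auc(scores[labels], scores[~labels])
            directions[index] = res.direction
            oriented[index] = scores if res.direction == "positive-high" else -scores

        singles = {}
        for index in study_defaults.INDICES:
            single = delong_test(oriented[index], oriented[index], labels, names=(index, index))
            roc = single.entries[index]
            roc.direction = directions[index]
            singles[index] = roc

        significant = [i for i in study_defaults.INDICES if singles[i].p_value < alpha]
        candidates = significant if len(significant) >= 2 else list(study_defaults.INDICES)
        pair = tuple(sorted(candidates, key=lambda i: singles[i].auc, reverse=True)[:2])
        cmp = delong_test(oriented[pair[0]], oriented[pair[1]], labels, names=pair)
        result = ROCComparison(
            layer=layer,
            entries=singles,
            pair=pair,
            delta_auc=cmp.delta_auc,
            delta_se=cmp.delta_se,
            delta_ci=cmp.delta_ci,
            p_value=cmp.p_value,
        )
        results.append(result)
    return results


def table1_to_frame(rows):
    """Tabular (DataFrame) view of :func:`build_table1` output."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "layer": r.layer,
                "region": r.region,
                "index": r.index,
                "patient_mean": r.patient_mean,
                "patient_sd": r.patient_sd,
                "control_mean": r.control_mean,
                "control_sd": r.control_sd,
                "test": r.test,
                "p_value": r.p_value,
                "significant": r.significant,
                "decrease_ratio_pct": r.decrease_ratio_pct,
            }
            for r in rows
        ]
    )


def table2_to_frame(results):
    """Tabular (DataFrame) view of :func:`build_table2` output."""
    import pandas as pd

    rows = []
    for res in results:
        for index, roc in res.entries.items():
            rows.append(
                {
                    "layer": res.layer,
                    "row": index,
                    "auc": roc.auc,
                    "se": roc.se,
                    "ci_low": roc.ci[0],
                    "ci_high": roc.ci[1],
                    "p_value": roc.p_value,
                    "direction": roc.direction,
                }
            )
        rows.append(
            {
                "layer": res.layer,
                "row": f"difference:{res.pair[0]}-{res.pair[1]}",
                "auc": res.delta_auc,
                "se": res.delta_se,
                "ci_low": res.delta_ci[0],
                "ci_high": res.delta_ci[1],
                "p_value": res.p_value,
                "direction": "",
            }
        )
    return pd.DataFrame(rows)
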