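"""Group-comparison statistics for the lesion cohort.

The pipeline mirrors a conventional clinical analysis: a Shapiro-Wilk
normality gate chooses between an unpaired (Welch) t-test and the two-sided
rank-sum (Mann-Whitney) test; the rank-sum p-value is computed by full
enumeration of labelings for small samples and by the tie-corrected normal
approximation otherwise.  Diagnostic accuracy uses the ROC curve with the
cutoff maximizing Youden's J = sensitivity + specificity - 1 (ties broken
toward the smaller threshold), and correlation uses Spearman's rho.
Raw p-values are reported without multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "RocResult",
    "normality_gate",
    "exact_rank_sum_p",
    "compare_groups",
    "roc_youden",
    "spearman_rho",
    "summarize_cohort",
    "COMPARISON_VARIABLES",
]

#: the six per-lesion variables compared between etiologies
COMPARISON_VARIABLES = ("SUV_max", "LBR_suv", "Ki_max", "LBR_ki", "Vd_max", "LBR_vd")


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test: str  # "t" or "wilcoxon" (rank-sum)
    p_value: float
    significant: bool
    parametric: bool
    summary_a: dict = field(default_factory=dict)
    summary_b: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    youden_cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    auc: float


def _check_group(values: np.ndarray, min_n: int = 1) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.size < min_n:
        raise ValueError(f"group needs at least {min_n} values")
    return values


def normality_gate(values_a, values_b, alpha: float = 0.05) -> bool:
    """True iff the Shapiro-Wilk p-value is >= alpha in BOTH groups.

    Zero-variance (constant) groups are signalled as an error rather than
    silently passed through the test.
    """
    a = _check_group(values_a, 3)
    b = _check_group(values_b, 3)
    for g in (a, b):
        if np.ptp(g) == 0:
            raise ValueError("zero-variance group: normality is undefined")
    return bool(stats.shapiro(a).pvalue >= alpha and stats.shapiro(b).pvalue >= alpha)


def exact_rank_sum_p(values_a, values_b) -> float:
    """Two-sided exact rank-sum p by full enumeration of group labelings.

    Uses mid-ranks, so ties are handled exactly.  The p-value is the
    probability, over all C(n_a+n_b, n_a) labelings, of a rank sum at least
    as far from its null mean as the observed one.
    """
    a = _check_group(values_a)
    b = _check_group(values_b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a, n_tot = a.size, pooled.size
    observed = ranks[:n_a].sum()
    mu = n_a * (n_tot + 1) / 2.0
    dev = abs(observed - mu) - 1e-9
    hits = sum(
        1 for combo in combinations(range(n_tot), n_a)
        if abs(ranks[list(combo)].sum() - mu) >= dev
    )
    return hits / comb(n_tot, n_a)


def _summary(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "n": int(values.size),
        "median": float(med),
        "iqr": float(q3 - q1),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
    }


def compare_groups(
    values_a,
    values_b,
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
    exact_max_n: int = 12,
    variable: str = "",
) -> GroupComparison:
    """Normality-gated unpaired comparison of two independent groups.

    Welch's t-test when both groups pass the Shapiro-Wilk gate; otherwise
    the two-sided rank-sum test (exact enumeration when n_a + n_b <=
    ``exact_max_n``, tie-corrected normal approximation above).
    """
    a = _check_group(values_a)
    b = _check_group(values_b)
    try:
        parametric = normality_gate(a, b, alpha=normality_alpha)
    except ValueError:
        parametric = False  # degenerate/small groups fall back to ranks
    if parametric:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        test = "t"
    else:
        if a.size + b.size <= exact_max_n:
            p = exact_rank_sum_p(a, b)
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                         method="asymptotic").pvalue)
        test = "wilcoxon"
    return GroupComparison(
        variable=variable,
        test=test,
        p_value=p,
        significant=bool(p < alpha),
        parametric=parametric,
        summary_a=_summary(a),
        summary_b=_summary(b),
    )


def roc_youden(scores, labels) -> RocResult:
    """ROC analysis with the Youden-index operating point.

    Candidate thresholds are the midpoints between consecutive sorted unique
    scores plus +/- infinity; a case is called positive when its score is >=
    the threshold.  The cutoff is the smallest threshold maximizing
    J = sensitivity + specificity - 1; the AUC is the trapezoid over the
    full curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    thr = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]])
    sens = (pos[None, :] >= thr[:, None]).mean(axis=1)
    spec = (neg[None, :] < thr[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)[0]  # smallest threshold wins
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return RocResult(
        thresholds=thr,
        sensitivities=sens,
        specificities=spec,
        youden_cutoff=float(thr[best]),
        sensitivity_at_cutoff=float(sens[best]),
        specificity_at_cutoff=float(spec[best]),
        auc=auc,
    )


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties) with the two-sided
    t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(stats.rankdata(x)) == 0 or np.ptp(stats.rankdata(y)) == 0:
        raise ValueError("zero rank variance")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def summarize_cohort(records: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Cohort summary: per-variable group comparison, pooled paired
    LBR(Ki)-vs-LBR(SUV) contrast, and their Spearman correlation.

    ``records`` must contain the six comparison variables and a ``group``
    column with values "cancer" and "inflammatory".
    """
    groups = records["group"].to_numpy()
    cancer = records[groups == "cancer"]
    inflam = records[groups == "inflammatory"]
    if len(cancer) == 0 or len(inflam) == 0:
        raise ValueError("empty group: need both cancer and inflammatory lesions")
    variables = {}
    for var in COMPARISON_VARIABLES:
        cmp = compare_groups(cancer[var].to_numpy(), inflam[var].to_numpy(),
                             alpha=alpha, variable=var)
        variables[var] = {
            "cancer": cmp.summary_a,
            "inflammatory": cmp.summary_b,
            "test": cmp.test,
            "p_value": cmp.p_value,
            "significant": cmp.significant,
        }
    lbr_ki = records["LBR_ki"].to_numpy()
    lbr_suv = records["LBR_suv"].to_numpy()
    diffs = lbr_ki - lbr_suv
    if np.all(diffs == 0):
        pooled_p = 1.0
    else:
        pooled_p = float(stats.wilcoxon(lbr_ki, lbr_suv).pvalue)
    rho, rho_p = spearman_rho(lbr_ki, lbr_suv)
    return {
        "variables": variables,
        "pooled_lbr": {
            "n": int(len(records)),
            "lbr_ki_median": float(np.median(lbr_ki)),
            "lbr_suv_median": float(np.median(lbr_suv)),
            "p_value": pooled_p,
            "test": "signed-rank",
        },
        "correlation": {"rho": rho, "p_value": rho_p, "pair": ["LBR_ki", "LBR_suv"]},
    }
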