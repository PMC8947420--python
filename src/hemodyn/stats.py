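"""Cohort-level statistics: normality, paired tests, within-subject ANOVA
with Tukey post hoc, and ROC/AUC posture discrimination.

The repeated-measures ANOVA is the balanced one-way within-subject design:
F = MS_condition / MS_(condition x subject), df = (k-1, (k-1)(n-1)).  A
Greenhouse-Geisser sphericity correction is computed alongside the
uncorrected p-value (the default display) so both are available.  Tukey
comparisons use the same within-subject error term with studentized-range
p-values.  AUC uses the Mann-Whitney identity with ties counted half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateRangeError, DesignError, ParameterError, SampleSizeError

ALPHA = 0.05  # study-wide significance threshold


def shapiro_wilk(sample: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p) for 3 <= n <= 5000."""
    sample = np.asarray(sample, dtype=float)
    if not (3 <= sample.size <= 5000):
        raise SampleSizeError(f"Shapiro-Wilk needs 3..5000 observations, got {sample.size}")
    if np.ptp(sample) == 0:
        raise DegenerateRangeError("normality test undefined for a constant sample")
    w, p = sps.shapiro(sample)
    return float(w), float(p)


def paired_compare(
    a: np.ndarray, b: np.ndarray, normal: bool
) -> tuple[float, float]:
    """Paired two-sided comparison: Student t when normal, else Wilcoxon."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise SampleSizeError("paired samples must share a length of at least 3")
    d = a - b
    if np.all(d == 0):
        if normal:
            raise DegenerateRangeError("all paired differences are zero; t undefined")
        return 0.0, 1.0  # Wilcoxon convention: no evidence of a shift
    if normal:
        if np.ptp(d) == 0:
            raise DegenerateRangeError("constant non-zero differences; t undefined")
        t, p = sps.ttest_rel(a, b)
        return float(t), float(p)
    res = sps.wilcoxon(a, b, zero_method="wilcox", method="auto")
    return float(res.statistic), float(res.pvalue)


def _pivot(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Subjects x conditions matrix for one metric, checked for balance."""
    required = {"subject", "posture", "metric", "value"}
    if not required.issubset(table.columns):
        raise DesignError(f"cohort table must have columns {sorted(required)}")
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise DesignError(f"no rows for metric {metric!r}")
    wide = sub.pivot_table(
        index="subject", columns="posture", values="value", aggfunc="first"
    )
    na = wide.isna()
    if na.any().any():
        subj = na.index[na.any(axis=1)][0]
        cond = na.columns[na.loc[subj]][0]
        raise DesignError(
            f"missing cell ({subj}, {cond}); repeated measures need a complete design"
        )
    counts = sub.groupby(["subject", "posture"]).size()
    if (counts > 1).any():
        raise DesignError("duplicate (subject, posture) rows for metric")
    return wide


@dataclass
class RmAnovaResult:
    F: float
    df_effect: int
    df_error: int
    p: float
    gg_epsilon: float
    p_gg: float
    ms_effect: float
    ms_error: float
    n_subjects: int
    k_conditions: int


def rm_anova_matrix(data: np.ndarray) -> RmAnovaResult:
    """One-way within-subject ANOVA on an (n subjects x k conditions) array."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise DesignError("data must be subjects x conditions")
    n, k = data.shape
    if k < 2 or n < 3:
        raise DesignError("need at least 2 conditions and 3 subjects")
    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    resid = data - cond_means[None, :] - subj_means[:, None] + grand
    ss_err = np.sum(resid**2)
    df_effect = k - 1
    df_error = (k - 1) * (n - 1)
    ms_effect = ss_cond / df_effect
    ms_error = ss_err / df_error
    if ms_error == 0:
        f = 0.0 if ms_effect == 0 else np.inf
        p = 1.0 if ms_effect == 0 else 0.0
    else:
        f = ms_effect / ms_error
        p = float(sps.f.sf(f, df_effect, df_error))
    eps = _greenhouse_geisser(data)
    if ms_error == 0:
        p_gg = p
    else:
        p_gg = float(sps.f.sf(f, eps * df_effect, eps * df_error))
    return RmAnovaResult(
        F=float(f),
        df_effect=df_effect,
        df_error=df_error,
        p=p,
        gg_epsilon=float(eps),
        p_gg=p_gg,
        ms_effect=float(ms_effect),
        ms_error=float(ms_error),
        n_subjects=n,
        k_conditions=k,
    )


def _greenhouse_geisser(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the condition covariance matrix."""
    k = data.shape[1]
    s = np.cov(data, rowvar=False, ddof=1)
    mean_diag = np.trace(s) / k
    mean_all = s.mean()
    row_means = s.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(s**2) - 2 * k * np.sum(row_means**2) + k**2 * mean_all**2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def rm_anova(table: pd.DataFrame, metric: str) -> RmAnovaResult:
    """Repeated-measures ANOVA for one metric of a tidy cohort table."""
    return rm_anova_matrix(_pivot(table, metric).to_numpy())


def tukey_hsd(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """All pairwise condition comparisons with studentized-range p-values.

    Uses the within-subject error term of the repeated-measures ANOVA:
    q = |mean_i - mean_j| / sqrt(MS_error / n), compared against the
    studentized-range distribution with k groups and the ANOVA error df.
    """
    wide = _pivot(table, metric)
    data = wide.to_numpy()
    res = rm_anova_matrix(data)
    n, k = data.shape
    se = np.sqrt(res.ms_error / n)
    rows = []
    conds = list(wide.columns)
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(data[:, i].mean() - data[:, j].mean())
            if se == 0:
                p_adj = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / se
                p_adj = float(sps.studentized_range.sf(q, k, res.df_error))
            rows.append(
                {"a": conds[i], "b": conds[j], "difference": diff, "p_adj": p_adj}
            )
    return pd.DataFrame(rows)


@dataclass
class RocResult:
    auc: float  # oriented: max(raw, 1 - raw)
    auc_raw: float
    orientation_flipped: bool
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_auc(values_group0: np.ndarray, values_group1: np.ndarray) -> RocResult:
    """ROC curve and AUC for separating two groups of scalar scores.

    AUC is computed by the Mann-Whitney identity — the fraction of
    (group1, group0) pairs in which the group-1 value is larger, ties
    counted half.  Because the class polarity of a posture pair is a
    labelling convention, the reported ``auc`` is max(raw, 1 - raw) with
    the orientation flagged.
    """
    g0 = np.asarray(values_group0, dtype=float)
    g1 = np.asarray(values_group1, dtype=float)
    if g0.size == 0 or g1.size == 0:
        raise ParameterError("both groups must be non-empty")
    combined = np.concatenate((g0, g1))
    ranks = sps.rankdata(combined)
    r1 = ranks[g0.size :].sum()
    u1 = r1 - g1.size * (g1.size + 1) / 2.0
    auc_raw = float(u1 / (g0.size * g1.size))
    # curve over all observed thresholds (predict group 1 when value >= thr)
    thresholds = np.concatenate(([np.inf], np.unique(combined)[::-1]))
    tpr = np.array([(g1 >= thr).mean() for thr in thresholds])
    fpr = np.array([(g0 >= thr).mean() for thr in thresholds])
    flipped = auc_raw < 0.5
    return RocResult(
        auc=max(auc_raw, 1.0 - auc_raw),
        auc_raw=auc_raw,
        orientation_flipped=flipped,
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
    )


def merge_hemispheres(
    left: np.ndarray, right: np.ndarray, alpha: float = ALPHA
) -> tuple[np.ndarray | None, dict]:
    """Average hemispheres only when a paired test finds no difference.

    Normality of the paired differences picks the test (t vs Wilcoxon).
    Returns ``(merged_or_None, report)``; ``None`` means the hemispheres
    differ and both sides should be retained and flagged.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    d = left - right
    if np.ptp(d) == 0:
        merged = (left + right) / 2.0
        return merged, {"normal": None, "p": 1.0, "merged": True}
    _, p_norm = shapiro_wilk(d)
    normal = p_norm > alpha
    stat, p = paired_compare(left, right, normal=normal)
    if p <= alpha:
        return None, {"normal": normal, "p": p, "statistic": stat, "merged": False}
    return (left + right) / 2.0, {
        "normal": normal,
        "p": p,
        "statistic": stat,
        "merged": True,
    }
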