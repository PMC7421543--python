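"""Agreement, screening and error-attribution statistics.

Covers epoch-level detection metrics (Cohen's kappa with its
marginal-constrained maximum and the prevalence/bias indexes that
contextualise it), recording-level AHI agreement (Spearman correlation,
ICC(2,1) absolute agreement with its F-based confidence interval,
Bland-Altman bias and limits of agreement), OSA screening and severity
performance (per-threshold contingency metrics, ROC AUC over the estimated
AHI, linearly weighted kappa on the 4x4 severity table), the considerable
over/under-estimation flags, and an elastic-net regression attributing the
AHI estimation error to recording characteristics.

Error sign convention everywhere: reference minus estimated AHI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.linear_model import ElasticNetCV
from sklearn.metrics import (
    average_precision_score,
    cohen_kappa_score,
    roc_auc_score,
)
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan

SEVERITY_EDGES = (5.0, 15.0, 30.0)
SCREENING_THRESHOLDS = (5.0, 15.0, 30.0)


@dataclass
class ContingencyTable2x2:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be >= 0")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def binary_table(reference: np.ndarray, predicted: np.ndarray) -> ContingencyTable2x2:
    r = np.asarray(reference).astype(bool)
    p = np.asarray(predicted).astype(bool)
    return ContingencyTable2x2(
        tp=int(np.sum(r & p)),
        fp=int(np.sum(~r & p)),
        fn=int(np.sum(r & ~p)),
        tn=int(np.sum(~r & ~p)),
    )


def kappa_statistics(table: ContingencyTable2x2) -> dict:
    """Cohen's kappa, its marginal-constrained maximum, and the prevalence and
    bias indexes for a 2x2 table."""
    n = table.n
    po = (table.tp + table.tn) / n
    ref_pos = (table.tp + table.fn) / n
    ref_neg = (table.fp + table.tn) / n
    pred_pos = (table.tp + table.fp) / n
    pred_neg = (table.fn + table.tn) / n
    pe = ref_pos * pred_pos + ref_neg * pred_neg
    kappa = (po - pe) / (1 - pe) if pe < 1 else 1.0
    po_max = min(ref_pos, pred_pos) + min(ref_neg, pred_neg)
    kappa_max = (po_max - pe) / (1 - pe) if pe < 1 else 1.0
    return {
        "kappa": kappa,
        "kappa_max": kappa_max,
        "prevalence_index": abs((table.tp + table.fn) - (table.fp + table.tn)) / n,
        "bias_index": abs(table.fn - table.fp) / n,
    }


def weighted_kappa_max(confusion: np.ndarray) -> float:
    """Marginal-constrained maximum of the linearly weighted kappa.

    With the marginals of the observed table fixed, the cell arrangement that
    minimises the expected linear disagreement is a small transportation
    problem, solved exactly by linear programming.  For a 2x2 table this
    reduces to the familiar sum-of-minimum-marginals form.
    """
    c = np.asarray(confusion, dtype=float)
    n = c.sum()
    q = c.shape[0]
    v = np.abs(np.subtract.outer(np.arange(q), np.arange(q))).astype(float)  # disagreement
    row = c.sum(axis=1) / n
    col = c.sum(axis=0) / n
    d_e = float(np.sum(v * np.outer(row, col)))
    if d_e == 0:
        return 1.0
    # minimise sum v_ij x_ij s.t. row/col sums fixed
    a_eq = []
    b_eq = []
    for i in range(q):
        m = np.zeros((q, q))
        m[i, :] = 1
        a_eq.append(m.ravel())
        b_eq.append(row[i])
    for j in range(q - 1):  # last column constraint is redundant
        m = np.zeros((q, q))
        m[:, j] = 1
        a_eq.append(m.ravel())
        b_eq.append(col[j])
    res = optimize.linprog(
        v.ravel(), A_eq=np.asarray(a_eq), b_eq=np.asarray(b_eq), bounds=(0, None),
        method="highs",
    )
    if not res.success:
        raise RuntimeError("weighted kappa maximum LP failed")
    d_min = float(res.fun)
    return 1.0 - d_min / d_e


def epoch_metrics(
    labels: np.ndarray,
    predictions: np.ndarray,
    probabilities: np.ndarray,
    contributing: np.ndarray,
) -> dict:
    """Detection metrics over the epochs contributing to the AHI estimate
    (asleep, weight 1)."""
    sel = np.asarray(contributing).astype(bool)
    if not np.any(sel):
        raise ValueError("no contributing epochs")
    y = np.asarray(labels).astype(int)[sel]
    p = np.asarray(predictions).astype(int)[sel]
    prob = np.asarray(probabilities, dtype=float)[sel]
    table = binary_table(y, p)
    out = kappa_statistics(table)
    out["accuracy"] = (table.tp + table.tn) / table.n
    out["sensitivity"] = table.tp / (table.tp + table.fn) if table.tp + table.fn else np.nan
    out["specificity"] = table.tn / (table.tn + table.fp) if table.tn + table.fp else np.nan
    out["ppv"] = table.tp / (table.tp + table.fp) if table.tp + table.fp else np.nan
    if len(np.unique(y)) == 2:
        out["roc_auc"] = float(roc_auc_score(y, prob))
        out["pr_auc"] = float(average_precision_score(y, prob))
    else:
        out["roc_auc"] = np.nan
        out["pr_auc"] = np.nan
    out["table"] = table
    return out


def icc21(reference: np.ndarray, estimated: np.ndarray, alpha: float = 0.05) -> dict:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Computed from the two-way ANOVA mean squares with the F-distribution
    confidence interval for the absolute-agreement single-measure case.
    """
    x = np.column_stack([np.asarray(reference, float), np.asarray(estimated, float)])
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 paired recordings")
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else np.nan

    # McGraw & Wong F-based interval
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr
        )
    else:
        lower = upper = np.nan
    return {"icc": float(icc), "ci95": (float(lower), float(upper))}


@dataclass
class AgreementReport:
    spearman_rho: float
    spearman_p: float
    icc: float
    icc_ci95: tuple
    bias: float
    loa: float  # 1.96 x SD of the differences
    breusch_pagan_p: float
    screening: list = field(default_factory=list)
    severity_confusion: Optional[np.ndarray] = None
    weighted_kappa: float = np.nan
    weighted_kappa_max: float = np.nan


def ahi_agreement(reference: Sequence[float], estimated: Sequence[float]) -> AgreementReport:
    """Recording-level agreement between reference and estimated AHI.

    Bias is the mean of reference minus estimated (the estimation-error
    convention); limits of agreement are bias +/- 1.96 x SD of the
    differences.  The Breusch-Pagan p-value documents heteroscedasticity of
    the estimated-on-reference relation (the reason Spearman is used for
    correlation); it gates nothing.
    """
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimated, dtype=float)
    if len(ref) != len(est) or len(ref) < 3:
        raise ValueError("need at least 3 paired recordings")
    rho, p = stats.spearmanr(ref, est)
    icc = icc21(ref, est)
    diff = ref - est
    bias = float(diff.mean())
    loa = float(1.96 * diff.std(ddof=1))
    exog = sm.add_constant(ref)
    resid = sm.OLS(est, exog).fit().resid
    if np.ptp(ref) > 0 and np.ptp(resid) > 0:
        _, bp_p, _, _ = het_breuschpagan(resid, exog)
    else:
        bp_p = np.nan
    return AgreementReport(
        spearman_rho=float(rho),
        spearman_p=float(p),
        icc=icc["icc"],
        icc_ci95=icc["ci95"],
        bias=bias,
        loa=loa,
        breusch_pagan_p=float(bp_p),
    )


def screening_and_severity(
    reference: Sequence[float],
    estimated: Sequence[float],
    thresholds: Sequence[float] = SCREENING_THRESHOLDS,
) -> AgreementReport:
    """Screening rows per AHI threshold plus the 4x4 severity analysis."""
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimated, dtype=float)
    report = ahi_agreement(ref, est)
    for thr in thresholds:
        rbin = ref >= thr
        ebin = est >= thr
        row = {"threshold": float(thr), "n_above": int(ebin.sum())}
        table = binary_table(rbin, ebin)
        row.update(kappa_statistics(table))
        row["sensitivity"] = table.tp / (table.tp + table.fn) if table.tp + table.fn else np.nan
        row["specificity"] = table.tn / (table.tn + table.fp) if table.tn + table.fp else np.nan
        row["ppv"] = table.tp / (table.tp + table.fp) if table.tp + table.fp else np.nan
        if len(np.unique(rbin)) == 2:
            row["roc_auc"] = float(roc_auc_score(rbin, est))
            row["auc_defined"] = True
        else:
            row["roc_auc"] = np.nan
            row["auc_defined"] = False
        report.screening.append(row)

    ref_sev = np.digitize(ref, SEVERITY_EDGES)
    est_sev = np.digitize(est, SEVERITY_EDGES)
    confusion = np.zeros((4, 4), dtype=int)
    for r, e in zip(ref_sev, est_sev):
        confusion[r, e] += 1
    report.severity_confusion = confusion
    if np.ptp(ref_sev) == 0 and np.ptp(est_sev) == 0:
        report.weighted_kappa = 1.0 if ref_sev[0] == est_sev[0] else 0.0
    else:
        report.weighted_kappa = float(
            cohen_kappa_score(ref_sev, est_sev, weights="linear", labels=[0, 1, 2, 3])
        )
    report.weighted_kappa_max = weighted_kappa_max(confusion)
    return report


def flag_misestimation(reference: float, estimated: float) -> str:
    """'under' / 'over' / 'none' per the considerable-misestimation bounds.

    Underestimation: est < AHI/2 - 2.5 for 5 <= AHI < 15, or
    est < 2 AHI/3 - 5 for AHI >= 15.  Overestimation: est > 2 AHI + 5 for
    0 <= AHI < 15, or est > 3 AHI/2 + 7.5 for AHI >= 15.  A reference below 5
    can only be over-flagged.
    """
    ahi, est = float(reference), float(estimated)
    if ahi < 0:
        raise ValueError("reference AHI must be >= 0")
    if 5.0 <= ahi < 15.0 and est < ahi / 2.0 - 2.5:
        return "under"
    if ahi >= 15.0 and est < 2.0 * ahi / 3.0 - 5.0:
        return "under"
    if ahi < 15.0 and est > 2.0 * ahi + 5.0:
        return "over"
    if ahi >= 15.0 and est > 1.5 * ahi + 7.5:
        return "over"
    return "none"


def error_regression(
    characteristics: np.ndarray,
    errors: np.ndarray,
    feature_names: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> dict:
    """Elastic-net attribution of the AHI estimation error.

    Predictors are z-scored; the penalty strength and L1/L2 mix are chosen by
    5-fold cross-validation.  Returns the (z-scale) coefficients, intercept
    and in-sample r-squared.
    """
    x = np.asarray(characteristics, dtype=float)
    y = np.asarray(errors, dtype=float)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("characteristics must be n x p aligned with errors")
    if len(y) < 10:
        raise ValueError("need at least 10 recordings for the error regression")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xz = (x - mu) / sd
    enet = ElasticNetCV(
        l1_ratio=[0.1, 0.5, 0.7, 0.9, 0.95, 1.0],
        cv=5,
        random_state=seed,
        max_iter=50000,
    )
    enet.fit(xz, y)
    r2 = float(enet.score(xz, y))
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"x{j}" for j in range(x.shape[1])]
    )
    coefs = dict(zip(names, enet.coef_))
    return {
        "coefficients": coefs,
        "nonzero": {k: v for k, v in coefs.items() if v != 0.0},
        "intercept": float(enet.intercept_),
        "r2": r2,
        "l1_ratio": float(enet.l1_ratio_),
        "alpha": float(enet.alpha_),
    }
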