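"""Group-comparison and association statistics.

Mann-Whitney U with exact enumeration at small sample sizes and a
tie-corrected continuity-corrected normal approximation otherwise;
median-percent effect sizes; Benjamini-Hochberg FDR; exact two-sided Fisher
tests by hypergeometric enumeration in rational arithmetic; age/sex-adjusted
linear models with Cohen's f-squared; and single-predictor logistic ROC with
Youden-index operating points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mann_whitney", "median_pct_effect", "fdr_bh", "fisher_exact_2x2",
    "clinical_association", "roc_logistic", "AssociationResult", "RocResult",
]

#: below this smaller-group size the exact enumeration is used (the normal
#: approximation with continuity correction takes over at larger samples)
EXACT_MW_MIN_GROUP = 8
#: enumeration budget: fall back to the asymptotic p beyond this many splits
EXACT_MW_MAX_COMB = 500_000


def _rank_u(pooled_ranks: np.ndarray, idx_x: np.ndarray, n: int) -> float:
    return float(pooled_ranks[idx_x].sum() - n * (n + 1) / 2)


def mann_whitney(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U, p) where U is the min-group convention min(U_x, U_y), with
    midranks for ties.  ``method`` is "exact" (full enumeration of group
    assignments, valid with ties), "asymptotic" (tie-corrected normal
    approximation with continuity correction), or "auto" (exact when the
    smaller group has fewer than 8 observations and the enumeration is
    affordable).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(n * m / 2), 1.0
    ranks = stats.rankdata(pooled)
    u_x = _rank_u(ranks, np.arange(n), n)
    u_min = min(u_x, n * m - u_x)
    if method == "auto":
        feasible = math.comb(n + m, n) <= EXACT_MW_MAX_COMB
        method = "exact" if (min(n, m) < EXACT_MW_MIN_GROUP and feasible) \
            else "asymptotic"
    if method == "exact":
        total = 0
        extreme = 0
        nm = n * m
        for idx in combinations(range(n + m), n):
            u = _rank_u(ranks, np.array(idx), n)
            total += 1
            if min(u, nm - u) <= u_min + 1e-9:
                extreme += 1
        return u_min, extreme / total
    # tie-corrected normal approximation with continuity correction
    _, counts = np.unique(pooled, return_counts=True)
    nt = n + m
    tie_term = ((counts ** 3 - counts).sum()) / (nt * (nt - 1))
    var = n * m / 12 * (nt + 1 - tie_term)
    if var <= 0:
        return u_min, 1.0
    z = (u_min - n * m / 2 + 0.5) / math.sqrt(var)
    p = min(1.0, 2 * stats.norm.cdf(z))
    return u_min, float(p)


def median_pct_effect(x_patients, y_controls) -> float:
    """Percent difference of group medians: 100 (med_P - med_C) / |med_C|."""
    med_c = float(np.median(y_controls))
    if med_c == 0:
        raise ValueError("control median is zero: percent effect undefined")
    med_p = float(np.median(x_patients))
    return 100.0 * (med_p - med_c) / abs(med_c)


def fdr_bh(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values, reject flags), where adjusted p_(i) =
    min_{j >= i} m p_(j) / j capped at 1, and rejection means adjusted < alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted < alpha


# ---------------------------------------------------------------------------
# Fisher exact


@lru_cache(maxsize=100_000)
def _hypergeom_pmf_table(n: int, r: int, c: int) -> tuple:
    """Exact hypergeometric pmf over the support of cell a, as Fractions.

    Margins: row1 total r, column1 total c, grand total n.
    """
    lo = max(0, r + c - n)
    hi = min(r, c)
    denom = math.comb(n, c)
    return tuple(
        Fraction(math.comb(r, a) * math.comb(n - r, c - a), denom)
        for a in range(lo, hi + 1)
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value by hypergeometric enumeration.

    Sums, in exact rational arithmetic, the probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    table's, so ties in probability are handled without floating-point fuzz.
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be non-negative")
    n = a + b + c + d
    if n == 0 or (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
        return 1.0
    r, col = a + b, a + c
    pmf = _hypergeom_pmf_table(n, r, col)
    lo = max(0, r + col - n)
    p_obs = pmf[a - lo]
    return float(sum(p for p in pmf if p <= p_obs))


# ---------------------------------------------------------------------------
# covariate-adjusted linear models


@dataclass
class AssociationResult:
    """Age/sex-adjusted linear association of a nodal metric with a clinical
    score: slope of the clinical term, its two-sided p, and Cohen's f^2
    relative to the covariates-only model."""

    metric_name: str
    clinical_name: str
    region: str
    beta: float
    p_raw: float
    cohens_f2: float
    n_complete: int
    p_fdr: float | None = None

    @property
    def direction(self) -> int:
        return int(np.sign(self.beta))


def _ols_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Least-squares fit returning (coefs, R^2, standard errors)."""
    import statsmodels.api as sm
    model = sm.OLS(y, X).fit()
    return model.params, float(model.rsquared), model


def clinical_association(metric_values, clinical, age, sex,
                         metric_name: str = "metric",
                         clinical_name: str = "clinical",
                         region: str = "global") -> AssociationResult:
    """OLS of metric on (clinical, age, sex) with listwise deletion.

    ``sex`` may be "M"/"F" strings or a 0/1 indicator.  Cohen's f^2 =
    (R2_full - R2_cov) / (1 - R2_full) against the covariates-only model.
    Degenerate (constant) design columns are dropped with a warning.
    """
    import statsmodels.api as sm

    metric_values = np.asarray(metric_values, dtype=float)
    clinical = np.asarray(clinical, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    if sex.dtype.kind in "UOS":
        sex = (np.char.upper(sex.astype(str)) == "M").astype(float)
    sex = sex.astype(float)
    ok = np.isfinite(metric_values) & np.isfinite(clinical) & \
        np.isfinite(age) & np.isfinite(sex)
    if ok.sum() < 5:
        raise ValueError(f"fewer than 5 complete cases ({int(ok.sum())})")
    yv = metric_values[ok]
    if np.ptp(yv) == 0:
        raise ValueError("metric is constant across complete cases")
    if np.ptp(clinical[ok]) == 0:
        raise ValueError("clinical score is constant across complete cases")
    cols = {"clinical": clinical[ok], "age": age[ok], "sex": sex[ok]}
    for name in ("age", "sex"):
        if np.ptp(cols[name]) == 0:
            import logging
            logging.getLogger(__name__).warning(
                "dropping constant covariate %r from association model", name)
            del cols[name]
    X_full = sm.add_constant(np.column_stack(list(cols.values())))
    full = sm.OLS(yv, X_full).fit()
    covar_cols = [v for k, v in cols.items() if k != "clinical"]
    if covar_cols:
        X_cov = sm.add_constant(np.column_stack(covar_cols))
        r2_cov = float(sm.OLS(yv, X_cov).fit().rsquared)
    else:
        r2_cov = 0.0
    r2_full = float(full.rsquared)
    f2 = max(0.0, (r2_full - r2_cov) / (1.0 - r2_full)) \
        if r2_full < 1.0 else float("inf")
    return AssociationResult(
        metric_name=metric_name, clinical_name=clinical_name, region=region,
        beta=float(full.params[1]), p_raw=float(full.pvalues[1]),
        cohens_f2=f2, n_complete=int(ok.sum()))


# ---------------------------------------------------------------------------
# logistic ROC


@dataclass
class RocResult:
    """ROC of a single predictor for patient/control discrimination, with the
    Youden-optimal operating point and its confusion-matrix summaries."""

    predictor: str
    auc: float
    youden_threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    beta0: float = float("nan")
    beta1: float = float("nan")


def _logistic_irls(x: np.ndarray, y: np.ndarray, max_iter: int = 50,
                   tol: float = 1e-10) -> tuple[float, float]:
    """Single-predictor logistic regression by iteratively reweighted least
    squares; iteration is capped so perfectly separated data converge to a
    finite (large-slope) solution instead of diverging."""
    xs = (x - x.mean())
    scale = xs.std() or 1.0
    xs = xs / scale
    b0, b1 = 0.0, 0.0
    for _ in range(max_iter):
        eta = np.clip(b0 + b1 * xs, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-12)
        z = eta + (y - p) / w
        sw = w.sum()
        swx = (w * xs).sum()
        swxx = (w * xs * xs).sum()
        swz = (w * z).sum()
        swxz = (w * xs * z).sum()
        det = sw * swxx - swx ** 2
        if det <= 0:
            break
        nb0 = (swxx * swz - swx * swxz) / det
        nb1 = (sw * swxz - swx * swz) / det
        if abs(nb0 - b0) < tol and abs(nb1 - b1) < tol:
            b0, b1 = nb0, nb1
            break
        b0, b1 = nb0, nb1
    # back-transform to the original predictor scale
    slope = b1 / scale
    intercept = b0 - slope * x.mean()
    return float(intercept), float(slope)


def rank_auc(scores, labels) -> float:
    """Tie-corrected pairwise-concordance AUC of a raw score (positives=1)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    n1, n0 = len(pos), len(neg)
    return float((r_pos - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_logistic(predictor, labels, name: str = "predictor") -> RocResult:
    """Logistic-regression ROC with Youden-optimal operating point.

    Patients (label 1) are the positive class.  The ROC is swept over the
    logistic score oriented so that larger raw predictor values score higher;
    a predictor that ranks patients *below* controls therefore yields
    AUC < 0.5 rather than being silently flipped.  The trapezoid AUC is
    asserted against the tie-corrected rank AUC of the raw predictor.
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be 0 (control) / 1 (patient)")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    b0, b1 = _logistic_irls(x, y.astype(float))
    # The fitted probability is a monotone transform of x, so the curve is
    # swept on the raw-predictor scale (predict patient when x >= t), which
    # keeps the operating threshold in predictor units and stays well
    # defined even when the fitted slope is exactly zero.
    thresholds = np.concatenate([[np.inf], np.unique(x)[::-1]])
    n1 = int(y.sum())
    n0 = len(y) - n1
    tpr = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        pred = x >= t
        tpr[i] = (pred & (y == 1)).sum() / n1
        fpr[i] = (pred & (y == 0)).sum() / n0
    auc = float(np.trapezoid(tpr, fpr))
    auc_rank = rank_auc(x, y)
    assert abs(auc - auc_rank) < 1e-9, "trapezoid AUC != rank AUC"
    j = tpr - fpr
    ties = np.flatnonzero(np.isclose(j, j.max()))
    best = int(ties[np.argmax(tpr[ties])])  # tie-break toward sensitivity
    thr = thresholds[best]
    pred = x >= thr
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = n1 - tp
    tn = n0 - fp
    sens = tp / n1
    spec = tn / n0
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    acc = (tp + tn) / len(y)
    return RocResult(predictor=name, auc=auc, youden_threshold=float(thr),
                     sensitivity=float(sens), specificity=float(spec),
                     ppv=float(ppv), npv=float(npv), accuracy=float(acc),
                     beta0=b0, beta1=b1)
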