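"""From-formula implementations of the study's statistical toolkit.

Every statistic used by the haemorrhage analysis is implemented directly
from its defining formula — Pearson/Yates chi-square, Spearman rank
correlation on mid-ranks, ROC/AUC by trapezoid over grouped thresholds,
Cohen's kappa, intraclass correlation ICC(2,1)/ICC(3,1), Kruskal-Wallis
with tie correction, one-way ANOVA, and the Kolmogorov-Smirnov normality
test with the Lilliefors correction for estimated parameters.  The test
suite cross-checks each against an independent reference implementation;
nothing here wraps one.

No multiple-testing correction is applied anywhere: each p-value stands on
its own, mirroring standard practice for single pre-specified comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
from scipy import special
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: Optional[float] = None
    note: Optional[str] = None


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str


@dataclass(frozen=True)
class AgreementResult:
    value: float
    n_subjects: int
    n_raters: int
    method: str
    note: Optional[str] = None


@dataclass(frozen=True)
class ROCResult:
    """ROC curve and area.

    ``sensitivity`` and ``fpr`` (1 - specificity) are the operating points
    obtained by thresholding at every distinct score (ties grouped), from
    the all-negative (0, 0) to the all-positive (1, 1) corner; both are
    monotone non-decreasing.  ``auc`` is the trapezoidal area, identical to
    the Mann-Whitney probability with half credit for ties.
    """

    auc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    fpr: np.ndarray
    n_pos: int
    n_neg: int


def _midranks(x: np.ndarray) -> np.ndarray:
    """Mid-ranks (1-based; ties share the average of their positions)."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j + 1 < len(sx) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


# ---------------------------------------------------------------------------
# contingency tables


def chi_square(table, continuity_correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    Expected counts come from the row/column margins; with
    ``continuity_correction`` (2x2 tables only) Yates' correction subtracts
    0.5 from each |O - E|, clamped at zero.  df = (r-1)(c-1); the p-value is
    the upper chi-square tail.
    """
    O = np.asarray(table, dtype=float)
    if O.ndim != 2 or O.shape[0] < 2 or O.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(O < 0):
        raise ValueError("counts must be non-negative")
    r = O.sum(axis=1)
    c = O.sum(axis=0)
    if np.any(r == 0) or np.any(c == 0):
        raise ValueError("zero row or column margin gives expected count 0")
    E = np.outer(r, c) / O.sum()
    dev = np.abs(O - E)
    method = "pearson-chi2"
    if continuity_correction:
        if O.shape != (2, 2):
            raise ValueError("Yates correction applies to 2x2 tables only")
        dev = np.maximum(dev - 0.5, 0.0)
        method = "yates-chi2"
    stat = float(np.sum(dev ** 2 / E))
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    return TestResult(stat, float(sps.chi2.sf(stat, df)), method, df=df)


# ---------------------------------------------------------------------------
# rank correlation


def spearman(x, y, method: str = "t-approx") -> CorrelationResult:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    ``method='t-approx'`` (default) tests rho with t = rho sqrt((n-2)/(1-rho^2))
    on n-2 degrees of freedom; ``method='exact'`` enumerates all
    permutations of one variable (n <= 10) and reports the two-sided
    fraction with |rho| at least as extreme.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(np.nan, np.nan, n, "spearman-undefined-constant-input")
    rx, ry = _midranks(x), _midranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "exact":
        if n > 10:
            raise ValueError("exact permutation p is limited to n <= 10")
        p = _exact_spearman_p(rx, ry, rho)
        return CorrelationResult(rho, p, n, "spearman-exact-permutation")
    if abs(rho) >= 1.0:
        return CorrelationResult(rho, 0.0, n, "spearman-t")
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(rho, min(p, 1.0), n, "spearman-t")


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman, evaluated in chunks."""
    n = len(rx)
    rx_c = rx - rx.mean()
    denom = np.sqrt(np.sum(rx_c ** 2) * np.sum((ry - ry.mean()) ** 2))
    count = 0
    total = 0
    chunk = []
    tol = 1e-12
    for perm in permutations(ry):
        chunk.append(perm)
        if len(chunk) == 100_000:
            count += _chunk_extreme(np.array(chunk), rx_c, denom, abs(rho_obs), tol)
            total += len(chunk)
            chunk = []
    if chunk:
        count += _chunk_extreme(np.array(chunk), rx_c, denom, abs(rho_obs), tol)
        total += len(chunk)
    return count / total


def _chunk_extreme(perms: np.ndarray, rx_c: np.ndarray, denom: float,
                   rho_abs: float, tol: float) -> int:
    rhos = (perms - perms.mean(axis=1, keepdims=True)) @ rx_c / denom
    return int(np.count_nonzero(np.abs(rhos) >= rho_abs - tol))


# ---------------------------------------------------------------------------
# ROC


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC for a score predicting a binary event.

    Higher scores must predict the event (label 1); an ordinal predictor
    whose high values predict the non-event (e.g. MT grade versus
    haemorrhage) should be sign-flipped by the caller.  Tied scores are
    grouped at a single threshold; the trapezoidal area then equals the
    Mann-Whitney probability P(score_pos > score_neg) + 0.5 P(tie).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    thresholds = np.unique(scores)[::-1]
    sens = np.empty(len(thresholds) + 1)
    fpr = np.empty(len(thresholds) + 1)
    sens[0] = fpr[0] = 0.0
    for k, thr in enumerate(thresholds, start=1):
        pred = scores >= thr
        sens[k] = np.sum(pred & (labels == 1)) / n_pos
        fpr[k] = np.sum(pred & (labels == 0)) / n_neg
    auc = float(np.trapezoid(sens, fpr))
    return ROCResult(auc, thresholds, sens, fpr, n_pos, n_neg)


def mann_whitney_auc(scores, labels) -> float:
    """AUC by exhaustive pair counting: (concordant + ties/2) / (n1 n0)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    gt = np.sum(pos[:, None] > neg[None, :])
    eq = np.sum(pos[:, None] == neg[None, :])
    return float((gt + 0.5 * eq) / (len(pos) * len(neg)))


# ---------------------------------------------------------------------------
# agreement


def cohens_kappa(ratings_r1, ratings_r2, weights: Optional[str] = None) -> AgreementResult:
    """Cohen's kappa between two raters on a shared category set.

    Unweighted by default; ``weights='linear'`` or ``'quadratic'`` enables
    weighted kappa for ordinal categories.  Returns NaN with a note when
    chance agreement is 1 (both raters constant and identical).
    """
    r1 = np.asarray(ratings_r1)
    r2 = np.asarray(ratings_r2)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("ratings must be equal-length 1-D sequences")
    cats = np.unique(np.concatenate([r1, r2]))
    k = len(cats)
    idx = {c: i for i, c in enumerate(cats)}
    conf = np.zeros((k, k))
    for a, b in zip(r1, r2):
        conf[idx[a], idx[b]] += 1
    n = conf.sum()
    pm = conf / n
    row = pm.sum(axis=1)
    col = pm.sum(axis=0)
    if weights is None:
        w = 1.0 - np.eye(k)
    elif weights == "linear":
        w = np.abs(np.subtract.outer(np.arange(k), np.arange(k))) / max(k - 1, 1)
    elif weights == "quadratic":
        w = (np.subtract.outer(np.arange(k), np.arange(k)) / max(k - 1, 1)) ** 2
    else:
        raise ValueError("weights must be None, 'linear' or 'quadratic'")
    po_w = np.sum(w * pm)
    pe_w = np.sum(w * np.outer(row, col))
    if pe_w == 0:
        return AgreementResult(np.nan, int(n), k,
                               "cohens-kappa", note="undefined: chance agreement is 1")
    kappa = float(1.0 - po_w / pe_w)
    method = "cohens-kappa" if weights is None else f"cohens-kappa-{weights}"
    return AgreementResult(kappa, int(n), k, method)


def icc(ratings, kind: str = "icc2") -> AgreementResult:
    """Intraclass correlation from the two-way ANOVA mean squares.

    ``ratings`` is an n x k matrix (subjects x raters), complete.
    ``kind='icc2'`` (default) is the two-way random-effects,
    absolute-agreement, single-measure ICC(2,1) — the standard choice for
    two interchangeable readers of a continuous quantity; ``kind='icc3'``
    is the consistency form ICC(3,1).  Degenerate data with zero
    between-subject variance report 0 with a note.
    """
    Y = np.asarray(ratings, dtype=float)
    if Y.ndim != 2:
        raise ValueError("ratings must be an n x k matrix")
    n, k = Y.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    if np.any(~np.isfinite(Y)):
        raise ValueError("ratings matrix must be complete")
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if ss_rows == 0:
        return AgreementResult(0.0, n, k, kind,
                               note="degenerate: zero between-subject variance")
    if kind == "icc2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        val = (msr - mse) / denom
        method = "icc(2,1)-absolute-agreement"
    elif kind == "icc3":
        val = (msr - mse) / (msr + (k - 1) * mse)
        method = "icc(3,1)-consistency"
    else:
        raise ValueError("kind must be 'icc2' or 'icc3'")
    return AgreementResult(float(val), n, k, method)


# ---------------------------------------------------------------------------
# group comparisons


def kruskal_wallis(groups: Sequence) -> TestResult:
    """Kruskal-Wallis H on mid-ranks with the tie correction.

    p from the chi-square approximation with (g - 1) degrees of freedom.
    All observations identical yields H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    N = len(pooled)
    if N < 3:
        raise ValueError("need at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "kruskal-wallis", df=len(groups) - 1,
                          note="all observations identical")
    ranks = _midranks(pooled)
    H = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        start += len(g)
        H += len(g) * (r.mean() - (N + 1) / 2.0) ** 2
    H *= 12.0 / (N * (N + 1))
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (N ** 3 - N)
    H /= tie
    df = len(groups) - 1
    return TestResult(float(H), float(sps.chi2.sf(H, df)), "kruskal-wallis", df=df)


def oneway_anova(groups: Sequence) -> TestResult:
    """One-way fixed-effects ANOVA, F = MS_between / MS_within."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    N = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    df_b = len(groups) - 1
    df_w = N - len(groups)
    if ss_within == 0:
        if ss_between > 0:
            return TestResult(np.inf, 0.0, "anova-F", df=df_b,
                              note="zero within-group variance with unequal means")
        return TestResult(0.0, 1.0, "anova-F", df=df_b,
                          note="all observations identical")
    F = (ss_between / df_b) / (ss_within / df_w)
    return TestResult(float(F), float(sps.f.sf(F, df_b, df_w)), "anova-F", df=df_b)


# ---------------------------------------------------------------------------
# normality


def ks_normality(sample, corrected: bool = True) -> TestResult:
    """One-sample Kolmogorov-Smirnov test against a fitted normal.

    The reference normal uses the sample mean and the ddof=1 standard
    deviation.  Because the parameters are estimated from the same data,
    the naive asymptotic p-value is anti-conservative; by default the
    Lilliefors-corrected p (Dallal-Wilkinson approximation) is reported.
    ``corrected=False`` returns the naive Kolmogorov asymptotic p for
    comparison.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality test undefined")
    F = sps.norm.cdf((x - x.mean()) / sd)
    i = np.arange(1, n + 1)
    D = float(max(np.max(i / n - F), np.max(F - (i - 1) / n)))
    if corrected:
        return TestResult(D, _lilliefors_p(D, n), "ks-lilliefors")
    return TestResult(D, float(special.kolmogorov(np.sqrt(n) * D)), "ks-naive-asymptotic")


def _lilliefors_p(D: float, n: int) -> float:
    """Dallal-Wilkinson closed-form approximation to the Lilliefors p.

    Accurate in the rejection region (p <= 0.1); larger values are clipped
    to 1, which never changes a decision at conventional alpha.
    """
    if n > 100:
        D = D * (n / 100.0) ** 0.49
        n = 100
    p = np.exp(-7.01256 * D ** 2 * (n + 2.78019)
               + 2.99587 * D * np.sqrt(n + 2.78019)
               - 0.122119 + 0.974598 / np.sqrt(n) + 1.67997 / n)
    return float(min(p, 1.0))
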