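"""Reliability and validity statistics.

The evaluation toolkit used to qualify the instrument: Bland-Altman
repeatability of test-retest scores, Pearson correlations with Fisher-z
confidence intervals, the Hotelling-Williams test for two dependent
correlations sharing a variable, ROC AUC with a Hanley-McNeil interval,
odds ratios with Fisher's exact test for 2x2 prevalence tables, and the
LMG (Lindeman-Merenda-Gold) decomposition of regression R^2 into
per-regressor shares averaged over all orderings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.stats.contingency import odds_ratio as _conditional_or
from sklearn.metrics import roc_auc_score

__all__ = [
    "BlandAltmanResult", "LmgDecomposition", "TwoByTwo", "OddsRatioResult",
    "bland_altman", "pearson_with_ci", "williams_test", "roc_auc",
    "odds_ratio", "reconstruct_counts", "lmg_decomposition", "bonferroni",
]


# ---------------------------------------------------------------------------
# Bland-Altman repeatability
# ---------------------------------------------------------------------------


@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    t_statistic: float
    p_value: float
    limits: tuple  # mean_diff +/- 2 sd_diff
    pct_within_limits: float
    n: int

    @property
    def repeatable(self) -> bool:
        """Mean difference indistinguishable from 0 and >=95% within limits."""
        return self.p_value > 0.05 and self.pct_within_limits >= 95.0


def bland_altman(test1, test2) -> BlandAltmanResult:
    """Repeatability of paired measurements by the limits-of-agreement method."""
    x = np.asarray(test1, dtype=float)
    y = np.asarray(test2, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length paired vectors of length >= 3")
    d = y - x
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        # all differences identical; a constant zero difference is perfectly
        # repeatable, a constant nonzero one is a pure offset
        t, p = (0.0, 1.0) if mean == 0 else (math.inf, 0.0)
    else:
        t, p = stats.ttest_1samp(d, 0.0)
        t, p = float(t), float(p)
    limits = (mean - 2 * sd, mean + 2 * sd)
    within = float(np.mean((d >= limits[0]) & (d <= limits[1])) * 100)
    return BlandAltmanResult(mean, sd, t, p, limits, within, x.size)


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


def pearson_with_ci(x, y, alpha: float = 0.05):
    """Pearson r with Fisher-z confidence interval, df and p.

    Returns (r, (lo, hi), df, p) with df = n - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired vectors of length >= 4")
    r, p = stats.pearsonr(x, y)
    n = x.size
    z = np.arctanh(r)
    se = 1.0 / math.sqrt(n - 3)
    crit = stats.norm.ppf(1 - alpha / 2)
    ci = (float(np.tanh(z - crit * se)), float(np.tanh(z + crit * se)))
    return float(r), ci, n - 2, float(p)


def williams_test(r_jk: float, r_jh: float, r_kh: float, n: int):
    """Hotelling-Williams t for two dependent correlations sharing variable j.

    Tests r_jk == r_jh given the correlation r_kh between the competing
    predictors; t has n - 3 degrees of freedom (Williams 1959 / Steiger
    1980 formulation). Returns (t, two-sided p).
    """
    if n < 5:
        raise ValueError("Williams test needs n >= 5")
    for r in (r_jk, r_jh, r_kh):
        if not -1 < r < 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    detR = 1 - r_jk**2 - r_jh**2 - r_kh**2 + 2 * r_jk * r_jh * r_kh
    rbar = 0.5 * (r_jk + r_jh)
    num = (r_jk - r_jh) * math.sqrt((n - 1) * (1 + r_kh))
    den = math.sqrt(2 * ((n - 1) / (n - 3)) * detR
                    + rbar**2 * (1 - r_kh) ** 3)
    t = num / den
    p = 2 * stats.t.sf(abs(t), n - 3)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


def roc_auc(score, label, alpha: float = 0.05):
    """ROC AUC with a Hanley-McNeil confidence interval.

    AUC via the Mann-Whitney identity (ties count 1/2); CI from the
    Hanley-McNeil (1982) variance formula, clipped to [0, 1].
    """
    s = np.asarray(score, dtype=float)
    y = np.asarray(label)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    auc = float(roc_auc_score(y, s))
    n1 = int(np.sum(y == classes[1]))
    n2 = int(np.sum(y == classes[0]))
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2)
           + (n2 - 1) * (q2 - auc**2)) / (n1 * n2)
    se = math.sqrt(max(var, 0.0))
    crit = stats.norm.ppf(1 - alpha / 2)
    ci = (max(0.0, auc - crit * se), min(1.0, auc + crit * se))
    return auc, ci


# ---------------------------------------------------------------------------
# 2x2 prevalence tables
# ---------------------------------------------------------------------------


@dataclass
class TwoByTwo:
    """Counts a,b (group 1 exposed/unexposed), c,d (group 2)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("cell counts must be non-negative integers")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class OddsRatioResult:
    sample_or: float              # cross-product ratio ad/bc
    conditional_or: float         # conditional MLE (Fisher-test parity)
    fisher_p: float               # two-sided exact p
    ci_woolf: tuple
    ci_exact: tuple               # exact conditional CI
    haldane_corrected: bool = False


def odds_ratio(table: TwoByTwo, alpha: float = 0.05) -> OddsRatioResult:
    """Odds ratio with Fisher exact p and both Woolf and exact CIs.

    The sample estimate is the cross-product ratio; zero cells get the
    Haldane-Anscombe 0.5 correction (flagged) for the point estimate and
    Woolf CI, while the exact p and conditional CI are unaffected. The
    conditional-MLE estimate matches R's ``fisher.test`` output.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    haldane = 0 in (a, b, c, d)
    if haldane:
        aa, bb, cc, dd = (v + 0.5 for v in (a, b, c, d))
    else:
        aa, bb, cc, dd = a, b, c, d
    sample = (aa * dd) / (bb * cc)
    log_se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    crit = stats.norm.ppf(1 - alpha / 2)
    woolf = (sample * math.exp(-crit * log_se), sample * math.exp(crit * log_se))

    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    res = _conditional_or(table.as_array())
    ci = res.confidence_interval(1 - alpha)
    return OddsRatioResult(float(sample), float(res.statistic), float(p),
                           woolf, (float(ci.low), float(ci.high)), haldane)


def reconstruct_counts(prev1_pct: float, n1: int, prev2_pct: float,
                       n2: int, tol: float = 0.05) -> TwoByTwo:
    """Rebuild a 2x2 table from printed prevalence percentages and group Ns.

    Warns (ValueError is *not* raised) via a flag check: each prevalence
    times n must land within ``tol`` of an integer, else the printed
    percentage cannot come from these group sizes.
    """
    import warnings

    cells = []
    for prev, n in ((prev1_pct, n1), (prev2_pct, n2)):
        exact = prev / 100.0 * n
        k = round(exact)
        if abs(exact - k) > tol:
            warnings.warn(
                f"prevalence {prev}% of n={n} gives {exact:.3f}, "
                f"not within {tol} of an integer", stacklevel=2)
        cells.append(int(k))
    return TwoByTwo(cells[0], n1 - cells[0], cells[1], n2 - cells[1])


# ---------------------------------------------------------------------------
# LMG variance decomposition
# ---------------------------------------------------------------------------


@dataclass
class LmgDecomposition:
    names: list
    shares: np.ndarray  # fraction of response variance per regressor
    model_r2: float


def _r2_from_corr(ryx: np.ndarray, Rxx: np.ndarray, subset: tuple) -> float:
    if not subset:
        return 0.0
    idx = list(subset)
    r = ryx[idx]
    R = Rxx[np.ix_(idx, idx)]
    return float(r @ np.linalg.solve(R, r))


def lmg_decomposition(y, X, names=None) -> LmgDecomposition:
    """LMG relative importance: R^2 shares averaged over regressor orderings.

    share_j is the average, over all p! orderings, of the R^2 increment
    when regressor j enters; computed equivalently as a weighted average
    over subsets S not containing j of R^2(S u {j}) - R^2(S), with weight
    |S|! (p - |S| - 1)! / p!. Shares sum to the full-model R^2 exactly.
    Requires p <= 10 regressors (exact enumeration) and full column rank.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if p > 10:
        raise ValueError("exact LMG enumeration limited to p <= 10 regressors")
    if n <= p:
        raise ValueError("need more observations than regressors")
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]

    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    bad = [names[j] for j in range(p) if sd[j] == 0]
    if bad:
        raise ValueError(f"constant regressor column(s): {bad}")
    rank = np.linalg.matrix_rank(Xc)
    if rank < p:
        # name offending columns: those whose removal restores full rank
        offending = [names[j] for j in range(p)
                     if np.linalg.matrix_rank(np.delete(Xc, j, axis=1)) == rank]
        raise ValueError(f"rank-deficient regressor matrix; offending columns: "
                         f"{offending}")

    yc = y - y.mean()
    ysd = yc.std()
    if ysd == 0:
        raise ValueError("response has zero variance")
    Z = Xc / sd
    u = yc / ysd
    Rxx = (Z.T @ Z) / n
    ryx = (Z.T @ u) / n

    r2 = {(): 0.0}
    for size in range(1, p + 1):
        for subset in combinations(range(p), size):
            r2[subset] = _r2_from_corr(ryx, Rxx, subset)

    fact = [math.factorial(i) for i in range(p + 1)]
    shares = np.zeros(p)
    for j in range(p):
        others = [i for i in range(p) if i != j]
        for size in range(0, p):
            w = fact[size] * fact[p - size - 1] / fact[p]
            for subset in combinations(others, size):
                with_j = tuple(sorted(subset + (j,)))
                shares[j] += w * (r2[with_j] - r2[subset])
    model_r2 = r2[tuple(range(p))]
    return LmgDecomposition(list(names), shares, model_r2)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values (family size defaults to the list length)."""
    p = np.asarray(p_values, dtype=float)
    m = m or p.size
    return np.minimum(p * m, 1.0)
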