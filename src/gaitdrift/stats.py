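"""Repeated-measures statistics over control variables and classification rates.

The analysis pipeline mirrors standard practice for small repeated-measures
designs (n = 9 subjects x 4 time intervals):

* a Shapiro-Wilk normality gate decides between the parametric path
  (repeated-measures ANOVA with Mauchly's sphericity test, Greenhouse-Geisser
  correction and partial eta-squared, post-hoc paired t-tests) and the
  nonparametric path (Friedman test, post-hoc Wilcoxon signed-rank tests with
  the r = Z / sqrt(n) effect size);
* post-hoc p values are Bonferroni-adjusted over the comparison family
  (m = 6 for the 4-interval family, m = 15 for 6 sessions).

Partial eta-squared is computed from the *uncorrected* degrees of freedom,
eta2 = F*df1 / (F*df1 + df2), also when Greenhouse-Geisser-corrected degrees
of freedom are reported for the p value.  The Wilcoxon test reports the exact
two-sided p (enumeration over sign assignments) for up to 25 non-zero pairs
and the tie-corrected normal approximation above, together with the
SPSS-style Z statistic; r uses the total number of pairs by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DegenerateDataError",
    "TestResult",
    "RmAnovaResult",
    "eta_squared_partial",
    "shapiro_wilk_gate",
    "rm_anova",
    "friedman_test",
    "wilcoxon_signed_rank",
    "bonferroni",
    "posthoc_wilcoxon",
    "posthoc_paired_t",
    "results_to_frame",
]


class DegenerateDataError(ValueError):
    """All-zero differences, zero variance or similar degenerate input."""


@dataclass
class TestResult:
    __test__ = False  # statistical result container, not a pytest class

    name: str
    statistic: float
    df: float | tuple[float, float]
    p_raw: float
    p_adjusted: float | None = None
    effect_size: float | None = None
    effect_type: str | None = None
    correction_applied: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0):
            raise ValueError("p_raw outside [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_raw - 1e-12:
            raise ValueError("adjusted p below raw p")


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a subjects x conditions table")
    if np.isnan(arr).any():
        raise ValueError("incomplete table: missing cells")
    if arr.shape[1] < 2:
        raise ValueError("need at least 2 conditions")
    return arr


def eta_squared_partial(f: float, df1: float, df2: float) -> float:
    """Partial eta-squared from an F statistic and its uncorrected df."""
    return f * df1 / (f * df1 + df2)


def shapiro_wilk_gate(table, alpha_level: float = 0.05):
    """Decide the analysis path from per-condition Shapiro-Wilk tests.

    Returns ``(path, p_values, note)`` where path is ``'nonparametric'`` if
    any condition rejects normality at ``alpha_level`` (or is degenerate),
    else ``'parametric'``.  The path also drives the descriptive convention:
    mean +- sd on the parametric path, median (Q1-Q3) otherwise.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if np.isnan(arr).any():
        raise ValueError("incomplete table: missing cells")
    if arr.shape[0] < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3 per condition")
    p_values, notes = [], []
    for j in range(arr.shape[1]):
        col = arr[:, j]
        if np.ptp(col) == 0:
            p_values.append(0.0)
            notes.append(f"condition {j}: constant sample (degenerate input)")
            continue
        p_values.append(float(sps.shapiro(col).pvalue))
    path = (
        "nonparametric"
        if any(p < alpha_level for p in p_values) or notes
        else "parametric"
    )
    return path, p_values, "; ".join(notes)


@dataclass
class RmAnovaResult:
    f: float
    df1: float
    df2: float
    p: float
    eta_sq_partial: float
    mauchly_w: float | None
    mauchly_p: float | None
    gg_epsilon: float
    sphericity_violated: bool
    df1_corrected: float
    df2_corrected: float
    p_uncorrected: float

    def as_test_result(self) -> TestResult:
        return TestResult(
            name="rm_anova",
            statistic=self.f,
            df=(self.df1_corrected, self.df2_corrected)
            if self.sphericity_violated
            else (self.df1, self.df2),
            p_raw=self.p,
            effect_size=self.eta_sq_partial,
            effect_type="eta_sq_partial",
            correction_applied=self.sphericity_violated,
            note="Greenhouse-Geisser corrected df" if self.sphericity_violated else "",
        )


def _mauchly(arr: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity test on the orthonormal-contrast covariance."""
    n, k = arr.shape
    # orthonormal contrasts: QR of a (k, k-1) Helmert-like matrix
    h = np.eye(k) - 1.0 / k
    q, _ = np.linalg.qr(h[:, : k - 1])
    y = arr @ q  # (n, k-1)
    s = np.cov(y, rowvar=False, ddof=1)
    d = k - 1
    eig = np.linalg.eigvalsh(s)
    if np.any(eig <= 0):
        return 0.0, 0.0  # singular contrast covariance: maximal violation
    w = float(np.prod(eig) / (np.mean(eig) ** d))
    f_corr = (2 * d * d + d + 2) / (6.0 * d)
    chi2 = -(n - 1 - f_corr) * np.log(w)
    df = d * (d + 1) // 2 - 1
    if df <= 0:
        return 1.0, 1.0
    return w, float(sps.chi2.sf(chi2, df))


def _gg_epsilon(arr: np.ndarray) -> float:
    n, k = arr.shape
    h = np.eye(k) - 1.0 / k
    q, _ = np.linalg.qr(h[:, : k - 1])
    y = arr @ q
    s = np.cov(y, rowvar=False, ddof=1)
    d = k - 1
    eps = np.trace(s) ** 2 / (d * np.trace(s @ s))
    return float(np.clip(eps, 1.0 / d, 1.0))


def rm_anova(table, alpha_sphericity: float = 0.05) -> RmAnovaResult:
    """One-way within-subject ANOVA with sphericity machinery.

    F with df (k-1, (k-1)(n-1)); if Mauchly rejects at ``alpha_sphericity``
    (requires k >= 3), both df are multiplied by the Greenhouse-Geisser
    epsilon for the reported p.  Partial eta-squared always uses the
    uncorrected df.
    """
    arr = _as_table(table)
    n, k = arr.shape
    grand = arr.mean()
    ss_cond = n * np.sum((arr.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((arr.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((arr - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = float(k - 1), float((k - 1) * (n - 1))
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    f = float(ms_cond / ms_err) if ms_err > 0 else 0.0
    p_unc = float(sps.f.sf(f, df1, df2)) if ms_err > 0 else 1.0

    if k >= 3:
        w, mauchly_p = _mauchly(arr)
        eps = _gg_epsilon(arr)
        violated = mauchly_p < alpha_sphericity
    else:
        w, mauchly_p, eps, violated = None, None, 1.0, False
    df1_c, df2_c = eps * df1, eps * df2
    p = float(sps.f.sf(f, df1_c, df2_c)) if violated else p_unc
    return RmAnovaResult(
        f=f,
        df1=df1,
        df2=df2,
        p=p,
        eta_sq_partial=eta_squared_partial(f, df1, df2),
        mauchly_w=w,
        mauchly_p=mauchly_p,
        gg_epsilon=eps,
        sphericity_violated=violated,
        df1_corrected=df1_c,
        df2_corrected=df2_c,
        p_uncorrected=p_unc,
    )


def friedman_test(table) -> TestResult:
    """Friedman chi-square over conditions with average-rank tie handling."""
    arr = _as_table(table)
    n, k = arr.shape
    if np.all(np.ptp(arr, axis=1) == 0):
        return TestResult(
            name="friedman",
            statistic=0.0,
            df=float(k - 1),
            p_raw=1.0,
            note="all rows fully tied: no rank variation",
        )
    stat, p = sps.friedmanchisquare(*[arr[:, j] for j in range(k)])
    return TestResult(
        name="friedman", statistic=float(stat), df=float(k - 1), p_raw=float(p)
    )


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by enumeration of the sign-assignment distribution.

    Uses a subset-sum convolution over doubled ranks (integers even with
    average-rank ties), equivalent to summing over all 2^n assignments.
    """
    scaled = np.rint(2.0 * ranks).astype(int)
    total = int(scaled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w = int(np.rint(2.0 * w_plus))
    p_low = counts[: w + 1].sum()
    p_high = counts[w:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def wilcoxon_signed_rank(
    x, y, n_for_r: int | None = None, exact_limit: int = 25
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; the exact enumeration p is used for up to
    ``exact_limit`` non-zero pairs, the tie-corrected normal approximation
    (no continuity correction, SPSS convention) above.  The effect size is
    r = Z / sqrt(n) with n the total number of pairs unless ``n_for_r`` is
    given.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    n_total = len(d)
    d_nz = d[d != 0]
    n = len(d_nz)
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    if n < 5:
        raise ValueError("need at least 5 non-zero differences")
    ranks = sps.rankdata(np.abs(d_nz))
    w_plus = float(ranks[d_nz > 0].sum())

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        raise DegenerateDataError("zero variance in signed ranks")
    z = (w_plus - mean) / np.sqrt(var)

    if n <= exact_limit:
        p = _exact_signed_rank_p(ranks, w_plus)
        note = "exact enumeration"
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
        note = "normal approximation"
    n_r = n_for_r if n_for_r is not None else n_total
    return TestResult(
        name="wilcoxon_signed_rank",
        statistic=float(z),
        df=float(n),
        p_raw=p,
        effect_size=float(z / np.sqrt(n_r)),
        effect_type="r",
        note=note,
    )


def bonferroni(p_values, m: int | None = None):
    """p_adj = min(1, m * p); m defaults to the number of comparisons."""
    arr = np.atleast_1d(np.asarray(p_values, dtype=float))
    if m is None:
        m = arr.size
    if m < arr.size:
        raise ValueError("m must cover the number of comparisons")
    out = np.minimum(1.0, m * arr)
    return float(out[0]) if np.isscalar(p_values) or arr.size == 1 else out


def posthoc_wilcoxon(
    table, condition_names=None, m: int | None = None, n_for_r: int | None = None
) -> list[TestResult]:
    """All pairwise Wilcoxon tests with Bonferroni adjustment (default m = C(k,2))."""
    arr = _as_table(table)
    n, k = arr.shape
    names = condition_names or [f"C{j + 1}" for j in range(k)]
    pairs = list(combinations(range(k), 2))
    m = m if m is not None else len(pairs)
    results = []
    for i, j in pairs:
        try:
            res = wilcoxon_signed_rank(
                arr[:, i], arr[:, j], n_for_r=n_for_r or n
            )
        except DegenerateDataError:
            res = TestResult(
                name="wilcoxon_signed_rank",
                statistic=0.0,
                df=0.0,
                p_raw=1.0,
                note="all differences zero",
            )
        res.name = f"wilcoxon[{names[i]} vs {names[j]}]"
        res.p_adjusted = float(bonferroni(res.p_raw, m))
        res.correction_applied = True
        results.append(res)
    return results


def posthoc_paired_t(
    table, condition_names=None, m: int | None = None
) -> list[TestResult]:
    """All pairwise paired t-tests with Bonferroni adjustment (m = C(k,2))."""
    arr = _as_table(table)
    _, k = arr.shape
    names = condition_names or [f"C{j + 1}" for j in range(k)]
    pairs = list(combinations(range(k), 2))
    m = m if m is not None else len(pairs)
    results = []
    for i, j in pairs:
        t, p = sps.ttest_rel(arr[:, i], arr[:, j])
        results.append(
            TestResult(
                name=f"paired_t[{names[i]} vs {names[j]}]",
                statistic=float(t),
                df=float(arr.shape[0] - 1),
                p_raw=float(p),
                p_adjusted=float(bonferroni(float(p), m)),
                correction_applied=True,
            )
        )
    return results


def results_to_frame(results: list[TestResult], family: str = "") -> pd.DataFrame:
    """Tidy CSV-ready frame: family, comparison, statistic, df, p, effect."""
    rows = []
    for r in results:
        rows.append(
            {
                "family": family,
                "comparison": r.name,
                "statistic": r.statistic,
                "df": str(r.df),
                "p_raw": r.p_raw,
                "p_adj": r.p_adjusted,
                "effect": r.effect_size,
                "effect_type": r.effect_type,
                "note": r.note,
            }
        )
    return pd.DataFrame(rows)
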