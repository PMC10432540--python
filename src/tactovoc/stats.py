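"""Scoring and the study's statistical battery.

Percent-correct score tables feed paired t-tests (optionally reconstructed
from printed mean/SD/n summaries), a step-down Holm–Bonferroni correction
whose family size may exceed the number of p-values supplied (the study
corrects its secondary battery for 51 tests), within-subject repeated-
measures ANOVAs with one to three factors, Mauchly's sphericity test, and
Spearman rank correlations for the exploratory analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM

__all__ = [
    "SummaryStats",
    "TTestResult",
    "MauchlyResult",
    "percent_correct",
    "paired_t_from_summary",
    "paired_t",
    "holm_correction",
    "rm_anova",
    "mauchly_sphericity",
    "spearman",
]


@dataclass(frozen=True)
class SummaryStats:
    """Mean/SD/n of a within-subject difference, in percentage points."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("need at least 2 subjects")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_two_tailed: float
    p_corrected: float | None = None


@dataclass(frozen=True)
class MauchlyResult:
    w: float
    chi2: float
    df: int
    p: float


def percent_correct(trials: pd.DataFrame, by=("condition",)) -> pd.DataFrame:
    """100 * correct / total per grouping cell.

    ``trials`` needs a boolean ``correct`` column with no missing values
    (every trial must have been responded to).
    """
    if trials.empty:
        raise ValueError("empty trial table")
    if trials["correct"].isna().any():
        raise ValueError("trials without responses present")
    out = (
        trials.groupby(list(by), observed=True)["correct"]
        .agg(percent_correct=lambda c: 100.0 * np.mean(c), n_trials="size")
        .reset_index()
    )
    return out


def paired_t_from_summary(s: SummaryStats) -> TTestResult:
    """Paired t reconstructed from summary statistics: t = mean/(sd/sqrt(n))."""
    df = s.n - 1
    if s.sd == 0:
        if s.mean == 0:
            return TTestResult(t=0.0, df=df, p_two_tailed=1.0)
        # zero spread with a nonzero mean: flag as infinite
        return TTestResult(t=math.copysign(math.inf, s.mean), df=df, p_two_tailed=0.0)
    t = s.mean / (s.sd / math.sqrt(s.n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p_two_tailed=float(min(p, 1.0)))


def paired_t(x, y) -> TTestResult:
    """Two-tailed paired t-test on raw per-subject scores."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of at least 2 subjects")
    res = sps.ttest_rel(x, y)
    return TTestResult(
        t=float(res.statistic), df=x.size - 1, p_two_tailed=float(res.pvalue)
    )


def holm_correction(pvals, m: int | None = None) -> np.ndarray:
    """Step-down Holm–Bonferroni adjusted p-values.

    ``m`` is the family size and may exceed ``len(pvals)`` when the family
    includes tests whose p-values are not being adjusted here (the study's
    51-test secondary family).  Sorted ascending, the i-th smallest raw p
    is multiplied by (m - i) (0-based) and a running maximum enforces
    monotonicity; values are capped at 1.
    """
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    valid = ~np.isnan(p)  # undefined tests (e.g. zero-variance differences) propagate
    if np.any((p[valid] <= 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m cannot be smaller than the number of p-values")
    out = np.full_like(p, np.nan)
    pv = p[valid]
    if pv.size:
        order = np.argsort(pv, kind="stable")
        mult = m - np.arange(pv.size)
        stepped = np.minimum(np.maximum.accumulate(pv[order] * mult), 1.0)
        adj = np.empty_like(pv)
        adj[order] = stepped
        out[valid] = adj
    return out


def rm_anova(
    data: pd.DataFrame, dv: str, subject: str, within: list[str]
) -> pd.DataFrame:
    """Within-subject (repeated-measures) ANOVA on a balanced long table.

    Each effect is tested against its own effect-by-subject interaction
    mean square.  One to three within factors are supported; replicate
    observations per cell are averaged first.  Returns a tidy frame with
    columns effect, F, df_num, df_den, p.
    """
    if not 1 <= len(within) <= 3:
        raise ValueError("supports 1 to 3 within factors")
    cell_counts = data.groupby([subject, *within], observed=True)[dv].count()
    if cell_counts.empty or (cell_counts.unstack(within).isna().any().any()):
        raise ValueError("missing cells: design must be complete")
    # neutral column names sidestep the formula machinery's reserved words
    # (a factor literally named "C" collides with the contrast function)
    safe = {dv: "_dv", subject: "_subject"}
    safe.update({w: f"_w{i}" for i, w in enumerate(within)})
    res = AnovaRM(
        data.rename(columns=safe),
        depvar="_dv",
        subject="_subject",
        within=[safe[w] for w in within],
        aggregate_func="mean",
    ).fit()
    back = {v: k for k, v in safe.items()}
    tbl = res.anova_table.reset_index().rename(
        columns={
            "index": "effect",
            "F Value": "F",
            "Num DF": "df_num",
            "Den DF": "df_den",
            "Pr > F": "p",
        }
    )
    tbl["effect"] = tbl["effect"].map(
        lambda name: " x ".join(back[part] for part in name.split(":"))
    )
    return tbl[["effect", "F", "df_num", "df_den", "p"]]


def mauchly_sphericity(
    data: pd.DataFrame, dv: str, subject: str, within: str
) -> MauchlyResult:
    """Mauchly's test of sphericity for a within factor with >= 3 levels.

    W is computed on the covariance matrix of k-1 orthonormal contrasts of
    the subject-by-level means; the p-value uses the standard chi-square
    approximation with df = k(k-1)/2 - 1.
    """
    wide = data.groupby([subject, within], observed=True)[dv].mean().unstack(within)
    if wide.isna().any().any():
        raise ValueError("missing cells: design must be complete")
    x = wide.to_numpy(dtype=np.float64)
    n, k = x.shape
    if k < 3:
        raise ValueError("Mauchly's test needs a factor with at least 3 levels")
    if n <= k:
        raise ValueError("need more subjects than factor levels")
    # orthonormal contrasts: Helmert basis orthogonal to the unit vector
    full = np.linalg.qr(
        np.column_stack([np.ones(k), np.eye(k)[:, : k - 1]])
    )[0]
    contrasts = full[:, 1:]
    y = x @ contrasts
    s = np.cov(y, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(s)
    if np.any(eig <= 0):
        raise ValueError("contrast covariance is singular")
    d = k - 1
    w = float(np.prod(eig) / (np.mean(eig) ** d))
    f_corr = 1.0 - (2.0 * d * d + d + 2.0) / (6.0 * d * (n - 1.0))
    chi2 = -(n - 1.0) * f_corr * math.log(w)
    df = k * (k - 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, df))
    return MauchlyResult(w=w, chi2=float(chi2), df=df, p=p)


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation and two-tailed p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no rank correlation")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
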