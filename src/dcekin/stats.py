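"""Statistical layer: normality-routed group tests, paired tests, ROC, ICC.

The routing mirrors common radiology-study practice: each group is checked
for normality with a one-sample Kolmogorov-Smirnov test against a normal
with the sample's own mean and SD (the classical caveat applies — with
estimated parameters the KS test is conservative, the Lilliefors
correction is not applied); if both groups pass, an independent-samples
Welch t-test is used, otherwise the Mann-Whitney U test (exact for small
samples without ties). Discrimination of 6-month progressive disease is
quantified by the ROC area under the curve, and two-reader agreement by
the single-measure absolute-agreement intraclass correlation ICC(2,1)
with the conventional verbal grading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

__all__ = [
    "TestResult",
    "RocResult",
    "IccResult",
    "ALPHA",
    "ks_normality",
    "compare_groups",
    "paired_t",
    "roc_auc",
    "icc_agreement",
    "grade_icc",
]

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n: tuple
    route: str  # "parametric" | "nonparametric"

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must be in [0, 1]")


@dataclass(frozen=True)
class RocResult:
    auc: float
    n_positive: int
    n_negative: int
    orientation: str  # "higher" if larger scores predict the positive label

    def __post_init__(self) -> None:
        if not 0 <= self.auc <= 1:
            raise ValueError("auc must be in [0, 1]")
        if self.n_positive < 1 or self.n_negative < 1:
            raise ValueError("both classes must be present")


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    category: str


def ks_normality(sample, alpha: float = ALPHA):
    """One-sample KS test against N(sample mean, sample SD).

    Returns ``(statistic, p, is_normal)`` with ``is_normal = p >= alpha``.
    A zero-variance sample is never graded normal (a degenerate point mass
    has no defined KS null), so it routes to the nonparametric branch.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 3:
        raise ValueError("normality test needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.inf, 0.0, False
    res = sps.kstest(x, sps.norm(loc=x.mean(), scale=sd).cdf)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue >= alpha)


def _mannwhitney(a: np.ndarray, b: np.ndarray):
    """Two-sided Mann-Whitney U: exact for combined n <= 12 without ties,
    otherwise normal approximation with tie correction."""
    exact = len(a) + len(b) <= 12 and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(group_a, group_b) -> TestResult:
    """Two-sample comparison routed by normality of each group.

    Both groups KS-normal -> Welch independent-samples t-test; otherwise
    Mann-Whitney U. Two-sided throughout.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    # below n = 5 the KS gate has essentially no power, so a group that small
    # is never certified normal and the comparison stays nonparametric
    normal_a = len(a) >= 5 and ks_normality(a)[2]
    normal_b = len(b) >= 5 and ks_normality(b)[2]
    if normal_a and normal_b:
        res = sps.ttest_ind(a, b, equal_var=False)
        return TestResult(
            test_name="welch_t",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            n=(len(a), len(b)),
            route="parametric",
        )
    stat, p = _mannwhitney(a, b)
    return TestResult(
        test_name="mann_whitney_u",
        statistic=stat,
        p_value=p,
        n=(len(a), len(b)),
        route="nonparametric",
    )


def paired_t(before, after) -> TestResult:
    """Two-tailed paired t-test on the within-subject differences."""
    x = np.asarray(before, dtype=float)
    y = np.asarray(after, dtype=float)
    if x.shape != y.shape:
        raise ValueError("before and after must have equal length")
    if len(x) < 2:
        raise ValueError("paired test needs n >= 2")
    d = y - x
    if d.std(ddof=1) == 0:
        raise ValueError("paired differences have zero variance; t is undefined")
    res = sps.ttest_rel(x, y)
    return TestResult(
        test_name="paired_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(len(x),),
        route="parametric",
    )


def roc_auc(scores, labels) -> RocResult:
    """ROC area under the curve for binary labels.

    ``auc`` is directional — the probability that a random positive scores
    above a random negative, ties counting half — so negating all scores
    maps auc to 1 - auc. ``orientation`` records whether higher scores
    predict the positive label (auc >= 0.5) on these data.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(y, s))
    return RocResult(
        auc=auc,
        n_positive=n_pos,
        n_negative=n_neg,
        orientation="higher" if auc >= 0.5 else "lower",
    )


# verbal grading of agreement; half-open bands cover [-1, 1] exhaustively
_ICC_BANDS = (
    (0.81, "excellent"),
    (0.61, "good"),
    (0.41, "moderate"),
    (0.21, "fair"),
    (-np.inf, "poor"),
)


def grade_icc(icc: float) -> str:
    for lo, cat in _ICC_BANDS:
        if icc >= lo:
            return cat
    raise AssertionError("unreachable")


def icc_agreement(ratings) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is an (n_subjects, 2) array or DataFrame, one column per
    reader. Requires >= 3 subjects, exactly 2 readers and no missing
    cells (no imputation is attempted).
    """
    mat = np.asarray(ratings, dtype=float)
    if mat.ndim != 2 or mat.shape[1] != 2:
        raise ValueError("ratings must be an (n_subjects, 2) matrix")
    if mat.shape[0] < 3:
        raise ValueError("ICC needs at least 3 subjects")
    if not np.all(np.isfinite(mat)):
        raise ValueError("ratings contain missing or non-finite cells")
    n = mat.shape[0]
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), 2),
            "reader": np.tile([0, 1], n),
            "rating": mat.reshape(-1),
        }
    )
    res = pg.intraclass_corr(
        data=long, targets="subject", raters="reader", ratings="rating"
    )
    # absolute-agreement single-measure row; label differs across pingouin versions
    sel = res[res["Type"].isin(["ICC2", "ICC(A,1)"])]
    row = sel.iloc[0]
    icc = float(row["ICC"])
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    ci_low, ci_high = (float(v) for v in row[ci_col])
    return IccResult(icc=icc, ci_low=ci_low, ci_high=ci_high, category=grade_icc(icc))
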