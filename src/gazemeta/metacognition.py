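"""Type-2 ROC metacognitive sensitivity and its relation to autistic traits.

Metacognitive sensitivity asks how well trial-by-trial confidence
discriminates a subject's correct from incorrect responses.  With an
11-point confidence grid (0, 10, ..., 100) the criterion sweep takes each
level in turn as the low/high boundary -- starting where only a rating of
0 counts as low confidence and ending where only 100 counts as high --
and records the hit rate H(c) = P(high confidence | correct) against the
false-alarm rate F(c) = P(high confidence | incorrect).  The area under
the resulting Type-2 ROC curve (trapezoidal, anchored at (0,0) and (1,1))
is AUROC2: 0.5 means confidence carries no information about accuracy,
1.0 means perfect separation.

The trapezoidal area is mathematically identical to the pairwise
probability P(conf_correct > conf_incorrect) + 0.5 P(tie); the module
ships that enumeration (:func:`auroc2_pairwise_oracle`) as an independent
cross-check.

Individual-differences analyses: bivariate (AQ, AUROC2) outlier screening
by Mahalanobis distance against a chi-square(2) cutoff, Spearman rank
correlation with a t-approximation p-value, and a post hoc median-split
comparison of AUROC2 between low- and high-AQ groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trialdata import CONFIDENCE_GRID, filter_present_trials

__all__ = [
    "Type2ROC",
    "MetacogResult",
    "type2_roc",
    "auroc2",
    "auroc2_pairwise_oracle",
    "subject_auroc2",
    "mahalanobis_outliers",
    "spearman_with_t",
    "SpearmanResult",
    "median_split_compare",
    "MedianSplitResult",
    "analyze_metacognition",
]

_GRID = np.asarray(CONFIDENCE_GRID)


@dataclass
class Type2ROC:
    """Criterion-sweep hit/false-alarm curve for one subject.

    ``hit`` and ``fa`` are ordered by rising criterion (both therefore
    non-increasing); ``points()`` returns the curve sorted for integration
    with the (0,0)/(1,1) anchors attached.  The curve is undefined when the
    subject has no correct or no incorrect trials.
    """

    criteria: np.ndarray
    hit: np.ndarray
    fa: np.ndarray
    n_correct: int
    n_incorrect: int

    @property
    def defined(self) -> bool:
        return self.n_correct >= 1 and self.n_incorrect >= 1

    def points(self) -> tuple[np.ndarray, np.ndarray]:
        f = np.r_[1.0, self.fa, 0.0][::-1]
        h = np.r_[1.0, self.hit, 0.0][::-1]
        order = np.lexsort((h, f))
        return f[order], h[order]


@dataclass
class MetacogResult:
    subject_id: str
    auroc2: float          # NaN when undefined
    n_correct: int
    n_incorrect: int

    @property
    def defined(self) -> bool:
        return self.n_correct >= 1 and self.n_incorrect >= 1


def type2_roc(confidences, correctness) -> Type2ROC:
    """Build the Type-2 ROC by sweeping the confidence criterion.

    For each grid level c in {10, ..., 100}, "high confidence" means a
    rating >= c; the first criterion classes only 0 as low, the last only
    100 as high.  Confidences must lie on the 11-point grid.  A subject
    with no correct or no incorrect trials yields an undefined (but
    returned, not raised) curve.
    """
    conf = np.asarray(confidences)
    corr = np.asarray(correctness)
    if conf.shape != corr.shape:
        raise ValueError("confidences and correctness differ in length")
    if not np.isin(conf, _GRID).all():
        raise ValueError("confidences must lie on the grid 0,10,...,100")
    if not np.isin(corr, (0, 1)).all():
        raise ValueError("correctness must be binary 0/1")
    corr = corr.astype(bool)
    n1, n0 = int(corr.sum()), int((~corr).sum())
    criteria = _GRID[1:]  # 10 .. 100
    if n1 == 0 or n0 == 0:
        nanv = np.full(len(criteria), np.nan)
        return Type2ROC(criteria.copy(), nanv, nanv.copy(), n1, n0)
    hit = np.array([(conf[corr] >= c).mean() for c in criteria])
    fa = np.array([(conf[~corr] >= c).mean() for c in criteria])
    return Type2ROC(criteria.copy(), hit, fa, n1, n0)


def auroc2(roc: Type2ROC) -> float:
    """Trapezoidal area under the anchored, F-sorted Type-2 ROC curve.

    Returns NaN for an undefined curve (propagating the no-pairs signal).
    """
    if not roc.defined:
        return float("nan")
    f, h = roc.points()
    return float(np.trapezoid(h, f))


def auroc2_pairwise_oracle(confidences, correctness) -> float:
    """Pairwise-comparison AUROC2: mean over all (correct, incorrect)
    trial pairs of 1[conf_c > conf_i] + 0.5 * 1[tie].

    Deliberately brute-force; serves as the independent oracle for the
    criterion-sweep construction.  NaN when there are no pairs.
    """
    conf = np.asarray(confidences, dtype=float)
    corr = np.asarray(correctness).astype(bool)
    c1, c0 = conf[corr], conf[~corr]
    if len(c1) == 0 or len(c0) == 0:
        return float("nan")
    diff = c1[:, None] - c0[None, :]
    wins = (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(wins / (len(c1) * len(c0)))


def subject_auroc2(trials: pd.DataFrame,
                   implicit_present_only: bool = True) -> pd.DataFrame:
    """Per-subject AUROC2 over a single task's trials.

    Implicit-task input is restricted to object-present trials by default,
    mirroring the accuracy analyses.  Returns a DataFrame with columns
    subject_id, auroc2, n_correct, n_incorrect, defined.
    """
    tasks = trials["task"].unique()
    if len(tasks) > 1:
        raise ValueError("subject_auroc2 expects a single task's trials")
    if implicit_present_only and tasks[0] == "implicit":
        trials = filter_present_trials(trials)
    rows = []
    for sid, s in trials.groupby("subject_id", sort=True):
        roc = type2_roc(s["confidence"].to_numpy(), s["correct"].to_numpy())
        rows.append({"subject_id": sid, "auroc2": auroc2(roc),
                     "n_correct": roc.n_correct,
                     "n_incorrect": roc.n_incorrect,
                     "defined": roc.defined})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# outliers & correlation

def mahalanobis_outliers(points, alpha: float = 0.025):
    """Flag multivariate outliers by squared Mahalanobis distance.

    ``points`` is (n, k); distance is measured from the sample mean under
    the sample covariance and compared with the chi-square(k) quantile at
    1 - alpha.  Returns ``(include_mask, squared_distances)``.  Requires
    n >= 3 and a nonsingular covariance.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be 2-dimensional (n, k)")
    n, k = pts.shape
    if n < 3:
        raise ValueError("Mahalanobis screening needs >= 3 points")
    if np.isnan(pts).any():
        raise ValueError("points contain NaN")
    cov = np.cov(pts, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    try:
        cinv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular sample covariance: {e}") from e
    centered = pts - pts.mean(axis=0)
    d2 = np.einsum("ij,jk,ik->i", centered, cinv, centered)
    cutoff = stats.chi2.ppf(1.0 - alpha, df=k)
    return d2 <= cutoff, d2


@dataclass
class SpearmanResult:
    rho: float
    t: float
    df: int
    p: float
    n: int


def spearman_with_t(x, y) -> SpearmanResult:
    """Spearman rank correlation with t-approximation inference.

    rho is Pearson's correlation on average (tie-averaged) ranks;
    t = rho * sqrt((n-2)/(1-rho^2)) with df = n - 2 and a two-sided p.
    |rho| = 1 is reported with infinite t and p = 0; a constant input
    yields NaN rho (the undefined-correlation signal).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y differ in length")
    n = len(x)
    if n < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(float("nan"), float("nan"), n - 2,
                              float("nan"), n)
    rho = float(stats.spearmanr(x, y).statistic)
    if abs(rho) >= 1.0:
        return SpearmanResult(rho, float(np.sign(rho)) * np.inf, n - 2, 0.0, n)
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return SpearmanResult(rho, float(t), n - 2, p, n)


@dataclass
class MedianSplitResult:
    median: float
    mean_low: float
    mean_high: float
    n_low: int
    n_high: int
    t: float
    df: float
    p_two_sided: float
    p_one_sided: float


def median_split_compare(values, aq_scores,
                         equal_var: bool = True) -> MedianSplitResult:
    """Two-sample t test of a measure between low- and high-AQ groups.

    The split is at the sample AQ median with ties assigned to the low
    group.  Both the two-sided p and the one-sided p for the directional
    hypothesis mean(high) < mean(low) are reported.  Raises when either
    group has fewer than 2 members.
    """
    v = np.asarray(values, dtype=float)
    aq = np.asarray(aq_scores, dtype=float)
    if v.shape != aq.shape:
        raise ValueError("values and aq_scores differ in length")
    med = float(np.median(aq))
    low, high = v[aq <= med], v[aq > med]
    if len(low) < 2 or len(high) < 2:
        raise ValueError(
            f"median split leaves a degenerate group (n_low={len(low)}, "
            f"n_high={len(high)})")
    res = stats.ttest_ind(high, low, equal_var=equal_var)
    t = float(res.statistic)
    df = float(res.df)
    p2 = float(res.pvalue)
    p1 = p2 / 2 if t < 0 else 1 - p2 / 2  # H1: high < low
    return MedianSplitResult(med, float(low.mean()), float(high.mean()),
                             len(low), len(high), t, df, p2, float(p1))


def analyze_metacognition(
    trials: pd.DataFrame,
    subjects: pd.DataFrame,
    task: str,
    mahalanobis_alpha: float = 0.025,
) -> dict:
    """Full per-task metacognition analysis.

    Computes per-subject AUROC2, drops subjects with an undefined score
    (all-correct or all-incorrect; the dropped count is reported), screens
    bivariate (AQ, AUROC2) outliers by Mahalanobis distance, and reports
    the Spearman correlation with and without outliers plus the AQ
    median-split comparison (run on all defined subjects).
    """
    per = subject_auroc2(trials[trials["task"] == task])
    merged = per.merge(subjects[["subject_id", "aq_score"]], on="subject_id")
    defined = merged[merged["defined"]].reset_index(drop=True)
    n_undefined = int(len(merged) - len(defined))

    pts = defined[["aq_score", "auroc2"]].to_numpy(dtype=float)
    include, d2 = mahalanobis_outliers(pts, alpha=mahalanobis_alpha)
    kept = defined[include]

    out = {
        "task": task,
        "per_subject": merged,
        "n_subjects": int(len(merged)),
        "n_undefined": n_undefined,
        "n_outliers": int((~include).sum()),
        "outlier_ids": list(defined.loc[~include, "subject_id"]),
        "mean_auroc2": float(defined["auroc2"].mean()),
        "spearman_excluding_outliers": spearman_with_t(
            kept["aq_score"], kept["auroc2"]),
        "spearman_all": spearman_with_t(
            defined["aq_score"], defined["auroc2"]),
        "median_split": median_split_compare(
            defined["auroc2"], defined["aq_score"]),
    }
    return out
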